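"""Stratified signal screens and the sex-difference volcano statistic."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contingency import build_tables
from .faers_io import ReportSet
from .signals import AlgorithmOptions, compute_signals

logger = logging.getLogger(__name__)

STRATUM_VARIABLES = ("sex", "age_group", "reporter")


def stratified_signals(
    report_set: ReportSet,
    variable: str,
    level: str = "pt",
    opts: AlgorithmOptions | None = None,
) -> dict[str, pd.DataFrame]:
    """Signal tables recomputed entirely within each stratum level.

    Reports with a missing stratum value are excluded from every level (and
    counted); levels with zero target-drug reports are skipped with a log
    entry. Cells a, b, c, d are all restricted to reports in the level.
    """
    if variable not in STRATUM_VARIABLES:
        raise ValueError(f"stratum variable must be one of {STRATUM_VARIABLES}")
    values = report_set.reports[variable]
    out: dict[str, pd.DataFrame] = {}
    n_missing = int((values == "missing").sum())
    if n_missing:
        logger.info("stratified_signals(%s): %d reports with missing value excluded",
                    variable, n_missing)
    for lvl in sorted(values.unique()):
        if lvl == "missing":
            continue
        mask = values == lvl
        if not bool((report_set.reports["is_target"] & mask).any()):
            logger.info("stratified_signals(%s): level %r has no target reports; skipped",
                        variable, lvl)
            continue
        tables = build_tables(report_set, level=level, stratum=mask)
        sig = compute_signals(tables, opts)
        sig.insert(0, "stratum", lvl)
        out[lvl] = sig
    return out


@dataclass(frozen=True)
class VolcanoPoint:
    """One PT's female-vs-male contrast among target-drug reports."""

    pt: str
    or_value: float
    log2_or: float
    p_value: float
    p_adjusted: float
    label: str  # 'female' | 'male' | 'none'


def sex_volcano(
    report_set: ReportSet,
    min_count: int = 3,
    alpha: float = 0.05,
    contrast: str = "within_exposed",
    opts: AlgorithmOptions | None = None,
) -> pd.DataFrame:
    """Per-PT sex-difference statistic among target-drug reports.

    ``within_exposed`` (default): for each PT, the 2x2 of (female, male) x
    (PT present, PT absent) among target-drug reports of known sex; the odds
    ratio (Haldane delta = 0.5 when any cell is zero), a two-sided Fisher
    exact p-value, log2(OR) as the volcano x-axis, and a Benjamini-Hochberg
    adjusted p alongside. Positive log2(OR) means female-dominant.

    ``ror_ratio``: the alternative contrast — the ratio of the two
    sex-stratified reporting odds ratios against the background, with a
    normal-theory p-value from the summed log-ROR variances.

    Eligibility: PTs with at least ``min_count`` target reports in one sex.
    Labels are assigned at unadjusted p < alpha by the sign of log2(OR).
    """
    if contrast not in ("within_exposed", "ror_ratio"):
        raise ValueError("contrast must be 'within_exposed' or 'ror_ratio'")
    delta = (opts or AlgorithmOptions()).delta

    reports = report_set.reports
    known = reports["sex"].isin(["female", "male"])
    target = reports["is_target"] & known
    sub = report_set.subset(target)
    if len(sub) == 0:
        return pd.DataFrame(columns=["pt", "n_f_with", "n_f_without", "n_m_with",
                                     "n_m_without", "OR", "log2_OR", "p", "p_adj", "label"])
    reps = sub.reports
    n_f = int((reps["sex"] == "female").sum())
    n_m = int((reps["sex"] == "male").sum())
    pairs = sub.reactions.merge(reps[["primaryid", "sex"]], on="primaryid")
    pairs = pairs.drop_duplicates(["primaryid", "pt"])
    counts = (pairs.groupby(["pt", "sex"]).size().unstack(fill_value=0)
              .reindex(columns=["female", "male"], fill_value=0))

    eligible = counts[(counts["female"] >= min_count) | (counts["male"] >= min_count)]
    skipped = len(counts) - len(eligible)
    if skipped:
        logger.info("sex_volcano: %d PTs below the %d-report floor omitted",
                    skipped, min_count)

    rows = []
    for pt, row in eligible.iterrows():
        fw, mw = int(row["female"]), int(row["male"])
        fo, mo = n_f - fw, n_m - mw
        p = float(stats.fisher_exact([[fw, fo], [mw, mo]], alternative="two-sided")[1])
        if contrast == "within_exposed":
            cells = np.array([fw, fo, mw, mo], dtype=float)
            if (cells == 0).any():
                cells = cells + delta
            or_val = (cells[0] * cells[3]) / (cells[1] * cells[2])
        else:
            or_val, p = _ror_ratio(report_set, pt, delta)
        rows.append({"pt": pt, "n_f_with": fw, "n_f_without": fo,
                     "n_m_with": mw, "n_m_without": mo,
                     "OR": or_val, "log2_OR": float(np.log2(or_val)), "p": p})
    out = pd.DataFrame(rows)
    if len(out) == 0:
        out["p_adj"] = []
        out["label"] = []
        return out
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    out["label"] = np.where(
        (out["p"] < alpha) & (out["log2_OR"] > 0), "female",
        np.where((out["p"] < alpha) & (out["log2_OR"] < 0), "male", "none"),
    )
    return out.sort_values("p").reset_index(drop=True)


def _ror_ratio(report_set: ReportSet, pt: str, delta: float) -> tuple[float, float]:
    """log-normal contrast of female vs male sex-stratified RORs."""
    reports = report_set.reports
    stats_by_sex = {}
    for sex in ("female", "male"):
        mask = reports["sex"] == sex
        tables = build_tables(report_set, level="pt", stratum=mask)
        if pt not in tables.index:
            return float("nan"), float("nan")
        cells = tables.loc[pt, ["a", "b", "c", "d"]].to_numpy(dtype=float)
        if (cells == 0).any():
            cells = cells + delta
        a, b, c, d = cells
        stats_by_sex[sex] = (np.log((a / c) / (b / d)),
                             1 / a + 1 / b + 1 / c + 1 / d)
    diff = stats_by_sex["female"][0] - stats_by_sex["male"][0]
    var = stats_by_sex["female"][1] + stats_by_sex["male"][1]
    z = diff / np.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return float(np.exp(diff)), p
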