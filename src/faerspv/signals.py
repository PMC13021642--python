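"""The four disproportionality estimators and their signal criteria.

For a 2x2 table (a, b, c, d) with N = a+b+c+d:

    ROR  = (a/c)/(b/d),           95% CI = exp(ln ROR +- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))
    PRR  = [a/(a+b)]/[c/(c+d)],   95% CI = exp(ln PRR +- 1.96 * sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)))
    IC   = log2(a*N/((a+c)(a+b))), IC025 = IC - 1.96 * sqrt(1/a + 1/b + 1/c + 1/d) / ln 2
    EBGM = a*N/((a+c)(a+b)),       EBGM05 = EBGM * exp(-1.64 * sqrt(1/a + 1/b + 1/c + 1/d))

Signal criteria: ROR and PRR flag when the CI lower bound exceeds 1 and
a >= 3; BCPNN flags when IC025 > 0 and a >= 3; MGPS flags when EBGM05 > 2 and
a > 0. EBGM here is the shrinkage-free relative reporting ratio (the reduction
of MGPS consistent with the closed-form one-sided bound above); the full
gamma-Poisson empirical-Bayes fit is a documented extension point.

Two formula modes exist. ``standard`` (default) is above. ``paper-literal``
reproduces a published variant verbatim: the IC and EBGM numerators drop the
``a`` factor (becoming log2(N/((a+c)(a+b))) and N/((a+c)(a+b))) and IC025 is
exp(ln IC - 1.96*sqrt(.)), defined only for IC > 0. The literal variant exists
so the discrepancy with the standard observed/expected form is inspectable;
every output row records the mode that produced it.

Zero cells: when any of b, c, d is zero, a Haldane-Anscombe continuity
correction (delta, default 0.5) is added to all four cells. a = 0 is never
rescued — those rows come back not-evaluable (NaN points, EBGM 0) with all
flags False, and are excluded by the a-floors anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .contingency import ContingencyTable

ALGORITHMS = ("ROR", "PRR", "BCPNN", "MGPS")

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class AlgorithmOptions:
    """Formula mode and numerical conventions shared by the four estimators."""

    mode: str = "standard"          # 'standard' | 'paper-literal'
    delta: float = 0.5              # continuity correction when b, c or d = 0
    z_two_sided: float = 1.96
    z_one_sided: float = 1.64

    def __post_init__(self):
        if self.mode not in ("standard", "paper-literal"):
            raise ValueError(f"unknown formula mode {self.mode!r}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


class IntervalResult(NamedTuple):
    point: float
    lower: float
    upper: float
    flag: bool


class LowerBoundResult(NamedTuple):
    point: float
    lower: float
    flag: bool


def _corrected_cells(a, b, c, d, delta):
    """Apply the continuity correction row-wise where any of b, c, d is 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    needs = (b == 0) | (c == 0) | (d == 0)
    return (np.where(needs, a + delta, a), np.where(needs, b + delta, b),
            np.where(needs, c + delta, c), np.where(needs, d + delta, d))


def compute_signals(tables: pd.DataFrame, opts: AlgorithmOptions | None = None) -> pd.DataFrame:
    """All four estimators, bounds, flags and the consensus count per event.

    ``tables`` is the frame produced by :func:`faerspv.contingency.build_tables`
    (columns a, b, c, d). Not-evaluable rows (a = 0, or paper-literal IC <= 0)
    carry NaN metrics and False flags — never silent drops.
    """
    opts = opts or AlgorithmOptions()
    a0 = tables["a"].to_numpy(dtype=float)
    b0 = tables["b"].to_numpy(dtype=float)
    c0 = tables["c"].to_numpy(dtype=float)
    d0 = tables["d"].to_numpy(dtype=float)
    a, b, c, d = _corrected_cells(a0, b0, c0, d0, opts.delta)
    n = a + b + c + d
    evaluable = a0 > 0

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

        ror = (a / c) / (b / d)
        ror_lo = np.exp(np.log(ror) - opts.z_two_sided * se)
        ror_hi = np.exp(np.log(ror) + opts.z_two_sided * se)

        prr = (a / (a + b)) / (c / (c + d))
        se_prr = np.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        prr_lo = np.exp(np.log(prr) - opts.z_two_sided * se_prr)
        prr_hi = np.exp(np.log(prr) + opts.z_two_sided * se_prr)

        rrr = a * n / ((a + c) * (a + b))   # observed / expected
        if opts.mode == "standard":
            ic = np.log2(rrr)
            ic025 = ic - opts.z_two_sided * se / LN2
            ebgm = rrr
        else:  # paper-literal: numerators as printed, without the 'a' factor
            lit = n / ((a + c) * (a + b))
            ic = np.log2(lit)
            ic025 = np.where(ic > 0, np.exp(np.log(ic) - opts.z_two_sided * se), np.nan)
            ebgm = lit
        ebgm05 = ebgm * np.exp(-opts.z_one_sided * se)

    def _mask(x, extra_ok=True):
        return np.where(evaluable & extra_ok, x, np.nan)

    # paper-literal IC025 wraps ln(IC): defined only for IC > 0 (the IC point
    # itself remains reportable)
    ic025_ok = evaluable if opts.mode == "standard" else (evaluable & (ic > 0))
    out = pd.DataFrame({
        "a": a0.astype(int), "b": b0.astype(int),
        "c": c0.astype(int), "d": d0.astype(int),
        "ROR": _mask(ror), "ROR_lo": _mask(ror_lo), "ROR_hi": _mask(ror_hi),
        "PRR": _mask(prr), "PRR_lo": _mask(prr_lo), "PRR_hi": _mask(prr_hi),
        "IC": _mask(ic), "IC025": _mask(ic025, ic025_ok),
        "EBGM": np.where(evaluable, ebgm, 0.0),
        "EBGM05": np.where(evaluable, ebgm05, np.nan),
    }, index=tables.index)

    out["flag_ROR"] = evaluable & (a0 >= 3) & (out["ROR_lo"].to_numpy() > 1)
    out["flag_PRR"] = evaluable & (a0 >= 3) & (out["PRR_lo"].to_numpy() > 1)
    out["flag_BCPNN"] = (evaluable & (a0 >= 3)
                         & (np.nan_to_num(out["IC025"].to_numpy(), nan=-np.inf) > 0))
    out["flag_MGPS"] = (evaluable & (a0 > 0)
                        & (np.nan_to_num(out["EBGM05"].to_numpy(), nan=-np.inf) > 2))
    out["consensus"] = (out[["flag_ROR", "flag_PRR", "flag_BCPNN", "flag_MGPS"]]
                        .sum(axis=1).astype(int))
    out["mode"] = opts.mode
    return out


# --- scalar wrappers -------------------------------------------------------


def _single(table: ContingencyTable, opts: AlgorithmOptions | None):
    df = pd.DataFrame([{"a": table.a, "b": table.b, "c": table.c, "d": table.d}])
    return compute_signals(df, opts).iloc[0]


def ror(table: ContingencyTable, opts: AlgorithmOptions | None = None) -> IntervalResult:
    r = _single(table, opts)
    return IntervalResult(r["ROR"], r["ROR_lo"], r["ROR_hi"], bool(r["flag_ROR"]))


def prr(table: ContingencyTable, opts: AlgorithmOptions | None = None) -> IntervalResult:
    r = _single(table, opts)
    return IntervalResult(r["PRR"], r["PRR_lo"], r["PRR_hi"], bool(r["flag_PRR"]))


def ic(table: ContingencyTable, opts: AlgorithmOptions | None = None) -> LowerBoundResult:
    r = _single(table, opts)
    return LowerBoundResult(r["IC"], r["IC025"], bool(r["flag_BCPNN"]))


def ebgm(table: ContingencyTable, opts: AlgorithmOptions | None = None) -> LowerBoundResult:
    r = _single(table, opts)
    return LowerBoundResult(r["EBGM"], r["EBGM05"], bool(r["flag_MGPS"]))


# --- consensus -------------------------------------------------------------


def consensus(signals: pd.DataFrame) -> pd.DataFrame:
    """Partition flagged events into the 15 non-empty algorithm combinations.

    Returns a frame with columns combination (e.g. 'ROR+PRR+BCPNN'), count,
    and percentage of events flagged by at least one algorithm. Cells with no
    events are included with count 0 so the partition is explicit.
    """
    flags = signals[[f"flag_{alg}" for alg in ALGORITHMS]].to_numpy(dtype=bool)
    any_flag = flags.any(axis=1)
    n_flagged = int(any_flag.sum())
    rows = []
    for k in range(1, 5):
        for combo in combinations(range(4), k):
            in_cell = np.ones(len(flags), dtype=bool)
            for i in range(4):
                in_cell &= flags[:, i] if i in combo else ~flags[:, i]
            cnt = int(in_cell.sum())
            rows.append({
                "combination": "+".join(ALGORITHMS[i] for i in combo),
                "n_algorithms": k,
                "count": cnt,
                "percentage": round(100.0 * cnt / n_flagged, 1) if n_flagged else 0.0,
            })
    return pd.DataFrame(rows)
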