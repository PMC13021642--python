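"""Synthetic FAERS-style report generator with known ground truth.

Emulates the structure of FAERS quarterly extracts — DEMO / DRUG / REAC /
OUTC / THER plus stub INDI / RPSR tables in the "$"-delimited dialect — for a
background drug universe and one target drug, so that every downstream stage
(deduplication, contingency construction, disproportionality screening,
subgroup and onset analysis) can be exercised against injected effects.

Effect injection
----------------
Each report mentions preferred term (PT) *j* independently with probability
``p_j = mean_pts_per_report * q_j`` where ``q_j`` is the baseline multinomial
event-profile probability. An injected effect with multiplier ``theta`` acts
on the *pair-level reporting odds*: writing ``m`` for the expected number of
PT mentions per report, the background reporting odds of PT *j* are
``w_j = p_j / (m - p_j)`` and target reports use inclusion probabilities
solved (fixed point over the perturbed margin ``m'``) so that their reporting
odds are exactly ``theta * w_j``. The reporting odds ratio of a 2x2 table
built on report-event pairs therefore estimates ``theta`` directly, which is
what makes the ledger a usable oracle for the screening statistics.
Sex-specific multipliers rescale ``theta`` within the stated sex stratum, on
the same odds scale.

Non-injected PTs keep their background inclusion probability; when effects
are injected their pair-level odds ratio falls slightly below 1 because the
target margin grows — the familiar competition effect of strong signals in
spontaneous-report data, present here by construction and recorded as such.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from ._utils import dates_to_strings

TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

TARGET_DRUG_SYNONYMS = ("FRUQUINTINIB", "FRUZAQLA", "ELUNATE")

BACKGROUND_DRUGS = (
    "OXALIPLATIN", "IRINOTECAN", "FLUOROURACIL", "CAPECITABINE",
    "REGORAFENIB", "BEVACIZUMAB", "PEMBROLIZUMAB", "METFORMIN",
    "ATORVASTATIN", "LISINOPRIL", "OMEPRAZOLE", "ADALIMUMAB",
)


# ---------------------------------------------------------------------------
# configuration


class InjectedEffect(BaseModel):
    """A per-PT reporting-odds multiplier, optionally sex-specific."""

    pt: str
    theta: float = Field(ge=0.0)
    sex_multipliers: Optional[dict[str, float]] = None  # keys "F"/"M"

    @field_validator("sex_multipliers")
    @classmethod
    def _check_mults(cls, v):
        if v is not None:
            bad = set(v) - {"F", "M"}
            if bad:
                raise ValueError(f"sex_multipliers keys must be F/M, got {bad}")
            if any(m < 0 for m in v.values()):
                raise ValueError("sex multipliers must be >= 0")
        return v

    def effective_theta(self, sex: str) -> float:
        if self.sex_multipliers and sex in self.sex_multipliers:
            return self.theta * self.sex_multipliers[sex]
        return self.theta


class OnsetModel(BaseModel):
    """Distribution of days from therapy start to event."""

    distribution: Literal["exponential", "lognormal"] = "exponential"
    mean_days: float = Field(default=27.7, gt=0)
    sigma: float = Field(default=1.0, gt=0)  # lognormal shape

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.distribution == "exponential":
            days = rng.exponential(self.mean_days, n)
        else:
            mu = np.log(self.mean_days) - 0.5 * self.sigma**2
            days = rng.lognormal(mu, self.sigma, n)
        return np.floor(days).astype(np.int64)


class StrataWeights(BaseModel):
    """Categorical distributions for report-level strata (known values only;
    missingness is applied separately)."""

    sex: dict[str, float] = Field(
        default_factory=lambda: {"F": 0.442, "M": 0.558}
    )
    age_group: dict[str, float] = Field(
        default_factory=lambda: {
            "<18": 0.112, "18-64.9": 0.485, "65-85": 0.389, ">85": 0.014
        }
    )
    weight_group: dict[str, float] = Field(
        default_factory=lambda: {"<50": 0.146, "50-100": 0.773, ">100": 0.081}
    )
    reporter: dict[str, float] = Field(
        default_factory=lambda: {"CN": 0.452, "MD": 0.293, "OT": 0.169, "PH": 0.086}
    )
    country: dict[str, float] = Field(
        default_factory=lambda: {
            "US": 0.629, "CN": 0.146, "JP": 0.081, "GB": 0.030,
            "FR": 0.025, "IT": 0.021, "DE": 0.068,
        }
    )
    outcome: dict[str, float] = Field(
        default_factory=lambda: {
            "DE": 0.339, "HO": 0.248, "LT": 0.013, "DS": 0.006, "OT": 0.394
        }
    )

    @field_validator("sex", "age_group", "weight_group", "reporter", "country", "outcome")
    @classmethod
    def _normalized(cls, v: dict[str, float]) -> dict[str, float]:
        total = sum(v.values())
        if total <= 0 or any(w < 0 for w in v.values()):
            raise ValueError("stratum weights must be non-negative and sum > 0")
        return {k: w / total for k, w in v.items()}


def _default_missingness() -> dict[str, float]:
    # Calibrated to the missing-data pattern typical of spontaneous reports:
    # weight is almost always absent, age absent for about half of reports.
    return {
        "sex": 0.07,
        "age": 0.496,
        "weight": 0.811,
        "reporter": 0.248,
        "event_dt": 0.50,
        "start_dt": 0.50,
    }


class GeneratorConfig(BaseModel):
    """Full specification of one synthetic reporting universe."""

    n_background_reports: int = Field(ge=1)
    n_target_reports: int = Field(ge=0)
    event_vocabulary: list[tuple[str, str, float]]  # (PT, SOC, baseline prob)
    injected_effects: list[InjectedEffect] = Field(default_factory=list)
    duplicate_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    missingness: dict[str, float] = Field(default_factory=_default_missingness)
    onset_model: OnsetModel = Field(default_factory=OnsetModel)
    strata_weights: StrataWeights = Field(default_factory=StrataWeights)
    mean_pts_per_report: float = Field(default=2.0, gt=0)
    partial_date_fraction: float = Field(default=0.05, ge=0.0, le=1.0)
    combination_fraction: float = Field(default=0.30, ge=0.0, le=1.0)
    window_start: str = "20231001"
    window_end: str = "20250331"
    target_drug_names: tuple[str, ...] = TARGET_DRUG_SYNONYMS
    background_drugs: tuple[str, ...] = BACKGROUND_DRUGS
    seed: int = 0

    @field_validator("event_vocabulary")
    @classmethod
    def _check_vocab(cls, v):
        if not v:
            raise ValueError("event_vocabulary must be non-empty")
        total = sum(q for _, _, q in v)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"event_vocabulary baseline probabilities must sum to 1 (got {total!r})"
            )
        if any(q < 0 for _, _, q in v):
            raise ValueError("baseline probabilities must be >= 0")
        socs: dict[str, str] = {}
        for pt, soc, _ in v:
            if pt in socs and socs[pt] != soc:
                raise ValueError(f"PT {pt!r} mapped to conflicting SOCs")
            socs[pt] = soc
        if len(socs) != len(v):
            raise ValueError("duplicate PT rows in event_vocabulary")
        return v

    @field_validator("missingness")
    @classmethod
    def _check_missingness(cls, v):
        for k, f in v.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"missingness[{k!r}] must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_cross(self):
        pts = {pt for pt, _, _ in self.event_vocabulary}
        for eff in self.injected_effects:
            if eff.pt not in pts:
                raise ValueError(
                    f"injected_effects: PT {eff.pt!r} not in event_vocabulary"
                )
        probs = np.array([q for _, _, q in self.event_vocabulary])
        if (self.mean_pts_per_report * probs).max() >= 0.95:
            raise ValueError(
                "mean_pts_per_report * baseline probability must stay below 0.95"
            )
        return self


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruthLedger:
    """Bookkeeping emitted alongside the tables: what was injected, which
    reports are duplicate versions of one case, what was masked."""

    theta_by_pt: dict[str, dict[str, float]]
    duplicate_groups: list[dict]  # {"caseid", "primaryids", "survivor"}
    masked_counts: dict[str, int]
    onset_model: dict
    n_cases: int
    n_reports: int
    target_inclusion_probs: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def intended_survivors(self) -> dict[str, str]:
        return {g["caseid"]: g["survivor"] for g in self.duplicate_groups}

    def to_jsonl(self) -> str:
        lines = [
            json.dumps({"record": "meta", "n_cases": self.n_cases,
                        "n_reports": self.n_reports}),
            json.dumps({"record": "onset", **self.onset_model}),
        ]
        for pt, th in sorted(self.theta_by_pt.items()):
            lines.append(json.dumps({"record": "theta", "pt": pt, **th}))
        for fieldname, cnt in sorted(self.masked_counts.items()):
            lines.append(json.dumps(
                {"record": "masked", "field": fieldname, "count": cnt}))
        for g in self.duplicate_groups:
            lines.append(json.dumps({"record": "duplicate_group", **g}))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "GroundTruthLedger":
        theta, groups, masked, onset = {}, [], {}, {}
        n_cases = n_reports = 0
        for line in text.splitlines():
            if not line.strip():
                continue
            rec = json.loads(line)
            kind = rec.pop("record")
            if kind == "meta":
                n_cases, n_reports = rec["n_cases"], rec["n_reports"]
            elif kind == "onset":
                onset = rec
            elif kind == "theta":
                theta[rec.pop("pt")] = rec
            elif kind == "masked":
                masked[rec["field"]] = rec["count"]
            elif kind == "duplicate_group":
                groups.append(rec)
        return cls(theta, groups, masked, onset, n_cases, n_reports)


@dataclass
class SyntheticDataset:
    tables: dict[str, pd.DataFrame]
    ledger: GroundTruthLedger
    pt_soc_map: pd.DataFrame


# ---------------------------------------------------------------------------
# inclusion-probability solver


def solve_target_probs(
    p: np.ndarray, theta: np.ndarray, max_iter: int = 500, tol: float = 1e-13
) -> np.ndarray:
    """Target-report PT inclusion probabilities achieving pair-odds ratio theta.

    Given background inclusion probabilities ``p`` (margin ``m = p.sum()``),
    find ``p'`` such that injected PTs (theta != 1) satisfy
    ``p'_j / (m' - p'_j) = theta_j * p_j / (m - p_j)`` where
    ``m' = m + sum(p' - p)``, while non-injected PTs keep ``p'_k = p_k``.
    Solved by fixed-point iteration on the perturbed margin ``m'``.

    Non-injected PTs cannot also keep a pair-odds ratio of exactly 1: pair
    shares sum to one on both arms, so raising some events' odds necessarily
    lowers the others' slightly — the competition effect seen in real
    spontaneous-report databases. Only the injected PTs' ratios are pinned.
    """
    m = float(p.sum())
    inj = theta != 1.0
    if not inj.any():
        return p.copy()
    w = theta[inj] * p[inj] / (m - p[inj])  # target pair odds of injected PTs
    base = m - float(p[inj].sum())          # margin mass of non-injected PTs
    s_inj = float((w / (1.0 + w)).sum())
    if s_inj >= 0.95:
        raise ValueError(
            "injected effects are jointly too strong for their baseline "
            "probabilities: the target pair margin diverges "
            f"(sum of injected pair shares {s_inj:.3f} >= 0.95); "
            "reduce theta or the baseline probabilities"
        )
    m_prime = m
    p_inj = p[inj].copy()
    for _ in range(max_iter):
        p_new = w * m_prime / (1.0 + w)
        m_new = base + float(p_new.sum())
        converged = abs(m_new - m_prime) < tol
        m_prime, p_inj = m_new, p_new
        if converged:
            break
    p_prime = p.copy()
    p_prime[inj] = p_inj
    if (p_prime >= 1.0).any():
        raise ValueError(
            "injected effects drive a PT inclusion probability to >= 1; "
            "reduce theta or the baseline probability"
        )
    return p_prime


# ---------------------------------------------------------------------------
# generation


def _draw_cat(rng: np.random.Generator, weights: dict[str, float], n: int) -> np.ndarray:
    keys = np.array(list(weights.keys()), dtype=object)
    probs = np.array(list(weights.values()), dtype=float)
    return keys[rng.choice(len(keys), size=n, p=probs)]


_AGE_BOUNDS = {"<18": (2.0, 17.9), "18-64.9": (18.0, 64.9),
               "65-85": (65.0, 85.0), ">85": (85.1, 97.0)}
_WT_BOUNDS = {"<50": (32.0, 49.9), "50-100": (50.0, 100.0), ">100": (100.1, 160.0)}


def generate_dataset(config: GeneratorConfig, seed: int | None = None) -> SyntheticDataset:
    """Generate one synthetic reporting universe.

    Returns the seven quarterly tables (as string-typed DataFrames in the
    FAERS dialect), the ground-truth ledger, and the PT->SOC map. Identical
    (config, seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_t, n_b = config.n_target_reports, config.n_background_reports
    n = n_t + n_b
    is_target = np.zeros(n, dtype=bool)
    is_target[:n_t] = True

    sw = config.strata_weights
    sex = _draw_cat(rng, sw.sex, n)
    age_grp = _draw_cat(rng, sw.age_group, n)
    lo = np.array([_AGE_BOUNDS[g][0] for g in age_grp])
    hi = np.array([_AGE_BOUNDS[g][1] for g in age_grp])
    age_years = lo + rng.random(n) * (hi - lo)
    wt_grp = _draw_cat(rng, sw.weight_group, n)
    wlo = np.array([_WT_BOUNDS[g][0] for g in wt_grp])
    whi = np.array([_WT_BOUNDS[g][1] for g in wt_grp])
    weight_kg = wlo + rng.random(n) * (whi - wlo)
    reporter = _draw_cat(rng, sw.reporter, n)
    country = _draw_cat(rng, sw.country, n)
    outcome = _draw_cat(rng, sw.outcome, n)

    # age units: mostly years, some decades/months to exercise normalization
    age_unit = _draw_cat(rng, {"YR": 0.90, "DEC": 0.05, "MON": 0.05}, n)
    age_value = np.where(
        age_unit == "YR", np.round(age_years, 0),
        np.where(age_unit == "DEC", np.round(age_years / 10.0, 1),
                 np.round(age_years * 12.0, 0)),
    )
    wt_unit = _draw_cat(rng, {"KG": 0.9, "LBS": 0.1}, n)
    wt_value = np.where(wt_unit == "KG", np.round(weight_kg, 1),
                        np.round(weight_kg / 0.45359237, 1))

    # --- reactions: independent Bernoulli per PT, odds-injected for target
    pts = [pt for pt, _, _ in config.event_vocabulary]
    q = np.array([p for _, _, p in config.event_vocabulary], dtype=float)
    p_bg = config.mean_pts_per_report * q
    effects = {e.pt: e for e in config.injected_effects}
    theta_by_sex = {}
    p_target_by_sex = {}
    for s in ("F", "M"):
        th = np.array([effects[pt].effective_theta(s) if pt in effects else 1.0
                       for pt in pts])
        theta_by_sex[s] = th
        p_target_by_sex[s] = solve_target_probs(p_bg, th)

    sex_is_f = sex == "F"
    pair_report_idx: list[np.ndarray] = []
    pair_pt_idx: list[np.ndarray] = []
    for j in range(len(pts)):
        thresh = np.full(n, p_bg[j])
        thresh[is_target & sex_is_f] = p_target_by_sex["F"][j]
        thresh[is_target & ~sex_is_f] = p_target_by_sex["M"][j]
        hit = np.flatnonzero(rng.random(n) < thresh)
        pair_report_idx.append(hit)
        pair_pt_idx.append(np.full(hit.size, j, dtype=np.int64))
    rep_idx = np.concatenate(pair_report_idx) if pair_report_idx else np.array([], int)
    pt_idx = np.concatenate(pair_pt_idx) if pair_pt_idx else np.array([], int)
    order = np.lexsort((pt_idx, rep_idx))
    rep_idx, pt_idx = rep_idx[order], pt_idx[order]

    # --- dates
    d0 = _dt.date(int(config.window_start[:4]), int(config.window_start[4:6]),
                  int(config.window_start[6:8])).toordinal()
    d1 = _dt.date(int(config.window_end[:4]), int(config.window_end[4:6]),
                  int(config.window_end[6:8])).toordinal()
    start_ord = rng.integers(d0, max(d0 + 1, d1 - 90), n)
    onset_days = config.onset_model.draw(rng, n)
    event_ord = start_ord + onset_days
    fda_ord = np.minimum(event_ord + rng.integers(0, 45, n), d1)

    # --- drug names
    tnames = np.array(config.target_drug_names, dtype=object)
    bnames = np.array(config.background_drugs, dtype=object)
    drugname = np.empty(n, dtype=object)
    prod_ai = np.empty(n, dtype=object)
    t_pick = rng.integers(0, len(tnames), n)
    b_pick = rng.integers(0, len(bnames), n)
    drugname[is_target] = tnames[t_pick[is_target]]
    prod_ai[is_target] = config.target_drug_names[0]
    drugname[~is_target] = bnames[b_pick[~is_target]]
    prod_ai[~is_target] = drugname[~is_target]
    # dose-suffix and name-blank variants on target rows
    u_variant = rng.random(n)
    suffix = is_target & (u_variant < 0.30)
    drugname[suffix] = drugname[suffix] + " 5MG CAPSULE"
    blank = is_target & (u_variant > 0.95)
    drugname[blank] = ""
    # combination partner for a fraction of target reports
    combo = is_target & (rng.random(n) < config.combination_fraction)
    combo_name = bnames[rng.integers(0, len(bnames), n)]

    # --- missingness (missing completely at random), recorded in the ledger
    miss = config.missingness
    masked_counts: dict[str, int] = {}

    def _mask(fieldname: str) -> np.ndarray:
        frac = miss.get(fieldname, 0.0)
        m = rng.random(n) < frac
        masked_counts[fieldname] = int(m.sum())
        return m

    sex_missing = _mask("sex")
    age_missing = _mask("age")
    wt_missing = _mask("weight")
    rep_missing = _mask("reporter")
    event_missing = _mask("event_dt")
    start_missing = _mask("start_dt")

    def _degrade(dates: pd.Series, u: np.ndarray) -> pd.Series:
        f = config.partial_date_fraction
        out = dates.copy()
        out[(u < f / 2)] = out[(u < f / 2)].str[:6]        # YYYYMM
        out[(u >= f / 2) & (u < f)] = out[(u >= f / 2) & (u < f)].str[:4]  # YYYY
        return out

    event_str = _degrade(pd.Series(dates_to_strings(event_ord)), rng.random(n))
    start_str = _degrade(pd.Series(dates_to_strings(start_ord)), rng.random(n))
    fda_str = dates_to_strings(fda_ord)
    event_str[event_missing] = ""
    start_str[start_missing] = ""

    # --- identifiers and duplicate versions; ids are int64 in memory (the
    # "$"-delimited files carry the same digits as text)
    caseid = 500_000_000 + np.arange(n, dtype=np.int64)
    primaryid = 100_000_000 + np.arange(n, dtype=np.int64)
    dup = rng.random(n) < config.duplicate_rate
    dup_idx = np.flatnonzero(dup)
    dup_primaryid = 200_000_000 + dup_idx.astype(np.int64)
    dup_fda_ord = fda_ord[dup_idx] - rng.integers(5, 90, dup_idx.size)
    dup_fda_str = dates_to_strings(dup_fda_ord)

    duplicate_groups = [
        {"caseid": int(caseid[i]), "primaryids": sorted([int(primaryid[i]), int(dpid)]),
         "survivor": int(primaryid[i])}
        for i, dpid in zip(dup_idx, dup_primaryid)
    ]

    def _with_dups(df: pd.DataFrame, base_index: np.ndarray,
                   overrides: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
        """Append duplicate-version rows (same content, new primaryid)."""
        sel = np.isin(base_index, dup_idx)
        if not sel.any():
            return df
        extra = df[sel].copy()
        pos = {i: k for k, i in enumerate(dup_idx)}
        which = np.array([pos[i] for i in base_index[sel]])
        extra["primaryid"] = dup_primaryid[which]
        if overrides:
            for col, vals in overrides.items():
                extra[col] = np.asarray(vals)[which]
        return pd.concat([df, extra], ignore_index=True)

    sex_out = sex.copy()
    sex_out[sex_missing] = ""
    age_out = np.round(age_value, 1).astype("U8").astype(object)
    age_out[age_missing] = ""
    age_unit_out = age_unit.copy()
    age_unit_out[age_missing] = ""
    wt_out = np.round(wt_value, 1).astype("U8").astype(object)
    wt_out[wt_missing] = ""
    wt_unit_out = wt_unit.copy()
    wt_unit_out[wt_missing] = ""
    reporter_out = reporter.copy()
    reporter_out[rep_missing] = ""

    demo = pd.DataFrame({
        "primaryid": primaryid,
        "caseid": caseid,
        "fda_dt": fda_str,
        "event_dt": event_str,
        "sex": sex_out,
        "age": age_out,
        "age_cod": age_unit_out,
        "wt": wt_out,
        "wt_cod": wt_unit_out,
        "occp_cod": reporter_out,
        "reporter_country": country,
    })
    demo = _with_dups(demo, np.arange(n), {"fda_dt": np.asarray(dup_fda_str, object)})

    drug_rows = [pd.DataFrame({
        "primaryid": primaryid,
        "drug_seq": "1",
        "role_cod": "PS",
        "drugname": drugname,
        "prod_ai": prod_ai,
    })]
    if combo.any():
        ci = np.flatnonzero(combo)
        drug_rows.append(pd.DataFrame({
            "primaryid": primaryid[ci],
            "drug_seq": "2",
            "role_cod": "SS",
            "drugname": combo_name[ci],
            "prod_ai": combo_name[ci],
        }))
    drug = pd.concat(drug_rows, ignore_index=True)
    drug_base_idx = np.concatenate([np.arange(n)] + ([np.flatnonzero(combo)] if combo.any() else []))
    drug = _with_dups(drug, drug_base_idx)

    pt_arr = np.array(pts, dtype=object)
    reac = pd.DataFrame({
        "primaryid": primaryid[rep_idx],
        "pt": pt_arr[pt_idx],
    })
    reac = _with_dups(reac, rep_idx)

    outc = pd.DataFrame({"primaryid": primaryid, "outc_cod": outcome})
    outc = _with_dups(outc, np.arange(n))

    ther = pd.DataFrame({
        "primaryid": primaryid,
        "dsg_drug_seq": "1",
        "start_dt": start_str,
    })
    ther = _with_dups(ther, np.arange(n))

    indi = pd.DataFrame({
        "primaryid": primaryid,
        "indi_drug_seq": "1",
        "indi_pt": "Product used for unknown indication",
    })
    rpsr = pd.DataFrame({"primaryid": primaryid, "rpsr_cod": "FGN"})

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
              "THER": ther, "INDI": indi, "RPSR": rpsr}
    for t in tables.values():
        t.sort_values("primaryid", kind="stable", inplace=True, ignore_index=True)

    theta_by_pt = {
        pt: {"base": effects[pt].theta if pt in effects else 1.0,
             "F": float(theta_by_sex["F"][j]),
             "M": float(theta_by_sex["M"][j])}
        for j, pt in enumerate(pts)
    }
    ledger = GroundTruthLedger(
        theta_by_pt=theta_by_pt,
        duplicate_groups=duplicate_groups,
        masked_counts=masked_counts,
        onset_model=config.onset_model.model_dump(),
        n_cases=n,
        n_reports=n + len(duplicate_groups),
        target_inclusion_probs={
            s: {pt: float(p_target_by_sex[s][j]) for j, pt in enumerate(pts)}
            for s in ("F", "M")
        },
    )
    return SyntheticDataset(tables=tables, ledger=ledger,
                            pt_soc_map=emit_pt_soc_map(config))


def emit_pt_soc_map(config: GeneratorConfig) -> pd.DataFrame:
    """Two-column PT -> SOC table covering the whole vocabulary."""
    return pd.DataFrame(
        [(pt, soc) for pt, soc, _ in config.event_vocabulary],
        columns=["pt", "soc"],
    )


# ---------------------------------------------------------------------------
# serialization


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the quarterly tables ("$"-delimited), the PT->SOC map (TSV) and
    the ground-truth ledger (JSON lines). Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in dataset.tables.items():
        p = outdir / f"{name}.txt"
        df.to_csv(p, sep="$", index=False, lineterminator="\n")
        paths[name] = p
    p = outdir / "pt_soc_map.tsv"
    dataset.pt_soc_map.to_csv(p, sep="\t", index=False, lineterminator="\n")
    paths["pt_soc_map"] = p
    p = outdir / "ledger.jsonl"
    p.write_text(dataset.ledger.to_jsonl())
    paths["ledger"] = p
    return paths


# ---------------------------------------------------------------------------
# stock configurations


_DEFAULT_VOCAB_WEIGHTED: list[tuple[str, str, float]] = [
    # (PT, SOC, relative weight) — normalized to probabilities below.
    ("Fatigue", "General disorders and administration site conditions", 60),
    ("Asthenia", "General disorders and administration site conditions", 35),
    ("Pyrexia", "General disorders and administration site conditions", 30),
    ("Oedema peripheral", "General disorders and administration site conditions", 18),
    ("Pain", "General disorders and administration site conditions", 40),
    ("Malaise", "General disorders and administration site conditions", 22),
    ("Death", "General disorders and administration site conditions", 28),
    ("Diarrhoea", "Gastrointestinal disorders", 55),
    ("Nausea", "Gastrointestinal disorders", 50),
    ("Vomiting", "Gastrointestinal disorders", 35),
    ("Abdominal pain", "Gastrointestinal disorders", 28),
    ("Constipation", "Gastrointestinal disorders", 20),
    ("Stomatitis", "Gastrointestinal disorders", 2),
    ("Rectal haemorrhage", "Gastrointestinal disorders", 7),
    ("Decreased appetite", "Metabolism and nutrition disorders", 30),
    ("Dehydration", "Metabolism and nutrition disorders", 12),
    ("Hypokalaemia", "Metabolism and nutrition disorders", 10),
    ("Weight decreased", "Investigations", 22),
    ("Blood pressure increased", "Investigations", 1),
    ("Platelet count decreased", "Investigations", 10),
    ("Neutrophil count decreased", "Investigations", 9),
    ("Alanine aminotransferase increased", "Investigations", 10),
    ("Aspartate aminotransferase increased", "Investigations", 10),
    ("Blood bilirubin increased", "Investigations", 7),
    ("Proteinuria", "Renal and urinary disorders", 0.9),
    ("Acute kidney injury", "Renal and urinary disorders", 12),
    ("Urinary tract infection", "Infections and infestations", 15),
    ("Pneumonia", "Infections and infestations", 18),
    ("Sepsis", "Infections and infestations", 10),
    ("Hypertension", "Vascular disorders", 20),
    ("Haemorrhage", "Vascular disorders", 10),
    ("Hypotension", "Vascular disorders", 12),
    ("Dysphonia", "Respiratory, thoracic and mediastinal disorders", 0.8),
    ("Dyspnoea", "Respiratory, thoracic and mediastinal disorders", 25),
    ("Cough", "Respiratory, thoracic and mediastinal disorders", 18),
    ("Epistaxis", "Respiratory, thoracic and mediastinal disorders", 8),
    ("Palmar-plantar erythrodysaesthesia syndrome", "Skin and subcutaneous tissue disorders", 0.8),
    ("Rash", "Skin and subcutaneous tissue disorders", 22),
    ("Alopecia", "Skin and subcutaneous tissue disorders", 12),
    ("Pruritus", "Skin and subcutaneous tissue disorders", 14),
    ("Myelosuppression", "Blood and lymphatic system disorders", 0.6),
    ("Anaemia", "Blood and lymphatic system disorders", 20),
    ("Thrombocytopenia", "Blood and lymphatic system disorders", 12),
    ("Neutropenia", "Blood and lymphatic system disorders", 12),
    ("Headache", "Nervous system disorders", 25),
    ("Dizziness", "Nervous system disorders", 20),
    ("Seizure", "Nervous system disorders", 6),
    ("Dysgeusia", "Nervous system disorders", 8),
    ("Disease progression", "Neoplasms benign, malignant and unspecified", 30),
    ("Tumour pain", "Neoplasms benign, malignant and unspecified", 8),
    ("Arthralgia", "Musculoskeletal and connective tissue disorders", 18),
    ("Back pain", "Musculoskeletal and connective tissue disorders", 14),
    ("Myalgia", "Musculoskeletal and connective tissue disorders", 10),
    ("Insomnia", "Psychiatric disorders", 14),
    ("Anxiety", "Psychiatric disorders", 12),
    ("Hypothyroidism", "Endocrine disorders", 7),
]


def default_vocabulary() -> list[tuple[str, str, float]]:
    """The stock ~56-PT vocabulary with normalized baseline probabilities."""
    total = sum(w for _, _, w in _DEFAULT_VOCAB_WEIGHTED)
    return [(pt, soc, w / total) for pt, soc, w in _DEFAULT_VOCAB_WEIGHTED]


def default_injected_effects() -> list[InjectedEffect]:
    """Stock injected effects: the target drug's characteristic signal profile
    (anti-angiogenic class toxicities, strongest on marrow suppression,
    dysphonia, hand-foot syndrome and proteinuria; hand-foot syndrome carries
    a female-dominant odds multiplier)."""
    return [
        InjectedEffect(pt="Myelosuppression", theta=29.31),
        InjectedEffect(pt="Dysphonia", theta=21.96),
        InjectedEffect(pt="Palmar-plantar erythrodysaesthesia syndrome",
                       theta=22.43, sex_multipliers={"F": 1.5, "M": 0.75}),
        InjectedEffect(pt="Proteinuria", theta=16.92),
        InjectedEffect(pt="Blood pressure increased", theta=11.86,
                       sex_multipliers={"F": 1.3, "M": 0.85}),
        InjectedEffect(pt="Stomatitis", theta=9.59),
        InjectedEffect(pt="Diarrhoea", theta=2.29),
    ]


def study_config(n_background_reports: int = 200_000,
                 n_target_reports: int = 2_000, seed: int = 0) -> GeneratorConfig:
    """The stock study universe: realistic strata, missingness, duplicates and
    a paper-profile set of injected effects."""
    return GeneratorConfig(
        n_background_reports=n_background_reports,
        n_target_reports=n_target_reports,
        event_vocabulary=default_vocabulary(),
        injected_effects=default_injected_effects(),
        seed=seed,
    )


def recovery_config(n_background_reports: int = 200_000,
                    n_target_reports: int = 2_000, seed: int = 0) -> GeneratorConfig:
    """Recovery benchmark: three designated PTs at baseline probability 0.005
    carrying odds multipliers 2, 8 and 16; duplicates and missingness off so
    each replicate isolates estimator behaviour."""
    vocab = default_vocabulary()
    designated = {"Diarrhoea": 2.0, "Stomatitis": 8.0, "Proteinuria": 16.0}
    rest = [(pt, soc, q) for pt, soc, q in vocab if pt not in designated]
    rest_total = sum(q for _, _, q in rest)
    scale = (1.0 - 0.005 * len(designated)) / rest_total
    vocab2 = [(pt, soc, q * scale) for pt, soc, q in rest]
    socs = {pt: soc for pt, soc, _ in vocab}
    vocab2 += [(pt, socs[pt], 0.005) for pt in designated]
    # exact renormalization against float drift
    tot = sum(q for _, _, q in vocab2)
    vocab2 = [(pt, soc, q / tot) for pt, soc, q in vocab2]
    return GeneratorConfig(
        n_background_reports=n_background_reports,
        n_target_reports=n_target_reports,
        event_vocabulary=vocab2,
        injected_effects=[InjectedEffect(pt=pt, theta=th)
                          for pt, th in designated.items()],
        duplicate_rate=0.0,
        missingness={},
        partial_date_fraction=0.0,
        seed=seed,
    )


def null_config(n_pts: int = 500, n_background_reports: int = 100_000,
                n_target_reports: int = 4_000, seed: int = 0) -> GeneratorConfig:
    """Null universe: >= 500 PTs, no injected effects (theta = 1 everywhere),
    mildly varying baseline frequencies."""
    w = 1.0 / np.sqrt(np.arange(1, n_pts + 1))
    q = w / w.sum()
    vocab = [(f"PT {i + 1:03d}", f"SOC {(i % 20) + 1:02d}", float(q[i]))
             for i in range(n_pts)]
    tot = sum(x for _, _, x in vocab)
    vocab = [(pt, soc, x / tot) for pt, soc, x in vocab]
    return GeneratorConfig(
        n_background_reports=n_background_reports,
        n_target_reports=n_target_reports,
        event_vocabulary=vocab,
        injected_effects=[],
        duplicate_rate=0.0,
        missingness={"sex": 0.07},
        partial_date_fraction=0.0,
        seed=seed,
    )
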