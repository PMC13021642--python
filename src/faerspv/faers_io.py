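"""Reading FAERS-style quarterly tables, case deduplication and
standardization of reports into an analyzable report set.

The quarterly dialect is "$"-delimited text with a header row, one file per
table (DEMO, DRUG, REAC, OUTC, THER, INDI, RPSR). Deduplication follows the
regulatory convention for spontaneous reports: submissions are grouped by
case identifier and only the version with the latest receipt date (FDA_DT)
is retained, ties broken by the larger report id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

from ._utils import (date_precision, date_sort_key, date_sort_keys,
                     map_uniques, parse_full_date)

logger = logging.getLogger(__name__)

FAERS_SEP = "$"

REQUIRED_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "fda_dt"],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
    "REAC": ["primaryid", "pt"],
    "OUTC": ["primaryid", "outc_cod"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
    "INDI": ["primaryid"],
    "RPSR": ["primaryid"],
}

CHILD_TABLES = ("DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")

OUTCOME_MAP = {"DE": "death", "LT": "life-threatening", "HO": "hospitalization",
               "DS": "disability"}

REPORTER_MAP = {"MD": "physician", "PH": "pharmacist", "CN": "consumer",
                "OT": "other health professional", "HP": "other health professional"}

# conversion factors to years
AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1.0 / 12.0,
                  "WK": 1.0 / 52.1775, "DY": 1.0 / 365.25}

WEIGHT_UNIT_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.45359237, "GMS": 0.001}

AGE_GROUPS = ("<18", "18-64.9", "65-85", ">85")
WEIGHT_GROUPS = ("<50", "50-100", ">100")


class FaersIOError(ValueError):
    """Structural problem in an input table (missing column, empty DEMO...)."""


# ---------------------------------------------------------------------------
# raw tables


@dataclass
class RawQuarter:
    """The seven tables of one (or several concatenated) quarters, typed as
    strings, with orphan child rows removed and counted."""

    tables: dict[str, pd.DataFrame]
    orphan_counts: dict[str, int] = dc_field(default_factory=dict)
    malformed_counts: dict[str, int] = dc_field(default_factory=dict)

    @property
    def demo(self) -> pd.DataFrame:
        return self.tables["DEMO"]

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]


def _validate_columns(name: str, df: pd.DataFrame, source: str) -> None:
    missing = [c for c in REQUIRED_COLUMNS.get(name, []) if c not in df.columns]
    if missing:
        raise FaersIOError(
            f"{source}: table {name} is missing mandatory column(s) {missing}"
        )


def read_table(path: str | Path, name: str, sep: str = FAERS_SEP) -> tuple[pd.DataFrame, int]:
    """Read one quarterly table; returns (frame, n_malformed_rows_skipped).

    All fields are kept as raw strings (dates included). Rows the parser
    cannot tokenize are skipped and counted, not fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FaersIOError(f"input file not found: {path}")
    bad = {"count": 0}

    def _on_bad(line: list[str]) -> None:
        bad["count"] += 1
        return None

    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     engine="python", on_bad_lines=_on_bad)
    _validate_columns(name, df, str(path))
    return df, bad["count"]


def from_frames(tables: dict[str, pd.DataFrame]) -> RawQuarter:
    """Build a RawQuarter from in-memory frames (e.g. generator output),
    applying the same validation and orphan accounting as file input.

    Columns are expected to be string-typed except the id columns, which may
    stay numeric (the file dialect carries the same digits as text)."""
    return _assemble({k: (v, 0) for k, v in tables.items()})


def read_quarter(paths: dict[str, str | Path], sep: str = FAERS_SEP) -> RawQuarter:
    """Read one quarter from files keyed by table name ('DEMO', 'DRUG', ...)."""
    loaded = {}
    for name in REQUIRED_COLUMNS:
        if name in paths:
            loaded[name] = read_table(paths[name], name, sep=sep)
    if "DEMO" not in loaded:
        raise FaersIOError("a quarter requires a DEMO table")
    return _assemble(loaded)


def _assemble(loaded: dict[str, tuple[pd.DataFrame, int]]) -> RawQuarter:
    demo = loaded["DEMO"][0]
    _validate_columns("DEMO", demo, "DEMO")
    if len(demo) == 0:
        raise FaersIOError("DEMO table is empty")
    known = set(demo["primaryid"])
    tables = {"DEMO": demo}
    orphans: dict[str, int] = {}
    malformed = {name: n_bad for name, (_, n_bad) in loaded.items()}
    for name, (df, _) in loaded.items():
        if name == "DEMO":
            continue
        _validate_columns(name, df, name)
        keep = df["primaryid"].isin(known)
        n_orphans = int((~keep).sum())
        if n_orphans:
            logger.warning("%s: %d orphan rows (primaryid absent from DEMO) dropped",
                           name, n_orphans)
        orphans[name] = n_orphans
        tables[name] = df[keep].reset_index(drop=True)
    for name in CHILD_TABLES:
        tables.setdefault(name, pd.DataFrame(columns=REQUIRED_COLUMNS.get(name, ["primaryid"])))
        orphans.setdefault(name, 0)
    return RawQuarter(tables=tables, orphan_counts=orphans, malformed_counts=malformed)


def concat_quarters(quarters: Iterable[RawQuarter]) -> RawQuarter:
    """Stack several quarters into one RawQuarter (union of all tables)."""
    quarters = list(quarters)
    if not quarters:
        raise FaersIOError("no quarters supplied")
    tables = {
        name: pd.concat([q.tables[name] for q in quarters if name in q.tables],
                        ignore_index=True)
        for name in quarters[0].tables
    }
    orphans: dict[str, int] = {}
    for q in quarters:
        for k, v in q.orphan_counts.items():
            orphans[k] = orphans.get(k, 0) + v
    return RawQuarter(tables=tables, orphan_counts=orphans)


# ---------------------------------------------------------------------------
# deduplication


def deduplicate(raw: RawQuarter) -> tuple[RawQuarter, pd.DataFrame]:
    """Collapse case versions: one surviving report per case key.

    The survivor is the row with the latest receipt date (partial dates are
    padded to their earliest day for ordering; unparseable dates sort first),
    ties broken by the larger report id. Idempotent. Returns the filtered
    RawQuarter and a discard log (primaryid, caseid, reason).
    """
    demo = raw.demo
    key_date = date_sort_keys(demo["fda_dt"])
    # numeric report ids when possible, else lexicographic fallback
    pid = pd.to_numeric(demo["primaryid"], errors="coerce")
    if pid.isna().any():
        order = np.lexsort((demo["primaryid"].to_numpy(), key_date))
    else:
        order = np.lexsort((pid.to_numpy(), key_date))
    ranked = demo.iloc[order]
    survivors = ranked.drop_duplicates("caseid", keep="last")
    discarded = demo.loc[~demo.index.isin(survivors.index), ["primaryid", "caseid"]].copy()
    discarded["reason"] = "duplicate_superseded"
    keep_ids = set(survivors["primaryid"])
    tables = {"DEMO": survivors.sort_index().reset_index(drop=True)}
    for name, df in raw.tables.items():
        if name == "DEMO":
            continue
        tables[name] = df[df["primaryid"].isin(keep_ids)].reset_index(drop=True)
    out = RawQuarter(tables=tables, orphan_counts=dict(raw.orphan_counts),
                     malformed_counts=dict(raw.malformed_counts))
    return out, discarded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# target-drug matching and PT -> SOC standardization


import re as _re


def _match_series(values: pd.Series, synonyms: list[str]) -> pd.Series:
    pattern = _re.compile("|".join(_re.escape(s.strip().upper()) for s in synonyms))
    hit = map_uniques(values,
                      lambda v: bool(pattern.search(str(v).upper())) if v is not None else False,
                      dtype=bool)
    return pd.Series(hit, index=values.index)


def match_target_drug(drug_rows: pd.DataFrame, synonyms: list[str]) -> pd.Series:
    """Boolean per DRUG row: does drugname or active ingredient contain any
    synonym (case-insensitive substring, trimmed)? All role codes are
    eligible, so combination regimens match."""
    if not synonyms:
        raise ValueError("synonym list must be non-empty")
    hit = _match_series(drug_rows["drugname"], synonyms)
    if "prod_ai" in drug_rows.columns:
        hit |= _match_series(drug_rows["prod_ai"], synonyms)
    return hit


def load_pt_soc_map(path: str | Path) -> pd.DataFrame:
    """Load the two-column tab-separated PT -> SOC map; conflicting duplicate
    rows are an error, consistent duplicates are collapsed."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise FaersIOError(f"PT->SOC map {path} needs two columns (pt, soc)")
    df = df.iloc[:, :2]
    df.columns = ["pt", "soc"]
    return validate_pt_soc_map(df)


def validate_pt_soc_map(mapping: pd.DataFrame) -> pd.DataFrame:
    per_pt = mapping.groupby("pt")["soc"].nunique()
    conflicts = per_pt[per_pt > 1]
    if len(conflicts):
        raise FaersIOError(
            f"conflicting SOC assignments for PT(s): {list(conflicts.index)[:5]}"
        )
    return mapping.drop_duplicates("pt").reset_index(drop=True)


def map_pt_to_soc(pt_set: Iterable[str], mapping: pd.DataFrame) -> tuple[dict[str, int], list[str]]:
    """SOC multiset (as counts) for a PT collection; unmapped PTs are returned
    separately, never silently dropped."""
    lut = dict(zip(mapping["pt"], mapping["soc"]))
    socs: dict[str, int] = {}
    unmapped: list[str] = []
    for pt in pt_set:
        soc = lut.get(pt)
        if soc is None:
            unmapped.append(pt)
        else:
            socs[soc] = socs.get(soc, 0) + 1
    return socs, unmapped


# ---------------------------------------------------------------------------
# standardized report set


@dataclass
class ReportRecord:
    """One deduplicated safety report in analysis-ready form."""

    primaryid: str
    caseid: str
    fda_dt: str
    event_dt: Optional[str]
    sex: str                      # 'female' / 'male' / 'missing'
    age_years: Optional[float]
    age_group: str                # '<18' / '18-64.9' / '65-85' / '>85' / 'missing'
    weight_kg: Optional[float]
    weight_group: str             # '<50' / '50-100' / '>100' / 'missing'
    country: str
    reporter: str
    outcomes: frozenset[str]
    pts: tuple[str, ...]
    socs: dict[str, int]
    unmapped_pts: tuple[str, ...]
    is_target: bool
    therapy_starts: tuple[str, ...]   # start dates of target-drug entries
    drugs: tuple[tuple[str, str, str], ...] = ()  # (name, role code, sequence)


def age_to_years(value: object, unit: object) -> float | None:
    try:
        x = float(str(value).strip())
    except (TypeError, ValueError):
        return None
    factor = AGE_UNIT_YEARS.get(str(unit).strip().upper() or "YR")
    if factor is None:
        factor = 1.0 if str(unit).strip() == "" else None
    if factor is None:
        return None
    return x * factor


def weight_to_kg(value: object, unit: object) -> float | None:
    try:
        x = float(str(value).strip())
    except (TypeError, ValueError):
        return None
    u = str(unit).strip().upper()
    factor = WEIGHT_UNIT_KG.get(u, 1.0 if u == "" else None)
    if factor is None:
        return None
    return x * factor


def age_group_of(age_years: float | None) -> str:
    """Bins [0,18), [18,65), [65,85], (85,inf): the printed labels '18-64.9'
    and '65-85' place 65 and 85 in the second and third bin respectively."""
    if age_years is None or age_years != age_years or age_years < 0:
        return "missing"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64.9"
    if age_years <= 85:
        return "65-85"
    return ">85"


def weight_group_of(kg: float | None) -> str:
    """Bins [0,50), [50,100], (100,inf); '50-100' inclusive of both bounds."""
    if kg is None or kg != kg or kg < 0:
        return "missing"
    if kg < 50:
        return "<50"
    if kg <= 100:
        return "50-100"
    return ">100"


@dataclass
class ReportSet:
    """Deduplicated, standardized reports: a report-level frame plus the
    report-event pair frame (the counting unit of the contingency stage)."""

    reports: pd.DataFrame      # one row per report
    reactions: pd.DataFrame    # columns: primaryid, pt, soc (soc may be '')
    drugs: pd.DataFrame = dc_field(default_factory=pd.DataFrame)  # retained DRUG rows
    exclusions: dict[str, int] = dc_field(default_factory=dict)
    unmapped_pt_count: int = 0

    def __len__(self) -> int:
        return len(self.reports)

    @property
    def n_target(self) -> int:
        return int(self.reports["is_target"].sum())

    def subset(self, mask: pd.Series) -> "ReportSet":
        reps = self.reports[mask]
        ids = set(reps["primaryid"])
        drugs = self.drugs
        if len(drugs):
            drugs = drugs[drugs["primaryid"].isin(ids)].reset_index(drop=True)
        return ReportSet(
            reports=reps.reset_index(drop=True),
            reactions=self.reactions[self.reactions["primaryid"].isin(ids)].reset_index(drop=True),
            drugs=drugs,
            exclusions=dict(self.exclusions),
        )

    def records(self) -> Iterator[ReportRecord]:
        drugs_by_id: dict = {}
        if len(self.drugs):
            for pid, name, role, seq in self.drugs[
                    ["primaryid", "drugname", "role_cod", "drug_seq"]].itertuples(index=False):
                drugs_by_id.setdefault(pid, []).append((name, role, seq))
        pts_by_id: dict[str, list[str]] = {}
        socs_by_id: dict[str, dict[str, int]] = {}
        unmapped_by_id: dict[str, list[str]] = {}
        for pid, pt, soc in self.reactions[["primaryid", "pt", "soc"]].itertuples(index=False):
            pts_by_id.setdefault(pid, []).append(pt)
            if soc:
                d = socs_by_id.setdefault(pid, {})
                d[soc] = d.get(soc, 0) + 1
            else:
                unmapped_by_id.setdefault(pid, []).append(pt)
        for row in self.reports.itertuples(index=False):
            pid = row.primaryid
            yield ReportRecord(
                primaryid=str(pid), caseid=str(row.caseid), fda_dt=row.fda_dt,
                event_dt=row.event_dt or None, sex=row.sex,
                age_years=None if row.age_years != row.age_years else float(row.age_years),
                age_group=row.age_group,
                weight_kg=None if row.weight_kg != row.weight_kg else float(row.weight_kg),
                weight_group=row.weight_group, country=row.country,
                reporter=row.reporter,
                outcomes=frozenset(row.outcomes.split("|")) - {""},
                pts=tuple(pts_by_id.get(pid, ())),
                socs=socs_by_id.get(pid, {}),
                unmapped_pts=tuple(unmapped_by_id.get(pid, ())),
                is_target=bool(row.is_target),
                therapy_starts=tuple((row.therapy_starts or "").split("|")) if row.therapy_starts else (),
                drugs=tuple(drugs_by_id.get(pid, ())),
            )


def _join_by_id(df: pd.DataFrame, col: str) -> pd.Series:
    """'|'-joined sorted values per primaryid; fast path for the dominant
    one-row-per-report case."""
    multi = df.duplicated("primaryid", keep=False)
    singles = df[~multi]
    out = pd.Series(singles[col].to_numpy(), index=singles["primaryid"].to_numpy())
    if multi.any():
        joined = (df[multi].sort_values([col], kind="stable")
                  .groupby("primaryid")[col].agg("|".join))
        out = pd.concat([out, joined])
    return out


def build_report_set(
    raw: RawQuarter,
    synonyms: list[str],
    pt_soc_map: pd.DataFrame | None = None,
    window: tuple[str, str] | None = None,
) -> ReportSet:
    """Standardize a deduplicated RawQuarter into a ReportSet.

    Reports with no PT are excluded (and counted); an optional receipt-date
    window [start, end] (YYYYMMDD, inclusive) filters reports.
    """
    demo = raw.demo.copy()
    exclusions: dict[str, int] = {}

    if window is not None:
        lo, hi = date_sort_key(window[0]), date_sort_key(window[1])
        keys = date_sort_keys(demo["fda_dt"])
        in_window = (keys >= lo) & (keys <= hi)
        exclusions["outside_window"] = int((~in_window).sum())
        demo = demo[in_window]

    drug = raw["DRUG"]
    hits = match_target_drug(drug, synonyms)
    target_ids = set(drug.loc[hits, "primaryid"])
    demo["is_target"] = demo["primaryid"].isin(target_ids)

    reac = raw["REAC"][["primaryid", "pt"]].copy()
    nonblank = map_uniques(reac["pt"],
                           lambda v: bool(str(v).strip()) if v is not None else False,
                           dtype=bool)
    reac = reac[nonblank]
    has_pt = demo["primaryid"].isin(set(reac["primaryid"]))
    exclusions["no_pt"] = int((~has_pt).sum())
    demo = demo[has_pt].reset_index(drop=True)
    reac = reac[reac["primaryid"].isin(set(demo["primaryid"]))].reset_index(drop=True)

    unmapped_count = 0
    if pt_soc_map is not None:
        mapping = validate_pt_soc_map(pt_soc_map)
        lut = dict(zip(mapping["pt"], mapping["soc"]))
        reac["soc"] = reac["pt"].map(lut).fillna("")
        unmapped_count = int((reac["soc"] == "").sum())
    else:
        reac["soc"] = ""

    # demographics normalization (vectorized; unit unknown -> value unusable)
    def _unit_factor(factors: dict[str, float]):
        def f(u):
            key = str(u).strip().upper() if u is not None else ""
            return factors.get(key, 1.0 if key == "" else np.nan)
        return f

    def _convert(values: pd.Series, units: pd.Series, factors: dict[str, float]) -> np.ndarray:
        x = pd.to_numeric(values, errors="coerce").to_numpy(dtype=float)
        f = map_uniques(units, _unit_factor(factors), dtype=float)
        return x * f

    blank = pd.Series("", index=demo.index)
    age_years = _convert(demo.get("age", blank), demo.get("age_cod", blank),
                         AGE_UNIT_YEARS)
    weight_kg = _convert(demo.get("wt", blank), demo.get("wt_cod", blank),
                         WEIGHT_UNIT_KG)

    _sex_lut = {"F": "female", "M": "male"}
    sex = map_uniques(demo.get("sex", blank),
                      lambda v: _sex_lut.get(str(v).strip().upper() if v is not None else "",
                                             "missing"))
    reporter = map_uniques(demo.get("occp_cod", blank),
                           lambda v: REPORTER_MAP.get(str(v).strip().upper() if v is not None else "",
                                                      "missing"))

    outc = raw["OUTC"]
    if len(outc):
        oc = outc[["primaryid", "outc_cod"]].copy()
        oc["outcome"] = map_uniques(
            oc["outc_cod"],
            lambda v: OUTCOME_MAP.get(str(v).strip().upper() if v is not None else "", "other"))
        oc = oc.drop_duplicates(["primaryid", "outcome"])
        outcomes = _join_by_id(oc, "outcome")
    else:
        outcomes = pd.Series(dtype=object)

    ther = raw["THER"]
    target_drug_rows = drug.loc[hits, ["primaryid", "drug_seq"]]
    if len(ther) and len(target_drug_rows):
        t = ther.merge(target_drug_rows,
                       left_on=["primaryid", "dsg_drug_seq"],
                       right_on=["primaryid", "drug_seq"], how="inner")
        t = t[map_uniques(t["start_dt"],
                          lambda v: bool(str(v).strip()) if v is not None else False,
                          dtype=bool)]
        starts = _join_by_id(t, "start_dt")
    else:
        starts = pd.Series(dtype=object)

    reports = pd.DataFrame({
        "primaryid": demo["primaryid"].to_numpy(),
        "caseid": demo["caseid"].to_numpy(),
        "fda_dt": demo["fda_dt"].to_numpy(),
        "event_dt": demo.get("event_dt", pd.Series("", index=demo.index)).to_numpy(),
        "sex": sex,
        "age_years": age_years,
        "weight_kg": weight_kg,
        "country": map_uniques(demo.get("reporter_country", blank),
                               lambda v: str(v) if v is not None and str(v).strip() else "missing"),
        "reporter": reporter,
        "is_target": demo["is_target"].to_numpy(),
    })
    ay = reports["age_years"].to_numpy()
    reports["age_group"] = np.select(
        [np.isnan(ay) | (ay < 0), ay < 18, ay < 65, ay <= 85],
        ["missing", "<18", "18-64.9", "65-85"], default=">85")
    wk = reports["weight_kg"].to_numpy()
    reports["weight_group"] = np.select(
        [np.isnan(wk) | (wk < 0), wk < 50, wk <= 100],
        ["missing", "<50", "50-100"], default=">100")
    reports["outcomes"] = reports["primaryid"].map(outcomes).fillna("other")
    reports["therapy_starts"] = reports["primaryid"].map(starts).fillna("")

    retained = set(reports["primaryid"])
    drug_cols = [c for c in ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai")
                 if c in drug.columns]
    drugs = drug.loc[drug["primaryid"].isin(retained), drug_cols].reset_index(drop=True)
    return ReportSet(reports=reports, reactions=reac, drugs=drugs,
                     exclusions=exclusions, unmapped_pt_count=unmapped_count)


def load_reports(
    paths_by_quarter: list[dict[str, str | Path]],
    synonyms: list[str],
    pt_soc_map_path: str | Path | None = None,
    window: tuple[str, str] | None = None,
) -> tuple[ReportSet, pd.DataFrame]:
    """Convenience end-to-end ingest: read quarters, deduplicate across them,
    standardize. Returns (report set, dedup discard log)."""
    raw = concat_quarters(read_quarter(p) for p in paths_by_quarter)
    deduped, discard_log = deduplicate(raw)
    mapping = load_pt_soc_map(pt_soc_map_path) if pt_soc_map_path else None
    return build_report_set(deduped, synonyms, mapping, window=window), discard_log


def onset_precision_ok(s: object) -> bool:
    return date_precision(s) == "day" and parse_full_date(s) is not None
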