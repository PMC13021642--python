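"""2x2 contingency tables for drug-event disproportionality screening.

The counting unit at PT level is the report-event pair: for event *e*,

    a = target-drug reports mentioning e
    b = target-drug report-event pairs on all other events
    c = non-target reports mentioning e
    d = non-target report-event pairs on all other events

so N = a+b+c+d equals the total number of report-event pairs in the corpus
(constant across events of one run) and exceeds the number of reports — a
consequence of pair counting that is deliberate and documented. At SOC level
the default counts a report once per SOC even when several of its PTs share
the SOC (switchable to per-pair counting).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .faers_io import ReportSet


class ContingencyError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts of one drug-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ContingencyError("contingency cells must be >= 0")
        if self.a + self.b + self.c + self.d <= 0:
            raise ContingencyError("contingency table must have N > 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def build_tables(
    report_set: ReportSet,
    level: str = "pt",
    stratum: pd.Series | None = None,
    soc_counting: str = "per_report",
    events: list[str] | None = None,
) -> pd.DataFrame:
    """Event-by-event 2x2 cell counts.

    Parameters
    ----------
    report_set : deduplicated, standardized reports.
    level : 'pt' or 'soc'.
    stratum : optional boolean mask aligned with ``report_set.reports``
        restricting the analysis to one stratum.
    soc_counting : 'per_report' (default: a report counts once per SOC) or
        'per_pair' (every PT mention counts) — only relevant at SOC level.
    events : optional explicit event universe; events never mentioned get
        a = c = 0 rows (they are screened out downstream by the a-floor).

    Returns a frame indexed by event with integer columns a, b, c, d.
    """
    if level not in ("pt", "soc"):
        raise ContingencyError(f"level must be 'pt' or 'soc', got {level!r}")
    reports = report_set.reports
    if stratum is not None:
        reports = reports[stratum.to_numpy()]
    if len(reports) == 0:
        raise ContingencyError("no reports to tabulate")

    pairs = report_set.reactions.merge(
        reports[["primaryid", "is_target"]], on="primaryid", how="inner"
    )
    if level == "soc":
        if (pairs["soc"] == "").all():
            raise ContingencyError("SOC-level tables require a PT->SOC mapping")
        pairs = pairs[pairs["soc"] != ""]
        pairs = pairs.rename(columns={"soc": "event"})[["primaryid", "event", "is_target"]]
        if soc_counting == "per_report":
            pairs = pairs.drop_duplicates(["primaryid", "event"])
        elif soc_counting != "per_pair":
            raise ContingencyError("soc_counting must be 'per_report' or 'per_pair'")
    else:
        pairs = pairs.rename(columns={"pt": "event"})[["primaryid", "event", "is_target"]]

    if len(pairs) == 0:
        raise ContingencyError("no report-event pairs to tabulate")

    counts = (pairs.groupby(["event", "is_target"]).size()
              .unstack(fill_value=0).reindex(columns=[False, True], fill_value=0))
    counts.columns = ["c", "a"]
    total_target = int(counts["a"].sum())
    total_background = int(counts["c"].sum())
    out = pd.DataFrame({
        "a": counts["a"].astype(int),
        "b": (total_target - counts["a"]).astype(int),
        "c": counts["c"].astype(int),
        "d": (total_background - counts["c"]).astype(int),
    })
    out.index.name = "event"
    if events is not None:
        out = out.reindex(sorted(set(events) | set(out.index)))
        out["a"] = out["a"].fillna(0).astype(int)
        out["c"] = out["c"].fillna(0).astype(int)
        out["b"] = out["b"].fillna(total_target).astype(int)
        out["d"] = out["d"].fillna(total_background).astype(int)
    return out.sort_index()


def table_for(tables: pd.DataFrame, event: str) -> ContingencyTable:
    """One event's cells as a ContingencyTable."""
    row = tables.loc[event]
    return ContingencyTable(int(row["a"]), int(row["b"]), int(row["c"]), int(row["d"]))
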