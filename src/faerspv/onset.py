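"""Time-to-onset: days from first target-drug therapy start to the event.

Only full-precision (YYYYMMDD) dates enter the computation; partial dates are
usable for deduplication ordering elsewhere but never for onset. Negative
differences (event before the first therapy start) are excluded and counted.
Default bins, in days: [0-30], [31-60], [61-90], [91-180], [181-360], >360 —
day 0 and day 30 both fall in the first bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import parse_full_date, percentage
from .faers_io import ReportSet

DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)


def bin_labels(edges: tuple[int, ...] = DEFAULT_BIN_EDGES) -> list[str]:
    labels = [f"0-{edges[0]}"]
    labels += [f"{lo + 1}-{hi}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{edges[-1]}")
    return labels


def compute_onsets(report_set: ReportSet, anchor: str = "event_dt") -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-report onset in days for target-drug reports.

    anchor : 'event_dt' (default) or 'fda_dt' — which date is treated as the
        event occurrence (the receipt-date alternative is available because
        spontaneous-report extracts do not always carry an event date).

    Returns (frame with primaryid/days, exclusion counts by reason).
    """
    if anchor not in ("event_dt", "fda_dt"):
        raise ValueError("anchor must be 'event_dt' or 'fda_dt'")
    reports = report_set.reports
    target = reports[reports["is_target"]]
    exclusions = {"no_event_date": 0, "partial_event_date": 0,
                  "no_therapy_start": 0, "partial_therapy_start": 0,
                  "negative_onset": 0}
    out_ids: list[str] = []
    out_days: list[int] = []
    for row in target.itertuples(index=False):
        ev_raw = getattr(row, anchor)
        if not str(ev_raw).strip():
            exclusions["no_event_date"] += 1
            continue
        ev = parse_full_date(ev_raw)
        if ev is None:
            exclusions["partial_event_date"] += 1
            continue
        starts_raw = [s for s in (row.therapy_starts or "").split("|") if s.strip()]
        if not starts_raw:
            exclusions["no_therapy_start"] += 1
            continue
        starts = [parse_full_date(s) for s in starts_raw]
        starts = [s for s in starts if s is not None]
        if not starts:
            exclusions["partial_therapy_start"] += 1
            continue
        days = (ev - min(starts)).days
        if days < 0:
            exclusions["negative_onset"] += 1
            continue
        out_ids.append(row.primaryid)
        out_days.append(days)
    return pd.DataFrame({"primaryid": out_ids, "days": out_days}), exclusions


@dataclass
class OnsetSummary:
    """Binned onset counts and one-decimal (half-up) percentages."""

    table: pd.DataFrame            # bin, count, percentage
    n_with_onset: int
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
    exclusions: dict[str, int] = field(default_factory=dict)


def summarize_onsets(
    onsets: pd.DataFrame | np.ndarray | list[int],
    bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES,
    exclusions: dict[str, int] | None = None,
) -> OnsetSummary:
    """Bin onset days; empty input yields an all-zero summary with n = 0."""
    if isinstance(onsets, pd.DataFrame):
        days = onsets["days"].to_numpy()
    else:
        days = np.asarray(onsets)
    if (np.asarray(days) < 0).any():
        raise ValueError("onset days must be >= 0")
    labels = bin_labels(bin_edges)
    edges = [-0.5] + [e + 0.5 for e in bin_edges] + [np.inf]
    counts, _ = np.histogram(days, bins=edges)
    n = int(len(days))
    table = pd.DataFrame({
        "bin": labels,
        "count": counts.astype(int),
        "percentage": [percentage(c, n) for c in counts],
    })
    return OnsetSummary(table=table, n_with_onset=n, bin_edges=bin_edges,
                        exclusions=exclusions or {})
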