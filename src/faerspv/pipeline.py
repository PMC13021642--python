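"""End-to-end orchestration: ingest -> dedup -> match -> contingency ->
disproportionality -> consensus -> subgroup -> volcano -> onset ->
demographics, with every artifact written as CSV plus a machine-readable run
manifest (config hash, seed, per-stage row counts, artifact hashes)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from ._utils import percentage
from .contingency import build_tables
from .faers_io import (ReportSet, build_report_set, concat_quarters,
                       deduplicate, from_frames, load_pt_soc_map, read_quarter)
from .onset import DEFAULT_BIN_EDGES, compute_onsets, summarize_onsets
from .signals import ALGORITHMS, AlgorithmOptions, compute_signals, consensus
from .subgroup import sex_volcano, stratified_signals
from .synthetic import TARGET_DRUG_SYNONYMS, GeneratorConfig, generate_dataset


class RunConfig(BaseModel):
    """One pipeline run: either quarterly input files or a synthetic universe."""

    input_quarters: list[dict[str, str]] = Field(default_factory=list)
    synthetic: Optional[GeneratorConfig] = None
    pt_soc_map: Optional[str] = None
    target_synonyms: list[str] = list(TARGET_DRUG_SYNONYMS)
    window_start: Optional[str] = None
    window_end: Optional[str] = None
    formula_mode: str = "standard"
    delta: float = 0.5
    strata: list[str] = Field(default_factory=lambda: ["sex", "age_group", "reporter"])
    volcano_contrast: str = "within_exposed"
    soc_counting: str = "per_report"
    onset_bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
    onset_anchor: str = "event_dt"
    output_dir: str = "faerspv_out"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if not self.input_quarters and self.synthetic is None:
            raise ValueError("config needs input_quarters or a synthetic section")
        if (self.window_start is None) != (self.window_end is None):
            raise ValueError("window_start and window_end must be set together")
        if self.window_start and self.window_start > self.window_end:
            raise ValueError("window start must be <= end")
        for p in self.input_quarters:
            for f in p.values():
                if not Path(f).exists():
                    raise ValueError(f"input file does not exist: {f}")
        if self.pt_soc_map and not Path(self.pt_soc_map).exists():
            raise ValueError(f"PT->SOC map does not exist: {self.pt_soc_map}")
        return self

    def algorithm_options(self) -> AlgorithmOptions:
        return AlgorithmOptions(mode=self.formula_mode, delta=self.delta)


@dataclass
class RunResult:
    report_set: ReportSet
    artifacts: dict[str, Path]
    manifest: dict


def summarize_demographics(report_set: ReportSet | pd.DataFrame,
                           top_countries: int = 6) -> pd.DataFrame:
    """Counts and one-decimal half-up percentages by sex, weight group, age
    group, outcome, reporter and top countries; denominator = total reports.

    Outcome categories are per-report flags (a report with several outcome
    codes counts once in each category), so the outcome block can exceed the
    total; every other block partitions the report set exactly.
    """
    reports = report_set.reports if isinstance(report_set, ReportSet) else report_set
    total = len(reports)
    rows = [{"variable": "overall", "category": "all", "count": total,
             "percentage": percentage(total, total)}]

    def _block(variable: str, counts: dict[str, int], order: list[str]):
        for cat in order:
            rows.append({"variable": variable, "category": cat,
                         "count": int(counts.get(cat, 0)),
                         "percentage": percentage(counts.get(cat, 0), total)})

    sex_counts = reports["sex"].value_counts().to_dict()
    _block("sex", sex_counts, ["female", "male", "missing"])
    wt = reports["weight_group"].value_counts().to_dict()
    _block("weight_group", wt, ["<50", "50-100", ">100", "missing"])
    age = reports["age_group"].value_counts().to_dict()
    _block("age_group", age, ["<18", "18-64.9", "65-85", ">85", "missing"])

    out_counts: dict[str, int] = {}
    for cats in reports["outcomes"]:
        for cat in set(str(cats).split("|")) - {""}:
            out_counts[cat] = out_counts.get(cat, 0) + 1
    _block("outcome", out_counts,
           ["death", "disability", "hospitalization", "life-threatening", "other"])

    rep = reports["reporter"].value_counts().to_dict()
    _block("reporter", rep,
           ["consumer", "other health professional", "pharmacist", "physician", "missing"])

    country = reports["country"].value_counts()
    _block("country", country.to_dict(), list(country.index[:top_countries]))
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_input(config: RunConfig) -> tuple[ReportSet, pd.DataFrame, dict]:
    """Resolve the configured input into a standardized report set."""
    counts: dict[str, int] = {}
    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic, seed=config.seed)
        raw = from_frames(dataset.tables)
        mapping = dataset.pt_soc_map
    else:
        raw = concat_quarters(read_quarter(p) for p in config.input_quarters)
        mapping = load_pt_soc_map(config.pt_soc_map) if config.pt_soc_map else None
    counts["raw_reports"] = len(raw.demo)
    deduped, discard_log = deduplicate(raw)
    counts["duplicate_discarded"] = len(discard_log)
    window = ((config.window_start, config.window_end)
              if config.window_start else None)
    rs = build_report_set(deduped, config.target_synonyms, mapping, window=window)
    counts["excluded_no_pt"] = rs.exclusions.get("no_pt", 0)
    counts["excluded_outside_window"] = rs.exclusions.get("outside_window", 0)
    counts["retained_reports"] = len(rs)
    counts["target_reports"] = rs.n_target
    return rs, discard_log, counts


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write the artifact bundle.

    Identical config + inputs produce byte-identical artifacts; the manifest
    records the config hash, seed, per-stage row counts, formula mode and the
    sha256 of every artifact. Any stage failure aborts with the stage named
    and partially written outputs removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    opts = config.algorithm_options()
    stage = "ingest"
    try:
        rs, discard_log, counts = load_input(config)

        def _write(name: str, df: pd.DataFrame, index: bool = False) -> None:
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=index, lineterminator="\n")
            artifacts[name] = p

        _write("dedup_discards", discard_log)

        stage = "demographics"
        _write("demographics", summarize_demographics(rs))

        stage = "signals"
        has_soc = (rs.reactions["soc"] != "").any()
        pt_tables = build_tables(rs, level="pt")
        pt_signals = compute_signals(pt_tables, opts)
        _write("signals_pt", pt_signals, index=True)
        counts["pt_events"] = len(pt_signals)
        if has_soc:
            soc_tables = build_tables(rs, level="soc", soc_counting=config.soc_counting)
            _write("signals_soc", compute_signals(soc_tables, opts), index=True)

        stage = "consensus"
        _write("venn_partition", consensus(pt_signals))

        stage = "subgroup"
        for var in config.strata:
            strata = stratified_signals(rs, var, opts=opts)
            if strata:
                stacked = pd.concat(strata.values())
                _write(f"signals_by_{var}", stacked, index=True)

        stage = "volcano"
        _write("sex_volcano", sex_volcano(rs, contrast=config.volcano_contrast, opts=opts))

        stage = "onset"
        onsets, onset_excl = compute_onsets(rs, anchor=config.onset_anchor)
        summary = summarize_onsets(onsets, config.onset_bin_edges, onset_excl)
        counts["onset_reports"] = summary.n_with_onset
        _write("onset_bins", summary.table)
        _write("onset_exclusions",
               pd.DataFrame(sorted(onset_excl.items()), columns=["reason", "count"]))
    except Exception as err:
        for p in artifacts.values():
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    cfg_json = config.model_dump_json()
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "formula_mode": opts.mode,
        "row_counts": counts,
        "artifacts": {k: {"path": str(v), "sha256": _sha256(v)}
                      for k, v in sorted(artifacts.items())},
        "algorithms": list(ALGORITHMS),
    }
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    artifacts["manifest"] = mp
    return RunResult(report_set=rs, artifacts=artifacts, manifest=manifest)
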