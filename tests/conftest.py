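import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import faerspv as fp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def run_synthetic(config: fp.GeneratorConfig, seed: int | None = None):
    """Generator -> ingest -> dedup -> standardize, returning the report set
    and the dataset (ledger included)."""
    ds = fp.generate_dataset(config, seed=seed)
    raw = fp.from_frames(ds.tables)
    deduped, discard_log = fp.deduplicate(raw)
    rs = fp.build_report_set(deduped, list(config.target_drug_names), ds.pt_soc_map)
    return rs, ds, discard_log


@pytest.fixture(scope="session")
def small_study():
    """One modest study universe shared by read-only tests."""
    cfg = fp.study_config(n_background_reports=12_000, n_target_reports=1_200, seed=11)
    rs, ds, discard_log = run_synthetic(cfg)
    return {"config": cfg, "report_set": rs, "dataset": ds, "discards": discard_log}


def toy_report_set(rows: list[dict], reactions: list[tuple]) -> fp.ReportSet:
    """Hand-built ReportSet: rows are report dicts (defaults filled in),
    reactions are (primaryid, pt[, soc]) tuples."""
    defaults = dict(caseid="1", fda_dt="20240601", event_dt="", sex="missing",
                    age_years=np.nan, weight_kg=np.nan, country="US",
                    reporter="missing", is_target=False, age_group="missing",
                    weight_group="missing", outcomes="other", therapy_starts="")
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        full.append(d)
    reports = pd.DataFrame(full)
    reac = pd.DataFrame(
        [(r[0], r[1], r[2] if len(r) > 2 else "") for r in reactions],
        columns=["primaryid", "pt", "soc"],
    )
    return fp.ReportSet(reports=reports, reactions=reac)
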