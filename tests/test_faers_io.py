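"""Quarterly-table ingestion, case deduplication, drug matching and
PT -> SOC standardization."""

import pandas as pd
import pytest

import faerspv as fp
from faerspv.faers_io import (FaersIOError, age_group_of, age_to_years,
                              validate_pt_soc_map, weight_group_of,
                              weight_to_kg)

from conftest import run_synthetic


def write_quarter(tmp_path, demo_rows, reac_rows=None, drug_rows=None):
    paths = {}
    demo = pd.DataFrame(demo_rows)
    p = tmp_path / "DEMO.txt"
    demo.to_csv(p, sep="$", index=False)
    paths["DEMO"] = p
    if reac_rows is not None:
        p = tmp_path / "REAC.txt"
        pd.DataFrame(reac_rows).to_csv(p, sep="$", index=False)
        paths["REAC"] = p
    if drug_rows is not None:
        p = tmp_path / "DRUG.txt"
        pd.DataFrame(drug_rows).to_csv(p, sep="$", index=False)
        paths["DRUG"] = p
    return paths


DEMO3 = [{"primaryid": i, "caseid": i, "fda_dt": "20240101"} for i in (1, 2, 3)]


class TestReadQuarter:
    def test_toy_quarter_reads_clean(self, tmp_path):
        paths = write_quarter(tmp_path, DEMO3,
                              reac_rows=[{"primaryid": i, "pt": "Nausea"} for i in (1, 2, 3)])
        raw = fp.read_quarter(paths)
        assert len(raw.demo) == 3
        assert raw.orphan_counts["REAC"] == 0

    def test_orphan_reaction_counted_and_dropped(self, tmp_path):
        paths = write_quarter(tmp_path, DEMO3,
                              reac_rows=[{"primaryid": 1, "pt": "Nausea"},
                                         {"primaryid": 99, "pt": "Rash"}])
        raw = fp.read_quarter(paths)
        assert raw.orphan_counts["REAC"] == 1
        assert len(raw["REAC"]) == 1

    def test_missing_mandatory_column_names_file_and_column(self, tmp_path):
        p = tmp_path / "DEMO.txt"
        pd.DataFrame([{"primaryid": 1, "fda_dt": "20240101"}]).to_csv(p, sep="$", index=False)
        with pytest.raises(FaersIOError, match="caseid"):
            fp.read_quarter({"DEMO": p})

    def test_empty_demo_fails(self, tmp_path):
        p = tmp_path / "DEMO.txt"
        pd.DataFrame(columns=["primaryid", "caseid", "fda_dt"]).to_csv(p, sep="$", index=False)
        with pytest.raises(FaersIOError, match="empty"):
            fp.read_quarter({"DEMO": p})

    def test_dollar_inside_quoted_field_preserved(self, tmp_path):
        drug_rows = [{"primaryid": 1, "drug_seq": 1, "role_cod": "PS",
                      "drugname": "BRAND 5MG $ 10MG", "prod_ai": "X"}]
        paths = write_quarter(tmp_path, DEMO3, drug_rows=drug_rows)
        raw = fp.read_quarter(paths)
        assert raw["DRUG"].loc[0, "drugname"] == "BRAND 5MG $ 10MG"

    def test_generator_output_roundtrips_through_files(self, tmp_path, small_study):
        paths = fp.write_dataset(small_study["dataset"], tmp_path)
        raw = fp.read_quarter({k: paths[k] for k in
                               ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI", "RPSR")})
        assert len(raw.demo) == small_study["dataset"].ledger.n_reports
        assert sum(raw.orphan_counts.values()) == 0


class TestDeduplicate:
    def _dedup(self, demo_rows):
        raw = fp.from_frames({"DEMO": pd.DataFrame(demo_rows).astype(str)})
        out, log = fp.deduplicate(raw)
        return out.demo, log

    def test_latest_receipt_date_survives(self):
        demo, log = self._dedup([
            {"primaryid": "1111", "caseid": "111", "fda_dt": "20240101"},
            {"primaryid": "1112", "caseid": "111", "fda_dt": "20240315"},
        ])
        assert list(demo["primaryid"]) == ["1112"]
        assert list(log["primaryid"]) == ["1111"]
        assert (log["reason"] == "duplicate_superseded").all()

    def test_tie_broken_by_larger_report_id(self):
        demo, _ = self._dedup([
            {"primaryid": "5", "caseid": "111", "fda_dt": "20240101"},
            {"primaryid": "9", "caseid": "111", "fda_dt": "20240101"},
        ])
        assert list(demo["primaryid"]) == ["9"]

    def test_partial_dates_ordered_by_earliest_day_padding(self):
        # 202402 pads to 20240201 and beats 20240101
        demo, _ = self._dedup([
            {"primaryid": "1", "caseid": "7", "fda_dt": "20240101"},
            {"primaryid": "2", "caseid": "7", "fda_dt": "202402"},
        ])
        assert list(demo["primaryid"]) == ["2"]

    def test_idempotent(self):
        rows = [{"primaryid": str(i), "caseid": str(i % 3), "fda_dt": f"2024010{i+1}"}
                for i in range(6)]
        raw = fp.from_frames({"DEMO": pd.DataFrame(rows)})
        once, _ = fp.deduplicate(raw)
        twice, log2 = fp.deduplicate(once)
        pd.testing.assert_frame_equal(once.demo, twice.demo)
        assert len(log2) == 0

    def test_survivor_count_equals_distinct_case_keys(self, small_study):
        ds = small_study["dataset"]
        raw = fp.from_frames(ds.tables)
        deduped, _ = fp.deduplicate(raw)
        assert len(deduped.demo) == ds.tables["DEMO"]["caseid"].nunique()

    def test_survivors_match_ledger_intent_exactly(self, small_study):
        ds = small_study["dataset"]
        raw = fp.from_frames(ds.tables)
        deduped, _ = fp.deduplicate(raw)
        chosen = dict(zip(deduped.demo["caseid"], deduped.demo["primaryid"]))
        groups = ds.ledger.duplicate_groups
        assert len(groups) > 0
        assert all(chosen[g["caseid"]] == g["survivor"] for g in groups)


class TestTargetMatching:
    def _match(self, drugname, prod_ai="", synonyms=("Fruquintinib", "Fruzaqla", "Elunate")):
        df = pd.DataFrame([{"primaryid": 1, "drug_seq": 1, "role_cod": "SS",
                            "drugname": drugname, "prod_ai": prod_ai}])
        return bool(fp.match_target_drug(df, list(synonyms))[0])

    def test_brand_with_dose_suffix_matches(self):
        assert self._match("FRUZAQLA 5MG CAPSULE")

    def test_other_drug_does_not_match(self):
        assert not self._match("REGORAFENIB")

    def test_active_ingredient_matches_when_name_blank(self):
        assert self._match("", prod_ai="fruquintinib")

    def test_case_insensitive_and_trimmed(self):
        assert self._match("elunate 1mg", synonyms=["  ELUNATE  "])

    def test_empty_synonym_list_rejected(self):
        df = pd.DataFrame([{"drugname": "X", "prod_ai": ""}])
        with pytest.raises(ValueError):
            fp.match_target_drug(df, [])


class TestPtSocMapping:
    MAP = pd.DataFrame({"pt": ["Proteinuria", "Nausea"],
                        "soc": ["Renal and urinary disorders",
                                "Gastrointestinal disorders"]})

    def test_known_pt_maps_to_its_soc(self):
        socs, unmapped = fp.map_pt_to_soc({"Proteinuria"}, self.MAP)
        assert socs == {"Renal and urinary disorders": 1}
        assert unmapped == []

    def test_empty_pt_set(self):
        socs, unmapped = fp.map_pt_to_soc(set(), self.MAP)
        assert socs == {} and unmapped == []

    def test_unmapped_pt_collected(self):
        socs, unmapped = fp.map_pt_to_soc(["Vertigo"], self.MAP)
        assert socs == {} and unmapped == ["Vertigo"]

    def test_conflicting_rows_fail(self):
        bad = pd.DataFrame({"pt": ["A", "A"], "soc": ["S1", "S2"]})
        with pytest.raises(FaersIOError, match="conflicting"):
            validate_pt_soc_map(bad)

    def test_consistent_duplicates_collapsed(self):
        ok = pd.DataFrame({"pt": ["A", "A"], "soc": ["S1", "S1"]})
        assert len(validate_pt_soc_map(ok)) == 1


class TestNormalization:
    @pytest.mark.parametrize("value,unit,years", [
        ("60", "YR", 60.0), ("6", "DEC", 60.0), ("24", "MON", 2.0),
        ("730.5", "DY", 2.0), ("52.1775", "WK", 1.0), ("60", "", 60.0),
        ("", "YR", None), ("abc", "YR", None), ("60", "XXX", None),
    ])
    def test_age_unit_conversion(self, value, unit, years):
        got = age_to_years(value, unit)
        if years is None:
            assert got is None or got != got
        else:
            assert got == pytest.approx(years)

    @pytest.mark.parametrize("age,group", [
        (17.9, "<18"), (18.0, "18-64.9"), (64.9, "18-64.9"), (65.0, "65-85"),
        (85.0, "65-85"), (85.1, ">85"), (None, "missing"),
    ])
    def test_age_group_boundaries(self, age, group):
        assert age_group_of(age) == group

    @pytest.mark.parametrize("kg,group", [
        (49.9, "<50"), (50.0, "50-100"), (100.0, "50-100"), (100.1, ">100"),
        (None, "missing"),
    ])
    def test_weight_group_boundaries(self, kg, group):
        assert weight_group_of(kg) == group

    def test_pounds_converted(self):
        assert weight_to_kg("220.462", "LBS") == pytest.approx(100.0, rel=1e-4)

    def test_outcome_codes_mapped_per_report_category(self):
        tables = {
            "DEMO": pd.DataFrame([{"primaryid": "1", "caseid": "1",
                                   "fda_dt": "20240101", "sex": "F"}]),
            "DRUG": pd.DataFrame([{"primaryid": "1", "drug_seq": "1",
                                   "role_cod": "PS", "drugname": "FRUZAQLA"}]),
            "REAC": pd.DataFrame([{"primaryid": "1", "pt": "Nausea"}]),
            "OUTC": pd.DataFrame([{"primaryid": "1", "outc_cod": c}
                                  for c in ("DE", "HO", "CA", "HO")]),
        }
        raw = fp.from_frames(tables)
        rs = fp.build_report_set(raw, ["FRUZAQLA"])
        rec = next(rs.records())
        assert rec.outcomes == frozenset({"death", "hospitalization", "other"})
        assert rec.sex == "female" and rec.is_target

    def test_reports_without_pt_are_excluded_and_counted(self):
        tables = {
            "DEMO": pd.DataFrame([{"primaryid": str(i), "caseid": str(i),
                                   "fda_dt": "20240101"} for i in (1, 2)]),
            "DRUG": pd.DataFrame([{"primaryid": "1", "drug_seq": "1",
                                   "role_cod": "PS", "drugname": "X"}]),
            "REAC": pd.DataFrame([{"primaryid": "1", "pt": "Nausea"}]),
        }
        rs = fp.build_report_set(fp.from_frames(tables), ["FRUZAQLA"])
        assert len(rs) == 1
        assert rs.exclusions["no_pt"] == 1

    def test_window_filter_on_receipt_date(self):
        tables = {
            "DEMO": pd.DataFrame([
                {"primaryid": "1", "caseid": "1", "fda_dt": "20230915"},
                {"primaryid": "2", "caseid": "2", "fda_dt": "20240601"},
            ]),
            "DRUG": pd.DataFrame([{"primaryid": "2", "drug_seq": "1",
                                   "role_cod": "PS", "drugname": "X"}]),
            "REAC": pd.DataFrame([{"primaryid": i, "pt": "Nausea"} for i in ("1", "2")]),
        }
        rs = fp.build_report_set(fp.from_frames(tables), ["X"],
                                 window=("20231001", "20250331"))
        assert len(rs) == 1
        assert rs.exclusions["outside_window"] == 1

    def test_unmapped_pts_counted_not_dropped(self, small_study):
        cfg = small_study["config"]
        ds = small_study["dataset"]
        partial_map = ds.pt_soc_map.iloc[:10]
        raw = fp.from_frames(ds.tables)
        deduped, _ = fp.deduplicate(raw)
        rs = fp.build_report_set(deduped, list(cfg.target_drug_names), partial_map)
        assert rs.unmapped_pt_count > 0
        assert len(rs.reactions) == (rs.reactions["soc"] != "").sum() + rs.unmapped_pt_count
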