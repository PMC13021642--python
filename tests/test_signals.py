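"""The four disproportionality estimators against an independent scalar
recomputation of the closed forms, their signal criteria, and the consensus
partition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import faerspv as fp
from faerspv.contingency import ContingencyTable
from faerspv.signals import AlgorithmOptions

# ---------------------------------------------------------------------------
# independent scalar oracle (plain math module, no shared code path)


def oracle(a, b, c, d, mode="standard", delta=0.5):
    if a == 0:
        return None
    if b == 0 or c == 0 or d == 0:
        a, b, c, d = a + delta, b + delta, c + delta, d + delta
    n = a + b + c + d
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ror = (a / c) / (b / d)
    ror_ci = (math.exp(math.log(ror) - 1.96 * se), math.exp(math.log(ror) + 1.96 * se))
    prr = (a / (a + b)) / (c / (c + d))
    se_prr = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    prr_ci = (math.exp(math.log(prr) - 1.96 * se_prr),
              math.exp(math.log(prr) + 1.96 * se_prr))
    if mode == "standard":
        rrr = a * n / ((a + c) * (a + b))
        ic = math.log2(rrr)
        ic025 = ic - 1.96 * se / math.log(2)
        ebgm = rrr
    else:
        lit = n / ((a + c) * (a + b))
        ic = math.log2(lit)
        ic025 = math.exp(math.log(ic) - 1.96 * se) if ic > 0 else None
        ebgm = lit
    ebgm05 = ebgm * math.exp(-1.64 * se)
    return dict(ROR=ror, ROR_lo=ror_ci[0], ROR_hi=ror_ci[1],
                PRR=prr, PRR_lo=prr_ci[0], PRR_hi=prr_ci[1],
                IC=ic, IC025=ic025, EBGM=ebgm, EBGM05=ebgm05)


def metrics(a, b, c, d, **kw):
    opts = AlgorithmOptions(**kw) if kw else None
    df = pd.DataFrame([{"a": a, "b": b, "c": c, "d": d}])
    return fp.compute_signals(df, opts).iloc[0]


class TestClosedForms:
    def test_symmetric_table_gives_ror_one(self):
        assert metrics(1, 99, 99, 9801)["ROR"] == pytest.approx(1.0, abs=1e-12)

    def test_reference_table_values(self):
        r = metrics(10, 90, 100, 9800)
        o = oracle(10, 90, 100, 9800)
        for k, v in o.items():
            assert r[k] == pytest.approx(v, rel=1e-12), k
        assert r["ROR"] == pytest.approx(10.8889, abs=5e-4)
        assert r["ROR_lo"] == pytest.approx(5.50, abs=0.02)
        assert r["ROR_hi"] == pytest.approx(21.55, abs=0.02)
        assert r["PRR"] == pytest.approx(9.9, abs=1e-9)
        assert r["PRR_lo"] == pytest.approx(5.33, abs=0.02)
        assert r["PRR_hi"] == pytest.approx(18.39, abs=0.02)
        assert r["IC"] == pytest.approx(math.log2(10000 * 10 / (110 * 100)), rel=1e-12)
        assert r["IC"] == pytest.approx(3.1844, abs=5e-4)
        assert r["EBGM"] == pytest.approx(9.0909, abs=5e-4)
        assert r["EBGM05"] == pytest.approx(5.14, abs=5e-3)
        assert r[["flag_ROR", "flag_PRR", "flag_BCPNN", "flag_MGPS"]].all()

    def test_observed_equals_expected_is_null(self):
        r = metrics(10, 90, 990, 8910)
        assert r["IC"] == pytest.approx(0.0, abs=1e-12)
        assert r["EBGM"] == pytest.approx(1.0, abs=1e-12)

    def test_balanced_table_prr_is_one(self):
        assert metrics(7, 7, 7, 7)["PRR"] == pytest.approx(1.0)

    def test_scalar_wrappers_agree_with_frame(self):
        t = ContingencyTable(10, 90, 100, 9800)
        r = metrics(10, 90, 100, 9800)
        assert fp.ror(t).point == pytest.approx(r["ROR"])
        assert fp.prr(t).lower == pytest.approx(r["PRR_lo"])
        assert fp.ic(t).lower == pytest.approx(r["IC025"])
        assert fp.ebgm(t).lower == pytest.approx(r["EBGM05"])


class TestCriteria:
    def test_low_count_never_flagged_despite_high_lower_bound(self):
        r = metrics(2, 10, 2, 10_000)
        assert r["ROR_lo"] > 1  # interval clear of 1, yet a < 3
        assert not r["flag_ROR"] and not r["flag_PRR"] and not r["flag_BCPNN"]
        r2 = metrics(2, 50, 10, 1000)
        assert not r2[["flag_ROR", "flag_PRR", "flag_BCPNN"]].any()

    def test_mgps_threshold_is_two(self):
        # find a table with 1 < EBGM05 <= 2 -> not flagged
        r = metrics(30, 970, 2000, 97000)
        assert 1.0 < r["EBGM05"] <= 2.0
        assert not r["flag_MGPS"]

    def test_a_zero_not_evaluable_with_flags_false(self):
        r = metrics(0, 50, 10, 1000)
        assert np.isnan(r["ROR"]) and np.isnan(r["PRR"]) and np.isnan(r["IC"])
        assert r["EBGM"] == 0.0
        assert r["consensus"] == 0

    def test_zero_cell_continuity_correction(self):
        r = metrics(5, 0, 10, 1000)
        o = oracle(5, 0, 10, 1000)
        assert r["ROR"] == pytest.approx(o["ROR"], rel=1e-12)
        assert np.isfinite(r["ROR_lo"])


class TestPaperLiteralMode:
    def test_numerator_drops_a(self):
        r = metrics(10, 90, 100, 9800, mode="paper-literal")
        o = oracle(10, 90, 100, 9800, mode="paper-literal")
        assert r["IC"] == pytest.approx(o["IC"], rel=1e-12)  # negative: N < (a+c)(a+b)
        assert r["EBGM"] == pytest.approx(10000 / (110 * 100), rel=1e-12)
        assert r["mode"] == "paper-literal"

    def test_literal_ic025_where_defined(self):
        r = metrics(10, 90, 100, 98_000, mode="paper-literal")
        o = oracle(10, 90, 100, 98_000, mode="paper-literal")
        assert o["IC"] > 0
        assert r["IC025"] == pytest.approx(o["IC025"], rel=1e-12)

    def test_nonpositive_ic_not_evaluable(self):
        # N/((a+c)(a+b)) <= 1 -> literal IC <= 0 -> IC025 undefined
        r = metrics(50, 500, 500, 5000, mode="paper-literal")
        assert np.isnan(r["IC025"]) and not r["flag_BCPNN"]

    def test_mode_recorded_per_row(self):
        assert metrics(10, 90, 100, 9800)["mode"] == "standard"


cells = st.integers(min_value=0, max_value=100_000)


class TestProperties:
    @given(a=cells, b=cells, c=cells, d=cells)
    @settings(max_examples=300, deadline=None)
    def test_matches_independent_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        r = metrics(a, b, c, d)
        o = oracle(a, b, c, d)
        if o is None:
            assert np.isnan(r["ROR"])
            return
        for k, v in o.items():
            if v is None:
                continue
            assert r[k] == pytest.approx(v, rel=1e-10), k

    @given(a=st.integers(1, 1000), b=st.integers(1, 1000),
           c=st.integers(1, 1000), d=st.integers(1, 1000))
    @settings(max_examples=200, deadline=None)
    def test_ror_prr_algebraic_identity(self, a, b, c, d):
        r = metrics(a, b, c, d)
        assert r["ROR"] / r["PRR"] == pytest.approx(d * (a + b) / (b * (c + d)),
                                                    rel=1e-10)
        if r["ROR"] > 1:
            assert r["ROR"] >= r["PRR"] or d * (a + b) < b * (c + d)

    @given(a=st.integers(1, 500), b=st.integers(1, 500),
           c=st.integers(1, 500), d=st.integers(1, 500),
           k=st.integers(2, 50))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_of_points_and_narrowing_intervals(self, a, b, c, d, k):
        r1 = metrics(a, b, c, d)
        rk = metrics(k * a, k * b, k * c, k * d)
        for key in ("ROR", "PRR", "IC", "EBGM"):
            assert rk[key] == pytest.approx(r1[key], rel=1e-9)
        assert rk["ROR_hi"] - rk["ROR_lo"] < r1["ROR_hi"] - r1["ROR_lo"]

    @given(a=st.integers(1, 200), b=st.integers(1, 1000),
           c=st.integers(1, 1000), d=st.integers(1, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_ror_and_prr_strictly_monotone_in_a(self, a, b, c, d):
        r1 = metrics(a, b, c, d)
        r2 = metrics(a + 1, b, c, d)
        for key in ("ROR", "PRR"):
            assert r2[key] > r1[key]

    @given(a=st.integers(1, 200), b=st.integers(2000, 10_000),
           c=st.integers(2000, 10_000), d=st.integers(2000, 100_000))
    @settings(max_examples=100, deadline=None)
    def test_ic_and_ebgm_monotone_in_a_for_rare_events(self, a, b, c, d):
        """Observed/expected grows with a whenever the event is rare relative
        to the margins (1/a > 1/(a+b) + 1/(a+c)), the regime screening
        operates in; at a comparable to the margins it can dip."""
        r1 = metrics(a, b, c, d)
        r2 = metrics(a + 1, b, c, d)
        for key in ("IC", "EBGM"):
            assert r2[key] > r1[key]

    @given(a=st.integers(0, 2), b=cells, c=cells, d=cells)
    @settings(max_examples=100, deadline=None)
    def test_a_floor_suppresses_flags(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        r = metrics(a, b, c, d)
        assert not r["flag_ROR"] and not r["flag_PRR"] and not r["flag_BCPNN"]


class TestConsensus:
    def _signals(self, flag_rows):
        df = pd.DataFrame(flag_rows,
                          columns=["flag_ROR", "flag_PRR", "flag_BCPNN", "flag_MGPS"])
        return df

    def test_partition_of_crafted_flags(self):
        sig = self._signals([
            (True, True, True, True),    # 4-way cell
            (True, True, True, False),   # ROR+PRR+BCPNN cell
            (False, False, False, True), # MGPS only
            (False, False, False, False),
        ])
        venn = fp.consensus(sig)
        as_map = dict(zip(venn["combination"], venn["count"]))
        assert as_map["ROR+PRR+BCPNN+MGPS"] == 1
        assert as_map["ROR+PRR+BCPNN"] == 1
        assert as_map["MGPS"] == 1
        assert venn["count"].sum() == 3  # events flagged by >= 1 algorithm

    def test_percentages_relative_to_flagged_events(self):
        sig = self._signals([(True, True, True, True)] * 3 +
                            [(True, False, False, False)] * 1)
        venn = fp.consensus(sig)
        as_map = dict(zip(venn["combination"], venn["percentage"]))
        assert as_map["ROR+PRR+BCPNN+MGPS"] == 75.0
        assert as_map["ROR"] == 25.0

    def test_cells_are_mutually_exclusive_and_sum(self, small_study):
        sig = fp.compute_signals(fp.build_tables(small_study["report_set"]))
        venn = fp.consensus(sig)
        assert venn["count"].sum() == int((sig["consensus"] > 0).sum())
        assert venn["n_algorithms"].between(1, 4).all()
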