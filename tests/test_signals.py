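"""Disproportionality metrics, contingency building, and gender contrasts.

``oracle_metrics`` is an independent straight-line re-implementation of the
printed formulas used to cross-check ``compute_metrics`` over an exhaustive
sweep of small tables.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pvsignal as pv
from pvsignal.signals import ContingencyTable, compute_metrics

from conftest import make_report


# --------------------------------------------------------------------------
# independent oracle: plain transliteration of the four formulas
# --------------------------------------------------------------------------

def oracle_metrics(a, b, c, d):
    n = a + b + c + d
    out = {}
    nan = float("nan")

    if a > 0 and b > 0 and c > 0 and d > 0:
        ror = (a / c) / (b / d)
        w = 1.959963984540054 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        out["ror"], out["ror_lo"], out["ror_hi"] = (
            ror, ror * math.exp(-w), ror * math.exp(w))
    else:
        out["ror"] = out["ror_lo"] = out["ror_hi"] = nan

    if a > 0 and c > 0:
        prr = (a / (a + b)) / (c / (c + d))
        w = 1.959963984540054 * math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        out["prr"], out["prr_lo"], out["prr_hi"] = (
            prr, prr * math.exp(-w), prr * math.exp(w))
    else:
        out["prr"] = out["prr_lo"] = out["prr_hi"] = nan
    if (a + b) and (c + d) and (a + c) and (b + d):
        out["chi2"] = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    else:
        out["chi2"] = nan

    g = 1 * (n + 2) * (n + 2) / ((a + b + 1) * (a + c + 1))
    eic = math.log2((a + 1) * (n + 2) * (n + 2) / ((n + g) * (a + b + 1) * (a + c + 1)))
    vic = (1 / math.log(2) ** 2) * (
        (n - a + g - 1) / ((a + 1) * (1 + n + g))
        + (n - (a + b) + 2 - 1) / ((a + b + 1) * (1 + n + 2))
        + (n - (a + c) + 2 - 1) / ((a + c + 1) * (1 + n + 2)))
    out["ic"], out["ic025"] = eic, eic - 2 * math.sqrt(vic)

    if a > 0:
        out["ebgm"] = a * n / ((a + c) * (a + b))
        if b > 0 and c > 0 and d > 0:
            out["ebgm05"] = math.exp(
                math.log(out["ebgm"])
                - 1.6448536269514722 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
        else:
            out["ebgm05"] = nan
    else:
        out["ebgm"] = out["ebgm05"] = nan

    out["flag_ror"] = a >= 3 and not math.isnan(out["ror_lo"]) and out["ror_lo"] > 1
    out["flag_prr"] = (a >= 3 and not math.isnan(out["chi2"]) and out["chi2"] >= 4
                       and not math.isnan(out["prr_lo"]) and out["prr_lo"] > 1)
    out["flag_bcpnn"] = a >= 3 and out["ic025"] > 0
    out["flag_mgps"] = (a > 0 and not math.isnan(out["ebgm05"])
                        and out["ebgm05"] > 2)
    out["signal"] = (out["flag_ror"] and out["flag_prr"]
                     and out["flag_bcpnn"] and out["flag_mgps"])
    return out


def assert_matches_oracle(a, b, c, d, tol=1e-12):
    got = compute_metrics(ContingencyTable(a, b, c, d)).to_dict()
    want = oracle_metrics(a, b, c, d)
    for key, expected in want.items():
        actual = got[key]
        if isinstance(expected, bool):
            assert actual == expected, (a, b, c, d, key)
        elif isinstance(expected, float) and math.isnan(expected):
            assert math.isnan(actual), (a, b, c, d, key)
        else:
            assert actual == pytest.approx(expected, abs=tol, rel=tol), \
                (a, b, c, d, key)


class TestComputeMetrics:
    def test_symmetric_table_is_null(self):
        m = compute_metrics(ContingencyTable(5, 5, 5, 5))
        assert m.ror == pytest.approx(1.0)
        assert m.prr == pytest.approx(1.0)
        assert m.chi2 == pytest.approx(0.0)
        assert m.ebgm == pytest.approx(1.0)
        assert not (m.flag_ror or m.flag_prr or m.flag_bcpnn or m.flag_mgps)
        assert not m.signal

    def test_hand_arithmetic_example(self):
        # a=10, b=90, c=100, d=9900: ROR = ad/bc = 11.0
        m = compute_metrics(ContingencyTable(10, 90, 100, 9900))
        assert m.ror == pytest.approx(11.0)
        half = 1.959963984540054 * math.sqrt(1 / 10 + 1 / 90 + 1 / 100 + 1 / 9900)
        assert m.ror_lo == pytest.approx(11.0 * math.exp(-half))
        assert m.ror_hi == pytest.approx(11.0 * math.exp(half))

    def test_count_threshold_gates_flags_regardless_of_estimates(self):
        # a=2 fails the a>=3 precondition however extreme the association
        m = compute_metrics(ContingencyTable(2, 1, 1, 10000))
        assert m.ror > 100
        assert not m.flag_ror and not m.flag_prr and not m.flag_bcpnn

    def test_zero_cells_marked_undefined_and_fail_flags(self):
        m = compute_metrics(ContingencyTable(0, 10, 5, 100))
        assert math.isnan(m.ror) and math.isnan(m.prr) and math.isnan(m.ebgm)
        assert not m.signal
        assert not math.isnan(m.ic)  # BCPNN priors smooth zero cells

    def test_negative_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)

    def test_exhaustive_sweep_small_cells_matches_oracle(self):
        for a in range(7):
            for b in range(7):
                for c in range(7):
                    for d in range(7):
                        if a + b + c + d == 0:
                            continue
                        assert_matches_oracle(a, b, c, d)

    @given(st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500), st.integers(1, 500))
    @settings(derandomize=True, max_examples=80)
    def test_transposition_and_swap_invariances(self, a, b, c, d):
        m = compute_metrics(ContingencyTable(a, b, c, d))
        mt = compute_metrics(ContingencyTable(c, d, a, b))
        assert m.ror == pytest.approx(1.0 / mt.ror)
        swap = compute_metrics(ContingencyTable(a, c, b, d))
        assert m.ebgm == pytest.approx(swap.ebgm)

    @given(st.integers(1, 200), st.integers(1, 200),
           st.integers(1, 200), st.integers(1, 200), st.integers(2, 8))
    @settings(derandomize=True, max_examples=60)
    def test_scaling_preserves_points_and_narrows_cis(self, a, b, c, d, k):
        m = compute_metrics(ContingencyTable(a, b, c, d))
        mk = compute_metrics(ContingencyTable(k * a, k * b, k * c, k * d))
        assert mk.ror == pytest.approx(m.ror)
        assert mk.prr == pytest.approx(m.prr)
        assert mk.ebgm == pytest.approx(m.ebgm)
        assert (mk.ror_hi - mk.ror_lo) <= (m.ror_hi - m.ror_lo) + 1e-12

    def test_independence_limit_at_n_1e6(self):
        # a = (a+b)(a+c)/N exactly
        m = compute_metrics(ContingencyTable(1000, 9000, 99000, 891000))
        assert m.ror == pytest.approx(1.0, abs=1e-12)
        assert m.prr == pytest.approx(1.0, abs=1e-12)
        assert m.ebgm == pytest.approx(1.0, abs=1e-12)
        assert m.chi2 == pytest.approx(0.0, abs=1e-9)
        assert abs(m.ic) < 0.01

    def test_signal_implies_every_flag(self):
        m = compute_metrics(ContingencyTable(50, 100, 100, 10000))
        assert m.signal
        assert m.flag_ror and m.flag_prr and m.flag_bcpnn and m.flag_mgps


class TestBuildTable:
    def test_pair_enumeration_oracle(self, four_report_store):
        t = pv.build_table(four_report_store, "drugx", "PT1")
        # drugx reports: 1 (PT1), 2 (PT2); others: 3 (PT1), 4 (PT3)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_absent_term_gives_zero_a_and_c(self, four_report_store):
        t = pv.build_table(four_report_store, "drugx", "PT99")
        assert t.a == 0 and t.c == 0

    def test_n_constant_across_terms(self, four_report_store):
        n = {pv.build_table(four_report_store, "drugx", pt).n
             for pt in ("PT1", "PT2", "PT3")}
        assert n == {4}

    def test_within_report_duplicate_pts_count_once(self):
        store = [make_report("1", drugs=[("drugx", "PS")],
                             reactions=["PT1", "PT1", "PT2"]),
                 make_report("2", drugs=[("drugy", "PS")], reactions=["PT1"])]
        t = pv.build_table(store, "drugx", "PT1")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 0)

    def test_soc_table_sums_member_pt_a_cells(self, four_report_store):
        meddra = pv.MeddraDict({"PT1": "SOC_A", "PT2": "SOC_A", "PT3": "SOC_B"})
        soc = pv.build_table(four_report_store, "drugx", "SOC_A",
                             level="SOC", meddra=meddra)
        a_sum = sum(pv.build_table(four_report_store, "drugx", pt).a
                    for pt in ("PT1", "PT2"))
        assert soc.a == a_sum

    def test_unknown_soc_is_lookup_error(self, four_report_store):
        meddra = pv.MeddraDict({"PT1": "SOC_A", "PT2": "SOC_A", "PT3": "SOC_B"})
        from pvsignal.errors import MeddraLookupError
        with pytest.raises(MeddraLookupError):
            pv.build_table(four_report_store, "drugx", "SOC_MISSING",
                           level="SOC", meddra=meddra)


class TestScreenTerms:
    def test_min_a_filter_and_ranking(self):
        store = ([make_report(str(i), drugs=[("drugx", "PS")], reactions=["PT1"])
                  for i in range(6)]
                 + [make_report(str(10 + i), drugs=[("drugx", "PS")],
                                reactions=["PT2"]) for i in range(2)]
                 + [make_report(str(20 + i), drugs=[("drugy", "PS")],
                                reactions=["PT1", "PT2"]) for i in range(5)])
        df = pv.screen_terms(store, "drugx", min_a=3)
        assert list(df.term) == ["PT1"]  # PT2 has a=2 < 3
        full = pv.screen_terms(store, "drugx", min_a=0)
        assert list(full.a) == sorted(full.a, reverse=True)

    def test_common_signals_intersection(self):
        import pandas as pd
        res = {
            "d1": pd.DataFrame({"term": ["PT1", "PT2"], "signal": [True, True]}),
            "d2": pd.DataFrame({"term": ["PT1", "PT3"], "signal": [True, True]}),
        }
        assert pv.common_signals(res) == ["PT1"]


class TestGenderRor:
    def test_identical_proportions_gives_null(self):
        store = ([make_report(str(i), gender="F", drugs=[("drugx", "PS")],
                              reactions=["PT1" if i < 5 else "PT2"]) for i in range(10)]
                 + [make_report(str(20 + i), gender="M", drugs=[("drugx", "PS")],
                                reactions=["PT1" if i < 5 else "PT2"]) for i in range(10)])
        g = pv.gender_ror(store, "drugx", "PT1")
        assert g.ror == pytest.approx(1.0)
        assert g.p_value > 0.9

    def test_female_heavy_pt_flags_female_risk(self):
        store = ([make_report(str(i), gender="F", drugs=[("drugx", "PS")],
                              reactions=["PT1" if i < 8 else "PT2"]) for i in range(10)]
                 + [make_report(str(20 + i), gender="M", drugs=[("drugx", "PS")],
                                reactions=["PT1" if i < 2 else "PT2"]) for i in range(10)])
        g = pv.gender_ror(store, "drugx", "PT1")
        assert g.ror > 1 and g.direction == "female_risk"

    def test_single_gender_store_is_undefined_marked(self):
        store = [make_report(str(i), gender="F", drugs=[("drugx", "PS")],
                             reactions=["PT1"]) for i in range(5)]
        g = pv.gender_ror(store, "drugx", "PT1")
        assert not g.defined and g.direction is None

    def test_pearson_chi2_matches_scipy_without_correction(self):
        from scipy.stats import chi2_contingency
        store = ([make_report(str(i), gender="F", drugs=[("drugx", "PS")],
                              reactions=["PT1" if i < 7 else "PT2"]) for i in range(12)]
                 + [make_report(str(30 + i), gender="M", drugs=[("drugx", "PS")],
                                reactions=["PT1" if i < 3 else "PT2"]) for i in range(11)])
        g = pv.gender_ror(store, "drugx", "PT1")
        chi2, p, _, _ = chi2_contingency(
            np.array([[g.a, g.b], [g.c, g.d]]), correction=False)
        assert g.p_value == pytest.approx(p)
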