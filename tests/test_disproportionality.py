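"""Disproportionality estimators, signal criteria, table building.

Frozen expected values were computed with independent high-precision
oracles (sympy/mpmath transcriptions of the defining formulas) before the
implementation was written.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from faerspv.casestore import build_corpus
from faerspv.disproportionality import (
    BcpnnHyperparams,
    ContingencyTable,
    bcpnn_full,
    build_tables,
    chi_square,
    compute_signal_stats,
    ebgm,
    evaluate_signal,
    ic_simple,
    prr,
    ror,
    run_stratified,
    signal_frame,
)
from faerspv.synthetic import fixture_term_map, make_fixture

T2080 = ContingencyTable(20, 80, 100, 900)
PROPORTIONAL = ContingencyTable(10, 90, 100, 900)

tables_strategy = st.builds(
    ContingencyTable,
    a=st.integers(1, 500), b=st.integers(1, 10_000),
    c=st.integers(1, 10_000), d=st.integers(1, 1_000_000))


class TestContingencyTable:
    def test_margins(self):
        t = T2080
        assert (t.n_observed, t.n_drug, t.n_effect, t.n_total) == (20, 100, 120, 1100)
        assert t.n_expected == pytest.approx(100 * 120 / 1100)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 0, 0, 0)


class TestEstimators:
    def test_proportional_table_is_null(self):
        assert ror(PROPORTIONAL).value == pytest.approx(1.0)
        assert prr(PROPORTIONAL).value == pytest.approx(1.0)
        assert ebgm(PROPORTIONAL).value == pytest.approx(1.0)
        assert chi_square(ContingencyTable(10, 90, 20, 180)) == pytest.approx(0.0)

    def test_ror_frozen(self):
        e = ror(T2080)
        assert e.value == pytest.approx(2.25)
        assert e.low == pytest.approx(1.3220127820, rel=1e-9)
        assert e.high == pytest.approx(3.8293880883, rel=1e-9)

    def test_prr_frozen(self):
        assert prr(T2080).value == pytest.approx(2.0)

    def test_chi2_frozen(self):
        assert chi_square(T2080) == pytest.approx(9.3537414966, rel=1e-9)

    def test_ic_frozen(self):
        ic, lo, hi = ic_simple(T2080)
        assert ic == pytest.approx(0.8454400693, rel=1e-9)
        assert lo == pytest.approx(0.0950443824, rel=1e-8)
        assert hi == pytest.approx(1.3701244908, rel=1e-8)

    def test_ic_zero_when_observed_equals_expected(self):
        # a = 10 = Nexpected for this table
        ic, _, _ = ic_simple(PROPORTIONAL)
        assert ic == pytest.approx(0.0)

    def test_ic_negative_when_under_expected(self):
        t = ContingencyTable(0, 100, 50, 850)
        ic, _, _ = ic_simple(t)
        assert ic == math.log2((0 + 0.5) / (t.n_expected + 0.5)) and ic < 0

    def test_bcpnn_frozen(self):
        e_ic, v_ic, ic2sd = bcpnn_full(T2080)
        assert e_ic == pytest.approx(0.798998325267, rel=1e-9)
        assert v_ic == pytest.approx(0.131297018349, rel=1e-9)
        assert ic2sd == pytest.approx(0.0742997166, rel=1e-7)

    def test_bcpnn_prior_keeps_zero_cell_finite(self):
        e_ic, v_ic, _ = bcpnn_full(ContingencyTable(0, 100, 50, 850))
        assert math.isfinite(e_ic) and math.isfinite(v_ic)

    def test_bcpnn_null_shrinks_to_zero_with_n(self):
        """On an exactly proportional table E(IC) -> 0 as N grows."""
        values = [abs(bcpnn_full(ContingencyTable(k, 9 * k, 9 * k, 81 * k))[0])
                  for k in (10, 100, 1000)]
        assert values == sorted(values, reverse=True)
        assert values[-1] < 0.01

    def test_ebgm_frozen(self):
        e = ebgm(T2080)
        assert e.value == pytest.approx(11 / 6, rel=1e-12)
        assert e.low == pytest.approx(1.0771956002, rel=1e-9)

    def test_zero_cell_continuity_correction(self):
        t = ContingencyTable(3, 0, 50, 947)
        for fn in (ror, prr, ebgm):
            e = fn(t)
            assert e.corrected and math.isfinite(e.value) and e.value > 0

    @given(tables_strategy)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_chi2_matches_generic_pearson(self, t):
        expected = chi2_contingency([[t.a, t.b], [t.c, t.d]],
                                    correction=False)[0]
        assert chi_square(t) == pytest.approx(expected, rel=1e-9)

    @given(tables_strategy)
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_interval_orderings(self, t):
        ic, lo, hi = ic_simple(t)
        assert lo < ic < hi
        e = ebgm(t)
        assert e.low < e.value < e.high
        r = ror(t)
        assert r.low < r.value < r.high

    @pytest.mark.parametrize("a, nd, ne, n", [
        (30, 4000, 3000, 1_000_000),
        (50, 20_000, 8000, 5_000_000),
        (5, 1000, 900, 2_000_000),
    ])
    def test_rare_event_convergence(self, a, nd, ne, n):
        """For rare events ROR, PRR and EBGM agree to < 1%."""
        t = ContingencyTable(a, nd - a, ne - a, n - nd - ne + a)
        assert t.a / t.n_drug < 0.01 and t.c / (t.c + t.d) < 0.01
        r, p, e = ror(t).value, prr(t).value, ebgm(t).value
        assert abs(r - p) / p < 0.01
        assert abs(e - p) / p < 0.01


class TestSignalCriteria:
    def test_a_below_three_never_signals(self):
        t = ContingencyTable(2, 8, 100, 10_000)
        stats = compute_signal_stats(t)
        assert not stats.ror_signal and not stats.prr_signal
        assert not stats.signal_all

    def test_flag_pattern_on_reference_table(self):
        stats = compute_signal_stats(T2080)
        assert stats.ror_signal
        assert stats.prr_signal  # PRR = 2.0, chi2 ~ 9.35
        assert stats.bcpnn_signal  # IC025 ~ 0.095 > 0
        assert not stats.mgps_signal  # EBGM05 ~ 1.08 < 2
        assert not stats.signal_all

    def test_ic_minus_2sd_criterion_variant(self):
        stats = compute_signal_stats(T2080, bcpnn_criterion="ic_minus_2sd")
        assert stats.bcpnn_signal == (stats.ic_minus_2sd > 0)

    def test_unsmoothed_ic_variant(self):
        stats = compute_signal_stats(T2080, ic_smoothed=False)
        assert stats.ic == pytest.approx(math.log2(20 / T2080.n_expected))


class TestBuildTables:
    def test_four_case_fixture(self):
        bundle = make_fixture("four-case")
        cases, _, _, _ = build_corpus([bundle], fixture_term_map())
        tables = build_tables(cases, ["10001052"])
        t = tables["Drugx"]
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_case_listing_drug_twice_counts_once(self):
        from faerspv.io import RawDrugRecord
        bundle = make_fixture("four-case")
        # add a second entry of drug X to the first case
        bundle.drug.append(RawDrugRecord("101", "2", "SS", "DRUGX"))
        cases, _, _, _ = build_corpus([bundle], fixture_term_map())
        t = build_tables(cases, ["10001052"])["Drugx"]
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_absent_drug_emits_no_table(self):
        bundle = make_fixture("four-case")
        cases, _, _, _ = build_corpus([bundle], fixture_term_map())
        assert "Remdesivir" not in build_tables(cases, ["10001052"])

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            build_tables({}, ["10001052"])

    def test_margins_sum_to_stratum_size(self, small_corpus):
        cases = small_corpus["cases"]
        for t in build_tables(cases, ["10001052"]).values():
            assert t.n_total == len(cases)

    def test_exhaustive_recount_equivalence(self, small_corpus):
        """On a <= 200-case corpus the builder matches a case-by-case
        brute-force recount for every drug."""
        cases = dict(list(small_corpus["cases"].items())[:200])
        tables = build_tables(cases, ["10001052"])
        drugs = {name for c in cases.values() for name in c.drug_names()}
        assert set(tables) == drugs
        for drug in drugs:
            a = b = c_ = d = 0
            for case in cases.values():
                has_drug = drug in case.drug_names()
                has_event = "10001052" in case.pt_codes()
                if has_drug and has_event:
                    a += 1
                elif has_drug:
                    b += 1
                elif has_event:
                    c_ += 1
                else:
                    d += 1
            t = tables[drug]
            assert (t.a, t.b, t.c, t.d) == (a, b, c_, d)


class TestStratified:
    def _sex_differential_corpus(self):
        """Drug X's event co-reporting is much stronger in females."""
        from faerspv.casestore import CaseReport, DrugUse, Reaction
        cases = {}
        spec = [("F", True, True)] * 20 + [("F", True, False)] * 10 \
            + [("F", False, True)] * 5 + [("F", False, False)] * 165 \
            + [("M", True, True)] * 4 + [("M", True, False)] * 26 \
            + [("M", False, True)] * 6 + [("M", False, False)] * 164
        for i, (sex, has_x, has_t) in enumerate(spec):
            cid = str(i)
            case = CaseReport(caseid=cid, primaryid=cid + "1", fda_dt=None,
                              sex=sex)
            case.drugs = [DrugUse("X" if has_x else "Y", {"PS"})]
            case.reactions = [Reaction("10001052" if has_t else "90000001",
                                       None)]
            cases[cid] = case
        return cases

    def test_planted_sex_difference_recovered(self):
        cases = self._sex_differential_corpus()
        out = run_stratified(cases, ["10001052"], ["sex"])
        f = out[("sex", "F")]
        m = out[("sex", "M")]
        ror_f = float(f.loc[f.drug == "X", "ROR"].iloc[0])
        ror_m = float(m.loc[m.drug == "X", "ROR"].iloc[0])
        assert ror_f > ror_m

    def test_whole_corpus_stratum_matches_unstratified(self, small_corpus):
        cases = small_corpus["cases"]
        plain = signal_frame(build_tables(cases, ["10001052"]))
        via_stratum = signal_frame(
            build_tables(cases, ["10001052"], stratum=("none", "")))
        assert plain.equals(via_stratum)

    def test_stratum_without_exposure_omits_drug(self):
        cases = self._sex_differential_corpus()
        # remove drug X from every male case
        for case in cases.values():
            if case.sex == "M":
                case.drugs = [d for d in case.drugs if d.name != "X"]
        out = run_stratified(cases, ["10001052"], ["sex"])
        assert "X" not in set(out[("sex", "M")].drug)
        assert "X" in set(out[("sex", "F")].drug)


class TestRanking:
    def test_ranked_by_a_then_name(self, small_corpus):
        frame = signal_frame(build_tables(small_corpus["cases"], ["10001052"]))
        keys = list(zip(-frame["a"], frame["drug"]))
        assert keys == sorted(keys)
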