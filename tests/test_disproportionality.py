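"""Reporting odds ratio, signal criterion, ranking and label comparison."""

from __future__ import annotations

import random
from decimal import Decimal, getcontext
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.disproportionality import (
    ContingencyTable,
    EmptyTargetError,
    SignalEstimate,
    build_contingency,
    compute_ror,
    detect_signal,
    flag_new_signals,
    mapped_events,
    new_signal_table,
    rank_signals,
    run_signal_scan,
    soc_signal_counts,
    stratified_scan,
)
from tests.conftest import make_case


def ror_oracle(a, b, c, d):
    """Exact cross-ratio in rational arithmetic."""
    return Fraction(a * d, b * c)


def ci_oracle(a, b, c, d):
    """Wald interval evaluated at 50 decimal digits of precision."""
    getcontext().prec = 50
    log_ror = (Decimal(a) * Decimal(d) / (Decimal(b) * Decimal(c))).ln()
    se = (
        1 / Decimal(a) + 1 / Decimal(b) + 1 / Decimal(c) + 1 / Decimal(d)
    ).sqrt()
    z = Decimal("1.96")
    return (log_ror - z * se).exp(), (log_ror + z * se).exp()


class TestComputeRor:
    def test_equal_reporting_proportions(self):
        est = compute_ror(ContingencyTable(5, 5, 50, 50))
        assert est.ror == pytest.approx(1.0)
        assert est.ci_low < 1.0 < est.ci_high

    def test_hand_evaluated_example(self):
        est = compute_ror(ContingencyTable(10, 90, 100, 9900))
        assert est.ror == pytest.approx(11.0)
        assert est.ci_low == pytest.approx(5.5596, rel=1e-3)
        assert est.ci_high == pytest.approx(21.7643, rel=1e-3)

    @pytest.mark.parametrize(
        "table",
        [
            ContingencyTable(0, 7, 3, 100),
            ContingencyTable(7, 0, 3, 100),
            ContingencyTable(7, 3, 0, 100),
            ContingencyTable(7, 3, 100, 0),
        ],
    )
    def test_zero_cell_is_undefined(self, table):
        assert compute_ror(table) is None

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 1, 1, 1)

    def test_matches_high_precision_oracle_on_random_tables(self):
        rng = random.Random(7)
        for _ in range(1000):
            a, b, c, d = (rng.randint(1, 5000) for _ in range(4))
            est = compute_ror(ContingencyTable(a, b, c, d))
            assert est.ror == pytest.approx(float(ror_oracle(a, b, c, d)), rel=1e-12)
            lo, hi = ci_oracle(a, b, c, d)
            assert est.ci_low == pytest.approx(float(lo), rel=1e-12)
            assert est.ci_high == pytest.approx(float(hi), rel=1e-12)

    def test_matches_statsmodels_cross_check(self):
        sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = random.Random(11)
        for _ in range(50):
            a, b, c, d = (rng.randint(1, 500) for _ in range(4))
            est = compute_ror(ContingencyTable(a, b, c, d))
            t2 = sm_ct.Table2x2([[a, b], [c, d]])
            assert est.ror == pytest.approx(t2.oddsratio, rel=1e-9)
            lo, hi = t2.oddsratio_confint(0.05)
            # statsmodels recomputes the normal quantile; 1.96 is fixed here.
            assert est.ci_low == pytest.approx(lo, rel=1e-3)
            assert est.ci_high == pytest.approx(hi, rel=1e-3)

    @settings(max_examples=200, derandomize=True)
    @given(st.tuples(*[st.integers(1, 10_000)] * 4))
    def test_row_swap_symmetry(self, cells):
        """Swapping drug rows inverts the ROR and swaps/inverts the CI."""
        t = ContingencyTable(*cells)
        est, swapped = compute_ror(t), compute_ror(t.swapped_rows())
        assert swapped.ror == pytest.approx(1 / est.ror, rel=1e-9)
        assert swapped.ci_low == pytest.approx(1 / est.ci_high, rel=1e-9)
        assert swapped.ci_high == pytest.approx(1 / est.ci_low, rel=1e-9)

    def test_strictly_increasing_in_a(self):
        prev_ror, prev_low = 0.0, 0.0
        for a in range(1, 60):
            est = compute_ror(ContingencyTable(a, 50, 40, 400))
            assert est.ror > prev_ror and est.ci_low > prev_low
            prev_ror, prev_low = est.ror, est.ci_low


class TestSignalCriterion:
    def test_signal_requires_ci_and_count(self):
        strong = compute_ror(ContingencyTable(113, 1700, 3000, 280_000))
        assert strong.ci_low > 1
        assert detect_signal(strong, 113)
        assert not detect_signal(strong, 2)  # count rule
        null = compute_ror(ContingencyTable(50, 5000, 55, 5000))
        assert not detect_signal(null, 50)  # CI rule
        assert not detect_signal(None, 50)  # undefined ROR


class TestScan:
    def test_hand_counted_contingency(self, toy_meddra):
        target = [
            make_case("1", events=("Pyrexia", "Diarrhoea")),
            make_case("2", events=("Pyrexia",)),
        ]
        background = [
            make_case("3", events=("Pyrexia",)),
            make_case("4", events=("Diarrhoea",)),
        ]
        t = build_contingency(target, background, "Pyrexia", toy_meddra)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 1)

    def test_absent_pt_has_zero_a(self, toy_meddra):
        t = build_contingency(
            [make_case("1", events=("Pyrexia",))],
            [make_case("2", events=("Asthenia",))],
            "Cardiac arrest",
            toy_meddra,
        )
        assert t.a == 0

    def test_pair_conservation(self, toy_meddra):
        """Sum of a over PTs equals total target report x PT pairs."""
        target = [
            make_case("1", events=("Pyrexia", "Diarrhoea", "Renal calculus")),
            make_case("2", events=("Pyrexia", "PYREXIA")),  # collapses via mapping
        ]
        background = [make_case("3", events=("Asthenia",))]
        estimates = run_signal_scan(target, background, toy_meddra, min_count=1)
        total_pairs = sum(len(mapped_events(c, toy_meddra)) for c in target)
        assert sum(e.n for e in estimates) == total_pairs == 4

    def test_unmapped_terms_retained_without_soc(self, toy_meddra):
        estimates = run_signal_scan(
            [make_case("1", events=("Mystery syndrome",))],
            [make_case("2", events=("Pyrexia",))],
            toy_meddra,
        )
        (e,) = estimates
        assert e.pt == "Mystery syndrome" and e.soc is None

    def test_empty_target_refused(self, toy_meddra):
        with pytest.raises(EmptyTargetError):
            run_signal_scan([], [make_case("1")], toy_meddra)

    def test_single_occurrence_never_signal(self, toy_meddra):
        estimates = run_signal_scan(
            [make_case("1", events=("Pyrexia", "Diarrhoea"))],
            [make_case("2", events=("Diarrhoea",)), make_case("3", events=("Asthenia",))],
            toy_meddra,
        )
        assert all(not e.is_signal for e in estimates)


class TestStratified:
    def _cases(self):
        target = [
            make_case("1", events=("Pyrexia",), sex="F", age_years=10, country="US"),
            make_case("2", events=("Pyrexia",), sex="M", age_years=70, country="US"),
            make_case("3", events=("Diarrhoea",), sex="UNK", age_years=None),
        ]
        background = [
            make_case("4", events=("Diarrhoea",), sex="F", country="US"),
            make_case("5", events=("Pyrexia",), sex="M", country="GB"),
        ]
        return target, background

    def test_sex_strata_exclude_unknown(self, toy_meddra):
        target, background = self._cases()
        result = stratified_scan(target, background, toy_meddra, "sex")
        assert set(result) == {"Female", "Male"}
        assert sum(e.n for ests in result.values() for e in ests) == 2

    def test_within_comparator_restricts_background(self, toy_meddra):
        target, background = self._cases()
        within = stratified_scan(target, background, toy_meddra, "sex", comparator="within")
        # Male stratum: background is only case 5 (M); a=1, c=1
        (male_est,) = within["Male"]
        assert male_est.table.c == 1
        globally = stratified_scan(target, background, toy_meddra, "sex", comparator="global")
        (male_g,) = globally["Male"]
        assert male_g.table.c + male_g.table.d == 2  # both background cases

    def test_estimates_carry_stratum_label(self, toy_meddra):
        target, background = self._cases()
        result = stratified_scan(target, background, toy_meddra, "age_group")
        for label, ests in result.items():
            for e in ests:
                assert e.stratum == f"age_group:{label}"


class TestRanking:
    def _est(self, pt, ror, n, signal=True, soc="Cardiac disorders"):
        return SignalEstimate(
            pt=pt, soc=soc, stratum="overall", n=n, ror=ror,
            ci_low=ror / 2 if ror else None, ci_high=ror * 2 if ror else None,
            is_signal=signal,
        )

    def test_tie_rule(self):
        ests = [
            self._est("A", 10, 3),
            self._est("B", 7, 9),
            self._est("C", 7, 4),
            self._est("D", 2, 8),
        ]
        top = rank_signals(ests, by="ror", k=3)
        assert [e.pt for e in top] == ["A", "B", "C"]

    def test_fewer_than_k_returns_all(self):
        ests = [self._est("A", 10, 3), self._est("B", 7, 9, signal=False)]
        assert [e.pt for e in rank_signals(ests, by="count", k=5)] == ["A"]

    def test_count_ranking_orders_by_frequency(self):
        ests = [
            self._est("Asthenia", 6.24, 113),
            self._est("Fatigue", 2.08, 92),
            self._est("Death", 1.41, 69),
        ]
        top = rank_signals(ests, by="count", k=3)
        assert [e.pt for e in top] == ["Asthenia", "Fatigue", "Death"]

    def test_soc_signal_counts(self):
        ests = [
            self._est("A", 5, 10, soc="Cardiac disorders"),
            self._est("B", 5, 10, soc="Cardiac disorders"),
            self._est("C", 5, 10, soc="Eye disorders", signal=False),
        ]
        assert soc_signal_counts(ests) == {"Cardiac disorders": 2}


class TestNewSignals:
    def _signals(self):
        return [
            SignalEstimate("Diarrhoea", "Gastrointestinal disorders", "overall",
                           40, 3.0, 2.0, 4.5, True),
            SignalEstimate("Cardiac arrest", "Cardiac disorders", "overall",
                           13, 3.97, 2.30, 6.85, True),
            SignalEstimate("Oddity", "Cardiac disorders", "overall",
                           9, 5.0, 2.0, 12.0, True),
            SignalEstimate("Pyrexia", "General disorders and administration site conditions",
                           "overall", 2, 2.0, 1.1, 3.6, False),
        ]

    def test_labelled_pt_not_new(self):
        flagged = flag_new_signals(self._signals(), {"Diarrhoea", "Pyrexia"})
        by_pt = {e.pt: e for e in flagged}
        assert by_pt["Diarrhoea"].is_new is False
        assert by_pt["Cardiac arrest"].is_new is True
        assert by_pt["Pyrexia"].is_new is False  # not a signal at all

    def test_empty_label_list_flags_all_signals(self):
        flagged = flag_new_signals(self._signals(), set())
        assert all(e.is_new for e in flagged if e.is_signal)

    def test_min_n_threshold_boundary(self):
        flagged = flag_new_signals(self._signals(), {"Diarrhoea"})
        table = new_signal_table(flagged, min_n=10)
        assert [e.pt for e in table] == ["Cardiac arrest"]  # n=9 excluded
        assert any(e.pt == "Oddity" and e.is_new for e in flagged)  # retained in full
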