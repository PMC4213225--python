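"""2x2 statistics, Clopper-Pearson intervals, case-definition evaluation."""

import math

import numpy as np
import pytest
from scipy.stats import binom

import amivalid as av
from amivalid.synthetic import ITEM_AGREEMENT_COUNTS


class TestTwoByTwo:
    def test_counts_by_quadrant(self):
        tab = av.two_by_two([True, True, False, False], [True, False, True, False])
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (1, 1, 1, 1)

    def test_all_negative(self):
        tab = av.two_by_two([False] * 5, [False] * 5)
        assert (tab.tp, tab.fp, tab.fn, tab.tn) == (0, 0, 0, 5)

    def test_single_false_positive(self):
        assert av.two_by_two([True], [False]) == av.TwoByTwo(0, 1, 0, 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="align"):
            av.two_by_two([True], [True, False])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            av.TwoByTwo(-1, 0, 0, 0)


def ci_by_bisection(k, n, level=0.95, tol=1e-10):
    """Independent oracle: invert the binomial tail probabilities directly."""
    alpha = 1 - level

    def solve(f, lo, hi):
        while hi - lo > tol:
            mid = (lo + hi) / 2
            if f(mid):
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    low = 0.0 if k == 0 else solve(lambda p: binom.sf(k - 1, n, p) < alpha / 2, 0.0, 1.0)
    high = 1.0 if k == n else solve(lambda p: binom.cdf(k, n, p) >= alpha / 2, 0.0, 1.0)
    return low, high


class TestExactBinomialCI:
    def test_boundary_conventions(self):
        assert av.exact_binomial_ci(0, 10)[0] == 0.0
        assert av.exact_binomial_ci(10, 10)[1] == 1.0

    def test_small_numerator_interval_at_two_decimals(self):
        low, high = av.exact_binomial_ci(22, 24)
        assert (av.round_half_up(low), av.round_half_up(high)) == (0.73, 0.99)

    def test_large_numerator_interval_at_two_decimals(self):
        low, high = av.exact_binomial_ci(240, 248)
        assert (av.round_half_up(low), av.round_half_up(high)) == (0.94, 0.99)

    @pytest.mark.parametrize("k,n", [(0, 10), (1, 10), (5, 10), (22, 24), (240, 248), (50, 50)])
    def test_matches_tail_inversion_by_bisection(self, k, n):
        got = av.exact_binomial_ci(k, n)
        want = ci_by_bisection(k, n)
        assert got == pytest.approx(want, abs=1e-8)

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(3, 17), (22, 24), (199, 233)]:
            assert av.exact_binomial_ci(k, n) == pytest.approx(
                proportion_confint(k, n, alpha=0.05, method="beta"), abs=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            av.exact_binomial_ci(5, 4)
        with pytest.raises(ValueError):
            av.exact_binomial_ci(-1, 4)

    def test_coverage_at_nominal_level(self):
        """95% intervals cover the truth in at least 93% of simulated draws."""
        rng = np.random.default_rng(123)
        p, n = 0.9, 50
        draws = rng.binomial(n, p, size=2000)
        covered = 0
        for k in draws:
            low, high = av.exact_binomial_ci(int(k), n)
            covered += low <= p <= high
        assert covered / 2000 >= 0.93


class TestAccuracy:
    def test_aspirin_row_two_decimals(self):
        st = av.accuracy(av.TwoByTwo(293, 7, 9, 29))
        assert av.round_half_up(st.sensitivity.value) == 0.97
        assert av.round_half_up(st.ppv.value) == 0.98
        assert av.round_half_up(st.npv.value) == 0.76
        # 29/36 = 0.8056; the published table shows this cell truncated
        assert abs(st.specificity.value - 0.80) < 0.01

    def test_cabg_sensitivity_with_interval(self):
        st = av.accuracy(av.TwoByTwo(22, 2, 2, 312))
        sens = st.sensitivity
        assert av.round_half_up(sens.value) == 0.92
        assert (av.round_half_up(sens.ci_low), av.round_half_up(sens.ci_high)) == (0.73, 0.99)

    def test_perfect_two_case_table(self):
        st = av.accuracy(av.TwoByTwo(1, 0, 0, 1))
        assert all(
            getattr(st, m).value == 1.0 for m in ("sensitivity", "specificity", "ppv", "npv")
        )

    def test_equals_hand_computed_ratios_on_all_agreement_rows(self):
        for item, (tp, fp, fn, tn) in ITEM_AGREEMENT_COUNTS.items():
            st = av.accuracy(av.TwoByTwo(tp, fp, fn, tn))
            assert st.sensitivity.value == pytest.approx(tp / (tp + fn))
            assert st.specificity.value == pytest.approx(tn / (tn + fp))
            assert st.ppv.value == pytest.approx(tp / (tp + fp))
            assert st.npv.value == pytest.approx(tn / (tn + fn))
            # the point estimate always lies inside its own interval
            for m in ("sensitivity", "specificity", "ppv", "npv"):
                est = getattr(st, m)
                assert est.ci_low <= est.value <= est.ci_high

    def test_zero_denominator_metric_absent_others_returned(self):
        st = av.accuracy(av.TwoByTwo(0, 0, 0, 4))
        assert st.sensitivity is None and st.ppv is None
        assert st.specificity.value == 1.0 and st.npv.value == 1.0


class TestCaseDefinitions:
    def test_scenario_reproduces_any_antiplatelet_row(self):
        defn = av.CaseDefinition(label="any + antiplatelet", position="any", require_antiplatelet=True)
        cases = av.case_definition_scenario(defn, 338, 284, n_confirmed_total=297)
        res = av.evaluate_case_definition(defn, cases)
        assert (res.n_claims_positive, res.n_true_positive) == (338, 284)
        assert av.round_half_up(res.sensitivity) == 0.96
        assert av.round_half_up(res.ppv) == 0.84

    def test_scenario_reproduces_principal_ptca_row(self):
        defn = av.CaseDefinition(label="principal + PTCA", position="principal", require_ptca=True)
        cases = av.case_definition_scenario(defn, 194, 184, n_confirmed_total=297)
        res = av.evaluate_case_definition(defn, cases)
        assert av.round_half_up(res.sensitivity) == 0.62
        assert av.round_half_up(res.ppv) == 0.95

    def test_all_confirmed_bare_definition_is_perfect(self):
        defn = av.CaseDefinition(label="any", position="any")
        cases = av.case_definition_scenario(
            av.CaseDefinition(position="principal"), 10, 10, n_confirmed_total=10, n_filler_negative=0
        )
        res = av.evaluate_case_definition(defn, cases)
        assert res.sensitivity == 1.0 and res.ppv == 1.0

    def test_tightening_never_increases_counts(self, study_summary):
        """Adding requirements can only shrink the claims-positive set."""
        rows = study_summary["table1"]
        by_label = {r["criteria"]: r for r in rows}
        chains = [
            ("any 410 + antiplatelet", "any 410 + heparin + antiplatelet"),
            ("principal 410", "principal 410 + antiplatelet", "principal 410 + heparin + antiplatelet"),
            ("principal 410", "principal 410 + catheterization"),
        ]
        for chain in chains:
            for loose, tight in zip(chain, chain[1:]):
                assert by_label[tight]["n_claims_positive"] <= by_label[loose]["n_claims_positive"]
                assert by_label[tight]["sensitivity"] <= by_label[loose]["sensitivity"]

    def test_unadjudicated_cases_rejected(self):
        case = av.LinkedCase(
            case_id="c1",
            claims=av.ClaimsEncounter(record_id="c1", diagnoses=("410.11",)),
            chart=av.ChartEncounter(record_id="h1"),
        )
        with pytest.raises(ValueError, match="adjudication"):
            av.evaluate_case_definition(av.CaseDefinition(position="any"), [case])


def test_round_half_up_display_rule():
    assert av.round_half_up(0.955) == 0.96
    assert av.round_half_up(0.9288) == 0.93
    assert av.round_half_up(0.845) == 0.85
    assert av.round_half_up(84.31, 1) == 84.3
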