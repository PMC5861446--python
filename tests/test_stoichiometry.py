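"""Labeling/dimerization model, histograms and fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smstoich import (LabelingModel, StoichiometryMixtureModel, build_histogram,
                      expected_step_distribution, fit_geometric_tail,
                      infer_dimer_fraction, linear_relation, two_step_ratio)
from smstoich.stoichiometry import GeometricFit, per_event_label_pmf

from oracle_utils import (enumerate_step_distribution, grid_search_geometric,
                          monte_carlo_two_step_fraction, ols_by_hand)


class TestDimerInference:
    def test_zero_two_step_fraction_means_no_dimers(self):
        assert infer_dimer_fraction(0.0, 0.58) == 0.0

    def test_full_labeling_collapses_to_direct_fraction(self):
        # with every protomer labelled, the observed two-step fraction IS
        # the dimer fraction
        assert infer_dimer_fraction(0.12, 1.0) == pytest.approx(0.12, abs=1e-12)

    def test_reference_parameters_give_227_percent_dimers(self):
        d = infer_dimer_fraction(0.12, 0.58)
        assert d == pytest.approx(0.2266, abs=5e-4)

    def test_matches_forward_monte_carlo(self):
        d = infer_dimer_fraction(0.12, 0.58)
        rng = np.random.default_rng(0)
        f2_sim = monte_carlo_two_step_fraction(d, 0.58, 1_000_000, rng)
        assert f2_sim == pytest.approx(0.12, abs=3 * 0.33 / 1000)

    def test_unattainable_fraction_rejected(self):
        # at p_label=0.5 even an all-dimer population shows at most
        # p/(2-p) = 1/3 two-step spots
        with pytest.raises(ValueError, match="unattainable"):
            infer_dimer_fraction(0.5, 0.5)

    @given(f2=st.floats(0.0, 0.3), p=st.floats(0.4, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_is_exact(self, f2, p):
        if f2 >= p / (2.0 - p):
            return
        model = LabelingModel.from_observed(f2, p)
        assert model.forward_two_step_fraction() == pytest.approx(f2, abs=1e-10)


class TestExpectedStepDistribution:
    def test_single_fully_labeled_monomer_always_one_step(self):
        dist = expected_step_distribution(1, 1.0, 0.0)
        assert dist.probabilities == pytest.approx([0.0, 1.0, 0.0])

    @pytest.mark.parametrize("k", [0, 1, 2, 3])
    def test_matches_enumeration_oracle(self, k):
        p, d = 0.58, infer_dimer_fraction(0.12, 0.58)
        dist = expected_step_distribution(k, p, d)
        oracle = enumerate_step_distribution(k, p, d)
        assert dist.probabilities == pytest.approx(oracle, abs=1e-12)

    def test_two_bound_molecules_conditional_distribution(self):
        # frozen from the enumeration oracle at the reference parameters
        d = infer_dimer_fraction(0.12, 0.58)
        dist = expected_step_distribution(2, 0.58, d)
        assert dist.conditional[1:5] == pytest.approx(
            [0.4704, 0.4246, 0.0983, 0.0067], abs=5e-4)

    def test_two_bound_molecules_predict_90_percent_ratio(self):
        d = infer_dimer_fraction(0.12, 0.58)
        dist = expected_step_distribution(2, 0.58, d)
        assert dist.two_step_ratio() == pytest.approx(90.25, abs=0.1)

    @given(k=st.integers(0, 6), p=st.floats(0.05, 1.0), d=st.floats(0.0, 1.0))
    @settings(max_examples=200, deadline=None)
    def test_normalization(self, k, p, d):
        dist = expected_step_distribution(k, p, d)
        assert abs(dist.probabilities.sum() - 1.0) < 1e-12
        if dist.probabilities[0] < 1.0:
            assert abs(dist.conditional.sum() - 1.0) < 1e-9

    def test_ratio_increases_with_weight_of_two_molecule_complexes(self):
        p, d = 0.58, infer_dimer_fraction(0.12, 0.58)
        d1 = expected_step_distribution(1, p, d)
        d2 = expected_step_distribution(2, p, d)
        ratios = []
        for w2 in (0.0, 0.25, 0.5, 0.75, 1.0):
            mix = (1 - w2) * d1.probabilities[1:3].copy()
            mix = np.array([
                (1 - w2) * d1.probabilities[1] + w2 * d2.probabilities[1],
                (1 - w2) * d1.probabilities[2] + w2 * d2.probabilities[2]])
            ratios.append(mix[1] / mix[0])
        assert np.all(np.diff(ratios) > 0)


class TestHistogram:
    def test_frequencies_and_binomial_error_bars(self):
        hist = build_histogram([1] * 25, 100)
        assert hist.frequencies["1"] == pytest.approx(25.0)
        # 100*sqrt(100*0.25*0.75)/100
        assert hist.error_bars["1"] == pytest.approx(4.330127, abs=1e-5)

    def test_empty_class_has_zero_error_bar(self):
        hist = build_histogram([1] * 10, 50)
        assert hist.frequencies["3"] == 0.0
        assert hist.error_bars["3"] == 0.0

    def test_certain_class_has_zero_error_bar(self):
        hist = build_histogram([2] * 100, 100)
        assert hist.error_bars["2"] == 0.0

    def test_counts_above_five_and_x_fold_into_their_classes(self):
        hist = build_histogram([7, ">5", "x", 5, 1], 10)
        assert hist.counts[">5"] == 2
        assert hist.counts["x"] == 1
        assert hist.colocalized_fraction == pytest.approx(50.0)

    def test_rejects_more_classified_than_rna_spots(self):
        with pytest.raises(ValueError):
            build_histogram([1, 2, 3], 2)

    @given(total=st.integers(1, 10_000), count=st.integers(0, 10_000))
    @settings(max_examples=300, deadline=None)
    def test_error_bar_formula_matches_binomial_sd(self, total, count):
        if count > total:
            return
        hist = build_histogram([1] * count, total)
        p = count / total
        expected = 100.0 * np.sqrt(total * p * (1 - p)) / total
        assert hist.error_bars["1"] == pytest.approx(expected, abs=1e-12)


class TestTwoStepRatio:
    def test_direct_count_ratio(self):
        hist = build_histogram([1] * 100 + [2] * 58, 200)
        assert two_step_ratio(hist) == pytest.approx(58.0)

    def test_zero_two_step_class(self):
        hist = build_histogram([1] * 10, 20)
        assert two_step_ratio(hist) == 0.0

    def test_empty_one_step_class_raises(self):
        hist = build_histogram([2] * 10, 20)
        with pytest.raises(ValueError):
            two_step_ratio(hist)


class TestGeometricTail:
    def test_self_consistency_on_exact_geometric_counts(self):
        p = 0.3
        weights = np.array([p * (1 - p) ** i for i in range(4)])
        weights /= weights.sum()
        counts = {str(n): int(round(w * 1e6)) for n, w in zip(range(2, 6), weights)}
        fit = fit_geometric_tail(counts, support=(2, 3, 4, 5))
        assert fit.p_geo == pytest.approx(0.3, abs=1e-4)

    def test_matches_grid_search_oracle_on_uniform_counts(self):
        counts = {"2": 50, "3": 50, "4": 50, "5": 50}
        fit = fit_geometric_tail(counts, support=(2, 3, 4, 5))
        oracle = grid_search_geometric(np.array([50.0] * 4), (2, 3, 4, 5))
        assert fit.p_geo == pytest.approx(oracle, abs=1e-4)

    def test_empty_support_raises(self):
        with pytest.raises(ValueError):
            fit_geometric_tail({"2": 0, "3": 0, "4": 0, "5": 0})

    def test_all_mass_at_lower_edge_is_degenerate(self):
        fit = fit_geometric_tail({"2": 100, "3": 0, "4": 0, "5": 0})
        assert fit.degenerate
        assert fit.p_geo == 1.0


class TestMixtureModel:
    @staticmethod
    def _model():
        return LabelingModel.from_observed(0.12, 0.58)

    def test_pure_component_recovers_itself(self):
        # histogram built from the exact k=2 expected counts
        model = self._model()
        dist = model.step_distribution(2)
        labels = []
        for j in range(1, len(dist.conditional)):
            labels.extend([j] * int(round(10_000 * dist.conditional[j])))
        hist = build_histogram(labels, len(labels))
        res = StoichiometryMixtureModel(hist, model, components=(1, 2)).fit()
        assert res.observed_weights[1] >= 0.99

    def test_60_40_mixture_recovered_within_5_points(self):
        # population draw: k per complex, then unconditional step counts;
        # invisible (zero-step) complexes never enter the histogram
        model = self._model()
        rng = np.random.default_rng(2)
        n = 5000
        ks = rng.choice([1, 2], size=n, p=[0.6, 0.4])
        labels = []
        for k in ks:
            dist = model.step_distribution(int(k))
            j = int(rng.choice(len(dist.probabilities), p=dist.probabilities))
            if j >= 1:
                labels.append(j)
        hist = build_histogram(labels, n)
        res = StoichiometryMixtureModel(hist, model, components=(1, 2)).fit()
        assert res.population_weights == pytest.approx([0.6, 0.4], abs=0.05)

    def test_duplicate_components_flagged_nonidentifiable(self):
        model = self._model()
        hist = build_histogram([1] * 50 + [2] * 30, 100)
        res = StoichiometryMixtureModel(hist, model, components=(2, 2)).fit()
        assert not res.identifiable

    def test_summary_lists_components(self):
        model = self._model()
        hist = build_histogram([1] * 50 + [2] * 30, 100)
        res = StoichiometryMixtureModel(hist, model, components=(1, 2)).fit()
        text = res.summary()
        assert "k=1" in text and "k=2" in text and "log-likelihood" in text


class TestLinearRelation:
    def test_exact_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [2 * v + 1 for v in x]
        slope, intercept, r2 = linear_relation(x, y)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_response_has_zero_r2(self):
        slope, intercept, r2 = linear_relation([1, 2, 3], [5, 5, 5])
        assert r2 == 0.0

    def test_matches_hand_computed_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 5)
        y = 0.7 * x + 10 + rng.normal(0, 5, 5)
        assert linear_relation(x, y) == pytest.approx(ols_by_hand(x, y), abs=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            linear_relation([1, 2], [1, 2])


@given(p=st.floats(0.01, 1.0), d=st.floats(0.0, 1.0))
@settings(max_examples=200, deadline=None)
def test_per_event_pmf_is_a_distribution(p, d):
    q = per_event_label_pmf(p, d)
    assert abs(q.sum() - 1.0) < 1e-12
    assert np.all(q >= 0)
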