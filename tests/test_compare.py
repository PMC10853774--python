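"""Correlation scoring, distribution selection, outlier calling, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minishape import (
    ComparisonResult,
    DifferentialProfile,
    ReactivityProfile,
    RegionAnnotation,
    assign_regions,
    differential_profile,
    fit_distribution,
    iqr_outliers,
    pearson_correlation,
    rank_designs,
    simulate_profile_pair,
)
from minishape.reactivity import MISSING
from minishape.errors import DegeneracyError, SpecificationError, StateError


def _unit(values):
    return ReactivityProfile(np.asarray(values, float), state="unit_scaled")


class TestPearson:
    def test_identical_profiles_correlate_perfectly(self):
        prof = _unit([0.1, 0.5, 0.9, 0.3, 0.7])
        assert pearson_correlation(prof, prof).rho == pytest.approx(1.0)

    def test_reflected_profile_anticorrelates(self):
        x = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        assert pearson_correlation(_unit(x), _unit(1 - x)).rho == pytest.approx(-1.0)

    def test_monte_carlo_recovery_of_target_correlation(self):
        """Mean sample correlation over 200 seeds at n=284 recovers the
        simulated population correlation within +-0.05."""
        rhos = [
            pearson_correlation(*simulate_profile_pair(284, 0.6, seed)[:2]).rho
            for seed in range(200)
        ]
        assert abs(np.mean(rhos) - 0.6) < 0.05

    def test_noise_adjustment_disattenuates_upward(self):
        exp, pred, _ = simulate_profile_pair(284, 0.6, 0)
        noise = np.full(284, 0.05)
        res = pearson_correlation(exp, pred, noise=noise)
        assert res.rho_noise_adjusted >= res.rho
        assert res.rho_noise_adjusted <= 1.0

    def test_too_few_complete_pairs_raises(self):
        a = _unit([0.1, MISSING, MISSING, 0.5])
        b = _unit([0.2, 0.3, 0.4, 0.5])
        with pytest.raises(DegeneracyError):
            pearson_correlation(a, b)

    def test_zero_variance_raises(self):
        with pytest.raises(DegeneracyError):
            pearson_correlation(_unit([0.5, 0.5, 0.5]), _unit([0.1, 0.2, 0.3]))


class TestDifferential:
    def test_identical_profiles_give_zero_deltas(self):
        prof = _unit([0.1, 0.5, 0.9])
        assert np.allclose(differential_profile(prof, prof).deltas, 0.0)

    def test_maximal_underprediction_is_plus_one(self):
        d = differential_profile(_unit([1.0, 0.0]), _unit([0.0, 1.0]))
        assert d.deltas[0] == pytest.approx(1.0)
        assert d.deltas[1] == pytest.approx(-1.0)

    def test_elementwise_equality_with_brute_force(self):
        rng = np.random.default_rng(9)
        a, b = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        d = differential_profile(_unit(a), _unit(b))
        assert np.allclose(d.deltas, a - b)

    def test_antisymmetry(self):
        rng = np.random.default_rng(10)
        a, b = _unit(rng.uniform(0, 1, 30)), _unit(rng.uniform(0, 1, 30))
        assert np.allclose(
            differential_profile(a, b).deltas, -differential_profile(b, a).deltas
        )

    def test_missing_in_either_input_is_missing_in_output(self):
        a = _unit([0.1, MISSING, 0.9])
        b = _unit([0.2, 0.3, MISSING])
        d = differential_profile(a, b)
        assert d.deltas[1] == MISSING and d.deltas[2] == MISSING

    def test_unscaled_state_rejected(self):
        raw = ReactivityProfile(np.array([0.1, 0.2]), state="raw")
        with pytest.raises(StateError):
            differential_profile(raw, raw)


class TestDistributionFit:
    def test_heavy_tailed_sample_selects_cauchy_over_normal(self):
        """Samples from a heavy-tailed location-scale law at loc 0, scale
        0.1: the Cauchy family must outrank the Normal and recover the
        parameters within +-0.02."""
        rng = np.random.default_rng(12)
        data = rng.standard_cauchy(5000) * 0.1
        fits = fit_distribution(data, ["cauchy", "norm"])
        assert fits[0].family == "cauchy"
        assert abs(fits[0].location) < 0.02
        assert abs(fits[0].scale - 0.1) < 0.02

    def test_gaussian_sample_selects_normal_over_cauchy(self):
        rng = np.random.default_rng(13)
        data = rng.normal(0, 0.1, 5000)
        fits = fit_distribution(data, ["cauchy", "norm"])
        assert fits[0].family == "norm"

    def test_identical_candidates_tie_in_input_order(self):
        rng = np.random.default_rng(14)
        data = rng.normal(0, 0.1, 500)
        fits = fit_distribution(data, ["norm", "norm"])
        assert fits[0].goodness == fits[1].goodness
        assert [f.family for f in fits] == ["norm", "norm"]

    def test_constant_deltas_degenerate(self):
        with pytest.raises(DegeneracyError):
            fit_distribution(np.zeros(100), ["cauchy", "norm"])


def brute_force_quantile(data, q):
    """Independent linear-interpolation quantile between order statistics."""
    xs = sorted(data)
    h = (len(xs) - 1) * q
    lo, hi = int(np.floor(h)), int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestIQROutliers:
    def test_hand_computed_quartiles_and_fences(self):
        data = np.array([-0.2, -0.1, 0.0, 0.1, 0.2])
        report = iqr_outliers(DifferentialProfile(data))
        assert report.q1 == pytest.approx(brute_force_quantile(data, 0.25))
        assert report.q3 == pytest.approx(brute_force_quantile(data, 0.75))
        assert report.upper_fence == pytest.approx(report.q3 + 3 * report.iqr)
        assert report.lower_fence == pytest.approx(report.q1 - 3 * report.iqr)
        assert len(report.outliers) == 0

    def test_single_planted_extreme_is_the_only_outlier(self):
        rng = np.random.default_rng(15)
        data = rng.uniform(-0.05, 0.05, 100)
        base = iqr_outliers(DifferentialProfile(data))
        data[42] = base.q3 + 10 * base.iqr
        report = iqr_outliers(DifferentialProfile(data))
        assert [(o.position, o.sign) for o in report.outliers] == [(43, "high")]

    def test_nine_planted_outliers_recovered_without_false_positives(self):
        """Heavy-tailed deltas clipped inside the fences, with nine planted
        far beyond both fences: exactly the nine are called."""
        rng = np.random.default_rng(16)
        data = np.clip(rng.standard_cauchy(284) * 0.05, -0.3, 0.3)
        positions = [10, 30, 50, 80, 120, 160, 200, 240, 280]
        for i, pos in enumerate(positions):
            data[pos - 1] = 0.95 if i % 2 == 0 else -0.95
        report = iqr_outliers(DifferentialProfile(data))
        assert sorted(o.position for o in report.outliers) == positions
        signs = {o.position: o.sign for o in report.outliers}
        assert signs[10] == "high" and signs[30] == "low"

    def test_absolute_mode_uses_symmetric_fences(self):
        data = np.array([-0.2, -0.1, 0.0, 0.1, 0.2, 0.7])
        report = iqr_outliers(DifferentialProfile(data), mode="absolute")
        assert report.upper_fence == pytest.approx(-report.lower_fence)

    def test_fence_ordering_invariant(self):
        rng = np.random.default_rng(17)
        report = iqr_outliers(DifferentialProfile(rng.normal(0, 0.2, 200)))
        assert report.lower_fence <= report.q1 <= report.q3 <= report.upper_fence

    @given(mult=st.floats(min_value=1.0, max_value=2.9))
    @settings(max_examples=25, deadline=None)
    def test_widening_the_multiplier_never_adds_outliers(self, mult):
        rng = np.random.default_rng(18)
        deltas = DifferentialProfile(rng.standard_cauchy(150) * 0.1)
        narrow = {o.position for o in iqr_outliers(deltas, multiplier=mult).outliers}
        wide = {o.position for o in iqr_outliers(deltas, multiplier=mult + 1).outliers}
        assert wide <= narrow

    def test_insufficient_data_raises(self):
        with pytest.raises(SpecificationError):
            iqr_outliers(DifferentialProfile(np.array([0.1, 0.2, 0.3])))


class TestRegionAssignment:
    def _report_for(self, labels):
        values = np.zeros(len(labels) + 20)
        values[: len(labels)] = 5.0  # far outliers
        deltas = DifferentialProfile(
            values, labels=tuple(labels) + tuple(range(1000, 1020))
        )
        return iqr_outliers(deltas)

    def test_central_loop_residue_assigned(self):
        from minishape import DEFAULT_REGIONS

        report = assign_regions(self._report_for([2453]), DEFAULT_REGIONS)
        assert report.outliers[0].region == "central loop"
        assert report.regions_hit == ("central loop",)

    def test_label_in_no_region_is_unassigned(self):
        from minishape import DEFAULT_REGIONS

        report = assign_regions(self._report_for([9999]), DEFAULT_REGIONS)
        assert report.outliers[0].region == "unassigned"

    def test_overlapping_regions_first_declared_wins(self):
        regions = [
            RegionAnnotation("first", frozenset([2453, 2454])),
            RegionAnnotation("second", frozenset([2453])),
        ]
        report = assign_regions(self._report_for([2453]), regions)
        # brute-force membership scan oracle
        expected = next(r.name for r in regions if 2453 in r.positions)
        assert report.outliers[0].region == expected == "first"


class TestRanking:
    RHOS = {
        "WT": 0.61,
        "1.1": 0.75,
        "1.2": 0.53,
        "1.3": 0.69,
        "1.4": 0.68,
        "1.5": 0.48,
        "1.6": 0.68,
        "1.7": 0.45,
    }

    def _entries(self, rhos):
        return {
            name: ComparisonResult(rho=r, rho_noise_adjusted=r, n_positions=284)
            for name, r in rhos.items()
        }

    def test_design_table_flags_improved_and_worse(self):
        ranked = rank_designs(self._entries(self.RHOS), "WT")
        assert ranked[0].design_name == "1.1"
        improved = {d.design_name for d in ranked if d.flag == "improved"}
        worse = {d.design_name for d in ranked if d.flag == "worse"}
        assert improved == {"1.1", "1.3", "1.4", "1.6"}
        assert worse == {"1.2", "1.5", "1.7"}

    def test_single_reference_entry_has_no_flags(self):
        ranked = rank_designs(self._entries({"WT": 0.61}), "WT")
        assert len(ranked) == 1 and ranked[0].flag == "reference"

    def test_ties_stable_by_design_name(self):
        ranked = rank_designs(self._entries({"b": 0.5, "a": 0.5, "WT": 0.4}), "WT")
        assert [d.design_name for d in ranked[:2]] == ["a", "b"]
        assert {ranked[0].flag, ranked[1].flag} == {"improved"}

    def test_output_is_permutation_of_input(self):
        ranked = rank_designs(self._entries(self.RHOS), "WT")
        assert {d.design_name for d in ranked} == set(self.RHOS)

    def test_missing_reference_raises(self):
        with pytest.raises(SpecificationError):
            rank_designs(self._entries({"a": 0.5}), "WT")
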