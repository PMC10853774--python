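"""Background subtraction, normalization, scaling and reactivity classes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minishape import (
    HeatmapThresholds,
    MISSING,
    RawMeasurement,
    ReactivityProfile,
    classify_reactivity,
    count_reactive_paired,
    normalize_to_hairpins,
    parse_dotbracket,
    scale_unit,
    subtract_background,
)
from minishape.errors import (
    AlignmentError,
    DegeneracyError,
    NormalizationError,
    StateError,
    StructureError,
)


def _mods(arrays):
    return [RawMeasurement(a, "modified", f"m{i}") for i, a in enumerate(arrays)]


def _ctls(arrays):
    return [RawMeasurement(a, "control", f"c{i}") for i, a in enumerate(arrays)]


class TestBackgroundSubtraction:
    def test_identical_conditions_give_zero_profile(self):
        vals = np.array([1.0, 2.0, 3.0])
        prof = subtract_background(_mods([vals]), _ctls([vals]))
        assert np.allclose(prof.values, 0.0)
        assert prof.state == "background_subtracted"

    def test_replicate_means_recovered_with_propagated_error(self):
        """3 modified + 2 control replicates: the value is the difference of
        the two replicate means and the error the quadrature sum of the two
        standard errors of the mean (closed-form oracle)."""
        rng = np.random.default_rng(11)
        truth = np.array([0.5, 1.5, 2.5, 0.8])
        mods = [truth + rng.normal(0, 0.1, 4) + 0.2 for _ in range(3)]
        ctls = [np.full(4, 0.2) + rng.normal(0, 0.1, 4) for _ in range(2)]
        mods = [np.clip(m, 0, None) for m in mods]
        ctls = [np.clip(c, 0, None) for c in ctls]
        prof = subtract_background(_mods(mods), _ctls(ctls))
        mean_mod = np.mean(mods, axis=0)
        mean_ctl = np.mean(ctls, axis=0)
        expected = np.clip(mean_mod - mean_ctl, 0, None)
        sem = lambda stack: np.std(stack, axis=0, ddof=1) / np.sqrt(len(stack))
        expected_err = np.hypot(sem(np.array(mods)), sem(np.array(ctls)))
        assert np.allclose(prof.values, expected)
        assert np.allclose(prof.errors, expected_err)
        # recovered means lie within the population error of the difference:
        # sd 0.1 per replicate, so SE(diff) = 0.1 * sqrt(1/3 + 1/2)
        assert np.all(
            np.abs(prof.values - truth) <= 4 * 0.1 * np.sqrt(1 / 3 + 1 / 2)
        )

    def test_control_exceeding_modification_clamps_to_zero(self):
        prof = subtract_background(
            _mods([np.array([0.1, 1.0])]), _ctls([np.array([0.5, 0.2])])
        )
        assert prof.values[0] == 0.0 and prof.values[1] == pytest.approx(0.8)

    def test_missing_positions_propagate(self):
        prof = subtract_background(
            _mods([np.array([MISSING, 1.0])]), _ctls([np.array([0.2, 0.2])])
        )
        assert prof.values[0] == MISSING

    def test_replicate_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            subtract_background(
                _mods([np.array([1.0, 2.0])]), _ctls([np.array([1.0])])
            )


class TestHairpinNormalization:
    def _profile(self, values):
        return ReactivityProfile(values, state="background_subtracted")

    def test_reference_mean_two_halves_everything(self):
        prof = self._profile(np.array([2.0, 2.0, 4.0, 1.0]))
        out = normalize_to_hairpins(prof, [1, 2])
        assert np.allclose(out.values, [1.0, 1.0, 2.0, 0.5])

    def test_reference_mean_is_exactly_one_after(self):
        rng = np.random.default_rng(3)
        prof = self._profile(rng.uniform(0.5, 3.0, 50))
        out = normalize_to_hairpins(prof, range(1, 11))
        assert np.mean(out.values[:10]) == pytest.approx(1.0)

    def test_known_scale_factor_recovered(self):
        """Scaling the input by s leaves the normalized output unchanged
        (algebraic oracle: normalization divides s back out)."""
        rng = np.random.default_rng(4)
        base = rng.uniform(0.1, 2.0, 30)
        for s in (0.5, 3.0, 17.0):
            out_base = normalize_to_hairpins(self._profile(base), [1, 2, 3])
            out_scaled = normalize_to_hairpins(self._profile(s * base), [1, 2, 3])
            assert np.allclose(out_base.values, out_scaled.values)

    def test_nonpositive_reference_mean_raises(self):
        prof = self._profile(np.array([0.0, 0.0, 1.0]))
        with pytest.raises(NormalizationError):
            normalize_to_hairpins(prof, [1, 2])

    def test_wrong_state_raises(self):
        prof = ReactivityProfile(np.array([1.0, 2.0]), state="raw")
        with pytest.raises(StateError):
            normalize_to_hairpins(prof, [1])


class TestUnitScaling:
    def test_simple_example(self):
        prof = ReactivityProfile(
            np.array([0.0, 2.0, 4.0]), state="hairpin_normalized"
        )
        assert np.allclose(scale_unit(prof).values, [0.0, 0.5, 1.0])

    def test_profile_already_spanning_unit_interval_unchanged(self):
        prof = ReactivityProfile(
            np.array([0.0, 0.3, 1.0]), state="hairpin_normalized"
        )
        assert np.allclose(scale_unit(prof).values, prof.values)

    def test_idempotence(self):
        rng = np.random.default_rng(5)
        prof = ReactivityProfile(rng.uniform(0, 3, 40), state="hairpin_normalized")
        once = scale_unit(prof)
        twice = scale_unit(once)
        assert np.allclose(once.values, twice.values)

    def test_constant_profile_is_degenerate(self):
        prof = ReactivityProfile(np.full(5, 2.0), state="hairpin_normalized")
        with pytest.raises(DegeneracyError):
            scale_unit(prof)

    def test_missing_values_excluded_from_range(self):
        prof = ReactivityProfile(
            np.array([MISSING, 1.0, 3.0]), state="hairpin_normalized"
        )
        out = scale_unit(prof)
        assert out.values[0] == MISSING
        assert np.allclose(out.values[1:], [0.0, 1.0])


class TestClassification:
    @pytest.mark.parametrize(
        "value, kind, expected",
        [
            (1.6, "experimental", "high"),
            (0.4, "experimental", "low"),
            (1.5, "experimental", "intermediate"),  # strict inequality
            (0.5, "experimental", "intermediate"),
            (0.6, "predicted", "high"),
            (0.2, "predicted", "low"),
            (MISSING, "experimental", "missing"),
        ],
    )
    def test_category_boundaries(self, value, kind, expected):
        prof = ReactivityProfile(np.array([value]))
        assert classify_reactivity(prof, kind=kind) == [expected]

    def test_partition_every_position_exactly_once(self):
        rng = np.random.default_rng(6)
        prof = ReactivityProfile(rng.uniform(0, 3, 200))
        cats = classify_reactivity(prof)
        assert len(cats) == 200
        assert set(cats) <= {"high", "intermediate", "low"}


class TestPairedReactivity:
    def test_all_paired_below_threshold(self):
        structure = "((((....))))"
        prof = ReactivityProfile(np.full(12, 0.1))
        reactive, paired, frac = count_reactive_paired(prof, structure)
        assert (reactive, paired, frac) == (0, 8, 0.0)

    def test_seventeen_of_140_paired_is_12_1_percent(self):
        """Fixture with 140 paired positions of which 17 clear the
        significance predicate."""
        structure = "(" * 70 + "...." + ")" * 70  # 140 paired + 4 loop
        values = np.full(144, 0.1)
        values[:17] = 2.0  # 17 reactive paired positions
        values[70:74] = 2.0  # loop reactivity does not count
        prof = ReactivityProfile(values)
        reactive, paired, frac = count_reactive_paired(prof, structure)
        assert (reactive, paired) == (17, 140)
        assert frac == 12.1

    def test_random_instance_matches_brute_force(self):
        rng = np.random.default_rng(7)
        structure = "((..((...))..))" * 4
        values = rng.uniform(0, 2, len(structure))
        prof = ReactivityProfile(values)
        reactive, paired, frac = count_reactive_paired(prof, structure)
        partner = parse_dotbracket(structure)
        brute_paired = sum(p is not None for p in partner)
        brute_reactive = sum(
            p is not None and v > 0.5 for p, v in zip(partner, values)
        )
        assert (reactive, paired) == (brute_reactive, brute_paired)
        assert frac == round(100 * brute_reactive / brute_paired, 1)

    def test_unbalanced_dotbracket_raises(self):
        prof = ReactivityProfile(np.zeros(3))
        with pytest.raises(StructureError):
            count_reactive_paired(prof, "(()")
        with pytest.raises(StructureError):
            count_reactive_paired(prof, "())")


@given(scale=st.floats(min_value=0.01, max_value=100.0))
@settings(max_examples=30, deadline=None)
def test_hairpin_normalization_scale_invariance(scale):
    """normalize(c * x) == normalize(x) for any c > 0."""
    rng = np.random.default_rng(8)
    base = rng.uniform(0.1, 2.0, 25)
    a = normalize_to_hairpins(
        ReactivityProfile(base, state="background_subtracted"), [1, 2, 3]
    )
    b = normalize_to_hairpins(
        ReactivityProfile(scale * base, state="background_subtracted"), [1, 2, 3]
    )
    assert np.allclose(a.values, b.values)
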