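"""Group statistics: z-scores, bootstrap, effect sizes, rank-sum, trajectories."""

import numpy as np
import pytest

from conftest import brute_force_ranksum_p
from foldmorph.errors import ConfigurationError, DegenerateFitError, DomainError
from foldmorph.stats import (
    bootstrap_means,
    compare_cohorts,
    effect_size_d,
    ranksum_p,
    trajectory_points,
    zscore_to_reference,
)
from foldmorph.synth import CohortSpec, generate_cohort


class TestZScore:
    def test_reference_mean_maps_to_zero(self):
        ref = [1.0, 2.0, 3.0]
        assert zscore_to_reference(2.0, ref) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # reference {0, 2}: mean 1, sd sqrt(2); value 1 + sqrt(2) -> z = 1
        assert zscore_to_reference(1 + np.sqrt(2), [0.0, 2.0]) == pytest.approx(1.0)

    def test_self_zscores_standardized(self):
        rng = np.random.default_rng(0)
        v = rng.normal(5, 3, 100)
        z = zscore_to_reference(v, v)
        assert z.mean() == pytest.approx(0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_zero_spread_reference_rejected(self):
        with pytest.raises(DegenerateFitError):
            zscore_to_reference(1.0, [2.0, 2.0])

    def test_log_base_invariance(self):
        """z-scores are unchanged by an affine rescaling such as a log-base switch."""
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, 50)
        ref = rng.normal(0, 1, 50)
        np.testing.assert_allclose(
            zscore_to_reference(v, ref),
            zscore_to_reference(v * np.log(10), ref * np.log(10)),
            atol=1e-12,
        )


class TestBootstrap:
    def test_constant_sample_bootstraps_to_constant(self):
        boots = bootstrap_means(np.full(7, 3.25), n_boot=100, seed=0)
        np.testing.assert_array_equal(boots, 3.25)
        assert len(boots) == 100

    def test_seed_determinism(self):
        v = np.arange(20.0)
        np.testing.assert_array_equal(
            bootstrap_means(v, seed=42), bootstrap_means(v, seed=42)
        )

    def test_bootstrap_mean_consistency(self):
        rng = np.random.default_rng(2)
        v = rng.normal(10, 2, 10_000)
        boots = bootstrap_means(v, n_boot=100, seed=3)
        se = v.std(ddof=1) / np.sqrt(len(v) * 100)
        assert boots.mean() == pytest.approx(v.mean(), abs=5 * se * np.sqrt(100))

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            bootstrap_means([])


class TestEffectSize:
    def test_swap_flips_sign_exactly(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 100), rng.normal(0.5, 1, 100)
        assert effect_size_d(a, b) == -effect_size_d(b, a)

    def test_unit_shift_recovered(self):
        rng = np.random.default_rng(5)
        ref = rng.normal(0, 1, 200)
        z_ref = zscore_to_reference(ref, ref)
        z_cmp = zscore_to_reference(ref + ref.std(ddof=1), ref)
        d = effect_size_d(
            bootstrap_means(z_ref, seed=6), bootstrap_means(z_cmp, seed=7)
        )
        assert d == pytest.approx(1.0, abs=0.1)

    def test_identical_cohorts_near_zero(self):
        rng = np.random.default_rng(8)
        v = rng.normal(0, 1, 200)
        z = zscore_to_reference(v, v)
        d = effect_size_d(bootstrap_means(z, seed=9), bootstrap_means(z, seed=10))
        assert abs(d) < 0.05


class TestRankSum:
    def test_separated_triples_exact_p(self):
        assert ranksum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_p_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(2, 6), rng.integers(2, 7)
        a = rng.normal(0, 1, n)
        b = rng.normal(0.5, 1, m)
        assert ranksum_p(a, b) == pytest.approx(brute_force_ranksum_p(a, b), abs=1e-12)

    def test_large_shifted_samples_highly_significant(self):
        rng = np.random.default_rng(9)
        assert ranksum_p(rng.normal(0, 1, 100), rng.normal(1, 1, 100)) < 1e-3

    def test_p_symmetric_under_swap(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 30), rng.normal(0.3, 1, 25)
        assert ranksum_p(a, b) == pytest.approx(ranksum_p(b, a), abs=1e-12)

    def test_tied_small_samples_fall_back_to_approximation(self):
        # ties preclude exact enumeration; the corrected approximation must
        # still see no difference between identical samples
        p = ranksum_p([1, 1, 2], [1, 2, 2])
        assert 0.3 < p <= 1.0


class TestCompareCohorts:
    def test_reference_against_itself_is_null(self):
        t = generate_cohort(CohortSpec(n_subjects=100, seed=1))
        effects = compare_cohorts(t, t, ("K", "I", "S"), seed=2)
        for e in effects:
            assert abs(e.d) < 0.05
            assert not e.significant

    def test_seeded_reproducibility(self):
        a = generate_cohort(CohortSpec(n_subjects=40, seed=3))
        b = generate_cohort(CohortSpec(n_subjects=40, seed=4, group="patient"))
        e1 = compare_cohorts(a, b, ("K", "S"), seed=5)
        e2 = compare_cohorts(a, b, ("K", "S"), seed=5)
        for x, y in zip(e1, e2):
            assert x.d == y.d and x.p == y.p
            np.testing.assert_array_equal(x.boot_ref, y.boot_ref)

    def test_pure_thickness_shift_propagates_linearly(self):
        """A delta in logT2 lands on (K, I, S) via the basis coefficients."""
        ref = generate_cohort(CohortSpec(n_subjects=150, seed=6))
        shifted = ref.copy()
        delta = 0.02  # in logT2
        shifted.data["T_mm"] = shifted.data["T_mm"] * 10 ** (delta / 2)
        effects = {
            e.measure: e
            for e in compare_cohorts(ref, shifted, ("logT2", "K", "I", "S"), seed=7)
        }
        from foldmorph.components import components_table

        aug = components_table(ref, log_columns=True)
        for meas, coeff in (("logT2", 1.0), ("K", 0.25), ("I", 1.0), ("S", -2.25)):
            expected = delta * coeff / aug[meas].std(ddof=1)
            assert effects[meas].d == pytest.approx(expected, abs=0.05), meas

    def test_imposed_component_offsets_recovered(self):
        imposed = np.array([0.35, -0.4, 0.48])
        errs = []
        for rep in range(10):
            ref = generate_cohort(CohortSpec(n_subjects=60, seed=100 + 2 * rep))
            cmp_ = generate_cohort(
                CohortSpec(
                    n_subjects=60,
                    seed=101 + 2 * rep,
                    group="patient",
                    group_offsets=tuple(imposed),
                    offsets_in_sd=True,
                )
            )
            effects = compare_cohorts(ref, cmp_, ("K", "I", "S"), seed=rep)
            errs.append([e.d for e in effects] - imposed)
        np.testing.assert_allclose(np.mean(errs, axis=0), 0, atol=0.12)

    def test_recovery_bias_shrinks_with_n(self):
        imposed = np.array([0.3, -0.3, 0.3])
        bias = {}
        for n_subj in (25, 60, 250):
            errs = []
            for rep in range(6):
                ref = generate_cohort(CohortSpec(n_subjects=n_subj, seed=500 + rep))
                cmp_ = generate_cohort(
                    CohortSpec(n_subjects=n_subj, seed=600 + rep, group="b",
                               group_offsets=tuple(imposed), offsets_in_sd=True)
                )
                effects = compare_cohorts(ref, cmp_, ("K", "I", "S"), seed=rep)
                errs.append([e.d for e in effects] - imposed)
            bias[n_subj] = np.abs(np.mean(errs, axis=0)).max()
        assert bias[250] < bias[25] + 0.05  # no growth; large n is tight
        assert bias[250] < 0.08

    def test_unknown_measure_rejected(self):
        t = generate_cohort(CohortSpec(n_subjects=10, seed=11))
        with pytest.raises(ConfigurationError, match="unknown measure"):
            compare_cohorts(t, t, ("K", "GI"))


class TestTrajectories:
    def _effects(self, d_k, d_s, d_i):
        from foldmorph.stats import GroupEffect

        return [
            GroupEffect(m, d, 0.5, np.zeros(1), np.zeros(1), 10, 10)
            for m, d in (("K", d_k), ("S", d_s), ("I", d_i))
        ]

    def test_reference_sits_at_origin(self):
        pts = trajectory_points({"tle": self._effects(0.35, 0.48, -0.4)})
        assert pts[0].coordinates == (0.0, 0.0, 0.0)

    def test_condition_coordinates_are_its_effect_sizes(self):
        pts = trajectory_points({"tle": self._effects(0.35, 0.48, -0.4)})
        assert pts[1].coordinates == pytest.approx((0.35, 0.48, -0.4))

    def test_mirror_conditions_reflect_across_s_i_plane(self):
        pts = trajectory_points(
            {"up": self._effects(0.5, 0.2, 0.1), "down": self._effects(-0.5, 0.2, 0.1)}
        )
        up, down = pts[1], pts[2]
        assert up.d_K == -down.d_K
        assert (up.d_S, up.d_I) == (down.d_S, down.d_I)

    def test_missing_component_rejected(self):
        effects = self._effects(0.1, 0.2, 0.3)[:2]
        with pytest.raises(ConfigurationError, match="lacks"):
            trajectory_points({"x": effects})
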