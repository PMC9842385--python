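"""Permutation tests, FDR, scene-specificity null, and control ANOVAs."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import pisckit as pk
from pisckit.inference import (
    PermutationConfig,
    _mixed_anova_ss,
    bh_fdr,
    grouplabel_test,
    scene_shuffle_null,
    scene_subset_comparison,
    signflip_test,
    univariate_control,
    within_group_reliability,
)


def exact_signflip_p(values, tail="greater"):
    """Enumeration oracle over all 2^n sign patterns."""
    v = np.asarray(values, float)
    obs = v.mean()
    stats_ = [
        np.mean(np.array(signs) * v)
        for signs in itertools.product([-1.0, 1.0], repeat=len(v))
    ]
    stats_ = np.array(stats_)
    if tail == "greater":
        return np.mean(stats_ >= obs)
    if tail == "less":
        return np.mean(stats_ <= obs)
    return np.mean(np.abs(stats_) >= abs(obs))


class TestSignflip:
    def test_constant_positive_values_minimal_p(self):
        res = signflip_test(
            np.full(10, 2.5), PermutationConfig(1000, seed=0)
        )
        # only the all-positive flip (and at most its mirror) reaches obs
        assert res.p <= 0.01

    def test_exact_enumeration_matches_oracle(self, rng):
        v = rng.standard_normal(8)
        res = signflip_test(v, PermutationConfig(1000, seed=0), exact=True)
        assert res.p == pytest.approx(exact_signflip_p(v), abs=1e-12)

    def test_symmetric_values_half_p(self):
        v = np.array([1.0, -1.0, 0.5, -0.5, 2.0, -2.0])
        res = signflip_test(v, PermutationConfig(2000, seed=1), exact=True)
        assert res.p == pytest.approx(0.5, abs=0.1)

    def test_all_zero_values_p_one(self):
        with pytest.warns(UserWarning):
            res = signflip_test(np.zeros(5), PermutationConfig(500, seed=0))
        assert res.p == 1.0

    def test_p_floor_and_determinism(self, rng):
        v = rng.standard_normal(12) + 5
        cfg = PermutationConfig(500, seed=42)
        r1 = signflip_test(v, cfg)
        r2 = signflip_test(v, cfg)
        assert r1.p == r2.p >= 1 / 501
        assert np.array_equal(r1.null, r2.null)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            signflip_test(np.array([1.0, 2.0]), PermutationConfig(500))


class TestGroupLabel:
    def test_identical_groups_large_p(self, rng):
        v = rng.standard_normal(10)
        res = grouplabel_test(v, v.copy(), PermutationConfig(1000, seed=0))
        assert res.p >= 0.4

    def test_huge_shift_minimal_p(self, rng):
        b = rng.standard_normal(5)
        a = b + 100.0
        res = grouplabel_test(a, b, PermutationConfig(1000, seed=0))
        # only relabelings reproducing the original split (1 in C(10,5))
        # can reach the observed statistic
        expected_max = (1 + 1000 / 252 * 3) / 1001
        assert res.p <= expected_max

    def test_group_swap_maps_tails(self, rng):
        a = rng.standard_normal(6) + 1
        b = rng.standard_normal(7)
        pg = grouplabel_test(a, b, PermutationConfig(4000, seed=3)).p
        pl = grouplabel_test(
            b, a, PermutationConfig(4000, seed=3, tail="less")
        ).p
        # different permutation streams: equality is only up to MC error
        assert pg == pytest.approx(pl, abs=0.03)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            grouplabel_test(np.array([1.0]), np.ones(4),
                            PermutationConfig(500))


class TestBhFdr:
    def test_hand_computed_case(self):
        rejected, q = bh_fdr(np.array([0.01, 0.02, 0.9]), 0.05)
        np.testing.assert_array_equal(rejected, [True, True, False])
        np.testing.assert_allclose(q[:2], [0.03, 0.03])

    def test_all_ones_nothing_rejected(self):
        rejected, _ = bh_fdr(np.ones(6), 0.05)
        assert not rejected.any()

    def test_empty_input(self):
        rejected, q = bh_fdr(np.array([]))
        assert rejected.size == 0 and q.size == 0

    @given(
        st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=20),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_q_values_order_invariant(self, pvals, random):
        p = np.array(pvals)
        perm = np.arange(len(p))
        random.shuffle(perm)
        _, q1 = bh_fdr(p)
        _, q2 = bh_fdr(p[perm])
        np.testing.assert_allclose(q1[perm], q2, atol=1e-12)


class TestSceneShuffle:
    def test_single_scene_subset_rejected(self, tiny_spec):
        ds = pk.simulate_dataset(tiny_spec)
        with pytest.raises(ValueError):
            scene_shuffle_null(ds, 0, [0], PermutationConfig(100, seed=0))

    def test_deterministic_null(self, tiny_spec):
        ds = pk.simulate_dataset(tiny_spec)
        cfg = PermutationConfig(100, seed=5, scheme="scene_label")
        r1 = scene_shuffle_null(ds, 0, "critical", cfg)
        r2 = scene_shuffle_null(ds, 0, "critical", cfg)
        assert np.array_equal(r1.null, r2.null)
        assert r1.p == r2.p

    def test_group_level_variant_runs(self, tiny_spec):
        ds = pk.simulate_dataset(tiny_spec)
        cfg = PermutationConfig(100, seed=5, scheme="scene_label")
        res = scene_shuffle_null(ds, 0, "critical", cfg, per_subject=False)
        assert 0 < res.p <= 1

    def test_discriminates_scene_specific_from_generic(self):
        """Scene-specific planted signal is detected; a purely scene-generic
        shift of equal amplitude is not."""
        base = dict(n_rois=1, n_voxels=40, update_fraction=1.0)
        specific, generic = [], []
        for s in range(5):
            ds = pk.simulate_dataset(
                pk.SyntheticSpec(a_interp=2.0, a_generic=0.0, seed=s, **base)
            )
            specific.append(
                scene_shuffle_null(
                    ds, 0, "critical", PermutationConfig(500, seed=s)
                ).p
            )
            ds = pk.simulate_dataset(
                pk.SyntheticSpec(a_interp=0.0, a_generic=2.0, seed=s, **base)
            )
            generic.append(
                scene_shuffle_null(
                    ds, 0, "critical", PermutationConfig(500, seed=s)
                ).p
            )
        assert np.median(specific) < 0.025
        assert np.median(generic) > 0.1


class TestSceneSubsetComparison:
    def test_identical_subsets_zero_t(self, rng):
        x = rng.standard_normal(6)
        out = scene_subset_comparison({"critical": x, "all": x.copy()})
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "note"] == "zero-variance difference"

    def test_constant_offset_flagged(self, rng):
        x = rng.standard_normal(6)
        out = scene_subset_comparison({"critical": x + 1.0, "all": x})
        assert out.loc[0, "note"] == "zero-variance difference"
        assert np.isnan(out.loc[0, "t"])

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal(8), rng.standard_normal(8)
        out = scene_subset_comparison({"critical": a, "non_critical": b})
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert out.loc[0, "t"] == pytest.approx(t_manual, abs=1e-10)
        assert out.loc[0, "df"] == 7


class TestMixedAnova:
    def test_all_equal_zero_f(self):
        res = _mixed_anova_ss(np.full((12, 2), 3.0), [4, 4, 4])
        assert res["F_group"] == 0.0 and res["F_interaction"] == 0.0

    def test_planted_group_offset(self, rng):
        y = rng.standard_normal((30, 2)) * 0.1
        y[:10] += 5.0  # first group shifted in both conditions
        res = _mixed_anova_ss(y, [10, 10, 10])
        assert res["F_group"] > 100
        assert res["p_interaction"] > 0.01

    def test_group_p_uniform_under_null(self):
        rng = np.random.default_rng(0)
        ps = [
            _mixed_anova_ss(rng.standard_normal((15, 2)), [5, 5, 5])["p_group"]
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_univariate_control_clean_on_default_generator(self, tiny_spec):
        ds = pk.simulate_dataset(tiny_spec)
        tbl = univariate_control(ds)
        assert set(tbl.columns) >= {"F_group", "p_group", "F_interaction",
                                    "p_interaction"}
        assert len(tbl) == tiny_spec.n_rois
        assert np.isfinite(tbl["F_group"]).all()


class TestReliability:
    def test_noisier_group_detected(self, tiny_spec):
        ds = pk.simulate_dataset(tiny_spec)
        rng = np.random.default_rng(0)
        for phase in ("encoding", "recall"):
            arr = dict(ds.patterns)[("twist", phase)]
            arr += rng.standard_normal(arr.shape) * 5 * tiny_spec.sigma_noise
        _, anova = within_group_reliability(ds)
        assert anova.loc["C(group)", "PR(>F)"] < 0.01

    def test_equal_noise_no_group_effect(self, tiny_spec):
        # equal group sizes so reference-mean precision is matched across
        # groups; reliability values sharing a reference mean are positively
        # correlated, which inflates the ANOVA F somewhat, so the check is
        # on the typical p over several simulations rather than one draw
        spec = tiny_spec.replace(
            a_interp=0.0, a_generic=0.0, n_spoiled=6, n_twist=6, n_notwist=6
        )
        ps = []
        for s in range(12):
            _, anova = within_group_reliability(
                pk.simulate_dataset(spec.replace(seed=s))
            )
            ps.append(anova.loc["C(group)", "PR(>F)"])
        assert np.median(ps) > 0.05

    def test_reliability_decreases_with_noise(self):
        means = []
        for sigma in (0.5, 1.5, 3.0):
            spec = pk.SyntheticSpec(
                n_spoiled=6, n_twist=6, n_notwist=6, n_scenes=6,
                critical_ids=(0, 2, 4), n_voxels=20, n_rois=1,
                scene_lengths_s=(60.0,) * 6, sigma_noise=sigma, seed=3,
            )
            long, _ = within_group_reliability(pk.simulate_dataset(spec))
            means.append(long["z"].mean())
        assert means[0] > means[1] > means[2]


class TestPermutationConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            PermutationConfig(n_perm=10)
        with pytest.raises(ValueError):
            PermutationConfig(tail="sideways")
        with pytest.raises(ValueError):
            PermutationConfig(scheme="bogus")
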