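"""pISC core: Fisher z, reference means, contrasts, interaction index.

The load-bearing check is the brute-force oracle: a deliberately naive
triple-loop reimplementation of the whole contrast computation that the
vectorized path must match to 1e-12 on small random instances, including
random validity masks and leave-one-out reference averaging.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pisckit as pk
from pisckit.pisc import CLAMP_EPS, fisher_z

from conftest import random_pattern_set

# ---------------------------------------------------------------------------
# independent naive implementation


def _naive_z(x, m):
    r = np.corrcoef(x, m)[0, 1]
    return np.arctanh(np.clip(r, -(1 - CLAMP_EPS), 1 - CLAMP_EPS))


def naive_subject_z(target_pat, target_valid, ref, scenes, exclude=None):
    zs = []
    for s in scenes:
        if not target_valid[s]:
            continue
        pats = []
        for j, sid in enumerate(ref.subject_ids):
            if sid == exclude or not ref.valid[j, s]:
                continue
            pats.append(ref.patterns[j, s])
        if not pats:
            continue
        m = np.mean(pats, axis=0)
        if np.std(target_pat[s]) == 0 or np.std(m) == 0:
            continue
        zs.append(_naive_z(target_pat[s], m))
    return np.mean(zs) if zs else np.nan


def naive_contrast(target, ref_a, ref_b, scenes):
    out = []
    for i, sid in enumerate(target.subject_ids):
        ex_a = sid if target.group == ref_a.group else None
        ex_b = sid if target.group == ref_b.group else None
        za = naive_subject_z(
            target.patterns[i], target.valid[i], ref_a, scenes, ex_a
        )
        zb = naive_subject_z(
            target.patterns[i], target.valid[i], ref_b, scenes, ex_b
        )
        out.append(za - zb)
    return np.array(out)


# ---------------------------------------------------------------------------


class TestFisherZ:
    def test_anchor_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_clamped_at_unity(self):
        assert np.isfinite(fisher_z(1.0))
        assert fisher_z(1.0) == pytest.approx(np.arctanh(1 - CLAMP_EPS))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.2)

    @given(
        st.floats(-0.999, 0.999), st.floats(-0.999, 0.999)
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, r1, r2):
        if r1 < r2:
            assert fisher_z(r1) < fisher_z(r2)


class TestReferenceMean:
    def test_two_identical_subjects_leave_one_out(self, rng):
        ref = random_pattern_set(rng, 2, 3, 5)
        ref.patterns[1] = ref.patterns[0]
        out = pk.reference_mean_pattern(ref, 1, exclude_subject="g_0")
        np.testing.assert_array_equal(out, ref.patterns[1, 1])

    def test_nonmember_exclusion_noop(self, rng):
        ref = random_pattern_set(rng, 3, 2, 5)
        a = pk.reference_mean_pattern(ref, 0)
        b = pk.reference_mean_pattern(ref, 0, exclude_subject="elsewhere")
        np.testing.assert_array_equal(a, b)

    def test_matches_loop_mean(self, rng):
        ref = random_pattern_set(rng, 3, 2, 5, missing_prob=0.3)
        s = 1
        expected = np.mean(
            [ref.patterns[j, s] for j in range(3) if ref.valid[j, s]], axis=0
        )
        np.testing.assert_allclose(
            pk.reference_mean_pattern(ref, s), expected, atol=1e-14
        )

    def test_no_valid_subject_raises(self, rng):
        ref = random_pattern_set(rng, 2, 2, 4)
        ref.valid[:, 0] = False
        with pytest.raises(ValueError):
            pk.reference_mean_pattern(ref, 0)


class TestPiscSubject:
    def test_identical_to_reference_hits_clamp(self, rng):
        ref = random_pattern_set(rng, 3, 2, 6)
        ref.patterns[:] = ref.patterns[0]
        z = pk.pisc_subject(
            ref.patterns[0], np.ones(2, bool), ref, np.arange(2)
        )
        assert z == pytest.approx(np.arctanh(1 - CLAMP_EPS))

    def test_matches_naive_loop(self, rng):
        ref = random_pattern_set(rng, 3, 2, 7, missing_prob=0.2)
        target = rng.standard_normal((2, 7))
        z = pk.pisc_subject(target, np.ones(2, bool), ref, np.arange(2))
        expected = naive_subject_z(target, np.ones(2, bool), ref, range(2))
        assert z == pytest.approx(expected, abs=1e-12)


class TestContrast:
    @pytest.mark.parametrize("seed", range(8))
    def test_brute_force_oracle(self, seed):
        """Vectorized contrast equals the naive triple loop to 1e-12 on
        random small instances with random masks and leave-one-out."""
        rng = np.random.default_rng(seed)
        n_scenes = int(rng.integers(2, 5))
        n_vox = int(rng.integers(4, 11))
        target = random_pattern_set(
            rng, int(rng.integers(3, 6)), n_scenes, n_vox,
            group="twist", phase="recall", missing_prob=0.25,
        )
        # ref_b shares the target's group: exercises leave-one-out
        ref_a = random_pattern_set(
            rng, int(rng.integers(2, 6)), n_scenes, n_vox,
            group="spoiled", phase="encoding", missing_prob=0.25,
        )
        ref_b = random_pattern_set(
            rng, target.n_subjects, n_scenes, n_vox,
            group="twist", phase="encoding", missing_prob=0.25,
        )
        scenes = np.arange(n_scenes)
        got = pk.contrast(target, ref_a, ref_b, scenes).values
        expected = naive_contrast(target, ref_a, ref_b, scenes)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_identical_references_zero(self, rng):
        target = random_pattern_set(rng, 4, 3, 6, group="t")
        ref = random_pattern_set(rng, 3, 3, 6, group="a")
        out = pk.contrast(target, ref, ref, np.arange(3))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_reference_swap_negates(self, rng):
        target = random_pattern_set(rng, 4, 3, 6, group="t")
        ref_a = random_pattern_set(rng, 3, 3, 6, group="a")
        ref_b = random_pattern_set(rng, 3, 3, 6, group="b")
        ab = pk.contrast(target, ref_a, ref_b, np.arange(3)).values
        ba = pk.contrast(target, ref_b, ref_a, np.arange(3)).values
        np.testing.assert_allclose(ab, -ba, atol=1e-14)

    def test_scale_invariance(self, rng):
        target = random_pattern_set(rng, 4, 3, 6, group="t")
        ref_a = random_pattern_set(rng, 3, 3, 6, group="a")
        ref_b = random_pattern_set(rng, 3, 3, 6, group="b")
        base = pk.contrast(target, ref_a, ref_b, np.arange(3)).values
        for ps in (target, ref_a, ref_b):
            ps.patterns *= 37.5
        scaled = pk.contrast(target, ref_a, ref_b, np.arange(3)).values
        np.testing.assert_allclose(base, scaled, atol=1e-12)

    def test_masking_changes_only_that_subject(self, rng):
        target = random_pattern_set(rng, 5, 4, 6, group="t")
        ref_a = random_pattern_set(rng, 4, 4, 6, group="a")
        ref_b = random_pattern_set(rng, 4, 4, 6, group="b")
        full = pk.contrast(target, ref_a, ref_b, np.arange(4)).values
        target.valid[2, 1] = False
        masked = pk.contrast(target, ref_a, ref_b, np.arange(4)).values
        others = [i for i in range(5) if i != 2]
        np.testing.assert_array_equal(full[others], masked[others])
        assert full[2] != masked[2]

    def test_match_n_equalizes_references(self, rng):
        target = random_pattern_set(rng, 4, 3, 6, group="t", phase="recall")
        big = random_pattern_set(rng, 9, 3, 6, group="a")
        small = random_pattern_set(rng, 4, 3, 6, group="b")
        out = pk.contrast(
            target, big, small, np.arange(3), match_n=True,
            rng=np.random.default_rng(0),
        )
        assert out.comparison["ref_a"] == ("a", "encoding")
        # the drop is random: two different rngs give different values
        out2 = pk.contrast(
            target, big, small, np.arange(3), match_n=True,
            rng=np.random.default_rng(1),
        )
        assert not np.allclose(out.values, out2.values)


class TestInteraction:
    def _contrast_pair(self, rng, flip=False):
        target_e = random_pattern_set(rng, 4, 3, 6, group="twist")
        ra = random_pattern_set(rng, 3, 3, 6, group="no_twist")
        rb = random_pattern_set(rng, 3, 3, 6, group="spoiled")
        enc = pk.contrast(target_e, ra, rb, np.arange(3))
        rec = pk.contrast(target_e, ra, rb, np.arange(3))
        return enc, rec

    def test_identical_contrasts_zero_index(self, rng):
        enc, rec = self._contrast_pair(rng)
        res = pk.interaction_index(enc, rec)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-14)

    def test_label_exchange_negates_index(self, rng):
        target = random_pattern_set(rng, 4, 3, 6, group="twist")
        target_r = random_pattern_set(rng, 4, 3, 6, group="twist")
        ra = random_pattern_set(rng, 3, 3, 6, group="no_twist")
        rb = random_pattern_set(rng, 3, 3, 6, group="spoiled")
        enc = pk.contrast(target, ra, rb, np.arange(3))
        rec = pk.contrast(target_r, ra, rb, np.arange(3))
        idx = pk.interaction_index(enc, rec).values
        enc_x = pk.contrast(target, rb, ra, np.arange(3))
        rec_x = pk.contrast(target_r, rb, ra, np.arange(3))
        idx_x = pk.interaction_index(enc_x, rec_x).values
        np.testing.assert_allclose(idx, -idx_x, atol=1e-12)

    def test_subject_mismatch_rejected(self, rng):
        enc, _ = self._contrast_pair(rng)
        other = random_pattern_set(rng, 5, 3, 6, group="twist")
        ra = random_pattern_set(rng, 3, 3, 6, group="no_twist")
        rec = pk.contrast(other, ra, ra, np.arange(3))
        with pytest.raises(ValueError):
            pk.interaction_index(enc, rec)


class TestSceneLevel:
    def test_identical_references_all_zero(self, rng):
        target = random_pattern_set(rng, 4, 5, 6, group="t")
        ref = random_pattern_set(rng, 3, 5, 6, group="a")
        out = pk.scene_level_contrast(target, ref, ref, np.arange(5))
        assert out.unit == "scene"
        np.testing.assert_allclose(out.values, 0.0, atol=1e-14)

    def test_count_weighted_scene_mean_matches_subject_pipeline(self, rng):
        """With full validity, averaging scene values equals averaging the
        per-subject means (both reduce to the grand mean of z differences)."""
        target = random_pattern_set(rng, 4, 5, 6, group="t")
        ref_a = random_pattern_set(rng, 3, 5, 6, group="a")
        ref_b = random_pattern_set(rng, 3, 5, 6, group="b")
        scenes = np.arange(5)
        by_scene = pk.scene_level_contrast(target, ref_a, ref_b, scenes)
        by_subj = pk.contrast(target, ref_a, ref_b, scenes)
        assert np.mean(by_scene.values) == pytest.approx(
            np.mean(by_subj.values), abs=1e-12
        )

    def test_planted_critical_effect_largest_on_critical_scenes(self):
        spec = pk.SyntheticSpec(a_interp=2.0, sigma_noise=1.0,
                                update_fraction=1.0, n_voxels=40)
        diffs = []
        for s in range(10):
            ds = pk.simulate_dataset(spec.replace(seed=s))
            out = pk.scene_level_contrast(
                ds.pattern_set("twist", "recall", 0),
                ds.pattern_set("spoiled", "recall", 0),
                ds.pattern_set("no_twist", "recall", 0),
                np.arange(18),
            )
            crit = ds.scene_table.is_critical
            diffs.append(
                np.nanmean(out.values[crit]) - np.nanmean(out.values[~crit])
            )
        assert np.mean(diffs) > 0
        assert np.mean(np.array(diffs) > 0) >= 0.9
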