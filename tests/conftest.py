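import numpy as np
import pytest

from pisckit import ScenePatternSet, SyntheticSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_spec():
    """A fast, small-but-complete generative spec for pipeline tests."""
    return SyntheticSpec(
        n_spoiled=5, n_twist=6, n_notwist=5,
        n_scenes=6, critical_ids=(0, 2, 4),
        n_voxels=20, n_rois=2,
        scene_lengths_s=(60.0, 90.0, 45.0, 75.0, 60.0, 90.0),
        seed=7,
    )


def random_pattern_set(
    rng, n_subj, n_scenes, n_vox, group="g", phase="encoding",
    missing_prob=0.0,
):
    """Random pattern set with an optional random validity mask that always
    keeps at least one valid subject per scene and one scene per subject."""
    valid = rng.random((n_subj, n_scenes)) >= missing_prob
    for s in range(n_scenes):
        if not valid[:, s].any():
            valid[rng.integers(n_subj), s] = True
    for i in range(n_subj):
        if not valid[i].any():
            valid[i, rng.integers(n_scenes)] = True
    return ScenePatternSet(
        patterns=rng.standard_normal((n_subj, n_scenes, n_vox)),
        valid=valid,
        group=group,
        phase=phase,
        subject_ids=[f"{group}_{i}" for i in range(n_subj)],
    )
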