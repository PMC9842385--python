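"""Intersubject pattern correlation (pISC) and the directed group contrasts.

For each scene, a target subject's spatial pattern is Pearson-correlated
with the *average* pattern of a reference group for the same scene.  When
the target subject belongs to the reference group the reference average
leaves that subject out, so every comparison is across subjects.  Scene
correlations are Fisher-z transformed, then averaged across the analysed
scenes; the unit of all hypothesis tests is the per-subject difference of
two such averages (reference A minus reference B).

The interaction index quantifies memory updating in the twist group: with
both contrasts oriented as (no-twist reference minus spoiled reference),

    index = encoding contrast - recall contrast

is positive when the twist group's recall patterns have moved toward the
spoiled (Ghost) group relative to their encoding patterns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import ScenePatternSet

logger = logging.getLogger(__name__)

#: correlations are clamped to +/-(1 - CLAMP_EPS) before arctanh so that
#: noiseless synthetic data (r = 1 exactly) keeps a finite Fisher z
CLAMP_EPS = 1e-7

__all__ = [
    "PiscContrast",
    "InteractionResult",
    "fisher_z",
    "reference_mean_pattern",
    "pisc_subject",
    "contrast",
    "interaction_index",
    "scene_level_contrast",
    "dataset_interaction",
]


@dataclass
class PiscContrast:
    """Per-unit Fisher-z difference between two reference comparisons."""

    values: np.ndarray
    unit: str  # "subject" or "scene"
    ids: list
    comparison: dict = field(default_factory=dict)
    scene_subset: np.ndarray | None = None
    roi_id: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class InteractionResult:
    """Per-ROI interaction index over twist-group subjects."""

    roi_id: int
    values: np.ndarray
    subject_ids: list
    p: float = np.nan
    q: float = np.nan

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


def fisher_z(r):
    """Variance-stabilizing arctanh transform of a Pearson correlation.

    Correlations are clamped to ``1 - 1e-7`` in magnitude so perfect
    correlations map to a large finite z rather than infinity.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlations must lie in [-1, 1]")
    out = np.arctanh(np.clip(r, -(1 - CLAMP_EPS), 1 - CLAMP_EPS))
    return float(out) if out.ndim == 0 else out


def reference_mean_pattern(
    ref: ScenePatternSet, scene: int, exclude_subject: str | None = None
) -> np.ndarray:
    """Average pattern over the reference group's valid subjects for one
    scene, optionally leaving one subject out (a non-member is a no-op)."""
    keep = ref.valid[:, scene].copy()
    if exclude_subject is not None and exclude_subject in ref.subject_ids:
        keep[ref.subject_ids.index(exclude_subject)] = False
    if not keep.any():
        raise ValueError(f"no valid reference subjects for scene {scene}")
    return ref.patterns[keep, scene].mean(axis=0)


def _scene_z_matrix(
    target: ScenePatternSet,
    ref: ScenePatternSet,
    scene_idx: np.ndarray,
    leave_one_out: bool,
) -> np.ma.MaskedArray:
    """Fisher-z pISC for every (target subject, scene) pair.

    Returns a masked ``n_subjects x len(scene_idx)`` array; entries are
    masked where the target scene is invalid, the reference has no valid
    subject, or either pattern has zero spatial variance.
    """
    X = target.patterns[:, scene_idx]  # n x s x v
    tv = target.valid[:, scene_idx]
    Rf = ref.patterns[:, scene_idx]
    rv = ref.valid[:, scene_idx].astype(float)

    sums = np.einsum("msv,ms->sv", Rf, rv)
    counts = rv.sum(axis=0)  # per scene
    n, s = X.shape[:2]

    if leave_one_out:
        ref_index = {sid: j for j, sid in enumerate(ref.subject_ids)}
        j = np.array(
            [ref_index.get(sid, -1) for sid in target.subject_ids], dtype=int
        )
        member = j >= 0
        cnt = np.tile(counts, (n, 1))
        M = np.tile(sums, (n, 1, 1))
        jm = j[member]
        cnt[member] -= rv[jm]
        M[member] -= Rf[jm] * rv[jm][..., None]
        M = M / np.maximum(cnt, 1.0)[..., None]
        mc = M - M.mean(axis=-1, keepdims=True)
    else:
        cnt = np.broadcast_to(counts, (n, s))
        M = sums / np.maximum(counts, 1.0)[:, None]
        mc1 = M - M.mean(axis=-1, keepdims=True)
        mc = np.broadcast_to(mc1, (n, s, mc1.shape[-1]))

    xc = X - X.mean(axis=-1, keepdims=True)
    num = np.einsum("nsv,nsv->ns", xc, mc)
    xn = np.linalg.norm(xc, axis=-1)
    mn = np.linalg.norm(mc, axis=-1)
    ok = tv & (cnt > 0)
    flat = (xn == 0) | (mn == 0)
    n_flat = int((flat & ok).sum())
    if n_flat:
        logger.warning(
            "skipping %d zero-variance pattern pair(s) in pISC", n_flat
        )
    good = ok & ~flat
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(good, num / np.where(good, xn * mn, 1.0), 0.0)
    z = fisher_z(np.clip(r, -1.0, 1.0))
    return np.ma.masked_array(np.atleast_2d(z), mask=~good)


def pisc_subject(
    target_patterns: np.ndarray,
    target_valid: np.ndarray,
    ref: ScenePatternSet,
    scene_subset: np.ndarray | None = None,
    exclude_subject: str | None = None,
) -> float:
    """Mean Fisher-z pISC of one subject against a reference group.

    ``target_patterns`` is ``scenes x voxels``.  The mean runs over scenes
    valid on both sides; an all-invalid subject raises.
    """
    tset = ScenePatternSet(
        patterns=target_patterns[None],
        valid=np.asarray(target_valid, dtype=bool)[None],
        group="_target",
        phase=ref.phase,
        subject_ids=[exclude_subject or "_target"],
    )
    idx = (
        np.arange(tset.n_scenes) if scene_subset is None
        else np.asarray(scene_subset, dtype=int)
    )
    z = _scene_z_matrix(tset, ref, idx, leave_one_out=exclude_subject is not None)
    if z[0].mask.all():
        raise ValueError("no valid scene for this subject/reference pair")
    return float(z[0].mean())


def _subsample_reference(
    ref: ScenePatternSet, n_drop: int, rng: np.random.Generator
) -> ScenePatternSet:
    keep = np.sort(
        rng.choice(ref.n_subjects, size=ref.n_subjects - n_drop, replace=False)
    )
    return ScenePatternSet(
        patterns=ref.patterns[keep],
        valid=ref.valid[keep],
        group=ref.group,
        phase=ref.phase,
        roi_id=ref.roi_id,
        subject_ids=[ref.subject_ids[k] for k in keep],
    )


def contrast(
    target: ScenePatternSet,
    ref_a: ScenePatternSet,
    ref_b: ScenePatternSet,
    scene_subset: np.ndarray,
    match_n: bool = False,
    rng: np.random.Generator | None = None,
) -> PiscContrast:
    """Per-subject directed contrast: pISC(target, A) - pISC(target, B).

    Leave-one-out is applied automatically whenever the target group
    coincides with a reference group, so no subject is ever compared with
    an average containing their own data.  With ``match_n`` the larger
    reference (after accounting for leave-one-out) is randomly subsampled
    to the size of the smaller before averaging — re-draw per permutation
    iteration by passing a fresh ``rng``.
    """
    if ref_a.n_subjects == 0 or ref_b.n_subjects == 0:
        raise ValueError("reference sets must be non-empty")
    idx = np.asarray(scene_subset, dtype=int)
    loo_a = target.group == ref_a.group
    loo_b = target.group == ref_b.group
    if match_n:
        if rng is None:
            rng = np.random.default_rng()
        eff_a = ref_a.n_subjects - int(loo_a)
        eff_b = ref_b.n_subjects - int(loo_b)
        if eff_a > eff_b:
            ref_a = _subsample_reference(ref_a, eff_a - eff_b, rng)
        elif eff_b > eff_a:
            ref_b = _subsample_reference(ref_b, eff_b - eff_a, rng)
    za = _scene_z_matrix(target, ref_a, idx, loo_a)
    zb = _scene_z_matrix(target, ref_b, idx, loo_b)
    values = (za.mean(axis=1) - zb.mean(axis=1)).filled(np.nan)
    return PiscContrast(
        values=values,
        unit="subject",
        ids=list(target.subject_ids),
        comparison={
            "target": (target.group, target.phase),
            "ref_a": (ref_a.group, ref_a.phase),
            "ref_b": (ref_b.group, ref_b.phase),
        },
        scene_subset=idx,
        roi_id=target.roi_id,
    )


def interaction_index(
    enc_contrast: PiscContrast, rec_contrast: PiscContrast
) -> InteractionResult:
    """Encoding contrast minus recall contrast, per twist subject.

    Both inputs must be indexed by the same subjects and oriented as
    (no-twist reference minus spoiled reference); the result is positive
    when recall patterns have shifted toward the spoiled group.
    """
    if list(enc_contrast.ids) != list(rec_contrast.ids):
        raise ValueError("contrasts must be indexed by the same subjects")
    values = enc_contrast.values - rec_contrast.values
    return InteractionResult(
        roi_id=enc_contrast.roi_id,
        values=values,
        subject_ids=list(enc_contrast.ids),
    )


def scene_level_contrast(
    target: ScenePatternSet,
    ref_a: ScenePatternSet,
    ref_b: ScenePatternSet,
    scene_subset: np.ndarray,
) -> PiscContrast:
    """Per-scene contrast: mean over target subjects of (zA - zB).

    No averaging across scenes — one value per scene in the subset, for
    scene-resolved brain-behavior analyses.  Scenes with no valid subject
    come back as NaN.
    """
    idx = np.asarray(scene_subset, dtype=int)
    za = _scene_z_matrix(target, ref_a, idx, target.group == ref_a.group)
    zb = _scene_z_matrix(target, ref_b, idx, target.group == ref_b.group)
    values = (za - zb).mean(axis=0).filled(np.nan)
    return PiscContrast(
        values=values,
        unit="scene",
        ids=[int(s) for s in idx],
        comparison={
            "target": (target.group, target.phase),
            "ref_a": (ref_a.group, ref_a.phase),
            "ref_b": (ref_b.group, ref_b.phase),
        },
        scene_subset=idx,
        roi_id=target.roi_id,
    )


def dataset_interaction(dataset, roi: int, scene_idx: np.ndarray) -> InteractionResult:
    """Interaction index for one ROI of a full three-group dataset.

    Encoding contrast: twist-group encoding patterns vs (no-twist minus
    spoiled) encoding references.  Recall contrast: same orientation on
    recall patterns.  Index = encoding minus recall, per twist subject.
    """
    sets = {
        (g, p): dataset.pattern_set(g, p, roi)
        for g in ("spoiled", "twist", "no_twist")
        for p in ("encoding", "recall")
    }
    enc = contrast(
        sets[("twist", "encoding")],
        sets[("no_twist", "encoding")],
        sets[("spoiled", "encoding")],
        scene_idx,
    )
    rec = contrast(
        sets[("twist", "recall")],
        sets[("no_twist", "recall")],
        sets[("spoiled", "recall")],
        scene_idx,
    )
    return interaction_index(enc, rec)
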