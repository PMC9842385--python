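"""Ground-truth generator for the three-group twist design.

The generator emulates the latent structure the pISC analyses assume: each
scene has a spatial pattern shared by everyone who processes that scene;
critical scenes additionally carry an interpretation-specific pattern that
differs between the two readings of the story (Doctor vs Ghost); a
scene-generic interpretation component captures a coarse "mental state"
shared across scenes; and each subject adds i.i.d. Gaussian voxel noise.

Group structure: the spoiled group holds the Ghost interpretation at both
encoding and recall (``mix=1``); the no-twist group holds Doctor throughout
(``mix=0``); the twist group encodes as Doctor and recalls with a
per-subject update fraction drawn around ``update_fraction`` — 0 means no
updating, 1 a full shift to the Ghost interpretation.  Behavioral twist
scores (the 1–5 "ghostness" rating of each recalled scene) are coupled to
the planted update fractions at a configurable correlation.

Everything is deterministic given the spec (including its seed); each
subject draws from an independent substream of the master seed, so changing
one group's size never reshuffles another subject's data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extraction import _convolved_regressor
from .types import Dataset, EventDesign, RoiTimeSeries, SceneTable

__all__ = [
    "SyntheticSpec",
    "LatentComponents",
    "make_scene_table",
    "sample_latents",
    "subject_pattern",
    "simulate_dataset",
    "simulate_recall_run",
]

# Scene durations (s) for the default 18-scene stimulus; mean ~2 min with a
# short minimum and a long maximum, totalling just under an hour.
_DEFAULT_SCENE_LENGTHS = (
    90.0, 130.0, 45.0, 200.0, 110.0, 26.0, 150.0, 356.0, 95.0,
    130.0, 75.0, 180.0, 60.0, 240.0, 120.0, 160.0, 85.0, 140.0,
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of the generative model.

    Amplitudes are in arbitrary BOLD units; ``a_interp`` and ``a_generic``
    are only expressed in ``planted_rois`` so that effect-free control ROIs
    exist in the same dataset.
    """

    n_spoiled: int = 18
    n_twist: int = 19
    n_notwist: int = 20
    n_scenes: int = 18
    critical_ids: tuple[int, ...] = (0, 4, 7, 9, 12, 14, 16)
    n_voxels: int = 60
    n_rois: int = 2
    planted_rois: tuple[int, ...] = (0,)
    a_scene: float = 1.0
    a_interp: float = 1.0
    a_generic: float = 0.0
    update_fraction: float = 0.7
    update_concentration: float = 10.0
    sigma_noise: float = 2.0
    tr_seconds: float = 1.5
    scene_lengths_s: tuple[float, ...] = _DEFAULT_SCENE_LENGTHS
    recall_miss_prob: float = 0.05
    behavior_coupling: float = 0.5
    n_twist_raters: int = 4
    n_memory_raters: int = 2
    rater_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_spoiled, self.n_twist, self.n_notwist,
            self.n_scenes, self.n_voxels, self.n_rois,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        for name in ("update_fraction", "recall_miss_prob", "behavior_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if not set(self.critical_ids) <= set(range(self.n_scenes)):
            raise ValueError("critical_ids must be scene indices")
        if len(self.scene_lengths_s) != self.n_scenes:
            raise ValueError("scene_lengths_s must have n_scenes entries")
        if any(l <= 0 for l in self.scene_lengths_s):
            raise ValueError("scene lengths must be positive")
        if not set(self.planted_rois) <= set(range(self.n_rois)):
            raise ValueError("planted_rois must be ROI indices")

    def replace(self, **kw) -> "SyntheticSpec":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        for k in ("critical_ids", "scene_lengths_s", "planted_rois"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class LatentComponents:
    """Shared spatial components, one set per ROI.

    All component vectors are unit norm before amplitude scaling; for
    non-critical scenes the Doctor and Ghost patterns are identical, so
    only critical scenes can carry a scene-specific interpretation effect.
    """

    scene_patterns: np.ndarray  # rois x scenes x voxels
    doctor_patterns: np.ndarray
    ghost_patterns: np.ndarray
    generic_doctor: np.ndarray  # rois x voxels
    generic_ghost: np.ndarray


def _unit_rows(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    # zero-mean across voxels so components carry no univariate signal,
    # then unit norm
    x = rng.standard_normal(shape)
    x = x - x.mean(axis=-1, keepdims=True)
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


def _rng_for(spec: SyntheticSpec, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=key)
    )


def make_scene_table(spec: SyntheticSpec) -> SceneTable:
    """Contiguous scene segmentation from the spec's per-scene durations."""
    lengths = np.asarray(spec.scene_lengths_s, dtype=float)
    offsets = np.cumsum(lengths)
    onsets = offsets - lengths
    crit = np.zeros(spec.n_scenes, dtype=bool)
    crit[list(spec.critical_ids)] = True
    return SceneTable(
        scene_id=np.arange(spec.n_scenes),
        onset_s=onsets,
        offset_s=offsets,
        is_critical=crit,
    )


def sample_latents(spec: SyntheticSpec) -> LatentComponents:
    """Draw the shared component basis (deterministic for a fixed seed)."""
    rng = _rng_for(spec, 99)
    R, S, V = spec.n_rois, spec.n_scenes, spec.n_voxels
    scene = _unit_rows(rng, (R, S, V))
    doctor = _unit_rows(rng, (R, S, V))
    ghost = doctor.copy()
    crit = np.array(sorted(spec.critical_ids), dtype=int)
    ghost[:, crit] = _unit_rows(rng, (R, len(crit), V))
    gen_d = _unit_rows(rng, (R, V))
    gen_g = _unit_rows(rng, (R, V))
    return LatentComponents(scene, doctor, ghost, gen_d, gen_g)


def _roi_amplitudes(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-ROI interpretation amplitudes (zero outside planted ROIs)."""
    a_i = np.zeros(spec.n_rois)
    a_g = np.zeros(spec.n_rois)
    a_i[list(spec.planted_rois)] = spec.a_interp
    a_g[list(spec.planted_rois)] = spec.a_generic
    return a_i, a_g


def _noiseless_patterns(
    latents: LatentComponents, spec: SyntheticSpec, mix: float
) -> np.ndarray:
    """Noiseless ``rois x scenes x voxels`` patterns for one mix value."""
    a_i, a_g = _roi_amplitudes(spec)
    p = spec.a_scene * latents.scene_patterns
    p = p + a_i[:, None, None] * (
        (1 - mix) * latents.doctor_patterns + mix * latents.ghost_patterns
    )
    p = p + a_g[:, None, None] * (
        (1 - mix) * latents.generic_doctor
        + mix * latents.generic_ghost
    )[:, None, :]
    return p


def _noiseless_pattern(
    latents: LatentComponents, spec: SyntheticSpec, roi: int, scene: int,
    mix: float,
) -> np.ndarray:
    return _noiseless_patterns(latents, spec, mix)[roi, scene]


def subject_pattern(
    latents: LatentComponents,
    scene: int,
    mix: float,
    spec: SyntheticSpec,
    rng: np.random.Generator,
    roi: int = 0,
) -> np.ndarray:
    """One subject's noisy spatial pattern for one scene.

    ``mix`` is the weight on the Ghost interpretation (0 = pure Doctor).
    """
    p = _noiseless_pattern(latents, spec, roi, scene, mix)
    return p + rng.normal(0.0, spec.sigma_noise, spec.n_voxels)


def _group_mixes(
    spec: SyntheticSpec, group: str, phase: str, update: np.ndarray
) -> np.ndarray:
    n = {"spoiled": spec.n_spoiled, "twist": spec.n_twist,
         "no_twist": spec.n_notwist}[group]
    if group == "spoiled":
        return np.ones(n)
    if group == "no_twist":
        return np.zeros(n)
    return update if phase == "recall" else np.zeros(n)


def _draw_update_fractions(spec: SyntheticSpec) -> np.ndarray:
    rng = _rng_for(spec, 97)
    m, c = spec.update_fraction, spec.update_concentration
    if m in (0.0, 1.0) or c <= 0:
        return np.full(spec.n_twist, m)
    return rng.beta(m * c, (1 - m) * c, size=spec.n_twist)


def _behavior_levels(spec: SyntheticSpec, update: np.ndarray) -> np.ndarray:
    """Per-twist-subject behavioral ghostness level in [0, 1], coupled to
    the planted update fraction at ``behavior_coupling``."""
    rng = _rng_for(spec, 96)
    rho = spec.behavior_coupling
    sd = update.std()
    if sd == 0:
        return update.copy()
    z = (update - update.mean()) / sd
    y = rho * z + np.sqrt(1.0 - rho**2) * rng.standard_normal(len(update))
    return np.clip(update.mean() + sd * y, 0.0, 1.0)


def _make_behavior_table(
    spec: SyntheticSpec,
    update: np.ndarray,
    recall_valid: dict[str, np.ndarray],
    subject_ids: dict[str, list[str]],
) -> pd.DataFrame:
    """Long rater table: subject x scene x rater twist and memory ratings."""
    rng = _rng_for(spec, 95)
    levels = _behavior_levels(spec, update)
    crit = np.zeros(spec.n_scenes, dtype=bool)
    crit[list(spec.critical_ids)] = True
    frames = []
    for group in ("spoiled", "twist", "no_twist"):
        ids = np.asarray(subject_ids[group])
        n = len(ids)
        subj_level = {
            "spoiled": np.ones(n), "twist": levels, "no_twist": np.zeros(n)
        }[group]
        # subject x scene ghostness level: twist only shifts critical scenes
        level = np.where(crit[None, :], subj_level[:, None], 0.0)
        S, R = spec.n_scenes, spec.n_twist_raters
        tw = np.clip(
            1.0 + 4.0 * level[:, :, None]
            + rng.normal(0, spec.rater_sd, (n, S, R)),
            1.0, 5.0,
        )
        mem = np.clip(4.0 + rng.normal(0, spec.rater_sd, (n, S, R)), 1.0, 5.0)
        mem[:, :, spec.n_memory_raters:] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(ids, S * R),
                    "group": group,
                    "scene_id": np.tile(np.repeat(np.arange(S), R), n),
                    "rater_id": np.tile(
                        [f"rater_{r}" for r in range(R)], n * S
                    ),
                    "twist_rating": tw.ravel(),
                    "memory_rating": mem.ravel(),
                    "recognized": np.repeat(
                        recall_valid[group].astype(bool).ravel(), R
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(spec: SyntheticSpec) -> Dataset:
    """Generate a full dataset: patterns for every group x phase x ROI,
    recall validity, a rater-level behavior table, and the truth record.
    """
    latents = sample_latents(spec)
    update = _draw_update_fractions(spec)
    group_sizes = {
        "spoiled": spec.n_spoiled, "twist": spec.n_twist,
        "no_twist": spec.n_notwist,
    }
    subject_ids = {
        g: [f"{g}_{i:02d}" for i in range(n)] for g, n in group_sizes.items()
    }

    patterns: dict[tuple[str, str], np.ndarray] = {}
    valid: dict[tuple[str, str], np.ndarray] = {}
    R, S, V = spec.n_rois, spec.n_scenes, spec.n_voxels
    for gi, group in enumerate(("spoiled", "twist", "no_twist")):
        n = group_sizes[group]
        for phase in ("encoding", "recall"):
            arr = np.empty((n, R, S, V))
            vmask = np.ones((n, S), dtype=bool)
            mixes = _group_mixes(spec, group, phase, update)
            mean_cache: dict[float, np.ndarray] = {}
            for si in range(n):
                srng = _rng_for(spec, gi, si, 0 if phase == "encoding" else 1)
                m = float(mixes[si])
                if m not in mean_cache:
                    mean_cache[m] = _noiseless_patterns(latents, spec, m)
                arr[si] = mean_cache[m] + srng.normal(
                    0, spec.sigma_noise, (R, S, V)
                )
                if phase == "recall":
                    vmask[si] = srng.random(S) >= spec.recall_miss_prob
                    if not vmask[si].any():  # keep at least one scene
                        vmask[si, srng.integers(S)] = True
            patterns[(group, phase)] = arr
            valid[(group, phase)] = vmask

    recall_valid = {
        g: valid[(g, "recall")] for g in group_sizes
    }
    behavior = _make_behavior_table(spec, update, recall_valid, subject_ids)
    truth = {
        "update_fraction": update,
        "behavior_level": _behavior_levels(spec, update),
        "spec": spec.to_dict(),
    }
    return Dataset(
        patterns=patterns,
        valid=valid,
        subject_ids=subject_ids,
        scene_table=make_scene_table(spec),
        behavior=behavior,
        truth=truth,
    )


def default_event_design(
    spec: SyntheticSpec,
    cue_duration_s: float = 12.0,
    recall_duration_s: float = 30.0,
    gap_s: float = 14.0,
) -> EventDesign:
    """Cued-recall timing: for each scene, a movie cue, a countdown gap,
    then a self-paced recall epoch."""
    onsets, cue_onsets = [], []
    t = 0.0
    for _ in range(spec.n_scenes):
        cue_onsets.append(t)
        t += cue_duration_s + gap_s
        onsets.append(t)
        t += recall_duration_s + 6.0
    n_tr = int(np.ceil((t + 20.0) / spec.tr_seconds))
    return EventDesign(
        scene_id=np.arange(spec.n_scenes),
        onset_s=np.array(onsets),
        duration_s=np.full(spec.n_scenes, recall_duration_s),
        recognized=np.ones(spec.n_scenes, dtype=bool),
        cue_onset_s=np.array(cue_onsets),
        cue_duration_s=np.full(spec.n_scenes, cue_duration_s),
        n_tr=n_tr,
        tr_seconds=spec.tr_seconds,
    )


def simulate_recall_run(
    spec: SyntheticSpec,
    mix: float,
    latents: LatentComponents | None = None,
    event_design: EventDesign | None = None,
    roi: int = 0,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
    cue_offset: float = 5.0,
) -> tuple[RoiTimeSeries, EventDesign]:
    """Simulate one subject's recall-run BOLD series for one ROI.

    The signal is the HRF-convolved sum of per-event boxcars whose
    per-voxel amplitude is the scene's noiseless spatial pattern, plus cue
    epochs with a distinct (higher) mean-intensity offset shared across
    voxels, plus white noise.  Returns the series and the event design
    used (which marks cue vs recall epochs).
    """
    if latents is None:
        latents = sample_latents(spec)
    if event_design is None:
        event_design = default_event_design(spec)
    if rng is None:
        rng = _rng_for(spec, 94)
    if noise_sd is None:
        noise_sd = spec.sigma_noise

    n_tr, tr = event_design.n_tr, event_design.tr_seconds
    data = np.zeros((n_tr, spec.n_voxels))
    for e in range(event_design.n_events):
        reg = _convolved_regressor(
            np.array([event_design.onset_s[e]]),
            np.array([event_design.duration_s[e]]),
            n_tr, tr,
        )
        amp = _noiseless_pattern(
            latents, spec, roi, int(event_design.scene_id[e]), mix
        )
        data += np.outer(reg, amp)
    if len(event_design.cue_onset_s):
        cue_reg = _convolved_regressor(
            event_design.cue_onset_s, event_design.cue_duration_s, n_tr, tr
        )
        data += cue_offset * cue_reg[:, None]
    data += rng.normal(0, noise_sd, data.shape)
    ts = RoiTimeSeries(data=data, tr_seconds=tr, run_id=f"recall_roi{roi}")
    return ts, event_design
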