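"""Core data containers for scene-level pattern analysis.

The central object is :class:`ScenePatternSet`: for one group of subjects,
one experimental phase (movie encoding or cued recall) and one ROI, a
``subjects x scenes x voxels`` array of spatial activity patterns together
with a ``subjects x scenes`` validity mask (a recall scene that was not
recognized, or a scene window covering no TRs, is masked rather than
zero-filled).  Everything downstream — intersubject pattern correlations,
group contrasts, permutation tests — consumes these sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

GROUPS = ("spoiled", "twist", "no_twist")
PHASES = ("encoding", "recall")


@dataclass(frozen=True)
class SceneTable:
    """Scene segmentation of the stimulus: half-open intervals in seconds.

    ``is_critical`` flags the scenes whose interpretation is most changed
    by the twist; these form the default analysis subset.
    """

    scene_id: np.ndarray
    onset_s: np.ndarray
    offset_s: np.ndarray
    is_critical: np.ndarray

    def __post_init__(self) -> None:
        sid = np.asarray(self.scene_id, dtype=int)
        on = np.asarray(self.onset_s, dtype=float)
        off = np.asarray(self.offset_s, dtype=float)
        crit = np.asarray(self.is_critical, dtype=bool)
        if not (len(sid) == len(on) == len(off) == len(crit)):
            raise ValueError("scene table columns must have equal length")
        if np.any(off <= on):
            raise ValueError("every scene must have offset_s > onset_s")
        order = np.argsort(on)
        if np.any(off[order][:-1] > on[order][1:] + 1e-9):
            raise ValueError("scenes must not overlap")
        if crit.sum() < 1:
            raise ValueError("at least one scene must be critical")
        object.__setattr__(self, "scene_id", sid)
        object.__setattr__(self, "onset_s", on)
        object.__setattr__(self, "offset_s", off)
        object.__setattr__(self, "is_critical", crit)

    @property
    def n_scenes(self) -> int:
        return len(self.scene_id)

    @property
    def critical_ids(self) -> np.ndarray:
        return self.scene_id[self.is_critical]

    def subset_indices(self, subset: "str | Sequence[int]") -> np.ndarray:
        """Resolve a scene-subset name to positional indices.

        Accepts ``"critical"``, ``"non_critical"``, ``"all"`` or an explicit
        sequence of scene ids.
        """
        if isinstance(subset, str):
            if subset == "critical":
                return np.flatnonzero(self.is_critical)
            if subset == "non_critical":
                return np.flatnonzero(~self.is_critical)
            if subset == "all":
                return np.arange(self.n_scenes)
            raise ValueError(f"unknown scene subset {subset!r}")
        ids = np.asarray(list(subset), dtype=int)
        lookup = {s: i for i, s in enumerate(self.scene_id)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise ValueError(f"scene ids not in table: {missing}")
        return np.array([lookup[s] for s in ids], dtype=int)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scene_id": self.scene_id,
                "onset_s": self.onset_s,
                "offset_s": self.offset_s,
                "is_critical": self.is_critical.astype(int),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SceneTable":
        return cls(
            scene_id=df["scene_id"].to_numpy(),
            onset_s=df["onset_s"].to_numpy(float),
            offset_s=df["offset_s"].to_numpy(float),
            is_critical=df["is_critical"].to_numpy().astype(bool),
        )


@dataclass
class RoiTimeSeries:
    """A ``TR x voxel`` BOLD time series for one ROI of one run."""

    data: np.ndarray
    tr_seconds: float
    run_id: str = ""
    zscored: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("time series must be TR x voxel with >= 2 TRs")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_tr(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EventDesign:
    """Recall-run event timing: per-scene recall epochs plus movie-cue epochs.

    Recall epochs carry the scene id and a recognized flag; unrecognized
    scenes are still modeled but their betas are masked invalid downstream.
    """

    scene_id: np.ndarray
    onset_s: np.ndarray
    duration_s: np.ndarray
    recognized: np.ndarray
    cue_onset_s: np.ndarray
    cue_duration_s: np.ndarray
    n_tr: int
    tr_seconds: float

    def __post_init__(self) -> None:
        sid = np.asarray(self.scene_id, dtype=int)
        on = np.asarray(self.onset_s, dtype=float)
        dur = np.asarray(self.duration_s, dtype=float)
        rec = np.asarray(self.recognized, dtype=bool)
        con = np.asarray(self.cue_onset_s, dtype=float)
        cdur = np.asarray(self.cue_duration_s, dtype=float)
        if not (len(sid) == len(on) == len(dur) == len(rec)):
            raise ValueError("event columns must align")
        if np.any(dur <= 0) or np.any(cdur <= 0):
            raise ValueError("durations must be positive")
        run_end = self.n_tr * self.tr_seconds
        if np.any(on + dur > run_end + 1e-9) or (
            len(con) and np.any(con + cdur > run_end + 1e-9)
        ):
            raise ValueError("events extend past the end of the run")
        order = np.argsort(on)
        if np.any((on[order] + dur[order])[:-1] > on[order][1:] + 1e-9):
            raise ValueError("recall epochs must not overlap")
        for name, val in (
            ("scene_id", sid),
            ("onset_s", on),
            ("duration_s", dur),
            ("recognized", rec),
            ("cue_onset_s", con),
            ("cue_duration_s", cdur),
        ):
            object.__setattr__(self, name, val)

    @property
    def n_events(self) -> int:
        return len(self.scene_id)


@dataclass
class ScenePatternSet:
    """Scene-level spatial patterns for one group, phase and ROI."""

    patterns: np.ndarray  # subjects x scenes x voxels
    valid: np.ndarray  # subjects x scenes (bool)
    group: str
    phase: str
    roi_id: int = 0
    subject_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 3:
            raise ValueError("patterns must be subjects x scenes x voxels")
        if self.valid is None:
            self.valid = np.ones(self.patterns.shape[:2], dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.patterns.shape[:2]:
            raise ValueError("valid mask must be subjects x scenes")
        if not self.subject_ids:
            self.subject_ids = [
                f"{self.group}_{i:02d}" for i in range(self.patterns.shape[0])
            ]
        self.subject_ids = list(self.subject_ids)

    @property
    def n_subjects(self) -> int:
        return self.patterns.shape[0]

    @property
    def n_scenes(self) -> int:
        return self.patterns.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.patterns.shape[2]

    def take_scenes(self, idx: np.ndarray) -> "ScenePatternSet":
        return replace(
            self, patterns=self.patterns[:, idx], valid=self.valid[:, idx]
        )


@dataclass
class Dataset:
    """A full three-group, two-phase, multi-ROI dataset.

    ``patterns[(group, phase)]`` is ``subjects x rois x scenes x voxels``;
    ``valid[(group, phase)]`` is ``subjects x scenes`` (shared across ROIs —
    a missed recall is missed in every ROI).
    """

    patterns: Mapping[tuple[str, str], np.ndarray]
    valid: Mapping[tuple[str, str], np.ndarray]
    subject_ids: Mapping[str, Sequence[str]]
    scene_table: SceneTable
    behavior: "pd.DataFrame | None" = None
    truth: dict | None = None

    @property
    def n_rois(self) -> int:
        return next(iter(self.patterns.values())).shape[1]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(g for g, _ in self.patterns))

    def pattern_set(self, group: str, phase: str, roi: int) -> ScenePatternSet:
        arr = self.patterns[(group, phase)]
        return ScenePatternSet(
            patterns=arr[:, roi],
            valid=np.array(self.valid[(group, phase)]),
            group=group,
            phase=phase,
            roi_id=roi,
            subject_ids=list(self.subject_ids[group]),
        )

    def iter_rois(self) -> Iterator[int]:
        return iter(range(self.n_rois))
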