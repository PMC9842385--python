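"""Optional NIfTI ingestion: 4D BOLD + integer parcellation -> ROI series.

Only imported when volumetric input is used; the core pipeline works
entirely on array archives.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import EventDesign, RoiTimeSeries

__all__ = ["load_roi_timeseries", "read_event_design"]


def load_roi_timeseries(
    bold_path: str, atlas_path: str, tr_seconds: float
) -> dict[int, RoiTimeSeries]:
    """Split a 4D BOLD volume into one TR x voxel series per atlas label.

    The atlas is an integer label volume on the same grid; label 0 is
    background.
    """
    import nibabel as nib

    bold = np.asanyarray(nib.load(bold_path).dataobj)
    labels = np.asanyarray(nib.load(atlas_path).dataobj).astype(int)
    if bold.shape[:3] != labels.shape:
        raise ValueError(
            f"BOLD grid {bold.shape[:3]} does not match atlas {labels.shape}"
        )
    out = {}
    for roi in np.unique(labels):
        if roi == 0:
            continue
        mask = labels == roi
        out[int(roi)] = RoiTimeSeries(
            data=bold[mask].T.astype(float),
            tr_seconds=tr_seconds,
            run_id=f"roi_{roi}",
        )
    return out


def read_event_design(
    path: str, n_tr: int, tr_seconds: float
) -> EventDesign:
    """Read a BIDS-events-like TSV (onset, duration, scene_id, epoch_type,
    recognized) into an EventDesign."""
    df = pd.read_csv(path, sep="\t")
    recall = df[df["epoch_type"] == "recall"].sort_values("onset")
    cue = df[df["epoch_type"] == "cue"].sort_values("onset")
    return EventDesign(
        scene_id=recall["scene_id"].to_numpy(int),
        onset_s=recall["onset"].to_numpy(float),
        duration_s=recall["duration"].to_numpy(float),
        recognized=recall.get(
            "recognized", pd.Series(np.ones(len(recall)))
        ).to_numpy().astype(bool),
        cue_onset_s=cue["onset"].to_numpy(float),
        cue_duration_s=cue["duration"].to_numpy(float),
        n_tr=n_tr,
        tr_seconds=tr_seconds,
    )
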