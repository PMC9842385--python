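"""Turn ROI time series into scene-level spatial patterns.

Encoding patterns are temporal averages of the (run z-scored) movie time
series within each scene window.  Recall patterns are least-squares-separate
(LSS) event betas: one GLM per recall event, with that event's HRF-convolved
boxcar as the target regressor, the remaining recall events and the movie-cue
epochs as nuisance regressors, and an intercept.  The LSS route is what makes
the recall patterns robust to the large mean-intensity difference between
audiovisual cue epochs and verbal recall epochs.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .types import EventDesign, RoiTimeSeries, SceneTable

__all__ = [
    "zscore_run",
    "scene_average",
    "hrf_double_gamma",
    "build_lss_designs",
    "estimate_lss_betas",
]


def zscore_run(ts: RoiTimeSeries, ddof: int = 0) -> RoiTimeSeries:
    """Z-score every voxel across the entire run.

    Uses the population (``ddof=0``) standard deviation by default, the
    common neuroimaging convention.  Idempotent up to floating point.

    Raises
    ------
    ValueError
        If any voxel is constant over time (names the offending voxel so
        the caller can drop it).
    """
    sd = ts.data.std(axis=0, ddof=ddof)
    # treat float-rounding residual variance of a constant column as zero
    tol = (np.abs(ts.data).max(axis=0) + 1.0) * 1e-12
    zero = np.flatnonzero(sd <= tol)
    if zero.size:
        raise ValueError(
            f"zero temporal variance in voxel(s) {zero.tolist()}; "
            "drop them before z-scoring"
        )
    data = (ts.data - ts.data.mean(axis=0)) / sd
    return replace(ts, data=data, zscored=True)


def scene_average(
    ts: RoiTimeSeries, scene_table: SceneTable, lag_tr: int = 0
) -> np.ndarray:
    """Average the time series within each scene window.

    A TR with start time ``t`` belongs to scene ``s`` when
    ``onset_s <= (t - lag_tr * tr) < offset_s`` — the half-open rule
    partitions the run with no double counting.  ``lag_tr`` shifts the
    windows later to absorb hemodynamic delay; the default of 0 is
    appropriate because all group contrasts compare like with like, so a
    common lag cancels.

    Returns a ``scenes x voxels`` array.
    """
    t_start = (np.arange(ts.n_tr) - lag_tr) * ts.tr_seconds
    out = np.empty((scene_table.n_scenes, ts.n_voxels))
    for i, (on, off) in enumerate(
        zip(scene_table.onset_s, scene_table.offset_s)
    ):
        sel = (t_start >= on) & (t_start < off)
        if not sel.any():
            raise ValueError(
                f"scene {scene_table.scene_id[i]} window [{on}, {off}) "
                "covers zero TRs"
            )
        out[i] = ts.data[sel].mean(axis=0)
    return out


def hrf_double_gamma(tr_seconds: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Positive gamma peaking near 5 s, undershoot gamma peaking near 15 s
    with amplitude ratio 1/6; zero at t=0; normalized so the kernel peak
    is 1.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0, duration_s + 1e-9, tr_seconds)
    # gamma pdf with shape a, scale b peaks at (a-1)*b
    peak = _gamma_density(t, shape=6.0, scale=1.0)  # peak at 5 s
    under = _gamma_density(t, shape=16.0, scale=1.0)  # peak at 15 s
    h = peak - under / 6.0
    return h / h.max()


def _gamma_density(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    from scipy.stats import gamma

    return gamma.pdf(t, a=shape, scale=scale)


def _convolved_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_tr: int,
    tr_seconds: float,
    oversample: int = 16,
) -> np.ndarray:
    """HRF-convolved boxcar on an oversampled grid, downsampled to TRs."""
    dt = tr_seconds / oversample
    n_fine = n_tr * oversample
    box = np.zeros(n_fine)
    for on, dur in zip(onsets, durations):
        i0 = int(round(on / dt))
        i1 = int(round((on + dur) / dt))
        box[i0 : min(i1, n_fine)] = 1.0
    t_fine = np.arange(0, 32.0 + 1e-9, dt)
    h = hrf_double_gamma(dt, 32.0)
    sig = np.convolve(box, h)[:n_fine]
    return sig[::oversample]


def build_lss_designs(
    event_design: EventDesign,
    lss_other: str = "pooled",
) -> list[np.ndarray]:
    """One design matrix per recall event, LSS style.

    For target event ``e`` the columns are: the HRF-convolved boxcar for
    ``e``; the remaining recall events (pooled into one regressor by
    default, or one column each with ``lss_other="separate"``); one column
    pooling all cue epochs; an intercept.  Columns that would be empty
    (no other events, no cues) are omitted.

    Raises
    ------
    ValueError
        If any design is rank deficient (reports the design's shape and
        target event).
    """
    if event_design.n_events < 1:
        raise ValueError("need at least one recall event")
    if lss_other not in ("pooled", "separate"):
        raise ValueError("lss_other must be 'pooled' or 'separate'")
    n_tr, tr = event_design.n_tr, event_design.tr_seconds

    event_cols = [
        _convolved_regressor(
            np.array([on]), np.array([dur]), n_tr, tr
        )
        for on, dur in zip(event_design.onset_s, event_design.duration_s)
    ]
    cue_col = None
    if len(event_design.cue_onset_s):
        cue_col = _convolved_regressor(
            event_design.cue_onset_s, event_design.cue_duration_s, n_tr, tr
        )

    designs = []
    for e in range(event_design.n_events):
        cols = [event_cols[e]]
        others = [event_cols[j] for j in range(event_design.n_events) if j != e]
        if others:
            if lss_other == "pooled":
                cols.append(np.sum(others, axis=0))
            else:
                cols.extend(others)
        if cue_col is not None:
            cols.append(cue_col)
        cols.append(np.ones(n_tr))
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient LSS design for event {e}: shape {X.shape}"
            )
        designs.append(X)
    return designs


def estimate_lss_betas(
    ts: RoiTimeSeries,
    event_design: EventDesign,
    lss_other: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Ordinary-least-squares LSS betas: one spatial pattern per scene.

    The input series is used as-is (betas are scale-bearing, so no
    z-scoring is applied here).  Returns ``(betas, valid)`` where betas is
    ``scenes x voxels`` (target-column coefficients, ordered by scene_id
    order of the design) and ``valid`` masks out scenes with
    ``recognized=False``.
    """
    designs = build_lss_designs(event_design, lss_other=lss_other)
    if designs[0].shape[0] != ts.n_tr:
        raise ValueError(
            f"design has {designs[0].shape[0]} TRs but series has {ts.n_tr}"
        )
    betas = np.empty((event_design.n_events, ts.n_voxels))
    for e, X in enumerate(designs):
        coef, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
        betas[e] = coef[0]
    valid = event_design.recognized.copy()
    return betas, valid
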