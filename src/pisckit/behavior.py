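"""Rater-score aggregation and brain-behavior coupling.

Recall transcripts are scored scene by scene on a 1-5 "ghostness" scale
(1 = purely the Doctor interpretation, 5 = purely the Ghost
interpretation) by several raters, and separately for recall accuracy
(memory score).  This module aggregates raw rater tables, quantifies
inter-rater reliability, runs the group-level twist-score comparisons, and
correlates behavioral twist scores with neural pattern-change measures at
the subject and the scene level.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .inference import PermutationConfig, bh_fdr
from .pisc import PiscContrast

__all__ = [
    "aggregate_raters",
    "inter_rater_reliability",
    "group_score_tests",
    "brain_behavior_subject",
    "brain_behavior_scene",
]

_RAW_COLUMNS = (
    "subject_id", "group", "scene_id", "rater_id",
    "twist_rating", "memory_rating", "recognized",
)


def aggregate_raters(raw: pd.DataFrame) -> pd.DataFrame:
    """Average ratings across raters: one row per subject x scene.

    Twist ratings average over all raters that scored the scene; memory
    ratings average over the (possibly different) memory raters.  Ratings
    outside [1, 5] raise with the offending rows named.
    """
    missing = set(_RAW_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"raw rating table missing columns: {sorted(missing)}")
    for col in ("twist_rating", "memory_rating"):
        vals = raw[col].dropna()
        bad = vals[(vals < 1) | (vals > 5)]
        if len(bad):
            raise ValueError(
                f"{col} outside the 1-5 scale at rows {bad.index.tolist()[:5]}"
            )
    agg = (
        raw.groupby(["subject_id", "group", "scene_id"], sort=True)
        .agg(
            twist_score=("twist_rating", "mean"),
            memory_score=("memory_rating", "mean"),
            n_raters=("twist_rating", "count"),
            recognized=("recognized", "any"),
        )
        .reset_index()
    )
    return agg


def inter_rater_reliability(
    raw: pd.DataFrame, kind: str = "twist"
) -> pd.DataFrame:
    """Pairwise Pearson correlations between raters over subject x scene rows.

    A rater with constant scores yields NaN against every other rater.
    """
    col = {"twist": "twist_rating", "memory": "memory_rating"}[kind]
    wide = raw.pivot_table(
        index=["subject_id", "scene_id"], columns="rater_id", values=col
    )
    wide = wide.dropna(axis=1, how="all")
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    if wide.dropna().shape[0] < 3:
        raise ValueError("need at least 3 jointly scored items")
    return wide.corr(method="pearson", min_periods=3)


def _subject_twist_scores(
    table: pd.DataFrame, critical_ids: np.ndarray
) -> pd.DataFrame:
    sub = table[table["scene_id"].isin(np.asarray(critical_ids))]
    return (
        sub.groupby(["subject_id", "group"], sort=True)
        .agg(
            twist_score=("twist_score", "mean"),
            memory_score=("memory_score", "mean"),
        )
        .reset_index()
    )


def group_score_tests(
    table: pd.DataFrame, critical_ids: np.ndarray
) -> pd.DataFrame:
    """Two-sample t-tests on subject twist scores between groups.

    The subject-level twist score is the mean over critical scenes.
    Reports twist-vs-no-twist and twist-vs-spoiled pooled-variance t-tests
    (df = nA + nB - 2) and, for reference, the across-subject correlation
    between twist and memory scores.
    """
    scores = _subject_twist_scores(table, critical_ids)
    rows = []
    for ga, gb in (("twist", "no_twist"), ("twist", "spoiled")):
        a = scores.loc[scores["group"] == ga, "twist_score"].to_numpy()
        b = scores.loc[scores["group"] == gb, "twist_score"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs >= 2 subjects")
        if np.ptp(np.concatenate([a, b])) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append(
            {"comparison": f"{ga}_vs_{gb}", "t": float(t), "p": float(p),
             "df": len(a) + len(b) - 2,
             "mean_a": float(a.mean()), "mean_b": float(b.mean())}
        )
    ok = scores.dropna(subset=["twist_score", "memory_score"])
    if len(ok) >= 3 and ok["memory_score"].std() > 0:
        r, rp = stats.pearsonr(ok["twist_score"], ok["memory_score"])
    else:
        r, rp = np.nan, np.nan
    out = pd.DataFrame(rows)
    out.attrs["twist_memory_r"] = float(r)
    out.attrs["twist_memory_p"] = float(rp) if np.isfinite(rp) else np.nan
    return out


def brain_behavior_subject(
    neural_change: np.ndarray,
    subject_ids: list,
    table: pd.DataFrame,
    critical_ids: np.ndarray,
    cfg: PermutationConfig | None = None,
    parametric: bool = False,
) -> tuple[float, float]:
    """Correlate per-subject neural pattern change with twist scores.

    ``neural_change`` is the twist-group encoding-recall contrast value
    per subject (positive = recall pattern closer to the spoiled group's
    encoding).  Returns ``(r, p)``; p is a subject-shuffle permutation
    p-value by default, the parametric Pearson p with
    ``parametric=True``.
    """
    neural = np.asarray(neural_change, dtype=float)
    scores_df = _subject_twist_scores(table, critical_ids)
    scores_df = scores_df.set_index("subject_id")
    scores = scores_df.reindex(subject_ids)["twist_score"].to_numpy()
    ok = ~(np.isnan(neural) | np.isnan(scores))
    neural, scores = neural[ok], scores[ok]
    if len(neural) < 4:
        raise ValueError("need at least 4 subjects")
    r, p_param = stats.pearsonr(neural, scores)
    if parametric:
        return float(r), float(p_param)
    cfg = cfg or PermutationConfig(tail="two_sided")
    rng = cfg.rng()
    null = np.empty(cfg.n_perm)
    for i in range(cfg.n_perm):
        null[i] = stats.pearsonr(neural, rng.permutation(scores))[0]
    if cfg.tail == "greater":
        k = np.sum(null >= r)
    elif cfg.tail == "less":
        k = np.sum(null <= r)
    else:
        k = np.sum(np.abs(null) >= abs(r))
    return float(r), float((1 + k) / (cfg.n_perm + 1))


def brain_behavior_scene(
    scene_contrasts: "dict[int, PiscContrast]",
    table: pd.DataFrame,
    q_level: float = 0.05,
) -> pd.DataFrame:
    """Correlate scene-level neural contrasts with scene-mean twist scores.

    For each ROI: Pearson r between the per-scene neural contrast (mean
    over twist-group subjects) and the per-scene twist score averaged
    across twist-group subjects, with BH-FDR across ROIs.  Scenes masked
    (NaN) on the neural side are dropped pairwise; a flat twist-score
    vector makes r undefined and is reported as NaN.
    """
    twist_tbl = table[table["group"] == "twist"]
    scene_scores = twist_tbl.groupby("scene_id")["twist_score"].mean()
    rows = []
    for roi, con in scene_contrasts.items():
        if con.unit != "scene":
            raise ValueError("scene-level contrasts required")
        scene_ids = np.asarray(con.ids)
        neural = np.asarray(con.values, dtype=float)
        scores = scene_scores.reindex(scene_ids).to_numpy()
        ok = ~(np.isnan(neural) | np.isnan(scores))
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 usable scenes for ROI {roi}")
        if np.ptp(scores[ok]) == 0 or np.ptp(neural[ok]) == 0:
            rows.append({"roi_id": roi, "r": np.nan, "p": np.nan,
                         "n_scenes": int(ok.sum())})
            continue
        r, p = stats.pearsonr(neural[ok], scores[ok])
        # a perfect correlation gives parametric p = 0 exactly; keep it in
        # (0, 1] for the FDR step
        rows.append({"roi_id": roi, "r": float(r),
                     "p": max(float(p), np.finfo(float).tiny),
                     "n_scenes": int(ok.sum())})
    out = pd.DataFrame(rows).set_index("roi_id")
    defined = out["p"].notna()
    out["q"] = np.nan
    out["significant"] = False
    if defined.any():
        rej, qv = bh_fdr(out.loc[defined, "p"].to_numpy(), q_level)
        out.loc[defined, "q"] = qv
        out.loc[defined, "significant"] = rej
    return out
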