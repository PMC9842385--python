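"""Nonparametric inference for pISC contrasts.

All main tests are permutation-based: a sign-flip test for per-subject
difference values (the nonparametric analogue of a paired t-test), a
group-label shuffle for two-sample comparisons, and a scene-shuffle null
that destroys event-level scene correspondence while preserving any
scene-generic group structure — the tool that separates scene-specific
event representations from coarse differences in overall mental state.
Permutation p-values use the (1 + k) / (B + 1) convention, so a p of
exactly zero is never reported.  Multiple comparisons across ROIs are
handled with Benjamini-Hochberg FDR.

Two parametric control analyses are included: a mixed 3 (group, between) x
2 (condition, within) ANOVA on univariate regional means, computed from
explicit sums of squares, and an omnibus ANOVA on within-group
leave-one-out reliability values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import pisc
from .types import Dataset, ScenePatternSet

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "TestResult",
    "signflip_test",
    "grouplabel_test",
    "scene_shuffle_null",
    "bh_fdr",
    "scene_subset_comparison",
    "univariate_control",
    "within_group_reliability",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_perm: int = 1000
    seed: int | None = None
    tail: str = "greater"  # greater | less | two_sided
    scheme: str = "sign_flip"  # sign_flip | group_label | scene_label

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        if self.tail not in ("greater", "less", "two_sided"):
            raise ValueError(f"unknown tail {self.tail!r}")
        if self.scheme not in ("sign_flip", "group_label", "scene_label"):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TestResult:
    observed: float
    null: np.ndarray
    p: float
    tail: str
    scheme: str
    q: float = np.nan
    roi_id: int | None = None

    @property
    def n_perm(self) -> int:
        return len(self.null)


def _perm_p(observed: float, null: np.ndarray, tail: str) -> float:
    b = len(null)
    if tail == "greater":
        k = int(np.sum(null >= observed))
    elif tail == "less":
        k = int(np.sum(null <= observed))
    else:
        k = int(np.sum(np.abs(null) >= abs(observed)))
    return (1 + k) / (b + 1)


def signflip_test(
    values: np.ndarray,
    cfg: PermutationConfig,
    exact: bool = False,
    roi_id: int | None = None,
) -> TestResult:
    """Sign-flip permutation test of mean(values) against zero.

    The null flips the sign of each subject's difference value
    independently; with ``exact=True`` all 2^n sign patterns are
    enumerated instead of sampled (n <= 20).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 3:
        raise ValueError("need at least 3 difference values")
    obs = float(v.mean())
    if np.all(v == 0):
        warnings.warn("all difference values are zero; p = 1")
        null = np.zeros(cfg.n_perm)
        return TestResult(0.0, null, 1.0, cfg.tail, "sign_flip", roi_id=roi_id)
    if exact:
        if len(v) > 20:
            raise ValueError("exact enumeration limited to n <= 20")
        signs = np.array(
            np.meshgrid(*([[-1.0, 1.0]] * len(v)), indexing="ij")
        ).reshape(len(v), -1).T
        null = signs @ v / len(v)
        if cfg.tail == "greater":
            p = float(np.mean(null >= obs))
        elif cfg.tail == "less":
            p = float(np.mean(null <= obs))
        else:
            p = float(np.mean(np.abs(null) >= abs(obs)))
        return TestResult(obs, null, p, cfg.tail, "sign_flip", roi_id=roi_id)
    rng = cfg.rng()
    signs = rng.integers(0, 2, size=(cfg.n_perm, len(v))) * 2.0 - 1.0
    null = signs @ v / len(v)
    return TestResult(
        obs, null, _perm_p(obs, null, cfg.tail), cfg.tail, "sign_flip",
        roi_id=roi_id,
    )


def grouplabel_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    cfg: PermutationConfig,
    roi_id: int | None = None,
) -> TestResult:
    """Independent-sample permutation test of mean(A) - mean(B).

    The null relabels the pooled values, preserving the group sizes.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 values")
    obs = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    rng = cfg.rng()
    order = np.argsort(rng.random((cfg.n_perm, len(pooled))), axis=1)
    shuffled = pooled[order]
    null = shuffled[:, : len(a)].mean(axis=1) - shuffled[:, len(a):].mean(axis=1)
    return TestResult(
        obs, null, _perm_p(obs, null, cfg.tail), cfg.tail, "group_label",
        roi_id=roi_id,
    )


def _shuffle_scenes(
    pset: ScenePatternSet,
    subset: np.ndarray,
    rng: np.random.Generator,
    per_subject: bool,
) -> ScenePatternSet:
    """Permute scene labels within the subset (independently per subject,
    or one shared permutation for the whole group)."""
    k = len(subset)
    pat = pset.patterns.copy()
    val = pset.valid.copy()
    if per_subject:
        perms = np.argsort(rng.random((pset.n_subjects, k)), axis=1)
        rows = np.arange(pset.n_subjects)[:, None]
        pat[:, subset] = pset.patterns[:, subset][rows, perms]
        val[:, subset] = pset.valid[:, subset][rows, perms]
    else:
        perm = rng.permutation(k)
        pat[:, subset] = pset.patterns[:, subset][:, perm]
        val[:, subset] = pset.valid[:, subset][:, perm]
    return ScenePatternSet(
        patterns=pat, valid=val, group=pset.group, phase=pset.phase,
        roi_id=pset.roi_id, subject_ids=list(pset.subject_ids),
    )


def scene_shuffle_null(
    dataset: Dataset,
    roi: int,
    scene_subset: "str | np.ndarray",
    cfg: PermutationConfig,
    per_subject: bool = True,
) -> TestResult:
    """Scene-specificity null for the interaction index in one ROI.

    Per iteration, scene labels inside the analysed subset are shuffled
    within each subject (``per_subject=False`` shares one permutation per
    group instead), the full pISC interaction index is recomputed, and the
    observed index is compared against the resulting null (one-tailed by
    default).  A subset of fewer than 2 scenes leaves nothing to shuffle
    and raises.
    """
    full_idx = dataset.scene_table.subset_indices(scene_subset)
    if len(full_idx) < 2:
        raise ValueError("scene shuffle needs at least 2 scenes in subset")
    # restrict to the analysed scenes up front; the shuffle then permutes
    # every remaining scene label
    sets = {
        (g, p): dataset.pattern_set(g, p, roi).take_scenes(full_idx)
        for g in ("spoiled", "twist", "no_twist")
        for p in ("encoding", "recall")
    }
    idx = np.arange(len(full_idx))

    def _interaction(sdict) -> float:
        enc = pisc.contrast(
            sdict[("twist", "encoding")], sdict[("no_twist", "encoding")],
            sdict[("spoiled", "encoding")], idx,
        )
        rec = pisc.contrast(
            sdict[("twist", "recall")], sdict[("no_twist", "recall")],
            sdict[("spoiled", "recall")], idx,
        )
        return pisc.interaction_index(enc, rec).mean

    observed = _interaction(sets)
    rng = cfg.rng()
    null = np.empty(cfg.n_perm)
    for it in range(cfg.n_perm):
        shuffled = {
            key: _shuffle_scenes(ps, idx, rng, per_subject)
            for key, ps in sets.items()
        }
        null[it] = _interaction(shuffled)
    return TestResult(
        observed, null, _perm_p(observed, null, cfg.tail), cfg.tail,
        "scene_label", roi_id=roi,
    )


def bh_fdr(
    pvals: np.ndarray, q_level: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(rejected, q_values)``; q-values are monotone-enforced and
    order-invariant.  Empty input yields empty output.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    reject, qvals, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return reject, qvals


def scene_subset_comparison(
    interactions_by_subset: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Paired t-tests across ROIs between scene-subset interaction indices.

    Compares critical vs all-scene and critical vs non-critical per-ROI
    interaction means; degrees of freedom are n_rois - 1.  A zero-variance
    difference (identical or constant-offset inputs) is reported with a
    note instead of an unbounded t.
    """
    if "critical" not in interactions_by_subset:
        raise ValueError("need a 'critical' subset")
    crit = np.asarray(interactions_by_subset["critical"], dtype=float)
    if len(crit) < 3:
        raise ValueError("need at least 3 ROIs for a paired t-test")
    rows = []
    for other in ("all", "non_critical"):
        if other not in interactions_by_subset:
            continue
        o = np.asarray(interactions_by_subset[other], dtype=float)
        if len(o) != len(crit):
            raise ValueError("subsets must cover the same ROI list")
        d = crit - o
        if np.ptp(d) <= 1e-10 * max(1.0, float(np.abs(d).max())):
            t = 0.0 if np.allclose(d, 0) else np.nan
            p = 1.0 if np.allclose(d, 0) else np.nan
            note = "zero-variance difference"
        else:
            t, p = stats.ttest_rel(crit, o)
            note = ""
        rows.append(
            {"comparison": f"critical_vs_{other}", "t": float(t),
             "p": float(p), "df": len(crit) - 1, "note": note}
        )
    return pd.DataFrame(rows)


def _mixed_anova_ss(y: np.ndarray, group_sizes: list[int]) -> dict:
    """Split-plot ANOVA from explicit sums of squares.

    ``y`` is ``subjects x conditions`` with subjects blocked by group in
    order.  Between factor: group; within factor: condition.
    """
    n_total, c = y.shape
    k = len(group_sizes)
    g_of = np.repeat(np.arange(k), group_sizes)
    grand = y.mean()
    subj_mean = y.mean(axis=1)
    cond_mean = y.mean(axis=0)
    group_mean = np.array([y[g_of == g].mean() for g in range(k)])
    cell_mean = np.array(
        [y[g_of == g].mean(axis=0) for g in range(k)]
    )  # k x c

    ng = np.asarray(group_sizes, dtype=float)
    ss_group = c * float(np.sum(ng * (group_mean - grand) ** 2))
    ss_subj = c * float(np.sum((subj_mean - group_mean[g_of]) ** 2))
    ss_cond = n_total * float(np.sum((cond_mean - grand) ** 2))
    ss_gc = float(
        np.sum(
            ng[:, None]
            * (cell_mean - group_mean[:, None] - cond_mean[None, :] + grand)
            ** 2
        )
    )
    resid = y - subj_mean[:, None] - cell_mean[g_of] + group_mean[g_of][:, None]
    ss_err = float(np.sum(resid**2))

    df_group, df_subj = k - 1, n_total - k
    df_cond, df_gc = c - 1, (k - 1) * (c - 1)
    df_err = (n_total - k) * (c - 1)

    def _f(ss_num, df_num, ss_den, df_den):
        if df_den <= 0:
            return np.nan, np.nan
        ms_den = ss_den / df_den
        ms_num = ss_num / df_num
        if ms_den == 0:
            return (0.0, 1.0) if ms_num == 0 else (np.inf, 0.0)
        f = ms_num / ms_den
        return f, float(stats.f.sf(f, df_num, df_den))

    f_group, p_group = _f(ss_group, df_group, ss_subj, df_subj)
    f_cond, p_cond = _f(ss_cond, df_cond, ss_err, df_err)
    f_gc, p_gc = _f(ss_gc, df_gc, ss_err, df_err)
    return {
        "F_group": f_group, "p_group": p_group,
        "F_condition": f_cond, "p_condition": p_cond,
        "F_interaction": f_gc, "p_interaction": p_gc,
        "df_group": df_group, "df_subj": df_subj,
        "df_interaction": df_gc, "df_error": df_err,
    }


def univariate_control(dataset: Dataset) -> pd.DataFrame:
    """Mixed group x condition ANOVA on univariate regional means, per ROI.

    The univariate response is each subject's mean activation over voxels
    and valid scenes (scene averages at encoding, LSS betas at recall); a
    group main effect or group-by-condition interaction here would signal
    that pattern effects could be driven by overall activation
    differences.
    """
    groups = ("spoiled", "twist", "no_twist")
    rows = []
    for roi in dataset.iter_rois():
        ys, sizes = [], []
        for g in groups:
            enc = dataset.pattern_set(g, "encoding", roi)
            rec = dataset.pattern_set(g, "recall", roi)
            n = enc.n_subjects
            y = np.empty((n, 2))
            dropped = 0
            for i in range(n):
                ev, rv = enc.valid[i], rec.valid[i]
                if not ev.any() or not rv.any():
                    dropped += 1
                    y[i] = np.nan
                    continue
                y[i, 0] = enc.patterns[i][ev].mean()
                y[i, 1] = rec.patterns[i][rv].mean()
            if dropped:
                logger.info(
                    "univariate control: dropped %d subject(s) in %s roi %d",
                    dropped, g, roi,
                )
            y = y[~np.isnan(y).any(axis=1)]
            ys.append(y)
            sizes.append(len(y))
        res = _mixed_anova_ss(np.vstack(ys), sizes)
        res["roi_id"] = roi
        rows.append(res)
    return pd.DataFrame(rows).set_index("roi_id")


def within_group_reliability(
    dataset: Dataset,
    rois: "list[int] | None" = None,
    scene_subset: "str | np.ndarray" = "critical",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leave-one-out within-group pISC reliability, plus an omnibus ANOVA.

    For every subject, phase and ROI, correlates the subject's scene
    patterns with the average of the rest of their own group and averages
    the Fisher-z values over scenes.  The omnibus ANOVA (group x condition
    x ROI) checks that no group is systematically noisier than the others.
    Returns ``(long_table, anova_table)``.
    """
    idx = dataset.scene_table.subset_indices(scene_subset)
    if rois is None:
        rois = list(dataset.iter_rois())
    recs = []
    for roi in rois:
        for g in ("spoiled", "twist", "no_twist"):
            if len(dataset.subject_ids[g]) < 3:
                raise ValueError("need >= 3 subjects per group")
            for phase in ("encoding", "recall"):
                ps = dataset.pattern_set(g, phase, roi)
                z = pisc._scene_z_matrix(ps, ps, idx, leave_one_out=True)
                zbar = z.mean(axis=1)
                for sid, val in zip(ps.subject_ids, zbar):
                    if val is np.ma.masked:
                        continue
                    recs.append(
                        {"subject_id": sid, "group": g, "condition": phase,
                         "roi": roi, "z": float(val)}
                    )
    long = pd.DataFrame(recs)
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    terms = ["C(group)", "C(condition)"]
    if long["roi"].nunique() > 1:
        terms.append("C(roi)")
    model = smf.ols(f"z ~ {' * '.join(terms)}", data=long).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    return long, anova
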