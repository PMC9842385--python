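"""Statsmodels-style front end: fit the full pISC analysis to a dataset.

:class:`MemoryUpdateModel` wraps a :class:`~pisckit.types.Dataset` (real
or simulated) and, on :meth:`~MemoryUpdateModel.fit`, runs the directed
group contrasts, the interaction index, their permutation tests with
BH-FDR across ROIs, the scene-content analyses, the univariate and
reliability controls, and the behavior couplings.  The returned
:class:`MemoryUpdateResults` carries per-ROI tables and a ``summary()``.

The five neural analyses, with their predicted one-tailed directions on
the (no-twist reference minus spoiled reference) orientation:

``enc_enc``
    Twist-group encoding vs both other groups' encoding; predicted
    positive (twist and no-twist share the Doctor interpretation).
``rec_rec``
    Same on recall; predicted negative (twist recall shifts toward the
    spoiled Ghost interpretation).
``interaction``
    Encoding minus recall contrast; predicted positive under updating.
``enc_rec_a``
    Similarity of each group's recall to spoiled *encoding*; twist vs
    no-twist compared with a group-label shuffle; predicted greater.
``enc_rec_b``
    Twist recall vs spoiled encoding minus twist recall vs (rest of) own
    encoding, sign-flip tested; the reference sets are N-matched by a
    random drop from the larger encoding set, redrawn at every
    permutation iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import behavior as bh
from . import inference as inf
from . import pisc
from .inference import PermutationConfig
from .types import Dataset

__all__ = ["MemoryUpdateModel", "MemoryUpdateResults"]

_ALL_ANALYSES = (
    "enc_enc", "rec_rec", "interaction", "enc_rec_a", "enc_rec_b",
    "scene_content", "univariate", "reliability", "behavior",
)


def _child_seed(root: np.random.SeedSequence, *key: int) -> int:
    return int(
        np.random.SeedSequence(
            entropy=root.entropy, spawn_key=tuple(key)
        ).generate_state(1)[0] % (2**31)
    )


@dataclass
class MemoryUpdateResults:
    """Estimates, permutation p-values and FDR q-values per ROI."""

    tables: dict[str, pd.DataFrame]
    contrasts: dict[str, dict[int, pisc.PiscContrast]]
    interactions: dict[int, pisc.InteractionResult]
    config: dict = field(default_factory=dict)

    def table(self, analysis: str) -> pd.DataFrame:
        return self.tables[analysis]

    def summary(self) -> str:
        lines = ["Memory-updating pISC analysis", "=" * 34]
        cfg = self.config
        lines.append(
            f"scene subset: {cfg.get('scene_subset')}   "
            f"n_perm: {cfg.get('n_perm')}   seed: {cfg.get('seed')}"
        )
        for name, tbl in self.tables.items():
            lines.append("")
            lines.append(f"[{name}]")
            lines.append(tbl.round(4).to_string())
        return "\n".join(lines)

    def plot_interaction(self, ax=None):
        """Bar plot of interaction indices per ROI with significance marks."""
        import matplotlib.pyplot as plt

        tbl = self.tables["interaction"]
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.5 * len(tbl), 3))
        ax.bar(tbl.index.astype(str), tbl["mean"], color="steelblue")
        for x, (_, row) in enumerate(tbl.iterrows()):
            if row.get("significant", False):
                ax.text(x, row["mean"], "*", ha="center", va="bottom")
        ax.axhline(0, color="k", lw=0.5)
        ax.set_xlabel("ROI")
        ax.set_ylabel("interaction index (z)")
        return ax


class MemoryUpdateModel:
    """The full between-group pISC pipeline over a three-group dataset.

    Parameters
    ----------
    dataset
        Scene-level patterns for all groups and phases, plus the scene
        table and (optionally) the rater-level behavior table.
    scene_subset
        Scenes entering the main contrasts: ``"critical"`` (default, the
        scenes whose interpretation the twist changes), ``"non_critical"``,
        ``"all"`` or explicit scene ids.
    n_perm
        Permutation iterations for every nonparametric test.
    analyses
        Which stages to run; default all.
    match_n
        Random-drop N-matching of the two encoding references in the
        ``enc_rec_b`` comparison.
    """

    def __init__(
        self,
        dataset: Dataset,
        scene_subset: "str | Sequence[int]" = "critical",
        n_perm: int = 1000,
        analyses: Sequence[str] = _ALL_ANALYSES,
        match_n: bool = True,
        fdr_q: float = 0.05,
    ) -> None:
        unknown = set(analyses) - set(_ALL_ANALYSES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        self.dataset = dataset
        self.scene_subset = scene_subset
        self.scene_idx = dataset.scene_table.subset_indices(scene_subset)
        self.n_perm = n_perm
        self.analyses = tuple(analyses)
        self.match_n = match_n
        self.fdr_q = fdr_q

    @classmethod
    def from_spec(cls, spec, **kwargs) -> "MemoryUpdateModel":
        """Simulate a dataset from a SyntheticSpec and wrap it."""
        from .synthetic import simulate_dataset

        return cls(simulate_dataset(spec), **kwargs)

    # ------------------------------------------------------------------
    def _sets(self, roi: int) -> dict:
        return {
            (g, p): self.dataset.pattern_set(g, p, roi)
            for g in ("spoiled", "twist", "no_twist")
            for p in ("encoding", "recall")
        }

    def _enc_rec_b_values(
        self, sets: dict, rng: np.random.Generator | None
    ) -> np.ndarray:
        con = pisc.contrast(
            sets[("twist", "recall")],
            sets[("spoiled", "encoding")],
            sets[("twist", "encoding")],
            self.scene_idx,
            match_n=self.match_n,
            rng=rng,
        )
        return con.values

    def fit(self, seed: int = 0) -> MemoryUpdateResults:
        root = np.random.SeedSequence(seed)
        ds = self.dataset
        tables: dict[str, pd.DataFrame] = {}
        contrasts: dict[str, dict[int, pisc.PiscContrast]] = {}
        interactions: dict[int, pisc.InteractionResult] = {}

        neural_specs = {
            "enc_enc": ("greater",),
            "rec_rec": ("less",),
            "interaction": ("greater",),
            "enc_rec_a": ("greater",),
            "enc_rec_b": ("greater",),
        }
        rows: dict[str, list] = {k: [] for k in neural_specs}
        for name in neural_specs:
            contrasts[name] = {}

        for roi in ds.iter_rois():
            sets = self._sets(roi)
            enc = pisc.contrast(
                sets[("twist", "encoding")], sets[("no_twist", "encoding")],
                sets[("spoiled", "encoding")], self.scene_idx,
            )
            rec = pisc.contrast(
                sets[("twist", "recall")], sets[("no_twist", "recall")],
                sets[("spoiled", "recall")], self.scene_idx,
            )
            inter = pisc.interaction_index(enc, rec)
            interactions[roi] = inter

            if "enc_enc" in self.analyses:
                cfg = PermutationConfig(
                    self.n_perm, _child_seed(root, 1, roi), "greater"
                )
                res = inf.signflip_test(enc.values, cfg, roi_id=roi)
                contrasts["enc_enc"][roi] = enc
                rows["enc_enc"].append((roi, res.observed, res.p))
            if "rec_rec" in self.analyses:
                cfg = PermutationConfig(
                    self.n_perm, _child_seed(root, 2, roi), "less"
                )
                res = inf.signflip_test(rec.values, cfg, roi_id=roi)
                contrasts["rec_rec"][roi] = rec
                rows["rec_rec"].append((roi, res.observed, res.p))
            if "interaction" in self.analyses:
                cfg = PermutationConfig(
                    self.n_perm, _child_seed(root, 3, roi), "greater"
                )
                res = inf.signflip_test(inter.values, cfg, roi_id=roi)
                rows["interaction"].append((roi, res.observed, res.p))
            if "enc_rec_a" in self.analyses:
                # per-subject similarity to spoiled encoding (single ref)
                tw_sim = self._similarity_to(
                    sets[("twist", "recall")], sets[("spoiled", "encoding")]
                )
                nt_sim = self._similarity_to(
                    sets[("no_twist", "recall")], sets[("spoiled", "encoding")]
                )
                cfg = PermutationConfig(
                    self.n_perm, _child_seed(root, 4, roi), "greater"
                )
                res = inf.grouplabel_test(tw_sim, nt_sim, cfg, roi_id=roi)
                contrasts["enc_rec_a"][roi] = pisc.PiscContrast(
                    values=tw_sim, unit="subject",
                    ids=list(sets[("twist", "recall")].subject_ids),
                    comparison={"target": ("twist", "recall"),
                                "ref": ("spoiled", "encoding")},
                    scene_subset=self.scene_idx, roi_id=roi,
                )
                rows["enc_rec_a"].append((roi, res.observed, res.p))
            if "enc_rec_b" in self.analyses:
                rng_obs = np.random.default_rng(_child_seed(root, 5, roi))
                values = self._enc_rec_b_values(
                    sets, rng_obs if self.match_n else None
                )
                obs = float(np.nanmean(values))
                rng_null = np.random.default_rng(_child_seed(root, 6, roi))
                null = np.empty(self.n_perm)
                for it in range(self.n_perm):
                    v = (
                        self._enc_rec_b_values(sets, rng_null)
                        if self.match_n else values
                    )
                    v = v[~np.isnan(v)]
                    signs = rng_null.integers(0, 2, len(v)) * 2.0 - 1.0
                    null[it] = float((signs * v).mean())
                p = (1 + int(np.sum(null >= obs))) / (self.n_perm + 1)
                contrasts["enc_rec_b"][roi] = pisc.PiscContrast(
                    values=values, unit="subject",
                    ids=list(sets[("twist", "recall")].subject_ids),
                    comparison={"target": ("twist", "recall"),
                                "ref_a": ("spoiled", "encoding"),
                                "ref_b": ("twist", "encoding")},
                    scene_subset=self.scene_idx, roi_id=roi,
                )
                rows["enc_rec_b"].append((roi, obs, p))

        for name, rws in rows.items():
            if not rws:
                continue
            tbl = pd.DataFrame(
                rws, columns=["roi_id", "mean", "p"]
            ).set_index("roi_id")
            rej, qv = inf.bh_fdr(tbl["p"].to_numpy(), self.fdr_q)
            tbl["q"] = qv
            tbl["significant"] = rej
            tables[name] = tbl
            if name == "interaction":
                for roi in tbl.index:
                    interactions[roi].p = float(tbl.loc[roi, "p"])
                    interactions[roi].q = float(tbl.loc[roi, "q"])

        if "scene_content" in self.analyses:
            tables.update(self._fit_scene_content(root))
        if "univariate" in self.analyses:
            tables["univariate"] = inf.univariate_control(ds)
        if "reliability" in self.analyses:
            _, anova = inf.within_group_reliability(
                ds, scene_subset=self.scene_subset
            )
            tables["reliability"] = anova
        if "behavior" in self.analyses and ds.behavior is not None:
            tables.update(self._fit_behavior(root, contrasts))

        return MemoryUpdateResults(
            tables=tables,
            contrasts=contrasts,
            interactions=interactions,
            config={
                "scene_subset": self.scene_subset,
                "n_perm": self.n_perm,
                "seed": seed,
                "match_n": self.match_n,
                "fdr_q": self.fdr_q,
            },
        )

    # ------------------------------------------------------------------
    def _similarity_to(self, target, ref) -> np.ndarray:
        z = pisc._scene_z_matrix(
            target, ref, self.scene_idx, target.group == ref.group
        )
        return z.mean(axis=1).filled(np.nan)

    def _fit_scene_content(self, root) -> dict[str, pd.DataFrame]:
        ds = self.dataset
        by_subset = {}
        for subset in ("critical", "non_critical", "all"):
            idx = ds.scene_table.subset_indices(subset)
            by_subset[subset] = np.array(
                [
                    pisc.dataset_interaction(ds, roi, idx).mean
                    for roi in ds.iter_rois()
                ]
            )
        paired = (
            inf.scene_subset_comparison(by_subset)
            if ds.n_rois >= 3 else pd.DataFrame()
        )
        shuffle_rows = []
        for roi in ds.iter_rois():
            cfg = PermutationConfig(
                self.n_perm, _child_seed(root, 7, roi), "greater",
                scheme="scene_label",
            )
            res = inf.scene_shuffle_null(ds, roi, self.scene_subset, cfg)
            shuffle_rows.append((roi, res.observed, res.p))
        shuf = pd.DataFrame(
            shuffle_rows, columns=["roi_id", "observed", "p"]
        ).set_index("roi_id")
        rej, qv = inf.bh_fdr(shuf["p"].to_numpy(), self.fdr_q)
        shuf["q"] = qv
        shuf["significant"] = rej
        subset_tbl = pd.DataFrame(by_subset)
        subset_tbl.index.name = "roi_id"
        return {
            "scene_subsets": subset_tbl,
            "scene_subset_ttests": paired,
            "scene_shuffle": shuf,
        }

    def _fit_behavior(self, root, contrasts) -> dict[str, pd.DataFrame]:
        ds = self.dataset
        table = bh.aggregate_raters(ds.behavior)
        crit = ds.scene_table.critical_ids
        out: dict[str, pd.DataFrame] = {}
        out["behavior_group_tests"] = bh.group_score_tests(table, crit)
        source = contrasts.get("enc_rec_b") or contrasts.get("rec_rec")
        if source:
            rows = []
            for roi, con in source.items():
                cfg = PermutationConfig(
                    self.n_perm, _child_seed(root, 8, roi), "two_sided"
                )
                r, p = bh.brain_behavior_subject(
                    con.values, con.ids, table, crit, cfg
                )
                rows.append((roi, r, p))
            bb = pd.DataFrame(
                rows, columns=["roi_id", "r", "p"]
            ).set_index("roi_id")
            rej, qv = inf.bh_fdr(bb["p"].to_numpy(), self.fdr_q)
            bb["q"] = qv
            bb["significant"] = rej
            out["brain_behavior_subject"] = bb
        scene_cons = {
            roi: pisc.scene_level_contrast(
                self.dataset.pattern_set("twist", "recall", roi),
                self.dataset.pattern_set("spoiled", "recall", roi),
                self.dataset.pattern_set("no_twist", "recall", roi),
                ds.scene_table.subset_indices("all"),
            )
            for roi in ds.iter_rois()
        }
        out["brain_behavior_scene"] = bh.brain_behavior_scene(
            scene_cons, table, self.fdr_q
        )
        return out
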