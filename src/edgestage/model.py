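"""Top-level modelling interface.

:class:`StageBiomarkerModel` wraps a cohort (expression matrix, phenotype
table, optional protein-interaction pair universe) and a
:class:`~edgestage.config.PipelineConfig`; :meth:`StageBiomarkerModel.fit`
runs the full pipeline — preprocessing, stage-wise differential expression
and intersection, normal-reference fitting, the three edge feature
matrices, per-type random-forest rankings, and the composition grid search
— and returns a :class:`StageBiomarkerResults` carrying the estimates,
their cross-validated uncertainty, and prediction/summary/plot methods.

    >>> model = StageBiomarkerModel(expr, pheno, universe)
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    >>> res.predict(expr.sample("S0123"))
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort_io, edge_features, feature_selection, integration, node_features
from .cohort_io import ExpressionMatrix, PairUniverse, PhenotypeTable
from .config import PipelineConfig
from .errors import ValidationError

logger = logging.getLogger(__name__)


class StageBiomarkerModel:
    """Node+edge biomarker discovery for multi-class stage classification.

    Parameters
    ----------
    expression
        Genes × samples matrix.  Raw matrices are log2(x+1)-transformed
        and zero-filtered during :meth:`fit`; already-transformed matrices
        are only filtered.
    phenotype
        Sample → stage labels (``normal``, ``I``–``IV``).
    pair_universe
        Optional pair list (e.g. physical protein links).  Without one,
        edge features are built over all pairs among the intersection DEGs,
        capped deterministically.
    config
        Pipeline tunables; defaults are sensible for cohorts of a few
        hundred samples.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        phenotype: PhenotypeTable,
        pair_universe: PairUniverse | None = None,
        config: PipelineConfig | None = None,
    ):
        self.config = config or PipelineConfig()
        labelled = [s for s in phenotype.sample_ids if s in set(expression.sample_ids)]
        if not labelled:
            raise ValidationError("no labelled samples present in the expression matrix")
        self.phenotype = PhenotypeTable(phenotype.labels.loc[labelled])
        self.expression = expression
        self.pair_universe = pair_universe

    @classmethod
    def from_files(
        cls,
        expression_path,
        phenotype_path,
        pair_universe_path=None,
        config: PipelineConfig | None = None,
        already_log: bool = False,
    ) -> "StageBiomarkerModel":
        expr = cohort_io.read_expression(expression_path)
        if already_log:
            expr = ExpressionMatrix(expr.values, log_transformed=True)
        pheno = cohort_io.read_phenotype(phenotype_path)
        universe = None
        if pair_universe_path is not None:
            universe = cohort_io.read_pair_universe(pair_universe_path, expr)
        return cls(expr, pheno, universe, config)

    # -- pipeline stages ---------------------------------------------------

    def _preprocess(self) -> ExpressionMatrix:
        m = self.expression
        if not m.log_transformed:
            m = cohort_io.log_transform(m)
        return cohort_io.filter_low_expression(m, self.config.max_zero_fraction)

    def _resolve_universe(self, m: ExpressionMatrix, intersection: list[str]) -> PairUniverse:
        cfg = self.config
        if self.pair_universe is not None and cfg.pair_universe_mode == "ppi":
            genes = set(m.gene_ids)
            pairs = tuple(p for p in self.pair_universe if p[0] in genes and p[1] in genes)
            if not pairs:
                raise ValidationError("no universe pair survives gene filtering")
            return PairUniverse(pairs, source=self.pair_universe.source)
        if len(intersection) < 2:
            raise ValidationError(
                "fewer than two intersection DEGs: cannot build a fallback pair universe"
            )
        return cohort_io.pairs_from_genes(
            intersection, max_pairs=cfg.max_fallback_pairs, source="deg-pairs"
        )

    def fit(self, seed: int = 0) -> "StageBiomarkerResults":
        """Run the full pipeline; deterministic given ``seed``."""
        cfg = self.config
        m = self._preprocess()
        pheno = self.phenotype.restrict_to(m.sample_ids)

        de_results, intersection = node_features.stage_wise_de(
            m, pheno, test=cfg.de_test, fdr_alpha=cfg.fdr_alpha, min_abs_lfc=cfg.min_abs_lfc
        )
        logger.info("intersection DEGs: %d", len(intersection))
        if not intersection:
            raise ValidationError(
                "empty intersection DEG list: no stage-consistent node candidates"
            )

        universe = self._resolve_universe(m, intersection)
        reference = edge_features.fit_reference(m, pheno, universe)

        class_pheno = pheno
        if not cfg.include_normal:
            keep = [s for s in pheno.sample_ids if pheno.labels[s] != "normal"]
            class_pheno = PhenotypeTable(pheno.labels.loc[keep])
        labels = class_pheno.labels

        feats: dict[str, pd.DataFrame] = {
            "node": m.values.loc[intersection, list(labels.index)].T
        }
        edge_mats = {}
        for t in edge_features.FEATURE_TYPES:
            em = edge_features.build_edge_matrix(reference, m, class_pheno, t)
            edge_mats[t] = em
            feats[t] = em.values

        rankings = {}
        for t in integration.TYPE_ORDER:
            ranked = feature_selection.rank_by_forest(
                feats[t], labels, t,
                forest_params=cfg.forest_params, cv_folds=cfg.folds, seed=seed,
            )
            k = min(cfg.top_k, len(ranked))
            rankings[t] = feature_selection.RankedFeatureList(
                feature_type=t,
                entries=ranked.entries.iloc[:k].reset_index(drop=True),
                folds=ranked.folds,
                seed=seed,
            )

        selection, search_table = integration.grid_search_integration(
            rankings, feats, labels,
            max_per_type=cfg.max_per_type, max_total=cfg.max_total,
            forest_params=cfg.forest_params, folds=cfg.folds, seed=seed,
            average=cfg.f1_average,
        )
        bundle = integration.train_final_classifier(
            selection, feats, labels, reference, forest_params=cfg.forest_params
        )
        return StageBiomarkerResults(
            model=self,
            seed=seed,
            preprocessed=m,
            de_results=de_results,
            intersection_degs=intersection,
            pair_universe=universe,
            reference=reference,
            feature_matrices=feats,
            rankings=rankings,
            selection=selection,
            search_table=search_table,
            bundle=bundle,
        )


@dataclass
class StageBiomarkerResults:
    """Fitted pipeline state: rankings, the selected composition, and the
    deployable classifier bundle."""

    model: StageBiomarkerModel
    seed: int
    preprocessed: ExpressionMatrix
    de_results: dict[str, node_features.DeResult]
    intersection_degs: list[str]
    pair_universe: PairUniverse
    reference: edge_features.PairReferenceModel
    feature_matrices: dict[str, pd.DataFrame]
    rankings: dict[str, feature_selection.RankedFeatureList]
    selection: integration.IntegratedSelection
    search_table: pd.DataFrame
    bundle: integration.StageClassifierBundle

    @property
    def cv_f1(self) -> float:
        """Mean cross-validated multi-class F1 of the selected composition."""
        return self.selection.cv_f1.mean

    def predict(self, sample: pd.Series) -> tuple[str, dict[str, float]]:
        """Stage label and per-class scores for one expression vector."""
        return integration.classify_sample(self.bundle, sample)

    def f1_curve(self) -> pd.DataFrame:
        """Best mean F1 at each total feature count, from the search table."""
        return (
            self.search_table.groupby("total", as_index=False)["mean_f1"]
            .max()
            .sort_values("total", ignore_index=True)
        )

    def plot_f1_curve(self, ax=None):
        """Matplotlib plot of best F1 versus total features."""
        import matplotlib.pyplot as plt

        curve = self.f1_curve()
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["total"], curve["mean_f1"], marker="o")
        ax.set_xlabel("total number of features")
        ax.set_ylabel(f"mean CV {self.selection.cv_f1.average}-F1")
        ax.set_title("integrated composition search")
        return ax

    def summary(self) -> str:
        """Human-readable account of the fitted pipeline."""
        cfg = self.model.config
        lines = []
        w = 64
        lines.append("=" * w)
        lines.append("Stage biomarker discovery — node + edge features")
        lines.append("=" * w)
        counts = self.model.phenotype.counts()
        lines.append(
            "samples: " + ", ".join(f"{s}={counts[s]}" for s in cohort_io.STAGES)
        )
        lines.append(
            f"genes after filtering: {self.preprocessed.shape[0]}; "
            f"pair universe: {len(self.pair_universe)} ({self.pair_universe.source})"
        )
        for s in cohort_io.TUMOR_STAGES:
            lines.append(f"  DEGs stage {s:<3}: {len(self.de_results[s].degs)}")
        lines.append(f"intersection DEGs (node candidates): {len(self.intersection_degs)}")
        lines.append(
            f"reference: {self.reference.n} normals, {len(self.reference)} pairs "
            f"({self.reference.n_dropped_degenerate} degenerate dropped)"
        )
        lines.append("-" * w)
        lines.append("selected composition (top-ranked features per type):")
        for t in integration.TYPE_ORDER:
            chosen = [f for ft, f in self.selection.features if ft == t]
            lines.append(f"  {t:<10} {self.selection.counts[t]}: " + ", ".join(chosen))
        cv = self.selection.cv_f1
        lines.append(
            f"total features: {self.selection.total}; "
            f"CV {cv.average}-F1 = {cv.mean:.3f} "
            f"(sd {np.std(cv.fold_f1):.3f} over {cv.folds} folds, seed {self.seed})"
        )
        lines.append(
            f"search: {len(self.search_table)} compositions, "
            f"max_per_type={cfg.max_per_type}, max_total={cfg.max_total}"
        )
        lines.append("=" * w)
        return "\n".join(lines)

    def save_bundle(self, path) -> None:
        integration.save_bundle(self.bundle, path)


__all__ = ["StageBiomarkerModel", "StageBiomarkerResults"]
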