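"""Per-stage differential expression versus normal, and the cross-stage
intersection that defines the node-feature candidate pool.

Each tumour stage is contrasted against the normal group with a pluggable
two-sample test on log2 expression (Wilcoxon rank-sum by default, Welch's t
optionally), p-values are adjusted per stage by Benjamini–Hochberg, and a
gene is called differentially expressed when q <= fdr_alpha and
|log2 fold change| >= min_abs_lfc.  Genes called in *every* stage — the
intersection rather than the union — form the stage-consistent candidate
list.  A precomputed DEG list (e.g. from an external count-model tool) can
be plugged in via :func:`read_deg_list`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort_io import TUMOR_STAGES, ExpressionMatrix, PhenotypeTable
from .errors import ValidationError

DE_TESTS = ("rank_sum", "welch_t")


@dataclass
class DeResult:
    """Differential-expression result for one stage-vs-normal contrast.

    ``table`` has one row per gene with columns ``lfc`` (stage mean minus
    normal mean, log2 scale), ``pvalue``, ``qvalue`` (Benjamini–Hochberg)
    and boolean ``called``.
    """

    stage: str
    test: str
    fdr_alpha: float
    min_abs_lfc: float
    table: pd.DataFrame

    @property
    def degs(self) -> list[str]:
        """Called genes, ordered by ascending q-value then gene id."""
        called = self.table[self.table["called"]]
        ordered = called.sort_values(["qvalue", "gene"], kind="mergesort")
        return list(ordered["gene"])

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _two_sample_pvalues(a: np.ndarray, b: np.ndarray, test: str) -> np.ndarray:
    """Vectorised per-gene p-values for groups ``a``/``b`` (genes × samples)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        if test == "rank_sum":
            res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="asymptotic")
        else:
            res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # a gene constant across both groups has no test statistic: p = 1
    return np.where(np.isnan(p), 1.0, p)


def differential_expression(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    stage: str,
    test: str = "rank_sum",
    fdr_alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> DeResult:
    """One stage-vs-normal contrast over all genes of ``m``."""
    if not m.log_transformed:
        raise ValidationError("differential expression expects a log-transformed matrix")
    if test not in DE_TESTS:
        raise ValidationError(f"unknown test {test!r}; choose from {DE_TESTS}")
    if stage not in TUMOR_STAGES:
        raise ValidationError(f"stage must be one of {TUMOR_STAGES}, got {stage!r}")
    stage_samples = [s for s in pheno.samples_for(stage) if s in set(m.sample_ids)]
    normal_samples = [s for s in pheno.samples_for("normal") if s in set(m.sample_ids)]
    if not stage_samples:
        raise ValidationError(f"stage {stage!r} absent from phenotype")
    if len(stage_samples) < 3 or len(normal_samples) < 3:
        raise ValidationError("both groups need >= 3 samples")

    a = m.values[stage_samples].to_numpy(dtype=float)
    b = m.values[normal_samples].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    p = _two_sample_pvalues(a, b, test)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    called = (q <= fdr_alpha) & (np.abs(lfc) >= min_abs_lfc)
    table = pd.DataFrame(
        {
            "gene": m.gene_ids,
            "lfc": lfc,
            "pvalue": p,
            "qvalue": q,
            "called": called,
        }
    )
    return DeResult(stage=stage, test=test, fdr_alpha=fdr_alpha, min_abs_lfc=min_abs_lfc, table=table)


def intersect_stage_degs(per_stage: dict[str, list[str]]) -> list[str]:
    """Genes present in every stage's DEG list, in lexicographic order.

    ``per_stage`` must provide all four tumour stages.
    """
    missing = [s for s in TUMOR_STAGES if s not in per_stage]
    if missing:
        raise ValidationError(f"missing stage lists: {missing}")
    sets = [set(per_stage[s]) for s in TUMOR_STAGES]
    inter = set.intersection(*sets)
    return sorted(inter)


def stage_wise_de(
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    test: str = "rank_sum",
    fdr_alpha: float = 0.05,
    min_abs_lfc: float = 1.0,
) -> tuple[dict[str, DeResult], list[str]]:
    """Run all four stage contrasts and return (per-stage results, intersection)."""
    results = {
        s: differential_expression(m, pheno, s, test=test, fdr_alpha=fdr_alpha, min_abs_lfc=min_abs_lfc)
        for s in TUMOR_STAGES
    }
    intersection = intersect_stage_degs({s: r.degs for s, r in results.items()})
    return results, intersection


def read_deg_list(path) -> list[str]:
    """One gene per line; used to bypass the built-in test with external calls."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValidationError(f"empty DEG list {path}")
    if len(genes) != len(set(genes)):
        raise ValidationError(f"duplicate genes in DEG list {path}")
    return genes


def write_deg_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


__all__ = [
    "DE_TESTS",
    "DeResult",
    "differential_expression",
    "intersect_stage_degs",
    "stage_wise_de",
    "read_deg_list",
    "write_deg_list",
]
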