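"""Seeded synthetic cohorts with planted node and edge signal.

The generator emulates the statistical structure the framework assumes: a
normal reference cohort in which gene pairs follow stable bivariate linear
relationships, plus tumour-stage cohorts that reproduce the normal model
except for four kinds of planted perturbation:

* **node signal** — per-stage mean shifts on a reserved set of genes that
  belong to no pair, so node and edge signal stay disjoint;
* **ΔPCC signal** — pairs whose within-stage correlation is shifted by Δρ;
* **ΔCOV signal** — pairs whose covariance is amplitude-scaled without
  changing the correlation (the second gene's deviations are multiplied);
* **residual signal** — pairs whose second gene is displaced off the
  normal regression line by an additive log2 offset.

Expression is generated directly on the log2 scale (Gaussian around gene
baselines drawn from ``baseline_range``), matching where all downstream
math operates.  The pair universe is a forest: each pair introduces one new
"child" gene conditioned on an already-generated "parent" gene through

    z_child = rho * z_parent + sqrt(1 - rho^2) * eps,

which makes every pair's baseline correlation exact by construction while
allowing more genes than pairs.  Edge effects are multiplied by a per-stage
severity factor so perturbations grow with stage, mirroring progressive
network rewiring; node shifts are specified per stage directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    STAGES,
    TUMOR_STAGES,
    ExpressionMatrix,
    PairUniverse,
    PhenotypeTable,
    pair_label,
)
from .errors import DesignError, ValidationError


def _default_samples() -> dict[str, int]:
    return {s: 60 for s in STAGES}


def _default_node_shift() -> dict[str, float]:
    return {"I": 2.0, "II": 2.5, "III": 3.0, "IV": 3.5}


def _default_severity() -> dict[str, float]:
    return {"I": 0.4, "II": 0.6, "III": 0.8, "IV": 1.0}


@dataclass
class CohortDesign:
    """Full parameterisation of one synthetic cohort.

    Effect sizes are in the units of the corresponding feature: node shifts
    and residual offsets in log2 expression, ``delta_rho`` as a correlation
    change, ``cov_scale`` as a multiplicative covariance factor at full
    severity.  ``stage_severity`` scales the three edge effects per stage
    (node shifts are already per stage).
    """

    n_genes: int = 300
    n_pairs: int = 200
    samples_per_class: dict[str, int] = field(default_factory=_default_samples)
    n_node_genes: int = 10
    node_shift: dict[str, float] = field(default_factory=_default_node_shift)
    n_pcc_pairs: int = 8
    delta_rho: float = -1.2
    n_cov_pairs: int = 8
    cov_scale: float = 6.0
    n_residual_pairs: int = 8
    residual_shift: float = 1.2
    stage_severity: dict[str, float] = field(default_factory=_default_severity)
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (3.0, 10.0)
    corr_range: tuple[float, float] = (0.4, 0.9)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 3 or self.n_pairs < 1:
            raise DesignError("need at least 3 genes and 1 pair")
        n_parents = self.n_genes - self.n_pairs - self.n_node_genes
        if n_parents < 1:
            raise DesignError(
                "n_genes must exceed n_pairs + n_node_genes: every pair adds a "
                "child gene and node genes are reserved outside the universe"
            )
        n_planted = self.n_pcc_pairs + self.n_cov_pairs + self.n_residual_pairs
        if n_planted > self.n_pairs:
            raise DesignError("more planted pairs than pairs in the universe")
        if self.noise_sd <= 0:
            raise DesignError("noise_sd must be positive")
        if self.cov_scale <= 0:
            raise DesignError("cov_scale must be positive")
        for s in STAGES:
            if self.samples_per_class.get(s, 0) < 1:
                raise DesignError(f"samples_per_class must cover stage {s!r}")
        lo, hi = self.corr_range
        if not (-1 < lo <= hi < 1):
            raise DesignError("corr_range must lie strictly inside (-1, 1)")
        sev_max = max(self.stage_severity.get(s, 1.0) for s in TUMOR_STAGES)
        for rho in (lo, hi):
            if abs(rho + self.delta_rho * sev_max) > 1:
                raise DesignError(
                    f"infeasible correlation change: baseline {rho} + "
                    f"delta_rho {self.delta_rho} x severity {sev_max} leaves [-1, 1]"
                )

    @classmethod
    def null(cls, seed: int = 0, **kw) -> "CohortDesign":
        """A design with every effect size zero (pure noise between classes)."""
        kw.setdefault("node_shift", {s: 0.0 for s in TUMOR_STAGES})
        kw.setdefault("delta_rho", 0.0)
        kw.setdefault("cov_scale", 1.0)
        kw.setdefault("residual_shift", 0.0)
        return cls(seed=seed, **kw)

    @classmethod
    def imbalanced(cls, seed: int = 0, scale: float = 0.5, **kw) -> "CohortDesign":
        """The 59/266/120/84/26 class profile, scaled down by ``scale``."""
        base = {"normal": 59, "I": 266, "II": 120, "III": 84, "IV": 26}
        kw.setdefault(
            "samples_per_class",
            {s: max(10, int(round(n * scale))) for s, n in base.items()},
        )
        return cls(seed=seed, **kw)


@dataclass
class CohortTruth:
    """Ground truth of one generated cohort, for recovery scoring."""

    design: CohortDesign
    planted_node_genes: tuple[str, ...]
    planted_pcc_pairs: tuple[tuple[str, str], ...]
    planted_cov_pairs: tuple[tuple[str, str], ...]
    planted_residual_pairs: tuple[tuple[str, str], ...]
    pair_baseline_rho: dict[tuple[str, str], float]

    def planted_for(self, feature_type: str):
        mapping = {
            "node": self.planted_node_genes,
            "delta_pcc": self.planted_pcc_pairs,
            "delta_cov": self.planted_cov_pairs,
            "residual": self.planted_residual_pairs,
        }
        if feature_type not in mapping:
            raise ValidationError(f"unknown feature type {feature_type!r}")
        return mapping[feature_type]


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def generate_cohort(
    design: CohortDesign,
) -> tuple[ExpressionMatrix, PhenotypeTable, PairUniverse, CohortTruth]:
    """Generate one cohort; a pure function of ``design`` (incl. its seed)."""
    design.validate()
    rng = np.random.default_rng(design.seed)

    n_node = design.n_node_genes
    n_children = design.n_pairs
    n_parents = design.n_genes - n_children - n_node
    genes = [_gene_id(i) for i in range(design.n_genes)]
    node_genes = genes[:n_node]
    parent_pool = np.arange(n_node, n_node + n_parents)
    child_idx = np.arange(n_node + n_parents, design.n_genes)

    lo, hi = design.corr_range
    rho = rng.uniform(lo, hi, size=n_children)
    parents = rng.choice(parent_pool, size=n_children, replace=True)

    pairs = [tuple(sorted((genes[parents[k]], genes[child_idx[k]]))) for k in range(n_children)]
    # children carry higher indices than parents, so the child is always
    # the lexicographically larger member ("y" gene) of its pair
    planted_pcc = tuple(pairs[: design.n_pcc_pairs])
    planted_cov = tuple(pairs[design.n_pcc_pairs : design.n_pcc_pairs + design.n_cov_pairs])
    planted_res = tuple(
        pairs[
            design.n_pcc_pairs + design.n_cov_pairs : design.n_pcc_pairs
            + design.n_cov_pairs
            + design.n_residual_pairs
        ]
    )

    baselines = rng.uniform(*design.baseline_range, size=design.n_genes)

    sev = {s: 0.0 for s in STAGES}
    sev.update({s: float(design.stage_severity.get(s, 1.0)) for s in TUMOR_STAGES})

    columns: list[str] = []
    labels: list[str] = []
    blocks: list[np.ndarray] = []
    counter = 0
    for stage in STAGES:
        m = design.samples_per_class[stage]
        z = np.empty((design.n_genes, m))
        z[: n_node + n_parents] = rng.normal(size=(n_node + n_parents, m))
        eps = rng.normal(size=(n_children, m))
        rho_eff = rho.copy()
        if stage != "normal":
            rho_eff[: design.n_pcc_pairs] = rho[: design.n_pcc_pairs] + design.delta_rho * sev[stage]
        zp = z[parents]
        zc = rho_eff[:, None] * zp + np.sqrt(1.0 - rho_eff[:, None] ** 2) * eps
        if stage != "normal":
            cov_lo = design.n_pcc_pairs
            cov_hi = cov_lo + design.n_cov_pairs
            # scaling the child's deviations multiplies the covariance but
            # leaves the correlation untouched
            amp = 1.0 + (design.cov_scale - 1.0) * sev[stage]
            zc[cov_lo:cov_hi] *= amp
            res_hi = cov_hi + design.n_residual_pairs
            zc[cov_hi:res_hi] += design.residual_shift * sev[stage] / design.noise_sd
        z[child_idx] = zc
        expr = baselines[:, None] + design.noise_sd * z
        if stage != "normal":
            shift = float(design.node_shift.get(stage, 0.0))
            expr[:n_node] += shift
        np.maximum(expr, 0.0, out=expr)  # keep the log-scale matrix nonnegative
        blocks.append(expr)
        columns.extend(f"S{counter + j:04d}" for j in range(m))
        labels.extend([stage] * m)
        counter += m

    values = pd.DataFrame(np.hstack(blocks), index=genes, columns=columns)
    expr_m = ExpressionMatrix(values, log_transformed=True)
    pheno = PhenotypeTable(pd.Series(labels, index=columns, dtype=object))
    universe = PairUniverse(tuple(sorted(pairs)), source=f"synthetic(seed={design.seed})")
    truth = CohortTruth(
        design=design,
        planted_node_genes=tuple(node_genes),
        planted_pcc_pairs=planted_pcc,
        planted_cov_pairs=planted_cov,
        planted_residual_pairs=planted_res,
        pair_baseline_rho={pairs[k]: float(rho[k]) for k in range(n_children)},
    )
    return expr_m, pheno, universe, truth


def truth_recovery_report(truth: CohortTruth, ranked, k: int) -> float:
    """Fraction of the planted features (of the ranking's type) in the top-k.

    ``ranked`` is a :class:`~edgestage.feature_selection.RankedFeatureList`;
    its ``feature_type`` selects which planted subset is scored.  Edge
    features are matched on their ``"A:B"`` labels.
    """
    if len(ranked) == 0:
        raise ValidationError("empty ranking")
    planted = truth.planted_for(ranked.feature_type)
    if not planted:
        raise ValidationError(f"no planted features of type {ranked.feature_type!r}")
    if ranked.feature_type == "node":
        wanted = set(planted)
    else:
        wanted = {pair_label(p) for p in planted}
    top = set(ranked.top(k))
    return len(wanted & top) / len(wanted)


def write_truth(truth: CohortTruth, path) -> None:
    """Plain key/value text dump of the planted sets (for test harnesses)."""
    with open(path, "w") as fh:
        fh.write(f"seed\t{truth.design.seed}\n")
        fh.write("node_genes\t" + ",".join(truth.planted_node_genes) + "\n")
        for name, pairs in (
            ("pcc_pairs", truth.planted_pcc_pairs),
            ("cov_pairs", truth.planted_cov_pairs),
            ("residual_pairs", truth.planted_residual_pairs),
        ):
            fh.write(name + "\t" + ",".join(pair_label(p) for p in pairs) + "\n")


__all__ = [
    "CohortDesign",
    "CohortTruth",
    "generate_cohort",
    "truth_recovery_report",
    "write_truth",
]
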