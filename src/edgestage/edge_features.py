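"""Normal-reference pair model and single-sample edge perturbation features.

For every gene pair (x, y) in the universe, the reference model stores the
sufficient statistics of the normal cohort — means, centred sums of squares
and cross-products — from which the Pearson correlation ``PCC_n``, the
sample covariance ``COV_n`` (denominator n−1), and the least-squares line
``y = b0 + b1 x`` all derive.  A single query sample then yields three
O(1)-per-pair perturbation features:

* ``delta_pcc`` — PCC over the n reference samples plus the query, minus
  ``PCC_n``: the correlation change one sample induces;
* ``delta_cov`` — the analogous covariance change, where the augmented
  (n+1)-point set uses its own sample denominator n;
* ``residual`` — the signed vertical distance of the query from the
  reference regression line.

Augmented statistics are computed by incremental (rank-one) update of the
stored sums; a brute-force recomputation over the concatenated n+1 points
agrees to ~1e-12 and serves as the test oracle.

Conventions: the pair is oriented with the lexicographically smaller gene
as x; the regression predicts y from x.  Pairs degenerate in the reference
(zero variance in either gene) are dropped at fit time; a degenerate
augmented set yields feature 0 with a warning rather than an error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import (
    ExpressionMatrix,
    PairUniverse,
    PhenotypeTable,
    pair_label,
)
from .errors import ValidationError

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("delta_pcc", "delta_cov", "residual")

_EPS = 1e-12


@dataclass
class PairReferenceModel:
    """Sufficient statistics of the normal cohort, per retained pair.

    All arrays are aligned with ``pairs``.  ``ss_x``/``ss_y`` are centred
    sums of squares, ``s_xy`` the centred cross-product sum.
    """

    pairs: tuple[tuple[str, str], ...]
    n: int
    mean_x: np.ndarray
    mean_y: np.ndarray
    ss_x: np.ndarray
    ss_y: np.ndarray
    s_xy: np.ndarray
    normal_sample_ids: tuple[str, ...]
    n_dropped_degenerate: int = 0

    @property
    def pcc(self) -> np.ndarray:
        return self.s_xy / np.sqrt(self.ss_x * self.ss_y)

    @property
    def cov(self) -> np.ndarray:
        return self.s_xy / (self.n - 1)

    @property
    def slope(self) -> np.ndarray:
        return self.s_xy / self.ss_x

    @property
    def intercept(self) -> np.ndarray:
        return self.mean_y - self.slope * self.mean_x

    @property
    def x_genes(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def y_genes(self) -> list[str]:
        return [p[1] for p in self.pairs]

    @property
    def pair_labels(self) -> list[str]:
        return [pair_label(p) for p in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def fit_reference(
    m: ExpressionMatrix, pheno: PhenotypeTable, universe: PairUniverse
) -> PairReferenceModel:
    """Fit the reference model on the normal samples of ``m``.

    Degenerate pairs (zero variance in either gene over the normals) are
    excluded; the dropped count is logged and stored on the model.
    """
    normals = [s for s in pheno.samples_for("normal") if s in set(m.sample_ids)]
    if len(normals) < 3:
        raise ValidationError(f"need >= 3 normal samples, found {len(normals)}")
    if len(universe) == 0:
        raise ValidationError("empty pair universe")
    genes = set(m.gene_ids)
    missing = [p for p in universe if p[0] not in genes or p[1] not in genes]
    if missing:
        raise ValidationError(f"universe pairs reference absent genes: {missing[:5]}")

    sub = m.values[normals]
    x_genes = [p[0] for p in universe]
    y_genes = [p[1] for p in universe]
    X = sub.loc[x_genes].to_numpy(dtype=float)
    Y = sub.loc[y_genes].to_numpy(dtype=float)
    n = X.shape[1]
    mean_x = X.mean(axis=1)
    mean_y = Y.mean(axis=1)
    dx = X - mean_x[:, None]
    dy = Y - mean_y[:, None]
    ss_x = np.einsum("ij,ij->i", dx, dx)
    ss_y = np.einsum("ij,ij->i", dy, dy)
    s_xy = np.einsum("ij,ij->i", dx, dy)

    ok = (ss_x > _EPS) & (ss_y > _EPS)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d degenerate pairs at reference fit", n_dropped)
    if not ok.any():
        raise ValidationError("every pair is degenerate over the normal samples")
    pairs = tuple(p for p, keep in zip(universe.pairs, ok) if keep)
    return PairReferenceModel(
        pairs=pairs,
        n=n,
        mean_x=mean_x[ok],
        mean_y=mean_y[ok],
        ss_x=ss_x[ok],
        ss_y=ss_y[ok],
        s_xy=s_xy[ok],
        normal_sample_ids=tuple(normals),
        n_dropped_degenerate=n_dropped,
    )


def _sample_xy(ref: PairReferenceModel, sample: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    needed = set(ref.x_genes) | set(ref.y_genes)
    missing = sorted(needed - set(sample.index))
    if missing:
        raise ValidationError(f"sample missing genes: {missing[:5]}")
    x = sample.loc[ref.x_genes].to_numpy(dtype=float)
    y = sample.loc[ref.y_genes].to_numpy(dtype=float)
    return x, y


def _augmented_sums(ref, x, y):
    """Rank-one update of the centred sums with one extra observation."""
    n = ref.n
    dx = x - ref.mean_x
    dy = y - ref.mean_y
    f = n / (n + 1.0)
    ss_x = ref.ss_x + f * dx * dx
    ss_y = ref.ss_y + f * dy * dy
    s_xy = ref.s_xy + f * dx * dy
    return ss_x, ss_y, s_xy


def delta_pcc(ref: PairReferenceModel, sample: pd.Series) -> np.ndarray:
    """Per-pair change in Pearson correlation when ``sample`` joins the normals.

    Bounded in [−2, 2].  Pairs whose augmented set is degenerate return 0
    with a warning.
    """
    x, y = _sample_xy(ref, sample)
    ss_x, ss_y, s_xy = _augmented_sums(ref, x, y)
    denom = ss_x * ss_y
    degenerate = denom <= _EPS
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} pairs degenerate after augmentation; feature set to 0"
        )
    pcc_aug = np.where(degenerate, ref.pcc, s_xy / np.sqrt(np.where(degenerate, 1.0, denom)))
    return pcc_aug - ref.pcc


def delta_cov(ref: PairReferenceModel, sample: pd.Series) -> np.ndarray:
    """Per-pair change in sample covariance when ``sample`` joins the normals.

    The reference covariance uses denominator n−1; the augmented (n+1)-point
    covariance uses its own sample denominator n.  Symmetric in the pair.
    """
    x, y = _sample_xy(ref, sample)
    _, _, s_xy = _augmented_sums(ref, x, y)
    return s_xy / ref.n - ref.cov


def residual(ref: PairReferenceModel, sample: pd.Series) -> np.ndarray:
    """Signed vertical distance of the sample from each pair's reference line."""
    x, y = _sample_xy(ref, sample)
    return y - (ref.intercept + ref.slope * x)


_FEATURE_FUNCS = {"delta_pcc": delta_pcc, "delta_cov": delta_cov, "residual": residual}


def single_sample_features(
    ref: PairReferenceModel, sample: pd.Series, feature_type: str
) -> np.ndarray:
    if feature_type not in _FEATURE_FUNCS:
        raise ValidationError(f"unknown feature type {feature_type!r}")
    return _FEATURE_FUNCS[feature_type](ref, sample)


def _loo_reference(ref: PairReferenceModel, x: np.ndarray, y: np.ndarray) -> PairReferenceModel:
    """Downdate the reference statistics by removing one observation."""
    n = ref.n
    if n < 4:
        raise ValidationError("leave-one-out needs >= 4 normal samples")
    mean_x = (n * ref.mean_x - x) / (n - 1)
    mean_y = (n * ref.mean_y - y) / (n - 1)
    f = n / (n - 1.0)
    dx = x - ref.mean_x
    dy = y - ref.mean_y
    return PairReferenceModel(
        pairs=ref.pairs,
        n=n - 1,
        mean_x=mean_x,
        mean_y=mean_y,
        ss_x=np.maximum(ref.ss_x - f * dx * dx, 0.0),
        ss_y=np.maximum(ref.ss_y - f * dy * dy, 0.0),
        s_xy=ref.s_xy - f * dx * dy,
        normal_sample_ids=ref.normal_sample_ids,
    )


@dataclass
class EdgeFeatureMatrix:
    """Samples × pairs matrix of one perturbation feature type."""

    feature_type: str
    values: pd.DataFrame  # rows: samples; columns: "GENE1:GENE2" labels
    reference_n: int

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        if self.values.isna().any().any():
            raise ValidationError("edge feature matrix contains missing values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def pair_labels(self) -> list[str]:
        return list(self.values.columns)


def build_edge_matrix(
    ref: PairReferenceModel,
    m: ExpressionMatrix,
    pheno: PhenotypeTable,
    feature_type: str,
) -> EdgeFeatureMatrix:
    """Featurize every labelled sample against the reference.

    Tumour samples perturb the full reference.  A normal sample that is
    part of the reference is featurized against a leave-one-out reference
    refit without it, avoiding the bias of perturbing a model that already
    contains the sample.
    """
    if feature_type not in _FEATURE_FUNCS:
        raise ValidationError(f"unknown feature type {feature_type!r}")
    missing = [s for s in pheno.sample_ids if s not in set(m.sample_ids)]
    if missing:
        raise ValidationError(f"labelled samples absent from matrix: {missing[:5]}")
    func = _FEATURE_FUNCS[feature_type]
    ref_members = set(ref.normal_sample_ids)
    rows = np.empty((len(pheno.sample_ids), len(ref)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-sample degeneracy warnings collapse to one log line
        for i, sid in enumerate(pheno.sample_ids):
            sample = m.values[sid]
            if sid in ref_members:
                x, y = _sample_xy(ref, sample)
                loo = _loo_reference(ref, x, y)
                rows[i] = func(loo, sample)
            else:
                rows[i] = func(ref, sample)
    values = pd.DataFrame(rows, index=list(pheno.sample_ids), columns=ref.pair_labels)
    return EdgeFeatureMatrix(feature_type=feature_type, values=values, reference_n=ref.n)


def write_edge_matrix(em: EdgeFeatureMatrix, path) -> None:
    """TSV dump plus a sidecar ``<path>.meta`` recording provenance."""
    out = em.values.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.10g")
    with open(f"{path}.meta", "w") as fh:
        fh.write(f"feature_type\t{em.feature_type}\n")
        fh.write(f"reference_n\t{em.reference_n}\n")
        fh.write(f"n_pairs\t{em.values.shape[1]}\n")


__all__ = [
    "FEATURE_TYPES",
    "PairReferenceModel",
    "EdgeFeatureMatrix",
    "fit_reference",
    "delta_pcc",
    "delta_cov",
    "residual",
    "single_sample_features",
    "build_edge_matrix",
    "write_edge_matrix",
]
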