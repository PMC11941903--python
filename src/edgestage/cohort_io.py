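"""Reading, writing and preprocessing of expression cohorts.

The on-disk dialects are plain tab-separated text:

* expression — genes as rows, first column the gene identifier, header row
  of sample identifiers (the UCSC Xena layout);
* phenotype — two columns ``sample`` and ``stage`` with a header;
* pair universe — a STRING-style whitespace-separated edge list
  (``gene1 gene2 [score]``), the optional score column ignored.

Preprocessing follows the usual bulk RNA-seq conventions: ``log2(x + 1)``
transformation and removal of genes with zero expression in more than half
of the samples (strictly greater than the configurable fraction).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

#: The five phenotype classes, in canonical order.
STAGES = ("normal", "I", "II", "III", "IV")

#: The four tumour stages (every class except ``normal``).
TUMOR_STAGES = ("I", "II", "III", "IV")


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the pair with the lexicographically smaller gene first."""
    return (a, b) if a <= b else (b, a)


def pair_label(pair: tuple[str, str]) -> str:
    """``(A, B) -> "A:B"`` — the notation used in all output tables."""
    return f"{pair[0]}:{pair[1]}"


@dataclass
class ExpressionMatrix:
    """A genes × samples expression matrix.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns.  No missing values are allowed.
    log_transformed
        Whether values are on the log2(x+1) scale.  Raw input is expected
        to be nonnegative.
    """

    values: pd.DataFrame
    log_transformed: bool = False

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if cols.has_duplicates:
            dupes = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample identifiers: {dupes[:5]}")
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.log_transformed and (self.values.to_numpy() < 0).any():
            raise ValidationError("log-transformed values must be >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` (order preserved as given)."""
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.log_transformed)

    def sample(self, sample_id: str) -> pd.Series:
        """A single sample's expression vector, indexed by gene."""
        if sample_id not in self.values.columns:
            raise ValidationError(f"unknown sample {sample_id!r}")
        return self.values[sample_id]


@dataclass
class PhenotypeTable:
    """Mapping sample identifier → stage label.

    Labels are restricted to :data:`STAGES`.  Samples without a usable
    stage annotation are dropped at load time.
    """

    labels: pd.Series

    def __post_init__(self) -> None:
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicate sample identifiers in phenotype")
        bad = sorted(set(self.labels.unique()) - set(STAGES))
        if bad:
            raise ValidationError(f"unknown stage labels: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.labels.index)

    def samples_for(self, stage: str) -> list[str]:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        return list(self.labels.index[self.labels == stage])

    def counts(self) -> dict[str, int]:
        return {s: int((self.labels == s).sum()) for s in STAGES}

    def restrict_to(self, sample_ids) -> "PhenotypeTable":
        keep = [s for s in self.labels.index if s in set(sample_ids)]
        return PhenotypeTable(self.labels.loc[keep])


@dataclass
class PairUniverse:
    """An unordered set of gene pairs over which edge features are built.

    ``pairs`` is stored sorted, each pair in canonical (lexicographic)
    orientation, so iteration order is deterministic.
    """

    pairs: tuple[tuple[str, str], ...]
    source: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.pairs:
            if a == b:
                raise ValidationError(f"self-pair {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValidationError(f"pair {(a, b)} not in canonical order")
            if (a, b) in seen:
                raise ValidationError(f"duplicate pair {(a, b)}")
            seen.add((a, b))
        self.pairs = tuple(sorted(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in p}


# ---------------------------------------------------------------------------
# expression I/O


def read_expression(path, dialect: str = "xena_tsv") -> ExpressionMatrix:
    """Read a genes × samples matrix from tab-separated text.

    The first column is the gene identifier, the header row holds sample
    identifiers.  Raises :class:`ParseError` on ragged rows (the pandas
    message names the offending line) and :class:`ValidationError` on
    duplicate gene identifiers.
    """
    if dialect != "xena_tsv":
        raise ValidationError(f"unknown expression dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed expression file {path}: {exc}") from exc
    if df.isna().any().any():
        # a short row pads with NaN rather than raising in the C parser
        bad = df.index[df.isna().any(axis=1)].tolist()
        raise ParseError(f"rows with missing fields in {path}: {bad[:5]}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    return ExpressionMatrix(df.astype(float), log_transformed=False)


def write_expression(m: ExpressionMatrix, path) -> None:
    """Write the matrix in the same tab-separated dialect read_expression expects."""
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_phenotype(path) -> PhenotypeTable:
    """Read a two-column (sample, stage) table; header required.

    Stage strings are normalised ("Stage II" → "II", "Normal" → "normal");
    samples whose label is missing or unrecognisable are dropped with a
    warning, mirroring the convention of keeping only staged samples.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"phenotype file {path} needs >= 2 columns")
    raw = df.iloc[:, :2]
    labels = {}
    dropped = 0
    for sample, stage in raw.itertuples(index=False):
        norm = _normalise_stage(stage)
        if norm is None:
            dropped += 1
            continue
        labels[str(sample)] = norm
    if dropped:
        warnings.warn(f"dropped {dropped} samples without a usable stage label")
    if not labels:
        raise ValidationError(f"no staged samples in {path}")
    return PhenotypeTable(pd.Series(labels, dtype=object))


def write_phenotype(pheno: PhenotypeTable, path) -> None:
    df = pd.DataFrame({"sample": pheno.labels.index, "stage": pheno.labels.values})
    df.to_csv(path, sep="\t", index=False)


def _normalise_stage(stage) -> str | None:
    if stage is None or (isinstance(stage, float) and np.isnan(stage)):
        return None
    s = str(stage).strip()
    if not s:
        return None
    low = s.lower()
    if low in ("normal", "solid tissue normal"):
        return "normal"
    if low.startswith("stage "):
        s = s[6:].strip()
    s = s.upper()
    return s if s in STAGES else None


# ---------------------------------------------------------------------------
# preprocessing


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return a new matrix with values log2(x + 1) and the flag set.

    Raises :class:`ValidationError` if the matrix is already transformed
    or contains negative values.
    """
    if m.log_transformed:
        raise ValidationError("matrix is already log-transformed")
    vals = m.values.to_numpy()
    if (vals < 0).any():
        raise ValidationError("negative expression values cannot be log-transformed")
    out = pd.DataFrame(np.log2(vals + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, log_transformed=True)


def filter_low_expression(
    m: ExpressionMatrix, max_zero_fraction: float = 0.5
) -> ExpressionMatrix:
    """Drop genes with zero expression in more than ``max_zero_fraction`` of samples.

    The inequality is strict: a gene whose zero fraction equals the
    threshold is retained.  Gene order is preserved; the operation is
    idempotent.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValidationError("max_zero_fraction must be in [0, 1]")
    zero_frac = (m.values == 0).mean(axis=1)
    keep = zero_frac <= max_zero_fraction
    if not keep.any():
        warnings.warn("low-expression filter removed every gene")
    return ExpressionMatrix(m.values.loc[keep], m.log_transformed)


# ---------------------------------------------------------------------------
# pair universe I/O


def read_pair_universe(path, m: ExpressionMatrix) -> PairUniverse:
    """Read a STRING-style edge list and restrict it to genes in ``m``.

    Self-pairs and duplicates (under either orientation) are dropped.  An
    optional third (score) column is ignored.  Raises
    :class:`ValidationError` if no pair survives.
    """
    genes = set(m.gene_ids)
    pairs: set[tuple[str, str]] = set()
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected at least two columns")
            n_lines += 1
            a, b = fields[0], fields[1]
            if a == b or a not in genes or b not in genes:
                continue
            pairs.add(canonical_pair(a, b))
    if not pairs:
        raise ValidationError(
            f"no usable pairs in {path} ({n_lines} edges read, "
            f"{len(genes)} genes available)"
        )
    logger.info("pair universe: %d pairs retained from %d edges", len(pairs), n_lines)
    return PairUniverse(tuple(sorted(pairs)), source=str(path))


def write_pair_universe(universe: PairUniverse, path) -> None:
    with open(path, "w") as fh:
        for a, b in universe.pairs:
            fh.write(f"{a}\t{b}\n")


def pairs_from_genes(genes, max_pairs: int | None = None, source: str = "all-pairs") -> PairUniverse:
    """All unordered pairs among ``genes``, optionally capped.

    The cap keeps the first ``max_pairs`` pairs in sorted (lexicographic)
    order — a deterministic rule used as the fallback universe when no
    protein-interaction edge list is supplied.
    """
    genes = sorted(set(genes))
    pairs = [
        (genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    if not pairs:
        raise ValidationError("need at least two genes to form pairs")
    return PairUniverse(tuple(pairs), source=source)


__all__ = [
    "STAGES",
    "TUMOR_STAGES",
    "ExpressionMatrix",
    "PhenotypeTable",
    "PairUniverse",
    "canonical_pair",
    "pair_label",
    "read_expression",
    "write_expression",
    "read_phenotype",
    "write_phenotype",
    "log_transform",
    "filter_low_expression",
    "read_pair_universe",
    "write_pair_universe",
    "pairs_from_genes",
]
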