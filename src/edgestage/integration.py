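"""Composition grid search over the four feature types, the
single-type-versus-integrated comparison harness, and single-sample
classification with a trained bundle.

A *composition* is a 4-tuple of per-type feature counts
``(c_node, c_delta_pcc, c_residual, c_delta_cov)``, each at least 1.  For a
composition, the top-``c`` features of each type's ranking (strict rank
prefixes) are pooled into one matrix and scored by cross-validated
multi-class F1; the grid search enumerates every composition within
``max_per_type`` and ``max_total`` and returns the argmax, ties broken by
smaller total and then lexicographic composition order so the result is
fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd

from .edge_features import PairReferenceModel, _loo_reference, _sample_xy, single_sample_features
from .errors import ValidationError
from .feature_selection import (
    CvResult,
    RankedFeatureList,
    cross_validated_f1,
    make_forest,
)

#: Composition order used everywhere a 4-tuple of counts appears.
TYPE_ORDER = ("node", "delta_pcc", "residual", "delta_cov")

BUNDLE_SCHEMA_VERSION = 1


def integrated_column(feature_type: str, feature: str) -> str:
    """Unique column name; the same gene pair may appear under several types."""
    return f"{feature_type}|{feature}"


@dataclass
class IntegratedSelection:
    """A per-type feature-count composition and its cross-validated score."""

    counts: dict[str, int]
    features: tuple[tuple[str, str], ...]  # (feature_type, feature id)
    cv_f1: CvResult

    def __post_init__(self) -> None:
        if set(self.counts) != set(TYPE_ORDER):
            raise ValidationError(f"counts must cover {TYPE_ORDER}")
        if any(c < 1 for c in self.counts.values()):
            raise ValidationError("every feature type needs count >= 1")
        if self.total != len(self.features):
            raise ValidationError("total count does not match the feature list")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def composition(self) -> tuple[int, ...]:
        return tuple(self.counts[t] for t in TYPE_ORDER)

    @property
    def columns(self) -> list[str]:
        return [integrated_column(t, f) for t, f in self.features]


def enumerate_compositions(max_per_type: int = 6, max_total: int = 20) -> list[tuple[int, ...]]:
    """All 4-tuples with 1 <= c_t <= max_per_type and sum <= max_total,
    in lexicographic order."""
    if max_total < len(TYPE_ORDER):
        raise ValidationError("max_total must allow one feature per type")
    r = range(1, max_per_type + 1)
    return [
        (a, b, c, d)
        for a in r
        for b in r
        for c in r
        for d in r
        if a + b + c + d <= max_total
    ]


def _composition_matrix(
    composition: tuple[int, ...],
    rankings: dict[str, RankedFeatureList],
    features: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, tuple[tuple[str, str], ...]]:
    cols = []
    chosen: list[tuple[str, str]] = []
    for t, c in zip(TYPE_ORDER, composition):
        names = rankings[t].top(c)
        block = features[t][names].copy()
        block.columns = [integrated_column(t, f) for f in names]
        cols.append(block)
        chosen.extend((t, f) for f in names)
    return pd.concat(cols, axis=1), tuple(chosen)


def _check_rankings(rankings, features, max_per_type: int) -> int:
    missing = [t for t in TYPE_ORDER if t not in rankings or t not in features]
    if missing:
        raise ValidationError(f"rankings/features missing for types: {missing}")
    shortest = min(len(rankings[t]) for t in TYPE_ORDER)
    if shortest < 1:
        raise ValidationError("every ranking needs at least one entry")
    if shortest < max_per_type:
        warnings.warn(
            f"shortest ranking has {shortest} entries; clipping max_per_type "
            f"from {max_per_type}"
        )
        return shortest
    return max_per_type


def grid_search_integration(
    rankings: dict[str, RankedFeatureList],
    features: dict[str, pd.DataFrame],
    labels: pd.Series,
    max_per_type: int = 6,
    max_total: int = 20,
    forest_params: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    average: str = "macro",
    total_exact: int | None = None,
) -> tuple[IntegratedSelection, pd.DataFrame]:
    """Score every composition and return the best one plus the full table.

    ``total_exact`` restricts the enumeration to compositions of exactly
    that total (used by the fixed-budget comparison harness).  The search
    table has one row per composition with its mean F1 — the basis of the
    F1-versus-total-features curve.
    """
    max_per_type = _check_rankings(rankings, features, max_per_type)
    comps = enumerate_compositions(max_per_type, max_total)
    if total_exact is not None:
        comps = [c for c in comps if sum(c) == total_exact]
    if not comps:
        raise ValidationError("no feasible composition under the given bounds")
    rows = []
    best = None  # (-mean_f1, total, composition) — minimised
    best_payload = None
    for comp in comps:
        X, chosen = _composition_matrix(comp, rankings, features)
        cv = cross_validated_f1(X, labels, forest_params, folds=folds, seed=seed, average=average)
        rows.append({**{f"c_{t}": c for t, c in zip(TYPE_ORDER, comp)},
                     "total": sum(comp), "mean_f1": cv.mean})
        key = (-cv.mean, sum(comp), comp)
        if best is None or key < best:
            best = key
            best_payload = (comp, chosen, cv)
    comp, chosen, cv = best_payload
    selection = IntegratedSelection(
        counts={t: c for t, c in zip(TYPE_ORDER, comp)}, features=chosen, cv_f1=cv
    )
    return selection, pd.DataFrame(rows)


def compare_feature_types(
    rankings: dict[str, RankedFeatureList],
    features: dict[str, pd.DataFrame],
    labels: pd.Series,
    budget: int = 11,
    max_per_type: int = 6,
    forest_params: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    average: str = "macro",
) -> pd.DataFrame:
    """Single-type top-``budget`` panels versus the best integrated
    composition of the same total, under identical folds and seed.

    Returns a five-row table (four single types plus ``integrated``) with
    columns ``feature_type``, ``n_features``, ``mean_f1``.
    """
    rows = []
    for t in TYPE_ORDER:
        b = budget
        if len(rankings[t]) < b:
            warnings.warn(f"ranking for {t} has {len(rankings[t])} < {budget} entries; clipping")
            b = len(rankings[t])
        names = rankings[t].top(b)
        cv = cross_validated_f1(
            features[t][names], labels, forest_params, folds=folds, seed=seed, average=average
        )
        rows.append({"feature_type": t, "n_features": b, "mean_f1": cv.mean})
    selection, _ = grid_search_integration(
        rankings, features, labels, max_per_type=max_per_type, max_total=budget,
        forest_params=forest_params, folds=folds, seed=seed, average=average,
        total_exact=budget,
    )
    rows.append({
        "feature_type": "integrated",
        "n_features": selection.total,
        "mean_f1": selection.cv_f1.mean,
    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# final classifier bundle


@dataclass
class StageClassifierBundle:
    """Everything needed to classify a single new sample: the selected
    composition, the normal-reference model, and the final forest refit on
    all training samples (CV scores are reported from the search, never
    from this refit)."""

    selection: IntegratedSelection
    reference: PairReferenceModel
    classifier: object
    classes: tuple[str, ...]
    schema_version: int = BUNDLE_SCHEMA_VERSION


def train_final_classifier(
    selection: IntegratedSelection,
    features: dict[str, pd.DataFrame],
    labels: pd.Series,
    reference: PairReferenceModel,
    forest_params: dict | None = None,
) -> StageClassifierBundle:
    """Refit a forest on all samples using the selected features."""
    X = pd.concat(
        [
            features[t][[f]].rename(columns={f: integrated_column(t, f)})
            for t, f in selection.features
        ],
        axis=1,
    )
    labels = labels.reindex(X.index)
    forest = make_forest(forest_params)
    forest.fit(X.to_numpy(dtype=float), labels.to_numpy())
    return StageClassifierBundle(
        selection=selection,
        reference=reference,
        classifier=forest,
        classes=tuple(forest.classes_),
    )


def _bundle_feature_vector(bundle: StageClassifierBundle, sample: pd.Series) -> np.ndarray:
    ref = bundle.reference
    # a sample that is part of the reference is featurized leave-one-out,
    # matching how the training matrices were built
    if sample.name in set(ref.normal_sample_ids):
        x, y = _sample_xy(ref, sample)
        ref = _loo_reference(ref, x, y)
    needed_types = {t for t, _ in bundle.selection.features if t != "node"}
    per_type: dict[str, dict[str, float]] = {}
    for t in needed_types:
        vals = single_sample_features(ref, sample, t)
        per_type[t] = dict(zip(ref.pair_labels, vals))
    out = np.empty(len(bundle.selection.features))
    missing: list[str] = []
    for i, (t, f) in enumerate(bundle.selection.features):
        if t == "node":
            if f not in sample.index:
                missing.append(f)
                continue
            out[i] = float(sample.loc[f])
        else:
            if f not in per_type[t]:
                missing.append(f)
                continue
            out[i] = per_type[t][f]
    if missing:
        raise ValidationError(f"sample missing required features: {missing}")
    return out


def classify_sample(
    bundle: StageClassifierBundle, sample: pd.Series
) -> tuple[str, dict[str, float]]:
    """Predict the stage of one expression vector.

    Computes the sample's node values and edge perturbation features for
    the selected composition against the stored reference, then applies the
    trained classifier.  Returns the predicted label and per-class scores
    summing to 1.
    """
    if bundle.schema_version != BUNDLE_SCHEMA_VERSION:
        raise ValidationError(
            f"bundle schema {bundle.schema_version} != supported {BUNDLE_SCHEMA_VERSION}"
        )
    vec = _bundle_feature_vector(bundle, sample)[None, :]
    proba = bundle.classifier.predict_proba(vec)[0]
    scores = {c: float(p) for c, p in zip(bundle.classes, proba)}
    label = max(scores.items(), key=lambda kv: (kv[1], kv[0]))[0]
    return label, scores


def save_bundle(bundle: StageClassifierBundle, path) -> None:
    joblib.dump({"schema_version": bundle.schema_version, "bundle": bundle}, path)


def load_bundle(path) -> StageClassifierBundle:
    payload = joblib.load(path)
    version = payload.get("schema_version")
    if version != BUNDLE_SCHEMA_VERSION:
        raise ValidationError(
            f"bundle schema version {version!r} is not supported "
            f"(expected {BUNDLE_SCHEMA_VERSION})"
        )
    return payload["bundle"]


__all__ = [
    "TYPE_ORDER",
    "BUNDLE_SCHEMA_VERSION",
    "IntegratedSelection",
    "StageClassifierBundle",
    "integrated_column",
    "enumerate_compositions",
    "grid_search_integration",
    "compare_feature_types",
    "train_final_classifier",
    "classify_sample",
    "save_bundle",
    "load_bundle",
]
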