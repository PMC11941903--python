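"""Random-forest importance ranking, cross-validated macro-F1 scoring, and
recursive feature elimination with cross-validation (RFECV).

Importance is the mean impurity-decrease importance averaged over the
training fits of a stratified k-fold split (a single full-data fit is
available via ``cv_folds=None``).  All scoring uses the multi-class F1
score; macro averaging is the default given severe stage imbalance, with
weighted averaging as a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError

RANKABLE_TYPES = ("node", "delta_pcc", "delta_cov", "residual")

#: Forest defaults: 100 trees keeps ~1000-fit composition searches tractable
#: on one CPU while leaving rankings stable (see methods note); sqrt(p)
#: features per split, unlimited depth, fixed seed.
DEFAULT_FOREST_PARAMS: dict = {
    "n_estimators": 100,
    "max_features": "sqrt",
    "random_state": 42,
    "n_jobs": 1,
}


def make_forest(forest_params: dict | None = None) -> RandomForestClassifier:
    params = dict(DEFAULT_FOREST_PARAMS)
    if forest_params:
        params.update(forest_params)
    return RandomForestClassifier(**params)


def _check_features_labels(features: pd.DataFrame, labels: pd.Series):
    if features.isna().any().any():
        raise ValidationError("feature matrix contains missing values")
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValidationError("every sample needs a label")
    if labels.nunique() < 2:
        raise ValidationError("need at least two classes")
    return features, labels


@dataclass
class CvResult:
    """Per-fold multi-class F1 scores of one cross-validated evaluation."""

    fold_f1: tuple[float, ...]
    folds: int
    seed: int
    average: str = "macro"

    @property
    def mean(self) -> float:
        return float(np.mean(self.fold_f1))

    def __post_init__(self) -> None:
        if len(self.fold_f1) != self.folds:
            raise ValidationError("fold count mismatch")


@dataclass
class RankedFeatureList:
    """Features ordered by non-increasing importance.

    ``entries`` columns: ``feature``, ``importance`` (>= 0).
    """

    feature_type: str
    entries: pd.DataFrame
    folds: int
    seed: int

    def __post_init__(self) -> None:
        if self.feature_type not in RANKABLE_TYPES:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        imp = self.entries["importance"].to_numpy()
        if (imp < 0).any():
            raise ValidationError("importances must be nonnegative")
        if (np.diff(imp) > 1e-12).any():
            raise ValidationError("importances must be sorted non-increasing")
        if self.entries["feature"].duplicated().any():
            raise ValidationError("duplicate feature ids in ranking")

    def __len__(self) -> int:
        return len(self.entries)

    def top(self, k: int) -> list[str]:
        return list(self.entries["feature"].iloc[:k])

    @property
    def importances(self) -> pd.Series:
        return self.entries.set_index("feature")["importance"]

    def write(self, path) -> None:
        out = self.entries.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.insert(2, "type", self.feature_type)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_ranking(path) -> RankedFeatureList:
    """Read a ranking written by :meth:`RankedFeatureList.write` (or by an
    external method, for the comparison harness)."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature", "type", "importance"}
    if not required.issubset(df.columns):
        raise ValidationError(f"ranking file {path} needs columns {sorted(required)}")
    ftype = df["type"].iloc[0]
    entries = df[["feature", "importance"]].reset_index(drop=True)
    return RankedFeatureList(feature_type=str(ftype), entries=entries, folds=0, seed=0)


def _stable_order(importances: np.ndarray, names: list[str]) -> np.ndarray:
    """Indices sorting by importance desc, feature name asc on ties."""
    order = sorted(range(len(names)), key=lambda i: (-importances[i], names[i]))
    return np.asarray(order)


def rank_by_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_type: str,
    forest_params: dict | None = None,
    cv_folds: int | None = 10,
    seed: int = 0,
) -> RankedFeatureList:
    """Rank ``features`` by impurity-decrease importance.

    With ``cv_folds`` set (default 10), importances are averaged over the
    training fits of a seeded stratified k-fold split; ``cv_folds=None``
    uses a single full-data fit.  Deterministic given the seed.
    """
    features, labels = _check_features_labels(features, labels)
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    names = list(features.columns)
    if cv_folds is None:
        forest = make_forest(forest_params)
        forest.fit(X, y)
        importances = forest.feature_importances_
        folds_used = 0
    else:
        folds_used = _usable_folds(labels, cv_folds)
        skf = StratifiedKFold(n_splits=folds_used, shuffle=True, random_state=seed)
        acc = np.zeros(X.shape[1])
        for train_idx, _ in skf.split(X, y):
            forest = make_forest(forest_params)
            forest.fit(X[train_idx], y[train_idx])
            acc += forest.feature_importances_
        importances = acc / folds_used
    order = _stable_order(importances, names)
    entries = pd.DataFrame(
        {"feature": [names[i] for i in order], "importance": importances[order]}
    )
    return RankedFeatureList(feature_type=feature_type, entries=entries, folds=folds_used, seed=seed)


def _usable_folds(labels: pd.Series, folds: int) -> int:
    min_class = int(labels.value_counts().min())
    if min_class < 2:
        raise ValidationError("every class needs >= 2 members for cross-validation")
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds from {folds}"
        )
        return min_class
    return folds


def cross_validated_f1(
    features: pd.DataFrame,
    labels: pd.Series,
    forest_params: dict | None = None,
    folds: int = 10,
    seed: int = 0,
    average: str = "macro",
) -> CvResult:
    """Stratified k-fold multi-class F1 of a forest on ``features``."""
    if average not in ("macro", "weighted"):
        raise ValidationError("average must be 'macro' or 'weighted'")
    features, labels = _check_features_labels(features, labels)
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy()
    folds_used = _usable_folds(labels, folds)
    skf = StratifiedKFold(n_splits=folds_used, shuffle=True, random_state=seed)
    scores = []
    for train_idx, test_idx in skf.split(X, y):
        forest = make_forest(forest_params)
        forest.fit(X[train_idx], y[train_idx])
        pred = forest.predict(X[test_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # absent-class folds yield 0-division warnings
            scores.append(float(f1_score(y[test_idx], pred, average=average, zero_division=0)))
    return CvResult(fold_f1=tuple(scores), folds=folds_used, seed=seed, average=average)


def rfecv_select(
    ranked: RankedFeatureList,
    features: pd.DataFrame,
    labels: pd.Series,
    k_final: int = 20,
    step: float = 0.1,
    forest_params: dict | None = None,
    folds: int = 10,
    seed: int = 0,
) -> tuple[RankedFeatureList, pd.DataFrame]:
    """Recursive feature elimination down to ``k_final`` features.

    Starting from the features of ``ranked``, each iteration records the
    cross-validated F1 of the current set, then drops the lowest-importance
    ``step`` fraction (at least one feature), re-ranking survivors with a
    fresh fold-averaged forest fit.  Returns the final top-``k_final``
    ranking and the F1-versus-size curve.
    """
    if k_final < 1:
        raise ValidationError("k_final must be >= 1")
    if len(ranked) < k_final:
        raise ValidationError(f"ranking has {len(ranked)} < k_final={k_final} features")
    current = ranked
    curve_sizes: list[int] = []
    curve_f1: list[float] = []
    while True:
        cols = current.top(len(current))
        cv = cross_validated_f1(features[cols], labels, forest_params, folds=folds, seed=seed)
        curve_sizes.append(len(cols))
        curve_f1.append(cv.mean)
        if len(cols) <= k_final:
            break
        n_drop = max(1, int(len(cols) * step))
        n_keep = max(k_final, len(cols) - n_drop)
        keep_cols = current.top(n_keep)
        current = rank_by_forest(
            features[keep_cols], labels, current.feature_type,
            forest_params=forest_params, cv_folds=folds, seed=seed,
        )
    curve = pd.DataFrame({"n_features": curve_sizes, "mean_f1": curve_f1})
    final = RankedFeatureList(
        feature_type=current.feature_type,
        entries=current.entries.iloc[:k_final].reset_index(drop=True),
        folds=current.folds,
        seed=seed,
    )
    return final, curve


def ranking_stability(
    features: pd.DataFrame,
    labels: pd.Series,
    feature_type: str,
    seeds: tuple[int, int] = (0, 1),
    forest_params: dict | None = None,
    cv_folds: int = 10,
) -> float:
    """Spearman correlation of importances across two ranking seeds."""
    r1 = rank_by_forest(features, labels, feature_type, forest_params, cv_folds, seeds[0])
    r2 = rank_by_forest(features, labels, feature_type, forest_params, cv_folds, seeds[1])
    a = r1.importances.sort_index()
    b = r2.importances.sort_index()
    rho = _sstats.spearmanr(a.to_numpy(), b.to_numpy()).statistic
    return float(rho)


__all__ = [
    "RANKABLE_TYPES",
    "DEFAULT_FOREST_PARAMS",
    "CvResult",
    "RankedFeatureList",
    "make_forest",
    "rank_by_forest",
    "read_ranking",
    "cross_validated_f1",
    "rfecv_select",
    "ranking_stability",
]
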