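import itertools

import joblib
import numpy as np
import pandas as pd
import pytest

from edgestage.errors import ValidationError
from edgestage.feature_selection import RankedFeatureList, rank_by_forest
from edgestage.integration import (
    TYPE_ORDER,
    classify_sample,
    compare_feature_types,
    enumerate_compositions,
    grid_search_integration,
    integrated_column,
    load_bundle,
    save_bundle,
    train_final_classifier,
)

from .conftest import FAST_FOREST


def _ranking(feature_type, features):
    entries = pd.DataFrame(
        {"feature": features, "importance": np.linspace(1.0, 0.5, len(features))}
    )
    return RankedFeatureList(feature_type=feature_type, entries=entries, folds=0, seed=0)


def _separable_pools(n_per_class=20, n_features=4, seed=0):
    """Every type's every feature separates the two classes perfectly."""
    rng = np.random.default_rng(seed)
    idx = [f"s{i}" for i in range(2 * n_per_class)]
    y = pd.Series(["a"] * n_per_class + ["b"] * n_per_class, index=idx)
    signal = np.r_[np.zeros(n_per_class), np.ones(n_per_class) * 10]
    pools, rankings = {}, {}
    for t in TYPE_ORDER:
        cols = {f"{t}_f{i}": signal + rng.normal(0, 0.05, len(idx)) for i in range(n_features)}
        pools[t] = pd.DataFrame(cols, index=idx)
        rankings[t] = _ranking(t, list(cols))
    return rankings, pools, y


class TestEnumeration:
    @pytest.mark.parametrize("max_per_type,max_total", [(3, 8), (6, 20), (2, 4)])
    def test_matches_direct_enumeration(self, max_per_type, max_total):
        got = enumerate_compositions(max_per_type, max_total)
        expected = [
            c
            for c in itertools.product(range(1, max_per_type + 1), repeat=4)
            if sum(c) <= max_total
        ]
        assert got == expected

    def test_every_composition_covers_all_types(self):
        for comp in enumerate_compositions(3, 9):
            assert min(comp) >= 1

    def test_infeasible_budget_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_compositions(3, 3)


class TestGridSearch:
    def test_tie_break_prefers_minimal_composition(self):
        # every composition scores F1=1.0 -> smallest total, lexicographic
        rankings, pools, y = _separable_pools()
        sel, table = grid_search_integration(
            rankings, pools, y, max_per_type=2, max_total=8,
            forest_params=FAST_FOREST, folds=4, seed=0,
        )
        assert sel.composition == (1, 1, 1, 1)
        assert sel.cv_f1.mean == pytest.approx(1.0)
        assert len(table) == len(enumerate_compositions(2, 8))

    def test_selected_features_are_rank_prefixes(self, small_cohort, small_feature_pools):
        _, pheno, _, _ = small_cohort
        labels = pheno.labels
        rankings = {
            t: rank_by_forest(small_feature_pools[t], labels, t, FAST_FOREST, cv_folds=5, seed=0)
            for t in TYPE_ORDER
        }
        sel, table = grid_search_integration(
            rankings, small_feature_pools, labels, max_per_type=2, max_total=6,
            forest_params=FAST_FOREST, folds=5, seed=0,
        )
        for t in TYPE_ORDER:
            chosen = [f for ft, f in sel.features if ft == t]
            assert chosen == rankings[t].top(sel.counts[t])
        assert (table["total"] <= 6).all()
        assert sel.total == len(sel.features)

    def test_noise_features_in_pool_do_not_change_optimum(self):
        rankings, pools, y = _separable_pools()
        sel0, _ = grid_search_integration(
            rankings, pools, y, max_per_type=2, max_total=8,
            forest_params=FAST_FOREST, folds=4, seed=0,
        )
        rng = np.random.default_rng(5)
        rankings2, pools2 = {}, {}
        for t in TYPE_ORDER:
            noise = pd.DataFrame(
                rng.normal(size=(len(y), 3)),
                columns=[f"{t}_noise{i}" for i in range(3)],
                index=pools[t].index,
            )
            pools2[t] = pd.concat([pools[t], noise], axis=1)
            entries = pd.concat(
                [
                    rankings[t].entries,
                    pd.DataFrame({"feature": noise.columns, "importance": [0.01, 0.005, 0.001]}),
                ],
                ignore_index=True,
            )
            rankings2[t] = RankedFeatureList(t, entries, folds=0, seed=0)
        sel1, _ = grid_search_integration(
            rankings2, pools2, y, max_per_type=2, max_total=8,
            forest_params=FAST_FOREST, folds=4, seed=0,
        )
        assert abs(sel1.cv_f1.mean - sel0.cv_f1.mean) <= 0.03

    def test_short_ranking_clips_with_warning(self):
        rankings, pools, y = _separable_pools(n_features=2)
        with pytest.warns(UserWarning, match="clipping"):
            sel, _ = grid_search_integration(
                rankings, pools, y, max_per_type=5, max_total=12,
                forest_params=FAST_FOREST, folds=4, seed=0,
            )
        assert max(sel.composition) <= 2


class TestCompareFeatureTypes:
    def test_output_shape_and_ranges(self):
        rankings, pools, y = _separable_pools()
        table = compare_feature_types(
            rankings, pools, y, budget=4, forest_params=FAST_FOREST, folds=4, seed=0
        )
        assert len(table) == 5
        assert set(table["feature_type"]) == set(TYPE_ORDER) | {"integrated"}
        assert table["mean_f1"].between(0, 1).all()
        integrated = table.set_index("feature_type").loc["integrated"]
        assert integrated["n_features"] == 4


@pytest.fixture(scope="module")
def trained(small_cohort, small_reference, small_feature_pools):
    _, pheno, _, _ = small_cohort
    labels = pheno.labels
    rankings = {
        t: rank_by_forest(small_feature_pools[t], labels, t, FAST_FOREST, cv_folds=5, seed=0)
        for t in TYPE_ORDER
    }
    sel, _ = grid_search_integration(
        rankings, small_feature_pools, labels, max_per_type=2, max_total=6,
        forest_params=FAST_FOREST, folds=5, seed=0,
    )
    return train_final_classifier(
        sel, small_feature_pools, labels, small_reference, FAST_FOREST
    )


class TestClassifySample:
    def test_scores_sum_to_one(self, trained, small_cohort):
        expr, pheno, _, _ = small_cohort
        label, scores = classify_sample(trained, expr.values[pheno.sample_ids[0]])
        assert sum(scores.values()) == pytest.approx(1.0, abs=1e-9)
        assert label in scores

    def test_deterministic(self, trained, small_cohort):
        expr, pheno, _, _ = small_cohort
        s = expr.values[pheno.sample_ids[-1]]
        assert classify_sample(trained, s) == classify_sample(trained, s)

    def test_training_sample_reproduces_stored_features(
        self, trained, small_cohort, small_feature_pools
    ):
        """Pipeline consistency for both a tumour and a reference-normal sample."""
        from edgestage.integration import _bundle_feature_vector

        expr, pheno, _, _ = small_cohort
        tumor = next(s for s in pheno.sample_ids if pheno.labels[s] == "III")
        normal = trained.reference.normal_sample_ids[0]
        for sid in (tumor, normal):
            vec = _bundle_feature_vector(trained, expr.values[sid])
            stored = np.array(
                [small_feature_pools[t].loc[sid, f] for t, f in trained.selection.features]
            )
            np.testing.assert_allclose(vec, stored, atol=1e-12)

    def test_missing_gene_rejected(self, trained, small_cohort):
        expr, pheno, _, _ = small_cohort
        t, f = trained.selection.features[0]
        gene = f if t == "node" else f.split(":")[0]
        sample = expr.values[pheno.sample_ids[0]].drop(gene)
        with pytest.raises(ValidationError):
            classify_sample(trained, sample)

    def test_bundle_round_trip(self, trained, small_cohort, tmp_path):
        expr, pheno, _, _ = small_cohort
        path = tmp_path / "bundle.joblib"
        save_bundle(trained, path)
        back = load_bundle(path)
        s = expr.values[pheno.sample_ids[3]]
        assert classify_sample(back, s) == classify_sample(trained, s)

    def test_wrong_schema_version_rejected(self, trained, tmp_path):
        path = tmp_path / "bundle.joblib"
        joblib.dump({"schema_version": 99, "bundle": trained}, path)
        with pytest.raises(ValidationError, match="schema"):
            load_bundle(path)


class TestColumnNaming:
    def test_same_pair_distinct_across_types(self):
        assert integrated_column("delta_pcc", "A:B") != integrated_column("delta_cov", "A:B")
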