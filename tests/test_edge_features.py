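import numpy as np
import pandas as pd
import pytest

from edgestage.cohort_io import ExpressionMatrix, PairUniverse, PhenotypeTable
from edgestage.edge_features import (
    build_edge_matrix,
    delta_cov,
    delta_pcc,
    fit_reference,
    residual,
)
from edgestage.errors import ValidationError


def _ref_from_points(x, y, extra_gene=None):
    """Reference over one pair gA (x) / gB (y) with the given normal points."""
    n = len(x)
    cols = [f"n{i}" for i in range(n)]
    data = {"gA": x, "gB": y}
    if extra_gene is not None:
        data["gC"] = extra_gene
    values = pd.DataFrame(data, index=cols).T
    m = ExpressionMatrix(values.astype(float), log_transformed=True)
    pheno = PhenotypeTable(pd.Series(["normal"] * n, index=cols, dtype=object))
    pairs = [("gA", "gB")] + ([("gA", "gC")] if extra_gene is not None else [])
    return m, pheno, fit_reference(m, pheno, PairUniverse(tuple(pairs)))


def _sample(x, y):
    return pd.Series({"gA": float(x), "gB": float(y)})


# -- brute-force oracles, independent of the incremental implementation ------


def brute_delta_pcc(xs, ys, x, y):
    before = np.corrcoef(xs, ys)[0, 1]
    after = np.corrcoef(np.append(xs, x), np.append(ys, y))[0, 1]
    return after - before


def brute_delta_cov(xs, ys, x, y):
    before = np.cov(xs, ys, ddof=1)[0, 1]
    after = np.cov(np.append(xs, x), np.append(ys, y), ddof=1)[0, 1]
    return after - before


class TestReferenceFit:
    def test_pcc_from_worked_example(self):
        # x=[1,2,3,4], y=[2,1,4,3]: s_xy=3, ss_x=ss_y=5 -> pcc = 3/5
        _, _, ref = _ref_from_points([1, 2, 3, 4], [2, 1, 4, 3])
        assert ref.pcc[0] == pytest.approx(0.6)
        assert ref.cov[0] == pytest.approx(1.0)  # 3 / (4-1)

    def test_identity_line(self):
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3])
        assert ref.pcc[0] == pytest.approx(1.0)
        assert ref.slope[0] == pytest.approx(1.0)
        assert ref.intercept[0] == pytest.approx(0.0)

    def test_constant_gene_pair_excluded(self):
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3], extra_gene=[4, 4, 4])
        assert ref.pairs == (("gA", "gB"),)
        assert ref.n_dropped_degenerate == 1

    def test_too_few_normals_rejected(self):
        values = pd.DataFrame({"n0": [1.0, 2.0], "n1": [2.0, 3.0]}, index=["gA", "gB"])
        m = ExpressionMatrix(values, log_transformed=True)
        pheno = PhenotypeTable(pd.Series(["normal", "normal"], index=["n0", "n1"]))
        with pytest.raises(ValidationError, match="normal"):
            fit_reference(m, pheno, PairUniverse((("gA", "gB"),)))


class TestDeltaPcc:
    def test_on_line_sample_leaves_correlation(self):
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3])
        assert delta_pcc(ref, _sample(4, 4))[0] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_off_line(self):
        # 4-point PCC = 0.5/sqrt(13.75); frozen from direct evaluation
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3])
        expected = 0.5 / np.sqrt(13.75) - 1.0
        assert delta_pcc(ref, _sample(4, 1))[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(-0.865, abs=5e-4)

    def test_bounded_by_two(self):
        rng = np.random.default_rng(0)
        _, _, ref = _ref_from_points([1, 2, 3, 5], [2, 1, 4, 3])
        for _ in range(100):
            x, y = rng.normal(0, 10, 2)
            assert abs(delta_pcc(ref, _sample(x, y))[0]) <= 2.0

    def test_missing_gene_rejected(self):
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValidationError, match="missing"):
            delta_pcc(ref, pd.Series({"gA": 1.0}))

    def test_affine_invariance_in_either_gene(self):
        rng = np.random.default_rng(1)
        xs, ys = rng.normal(5, 1, 20), rng.normal(5, 1, 20)
        _, _, ref = _ref_from_points(xs, ys)
        _, _, ref_scaled = _ref_from_points(3.0 * xs + 2.0, ys)
        s = rng.normal(5, 1, 2)
        a = delta_pcc(ref, _sample(s[0], s[1]))[0]
        b = delta_pcc(ref_scaled, _sample(3.0 * s[0] + 2.0, s[1]))[0]
        assert a == pytest.approx(b, abs=1e-10)


class TestDeltaCov:
    def test_worked_example(self):
        # normals on y=x (cov 1); adding (4,4): cov_4 = 5/3 -> delta = 2/3
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3])
        assert delta_cov(ref, _sample(4, 4))[0] == pytest.approx(2.0 / 3.0)

    def test_symmetric_in_pair_genes(self):
        rng = np.random.default_rng(2)
        xs, ys = rng.normal(5, 1, 15), rng.normal(5, 1, 15)
        _, _, ref_xy = _ref_from_points(xs, ys)
        _, _, ref_yx = _ref_from_points(ys, xs)
        x, y = rng.normal(5, 1, 2)
        assert delta_cov(ref_xy, _sample(x, y))[0] == pytest.approx(
            delta_cov(ref_yx, _sample(y, x))[0], abs=1e-12
        )

    def test_bilinear_scaling(self):
        rng = np.random.default_rng(3)
        xs, ys = rng.normal(5, 1, 20), rng.normal(5, 1, 20)
        _, _, ref = _ref_from_points(xs, ys)
        _, _, ref_scaled = _ref_from_points(2.0 * xs, ys)
        x, y = rng.normal(5, 1, 2)
        a = delta_cov(ref, _sample(x, y))[0]
        b = delta_cov(ref_scaled, _sample(2.0 * x, y))[0]
        assert b == pytest.approx(2.0 * a, abs=1e-10)


class TestResidual:
    def test_worked_examples(self):
        _, _, ref = _ref_from_points([1, 2, 3], [1, 2, 3])
        assert residual(ref, _sample(4, 1))[0] == pytest.approx(-3.0)
        assert residual(ref, _sample(4, 4))[0] == pytest.approx(0.0)
        _, _, ref2 = _ref_from_points([0, 1, 2], [1, 3, 5])  # y = 1 + 2x
        assert residual(ref2, _sample(2, 6))[0] == pytest.approx(1.0)

    def test_reference_residuals_sum_to_zero(self, small_cohort, small_reference):
        expr, pheno, _, _ = small_cohort
        ref = small_reference
        sums = np.zeros(len(ref))
        for sid in ref.normal_sample_ids:
            sums += residual(ref, expr.values[sid])
        np.testing.assert_allclose(sums, 0.0, atol=1e-9)


class TestIncrementalOracle:
    def test_matches_brute_force_recomputation(self, small_cohort, small_reference):
        expr, pheno, _, _ = small_cohort
        ref = small_reference
        normals = list(ref.normal_sample_ids)
        tumor = [s for s in pheno.sample_ids if pheno.labels[s] != "normal"]
        rng = np.random.default_rng(4)
        xs_all = expr.values.loc[ref.x_genes, normals].to_numpy()
        ys_all = expr.values.loc[ref.y_genes, normals].to_numpy()
        for _ in range(200):
            i = rng.integers(len(ref))
            sid = tumor[rng.integers(len(tumor))]
            sample = expr.values[sid]
            x, y = float(sample[ref.x_genes[i]]), float(sample[ref.y_genes[i]])
            assert delta_pcc(ref, sample)[i] == pytest.approx(
                brute_delta_pcc(xs_all[i], ys_all[i], x, y), abs=1e-10
            )
            assert delta_cov(ref, sample)[i] == pytest.approx(
                brute_delta_cov(xs_all[i], ys_all[i], x, y), abs=1e-10
            )


class TestEdgeMatrix:
    def test_row_count_matches_labelled_samples(self, small_cohort, small_edge_matrices):
        _, pheno, _, _ = small_cohort
        for em in small_edge_matrices.values():
            assert em.values.shape[0] == len(pheno.sample_ids)
            assert list(em.values.index) == pheno.sample_ids

    def test_planted_pairs_more_perturbed_than_null_pairs(self, small_cohort, small_edge_matrices):
        from edgestage.cohort_io import pair_label

        _, pheno, _, truth = small_cohort
        em = small_edge_matrices["delta_pcc"]
        stage = [s for s in pheno.sample_ids if pheno.labels[s] in ("III", "IV")]
        planted = {pair_label(p) for p in truth.planted_pcc_pairs}
        other_planted = {
            pair_label(p)
            for p in truth.planted_cov_pairs + truth.planted_residual_pairs
        }
        null_cols = [
            c for c in em.values.columns if c not in planted and c not in other_planted
        ]
        mean_planted = em.values.loc[stage, sorted(planted)].abs().mean().mean()
        mean_null = em.values.loc[stage, null_cols].abs().mean().mean()
        assert mean_planted > mean_null

    def test_normal_rows_use_leave_one_out_reference(self, small_cohort, small_reference):
        """A normal sample's row equals a brute-force refit without it."""
        expr, pheno, universe, _ = small_cohort
        ref = small_reference
        em = build_edge_matrix(ref, expr, pheno, "delta_pcc")
        sid = ref.normal_sample_ids[0]
        others = [s for s in pheno.sample_ids if pheno.labels[s] == "normal" and s != sid]
        loo_pheno = PhenotypeTable(
            pd.Series(["normal"] * len(others), index=others, dtype=object)
        )
        loo_ref = fit_reference(expr, loo_pheno, universe)
        expected = delta_pcc(loo_ref, expr.values[sid])
        np.testing.assert_allclose(em.values.loc[sid].to_numpy(), expected, atol=1e-9)

    def test_unknown_feature_type_rejected(self, small_cohort, small_reference):
        expr, pheno, _, _ = small_cohort
        with pytest.raises(ValidationError):
            build_edge_matrix(small_reference, expr, pheno, "mutual_information")
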