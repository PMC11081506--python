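"""Scoring algorithms: centering, projection, bases, score formulas, variants."""

import numpy as np
import pytest
from scipy import sparse

from reset.core import (
    score_cap,
    ExpressionMatrix,
    ResetParams,
    center_scale,
    delayed_center_scores,
    per_variable_adjust,
    project_onto_pcs,
    reconstruction_scores,
    reset_randomized,
    reset_reduced,
    reset_simplistic,
    set_basis,
)
from reset.rnla import SketchParams
from reset.core import _exact_svd


def expr(values, **kw):
    values = np.asarray(values, float) if not sparse.issparse(values) else values
    n, p = values.shape
    return ExpressionMatrix(
        values=values,
        sample_ids=[f"s{i}" for i in range(n)],
        gene_ids=[f"g{j + 1}" for j in range(p)],
    )


class TestCenterScale:
    def test_center_subtracts_column_mean(self):
        out = center_scale(np.array([[1.0], [2.0], [3.0]]), center=True, scale=False)
        assert np.allclose(out.ravel(), [-1, 0, 1])

    def test_constant_column_scales_to_zero_without_error(self):
        out = center_scale(np.array([[5.0], [5.0], [5.0]]), center=True, scale=True)
        assert np.allclose(out, 0.0)

    def test_sample_sd_convention(self):
        # column (0, 0, 6): mean 2, sample sd sqrt(24/2) = 3.4641
        out = center_scale(np.array([[0.0], [0.0], [6.0]]), center=True, scale=True)
        assert np.allclose(out.ravel(), [-0.57735, -0.57735, 1.15470], atol=1e-5)


class TestProjectOntoPcs:
    def test_full_signal_rank_preserves_frobenius_norm(self, rng):
        X = rng.standard_normal((30, 2)) @ rng.standard_normal((2, 12))
        P = project_onto_pcs(X, _exact_svd(X), 2)
        assert np.isclose(np.linalg.norm(P), np.linalg.norm(X), rtol=1e-8)

    def test_identity_matrix_norm(self):
        X = np.eye(4)
        P = project_onto_pcs(X, _exact_svd(X), 4)
        assert np.isclose(np.linalg.norm(P), 2.0)

    def test_projection_equals_u_times_sigma(self, rng):
        X = rng.standard_normal((100, 40))
        svd = _exact_svd(X)
        P = project_onto_pcs(X, svd, 5)
        assert np.allclose(P, svd.U[:, :5] * svd.sigma[:5], atol=1e-6)

    def test_b_beyond_components_raises(self, rng):
        X = rng.standard_normal((10, 4))
        with pytest.raises(ValueError):
            project_onto_pcs(X, _exact_svd(X), 5)


class TestSetBasis:
    def sketch(self, k=2):
        return SketchParams(target_rank=k, seed=0)

    def test_rank_capped_at_set_size(self, rng):
        X_s = rng.standard_normal((20, 5))
        Q, eff, used_random = set_basis(X_s, k=10, random_threshold=100, sketch=self.sketch(10))
        assert eff == 5 and not used_random and Q.shape == (20, 5)

    def test_duplicate_columns_yield_orthonormal_independent_basis(self, rng):
        col = rng.standard_normal((30, 1))
        other = rng.standard_normal((30, 1))
        X_s = np.hstack([col, col, other])
        Q, eff, _ = set_basis(X_s, k=2, random_threshold=100, sketch=self.sketch())
        assert eff == 2
        assert np.allclose(Q.T @ Q, np.eye(2), atol=1e-8)
        # span matches the exact rank-2 column space: residual of X_s is ~0
        assert np.linalg.norm(X_s - Q @ (Q.T @ X_s)) < 1e-8

    def test_threshold_is_strict_inequality(self, rng):
        X_s = rng.standard_normal((40, 90))
        _, _, used_random = set_basis(X_s, k=5, random_threshold=90, sketch=self.sketch(5))
        assert not used_random
        _, _, used_random = set_basis(X_s, k=5, random_threshold=89, sketch=self.sketch(5))
        assert used_random


class TestReconstructionScores:
    def test_basis_spanning_p_hits_cap_with_flag(self):
        P = np.eye(3)
        Q = np.eye(3)
        overall, per_sample, degenerate, n_deg = reconstruction_scores(P, Q)
        assert degenerate and n_deg == 3
        assert overall == pytest.approx(score_cap(P.shape))

    def test_orthogonal_basis_scores_zero(self, rng):
        P = np.zeros((4, 2))
        P[:2, :] = np.eye(2)
        Q = np.zeros((4, 1))
        Q[3, 0] = 1.0
        overall, per_sample, degenerate, _ = reconstruction_scores(P, Q)
        assert overall == 0.0 and np.allclose(per_sample, 0.0) and not degenerate

    def test_hand_computed_partial_projection(self):
        # P = I_2, basis = e1: ||E||_F = 1, overall = log2(sqrt(2)/1) = 0.5
        P = np.eye(2)
        Q = np.array([[1.0], [0.0]])
        overall, per_sample, _, _ = reconstruction_scores(P, Q)
        assert overall == pytest.approx(0.5)
        assert per_sample[0] == pytest.approx(score_cap(P.shape))
        assert per_sample[1] == pytest.approx(0.0)

    def test_l1_row_norms_supported(self, rng):
        P = rng.standard_normal((6, 3))
        Q = np.linalg.qr(rng.standard_normal((6, 2)))[0]
        _, s1, _, _ = reconstruction_scores(P, Q, norm_type="L1")
        E = P - Q @ (Q.T @ P)
        expected = np.maximum(np.log2(np.abs(P).sum(1) / np.abs(E).sum(1)), 0.0)
        assert np.allclose(s1, expected)

    def test_pythagorean_identity(self, rng):
        P = rng.standard_normal((25, 8))
        Q = np.linalg.qr(rng.standard_normal((25, 4)))[0]
        E = P - Q @ (Q.T @ P)
        lhs = np.linalg.norm(E) ** 2 + np.linalg.norm(Q.T @ P) ** 2
        assert np.isclose(lhs, np.linalg.norm(P) ** 2, rtol=1e-8)


class TestPerVariableAdjust:
    def make_scores(self, A, v):
        from reset.core import ResetScores

        m = A.n_sets
        return ResetScores(
            S=np.tile(v, (3, 1)), v=np.asarray(v, float), set_names=A.set_names,
            sample_ids=["a", "b", "c"], params_used=None,
            effective_ranks=np.ones(m, int), randomized=np.zeros(m, bool),
            degenerate_overall=np.zeros(m, bool), n_degenerate_samples=np.zeros(m, int),
        )

    def test_average_size_set_unchanged_and_others_scaled(self, annotation_factory):
        A = annotation_factory(60, {"a": range(10), "b": range(10, 30), "c": range(30, 60)})
        scores = self.make_scores(A, [1.0, 1.0, 1.0])
        adj = per_variable_adjust(scores, A)
        # mean size 20: size-10 set doubled, size-20 unchanged, size-30 scaled by 2/3
        assert np.allclose(adj.v, [2.0, 1.0, 2.0 / 3.0])
        assert np.allclose(adj.S[0], adj.v)

    def test_double_mean_size_halves_score(self, annotation_factory):
        A = annotation_factory(30, {"a": range(10), "b": range(10, 30)})
        adj = per_variable_adjust(self.make_scores(A, [1.0, 1.0]), A)
        assert adj.v[1] == pytest.approx(1.0 / (20 / 15))


class TestResetSimplistic:
    def test_identity_matrix_two_gene_set(self, annotation_factory):
        X = expr(np.eye(4))
        A = annotation_factory(4, {"s": [0, 1]})
        scores = reset_simplistic(X, A)
        assert scores.v[0] == pytest.approx(0.5)
        assert scores.S[0, 0] == pytest.approx(score_cap((4, 4)))
        assert scores.S[2, 0] == pytest.approx(0.0)

    def test_all_genes_full_rank_degenerate(self, rng, annotation_factory):
        X = expr(rng.standard_normal((6, 4)))
        A = annotation_factory(4, {"all": range(4)})
        scores = reset_simplistic(X, A)
        assert scores.degenerate_overall[0]
        assert scores.n_degenerate_samples[0] == 6

    def test_scores_nonnegative(self, rng, annotation_factory):
        X = expr(rng.standard_normal((30, 10)))
        A = annotation_factory(10, {"a": range(3), "b": range(5, 9)})
        scores = reset_simplistic(X, A)
        assert (scores.v >= 0).all() and (scores.S >= 0).all()


class TestResetReduced:
    def test_rank_one_signal_supported_on_set(self, rng, annotation_factory):
        u = rng.standard_normal((40, 1))
        w = np.zeros((1, 20))
        w[0, :6] = rng.standard_normal(6)
        X = expr(u @ w + 1e-9 * rng.standard_normal((40, 20)))
        A = annotation_factory(20, {"sig": range(6), "null": range(10, 16)})
        scores = reset_reduced(X, A, ResetParams(b=1, k=1, center=False))
        assert scores.v[0] > 20.0  # near-degenerate reconstruction of the signal
        # disjoint noise set: only chance alignment of one random direction
        assert scores.v[1] < 0.15

    def test_scores_nonnegative_and_finite(self, rng, annotation_factory):
        X = expr(rng.standard_normal((50, 30)))
        A = annotation_factory(30, {"a": range(8), "b": range(8, 24)})
        scores = reset_reduced(X, A, ResetParams(b=5, k=3))
        assert np.isfinite(scores.S).all() and (scores.S >= 0).all()
        assert np.isfinite(scores.v).all() and (scores.v >= 0).all()

    def test_b_larger_than_matrix_raises(self, rng, annotation_factory):
        X = expr(rng.standard_normal((10, 8)))
        A = annotation_factory(8, {"a": range(5)})
        with pytest.raises(ValueError):
            reset_reduced(X, A, ResetParams(b=9, k=2))


class TestResetRandomized:
    def test_same_seed_bit_identical(self, rng, annotation_factory):
        X = expr(rng.standard_normal((60, 40)))
        A = annotation_factory(40, {"a": range(20), "b": range(20, 40)})
        p = ResetParams(b=5, k=3, random_threshold=2, seed=42)
        s1 = reset_randomized(X, A, p)
        s2 = reset_randomized(X, A, p)
        assert np.array_equal(s1.S, s2.S) and np.array_equal(s1.v, s2.v)

    def test_low_threshold_forces_randomized_path(self, rng, annotation_factory):
        X = expr(rng.standard_normal((60, 40)))
        A = annotation_factory(40, {"a": range(12), "b": range(20, 40)})
        scores = reset_randomized(X, A, ResetParams(b=5, k=3, random_threshold=2, seed=0))
        assert scores.randomized.all()

    def test_exact_svd_high_threshold_reproduces_reduced_exactly(self, rng, annotation_factory):
        X = expr(rng.standard_normal((60, 40)))
        A = annotation_factory(40, {"a": range(20), "b": range(15, 40)})
        p = ResetParams(b=6, k=4, random_threshold=40, seed=1)
        assert np.array_equal(
            reset_randomized(X, A, p, exact_svd=True).S, reset_reduced(X, A, p).S
        )

    def test_per_var_divides_by_scaled_size(self, rng, annotation_factory):
        X = expr(rng.standard_normal((40, 30)))
        A = annotation_factory(30, {"a": range(10), "b": range(10, 30)})
        p = ResetParams(b=5, k=3, random_threshold=40, seed=2)
        base = reset_randomized(X, A, p)
        adj = reset_randomized(X, A, ResetParams(**{**p.__dict__, "per_var": True}))
        assert np.allclose(adj.v, base.v / (A.set_sizes / A.mean_size))

    def test_permutation_equivariance_deterministic_path(self, rng, annotation_factory):
        X = rng.standard_normal((30, 20))
        A = annotation_factory(20, {"a": range(8), "b": range(8, 20)})
        p = ResetParams(b=4, k=2, random_threshold=25, seed=3)
        perm = rng.permutation(30)
        s1 = reset_randomized(expr(X), A, p, exact_svd=True)
        s2 = reset_randomized(expr(X[perm]), A, p, exact_svd=True)
        assert np.allclose(s2.S, s1.S[perm], atol=1e-8)
        assert np.allclose(s2.v, s1.v, atol=1e-8)

    def test_nonpositive_ranks_rejected(self):
        with pytest.raises(ValueError):
            ResetParams(b=0, k=1)
        with pytest.raises(ValueError):
            ResetParams(b=1, k=0)


class TestNullScoreSizeDependence:
    def test_reduced_rank_removes_gross_size_dependence(self, annotation_factory):
        """Under iid noise, full-width reconstruction favors big sets strongly;
        the reduced-rank variant shrinks that size dependence to a small
        residual (big/small mean score ratio near 1 instead of several-fold)."""
        A = annotation_factory(200, {"small": range(20), "big": range(100, 180)})
        red_small, red_big, simp_small, simp_big = [], [], [], []
        for r in range(10):
            g = np.random.default_rng(500 + r)
            X = expr(g.standard_normal((300, 200)))
            v = reset_reduced(X, A, ResetParams(b=10, k=5)).v
            red_small.append(v[0])
            red_big.append(v[1])
            v = reset_simplistic(X, A).v
            simp_small.append(v[0])
            simp_big.append(v[1])
        simplistic_ratio = np.mean(simp_big) / np.mean(simp_small)
        reduced_ratio = np.mean(red_big) / np.mean(red_small)
        assert simplistic_ratio > 3.0
        assert 1.0 < reduced_ratio < 1.5


class TestDelayedCentering:
    def test_zero_mean_matrix_matches_standard_path(self, rng, annotation_factory):
        X = rng.standard_normal((50, 30))
        X -= X.mean(axis=0, keepdims=True)
        A = annotation_factory(30, {"a": range(10), "b": range(10, 30)})
        p = ResetParams(b=5, k=3, center=False, random_threshold=40, seed=5)
        delayed = delayed_center_scores(expr(sparse.csr_matrix(X)), A, p)
        # standard path with pre-centered input and exact SVD on same data
        standard = reset_randomized(expr(X), A, ResetParams(**{**p.__dict__, "center": True}))
        assert np.allclose(delayed.S, standard.S, atol=1e-10)
        assert np.allclose(delayed.v, standard.v, atol=1e-10)

    def test_full_matrix_never_densified(self, rng, annotation_factory, monkeypatch):
        X = sparse.random(200, 80, density=0.05, random_state=1, format="csr")
        A = annotation_factory(80, {"a": range(10), "b": range(40, 60)})
        shapes = []
        orig = sparse.csr_matrix.toarray

        def probe(self, *a, **kw):
            shapes.append(self.shape)
            return orig(self, *a, **kw)

        monkeypatch.setattr(sparse.csr_matrix, "toarray", probe)
        delayed_center_scores(expr(X), A, ResetParams(b=5, k=3, center=False, seed=6))
        assert shapes, "per-set sub-matrices should be densified"
        assert all(shape[1] <= 20 for shape in shapes)

    def test_nonzero_means_differ_but_stay_valid(self, rng, annotation_factory):
        X = rng.standard_normal((40, 20)) + 5.0
        A = annotation_factory(20, {"a": range(8), "b": range(8, 20)})
        delayed = delayed_center_scores(
            expr(sparse.csr_matrix(X)), A, ResetParams(b=4, k=2, center=False, seed=7)
        )
        standard = reset_randomized(expr(X), A, ResetParams(b=4, k=2, seed=7))
        assert not np.allclose(delayed.S, standard.S)
        for s in (delayed, standard):
            assert np.isfinite(s.S).all() and (s.S >= 0).all()

    def test_requires_center_false(self, rng, annotation_factory):
        X = expr(sparse.csr_matrix(rng.standard_normal((20, 10))))
        A = annotation_factory(10, {"a": range(5)})
        with pytest.raises(ValueError):
            delayed_center_scores(X, A, ResetParams(b=2, k=2, center=True))


class TestExpressionMatrix:
    def test_duplicate_gene_ids_first_kept(self, rng):
        X = ExpressionMatrix(
            values=rng.standard_normal((3, 3)),
            sample_ids=["a", "b", "c"],
            gene_ids=["g1", "g2", "g1"],
        )
        assert X.gene_ids == ["g1", "g2"] and X.shape == (3, 2)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(
                values=np.array([[1.0, np.inf], [0.0, 1.0]]),
                sample_ids=["a", "b"],
                gene_ids=["g1", "g2"],
            )

    def test_csv_roundtrip(self, tmp_path, rng):
        import pandas as pd

        df = pd.DataFrame(
            rng.integers(0, 5, (3, 4)).astype(float),
            index=["s1", "s2", "s3"],
            columns=["g1", "g2", "g3", "g4"],
        )
        path = tmp_path / "x.csv"
        df.to_csv(path)
        X = ExpressionMatrix.from_csv(path)
        assert X.sample_ids == ["s1", "s2", "s3"]
        assert np.allclose(X.values, df.to_numpy())
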