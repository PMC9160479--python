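"""PCA, (r)CCA, sparse multiblock PLS(-DA) against independent oracles."""

import numpy as np
import pandas as pd
import pytest

import adjuscreen as ads
from adjuscreen.multiblock import _default_design
from _oracles import brute_force_best_feature, cca_eigen_oracle, nipals_pls2


def shared_factor_data(rng, n=50, p=3, q=2, noise=0.5):
    z = rng.standard_normal(n)
    X = np.outer(z, rng.standard_normal(p)) + noise * rng.standard_normal((n, p))
    Y = np.outer(z, rng.standard_normal(q)) + noise * rng.standard_normal((n, q))
    return X, Y


class TestPCA:
    def test_perfectly_correlated_columns_one_component(self, rng):
        x = rng.standard_normal(20)
        model = ads.pca(np.column_stack([x, 2 * x]), n_components=2)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_loadings_orthonormal(self, rng):
        model = ads.pca(rng.standard_normal((10, 4)), n_components=4)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_full_reconstruction(self, rng):
        X = rng.standard_normal((10, 4))
        model = ads.pca(X, n_components=4)
        recon = model.scores @ model.loadings.T + model.center
        assert np.allclose(recon, X, atol=1e-10)

    def test_sign_convention_deterministic(self, rng):
        X = rng.standard_normal((15, 5))
        m1, m2 = ads.pca(X), ads.pca(X.copy())
        for k in range(m1.loadings.shape[1]):
            j = np.argmax(np.abs(m1.loadings[:, k]))
            assert m1.loadings[j, k] > 0
        assert np.array_equal(m1.loadings, m2.loadings)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            ads.pca(rng.standard_normal((5, 3)), n_components=4)


class TestCCA:
    def test_self_canonical_correlations_are_one(self, rng):
        X = rng.standard_normal((40, 3))
        model = ads.cca(X, X[:, :2] + 0.0)
        assert np.allclose(model.canonical_correlations, 1.0, atol=1e-8)

    def test_independent_blocks_near_zero(self, rng):
        X = rng.standard_normal((10_000, 2))
        Y = rng.standard_normal((10_000, 2))
        model = ads.cca(X, Y)
        assert model.canonical_correlations[0] < 0.05

    def test_matches_generalized_eigen_oracle(self, rng):
        X, Y = shared_factor_data(rng)
        model = ads.cca(X, Y)
        oracle = cca_eigen_oracle(X, Y, 2)
        assert np.allclose(model.canonical_correlations, oracle, atol=1e-8)

    def test_score_correlation_equals_rho(self, rng):
        X, Y = shared_factor_data(rng)
        model = ads.cca(X, Y)
        for k in range(2):
            r = np.corrcoef(model.x_scores[:, k], model.y_scores[:, k])[0, 1]
            assert r == pytest.approx(model.canonical_correlations[k], abs=1e-6)

    def test_small_n_directed_to_rcca(self, rng):
        with pytest.raises(ValueError, match="rcca"):
            ads.cca(rng.standard_normal((10, 6)), rng.standard_normal((10, 6)))


class TestRCCA:
    def test_lambda_to_zero_matches_cca(self, rng):
        X, Y = shared_factor_data(rng)
        loose = ads.rcca(X, Y, 1e-8, 1e-8)
        exact = ads.cca(X, Y)
        assert np.allclose(
            loose.canonical_correlations, exact.canonical_correlations, atol=1e-6
        )

    def test_lambda_to_infinity_is_cross_covariance_svd(self, rng):
        X, Y = shared_factor_data(rng)
        model = ads.rcca(X, Y, 1e6, 1e6)
        Xc, Yc = X - X.mean(0), Y - Y.mean(0)
        U, _, Vt = np.linalg.svd(Xc.T @ Yc / (len(X) - 1))

        def direction_gap(a, b):
            a, b = a / np.linalg.norm(a), b / np.linalg.norm(b)
            return min(np.abs(a - b).max(), np.abs(a + b).max())

        assert direction_gap(model.x_weights[:, 0], U[:, 0]) < 1e-4
        assert direction_gap(model.y_weights[:, 0], Vt[0]) < 1e-4

    def test_well_defined_when_features_exceed_samples(self, rng):
        X = rng.standard_normal((20, 30))
        Y = rng.standard_normal((20, 4))
        model = ads.rcca(X, Y, 0.1, 0.1)
        rho = model.canonical_correlations
        assert np.all((rho >= 0) & (rho <= 1))

    def test_singular_covariance_without_penalty_rejected(self, rng):
        X = rng.standard_normal((20, 30))
        with pytest.raises(np.linalg.LinAlgError):
            ads.rcca(X, rng.standard_normal((20, 2)), 0.0, 0.0)


class TestTuneRCC:
    def test_single_point_grid_returned(self, rng):
        X, Y = shared_factor_data(rng)
        l1, l2, surface = ads.tune_rcc(X, Y, lambda_grid=[0.3], folds=3, seed=0)
        assert (l1, l2) == (0.3, 0.3) and len(surface) == 1

    def test_scores_are_correlations(self, rng):
        X, Y = shared_factor_data(rng)
        _, _, surface = ads.tune_rcc(X, Y, lambda_grid=[1e-3, 1e-1], folds=3, seed=0)
        assert surface["cv_score"].between(-1, 1).all()

    def test_strong_shared_factor_beats_grid_extremes(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, Y = shared_factor_data(rng, n=40, p=8, q=4, noise=1.0)
            grid = [1e-4, 1e-2, 1e0]
            l1, l2, surface = ads.tune_rcc(X, Y, lambda_grid=grid, folds=4, seed=seed)
            chosen = surface.query("lambda1 == @l1 and lambda2 == @l2")["cv_score"].iloc[0]
            extremes = surface.query(
                "(lambda1 == 1e-4 and lambda2 == 1e-4) or (lambda1 == 1.0 and lambda2 == 1.0)"
            )["cv_score"]
            wins += chosen >= extremes.max() - 1e-12
        assert wins == 10


class TestSimilarityMatrix:
    def test_self_similarity_diagonal(self, rng):
        z = rng.standard_normal(60)
        X = np.column_stack([z + 0.05 * rng.standard_normal(60) for _ in range(3)])
        model = ads.rcca(X, X.copy(), 1e-6, 1e-6, n_dims=1)
        sim = ads.similarity_matrix(model, n_dims=1)
        assert np.all(np.diag(sim.to_numpy()) > 0.95)

    def test_entries_bounded(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, Y = shared_factor_data(rng, n=30, p=4, q=3)
            model = ads.rcca(X, Y, 0.05, 0.05)
            sim = ads.similarity_matrix(model).to_numpy()
            assert np.all(sim > -1 - 1e-9) and np.all(sim < 1 + 1e-9)

    def test_zero_dims_rejected(self, rng):
        X, Y = shared_factor_data(rng)
        with pytest.raises(ValueError):
            ads.similarity_matrix(ads.rcca(X, Y, 0.01, 0.01), n_dims=0)


class TestSoftSelect:
    def test_hand_computation(self):
        out = ads.soft_select(np.array([3.0, -1.0, 2.0]), keep=2)
        assert np.allclose(out, np.array([2.0, 0.0, 1.0]) / np.sqrt(5))

    def test_dense_limit_preserves_direction(self, rng):
        v = rng.standard_normal(6)
        out = ads.soft_select(v, keep=6)
        assert np.allclose(out, v / np.linalg.norm(v))

    def test_boundary_tie_keeps_lowest_index(self):
        out = ads.soft_select(np.array([2.0, -2.0]), keep=1)
        assert out[0] == pytest.approx(1.0) and out[1] == 0.0

    def test_keep_exceeding_length_warns(self, rng):
        with pytest.warns(UserWarning, match="exceeds"):
            out = ads.soft_select(np.array([1.0, 2.0]), keep=5)
        assert np.linalg.norm(out) == pytest.approx(1.0)

    def test_unit_norm_and_sparsity(self, rng):
        for keep in (1, 3, 5):
            v = rng.standard_normal(8)
            out = ads.soft_select(v, keep)
            assert np.linalg.norm(out) == pytest.approx(1.0)
            assert np.count_nonzero(out) <= keep


class TestBlockSPLS:
    def test_single_block_dense_matches_pls1(self, rng):
        X = rng.standard_normal((30, 8))
        y = (X @ rng.standard_normal(8) + rng.standard_normal(30))[:, None]
        model = ads.block_spls({"x": X}, y, {"x": 8})
        Xc, yc = X - X.mean(0), y - y.mean(0)
        w = (Xc.T @ yc[:, 0]) / np.linalg.norm(Xc.T @ yc[:, 0])
        gap = min(
            np.abs(model.weights["x"][:, 0] - w).max(),
            np.abs(model.weights["x"][:, 0] + w).max(),
        )
        assert gap < 1e-8

    def test_keepx_one_selects_max_covariance_feature(self, rng):
        X = rng.standard_normal((40, 6))
        y = (X[:, 2] + 0.3 * rng.standard_normal(40))[:, None]
        model = ads.block_spls({"x": X}, y, {"x": 1})
        selected = np.flatnonzero(model.weights["x"][:, 0])
        assert selected.tolist() == [brute_force_best_feature(X, y)]

    def test_dense_matches_nipals_pls2_multicomponent(self, rng):
        X = rng.standard_normal((25, 6))
        Y = X[:, :2] @ rng.standard_normal((2, 3)) + 0.5 * rng.standard_normal((25, 3))
        model = ads.block_spls({"x": X}, Y, {"x": 6}, n_comp=2, tol=1e-12)
        oracle = nipals_pls2(X, Y, 2)
        for h in range(2):
            gap = min(
                np.abs(model.weights["x"][:, h] - oracle[:, h]).max(),
                np.abs(model.weights["x"][:, h] + oracle[:, h]).max(),
            )
            assert gap < 1e-8

    def test_planted_features_recovered(self):
        hits = 0
        for seed in range(20):
            blocks, outcomes, truth = ads.generate_cohort(ads.SimConfig(seed=seed))
            scaled = {
                name: ads.scale_columns(b.data).data for name, b in blocks.items()
            }
            y = ads.scale_columns(outcomes[["totalIgG_fc"]]).data
            model = ads.block_spls(scaled, y, 10)
            found = set(model.selected_features["human_cytokine"][0])
            hits += len(found & set(truth.informative_human)) >= 4
        assert hits >= 16

    def test_scores_centered_weights_unit_norm(self, rng):
        X1 = rng.standard_normal((30, 7))
        X2 = rng.standard_normal((30, 5))
        Y = rng.standard_normal((30, 2))
        model = ads.block_spls({"a": X1, "b": X2}, Y, {"a": 3, "b": 2}, n_comp=2)
        for b in ("a", "b"):
            for h in range(2):
                assert np.linalg.norm(model.weights[b][:, h]) == pytest.approx(1.0)
                assert abs(model.scores[b][:, h].mean()) < 1e-10
                assert np.count_nonzero(model.weights[b][:, h]) <= model.keepX[b]

    def test_keepx_exceeding_features_rejected(self, rng):
        with pytest.raises(ValueError, match="keepX"):
            ads.block_spls(
                {"x": rng.standard_normal((10, 3))}, rng.standard_normal((10, 1)), {"x": 4}
            )


class TestDichotomize:
    def test_mean_split(self):
        labels = ads.dichotomize([1.0, 2.0, 3.0, 4.0])
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_value_at_mean_goes_low(self):
        labels = ads.dichotomize([0.0, 2.0, 4.0])
        assert labels[1] == "low"

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            ads.dichotomize([0.0, 0.0, 0.0])


class TestBlockSPLSDA:
    def planted(self, rng, delta=5.0, n=40, p=8):
        labels = np.array(["high"] * (n // 2) + ["low"] * (n // 2))
        X = rng.standard_normal((n, p))
        X[: n // 2, :3] += delta
        return {"x": X - X.mean(0)}, labels

    def test_planted_separation_selected_with_dominant_high(self, rng):
        blocks, labels = self.planted(rng)
        model = ads.block_splsda(blocks, labels, {"x": 3})
        selected = model.selected_features["x"][0]
        assert sorted(selected) == ["0", "1", "2"]
        assert all(model.dominant_class["x"][0][f] == "high" for f in selected)

    def test_label_swap_symmetry(self, rng):
        blocks, labels = self.planted(rng)
        swapped = np.where(labels == "high", "low", "high")
        m1 = ads.block_splsda(blocks, labels, {"x": 3})
        m2 = ads.block_splsda(blocks, swapped, {"x": 3})
        assert m1.selected_features["x"][0] == m2.selected_features["x"][0]
        for f in m1.selected_features["x"][0]:
            assert m1.dominant_class["x"][0][f] != m2.dominant_class["x"][0][f]

    def test_joint_row_permutation_invariance(self, rng):
        blocks, labels = self.planted(rng)
        perm = rng.permutation(len(labels))
        m1 = ads.block_splsda(blocks, labels, {"x": 3})
        m2 = ads.block_splsda({"x": blocks["x"][perm]}, labels[perm], {"x": 3})
        assert m1.selected_features["x"][0] == m2.selected_features["x"][0]
        assert np.allclose(m1.scores["x"][perm], m2.scores["x"], atol=1e-8)

    def test_default_keepx_configuration_shape(self, default_cohort):
        blocks, outcomes, _ = default_cohort
        scaled = {name: ads.scale_columns(b.data).data for name, b in blocks.items()}
        labels = ads.dichotomize(outcomes["totalIgG_fc"])
        model = ads.block_splsda(scaled, labels, keepX=10)
        for b in model.block_names:
            assert len(model.selected_features[b][0]) == 10

    def test_single_class_rejected(self, rng):
        blocks, labels = self.planted(rng)
        with pytest.raises(ValueError):
            ads.block_splsda(blocks, np.full_like(labels, "high"), {"x": 3})


class TestTuneBlockSPLSDA:
    def test_perfectly_separated_classes_zero_error(self, rng):
        blocks, labels = self.make_separable(rng)
        chosen, table = ads.tune_block_splsda(
            blocks, labels, keepX_grid=[2, 4], folds=3, repeats=2, seed=0
        )
        assert table["mean_ber"].min() == pytest.approx(0.0)

    def test_single_candidate_returned_with_error(self, rng):
        blocks, labels = self.make_separable(rng)
        chosen, table = ads.tune_block_splsda(
            blocks, labels, keepX_grid=[3], folds=3, repeats=1, seed=0
        )
        assert chosen == {"x": 3} and len(table) == 1

    def test_class_too_small_rejected(self, rng):
        blocks, labels = self.make_separable(rng)
        labels = np.array(["high"] * 3 + ["low"] * (len(labels) - 3))
        with pytest.raises(ValueError, match="stratify"):
            ads.tune_block_splsda(blocks, labels, keepX_grid=[2], folds=5)

    @staticmethod
    def make_separable(rng, n=30, p=6):
        labels = np.array(["high"] * (n // 2) + ["low"] * (n // 2))
        X = rng.standard_normal((n, p))
        X[: n // 2, :2] += 6.0
        return {"x": X}, labels


def test_default_design_shape():
    d = _default_design(3)
    assert d.shape == (4, 4)
    assert np.allclose(d, d.T)
    assert np.all(d[-1, :-1] == 1.0) and np.all(np.diag(d) == 0)
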