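import hashlib

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from neurosig.classifiers import (
    StratificationError,
    fit_lasso_pcr,
    fit_lda,
    fit_pca,
    make_subject_folds,
    predict,
    project,
    voxel_weights,
)
from neurosig.data_model import (
    CLASS_LABELS,
    BetaMap,
    BetaMapSet,
    BrainMask,
    DimensionError,
)


def _matrix_with_evr(shares, n=8, p=40, seed=0):
    """Data whose centered PCA has exactly the given explained-variance
    shares: built from orthonormal factors orthogonal to the ones vector."""
    rng = np.random.default_rng(seed)
    k = len(shares)
    base = np.c_[np.ones(n), rng.standard_normal((n, k))]
    q, _ = np.linalg.qr(base)
    u = q[:, 1 : k + 1]  # orthonormal, zero column means
    v, _ = np.linalg.qr(rng.standard_normal((p, k)))
    s = np.sqrt(np.asarray(shares))
    return u @ np.diag(s) @ v.T


def _set_from_matrix(x, mask=None):
    n, p = x.shape
    assert n % 3 == 0
    if mask is None:
        shape = (p, 1, 1)
        mask = BrainMask(inside=np.ones(shape, bool), affine=np.eye(4))
    maps = [
        BetaMap(f"s{i // 3:03d}", CLASS_LABELS[i % 3], "A", x[i])
        for i in range(n)
    ]
    return BetaMapSet(mask=mask, maps=maps)


class TestFitPca:
    def test_variance_threshold_rule(self):
        x = _matrix_with_evr([0.50, 0.30, 0.15, 0.05], n=9)
        _, _, evr, m = fit_pca(x, 0.90)
        np.testing.assert_allclose(evr[:4], [0.50, 0.30, 0.15, 0.05], atol=1e-10)
        assert m == 3  # cumulative reaches 0.95 >= 0.90 at 3 components

    def test_threshold_one_retains_full_rank(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((6, 20))
        _, _, _, m = fit_pca(x, 1.0)
        assert m == 5  # rank of 6 centered rows

    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(2)
        _, v, _, m = fit_pca(rng.standard_normal((12, 30)), 0.9)
        g = v[:, :m].T @ v[:, :m]
        assert np.max(np.abs(g - np.eye(m))) < 1e-10

    def test_full_reconstruction_identity(self):
        """All components reproduce the centered data (direct SVD oracle)."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal((30, 400))
        mean, v, _, _ = fit_pca(x, 1.0)
        xc = x - mean
        recon = (xc @ v) @ v.T
        assert np.max(np.abs(recon - xc)) < 1e-8

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((4, 4)), 0.0)


class TestLassoPcr:
    def test_huge_penalty_gives_null_model(self, signal_train):
        train, _ = signal_train
        model = fit_lasso_pcr(train, lambda_=1e6)
        assert np.all(model.B_coef == 0.0)
        pred = predict(model, train)
        freqs = np.bincount(train.labels(), minlength=3) / len(train)
        np.testing.assert_allclose(pred.probabilities, np.tile(freqs, (len(train), 1)),
                                   atol=1e-3)

    def test_tiny_penalty_matches_unpenalized_oracle(self):
        """On a separable 2-component problem, lambda ~ 0 reaches the
        training accuracy of an unpenalized multinomial fit."""
        rng = np.random.default_rng(4)
        centers = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 4.0]])
        z = np.vstack([
            centers[k] + 0.3 * rng.standard_normal((10, 2)) for k in range(3)
        ])
        basis, _ = np.linalg.qr(rng.standard_normal((30, 2)))
        x = z @ basis.T
        order = np.argsort(np.tile(np.arange(10), 3), kind="stable")
        x_maps = np.empty_like(x)
        # interleave classes so _set_from_matrix's subject/class layout holds
        for subj in range(10):
            for k in range(3):
                x_maps[subj * 3 + k] = x[k * 10 + subj]
        data = _set_from_matrix(x_maps)
        model = fit_lasso_pcr(data, lambda_=1e-6)
        acc = (predict(model, data).labels == data.labels()).mean()

        oracle = LogisticRegression(C=np.inf, max_iter=2000).fit(z, np.repeat([0, 1, 2], 10))
        oracle_acc = (oracle.predict(z) == np.repeat([0, 1, 2], 10)).mean()
        assert oracle_acc == 1.0
        assert acc == 1.0

    def test_cv_trace_reproducible(self, signal_train):
        train, _ = signal_train
        kw = dict(variance_threshold=0.9, n_folds=5, seed=3, n_lambda=15)
        m1 = fit_lasso_pcr(train, **kw)
        m2 = fit_lasso_pcr(train, **kw)
        np.testing.assert_array_equal(m1.lambda_path, m2.lambda_path)
        np.testing.assert_array_equal(m1.cv_deviance, m2.cv_deviance)
        assert m1.lambda_ == m2.lambda_

    def test_sparsity_monotone_in_lambda(self, signal_train):
        train, _ = signal_train
        lams = np.geomspace(1e-4, 1.0, 6)
        nnz = [fit_lasso_pcr(train, lambda_=l).n_nonzero for l in lams]
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))
        assert nnz[-1] == 0 or nnz[-1] < nnz[0]

    def test_variance_rule_sets_m(self, signal_train):
        train, _ = signal_train
        model = fit_lasso_pcr(train, variance_threshold=0.9, lambda_=0.1)
        cum = np.cumsum(model.explained_variance)
        assert cum[model.m - 1] >= 0.9 - 1e-12
        assert model.m == 1 or cum[model.m - 2] < 0.9

    def test_fold_missing_class_raises(self, cube_mask, rng):
        # only one subject carries the decrease condition
        maps = []
        for j in range(6):
            labels = CLASS_LABELS if j == 0 else CLASS_LABELS[:2]
            for lab in labels:
                maps.append(
                    BetaMap(f"s{j}", lab, "A", rng.standard_normal(64))
                )
        data = BetaMapSet(mask=cube_mask, maps=maps)
        with pytest.raises(StratificationError):
            fit_lasso_pcr(data, n_folds=3, seed=0, n_lambda=5)


class TestSubjectFolds:
    def test_subject_maps_never_split(self, signal_train):
        train, _ = signal_train
        subs = train.subject_ids()
        folds = make_subject_folds(subs, train.labels(), 5, seed=0)
        for tr, val in folds:
            assert set(subs[tr]).isdisjoint(set(subs[val]))

    def test_folds_partition_maps(self, signal_train):
        train, _ = signal_train
        folds = make_subject_folds(train.subject_ids(), train.labels(), 4, 1)
        all_val = np.concatenate([v for _, v in folds])
        assert sorted(all_val) == list(range(len(train)))


class TestLda:
    def test_collinear_class_means_put_separation_on_ld1(self):
        rng = np.random.default_rng(5)
        centers = np.array([[0.0, 0.0], [3.0, 0.0], [6.0, 0.0]])  # collinear
        x2 = np.vstack([
            centers[k] + 0.4 * rng.standard_normal((12, 2)) for k in range(3)
        ])
        x_maps = np.empty((36, 2))
        for subj in range(12):
            for k in range(3):
                x_maps[subj * 3 + k] = x2[k * 12 + subj]
        data = _set_from_matrix(x_maps)
        model = fit_lda(data)
        scores = project(model, data)
        y = data.labels()
        class_means = np.array([scores[y == k].mean(0) for k in range(3)])
        between = class_means.var(axis=0)
        assert between[1] < 0.02 * between[0]

    def test_high_accuracy_on_separated_mixture(self):
        """Well-separated 3-class Gaussian mixture: training accuracy ~ the
        (essentially perfect) Bayes rate."""
        rng = np.random.default_rng(6)
        p, per = 50, 100
        centers = 4.0 * rng.standard_normal((3, p)) / np.sqrt(p)
        x_maps = np.empty((3 * per, p))
        for subj in range(per):
            for k in range(3):
                x_maps[subj * 3 + k] = centers[k] + 0.3 * rng.standard_normal(p)
        data = _set_from_matrix(x_maps)
        model = fit_lda(data)
        acc = (predict(model, data).labels == data.labels()).mean()
        assert acc >= 0.99

    def test_discriminant_subspace_matches_scatter_oracle(self):
        """Low-dimensional full-rank case: the fitted discriminant subspace
        spans the top eigenvectors of S_W^-1 S_B."""
        rng = np.random.default_rng(7)
        p, per = 5, 60
        centers = np.array(
            [[2, 0, 0, 0, 0], [0, 2, 0, 0, 0], [0, 0, 2, 0, 0]], float
        )
        x_maps = np.empty((3 * per, p))
        y = np.empty(3 * per, int)
        for subj in range(per):
            for k in range(3):
                x_maps[subj * 3 + k] = centers[k] + rng.standard_normal(p)
                y[subj * 3 + k] = k
        data = _set_from_matrix(x_maps)
        model = fit_lda(data)

        grand = x_maps.mean(0)
        sw = np.zeros((p, p))
        sb = np.zeros((p, p))
        for k in range(3):
            xk = x_maps[y == k]
            mk = xk.mean(0)
            sw += (xk - mk).T @ (xk - mk)
            sb += len(xk) * np.outer(mk - grand, mk - grand)
        evals, evecs = np.linalg.eig(np.linalg.solve(sw, sb))
        oracle = np.real(evecs[:, np.argsort(-np.real(evals))[:2]])

        # principal angles between the two 2D subspaces are ~ 0
        qa, _ = np.linalg.qr(model.V_lda)
        qb, _ = np.linalg.qr(oracle)
        sv = np.linalg.svd(qa.T @ qb, compute_uv=False)
        assert np.all(sv > 0.999)

    def test_class_with_single_map_rejected(self, cube_mask, rng):
        maps = [
            BetaMap("s1", "neutral", "A", rng.standard_normal(64)),
            BetaMap("s2", "neutral", "A", rng.standard_normal(64)),
            BetaMap("s1", "negative", "A", rng.standard_normal(64)),
            BetaMap("s2", "negative", "A", rng.standard_normal(64)),
            BetaMap("s1", "decrease", "A", rng.standard_normal(64)),
        ]
        with pytest.raises(ValueError, match="at least 2"):
            fit_lda(BetaMapSet(mask=cube_mask, maps=maps))


class TestProjectPredict:
    def test_projection_self_consistency(self, signal_train):
        train, _ = signal_train
        model = fit_lasso_pcr(train, lambda_=0.05)
        scores = project(model, train)
        x = train.values_matrix()
        np.testing.assert_allclose(
            scores, (x - model.train_mean) @ model.V_pca, atol=1e-10
        )

    def test_train_mean_projects_to_zero(self, signal_train):
        train, _ = signal_train
        model = fit_lasso_pcr(train, lambda_=0.05)
        np.testing.assert_allclose(
            project(model, model.train_mean[None, :]), 0.0, atol=1e-10
        )

    def test_voxel_count_mismatch(self, signal_train):
        train, _ = signal_train
        model = fit_lasso_pcr(train, lambda_=0.05)
        with pytest.raises(DimensionError):
            project(model, np.zeros((2, 10)))

    def test_probabilities_sum_to_one(self, signal_train, rng):
        train, _ = signal_train
        model = fit_lda(train)
        x = rng.standard_normal((1000, train.mask.n_voxels))
        p = predict(model, x).probabilities
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-8)
        assert p.min() >= 0.0

    def test_prediction_never_mutates_model(self, signal_train, rng):
        train, _ = signal_train
        model = fit_lda(train)

        def state_hash(m):
            h = hashlib.sha256()
            for arr in (m.train_mean, m.V_lda, m.B_coef, m.intercepts):
                h.update(np.ascontiguousarray(arr).tobytes())
            return h.hexdigest()

        before = state_hash(model)
        predict(model, rng.standard_normal((50, train.mask.n_voxels)))
        project(model, rng.standard_normal((50, train.mask.n_voxels)))
        assert state_hash(model) == before


def test_voxel_weights_shape_and_rank_one_identity(signal_train):
    train, _ = signal_train
    model = fit_lasso_pcr(train, lambda_=0.05)
    w = voxel_weights(model)
    assert w.shape == (train.mask.n_voxels, 3)
    manual = model.V_pca @ model.B_coef
    np.testing.assert_array_equal(w, manual)
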