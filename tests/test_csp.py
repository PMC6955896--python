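"""CSP filters: oracle equivalence, eigenvalue structure, invariances."""

import numpy as np
import pytest
from scipy import linalg

from somabci import FOOT, HAND, TrialSet, fit_csp, transform_csp
from somabci.csp import _class_covariance


def _trialset_from_covs(cov_hand, cov_foot, n_trials=40, n_samples=500, seed=0):
    """Gaussian trials with the given per-class covariances."""
    rng = np.random.default_rng(seed)
    n_ch = cov_hand.shape[0]
    chol = {HAND: np.linalg.cholesky(cov_hand), FOOT: np.linalg.cholesky(cov_foot)}
    labels = np.array([HAND, FOOT] * (n_trials // 2), dtype=object)
    data = np.stack([chol[lab] @ rng.standard_normal((n_ch, n_samples))
                     for lab in labels])
    return TrialSet(data, labels, 100.0, "roi", [f"r{i}" for i in range(n_ch)])


def _random_spd(n, rng):
    a = rng.standard_normal((n, n))
    return a @ a.T + n * np.eye(n)


def _whitening_oracle(c_pos, c_neg):
    """Independent route: whiten the composite, then ordinary eigendecomposition."""
    comp = c_pos + c_neg
    vals, vecs = np.linalg.eigh(comp)
    whitener = vecs @ np.diag(vals ** -0.5) @ vecs.T
    evals, evecs = np.linalg.eigh(whitener @ c_pos @ whitener)
    order = np.argsort(evals)[::-1]
    return evals[order], whitener @ evecs[:, order]


class TestFitCSP:
    def test_no_discrimination_null(self, rng):
        c = _random_spd(4, rng)
        ts = _trialset_from_covs(c, c, n_trials=200, seed=1)
        model = fit_csp(ts, 1)
        assert np.all(np.abs(model.eigenvalues - 0.5) < 0.1)

    def test_separable_axes_toy(self):
        # hand varies only on channel 0, foot only on channel 1
        eps = 1e-9
        cov_h = np.diag([1.0, eps])
        cov_f = np.diag([eps, 1.0])
        ts = _trialset_from_covs(cov_h, cov_f, n_trials=60, seed=2)
        model = fit_csp(ts, 1)
        assert model.eigenvalues[0] > 0.99
        assert model.eigenvalues[-1] < 0.01
        top = np.abs(model.filters[:, 0]) / np.abs(model.filters[:, 0]).max()
        assert top[0] == 1.0 and top[1] < 0.05

    @pytest.mark.parametrize("n_ch", [4, 6, 8])
    def test_matches_whitening_oracle(self, n_ch, rng):
        c_pos, c_neg = _random_spd(n_ch, rng), _random_spd(n_ch, rng)
        # feed covariances through the public API via synthetic long trials
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=4, n_samples=50, seed=3)
        # bypass estimation noise: check the eigen-solution on exact covariances
        w, v = linalg.eigh(c_pos, c_pos + c_neg)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        w_oracle, v_oracle = _whitening_oracle(c_pos, c_neg)
        assert np.allclose(w, w_oracle, atol=1e-8)
        for k in range(n_ch):
            a = v[:, k] / np.linalg.norm(v[:, k])
            b = v_oracle[:, k] / np.linalg.norm(v_oracle[:, k])
            assert min(np.linalg.norm(a - b), np.linalg.norm(a + b)) < 1e-8

    def test_eigenvalue_symmetry_on_swapped_classes(self, rng):
        c_pos, c_neg = _random_spd(5, rng), _random_spd(5, rng)
        w_pos = np.sort(linalg.eigh(c_pos, c_pos + c_neg, eigvals_only=True))
        w_neg = np.sort(linalg.eigh(c_neg, c_pos + c_neg, eigvals_only=True))
        assert np.allclose(np.sort(1.0 - w_neg), w_pos, atol=1e-10)

    def test_filter_variance_identity(self, rng):
        c_pos, c_neg = _random_spd(4, rng), _random_spd(4, rng)
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=30, seed=4)
        model = fit_csp(ts, 2)
        cov = {lab: _class_covariance(ts.data[ts.labels == lab]) for lab in (HAND, FOOT)}
        for k, lam in enumerate(model.eigenvalues):
            w = model.filters[:, k]
            ratio = (w @ cov[HAND] @ w) / (w @ (cov[HAND] + cov[FOOT]) @ w)
            assert ratio == pytest.approx(lam, abs=1e-6)

    def test_mixing_invariance_of_eigenvalues(self, rng):
        c_pos, c_neg = _random_spd(4, rng), _random_spd(4, rng)
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=40, seed=5)
        mixing = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        mixed = TrialSet(np.einsum("ij,tjs->tis", mixing, ts.data), ts.labels,
                         ts.fs, "roi", list(ts.channel_names))
        # exact invariance on the plain covariance path (no per-trial rescaling)
        ev_a = fit_csp(ts, 1, shrinkage=0.0, trace_normalize=False).eigenvalues
        ev_b = fit_csp(mixed, 1, shrinkage=0.0, trace_normalize=False).eigenvalues
        assert np.allclose(ev_a, ev_b, atol=1e-8)
        # trace normalization perturbs the spectrum only mildly
        ev_c = fit_csp(ts, 1).eigenvalues
        ev_d = fit_csp(mixed, 1).eigenvalues
        assert np.allclose(ev_c, ev_d, atol=0.05)

    def test_single_class_rejected(self, rng):
        c = _random_spd(3, rng)
        ts = _trialset_from_covs(c, c, n_trials=10, seed=6)
        ts_single = TrialSet(ts.data, np.array([HAND] * 10, dtype=object), 100.0,
                             "roi", list(ts.channel_names))
        with pytest.raises(ValueError):
            fit_csp(ts_single, 1)

    def test_m_pairs_bounds(self, rng):
        c_pos, c_neg = _random_spd(4, rng), _random_spd(4, rng)
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=20, seed=7)
        with pytest.raises(ValueError):
            fit_csp(ts, 3)  # exceeds floor(4/2)
        with pytest.raises(ValueError):
            fit_csp(ts, 0)


class TestTransformCSP:
    def test_feature_normalization_identity(self, rng):
        c_pos, c_neg = _random_spd(2, rng), _random_spd(2, rng)
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=20, seed=8)
        model = fit_csp(ts, 1)
        feats = transform_csp(model, ts)
        assert feats.shape == (20, 2)
        assert np.allclose(np.exp(feats).sum(axis=1), 1.0)

    def test_duplicated_trial_identical_row(self, rng):
        c_pos, c_neg = _random_spd(4, rng), _random_spd(4, rng)
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=20, seed=9)
        model = fit_csp(ts, 2)
        dup = TrialSet(np.concatenate([ts.data, ts.data[:1]]),
                       np.concatenate([ts.labels, ts.labels[:1]]), 100.0,
                       "roi", list(ts.channel_names))
        feats = transform_csp(model, dup)
        assert np.array_equal(feats[0], feats[-1])

    def test_m_pairs_exceeding_capacity_rejected(self, rng):
        c_pos, c_neg = _random_spd(4, rng), _random_spd(4, rng)
        ts = _trialset_from_covs(c_pos, c_neg, n_trials=20, seed=10)
        model = fit_csp(ts, 1)
        with pytest.raises(ValueError):
            transform_csp(model, ts, m_pairs=3)

    def test_features_finite_with_shrinkage(self, rng):
        # rank-deficient trials (constant channel) still yield finite features
        data = rng.standard_normal((10, 3, 100))
        data[:, 2, :] = 1e-12 * data[:, 0, :]
        labels = np.array([HAND, FOOT] * 5, dtype=object)
        ts = TrialSet(data, labels, 100.0, "roi", ["a", "b", "c"])
        model = fit_csp(ts, 1, shrinkage=1e-6)
        assert np.isfinite(transform_csp(model, ts)).all()
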