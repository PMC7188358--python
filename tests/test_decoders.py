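"""CSP, FBCSP, LDA and MDRM against closed-form and brute-force oracles."""

import numpy as np
import pytest
from scipy.stats import binomtest

from opsalign import geometry as geo
from opsalign.decoders import (
    CSPLDA,
    MDRM,
    csp_features,
    fbcsp_features,
    fit_csp,
    fit_fbcsp,
    fit_lda,
    fit_mdrm,
    histogram_mutual_information,
    predict_lda,
    predict_mdrm,
)
from opsalign.signals import TrialSet, bandpass_filter
from conftest import trialset_with_covariances


def _two_class_gaussian_trials(rng, n_per_class=40, n_s=200, cov0=None, cov1=None, fs=100.0):
    cov0 = np.diag([4.0, 1.0, 1.0]) if cov0 is None else cov0
    cov1 = np.diag([1.0, 1.0, 4.0]) if cov1 is None else cov1
    data, labels = [], []
    for lab, cov in ((0, cov0), (1, cov1)):
        L = np.linalg.cholesky(cov)
        for _ in range(n_per_class):
            E = L @ rng.normal(size=(3, n_s))
            E -= E.mean(axis=1, keepdims=True)
            data.append(E)
            labels.append(lab)
    order = rng.permutation(len(data))
    return TrialSet(
        data=np.stack(data)[order],
        labels=np.array(labels)[order],
        channel_names=("C3", "Cz", "C4"),
        sampling_rate=fs,
    )


class TestCSP:
    def test_diagonal_class_covariances_analytic_eigenvalues(self):
        t0 = trialset_with_covariances(
            [np.diag([4.0, 1.0])] * 4 + [np.diag([1.0, 4.0])] * 4,
            labels=np.array([0] * 4 + [1] * 4),
        )
        model = fit_csp(t0, L=2)
        assert np.allclose(sorted(model.eigenvalues), [0.25, 4.0], atol=1e-9)
        # filters align with coordinate axes up to sign/scale
        for j in range(2):
            w = np.abs(model.W[:, j])
            assert w.max() / w.sum() > 1 - 1e-8

    def test_simultaneous_diagonalization(self, rng):
        trials = _two_class_gaussian_trials(rng)
        model = fit_csp(trials, L=2)
        C1, C2 = [], []
        for E, lab in zip(trials.data, trials.labels):
            (C1 if lab == 0 else C2).append(geo.trial_covariance(E, "trace_normalized"))
        for Ck in (sum(C1), sum(C2)):
            P = model.W.T @ Ck @ model.W
            off = P - np.diag(np.diag(P))
            assert np.max(np.abs(off)) / np.max(np.abs(np.diag(P))) < 1e-8

    def test_full_filter_set_invertible(self, rng):
        trials = _two_class_gaussian_trials(rng)
        model = fit_csp(trials, L=trials.n_channels - 1 + (trials.n_channels - 1) % 2)
        # L = 2 with 3 channels; request full even set explicitly
        model = fit_csp(trials, L=2)
        assert np.linalg.matrix_rank(model.W) == 2

    def test_odd_or_oversized_L_rejected(self, rng):
        trials = _two_class_gaussian_trials(rng)
        with pytest.raises(ValueError, match="even"):
            fit_csp(trials, L=3)
        with pytest.raises(ValueError, match="exceeds"):
            fit_csp(trials, L=4)

    def test_scale_invariance_of_features(self, rng):
        trials = _two_class_gaussian_trials(rng)
        model = fit_csp(trials, L=2)
        f1 = csp_features(model, trials.data[0])
        f2 = csp_features(model, 5.0 * trials.data[0])
        assert np.allclose(f1, f2, atol=1e-12)


class TestCSPFeatures:
    def test_normalization_sums_to_one(self, rng):
        trials = _two_class_gaussian_trials(rng)
        model = fit_csp(trials, L=2)
        f = csp_features(model, trials.data[0])
        assert np.isclose(np.exp(f).sum(), 1.0, atol=1e-10)

    def test_equal_variance_symmetry(self):
        # a trial whose projections have equal variance on both filters
        t0 = trialset_with_covariances(
            [np.diag([4.0, 1.0])] * 4 + [np.diag([1.0, 4.0])] * 4,
            labels=np.array([0] * 4 + [1] * 4),
        )
        model = fit_csp(t0, L=2)
        E = trialset_with_covariances([np.eye(2) * 2.0]).data[0]
        f = csp_features(model, E)
        assert np.allclose(f, np.log(0.5), atol=1e-9)

    def test_matches_brute_force(self, rng):
        trials = _two_class_gaussian_trials(rng)
        model = fit_csp(trials, L=2)
        E = trials.data[3]
        proj = model.W.T @ E
        var = np.array([np.mean((row - row.mean()) ** 2) for row in proj])
        expected = np.log(var / var.sum())
        assert np.allclose(csp_features(model, E), expected, atol=1e-10)


class TestMutualInformation:
    def test_planted_dependence_beats_permuted_labels(self, rng):
        wins = 0
        for rep in range(20):
            r = np.random.default_rng(rep)
            y = r.integers(0, 2, 200)
            x_dep = y + 0.5 * r.normal(size=200)
            x_perm = x_dep[r.permutation(200)]
            if histogram_mutual_information(x_dep, y) > histogram_mutual_information(x_perm, y):
                wins += 1
        assert wins == 20

    def test_independent_feature_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = rng.integers(0, 2, 5000)
        assert histogram_mutual_information(x, y) < 0.01


class TestFBCSP:
    def test_single_band_reduces_to_csp(self, rng):
        trials = _two_class_gaussian_trials(rng, n_s=300)
        model = fit_fbcsp(trials, bands=((8.0, 15.0),), n_select=2, filters_per_band=2)
        banded = bandpass_filter(trials, 8.0, 15.0)
        ref = fit_csp(banded, L=2)
        f_fb = fbcsp_features(model, trials)
        f_ref = np.stack([csp_features(ref, E) for E in banded.data])
        # selected filters span the same 2-filter set -> identical features
        # up to filter ordering
        assert np.allclose(np.sort(f_fb, axis=1), np.sort(f_ref, axis=1), atol=1e-8)

    def test_planted_band_selection(self, rng):
        # class difference lives only in the 8-15 Hz band (a 10.5-14 Hz
        # rhythm, clear of the 4-9 Hz bank edge) over a broadband noise
        # floor: every selected filter must come from that band
        from scipy import signal as sps

        n, n_s, fs = 40, 300, 100.0
        sos_mu = sps.butter(4, [10.5, 14.0], btype="bandpass", fs=fs, output="sos")
        data, labels = [], []
        for lab in (0, 1):
            for _ in range(n):
                mu = sps.sosfiltfilt(sos_mu, rng.normal(size=(3, n_s + 200)))[:, 100:-100]
                gain = np.array([2.0, 1.0, 0.5]) if lab == 0 else np.array([0.5, 1.0, 2.0])
                E = gain[:, None] * mu + 0.5 * rng.normal(size=(3, n_s))
                E -= E.mean(axis=1, keepdims=True)
                data.append(E)
                labels.append(lab)
        trials = TrialSet(
            data=np.stack(data),
            labels=np.array(labels),
            channel_names=("C3", "Cz", "C4"),
            sampling_rate=fs,
        )
        model = fit_fbcsp(trials, bands=((4.0, 9.0), (8.0, 15.0), (15.0, 30.0)), n_select=2)
        mu_band_idx = 1
        assert all(bi == mu_band_idx for bi, _ in model.selected)

    def test_band_outside_nyquist_rejected(self, rng):
        trials = _two_class_gaussian_trials(rng, fs=50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            fit_fbcsp(trials, bands=((8.0, 15.0), (15.0, 30.0)))


class TestLDA:
    def test_separated_clouds_perfect_training_accuracy(self, rng):
        x = np.concatenate([rng.normal(-5, 1, 100), rng.normal(5, 1, 100)])[:, None]
        y = np.repeat([0, 1], 100)
        model = fit_lda(x, y)
        assert np.mean(predict_lda(model, x) == y) == 1.0

    def test_mirrored_clouds_threshold_at_zero(self, rng):
        x0 = rng.normal(3, 1, 2000)
        x = np.concatenate([-x0, x0])[:, None]
        y = np.repeat([0, 1], 2000)
        model = fit_lda(x, y)
        # decision threshold -bias/weight must sit at the symmetry point
        assert abs(model.bias / model.weights[0]) < 0.05

    def test_matches_pooled_covariance_closed_form(self, rng):
        mu0, mu1 = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        cov = np.array([[2.0, 0.3], [0.3, 1.0]])
        L = np.linalg.cholesky(cov)
        x0 = rng.normal(size=(4000, 2)) @ L.T + mu0
        x1 = rng.normal(size=(4000, 2)) @ L.T + mu1
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], 4000)
        model = fit_lda(x, y)
        m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
        pooled = 0.5 * (np.cov(x0.T) + np.cov(x1.T))
        w_ref = np.linalg.solve(pooled, m1 - m0)
        cos = np.dot(model.weights, w_ref) / (
            np.linalg.norm(model.weights) * np.linalg.norm(w_ref)
        )
        assert cos > 1 - 1e-8


class TestMDRM:
    def test_constant_class_covariance_recovered(self):
        C0, C1 = np.diag([3.0, 1.0, 1.0]), np.diag([1.0, 1.0, 3.0])
        trials = trialset_with_covariances(
            [C0] * 4 + [C1] * 4, labels=np.array([0] * 4 + [1] * 4)
        )
        model = fit_mdrm(trials)
        assert np.allclose(model.centers[0], C0, atol=1e-8)
        assert np.allclose(model.centers[1], C1, atol=1e-8)

    def test_diagonal_pairs_give_geometric_mean_center(self):
        trials = trialset_with_covariances(
            [np.diag([1.0, 1.0, 1.0]), np.diag([4.0, 1.0, 1.0]),
             np.diag([2.0, 2.0, 2.0]), np.diag([2.0, 8.0, 2.0])],
            labels=np.array([0, 0, 1, 1]),
        )
        model = fit_mdrm(trials)
        assert np.allclose(model.centers[0], np.diag([2.0, 1.0, 1.0]), atol=1e-9)
        assert np.allclose(model.centers[1], np.diag([2.0, 4.0, 2.0]), atol=1e-9)

    def test_centers_match_direct_riemannian_mean(self, rng):
        trials = _two_class_gaussian_trials(rng, n_per_class=10)
        model = fit_mdrm(trials)
        for k in (0, 1):
            covs = [geo.trial_covariance(E) for E in trials.data[trials.labels == k]]
            assert np.allclose(model.centers[k], geo.riemannian_mean(covs), atol=1e-8)

    def test_class_center_classified_to_its_class(self, rng):
        trials = _two_class_gaussian_trials(rng, n_per_class=10)
        model = fit_mdrm(trials)
        for k in (0, 1):
            label, dists = predict_mdrm(model, model.centers[k])
            assert label == k
            assert dists[k] < 1e-10

    def test_equidistant_tie_goes_to_lowest_class(self):
        trials = trialset_with_covariances(
            [np.diag([4.0, 1.0, 1.0])] * 2 + [np.diag([0.25, 1.0, 1.0])] * 2,
            labels=np.array([0, 0, 1, 1]),
        )
        model = fit_mdrm(trials)
        label, dists = predict_mdrm(model, np.eye(3))
        assert np.isclose(dists[0], dists[1], atol=1e-9)
        assert label == 0

    def test_congruence_invariance_of_prediction(self, rng):
        trials = _two_class_gaussian_trials(rng, n_per_class=10)
        model = fit_mdrm(trials)
        W = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        from opsalign.decoders import MDRMModel

        C_test = geo.trial_covariance(trials.data[0])
        congruent = MDRMModel(
            centers=tuple(W @ C @ W.T for C in model.centers),
            class_labels=model.class_labels,
        )
        l1, _ = predict_mdrm(model, C_test)
        l2, _ = predict_mdrm(congruent, W @ C_test @ W.T)
        assert l1 == l2

    def test_above_chance_on_separated_synthetic_classes(self, rng):
        # true centers differ by delta_R >= 1.0; held-out accuracy must beat
        # chance at binomial p < 0.01
        cov0, cov1 = np.diag([2.0, 1.0, 1.0]), np.diag([0.7, 1.0, 1.5])
        assert geo.riemannian_distance(cov0, cov1) >= 1.0
        train = _two_class_gaussian_trials(rng, n_per_class=50, cov0=cov0, cov1=cov1)
        test = _two_class_gaussian_trials(rng, n_per_class=100, cov0=cov0, cov1=cov1)
        est = MDRM().fit(train)
        correct = int(np.sum(est.predict(test) == test.labels))
        assert binomtest(correct, test.n_trials, 0.5, alternative="greater").pvalue < 0.01

    def test_empty_class_rejected(self, rng):
        trials = _two_class_gaussian_trials(rng, n_per_class=5)
        only0 = trials.subset(np.flatnonzero(trials.labels == 0))
        model = fit_mdrm(only0)  # single-class fit is fine structurally
        assert len(model.centers) == 1


class TestPipelines:
    def test_csp_lda_pipeline_scale_invariant(self, rng):
        trials = _two_class_gaussian_trials(rng)
        est = CSPLDA().fit(trials)
        p1 = est.predict(trials)
        scaled = TrialSet(
            data=3.7 * trials.data,
            labels=trials.labels,
            channel_names=trials.channel_names,
            sampling_rate=trials.sampling_rate,
        )
        p2 = est.predict(scaled)
        assert np.array_equal(p1, p2)
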