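import numpy as np
import pytest

from opsalign.signals import TrialSet


def random_spd(rng: np.random.Generator, n: int = 3, scale: float = 1.0) -> np.ndarray:
    """Well-conditioned random SPD matrix."""
    X = rng.normal(size=(n, n))
    return scale * (X @ X.T + n * 0.2 * np.eye(n))


def trialset_with_covariances(covs, n_samples: int = 64, labels=None, rng=None) -> TrialSet:
    """TrialSet whose i-th trial has plain covariance exactly covs[i].

    Built from an orthonormal time basis: E = sqrt(N_s) * C^{1/2} Q with Q
    rows orthonormal and zero-mean, so E E^T / N_s = C and rows are zero-mean.
    """
    covs = [np.asarray(C, dtype=float) for C in covs]
    n_c = covs[0].shape[0]
    # zero-mean orthonormal rows from a DFT-like basis
    t = np.arange(n_samples)
    basis = np.stack(
        [np.cos(2 * np.pi * (k + 1) * t / n_samples) for k in range(n_c)]
    )
    basis -= basis.mean(axis=1, keepdims=True)
    basis /= np.linalg.norm(basis, axis=1, keepdims=True)
    trials = []
    for C in covs:
        w, U = np.linalg.eigh(C)
        sqrtC = (U * np.sqrt(w)) @ U.T
        trials.append(np.sqrt(n_samples) * sqrtC @ basis)
    if labels is None:
        labels = np.zeros(len(covs), dtype=int)
        labels[len(covs) // 2 :] = 1
    return TrialSet(
        data=np.stack(trials),
        labels=labels,
        channel_names=tuple(f"ch{i}" for i in range(n_c)),
        sampling_rate=float(n_samples),
    )


def sinusoid_trialset(freq: float, fs: float, duration: float = 3.0, n_channels: int = 3) -> TrialSet:
    t = np.arange(int(duration * fs)) / fs
    wave = np.sin(2 * np.pi * freq * t)
    data = np.tile(wave, (1, n_channels, 1))
    return TrialSet(
        data=data,
        labels=np.array([0]),
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
        sampling_rate=fs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
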