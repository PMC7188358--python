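"""Reference decoders: CSP + LDA, FBCSP + LDA, and MDRM.

CSP finds spatial filters w maximizing the variance ratio
w^T C1_bar w / w^T C2_bar w between the two class covariances (the
generalized eigenproblem C1_bar w = lambda C2_bar w); trials are summarized
by log normalized variances of the filtered time series.  FBCSP runs CSP per
frequency band and keeps the filters whose log-variance feature carries the
most mutual information about the label.  MDRM classifies a trial covariance
to the nearest per-class Riemannian center.

All fit functions consume a :class:`~opsalign.signals.TrialSet` with exactly
two classes; thin estimator classes (`CSPLDA`, `FBCSPLDA`, `MDRM`) wrap the
functions with a common fit/predict surface for the experiment harness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import geometry as geo
from .signals import TrialSet, bandpass_filter

__all__ = [
    "SpatialFilterModel",
    "fit_csp",
    "csp_features",
    "FBCSPModel",
    "fit_fbcsp",
    "fbcsp_features",
    "histogram_mutual_information",
    "LDAModel",
    "fit_lda",
    "predict_lda",
    "MDRMModel",
    "fit_mdrm",
    "predict_mdrm",
    "CSPLDA",
    "FBCSPLDA",
    "MDRM",
]


# --------------------------------------------------------------------------
# CSP
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpatialFilterModel:
    """CSP projection W (n_channels x L) with its generalized eigenvalues."""

    W: np.ndarray
    eigenvalues: np.ndarray
    band: tuple | None = None

    @property
    def L(self) -> int:
        return self.W.shape[1]


def _class_covariances(trials: TrialSet) -> tuple:
    classes = np.unique(trials.labels)
    if len(classes) != 2:
        raise ValueError(f"CSP requires exactly two classes, found {classes.tolist()}")
    covs = []
    for c in classes:
        Es = trials.data[trials.labels == c]
        covs.append(sum(geo.trial_covariance(E, mode="trace_normalized") for E in Es))
    return covs[0], covs[1]


def fit_csp(trials: TrialSet, L: int = 2, band: tuple | None = None) -> SpatialFilterModel:
    """Fit CSP filters on a two-class TrialSet.

    Solves C1_bar w = lambda C2_bar w and keeps the eigenvectors of the L/2
    largest and L/2 smallest eigenvalues.  Each filter is scaled so
    w^T (C1_bar + C2_bar) w = 1 and its largest-magnitude entry is positive
    (the eigenproblem fixes filters only up to sign and scale).
    """
    if L % 2 or L < 2:
        raise ValueError(f"filter count L must be even and >= 2, got {L}")
    if L > trials.n_channels:
        raise ValueError(f"L={L} exceeds the channel count {trials.n_channels}")
    C1, C2 = _class_covariances(trials)
    comp = C1 + C2
    if np.linalg.eigvalsh(comp)[0] <= 1e-12 * np.trace(comp) / comp.shape[0]:
        raise np.linalg.LinAlgError(
            "composite class covariance is singular; consider the covariance ridge"
        )
    lam, V = eigh(C1, C2)  # ascending
    lam, V = lam[::-1], V[:, ::-1]  # descending
    keep = list(range(L // 2)) + list(range(len(lam) - L // 2, len(lam)))
    W = V[:, keep]
    lam_keep = lam[keep]
    # normalize scale and sign
    for j in range(W.shape[1]):
        w = W[:, j]
        w = w / np.sqrt(w @ comp @ w)
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        W[:, j] = w
    return SpatialFilterModel(W=W, eigenvalues=lam_keep, band=band)


def csp_features(model: SpatialFilterModel, E: np.ndarray) -> np.ndarray:
    """Log normalized variance features f_j = log(var_j / sum_j var_j)."""
    E = np.asarray(E, dtype=float)
    if E.shape[0] != model.W.shape[0]:
        raise ValueError(f"trial has {E.shape[0]} channels, filters expect {model.W.shape[0]}")
    proj = model.W.T @ E
    var = proj.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero total variance after projection")
    return np.log(var / total)


def _feature_matrix(model: SpatialFilterModel, trials: TrialSet) -> np.ndarray:
    return np.stack([csp_features(model, E) for E in trials.data])


# --------------------------------------------------------------------------
# FBCSP
# --------------------------------------------------------------------------

def histogram_mutual_information(x: np.ndarray, y: np.ndarray, n_bins: int = 10) -> float:
    """Mutual information (nats) between a scalar feature and a binary label.

    The feature is discretized into ``n_bins`` equal-frequency bins; MI is
    the plug-in estimate on the resulting contingency table.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)
    mi = 0.0
    n = len(x)
    for b in np.unique(bins):
        for c in np.unique(y):
            p_xy = np.sum((bins == b) & (y == c)) / n
            if p_xy == 0:
                continue
            p_x = np.sum(bins == b) / n
            p_y = np.sum(y == c) / n
            mi += p_xy * np.log(p_xy / (p_x * p_y))
    return float(max(mi, 0.0))


@dataclass(frozen=True)
class FBCSPModel:
    """Per-band CSP models plus the mutual-information-selected filter subset.

    ``selected`` holds (band_index, filter_column) pairs ordered by
    decreasing MI score; features are the Eq-style log normalized variances
    computed jointly over the selected filters.
    """

    bands: tuple
    band_models: tuple
    selected: tuple
    mi_scores: np.ndarray
    filter_order: int = 4


def _band_variances(model: SpatialFilterModel, banded: TrialSet) -> np.ndarray:
    return np.stack([(model.W.T @ E).var(axis=1) for E in banded.data])


def fit_fbcsp(
    trials: TrialSet,
    bands=((4.0, 9.0), (8.0, 15.0), (15.0, 30.0)),
    n_select: int = 4,
    filters_per_band: int = 4,
) -> FBCSPModel:
    """Fit FBCSP: per-band CSP candidates, then MI-based filter selection.

    Each band contributes ``filters_per_band`` CSP filters; the scalar
    log-variance of each candidate filter on the training trials is scored
    by histogram mutual information with the label, and the ``n_select``
    best filters (across bands) are kept.
    """
    if len(bands) < 1:
        raise ValueError("need at least one band")
    nyq = trials.sampling_rate / 2
    for low, high in bands:
        if not 0 < low < high < nyq:
            raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist={nyq})")
    band_models, variances = [], []
    for band in bands:
        banded = bandpass_filter(trials, band[0], band[1])
        m = fit_csp(banded, L=min(filters_per_band, trials.n_channels - trials.n_channels % 2), band=tuple(band))
        band_models.append(m)
        variances.append(_band_variances(m, banded))
    candidates = [(bi, j) for bi, m in enumerate(band_models) for j in range(m.L)]
    if n_select > len(candidates):
        raise ValueError(f"n_select={n_select} exceeds {len(candidates)} candidate filters")
    scores = np.array(
        [
            histogram_mutual_information(np.log(variances[bi][:, j]), trials.labels)
            for bi, j in candidates
        ]
    )
    order = np.argsort(-scores, kind="stable")[:n_select]
    return FBCSPModel(
        bands=tuple(tuple(b) for b in bands),
        band_models=tuple(band_models),
        selected=tuple(candidates[i] for i in order),
        mi_scores=scores,
    )


def fbcsp_features(model: FBCSPModel, trials: TrialSet) -> np.ndarray:
    """Joint log normalized variance features over the selected filters."""
    per_band = {}
    for bi in {bi for bi, _ in model.selected}:
        low, high = model.bands[bi]
        banded = bandpass_filter(trials, low, high, order=model.filter_order)
        per_band[bi] = _band_variances(model.band_models[bi], banded)
    var = np.stack([per_band[bi][:, j] for bi, j in model.selected], axis=1)
    return np.log(var / var.sum(axis=1, keepdims=True))


# --------------------------------------------------------------------------
# LDA
# --------------------------------------------------------------------------

@dataclass
class LDAModel:
    """Two-class LDA with pooled covariance; ties broken toward class 0."""

    weights: np.ndarray
    bias: float
    class_labels: np.ndarray
    _impl: LinearDiscriminantAnalysis = field(repr=False, default=None)


def fit_lda(features: np.ndarray, labels: np.ndarray) -> LDAModel:
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels, dtype=int)
    impl = LinearDiscriminantAnalysis(solver="lsqr")
    impl.fit(features, labels)
    return LDAModel(
        weights=impl.coef_.ravel().copy(),
        bias=float(impl.intercept_[0]),
        class_labels=impl.classes_.copy(),
        _impl=impl,
    )


def predict_lda(model: LDAModel, features: np.ndarray) -> np.ndarray:
    features = np.atleast_2d(np.asarray(features, dtype=float))
    score = features @ model.weights + model.bias
    # score > 0 -> second class; exact ties fall to the lower class index
    return np.where(score > 0, model.class_labels[1], model.class_labels[0])


# --------------------------------------------------------------------------
# MDRM
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MDRMModel:
    centers: tuple
    class_labels: np.ndarray


def fit_mdrm(trials: TrialSet) -> MDRMModel:
    """Per-class Riemannian centers of plain trial covariances."""
    classes = np.unique(trials.labels)
    centers = []
    for c in classes:
        Es = trials.data[trials.labels == c]
        if len(Es) == 0:
            raise ValueError(f"class {c} has no trials")
        centers.append(geo.riemannian_mean([geo.trial_covariance(E) for E in Es]))
    return MDRMModel(centers=tuple(centers), class_labels=classes)


def predict_mdrm(model: MDRMModel, C_test: np.ndarray):
    """Nearest-center label under delta_R; returns (label, distances).

    Exact ties resolve to the lowest class index.
    """
    dists = np.array([geo.riemannian_distance(Ck, C_test) for Ck in model.centers])
    return int(model.class_labels[int(np.argmin(dists))]), dists


# --------------------------------------------------------------------------
# estimator wrappers for the experiment harness
# --------------------------------------------------------------------------

class CSPLDA:
    """CSP spatial filtering followed by LDA on log-variance features."""

    name = "CSP"

    def __init__(self, L: int = 2):
        self.L = L

    def fit(self, trials: TrialSet, valid: TrialSet | None = None, seed: int = 0):
        self.csp_ = fit_csp(trials, L=self.L)
        self.lda_ = fit_lda(_feature_matrix(self.csp_, trials), trials.labels)
        return self

    def predict(self, trials: TrialSet) -> np.ndarray:
        return predict_lda(self.lda_, _feature_matrix(self.csp_, trials))


class FBCSPLDA:
    """Filter-bank CSP with MI filter selection, followed by LDA."""

    name = "FBCSP"

    def __init__(self, bands=((4.0, 9.0), (8.0, 15.0), (15.0, 30.0)), n_select: int = 4):
        self.bands = bands
        self.n_select = n_select

    def fit(self, trials: TrialSet, valid: TrialSet | None = None, seed: int = 0):
        self.fbcsp_ = fit_fbcsp(trials, bands=self.bands, n_select=self.n_select)
        self.lda_ = fit_lda(fbcsp_features(self.fbcsp_, trials), trials.labels)
        return self

    def predict(self, trials: TrialSet) -> np.ndarray:
        return predict_lda(self.lda_, fbcsp_features(self.fbcsp_, trials))


class MDRM:
    """Minimum distance to Riemannian mean."""

    name = "MDRM"

    def __init__(self):
        pass

    def fit(self, trials: TrialSet, valid: TrialSet | None = None, seed: int = 0):
        self.model_ = fit_mdrm(trials)
        return self

    def predict(self, trials: TrialSet) -> np.ndarray:
        return np.array(
            [predict_mdrm(self.model_, geo.trial_covariance(E))[0] for E in trials.data]
        )
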