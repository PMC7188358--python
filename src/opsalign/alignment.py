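"""Riemannian re-centering of EEG trials: batch (PS) and online (OPS).

Re-centering whitens each subject's trials by the inverse square root of the
Riemannian center M of their trial covariances, so that after alignment the
covariance distribution of every subject is centered at the identity:

    C_hat = M^{-1/2} C M^{-1/2},     E_hat = (1/sqrt(N_s)) M^{-1/2} E.

The batch variant (pre-alignment strategy, PS) fits M on a subject's
training trials.  The online variant (OPS) maintains a running inductive
mean: on trial i+1 the mean moves along the geodesic toward the incoming
covariance by step 1/(i+1), and the SAME trial is then aligned with the
updated mean — no calibration data and no labels are ever needed.

Re-centering removes exactly the invertible linear mixing and gain factors
that differ between recording setups, which is why it restores transfer
across datasets: if every trial of a subject is transformed E -> A E, the
center becomes A M A^T and the aligned covariances change only by an
orthogonal congruence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import geometry as geo
from .signals import TrialSet

__all__ = [
    "AlignmentState",
    "fit_recenter",
    "apply_recenter",
    "ops_stream",
    "recenter_trialset",
    "aligned_covariance",
]


def aligned_covariance(E_hat: np.ndarray) -> np.ndarray:
    """Covariance of an aligned trial: the Gram matrix E_hat E_hat^T.

    The 1/sqrt(N_s) factor of the alignment transform already carries the
    per-sample normalization, so E_hat E_hat^T equals
    M^{-1/2} (E E^T / N_s) M^{-1/2} — no further division by N_s.
    """
    E_hat = np.asarray(E_hat, dtype=float)
    return E_hat @ E_hat.T


@dataclass
class AlignmentState:
    """Running Riemannian center of one subject's trial covariances.

    ``M`` is the center estimate after ``n_seen`` trials; it is undefined
    (None) until the first trial has been absorbed.
    """

    M: np.ndarray | None = None
    n_seen: int = 0
    subject_id: str | None = None

    def __post_init__(self):
        if (self.M is None) != (self.n_seen == 0):
            raise ValueError("M must be defined exactly when n_seen >= 1")
        if self.n_seen < 0:
            raise ValueError("n_seen must be nonnegative")
        if self.M is not None:
            self.M = geo.validate_spd(self.M, "M")

    # -- streaming interface: one trial at a time, labels never seen --------
    def update(self, E: np.ndarray) -> np.ndarray:
        """Absorb one trial into the running mean, then align that trial.

        The incoming trial's covariance updates the mean BEFORE the trial is
        aligned, so the first trial whitens itself exactly.
        Returns the aligned time series E_hat.
        """
        C = geo.trial_covariance(E, mode="plain")
        if self.n_seen == 0:
            self.M = C
        else:
            self.M = geo.recursive_mean_update(self.M, C, self.n_seen)
        self.n_seen += 1
        return _whiten(self.M, E)

    def align(self, E: np.ndarray) -> np.ndarray:
        """Align a trial with the current mean without updating it."""
        if self.M is None:
            raise ValueError("alignment state is unfitted (no trials seen)")
        return _whiten(self.M, E)

    def save(self, path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "M.npy", self.M if self.M is not None else np.empty((0, 0)))
        (path / "state.json").write_text(
            json.dumps({"n_seen": self.n_seen, "subject_id": self.subject_id})
        )
        return path

    @classmethod
    def load(cls, path) -> "AlignmentState":
        path = Path(path)
        meta = json.loads((path / "state.json").read_text())
        M = np.load(path / "M.npy")
        return cls(M=M if M.size else None, n_seen=meta["n_seen"], subject_id=meta["subject_id"])


def _whiten(M: np.ndarray, E: np.ndarray) -> np.ndarray:
    n_s = E.shape[1]
    return geo.matrix_power(M, -0.5) @ E / np.sqrt(n_s)


def fit_recenter(trials: TrialSet, *, allow_mixed_subjects: bool = False) -> AlignmentState:
    """Batch pre-alignment: M = Riemannian mean of all trial covariances.

    The state is scoped to one subject; fitting across subjects collapses
    distinct centers and must be requested explicitly.
    """
    if trials.n_trials < 1:
        raise ValueError("cannot fit re-centering on an empty TrialSet")
    if not allow_mixed_subjects and "+" in trials.subject_id:
        raise ValueError(
            f"TrialSet {trials.subject_id!r} pools several subjects; "
            "pass allow_mixed_subjects=True to re-center jointly"
        )
    covs = [geo.trial_covariance(E, mode="plain") for E in trials.data]
    M = geo.riemannian_mean(covs)
    return AlignmentState(M=M, n_seen=trials.n_trials, subject_id=trials.subject_id)


def apply_recenter(state: AlignmentState, E: np.ndarray) -> np.ndarray:
    """Align one trial with a fitted state: E_hat = (1/sqrt(N_s)) M^{-1/2} E."""
    return state.align(np.asarray(E, dtype=float))


def recenter_trialset(state: AlignmentState, trials: TrialSet) -> TrialSet:
    """Align every trial of a TrialSet with one fitted state (batch PS path)."""
    aligned = np.stack([state.align(E) for E in trials.data])
    return replace(trials, data=aligned)


def ops_stream(trials: TrialSet):
    """Online pre-alignment of a subject's trial stream.

    Trials are consumed in acquisition order (``trial_order``); each trial
    updates the running inductive mean and is aligned with the updated mean.
    Returns the aligned TrialSet (in acquisition order) and the final
    :class:`AlignmentState`.
    """
    if trials.n_trials == 0:
        raise ValueError("cannot stream an empty TrialSet")
    ordered = trials.in_acquisition_order()
    state = AlignmentState(subject_id=trials.subject_id)
    aligned = np.stack([state.update(E) for E in ordered.data])
    return replace(ordered, data=aligned), state
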