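"""Epoched-EEG containers, preprocessing chain and fold construction.

The unit every stage consumes is a :class:`TrialSet`: a stack of equally
shaped trials (channels x samples) with class labels and acquisition
metadata.  Preprocessing follows the standard motor-imagery chain: zero-phase
Butterworth band-pass, downsampling, sensorimotor channel selection.  After
filtering, each channel is explicitly re-centered to mean zero — every
covariance-based stage downstream assumes zero-mean channels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

__all__ = [
    "TrialSet",
    "SplitPlan",
    "bandpass_filter",
    "resample",
    "select_channels",
    "make_folds",
    "write_bundle",
    "read_bundle",
]

#: admitted per-channel mean after preprocessing, relative to channel std
ZERO_MEAN_RTOL = 1e-8


@dataclass(frozen=True)
class TrialSet:
    """Labeled epoched EEG trials with channel and acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Trial matrices in microvolts.
    labels : ndarray of int, shape (n_trials,)
        Class index per trial; exactly the declared two-class set may occur.
    channel_names : tuple of str
    sampling_rate : float, Hz
    subject_id, dataset_id : str
    trial_order : ndarray of int
        Acquisition index per trial — a permutation of 0..n_trials-1 used to
        replay the stream in online alignment.
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: tuple
    sampling_rate: float
    subject_id: str = "S0"
    dataset_id: str = "D0"
    trial_order: np.ndarray = None  # type: ignore[assignment]
    class_names: tuple = ("left", "right")

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        if data.ndim != 3:
            raise ValueError(f"data must be (n_trials, n_channels, n_samples), got {data.shape}")
        if labels.shape != (data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if len(self.channel_names) != data.shape[1]:
            raise ValueError("channel_names length must match the channel dimension")
        if not np.all(np.isfinite(data)):
            raise ValueError("trial data contains non-finite samples")
        bad = set(np.unique(labels)) - set(range(len(self.class_names)))
        if bad:
            raise ValueError(f"labels outside the declared class set: {sorted(bad)}")
        order = self.trial_order
        if order is None:
            order = np.arange(data.shape[0])
        else:
            order = np.asarray(order, dtype=int)
            if sorted(order.tolist()) != list(range(data.shape[0])):
                raise ValueError("trial_order must be a permutation of 0..n_trials-1")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "trial_order", order)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "TrialSet":
        """Sub-TrialSet at the given trial indices (acquisition ranks re-derived)."""
        idx = np.asarray(idx, dtype=int)
        # keep relative acquisition order: rank the retained order values
        order = np.argsort(np.argsort(self.trial_order[idx]))
        return replace(self, data=self.data[idx], labels=self.labels[idx], trial_order=order)

    def in_acquisition_order(self) -> "TrialSet":
        """Trials re-sorted so index order equals acquisition order."""
        idx = np.argsort(self.trial_order)
        return replace(
            self,
            data=self.data[idx],
            labels=self.labels[idx],
            trial_order=np.arange(self.n_trials),
        )


@dataclass(frozen=True)
class SplitPlan:
    """One train/validation/test split of a subject's trials."""

    fold_id: int
    train_idx: np.ndarray
    valid_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        for name in ("train_idx", "valid_idx", "test_idx"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=int))
        parts = [self.train_idx, self.valid_idx, self.test_idx]
        allidx = np.concatenate(parts)
        if len(set(allidx.tolist())) != len(allidx):
            raise ValueError("split partitions overlap")


def _demean(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=-1, keepdims=True)


def bandpass_filter(trials: TrialSet, low: float, high: float, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass of every trial.

    The filter is designed at ``order`` (the effective order doubles through
    forward-and-reverse application, cancelling phase distortion) and applied
    with ``filtfilt``.  Channels are re-centered to exact zero mean after
    filtering.
    """
    nyq = trials.sampling_rate / 2.0
    if not (0.0 < low < high < nyq):
        raise ValueError(
            f"band edges ({low}, {high}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    if order <= 0 or order % 2:
        raise ValueError(f"filter order must be positive and even, got {order}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=trials.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, trials.data, axis=-1)
    return replace(trials, data=_demean(filtered))


def resample(trials: TrialSet, target_rate: float) -> TrialSet:
    """Polyphase resampling of every trial to ``target_rate``.

    The resulting trial length must be integral; 3 s at any rate maps to
    3 * target_rate samples.
    """
    fs = trials.sampling_rate
    if target_rate > fs:
        raise ValueError(f"target rate {target_rate} exceeds current rate {fs}")
    if target_rate == fs:
        return trials
    from fractions import Fraction

    frac = Fraction(target_rate / fs).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    n_new = trials.n_samples * target_rate / fs
    if abs(n_new - round(n_new)) > 1e-9:
        raise ValueError(
            f"resampling {trials.n_samples} samples from {fs} to {target_rate} Hz "
            f"gives non-integer length {n_new}"
        )
    data = sps.resample_poly(trials.data, up, down, axis=-1)
    return replace(trials, data=_demean(data), sampling_rate=float(target_rate))


def select_channels(trials: TrialSet, names) -> TrialSet:
    """Reduce and reorder the channel dimension to ``names`` (case-insensitive)."""
    lookup = {n.lower(): i for i, n in enumerate(trials.channel_names)}
    idx = []
    for name in names:
        key = name.lower()
        if key not in lookup:
            raise KeyError(
                f"channel {name!r} not present; available: {list(trials.channel_names)}"
            )
        idx.append(lookup[key])
    idx = np.asarray(idx, dtype=int)
    return replace(
        trials,
        data=trials.data[:, idx, :],
        channel_names=tuple(trials.channel_names[i] for i in idx),
    )


def _partition_sizes(n: int) -> tuple:
    """80/10/10 sizes over the whole set: train = floor(0.8 n); the remainder
    is split as evenly as possible with validation taking the odd extra."""
    n_train = int(np.floor(0.8 * n))
    rest = n - n_train
    n_test = rest // 2
    n_valid = rest - n_test
    return n_train, n_valid, n_test


def _largest_remainder(total: int, counts: np.ndarray) -> np.ndarray:
    """Split ``total`` slots across classes proportionally to ``counts``."""
    target = total * counts / counts.sum()
    alloc = np.floor(target).astype(int)
    short = total - alloc.sum()
    order = np.argsort(-(target - alloc), kind="stable")
    alloc[order[:short]] += 1
    return alloc


def make_folds(trials: TrialSet, n_folds: int = 10, seed: int | None = None):
    """Stratified random 80/10/10 splits, repeated ``n_folds`` times.

    Partition sizes follow the whole-set rounding rule of
    :func:`_partition_sizes`; within each partition, class quotas are set by
    largest remainder so the class ratio stays within one trial of the
    overall ratio.  Fold ``f`` is seeded with ``seed + f`` (default base 0,
    so fold f simply uses seed f) and folds are independent shuffles.
    """
    base = 0 if seed is None else int(seed)
    classes = np.unique(trials.labels)
    counts = np.array([int(np.sum(trials.labels == c)) for c in classes])
    n_train, n_valid, n_test = _partition_sizes(trials.n_trials)
    tr_quota = _largest_remainder(n_train, counts)
    va_quota = _largest_remainder(n_valid, counts)
    te_quota = counts - tr_quota - va_quota
    if np.any(tr_quota < 1) or np.any(va_quota < 1) or np.any(te_quota < 1):
        raise ValueError(
            f"too few trials per class {dict(zip(classes.tolist(), counts.tolist()))} "
            "to fill every partition"
        )
    plans = []
    for f in range(n_folds):
        rng = np.random.default_rng(base + f)
        tr, va, te = [], [], []
        for c, t_c, v_c in zip(classes, tr_quota, va_quota):
            idx = rng.permutation(np.flatnonzero(trials.labels == c))
            tr.append(idx[:t_c])
            va.append(idx[t_c : t_c + v_c])
            te.append(idx[t_c + v_c :])
        plans.append(
            SplitPlan(
                fold_id=f,
                train_idx=np.sort(np.concatenate(tr)),
                valid_idx=np.sort(np.concatenate(va)),
                test_idx=np.sort(np.concatenate(te)),
                seed=base + f,
            )
        )
    return plans


def concat_trialsets(sets, subject_id: str | None = None) -> TrialSet:
    """Pool several TrialSets (same channels/rate) into one.

    The pooled subject_id joins the sources with '+', marking the set as
    multi-subject for alignment scoping.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("nothing to concatenate")
    first = sets[0]
    for t in sets[1:]:
        if t.channel_names != first.channel_names or t.sampling_rate != first.sampling_rate:
            raise ValueError("TrialSets disagree on channels or sampling rate")
        if t.n_samples != first.n_samples:
            raise ValueError("TrialSets disagree on trial length")
    offsets = np.cumsum([0] + [t.n_trials for t in sets[:-1]])
    return TrialSet(
        data=np.concatenate([t.data for t in sets]),
        labels=np.concatenate([t.labels for t in sets]),
        channel_names=first.channel_names,
        sampling_rate=first.sampling_rate,
        subject_id=subject_id or "+".join(t.subject_id for t in sets),
        dataset_id=first.dataset_id if all(t.dataset_id == first.dataset_id for t in sets) else "mixed",
        trial_order=np.concatenate([t.trial_order + off for t, off in zip(sets, offsets)]),
        class_names=first.class_names,
    )


def split_train_valid(trials: TrialSet, valid_fraction: float = 0.1, seed: int = 0):
    """Stratified random train/validation split (for model selection)."""
    rng = np.random.default_rng(seed)
    classes = np.unique(trials.labels)
    counts = np.array([int(np.sum(trials.labels == c)) for c in classes])
    n_valid = max(len(classes), int(round(valid_fraction * trials.n_trials)))
    quota = _largest_remainder(n_valid, counts)
    va, tr = [], []
    for c, q in zip(classes, quota):
        idx = rng.permutation(np.flatnonzero(trials.labels == c))
        va.append(idx[:q])
        tr.append(idx[q:])
    return trials.subset(np.sort(np.concatenate(tr))), trials.subset(np.sort(np.concatenate(va)))


def write_bundle(trials: TrialSet, path) -> Path:
    """Write an epochs bundle: data.npy + labels.npy + meta.json in a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / "data.npy", trials.data)
    np.save(path / "labels.npy", trials.labels)
    meta = {
        "channel_names": list(trials.channel_names),
        "sampling_rate": trials.sampling_rate,
        "subject_id": trials.subject_id,
        "dataset_id": trials.dataset_id,
        "trial_order": trials.trial_order.tolist(),
        "class_names": list(trials.class_names),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_bundle(path) -> TrialSet:
    """Read an epochs bundle written by :func:`write_bundle`."""
    path = Path(path)
    meta = json.loads((path / "meta.json").read_text())
    return TrialSet(
        data=np.load(path / "data.npy"),
        labels=np.load(path / "labels.npy"),
        channel_names=tuple(meta["channel_names"]),
        sampling_rate=meta["sampling_rate"],
        subject_id=meta["subject_id"],
        dataset_id=meta["dataset_id"],
        trial_order=np.asarray(meta["trial_order"], dtype=int),
        class_names=tuple(meta["class_names"]),
    )
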