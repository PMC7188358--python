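"""Evaluation protocols and the paired statistical comparison.

Three protocols, each producing a tidy result table (pandas DataFrame with
columns dataset_id, subject_id, fold, method, condition, accuracy):

* **within-subject** — 10 random 80/10/10 folds per subject; classical
  decoders fit on train+validation, networks use the validation partition
  for best-epoch selection; alignment condition "PS" re-centers with the
  training partition's Riemannian mean.
* **cross-subject (LOSO)** — leave-one-subject-out within a dataset; under
  condition "OPS" every subject (training and held-out alike) is re-centered
  by their own online stream before any pooling, so no calibration or label
  information crosses the subject boundary.
* **cross-dataset** — train on all subjects of one dataset, test on every
  subject of the others; the diagonal of the resulting accuracy matrix is
  the within-dataset LOSO accuracy.

Method comparisons use the two-sided Wilcoxon signed-rank test on accuracy
vectors paired by identical (dataset, subject/fold) cells.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .alignment import fit_recenter, ops_stream, recenter_trialset
from .signals import TrialSet, concat_trialsets, make_folds, split_train_valid

__all__ = [
    "ComparisonReport",
    "wilcoxon_signed_rank",
    "run_within_subject",
    "run_cross_subject_loso",
    "run_cross_dataset",
    "accuracy_matrix",
    "result_checksum",
]

CONDITIONS = ("none", "PS", "OPS")


# --------------------------------------------------------------------------
# Wilcoxon signed-rank comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComparisonReport:
    """Paired comparison of two accuracy vectors."""

    label_a: str
    label_b: str
    a: np.ndarray
    b: np.ndarray
    statistic: float
    p_value: float
    n_effective: int
    direction: int  # sign of the median paired difference a - b

    def __str__(self):
        arrow = {1: ">", -1: "<", 0: "="}[self.direction]
        return (
            f"{self.label_a} {arrow} {self.label_b}: W={self.statistic:.1f}, "
            f"p={self.p_value:.4g} (n={self.n_effective})"
        )


def wilcoxon_signed_rank(a, b, label_a: str = "A", label_b: str = "B") -> ComparisonReport:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; the null distribution is exact for
    n <= 12 effective pairs (when ranks are untied), otherwise the normal
    approximation with continuity and tie correction is used.  If every
    difference is zero the comparison degenerates to p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be equal-length 1-D arrays")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        return ComparisonReport(label_a, label_b, a, b, 0.0, 1.0, 0, 0)
    if len(nz) < 5:
        raise ValueError(f"need >= 5 nonzero paired differences, got {len(nz)}")
    ranks = sstats.rankdata(np.abs(nz))
    untied = len(np.unique(ranks)) == len(ranks)
    method = "exact" if (len(nz) <= 12 and untied) else "approx"
    res = sstats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"), alternative="two-sided",
        method=method,
    )
    return ComparisonReport(
        label_a,
        label_b,
        a,
        b,
        float(res.statistic),
        float(res.pvalue),
        int(len(nz)),
        int(np.sign(np.median(d))),
    )


# --------------------------------------------------------------------------
# shared plumbing
# --------------------------------------------------------------------------

def _check_conditions(conditions, allowed):
    for c in conditions:
        if c not in allowed:
            raise ValueError(f"condition {c!r} undefined here; allowed: {allowed}")


def _accuracy(est, test: TrialSet) -> float:
    return float(np.mean(est.predict(test) == test.labels))


def _ps_align(train: TrialSet, others):
    """Fit re-centering on the training partition, align all partitions."""
    state = fit_recenter(train, allow_mixed_subjects=True)
    return recenter_trialset(state, train), [recenter_trialset(state, t) for t in others]


def _is_net(est) -> bool:
    return hasattr(est, "builder")


# --------------------------------------------------------------------------
# protocols
# --------------------------------------------------------------------------

def run_within_subject(
    subjects,
    methods: dict,
    conditions=("none", "PS"),
    n_folds: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject k-fold evaluation of every method x condition cell."""
    _check_conditions(conditions, ("none", "PS"))
    rows = []
    for trials in subjects:
        folds = make_folds(trials, n_folds=n_folds, seed=seed)
        for plan in folds:
            train = trials.subset(plan.train_idx)
            valid = trials.subset(plan.valid_idx)
            test = trials.subset(plan.test_idx)
            for cond in conditions:
                if cond == "PS":
                    tr, (va, te) = _ps_align(train, [valid, test])
                else:
                    tr, va, te = train, valid, test
                for name, factory in methods.items():
                    est = factory()
                    if _is_net(est):
                        est.fit(tr, va, seed=plan.seed)
                    else:
                        est.fit(concat_trialsets([tr, va], subject_id=trials.subject_id), seed=plan.seed)
                    rows.append(
                        {
                            "dataset_id": trials.dataset_id,
                            "subject_id": trials.subject_id,
                            "fold": plan.fold_id,
                            "method": name,
                            "condition": cond,
                            "accuracy": _accuracy(est, te),
                        }
                    )
    return pd.DataFrame(rows)


def _align_subject_pool(subjects, condition):
    """Per-subject re-centering before pooling (training side of LOSO)."""
    if condition == "none":
        return list(subjects)
    if condition == "OPS":
        return [ops_stream(t)[0] for t in subjects]
    if condition == "PS":
        return [recenter_trialset(fit_recenter(t), t) for t in subjects]
    raise ValueError(condition)


def _align_test_subject(trials, condition):
    if condition == "none":
        return trials.in_acquisition_order()
    if condition == "OPS":
        return ops_stream(trials)[0]
    if condition == "PS":
        return recenter_trialset(fit_recenter(trials), trials)
    raise ValueError(condition)


def _fit_pooled(factory, pool: TrialSet, seed: int):
    est = factory()
    if _is_net(est):
        tr, va = split_train_valid(pool, valid_fraction=0.1, seed=seed)
        est.fit(tr, va, seed=seed)
    else:
        est.fit(pool, seed=seed)
    return est


def run_cross_subject_loso(
    subjects,
    methods: dict,
    conditions=("none", "OPS"),
    n_repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out within one dataset.

    Each held-out subject is decoded from a model trained on the pooled
    remaining subjects; repeats re-seed the split and weight initialization.
    The held-out subject's trials are aligned by their own online stream
    under OPS — labels and future trials are never touched.
    """
    subjects = list(subjects)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least two subjects")
    _check_conditions(conditions, CONDITIONS)
    rows = []
    for cond in conditions:
        aligned = _align_subject_pool(subjects, cond)
        for held in range(len(subjects)):
            pool = concat_trialsets([t for j, t in enumerate(aligned) if j != held])
            test = _align_test_subject(subjects[held], cond)
            for rep in range(n_repeats):
                rep_seed = seed + 1000 * rep + held
                for name, factory in methods.items():
                    est = _fit_pooled(factory, pool, rep_seed)
                    rows.append(
                        {
                            "dataset_id": subjects[held].dataset_id,
                            "subject_id": subjects[held].subject_id,
                            "fold": rep,
                            "method": name,
                            "condition": cond,
                            "accuracy": _accuracy(est, test),
                        }
                    )
    return pd.DataFrame(rows)


def run_cross_dataset(
    datasets: dict,
    methods: dict,
    conditions=("none", "OPS"),
    seed: int = 0,
    loso_repeats: int = 1,
    include_diagonal: bool = True,
) -> pd.DataFrame:
    """Train on each dataset, test on every other; diagonal = LOSO.

    Returns a tidy table with train_dataset/test_dataset columns; use
    :func:`accuracy_matrix` to lay it out as the square matrix whose
    off-diagonal cells measure cross-dataset transfer.
    """
    if len(datasets) < 2:
        raise ValueError("cross-dataset evaluation needs at least two datasets")
    _check_conditions(conditions, CONDITIONS)
    rows = []
    for cond in conditions:
        aligned = {d: _align_subject_pool(subs, cond) for d, subs in datasets.items()}
        for train_d, train_subs in aligned.items():
            pool = concat_trialsets(train_subs)
            fitted = {
                name: _fit_pooled(factory, pool, seed) for name, factory in methods.items()
            }
            for test_d, test_subs in datasets.items():
                if test_d == train_d:
                    continue
                for t in test_subs:
                    test = _align_test_subject(t, cond)
                    for name, est in fitted.items():
                        rows.append(
                            {
                                "train_dataset": train_d,
                                "test_dataset": test_d,
                                "subject_id": t.subject_id,
                                "fold": 0,
                                "method": name,
                                "condition": cond,
                                "accuracy": _accuracy(est, test),
                            }
                        )
        # diagonal: within-dataset LOSO
        if not include_diagonal:
            continue
        for d, subs in datasets.items():
            loso = run_cross_subject_loso(
                subs, methods, conditions=(cond,), n_repeats=loso_repeats, seed=seed
            )
            for _, r in loso.iterrows():
                rows.append(
                    {
                        "train_dataset": d,
                        "test_dataset": d,
                        "subject_id": r["subject_id"],
                        "fold": r["fold"],
                        "method": r["method"],
                        "condition": cond,
                        "accuracy": r["accuracy"],
                    }
                )
    return pd.DataFrame(rows)


def accuracy_matrix(result: pd.DataFrame, method: str, condition: str) -> pd.DataFrame:
    """Square train-dataset x test-dataset mean-accuracy matrix."""
    sub = result[(result["method"] == method) & (result["condition"] == condition)]
    return sub.pivot_table(index="train_dataset", columns="test_dataset", values="accuracy")


def result_checksum(result: pd.DataFrame) -> str:
    """Stable checksum of a result table (row order independent)."""
    canon = result.sort_values(list(result.columns)).reset_index(drop=True)
    text = canon.to_csv(index=False, float_format="%.12g")
    return hashlib.sha256(text.encode()).hexdigest()
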