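"""Poisson naive Bayes decoding of movement-amplitude tertiles.

Trials are labeled by amplitude tertile (k = 1, 2, 3; equal counts,
label 1 = smallest). Class-conditional rates ``lambda[k, i, t]`` are the
mean training count of unit ``i`` in time bin ``t`` over class-k trials
(floored to avoid zero likelihoods). The class of a test trial
maximizes the Poisson log posterior, summing log-likelihood over units
and time bins; ties resolve to the smallest label. The cross-validation
protocol repeats, for many iterations, a random subsample of units to a
fixed population size and a stratified 10-fold split, scoring the
percentage of correctly classified test trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PoissonNBModel",
    "ClassificationReport",
    "tertile_labels",
    "fit",
    "predict",
    "predict_many",
    "crossval",
]


@dataclass
class PoissonNBModel:
    lam: np.ndarray  # (classes, units, bins), floored > 0
    log_priors: np.ndarray  # (classes,)
    classes: np.ndarray  # label values, ascending
    lam_floor: float

    def __post_init__(self) -> None:
        if np.any(self.lam <= 0):
            raise ValueError("lambda must be strictly positive after flooring")


@dataclass
class ClassificationReport:
    accuracies: np.ndarray  # per-iteration % correct
    confusion: np.ndarray  # (classes, classes), rows = true label, pooled
    label: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracies))

    def ci95(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.accuracies, [2.5, 97.5])
        return float(lo), float(hi)


def tertile_labels(amplitudes: np.ndarray) -> np.ndarray:
    """Equal-count amplitude tertile labels in {1, 2, 3}.

    Ties are broken by stable sort; with n not divisible by 3 the
    remainder goes to the earliest classes, e.g. n = 4 gives class sizes
    (2, 1, 1). Label 1 is the smallest-amplitude tertile.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    n = amplitudes.size
    if np.unique(amplitudes).size < 3:
        raise ValueError("need at least 3 distinct amplitudes for tertiles")
    base, rem = divmod(n, 3)
    sizes = [base + (1 if k < rem else 0) for k in range(3)]
    order = np.argsort(amplitudes, kind="stable")
    labels = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = k
        start += size
    return labels


def fit(
    train_counts: np.ndarray,
    labels: np.ndarray,
    lam_floor: Optional[float] = None,
) -> PoissonNBModel:
    """Fit class-conditional Poisson rates and class priors.

    ``train_counts`` is (trials, units, bins). ``lambda[k]`` is the mean
    count over class-k training trials; zero-count cells are floored at
    ``1 / (N_k * n_bins)`` (the default) so no test count has zero
    likelihood. Priors are training class frequencies.
    """
    counts = np.asarray(train_counts, dtype=float)
    labels = np.asarray(labels)
    if counts.ndim != 3:
        raise ValueError("train_counts must be (trials, units, bins)")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    classes = np.unique(labels)
    lam = np.empty((classes.size, counts.shape[1], counts.shape[2]))
    priors = np.empty(classes.size)
    floor_used = np.inf
    for j, k in enumerate(classes):
        mask = labels == k
        nk = int(mask.sum())
        if nk == 0:
            raise ValueError(f"class {k} missing from training set")
        lam[j] = counts[mask].mean(axis=0)
        priors[j] = nk / labels.size
        fl = lam_floor if lam_floor is not None else 1.0 / (nk * counts.shape[2])
        lam[j] = np.maximum(lam[j], fl)
        floor_used = min(floor_used, fl)
    return PoissonNBModel(
        lam=lam, log_priors=np.log(priors), classes=classes, lam_floor=float(floor_used)
    )


def _log_posterior(model: PoissonNBModel, X: np.ndarray) -> np.ndarray:
    """Unnormalized log posterior per class for trials X (n, units, bins).

    The Poisson log-likelihood summed over units and bins, dropping the
    class-independent ``log x!`` term, plus the log prior.
    """
    log_lam = np.log(model.lam)  # (C, D, B)
    ll = np.tensordot(X, log_lam, axes=([1, 2], [1, 2]))  # (n, C)
    ll -= model.lam.sum(axis=(1, 2))[None, :]
    return ll + model.log_priors[None, :]


def predict_many(model: PoissonNBModel, X: np.ndarray) -> np.ndarray:
    """Maximum-posterior class per trial; ties go to the smallest label."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    if X.shape[1:] != model.lam.shape[1:]:
        raise ValueError("trial dimensions do not match the model")
    scores = _log_posterior(model, X)
    return model.classes[np.argmax(scores, axis=1)]


def predict(model: PoissonNBModel, x: np.ndarray) -> int:
    """Class label of a single trial (units, bins)."""
    return int(predict_many(model, np.asarray(x)[None])[0])


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per trial, class-balanced; every trial in exactly one fold."""
    fold = np.empty(labels.size, dtype=int)
    for k in np.unique(labels):
        idx = np.flatnonzero(labels == k)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def crossval(
    population_counts: np.ndarray,
    labels: np.ndarray,
    n_iter: int = 1000,
    n_folds: int = 10,
    subsample_to: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    label: str = "",
) -> ClassificationReport:
    """Resampled, stratified cross-validated classification accuracy.

    Per iteration: draw ``subsample_to`` units without replacement (to
    match population sizes across groups), split trials into
    ``n_folds`` stratified folds, train on all-but-one fold and test on
    the held-out fold, rotating through every fold; the iteration's
    accuracy is the percentage of correctly classified test trials.
    """
    counts = np.asarray(population_counts, dtype=float)
    labels = np.asarray(labels)
    if rng is None:
        rng = np.random.default_rng(0)
    n_trials, n_units, _ = counts.shape
    classes, class_counts = np.unique(labels, return_counts=True)
    if np.any(class_counts < n_folds):
        raise ValueError("every class needs at least n_folds trials")
    if subsample_to is not None and subsample_to > n_units:
        raise ValueError("subsample_to exceeds the available units")
    accuracies = np.empty(n_iter)
    confusion = np.zeros((classes.size, classes.size), dtype=np.int64)
    class_pos = {k: j for j, k in enumerate(classes)}
    for it in range(n_iter):
        if subsample_to is not None:
            sel = rng.choice(n_units, size=subsample_to, replace=False)
            data = counts[:, sel, :]
        else:
            data = counts
        fold = _stratified_folds(labels, n_folds, rng)
        n_correct = 0
        for f in range(n_folds):
            test = fold == f
            model = fit(data[~test], labels[~test])
            pred = predict_many(model, data[test])
            true = labels[test]
            n_correct += int(np.sum(pred == true))
            for t, p in zip(true, pred):
                confusion[class_pos[t], class_pos[p]] += 1
        accuracies[it] = 100.0 * n_correct / n_trials
    return ClassificationReport(accuracies=accuracies, confusion=confusion, label=label)
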