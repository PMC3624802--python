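"""Vetting candidate reference signatures by cross-validated elimination.

Viral metagenomes in public archives carry variable amounts of microbial
contamination, and a contaminated reference signature poisons downstream
abundance estimates.  The vetting procedure demands that every candidate
(e.g. viral, label +1) signature be separable from the opposing (microbial,
label -1) signatures by a linear classifier on domain frequencies:

1. Regularized least-squares (ridge) classifiers are trained under
   stratified 5-fold cross-validation; the ridge parameter is picked from a
   log-spaced grid by the same CV error.
2. The CV is repeated 10 times with fresh random partitions, so every
   sample is tested 10 times; its misclassification rate is the fraction of
   repeats in which its test-fold prediction was wrong.
3. The eligible sample with the highest rate is eliminated and the whole
   procedure restarts on the reduced set, until no test error occurs in any
   repeat.

Samples that survive are considered well distinguishable and safe to use as
mixture-model references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EliminationAborted, SelectionError

__all__ = [
    "LabeledProfileSet",
    "RLSModel",
    "SelectionResult",
    "DEFAULT_LAMBDA_GRID",
    "train_rls",
    "predict_rls",
    "decision_values",
    "cv_misclassification",
    "stepwise_eliminate",
]

#: Default ridge-parameter grid: 1e-4 ... 1e2, decade steps.
DEFAULT_LAMBDA_GRID = tuple(10.0 ** k for k in range(-4, 3))


@dataclass(frozen=True)
class LabeledProfileSet:
    """Row-normalized sample profiles with ±1 labels and eliminability flags."""

    sample_ids: tuple[str, ...]
    family_ids: tuple[str, ...]
    profiles: np.ndarray  # n_samples x n_families
    labels: np.ndarray  # ±1
    eligible: np.ndarray  # bool: may this sample be eliminated?

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "family_ids", tuple(str(f) for f in self.family_ids))
        X = np.asarray(self.profiles, dtype=float)
        y = np.asarray(self.labels, dtype=int)
        e = np.asarray(self.eligible, dtype=bool)
        n = len(self.sample_ids)
        if X.shape != (n, len(self.family_ids)):
            raise SelectionError(
                f"profiles shape {X.shape} does not match {n} samples x "
                f"{len(self.family_ids)} families"
            )
        if y.shape != (n,) or e.shape != (n,):
            raise SelectionError("labels/eligible must have one entry per sample")
        if len(set(self.sample_ids)) != n:
            raise SelectionError("duplicate sample ids")
        if not np.all(np.isin(y, (-1, 1))):
            raise SelectionError("labels must be +1 or -1")
        for cls in (-1, 1):
            if np.sum(y == cls) < 2:
                raise SelectionError(f"need at least 2 samples of class {cls:+d}")
        sums = X.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [self.sample_ids[i] for i in np.flatnonzero(np.abs(sums - 1) > 1e-6)]
            raise SelectionError(f"sample profile(s) not normalized: {bad}")
        object.__setattr__(self, "profiles", X)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "eligible", e)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, mask_or_indices) -> "LabeledProfileSet":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return LabeledProfileSet(
            tuple(self.sample_ids[i] for i in idx),
            self.family_ids,
            self.profiles[idx],
            self.labels[idx],
            self.eligible[idx],
        )


@dataclass(frozen=True)
class RLSModel:
    """Linear decision function sign(w·x + b) from a ridge fit."""

    family_ids: tuple[str, ...]
    weights: np.ndarray
    bias: float
    ridge: float

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.family_ids),) or not np.all(np.isfinite(w)):
            raise SelectionError("model weights must be finite, one per family")
        if not np.isfinite(self.bias):
            raise SelectionError("model bias must be finite")
        object.__setattr__(self, "weights", w)


def train_rls(train: LabeledProfileSet, ridge: float) -> RLSModel:
    """Fit w, b minimizing Σ (label − w·x − b)² + ridge·‖w‖² (bias unpenalized).

    With the data centered, the unpenalized bias drops out and the primal
    solution is (XᵀX + λI)⁻¹ Xᵀy.  When there are more families than
    samples, the push-through identity gives the cheaper, numerically
    identical sample-space (dual) form Xᵀ(XXᵀ + λI)⁻¹ y.
    """
    if not ridge > 0:
        raise SelectionError("ridge parameter must be > 0")
    X = train.profiles
    y = train.labels.astype(float)
    x_mean = X.mean(axis=0)
    y_mean = y.mean()
    Xc = X - x_mean
    yc = y - y_mean
    n, d = Xc.shape
    try:
        if d <= n:
            w = np.linalg.solve(Xc.T @ Xc + ridge * np.eye(d), Xc.T @ yc)
        else:
            alpha = np.linalg.solve(Xc @ Xc.T + ridge * np.eye(n), yc)
            w = Xc.T @ alpha
    except np.linalg.LinAlgError as exc:
        raise SelectionError(f"ridge system is singular (lambda={ridge}): {exc}")
    b = float(y_mean - w @ x_mean)
    return RLSModel(train.family_ids, w, b, float(ridge))


def decision_values(model: RLSModel, profiles: np.ndarray) -> np.ndarray:
    return np.atleast_2d(profiles) @ model.weights + model.bias


def predict_rls(model: RLSModel, profile) -> int:
    """Class of one profile: sign(w·x + b); an exact zero scores as +1."""
    score = float(np.asarray(profile, dtype=float) @ model.weights + model.bias)
    return 1 if score >= 0 else -1


def _predict_batch(model: RLSModel, profiles: np.ndarray) -> np.ndarray:
    return np.where(decision_values(model, profiles) >= 0, 1, -1)


def _stratified_folds(labels: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Random fold assignment preserving class proportions per fold."""
    folds = np.empty(labels.shape[0], dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def cv_misclassification(
    data: LabeledProfileSet,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed=None,
) -> np.ndarray:
    """Per-sample misclassification rate over repeated cross-validation.

    Each repeat draws a fresh stratified partition, fits ridge classifiers
    for every grid value, picks the grid value with the fewest total CV
    errors (ties: smallest lambda), and records whether each sample's
    test-fold prediction under that choice was wrong.  Returns per-sample
    (#repeats misclassified) / n_repeats, aligned with ``data.sample_ids``.
    """
    lambda_grid = sorted(float(l) for l in lambda_grid)
    if not lambda_grid:
        raise SelectionError("lambda grid is empty")
    for cls in (-1, 1):
        if int(np.sum(data.labels == cls)) < n_folds:
            raise SelectionError(
                f"class {cls:+d} has fewer than n_folds={n_folds} samples; "
                "stratified cross-validation is impossible"
            )
    rng = np.random.default_rng(seed)
    n = data.n_samples
    mis_counts = np.zeros(n)
    for _ in range(n_repeats):
        folds = _stratified_folds(data.labels, n_folds, rng)
        preds = np.empty((len(lambda_grid), n), dtype=int)
        for f in range(n_folds):
            test = folds == f
            train = data.subset(~test)
            for gi, lam in enumerate(lambda_grid):
                model = train_rls(train, lam)
                preds[gi, test] = _predict_batch(model, data.profiles[test])
        errors = (preds != data.labels).sum(axis=1)
        best = int(np.argmin(errors))  # argmin takes the first = smallest lambda
        mis_counts += preds[best] != data.labels
    return mis_counts / n_repeats


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of stepwise elimination."""

    retained_ids: tuple[str, ...]
    eliminated: tuple[tuple[str, float], ...]  # (sample_id, rate at elimination)
    n_rounds: int
    rng_seed: object
    stopped_clean: bool  # True: no test error remained; False: stalled/aborted

    @property
    def eliminated_ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.eliminated)


def stepwise_eliminate(
    data: LabeledProfileSet,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    n_folds: int = 5,
    n_repeats: int = 10,
    seed=None,
) -> SelectionResult:
    """Repeatedly eliminate the worst-classified eligible sample.

    Each round runs :func:`cv_misclassification` with a fresh partition
    stream drawn from ``seed``.  If every rate is zero the procedure stops
    clean.  Otherwise the eligible sample with the maximal rate (ties:
    lexicographically smallest id) is removed and the round repeats on the
    reduced set.  If errors persist but only on ineligible samples, the
    procedure stops without a clean bill (``stopped_clean=False``).  An
    elimination that would leave the sample's class with fewer than
    ``n_folds`` members aborts with the partial trace attached.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    current = data
    eliminated: list[tuple[str, float]] = []
    n_rounds = 0
    while True:
        n_rounds += 1
        child = ss.spawn(1)[0]
        rates = cv_misclassification(
            current, lambda_grid, n_folds=n_folds, n_repeats=n_repeats, seed=child
        )
        if not np.any(rates > 0):
            stopped_clean = True
            break
        elig_rates = np.where(current.eligible, rates, -np.inf)
        max_rate = elig_rates.max()
        if not max_rate > 0:
            stopped_clean = False  # errors only on ineligible samples
            break
        cand = np.flatnonzero(elig_rates == max_rate)
        victim = min(cand, key=lambda i: current.sample_ids[i])
        cls = current.labels[victim]
        if int(np.sum(current.labels == cls)) - 1 < n_folds:
            raise EliminationAborted(
                f"eliminating {current.sample_ids[victim]!r} would leave class "
                f"{cls:+d} with fewer than n_folds={n_folds} samples",
                SelectionResult(
                    retained_ids=current.sample_ids,
                    eliminated=tuple(eliminated),
                    n_rounds=n_rounds,
                    rng_seed=seed,
                    stopped_clean=False,
                ),
            )
        eliminated.append((current.sample_ids[victim], float(max_rate)))
        keep = np.ones(current.n_samples, dtype=bool)
        keep[victim] = False
        current = current.subset(keep)
    return SelectionResult(
        retained_ids=current.sample_ids,
        eliminated=tuple(eliminated),
        n_rounds=n_rounds,
        rng_seed=seed,
        stopped_clean=stopped_clean,
    )
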