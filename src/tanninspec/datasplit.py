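"""Hold-out partitioning and stratified k-fold CV for continuous targets.

The hold-out split is a seeded uniform random 75/25 partition.  Stratified
folds bin the target by quantiles (quintiles by default) and deal shuffled
samples round-robin across folds within strata, so every fold spans the
target's range and fold sizes differ by at most one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SplitIndex", "CVFolds", "holdout_split", "stratified_kfold", "kennard_stone_split"]


@dataclass(frozen=True)
class SplitIndex:
    calibration: np.ndarray
    prediction: np.ndarray
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        cal, pred = np.asarray(self.calibration), np.asarray(self.prediction)
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")
        object.__setattr__(self, "calibration", cal)
        object.__setattr__(self, "prediction", pred)


@dataclass(frozen=True)
class CVFolds:
    folds: tuple[np.ndarray, ...]
    bin_edges: np.ndarray
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)

    def iter_splits(self):
        """Yield (train_idx, test_idx) pairs, sklearn-style."""
        all_idx = np.concatenate(self.folds)
        for f in self.folds:
            yield np.setdiff1d(all_idx, f), f


def holdout_split(n: int, fraction: float = 0.75, seed: int = 0) -> SplitIndex:
    """Seeded random partition with |calibration| = round(fraction * n)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2 samples to split")
    n_cal = int(round(fraction * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError(f"fraction {fraction} leaves an empty partition for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(np.sort(perm[:n_cal]), np.sort(perm[n_cal:]), fraction, seed)


def stratified_kfold(y, k: int = 5, n_bins: int = 5, seed: int = 0) -> CVFolds:
    """Quantile-stratified k folds over a continuous target."""
    y = np.asarray(y, float)
    n = y.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count {n}")
    n_bins = max(1, min(n_bins, n // k if n // k else 1))
    edges = np.quantile(y, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    strata = np.clip(np.searchsorted(edges, y, side="right") - 1, 0, len(edges) - 2)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    cursor = int(rng.integers(k))
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        rng.shuffle(members)
        for idx in members:
            folds[cursor % k].append(int(idx))
            cursor += 1
    return CVFolds(tuple(np.sort(f) for f in folds), edges, seed)


def kennard_stone_split(X, fraction: float = 0.75) -> SplitIndex:
    """Distance-based (Kennard-Stone) calibration selection — an extension
    beyond the default random hold-out, for users who want representative
    coverage of spectral space in the calibration set."""
    X = np.asarray(X, float)
    n = X.shape[0]
    n_cal = int(round(fraction * n))
    if n_cal < 2 or n_cal >= n:
        raise ValueError("fraction leaves too few samples in a partition")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    chosen = [int(i), int(j)]
    remaining = set(range(n)) - set(chosen)
    while len(chosen) < n_cal:
        rem = np.fromiter(remaining, int)
        nxt = rem[np.argmax(d2[rem][:, chosen].min(axis=1))]
        chosen.append(int(nxt))
        remaining.remove(int(nxt))
    return SplitIndex(np.sort(chosen), np.sort(np.fromiter(remaining, int)), fraction, seed=-1)


def export_split(split: SplitIndex, path) -> None:
    """Write the assignment as CSV for audit."""
    rows = [(int(i), "calibration") for i in split.calibration] + [
        (int(i), "prediction") for i in split.prediction
    ]
    pd.DataFrame(sorted(rows), columns=["index", "set"]).to_csv(path, index=False)
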