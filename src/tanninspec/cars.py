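"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

Each Monte-Carlo run i of N draws a row subsample, fits a PLS model on the
currently retained bands, and turns the absolute regression coefficients
into sampling weights.  An exponential decreasing function (EDF) forces the
retained-band count down a fixed schedule r_i = a*exp(-k*i) with r_1 = 1 and
r_N = 2/p; adaptive reweighted sampling (weighted draw with replacement,
deduplicated) then competes the survivors.  Each run's retained set is
scored by RMSECV on the full calibration data, and the minimum-RMSECV
subset wins.  An outer stability loop repeats the whole procedure E times
and keeps bands selected in at least ``frequency_threshold`` of executions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from .datasplit import CVFolds, stratified_kfold

__all__ = ["CARSConfig", "CARSTrace", "CARSResult", "edf_ratio", "rmsecv",
           "cars_run", "select_features"]


@dataclass(frozen=True)
class CARSConfig:
    n_mc_runs: int = 100          # N: Monte-Carlo runs per execution
    row_sample_ratio: float = 0.8
    cv_folds: int = 5
    max_pls_components: int = 10
    stability_repeats: int = 10   # E: outer executions
    frequency_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mc_runs < 2:
            raise ValueError("n_mc_runs must be >= 2")
        if not 0 < self.row_sample_ratio < 1:
            raise ValueError("row_sample_ratio must lie in (0, 1)")
        if not 0 <= self.frequency_threshold <= 1:
            raise ValueError("frequency_threshold must lie in [0, 1]")
        if self.stability_repeats < 1:
            raise ValueError("stability_repeats must be >= 1")


@dataclass
class CARSTrace:
    """Diagnostics of one CARS execution."""

    retained_sets: list[np.ndarray]
    rmsecv_values: np.ndarray
    coefficients: list[np.ndarray]  # full-width coefficient vectors, zeros off-set
    best_run: int
    truncated: bool = False

    @property
    def retained_counts(self) -> np.ndarray:
        return np.array([s.size for s in self.retained_sets])

    @property
    def best_subset(self) -> np.ndarray:
        return self.retained_sets[self.best_run]

    def to_frame(self, wavelengths: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy per-run trace (for RMSECV-path / variable-count panels)."""
        return pd.DataFrame({
            "run": np.arange(1, len(self.retained_sets) + 1),
            "n_retained": self.retained_counts,
            "rmsecv": self.rmsecv_values,
        })


@dataclass
class CARSResult:
    selected: np.ndarray
    selection_frequency: np.ndarray
    traces: list[CARSTrace]
    fallback_used: bool = False

    def to_frame(self, wavelengths: np.ndarray | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"band_index": self.selected})
        if wavelengths is not None:
            df["wavelength_nm"] = np.asarray(wavelengths)[self.selected]
        df["frequency"] = self.selection_frequency[self.selected]
        return df


def edf_ratio(i: int, N: int, p: int) -> float:
    """Fraction of the p bands forcibly retainable at Monte-Carlo run i.

    r_i = a*exp(-k*i) with a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1), so
    r_1 = 1 (all bands) and r_N = 2/p (two bands).
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if p < 2:
        raise ValueError("p must be >= 2")
    if not 1 <= i <= N:
        raise ValueError(f"run index i={i} outside [1, {N}]")
    a = (p / 2.0) ** (1.0 / (N - 1))
    k = np.log(p / 2.0) / (N - 1)
    return float(a * np.exp(-k * i))


def _pls_components_cap(n_train: int, p: int, requested: int) -> int:
    return max(1, min(requested, n_train - 1, p))


def rmsecv(X, y, folds: CVFolds, n_components: int) -> float:
    """Pooled RMSE of fold-held-out PLS predictions over all samples."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    min_train = min(X.shape[0] - f.size for f in folds.folds)
    if n_components > min(min_train - 1, X.shape[1]) or n_components < 1:
        raise ValueError(
            f"n_components={n_components} infeasible for n={X.shape[0]}, "
            f"p={X.shape[1]}, folds={folds.k}"
        )
    resid = np.empty_like(y)
    for train, test in folds.iter_splits():
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit(X[train], y[train])
        resid[test] = pls.predict(X[test]).ravel() - y[test]
    return float(np.sqrt(np.mean(resid**2)))


def _select_n_components(X, y, folds: CVFolds, max_components: int) -> int:
    cap = _pls_components_cap(min(X.shape[0] - f.size for f in folds.folds),
                              X.shape[1], max_components)
    errs = [rmsecv(X, y, folds, nc) for nc in range(1, cap + 1)]
    return int(np.argmin(errs)) + 1


def cars_run(X, y, config: CARSConfig, seed: int | None = None) -> CARSTrace:
    """One CARS execution of N Monte-Carlo runs; see module docstring."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 predictor columns")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    folds = stratified_kfold(y, k=config.cv_folds, seed=int(rng.integers(2**31)))
    n_comp = _select_n_components(X, y, folds, config.max_pls_components)

    retained = np.arange(p)
    n_rows = max(2, int(round(config.row_sample_ratio * n)))
    sets: list[np.ndarray] = []
    errors: list[float] = []
    coefs: list[np.ndarray] = []
    truncated = False
    for i in range(1, config.n_mc_runs + 1):
        rows = rng.choice(n, size=n_rows, replace=False)
        nc = _pls_components_cap(n_rows, retained.size, n_comp)
        pls = PLSRegression(n_components=nc, scale=False)
        pls.fit(X[np.ix_(rows, retained)], y[rows])
        coef = pls.coef_.ravel()
        full_coef = np.zeros(p)
        full_coef[retained] = coef
        b = np.abs(coef)
        if b.sum() == 0:
            b = np.ones_like(b)
        w = b / b.sum()
        forced = max(2, int(round(edf_ratio(i, config.n_mc_runs, p) * p)))
        if forced < retained.size:
            top = np.argsort(w)[::-1][:forced]
            survivors, w_surv = retained[top], w[top]
        else:
            survivors, w_surv = retained, w
        draws = rng.choice(survivors, size=forced, replace=True, p=w_surv / w_surv.sum())
        new_retained = np.unique(draws)
        if new_retained.size < 2:
            truncated = True
            break
        retained = new_retained
        nc_full = _pls_components_cap(
            min(n - f.size for f in folds.folds), retained.size, n_comp)
        err = rmsecv(X[:, retained], y, folds, nc_full)
        sets.append(retained.copy())
        errors.append(err)
        coefs.append(full_coef)
    errors_arr = np.asarray(errors)
    # tie-break: minimum RMSECV, then smaller subset, then earlier run
    order = sorted(
        range(len(errors)),
        key=lambda j: (errors[j], sets[j].size, j),
    )
    best = order[0] if order else 0
    return CARSTrace(sets, errors_arr, coefs, best, truncated)


def select_features(X, y, config: CARSConfig) -> CARSResult:
    """Stability-aggregated CARS: E executions vote; bands selected in at
    least frequency_threshold * E executions form the result.  If the vote
    is empty the single best execution's subset is used (flagged)."""
    X = np.asarray(X, float)
    p = X.shape[1]
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=config.stability_repeats)
    traces = [cars_run(X, y, config, seed=int(s)) for s in seeds]
    counts = np.zeros(p)
    for tr in traces:
        counts[tr.best_subset] += 1
    freq = counts / len(traces)
    selected = np.flatnonzero(freq >= config.frequency_threshold) \
        if config.frequency_threshold > 0 else np.flatnonzero(freq > 0)
    fallback = False
    if selected.size == 0:
        best_tr = min(
            range(len(traces)),
            key=lambda j: (traces[j].rmsecv_values[traces[j].best_run],
                           traces[j].best_subset.size, j),
        )
        selected = np.sort(traces[best_tr].best_subset)
        fallback = True
    return CARSResult(np.sort(selected), freq, traces, fallback)
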