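"""End-to-end experiment: six dataset variants x three model families.

Variants: VNIR-Raw, SWIR-Raw, Whole-Raw (data-layer concatenation),
VNIR-Feature, SWIR-Feature (CARS subsets), Fused-Feature (feature-layer
concatenation).  CARS runs once per sensor on calibration rows only, so no
statistic of the held-out prediction set influences selection or tuning.
Replicated hold-out splits refit the families on the fused-feature variant
to supply RMSEP replicates for the ANOVA + Tukey HSD family comparison.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as M
from .cars import CARSConfig, CARSResult, select_features
from .cnn import CNNSpec
from .datasplit import CVFolds, SplitIndex, holdout_split, stratified_kfold
from .fusion import concat_data_layer, concat_feature_layer
from .models import SVRSpec, TrainedModel, fit_cnn, fit_pls, tune_fit_svr
from .simgrain import GeneratorParams, SampleSet, generate_sample_set
from .spectra_io import SpectraMatrix

logger = logging.getLogger("tanninspec")

ALL_VARIANTS = ("VNIR-Raw", "SWIR-Raw", "Whole-Raw",
                "VNIR-Feature", "SWIR-Feature", "Fused-Feature")
ALL_FAMILIES = ("PLS", "SVR", "CNN")

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "make_comparison", "build_variants", "ALL_VARIANTS", "ALL_FAMILIES"]


@dataclass(frozen=True)
class ExperimentConfig:
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    holdout_fraction: float = 0.75
    cv_k: int = 5
    strat_bins: int = 5
    cars: CARSConfig = field(default_factory=CARSConfig)
    svr: SVRSpec = field(default_factory=SVRSpec)
    cnn: CNNSpec = field(default_factory=CNNSpec)
    max_pls_components: int = 10
    families: tuple[str, ...] = ALL_FAMILIES
    variants: tuple[str, ...] = ALL_VARIANTS
    replicates: int = 10
    replicate_variant: str = "Fused-Feature"
    cv_metrics: bool = True
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorParams(**d["generator"])
        if "cars" in d:
            d["cars"] = CARSConfig(**d["cars"])
        if "svr" in d:
            spec = dict(d["svr"])
            for k in ("c_grid", "gamma_grid"):
                if k in spec:
                    spec[k] = tuple(spec[k])
            d["svr"] = SVRSpec(**spec)
        if "cnn" in d:
            spec = dict(d["cnn"])
            if "conv_blocks" in spec:
                spec["conv_blocks"] = tuple(tuple(b) for b in spec["conv_blocks"])
            d["cnn"] = CNNSpec(**spec)
        for k in ("families", "variants"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class ExperimentReport:
    cells: dict            # (variant, family) -> {partition label -> MetricsReport}
    models: dict           # (variant, family) -> TrainedModel
    cars_results: dict     # sensor -> CARSResult
    variant_widths: dict   # variant -> n features
    replicate_rmsep: dict  # family -> np.ndarray
    comparison: M.ComparisonReport | None
    residuals: M.ResidualSummary | None
    best_cell: tuple[str, str] | None
    split: SplitIndex
    config: ExperimentConfig

    def to_frame(self) -> pd.DataFrame:
        """Tidy model x partition x metric table (radar-chart ready)."""
        rows = []
        for (variant, family), parts in self.cells.items():
            for label, rep in parts.items():
                rows.append({
                    "variant": variant, "family": family, "set": label,
                    "n_features": self.variant_widths[variant],
                    "r2": rep.r2, "rmse": rep.rmse, "rpd": rep.rpd,
                    "bias": rep.bias, "sep": rep.sep,
                    "interpretation": rep.interpretation,
                })
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "metrics": self.to_frame().to_dict(orient="records"),
            "cars": {
                s: {"selected": r.selected.tolist(),
                    "frequency": r.selection_frequency[r.selected].tolist()}
                for s, r in self.cars_results.items()
            },
            "replicate_rmsep": {k: list(map(float, v))
                                for k, v in self.replicate_rmsep.items()},
            "comparison": None if self.comparison is None else {
                "F": self.comparison.f_statistic,
                "df": list(self.comparison.df),
                "p": self.comparison.p_value,
            },
            "best_cell": list(self.best_cell) if self.best_cell else None,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def build_variants(
    vnir: SpectraMatrix,
    swir: SpectraMatrix,
    cars_results: dict[str, CARSResult] | None,
    variants: tuple[str, ...] = ALL_VARIANTS,
) -> dict[str, np.ndarray]:
    """Full-cohort predictor matrix per enabled variant."""
    out: dict[str, np.ndarray] = {}
    for name in variants:
        if name == "VNIR-Raw":
            out[name] = vnir.values
        elif name == "SWIR-Raw":
            out[name] = swir.values
        elif name == "Whole-Raw":
            out[name] = concat_data_layer(vnir, swir).values
        elif name == "VNIR-Feature":
            out[name] = vnir.values[:, cars_results["VNIR"].selected]
        elif name == "SWIR-Feature":
            out[name] = swir.values[:, cars_results["SWIR"].selected]
        elif name == "Fused-Feature":
            out[name] = concat_feature_layer(
                vnir, cars_results["VNIR"], swir, cars_results["SWIR"]).values
        else:
            raise ValueError(f"unknown variant {name!r}")
    return out


def _fit_family(family: str, X, y, folds: CVFolds, config: ExperimentConfig,
                seed: int) -> TrainedModel:
    if family == "PLS":
        return fit_pls(X, y, folds, config.max_pls_components)
    if family == "SVR":
        return tune_fit_svr(X, y, config.svr, folds)
    if family == "CNN":
        return fit_cnn(X, y, replace(config.cnn, seed=seed))
    raise ValueError(f"unknown family {family!r}")


def _cv_predictions(family: str, model: TrainedModel, X, y, folds: CVFolds,
                    config: ExperimentConfig, seed: int) -> np.ndarray:
    """Held-out predictions refitting the *chosen* hyperparameters per fold."""
    from sklearn.base import clone
    from sklearn.cross_decomposition import PLSRegression

    yhat = np.empty_like(np.asarray(y, float))
    for train, test in folds.iter_splits():
        if family == "PLS":
            nc = min(model.metadata["n_components"], train.size - 1)
            m = PLSRegression(n_components=nc, scale=False).fit(X[train], y[train])
            yhat[test] = m.predict(X[test]).ravel()
        elif family == "SVR":
            m = clone(model.estimator).fit(X[train], y[train])
            yhat[test] = m.predict(X[test])
        else:
            tm = fit_cnn(X[train], y[train], replace(config.cnn, seed=seed))
            yhat[test] = tm.predict(X[test])
    return yhat


def run_experiment(
    config: ExperimentConfig, sample_set: SampleSet | None = None
) -> ExperimentReport:
    rng = np.random.default_rng(config.seed)
    seed_of = {k: int(s) for k, s in zip(
        ("generator", "split", "cars_vnir", "cars_swir", "folds", "model", "reps"),
        rng.integers(2**31, size=7),
    )}

    if sample_set is None:
        logger.info("generating synthetic cohort (n=%d)", config.generator.n_samples)
        sample_set = generate_sample_set(replace(config.generator, seed=seed_of["generator"]))
    y = np.asarray(sample_set.tannin, float)
    n = y.size

    split = holdout_split(n, config.holdout_fraction, seed_of["split"])
    cal, pred = split.calibration, split.prediction
    y_cal, y_pred = y[cal], y[pred]

    cars_results: dict[str, CARSResult] = {}
    need_cars = any(v.endswith("Feature") for v in config.variants)
    if need_cars:
        for sensor, block, skey in (("VNIR", sample_set.vnir, "cars_vnir"),
                                    ("SWIR", sample_set.swir, "cars_swir")):
            logger.info("CARS selection on %s (calibration rows only)", sensor)
            cars_results[sensor] = select_features(
                block.values[cal], y_cal, replace(config.cars, seed=seed_of[skey]))
            logger.info("%s: %d -> %d bands", sensor, block.grid.n_bands,
                        cars_results[sensor].selected.size)

    variants = build_variants(sample_set.vnir, sample_set.swir,
                              cars_results or None, config.variants)
    folds = stratified_kfold(y_cal, config.cv_k, config.strat_bins, seed_of["folds"])

    cells, fitted = {}, {}
    for vi, (vname, X) in enumerate(variants.items()):
        X_cal, X_pred = X[cal], X[pred]
        for fi, family in enumerate(config.families):
            cell_seed = (seed_of["model"] + 97 * vi + fi) % 2**31
            logger.info("fitting %s on %s (%d features)", family, vname, X.shape[1])
            model = _fit_family(family, X_cal, y_cal, folds, config, cell_seed)
            parts = {
                "calibration": M.evaluate(
                    M.PredictionSet(y_cal, model.predict(X_cal), "calibration")),
                "prediction": M.evaluate(
                    M.PredictionSet(y_pred, model.predict(X_pred), "prediction")),
            }
            if config.cv_metrics:
                cv_hat = _cv_predictions(family, model, X_cal, y_cal, folds,
                                         config, cell_seed)
                parts["cv"] = M.evaluate(M.PredictionSet(y_cal, cv_hat, "cv"))
            cells[(vname, family)] = parts
            fitted[(vname, family)] = model

    # replicated splits for the family comparison
    replicate_rmsep: dict[str, list[float]] = {f: [] for f in config.families}
    comparison = None
    if config.replicates >= 2 and config.replicate_variant in variants:
        Xrep = variants[config.replicate_variant]
        rep_rng = np.random.default_rng(seed_of["reps"])
        for r in range(config.replicates):
            s = holdout_split(n, config.holdout_fraction, int(rep_rng.integers(2**31)))
            yc, yp = y[s.calibration], y[s.prediction]
            f = stratified_kfold(yc, config.cv_k, config.strat_bins,
                                 int(rep_rng.integers(2**31)))
            for fi, family in enumerate(config.families):
                m = _fit_family(family, Xrep[s.calibration], yc, f, config,
                                int(rep_rng.integers(2**31)))
                replicate_rmsep[family].append(
                    M.rmse(M.PredictionSet(yp, m.predict(Xrep[s.prediction]))))
        if len(config.families) >= 2:
            comparison = make_comparison(replicate_rmsep)

    best_cell = None
    residuals = None
    pred_cells = {k: v["prediction"].r2 for k, v in cells.items()}
    if pred_cells:
        best_cell = max(pred_cells, key=pred_cells.get)
        best_ps = M.PredictionSet(
            y_pred, fitted[best_cell].predict(variants[best_cell[0]][pred]), "prediction")
        if best_ps.n >= 8:
            residuals = M.residual_summary(best_ps)

    return ExperimentReport(
        cells=cells,
        models=fitted,
        cars_results=cars_results,
        variant_widths={k: v.shape[1] for k, v in variants.items()},
        replicate_rmsep={k: np.asarray(v) for k, v in replicate_rmsep.items()},
        comparison=comparison,
        residuals=residuals,
        best_cell=best_cell,
        split=split,
        config=config,
    )


def make_comparison(replicate_rmsep: dict) -> M.ComparisonReport:
    """One-way ANOVA + Tukey HSD over per-family RMSEP replicate vectors."""
    groups = {k: np.asarray(v, float) for k, v in replicate_rmsep.items()}
    for fam, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"family {fam!r} has fewer than 2 replicates")
    return M.anova_tukey(groups)
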