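#!/usr/bin/env python
"""Fit and compare the 18 models (six dataset variants x PLS/SVR/CNN).

Reads the cohort written by 01_simulate_cohort.py, runs the full experiment
(CARS selection on calibration rows, six variants, three families,
replicated splits for the RMSEP ANOVA), and writes:

  model_metrics.csv      tidy variant x family x partition metric table
  comparison_anova.csv   one-way ANOVA F/p and Tukey HSD pairwise results
  replicate_rmsep.csv    per-family RMSEP replicates behind the ANOVA
  residual_summary.csv   residual diagnostics of the best prediction model
  experiment_report.json full machine-readable report

Prints the prediction-set metrics per cell and the family comparison.
"""

import argparse
from pathlib import Path

import pandas as pd

from tanninspec.cars import CARSConfig
from tanninspec.cnn import CNNSpec
from tanninspec.pipeline import ExperimentConfig, run_experiment
from tanninspec.simgrain import GeneratorParams, SampleSet
from tanninspec.spectra_io import read_spectra_table


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--mc-runs", type=int, default=100)
    ap.add_argument("--repeats", type=int, default=10,
                    help="CARS stability executions E")
    ap.add_argument("--replicates", type=int, default=10,
                    help="repeated splits feeding the RMSEP ANOVA")
    ap.add_argument("--quick", action="store_true",
                    help="reduced CARS/CNN settings for a fast smoke run")
    ap.add_argument("--cv-metrics", action="store_true",
                    help="also report cross-validation metrics per cell "
                         "(refits every family per fold; slow for the CNN "
                         "on full-width variants)")
    args = ap.parse_args()

    vnir = read_spectra_table(args.out / "vnir_spectra.csv", "VNIR")
    swir = read_spectra_table(args.out / "swir_spectra.csv", "SWIR")
    ref = pd.read_csv(args.out / "reference.csv")
    ss = SampleSet(
        sample_ids=list(ref["sample_id"]),
        vnir=vnir, swir=swir,
        tannin=ref["tannin_pct"].to_numpy(),
        moisture=ref["moisture_pct"].to_numpy(),
    )

    if args.quick:
        cars = CARSConfig(n_mc_runs=30, stability_repeats=3)
        cnn = CNNSpec(learning_rate=1e-3, max_epochs=150, patience=25,
                      val_fraction=0.25)
        replicates = min(args.replicates, 4)
    else:
        cars = CARSConfig(n_mc_runs=args.mc_runs, stability_repeats=args.repeats)
        cnn = CNNSpec(learning_rate=1e-3, max_epochs=500, patience=50,
                      val_fraction=0.25, n_restarts=2)
        replicates = args.replicates

    cfg = ExperimentConfig(
        generator=GeneratorParams(n_samples=len(ref)),
        cars=cars, cnn=cnn, replicates=replicates, seed=args.seed,
        cv_metrics=args.cv_metrics,
    )
    report = run_experiment(cfg, ss)

    frame = report.to_frame()
    frame.to_csv(args.out / "model_metrics.csv", index=False)
    pd.DataFrame({f: v for f, v in report.replicate_rmsep.items()}).to_csv(
        args.out / "replicate_rmsep.csv", index=False)
    if report.comparison is not None:
        comp = report.comparison
        comp.tukey.assign(F=comp.f_statistic, df1=comp.df[0], df2=comp.df[1],
                          p_anova=comp.p_value).to_csv(
            args.out / "comparison_anova.csv", index=False)
    if report.residuals is not None:
        pd.DataFrame([report.residuals.__dict__]).to_csv(
            args.out / "residual_summary.csv", index=False)
    (args.out / "experiment_report.json").write_text(report.to_json())

    pred = frame[frame["set"] == "prediction"]
    print(pred[["variant", "family", "n_features", "r2", "rmse", "rpd",
                "interpretation"]].to_string(index=False,
                                             float_format=lambda v: f"{v:.3f}"))
    if report.comparison is not None:
        c = report.comparison
        print(f"\nANOVA on replicate RMSEP: F({c.df[0]}, {c.df[1]}) = "
              f"{c.f_statistic:.2f}, p = {c.p_value:.2e}")
        print(c.tukey.to_string(index=False))
    v, f = report.best_cell
    best = report.cells[report.best_cell]["prediction"]
    print(f"\nbest prediction model: {f} on {v} "
          f"(R2_P = {best.r2:.2f}, RMSE_P = {best.rmse:.2f}, RPD_P = {best.rpd:.2f})")


if __name__ == "__main__":
    main()
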