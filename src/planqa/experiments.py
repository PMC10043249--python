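"""Benchmark experiment designs: depth sweep, λ sweep, baseline comparison.

Each run of the shared pipeline is: encode -> train autoencoder -> score ->
TPR==1 threshold -> metric suite.  Sweeps repeat every configuration over a
seed list and aggregate mean/max (mean/min for FPR and the anomalies
count), with medians logged alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autoencoder import AEConfig, fit_autoencoder, sample_errors
from .baselines import DetectorSpec, default_grids, detector_scores, evaluate_scores, grid_search
from .detection import roc_and_auc
from .schema import EncodedMatrix, PlanTable, encode_table, load_plan_table
from .synthetic import GenConfig, generate_dataset

__all__ = [
    "ExperimentConfig",
    "SweepTable",
    "run_depth_sweep",
    "run_lambda_sweep",
    "run_baseline_comparison",
]

log = logging.getLogger("planqa")

#: columns aggregated as mean/max vs mean/min
_MAX_METRICS = ("auc", "accuracy", "precision", "f1")
_MIN_METRICS = ("fpr", "anomalies")


@dataclass
class ExperimentConfig:
    """Dataset source plus the grids and repetition protocol."""

    gen: GenConfig = field(default_factory=GenConfig)
    dataset_path: str | None = None
    depths: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    lambdas: tuple[float, ...] = (0.1, 0.5, 0.9, 0.99)
    repeats: int = 10
    seeds: tuple[int, ...] | None = None
    ae: AEConfig = field(default_factory=lambda: AEConfig(depth=6))
    scale: str = "minmax"
    comparison_depth: int = 6

    def __post_init__(self) -> None:
        if self.seeds is None:
            self.seeds = tuple(range(self.repeats))
        elif len(self.seeds) != self.repeats:
            raise ValueError("repeats must equal len(seeds) when seeds are explicit")
        if any(not 1 <= d <= 9 for d in self.depths):
            raise ValueError("depths must lie in 1..9")

    def load_data(self) -> tuple[PlanTable, EncodedMatrix]:
        if self.dataset_path is not None:
            table = load_plan_table(self.dataset_path, format="csv")
        else:
            table, _ = generate_dataset(self.gen)
        if table.labels is None:
            raise ValueError("experiments require a labeled dataset")
        return table, encode_table(table, scale=self.scale)


@dataclass
class SweepTable:
    """Aggregated sweep summary plus the full per-run log."""

    summary: pd.DataFrame
    runs: pd.DataFrame


def _one_ae_run(
    data: EncodedMatrix, base: AEConfig, labels, **overrides
) -> dict:
    config = replace(base, **overrides)
    result = fit_autoencoder(data, config)
    scores = sample_errors(result.model, data, config.lambda_weight)
    metrics = evaluate_scores(scores, labels)
    return metrics.to_dict()


def _aggregate(runs: pd.DataFrame, by: str) -> pd.DataFrame:
    rows = []
    for key, grp in runs.groupby(by, sort=False):
        row: dict = {by: key, "n_runs": len(grp), "n_failed": int(grp["failed"].sum())}
        ok = grp[~grp["failed"]]
        for m in _MAX_METRICS:
            row[f"{m}_mean"] = ok[m].mean()
            row[f"{m}_max"] = ok[m].max()
            row[f"{m}_median"] = ok[m].median()
        for m in _MIN_METRICS:
            row[f"{m}_mean"] = ok[m].mean()
            row[f"{m}_min"] = ok[m].min()
            row[f"{m}_median"] = ok[m].median()
        rows.append(row)
    return pd.DataFrame(rows)


def _sweep(config: ExperimentConfig, param: str, grid) -> SweepTable:
    table, data = config.load_data()
    labels = table.label_array
    runs = []
    for value in grid:
        for seed in config.seeds:
            rec = {param: value, "seed": seed, "failed": False}
            try:
                rec.update(_one_ae_run(data, config.ae, labels, seed=seed, **{param: value}))
            except Exception as exc:  # recorded, not dropped
                log.error("run %s=%s seed=%s failed: %s", param, value, seed, exc)
                rec["failed"] = True
                rec["error"] = str(exc)
            runs.append(rec)
    runs_df = pd.DataFrame(runs)
    return SweepTable(summary=_aggregate(runs_df, param), runs=runs_df)


def run_depth_sweep(config: ExperimentConfig) -> SweepTable:
    """Train one autoencoder per (depth, seed) and aggregate per depth."""
    return _sweep(config, "depth", config.depths)


def run_lambda_sweep(config: ExperimentConfig) -> SweepTable:
    """Same pipeline varying only the λ loss weight."""
    if any(l < 0 for l in config.lambdas):
        raise ValueError("lambda values must be >= 0")
    return _sweep(config, "lambda_weight", config.lambdas)


def run_baseline_comparison(
    config: ExperimentConfig, objective: str = "auc"
) -> tuple[pd.DataFrame, dict[str, list[tuple[float, float]]]]:
    """Grid-searched baselines plus the autoencoder under one TPR==1 policy.

    Returns one row per detector and the ROC point lists for overlay plots.
    The autoencoder row averages metrics over the configured seeds; its
    ROC comes from the first seed's run.
    """
    table, data = config.load_data()
    labels = table.label_array
    rows: list[dict] = []
    roc_overlay: dict[str, list[tuple[float, float]]] = {}

    # autoencoder at the comparison depth, averaged over seeds
    ae_runs = []
    for seed in config.seeds:
        ae_runs.append(
            _one_ae_run(data, config.ae, labels, seed=seed, depth=config.comparison_depth)
        )
        if seed == config.seeds[0]:
            cfg = replace(config.ae, seed=seed, depth=config.comparison_depth)
            result = fit_autoencoder(data, cfg)
            scores = sample_errors(result.model, data, cfg.lambda_weight)
            roc_overlay["autoencoder"], _ = roc_and_auc(scores, labels)
    ae_df = pd.DataFrame(ae_runs)
    rows.append(
        {
            "detector": f"autoencoder(depth={config.comparison_depth})",
            "failed": False,
            **{m: ae_df[m].mean() for m in ("auc", "accuracy", "precision", "recall", "fpr", "f1")},
            "anomalies": ae_df["anomalies"].mean(),
        }
    )

    for kind, grid in default_grids(data.n_dims).items():
        try:
            result = grid_search(grid, data, labels, objective=objective)
            best = result.best
            scores = detector_scores(best, data)
            metrics = evaluate_scores(scores, labels)
            roc_overlay[kind], _ = roc_and_auc(scores, labels)
            rows.append(
                {"detector": best.label(), "failed": False, **metrics.to_dict()}
            )
        except Exception as exc:
            log.error("baseline %s failed: %s", kind, exc)
            rows.append({"detector": kind, "failed": True, "error": str(exc)})

    return pd.DataFrame(rows), roc_overlay
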