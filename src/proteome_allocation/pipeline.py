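"""End-to-end analysis driver: filter → correlate → classify → normalize →
slopes → aggregate → explained variability → shuffle null.

Every artifact is written as TSV/YAML under one output directory with the
seed and configuration echoed, so a run is reproducible bit-for-bit from
(inputs, config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate import accumulated_fraction_trend
from .correlation import classify_proteins, explained_variability, growth_correlations, threshold_sweep
from .datasets import NoiseSpec, ProteomicsDataset
from .errors import ConfigError
from .io import read_dataset, write_dataset
from .preprocess import FilterConfig, filter_conditions, normalize_to_mean
from .slopes import expected_slope_distribution, fit_all_slopes, group_trend
from .synthetic import shuffle_dataset, simulate_half_coordinated

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (the TSV trio) or ``simulation``
    (keyword arguments for :func:`simulate_half_coordinated`) must be
    given. ``seed`` feeds every stochastic stage (expected slope
    distribution, shuffle null, simulation noise).
    """

    output_dir: str = "results/run"
    input_paths: dict | None = None
    simulation: dict | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    correlation_threshold: float = 0.5
    sweep_thresholds: list[float] | None = None
    mc_reps: int = 100
    n_shuffles: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.simulation is None):
            raise ConfigError("exactly one of input_paths or simulation must be set")

    def load_data(self) -> ProteomicsDataset:
        if self.input_paths is not None:
            return read_dataset(
                self.input_paths["fractions"],
                self.input_paths["conditions"],
                self.input_paths.get("proteins"),
            )
        kwargs = dict(self.simulation)
        cv = kwargs.pop("cv", 0.25)
        kwargs.setdefault("noise", NoiseSpec(cv=cv, seed=self.seed))
        return simulate_half_coordinated(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a summary dict (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = config.load_data()

    filtered, drop_report = filter_conditions(data, config.filter)
    drop_report.to_csv(out / "dropped.tsv", sep="\t", index=False)

    profile = growth_correlations(filtered)
    classes = classify_proteins(profile, config.correlation_threshold)
    corr_table = profile.table.copy()
    corr_table["class"] = classes.as_series()
    corr_table.index.name = "protein_id"
    corr_table.to_csv(out / "correlations.tsv", sep="\t")

    normalized = normalize_to_mean(filtered)
    strong = [p for p in classes.strong_positive if p in set(normalized.protein_ids)]
    logger.info("pipeline: %d of %d proteins strongly positive at r > %s",
                len(strong), filtered.n_proteins, config.correlation_threshold)

    summary: dict = {
        "seed": config.seed,
        "n_proteins": filtered.n_proteins,
        "n_conditions": filtered.n_conditions,
        "n_strong_positive": len(strong),
        "n_strong_negative": len(classes.strong_negative),
        "correlation_threshold": config.correlation_threshold,
    }

    if strong:
        fits = fit_all_slopes(normalized, strong)
        fits.to_csv(out / "slopes.tsv", sep="\t")
        shared = group_trend(normalized, strong)
        summary["group_slope"] = shared.slope
        summary["group_intercept"] = shared.intercept
        summary["group_r_squared"] = shared.r_squared

        expected = expected_slope_distribution(
            fits, shared.slope, shared.intercept,
            normalized.growth_rates.values, reps=config.mc_reps, seed=config.seed,
        )
        pd.DataFrame({"slope": expected}).to_csv(out / "expected_slopes.tsv", sep="\t", index=False)

        ribo = [p for p in strong if bool(normalized.protein_meta.loc[p, "is_ribosomal"])]
        if ribo:
            rfit = group_trend(normalized, ribo)
            summary["ribosomal_slope"] = rfit.slope
            summary["ribosomal_r_squared"] = rfit.r_squared

        trend = accumulated_fraction_trend(filtered, strong)
        trend_table = pd.DataFrame(
            {"growth_rate": filtered.growth_rates, "accumulated_fraction": trend.accumulated}
        )
        trend_table.index.name = "condition_id"
        trend_table.to_csv(out / "accumulated.tsv", sep="\t")
        summary["accumulated_slope"] = trend.fit.slope
        summary["accumulated_r_squared"] = trend.fit.r_squared
        summary["alpha"] = trend.alpha
        summary["half_life_hours"] = trend.half_life

        var = explained_variability(normalized, strong, config.correlation_threshold)
        summary["explained_fraction"] = var.explained_fraction

    sweep_table, best = threshold_sweep(filtered, config.sweep_thresholds, normalized=normalized)
    sweep_table.to_csv(out / "threshold_sweep.tsv", sep="\t", index=False)
    summary["best_threshold"] = best
    summary["max_explained_fraction"] = float(sweep_table["explained_fraction"].max())

    if config.n_shuffles > 0:
        counts, max_explained = [], []
        for k in range(config.n_shuffles):
            shuffled = shuffle_dataset(filtered, seed=config.seed + k + 1)
            sprof = growth_correlations(shuffled)
            scls = classify_proteins(sprof, config.correlation_threshold)
            counts.append(len(scls.strong_positive))
            snorm = normalize_to_mean(shuffled)
            stable, _ = threshold_sweep(shuffled, config.sweep_thresholds, normalized=snorm)
            max_explained.append(float(stable["explained_fraction"].max()))
        null = pd.DataFrame({"n_strong_positive": counts, "max_explained_fraction": max_explained})
        null.to_csv(out / "shuffle_null.tsv", sep="\t", index=False)
        summary["shuffle_mean_strong_positive"] = float(np.mean(counts))
        summary["shuffle_mean_max_explained"] = float(np.mean(max_explained))

    config_echo = {
        "seed": config.seed,
        "correlation_threshold": config.correlation_threshold,
        "mc_reps": config.mc_reps,
        "n_shuffles": config.n_shuffles,
        "filter": asdict(config.filter),
        "simulation": config.simulation,
        "input_paths": config.input_paths,
    }
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump({"config": config_echo, "summary": _plain(summary)}, fh, sort_keys=False)
    write_dataset(filtered, out, prefix="filtered")
    return summary


def _plain(d: dict) -> dict:
    return {k: (float(v) if isinstance(v, (np.floating, float)) else int(v) if isinstance(v, (np.integer,)) else v) for k, v in d.items()}
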