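"""Accumulated proteome fraction, degradation-rate inference, reference prediction.

Summing the raw mass fractions of the strongly growth-correlated set per
condition gives the share of the proteome moving coordinately with
growth rate. Under the growth law with uniform first-order degradation,
that accumulated fraction is proportional to ``g + alpha``, so the fitted
trend line's extrapolated x-intercept is ``-alpha`` and the degradation
rate falls out of the fit as ``alpha = intercept / slope``; the protein
half-life is ``ln2 / alpha``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ProteomicsDataset
from .slopes import SlopeFit, fit_normalized_slope, group_trend

logger = logging.getLogger(__name__)

__all__ = [
    "AggregateTrend",
    "accumulated_fraction_trend",
    "infer_degradation",
    "predict_from_reference",
]


@dataclass
class AggregateTrend:
    """Per-condition accumulated fraction of a subset with its trend line."""

    accumulated: pd.Series
    fit: SlopeFit
    alpha: float
    half_life: float


def accumulated_fraction_trend(data: ProteomicsDataset, subset: list[str]) -> AggregateTrend:
    """Sum raw fractions of ``subset`` per condition and fit versus growth rate.

    Missing values are treated as absent from the sum; a warning is
    logged when more than 10% of the subset is missing in any condition.
    The fitted line feeds :func:`infer_degradation`.
    """
    if len(subset) == 0:
        raise ValueError("accumulated_fraction_trend needs a non-empty subset")
    sub = data.fractions.loc[list(subset)]
    missing_share = sub.isna().mean(axis=0)
    if (missing_share > 0.10).any():
        worst = missing_share.idxmax()
        logger.warning(
            "accumulated fraction: up to %.0f%% of subset missing (condition %s)",
            100 * missing_share.max(), worst,
        )
    accumulated = sub.sum(axis=0, skipna=True)
    fit = fit_normalized_slope(accumulated.values, data.growth_rates.values)
    if fit.slope > 0:
        alpha, half_life = infer_degradation(fit)
    else:
        alpha, half_life = math.nan, math.nan
    return AggregateTrend(accumulated, fit, alpha, half_life)


def infer_degradation(fit: SlopeFit) -> tuple[float, float]:
    """Degradation rate and half-life from a positive-slope trend line.

    A trend of the form ``a * (g + alpha)`` crosses zero at ``-alpha``,
    so ``alpha = intercept / slope`` (h⁻¹) and the half-life is
    ``ln2 / alpha`` hours (infinite when alpha = 0). A negative intercept
    yields a negative alpha with a warning — the degradation reading of
    the trend line is then violated.
    """
    if fit.slope <= 0:
        raise ValueError("degradation inference requires a positive slope")
    alpha = fit.intercept / fit.slope
    if alpha < 0:
        warnings.warn(f"negative inferred degradation rate ({alpha:.3g} /h): model violation")
        return alpha, math.nan
    half_life = math.inf if alpha == 0 else math.log(2.0) / alpha
    return alpha, half_life


def predict_from_reference(
    normalized: ProteomicsDataset,
    reference: list[str],
    target: str,
    train_conditions: list[str],
) -> tuple[pd.Series, float]:
    """Predict one protein's normalized fractions from reference proteins.

    Coordinated proteins share a single normalized line, so the group
    trend of the reference set over the training conditions, evaluated at
    each growth rate, is the prediction for the target (on the normalized
    scale the fixed target/reference ratio is 1). Returns the predictions
    over all conditions and the R² against the target's observed values
    on the held-out conditions.
    """
    if target in set(reference):
        raise ValueError("target must not be part of the reference set")
    if len(reference) == 0:
        raise ValueError("reference set is empty")
    if len(train_conditions) < 2:
        raise ValueError("need at least 2 training conditions")
    observed = normalized.fractions.loc[target]
    if observed.isna().mean() > 0.5:
        raise ValueError(f"target {target!r} missing in more than half the conditions")
    train = normalized.subset_conditions(list(train_conditions))
    fit = group_trend(train, reference)
    g = normalized.growth_rates
    predicted = pd.Series(fit.slope * g.values + fit.intercept, index=g.index)
    held_out = [c for c in normalized.condition_ids if c not in set(train_conditions)]
    eval_conditions = held_out if held_out else list(normalized.condition_ids)
    obs = observed.loc[eval_conditions]
    pred = predicted.loc[eval_conditions]
    mask = ~obs.isna()
    ss_res = float(((obs[mask] - pred[mask]) ** 2).sum())
    ss_tot = float(((obs[mask] - obs[mask].mean()) ** 2).sum())
    r_squared = 1.0 if ss_res == 0 else (1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0)
    return predicted, max(0.0, r_squared)
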