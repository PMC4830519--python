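"""Normalized-slope regression and the Monte-Carlo expected slope distribution.

After mean-normalization, proteins that share one response to growth rate
lie on one line; the per-protein OLS slope of normalized fraction versus
growth rate is therefore the coordination statistic. Observed slopes
scatter because of measurement noise even under perfect coordination, so
the null ("all proteins share a single slope") is calibrated by
simulation: each protein is re-drawn on the shared line with its own
residual noise and refit, and the pooled fitted slopes form the expected
distribution against which the observed histogram is compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ProteomicsDataset

__all__ = ["SlopeFit", "fit_normalized_slope", "expected_slope_distribution", "group_trend"]


@dataclass(frozen=True)
class SlopeFit:
    """OLS fit of (normalized) fraction on growth rate.

    ``slope`` has units of hours (normalized fraction per unit growth
    rate); ``residual_se`` is the standard deviation of residuals about
    the line with an n−2 denominator (0 when n = 2).
    """

    slope: float
    intercept: float
    r_squared: float
    residual_se: float
    n_obs: int

    def __post_init__(self) -> None:
        if self.n_obs < 2:
            raise ValueError("a line fit needs at least 2 points")
        if self.residual_se < 0:
            raise ValueError("residual_se must be non-negative")


def _ols(x: np.ndarray, y: np.ndarray) -> SlopeFit:
    """Closed-form simple OLS; shared by every fit in the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("a line fit needs at least 2 points")
    if np.ptp(x) == 0:
        raise np.linalg.LinAlgError("all growth rates identical: singular design")
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    slope = float(((x - xm) * (y - ym)).sum() / sxx)
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    ss_res = float((resid**2).sum())
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    se = 0.0 if n <= 2 else float(np.sqrt(ss_res / (n - 2)))
    # guard tiny negative float error
    r2 = min(1.0, max(0.0, r2))
    return SlopeFit(slope, float(intercept), r2, se, n)


def fit_normalized_slope(values, growth_rates) -> SlopeFit:
    """OLS of one protein's normalized fractions on growth rate.

    Missing values are dropped pairwise; at least 2 distinct growth rates
    are required.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(growth_rates, dtype=float)
    mask = ~np.isnan(y) & ~np.isnan(x)
    return _ols(x[mask], y[mask])


def fit_all_slopes(normalized: ProteomicsDataset, subset=None) -> pd.DataFrame:
    """Per-protein slope table (slope, intercept, r_squared, residual_se, n_obs)."""
    ids = list(subset) if subset is not None else normalized.protein_ids
    g = normalized.growth_rates.values
    rows = []
    for pid in ids:
        fit = fit_normalized_slope(normalized.fractions.loc[pid].values, g)
        rows.append(
            {
                "protein_id": pid,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "residual_se": fit.residual_se,
                "n_obs": fit.n_obs,
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def expected_slope_distribution(
    fits: list[SlopeFit] | pd.DataFrame,
    shared_slope: float,
    shared_intercept: float,
    growth_rates,
    reps: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Monte-Carlo slope distribution under the single-shared-slope null.

    For every protein and every rep, values on the shared line are
    perturbed with that protein's own Gaussian residual noise
    (``residual_se``) independently per condition and refit by OLS; all
    fitted slopes are pooled uniformly. With all residuals zero the
    distribution is a point mass at ``shared_slope``.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if isinstance(fits, pd.DataFrame):
        ses = fits["residual_se"].values.astype(float)
    else:
        ses = np.array([f.residual_se for f in fits], dtype=float)
    if (ses < 0).any():
        raise ValueError("residual_se must be non-negative")
    g = np.asarray(growth_rates, dtype=float)
    n = g.size
    rng = np.random.default_rng(seed)
    gm = g.mean()
    sxx = float(((g - gm) ** 2).sum())
    line = shared_slope * g + shared_intercept
    slopes = np.empty((ses.size, reps))
    for i, se in enumerate(ses):
        noise = rng.normal(0.0, se, size=(reps, n)) if se > 0 else np.zeros((reps, n))
        y = line[None, :] + noise
        # vectorized OLS slope per rep
        ym = y.mean(axis=1, keepdims=True)
        slopes[i] = ((g - gm)[None, :] * (y - ym)).sum(axis=1) / sxx
    return slopes.ravel()


def group_trend(normalized: ProteomicsDataset, subset: list[str]) -> SlopeFit:
    """OLS trend of the subset-average normalized fraction versus growth rate.

    Per condition, the normalized fractions of the subset proteins are
    averaged (ignoring missing values) — equivalent to the normalized sum
    re-normalized — and the averages are fit against growth rate. Used to
    compare e.g. the ribosomal group against the full strongly-correlated
    group.
    """
    if len(subset) == 0:
        raise ValueError("group_trend needs a non-empty subset")
    mean_profile = normalized.fractions.loc[list(subset)].mean(axis=0, skipna=True)
    return fit_normalized_slope(mean_profile.values, normalized.growth_rates.values)
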