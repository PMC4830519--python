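"""Per-protein correlation with growth rate, classification, explained variability.

The central descriptive statistic of the pipeline: the Pearson
correlation of every protein's fractions with the specific growth rate
across conditions. Proteins with r above a threshold (strictly) form the
"strongly positively correlated" set; the explained-variability statistic
then asks how much of the total variance of the mean-normalized proteome
a single shared line through that set accounts for.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ProteomicsDataset
from .errors import ConfigError
from .slopes import SlopeFit, _ols

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "Classification",
    "VariabilityResult",
    "growth_correlations",
    "classify_proteins",
    "explained_variability",
    "threshold_sweep",
]

CLASSES = ("strong_positive", "strong_negative", "other", "undefined")


@dataclass
class CorrelationProfile:
    """Per-protein Pearson correlation with growth rate.

    ``table`` is indexed by protein id with columns ``r`` (NaN when
    undefined) and ``n_obs`` (paired observations used).
    """

    table: pd.DataFrame

    @property
    def r(self) -> pd.Series:
        return self.table["r"]


@dataclass
class Classification:
    """Partition of protein ids at a correlation threshold."""

    strong_positive: list[str]
    strong_negative: list[str]
    other: list[str]
    undefined: list[str]
    threshold: float

    def as_series(self) -> pd.Series:
        out = {}
        for name in CLASSES:
            for pid in getattr(self, name):
                out[pid] = name
        return pd.Series(out, name="class")


@dataclass
class VariabilityResult:
    """Fraction of total normalized variance explained by one shared line."""

    explained_fraction: float
    subset_size: int
    threshold: float
    shared_fit: SlopeFit | None


def growth_correlations(data: ProteomicsDataset, min_obs: int = 3) -> CorrelationProfile:
    """Pearson r of each protein's fractions against growth rate.

    Missing values are dropped pairwise. Proteins with fewer than
    ``min_obs`` pairs or zero variance get ``r = NaN`` (class undefined)
    rather than aborting. Mean-normalization leaves every r unchanged
    (correlation is affine-invariant), so raw fractions are used.
    """
    g = data.growth_rates.values
    rows = data.fractions.values
    r = np.full(rows.shape[0], np.nan)
    n_obs = np.zeros(rows.shape[0], dtype=int)
    for i in range(rows.shape[0]):
        mask = ~np.isnan(rows[i])
        n = int(mask.sum())
        n_obs[i] = n
        if n < min_obs:
            continue
        x, y = g[mask], rows[i][mask]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            continue
        r[i] = np.corrcoef(x, y)[0, 1]
    return CorrelationProfile(
        pd.DataFrame({"r": r, "n_obs": n_obs}, index=data.fractions.index)
    )


def classify_proteins(profile: CorrelationProfile, threshold: float = 0.5) -> Classification:
    """Partition proteins by correlation sign and strength.

    Strictly ``r > threshold`` → strong_positive, ``r < -threshold`` →
    strong_negative; ties at exactly the threshold stay in ``other``.
    """
    if not 0 < threshold < 1:
        raise ConfigError(f"threshold must lie in (0, 1), got {threshold}")
    r = profile.table["r"]
    undefined = r.index[r.isna()]
    pos = r.index[r > threshold]
    neg = r.index[r < -threshold]
    rest = r.index.difference(pos).difference(neg).difference(undefined)
    return Classification(
        strong_positive=list(pos),
        strong_negative=list(neg),
        other=list(rest),
        undefined=list(undefined),
        threshold=threshold,
    )


def explained_variability(
    normalized: ProteomicsDataset, subset: list[str], threshold: float = np.nan
) -> VariabilityResult:
    """Share of total normalized variance captured by one line through ``subset``.

    All (growth rate, normalized fraction) points of the subset proteins
    are pooled and fit with a single OLS line; proteins outside the subset
    are "predicted" by their own mean (normalized value 1) and contribute
    no explained variance. The total sum of squares is taken around 1 —
    the per-protein mean — over every observed point, so

    ``explained = [SS_subset_around_1 − SS_subset_residual] / SS_total``.

    The pooled OLS fit can never do worse than the flat line at 1, so the
    result lies in [0, 1]. An empty subset yields 0 with a warning.
    """
    frame = normalized.fractions
    g = normalized.growth_rates
    total_ss = float(((frame - 1.0) ** 2).sum().sum())
    if len(subset) == 0:
        warnings.warn("explained_variability: empty subset, explained fraction is 0")
        return VariabilityResult(0.0, 0, threshold, None)
    missing = set(subset) - set(frame.index)
    if missing:
        raise KeyError(f"subset proteins not in data set: {sorted(missing)[:5]}")
    sub = frame.loc[list(subset)]
    long = sub.stack(future_stack=True).dropna()
    x = g.loc[long.index.get_level_values(1)].values
    y = long.values
    fit = _ols(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    subset_base = float(((y - 1.0) ** 2).sum())
    explained = subset_base - float((resid**2).sum())
    frac = explained / total_ss if total_ss > 0 else 0.0
    return VariabilityResult(float(frac), len(subset), threshold, fit)


def threshold_sweep(
    data: ProteomicsDataset,
    thresholds=None,
    normalized: ProteomicsDataset | None = None,
) -> tuple[pd.DataFrame, float]:
    """Explained variability of the strong-positive set across thresholds.

    ``data`` supplies raw fractions for the correlations; ``normalized``
    (computed on the fly if omitted) supplies the variance bookkeeping.
    Returns the sweep table (threshold, subset size, explained fraction)
    and the argmax threshold. Subset size is non-increasing in the
    threshold since superlevel sets are nested.
    """
    from .preprocess import normalize_to_mean

    if thresholds is None:
        thresholds = np.round(np.arange(0.05, 1.0, 0.05), 10)
    thresholds = list(thresholds)
    if len(thresholds) < 2:
        raise ConfigError("threshold sweep needs at least 2 thresholds")
    if normalized is None:
        normalized = normalize_to_mean(data)
    profile = growth_correlations(data)
    rows = []
    for t in thresholds:
        subset = classify_proteins(profile, t).strong_positive
        subset = [p for p in subset if p in set(normalized.fractions.index)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = explained_variability(normalized, subset, threshold=t)
        rows.append(
            {"threshold": t, "subset_size": res.subset_size, "explained_fraction": res.explained_fraction}
        )
    table = pd.DataFrame(rows)
    best = float(table.loc[table["explained_fraction"].idxmax(), "threshold"])
    return table, best
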