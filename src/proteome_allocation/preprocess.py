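"""Condition filtering and per-protein mean-normalization.

Filtering mirrors the data curation applied to the published data sets:
stationary-phase measurements are excluded outright (the growth laws
describe exponential growth only), and optionally conditions whose growth
rates skew the distribution — e.g. a couple of very fast rich-media
points in an otherwise narrow range — are removed until the sample
skewness of the retained growth rates falls under a limit.

Normalization divides every protein's row by its own mean across retained
conditions, so proteins sharing one response collapse onto one line
regardless of absolute abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import ProteomicsDataset
from .errors import InsufficientDataError, UndefinedStatisticError

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "sample_skewness", "filter_conditions", "normalize_to_mean"]


@dataclass
class FilterConfig:
    """Knobs of :func:`filter_conditions`.

    ``skewness_limit`` is the maximum tolerated |γ1| of the retained
    growth-rate distribution (``None`` disables the rule);
    ``min_observations`` is the fewest non-missing values a protein needs
    to stay in the data set.
    """

    drop_nonexponential: bool = True
    skewness_limit: float | None = None
    explicit_exclusions: list[str] = field(default_factory=list)
    min_observations: int = 3

    def __post_init__(self) -> None:
        if self.min_observations < 2:
            raise ValueError("min_observations must be at least 2")


def sample_skewness(values) -> float:
    """Population (biased) sample skewness γ1 = m3 / m2^{3/2}.

    Uses 1/n central moments; requires at least 3 values and non-zero
    variance.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise UndefinedStatisticError("skewness needs at least 3 values")
    if np.var(arr) == 0:
        raise UndefinedStatisticError("skewness undefined for zero-variance sample")
    return float(stats.skew(arr, bias=True))


def filter_conditions(
    data: ProteomicsDataset, config: FilterConfig = FilterConfig()
) -> tuple[ProteomicsDataset, pd.DataFrame]:
    """Drop conditions (and under-observed proteins); report every removal.

    Order of the rules: non-exponential conditions, explicit exclusions,
    then — if ``skewness_limit`` is set — greedy removal of the growth
    rate farthest from the median until |γ1| of the retained rates is
    within the limit or only 4 conditions remain. Proteins left with fewer
    than ``min_observations`` values are dropped last. Retained values are
    never altered.

    Returns the filtered data set and a report table with columns
    ``item``, ``kind`` and ``reason``.
    """
    removals: list[dict] = []
    keep = list(data.condition_ids)

    if config.drop_nonexponential:
        expo = data.condition_meta["is_exponential"].astype(bool)
        for cond in keep:
            if not expo.loc[cond]:
                removals.append({"item": cond, "kind": "condition", "reason": "non-exponential phase"})
        keep = [c for c in keep if expo.loc[c]]

    for cond in config.explicit_exclusions:
        if cond in keep:
            removals.append({"item": cond, "kind": "condition", "reason": "explicit exclusion"})
            keep = [c for c in keep if c != cond]

    if config.skewness_limit is not None:
        while len(keep) > 4:
            rates = data.growth_rates.loc[keep]
            gamma1 = sample_skewness(rates.values)
            if abs(gamma1) <= config.skewness_limit:
                break
            worst = (rates - rates.median()).abs().idxmax()
            removals.append(
                {
                    "item": worst,
                    "kind": "condition",
                    "reason": f"growth-rate skewness |{gamma1:.2f}| > {config.skewness_limit}",
                }
            )
            keep = [c for c in keep if c != worst]

    if len(keep) < 3:
        raise InsufficientDataError(f"only {len(keep)} conditions left after filtering")

    out = data.subset_conditions(keep)
    n_obs = out.fractions.notna().sum(axis=1)
    dropped_proteins = n_obs[n_obs < config.min_observations].index
    for pid in dropped_proteins:
        removals.append(
            {
                "item": pid,
                "kind": "protein",
                "reason": f"fewer than {config.min_observations} observations",
            }
        )
    if len(dropped_proteins):
        out = out.subset_proteins([p for p in out.protein_ids if p not in set(dropped_proteins)])

    report = pd.DataFrame(removals, columns=["item", "kind", "reason"])
    logger.info(
        "filter_conditions: kept %d/%d conditions, %d/%d proteins",
        out.n_conditions, data.n_conditions, out.n_proteins, data.n_proteins,
    )
    return out, report


def normalize_to_mean(data: ProteomicsDataset) -> ProteomicsDataset:
    """Divide each protein's row by its mean across (non-missing) conditions.

    Per-protein means of the result are exactly 1; proteins with an
    all-missing or all-zero row are dropped with a warning. Idempotent,
    and leaves every protein's correlation with growth rate unchanged.
    """
    means = data.fractions.mean(axis=1, skipna=True)
    bad = means.index[(means.isna()) | (means == 0)]
    frame = data.fractions.drop(index=bad)
    if len(bad):
        logger.warning("normalize_to_mean: dropping %d proteins with zero/missing mean", len(bad))
    normalized = frame.div(means.drop(index=bad), axis=0)
    return ProteomicsDataset(
        normalized,
        data.growth_rates.copy(),
        data.condition_meta.copy(),
        data.protein_meta.drop(index=bad),
        dict(data.provenance, normalized=True),
    )
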