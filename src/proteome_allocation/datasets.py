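"""The protein x condition mass-fraction container exchanged by the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ModelInvalidError

CONTROL_TYPES = ("batch", "chemostat", "accelerostat")

__all__ = ["ProteomicsDataset", "NoiseSpec", "CONTROL_TYPES"]


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian measurement noise: factor ``max(0, N(1, cv))``.

    The default coefficient of variation, 0.25, is the noise level of the
    half-coordinated benchmark data set; truncation at zero keeps mass
    fractions non-negative.
    """

    cv: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("noise cv must be non-negative")


@dataclass
class ProteomicsDataset:
    """Mass fractions of the proteome across growth conditions.

    ``fractions`` is a proteins x conditions matrix of dimensionless mass
    fractions (NaN = missing measurement). ``growth_rates`` holds the
    specific growth rate of each condition in h⁻¹. ``condition_meta``
    (indexed by condition) carries ``is_exponential``, ``medium`` and
    ``control_type``; ``protein_meta`` (indexed by protein) carries
    ``functional_group`` and ``is_ribosomal``, plus ``true_class`` for
    synthetic data with known ground truth. ``provenance`` records how the
    data came to be, including any generator seed.
    """

    fractions: pd.DataFrame
    growth_rates: pd.Series
    condition_meta: Optional[pd.DataFrame] = None
    protein_meta: Optional[pd.DataFrame] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fractions = pd.DataFrame(self.fractions).astype(float)
        self.growth_rates = pd.Series(self.growth_rates, dtype=float)
        if self.condition_meta is None:
            self.condition_meta = pd.DataFrame(
                {
                    "is_exponential": True,
                    "medium": "unspecified",
                    "control_type": "batch",
                },
                index=self.fractions.columns,
            )
        if self.protein_meta is None:
            self.protein_meta = pd.DataFrame(
                {"functional_group": "unspecified", "is_ribosomal": False},
                index=self.fractions.index,
            )
        self.validate()

    def validate(self) -> None:
        f = self.fractions
        if f.index.has_duplicates:
            raise ModelInvalidError("duplicate protein ids")
        if f.columns.has_duplicates:
            raise ModelInvalidError("duplicate condition ids")
        if (f.values[~np.isnan(f.values)] < 0).any():
            raise ModelInvalidError("mass fractions must be non-negative")
        if not self.provenance.get("normalized", False):
            # mean-normalized values are not mass fractions; only raw data
            # must respect proteome-mass conservation
            sums = f.sum(axis=0, skipna=True)
            if (sums > 1 + 1e-9).any():
                bad = sums[sums > 1 + 1e-9].index.tolist()
                raise ModelInvalidError(f"per-condition fraction sums exceed 1: {bad}")
        if not f.columns.equals(self.growth_rates.index):
            if set(f.columns) != set(self.growth_rates.index):
                raise ModelInvalidError("growth-rate index does not match condition ids")
            self.growth_rates = self.growth_rates.loc[f.columns]
        if not f.columns.equals(self.condition_meta.index):
            if set(f.columns) != set(self.condition_meta.index):
                raise ModelInvalidError("condition metadata does not match condition ids")
            self.condition_meta = self.condition_meta.loc[f.columns]
        if not f.index.equals(self.protein_meta.index):
            if set(f.index) != set(self.protein_meta.index):
                raise ModelInvalidError("protein metadata does not match protein ids")
            self.protein_meta = self.protein_meta.loc[f.index]
        expo = self.condition_meta["is_exponential"].astype(bool)
        if (self.growth_rates[expo] <= 0).any():
            raise ModelInvalidError("exponential conditions must have positive growth rate")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def n_proteins(self) -> int:
        return self.fractions.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.fractions.shape[1]

    def copy(self) -> "ProteomicsDataset":
        return ProteomicsDataset(
            self.fractions.copy(),
            self.growth_rates.copy(),
            self.condition_meta.copy(),
            self.protein_meta.copy(),
            dict(self.provenance),
        )

    def subset_conditions(self, keep: list[str]) -> "ProteomicsDataset":
        return ProteomicsDataset(
            self.fractions[keep],
            self.growth_rates.loc[keep],
            self.condition_meta.loc[keep],
            self.protein_meta.copy(),
            dict(self.provenance),
        )

    def subset_proteins(self, keep: list[str]) -> "ProteomicsDataset":
        return ProteomicsDataset(
            self.fractions.loc[keep],
            self.growth_rates.copy(),
            self.condition_meta.copy(),
            self.protein_meta.loc[keep],
            dict(self.provenance),
        )
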