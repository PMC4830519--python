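"""Generative model: intrinsic affinities, proteome fractions and growth laws.

Every gene *i* carries a condition-specific intrinsic affinity ``w_i(c)``
that lumps together its tendency to attract the shared bio-synthetic
machinery (promoter strength, RBS, transcription-factor state, ...).
Affinities only ever enter as ratios, so they are treated as dimensionless
relative weights.

The model's content is three statements:

1. Bio-synthetic resources are split in proportion to affinity, so the
   proteome fraction of gene *i* under condition *c* is
   ``p_i(c) = w_i(c) / sum_j w_j(c)``.
2. A designated bio-synthesis gene set ``G_B`` keeps constant affinities
   across conditions (summed weight ``W_B``), and the doubling time is the
   minimal doubling time ``T_B`` scaled by the proteome-to-biosynthesis
   ratio: ``tau(c) = T_B * sum_j w_j(c) / W_B``.
3. Combining the two with ``g = ln2 / tau`` gives the growth law for any
   constant-affinity gene: ``p_i = A * w_i * g`` with
   ``A = T_B / (ln2 * W_B)``; first-order degradation at rate ``alpha``
   shifts it to ``p_i = A * w_i * (g + alpha)``, and a Michaelis–Menten
   slow-down of the machinery at low growth divides by ``g / (g + g_half)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateConditionError, ModelInvalidError

LN2 = math.log(2.0)

__all__ = [
    "AffinityModel",
    "PredictionParams",
    "ConditionState",
    "proteome_fractions",
    "doubling_time",
    "growth_rate_from_doubling",
    "predicted_fraction",
    "synthesis_rate_multiplier",
    "lumped_constant",
]


@dataclass
class AffinityModel:
    """Intrinsic-affinity table plus the bio-synthesis sector.

    Parameters
    ----------
    affinities
        Genes x conditions table of non-negative affinity weights
        ``w_i(c)``. Index holds gene ids, columns hold condition ids.
    biosynthesis_ids
        Non-empty subset of the gene ids forming ``G_B``; their rows must
        be constant across conditions.
    t_b
        Minimal doubling time ``T_B`` in hours (the doubling time reached
        when the whole proteome is bio-synthetic machinery).
    """

    affinities: pd.DataFrame
    biosynthesis_ids: list[str]
    t_b: float = 1.0

    def __post_init__(self) -> None:
        self.affinities = pd.DataFrame(self.affinities).astype(float)
        self.biosynthesis_ids = list(self.biosynthesis_ids)
        self.validate()

    # -- structural invariants -------------------------------------------------

    def validate(self) -> None:
        a = self.affinities
        if a.index.has_duplicates or a.columns.has_duplicates:
            raise ModelInvalidError("duplicate gene or condition ids")
        if (a.values < 0).any() or np.isnan(a.values).any():
            raise ModelInvalidError("affinities must be finite and non-negative")
        if not self.biosynthesis_ids:
            raise ModelInvalidError("biosynthesis gene set is empty")
        missing = set(self.biosynthesis_ids) - set(a.index)
        if missing:
            raise ModelInvalidError(f"biosynthesis ids not in gene list: {sorted(missing)}")
        bio = a.loc[self.biosynthesis_ids]
        if not np.allclose(bio.values, bio.values[:, :1]):
            raise ModelInvalidError("biosynthesis gene affinities must be condition-independent")
        if self.w_b <= 0:
            raise ModelInvalidError("summed biosynthesis affinity W_B must be positive")
        if not self.t_b > 0:
            raise ModelInvalidError("minimal doubling time T_B must be positive")

    # -- derived quantities ----------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.affinities.index)

    @property
    def condition_ids(self) -> list[str]:
        return list(self.affinities.columns)

    @property
    def w_b(self) -> float:
        """Summed (condition-independent) affinity of the bio-synthesis set."""
        return float(self.affinities.loc[self.biosynthesis_ids].iloc[:, 0].sum())

    def total_affinity(self, condition: str) -> float:
        if condition not in self.affinities.columns:
            raise KeyError(f"unknown condition: {condition!r}")
        return float(self.affinities[condition].sum())

    # -- serialization ---------------------------------------------------------

    def to_config(self, path) -> None:
        """Write the model as a YAML config (genes, conditions, affinity table)."""
        payload = {
            "genes": self.gene_ids,
            "conditions": self.condition_ids,
            "affinities": {g: [float(v) for v in self.affinities.loc[g]] for g in self.gene_ids},
            "biosynthesis_ids": self.biosynthesis_ids,
            "t_b": float(self.t_b),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_config(cls, path) -> "AffinityModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        table = pd.DataFrame.from_dict(payload["affinities"], orient="index", dtype=float)
        table = table.loc[payload["genes"]]
        table.columns = payload["conditions"]
        return cls(table, payload["biosynthesis_ids"], float(payload["t_b"]))

    @classmethod
    def from_tsv(
        cls, path, biosynthesis_ids: Iterable[str], t_b: float = 1.0
    ) -> "AffinityModel":
        """Read a genes x conditions affinity matrix from a TSV file."""
        table = pd.read_csv(path, sep="\t", index_col=0)
        return cls(table, list(biosynthesis_ids), t_b)


@dataclass(frozen=True)
class PredictionParams:
    """Constants of the fraction-vs-growth-rate law.

    ``lumped_constant`` is ``A = T_B / (ln2 * W_B)`` (affinity⁻¹·time): all
    condition-independent constants folded into one factor.
    ``degradation_rate`` is the uniform first-order turnover rate ``alpha``
    in h⁻¹; it sets the extrapolated x-intercept ``-alpha`` of the law.
    ``saturation_g_half`` (h⁻¹) is the growth rate at which the machinery
    runs at half its maximal per-unit rate; 0 disables the correction.
    """

    lumped_constant: float
    degradation_rate: float = 0.0
    saturation_g_half: float = 0.0

    def __post_init__(self) -> None:
        if not self.lumped_constant > 0:
            raise ValueError("lumped_constant must be positive")
        if self.degradation_rate < 0:
            raise ValueError("degradation_rate must be non-negative")
        if self.saturation_g_half < 0:
            raise ValueError("saturation_g_half must be non-negative")


@dataclass(frozen=True)
class ConditionState:
    """Growth state of one condition (rate and doubling time are ln2-linked)."""

    condition_id: str
    growth_rate: float
    doubling_time: float
    is_exponential: bool = True

    def __post_init__(self) -> None:
        if not math.isclose(self.growth_rate * self.doubling_time, LN2, rel_tol=1e-9):
            raise ValueError("growth_rate * doubling_time must equal ln(2)")


def proteome_fractions(model: AffinityModel, condition: str) -> pd.Series:
    """Proteome fraction of every gene under one condition.

    ``p_i = w_i(c) / sum_j w_j(c)``; the returned vector is ordered like
    ``model.gene_ids`` and sums to 1.
    """
    total = model.total_affinity(condition)
    if total <= 0:
        raise DegenerateConditionError(
            f"condition {condition!r} has zero total affinity; fractions undefined"
        )
    return model.affinities[condition] / total


def doubling_time(model: AffinityModel, condition: str) -> float:
    """Doubling time ``tau(c) = T_B * sum_j w_j(c) / W_B`` in hours.

    Never less than ``T_B``, since the total affinity includes the
    bio-synthesis set itself.
    """
    w_b = model.w_b  # validate() guarantees > 0
    return model.t_b * model.total_affinity(condition) / w_b


def growth_rate_from_doubling(tau: float) -> float:
    """Specific growth rate ``g = ln2 / tau`` (h⁻¹) from a doubling time in hours."""
    if not tau > 0:
        raise ValueError(f"doubling time must be positive, got {tau}")
    return LN2 / tau


def growth_rate(model: AffinityModel, condition: str) -> float:
    """Convenience composition of :func:`doubling_time` and ``ln2/tau``."""
    return growth_rate_from_doubling(doubling_time(model, condition))


def lumped_constant(model: AffinityModel) -> float:
    """The constant ``A = T_B / (ln2 * W_B)`` of the growth law for this model."""
    return model.t_b / (LN2 * model.w_b)


def synthesis_rate_multiplier(g: float, g_half: float) -> float:
    """Michaelis–Menten factor ``g / (g + g_half)`` in (0, 1].

    Models per-machine bio-synthesis rates slowing at low growth; at
    ``g = g_half`` the machinery runs at half speed. ``g_half = 0``
    disables the correction (factor 1). ``g = 0`` with ``g_half > 0``
    is a degenerate no-synthesis state and returns the limit 0 with a
    warning.
    """
    if g < 0:
        raise ValueError("growth rate must be non-negative")
    if g_half < 0:
        raise ValueError("saturation half-max must be non-negative")
    if g_half == 0:
        return 1.0
    if g == 0:
        warnings.warn("g = 0 with saturating synthesis rate: no synthesis (degenerate)")
        return 0.0
    return g / (g + g_half)


def predicted_fraction(w_i: float, params: PredictionParams, g: float) -> float:
    """Predicted proteome fraction of a constant-affinity gene at growth rate ``g``.

    The base law is ``p_i = A * w_i * (g + alpha)`` — linear in ``g`` with
    x-intercept ``-alpha``. When ``saturation_g_half > 0`` the required
    synthesis flux is divided by the rate multiplier, which lowers the
    fitted slope and raises the intercept over any finite growth window.
    """
    if g < 0:
        raise ValueError("growth rate must be non-negative")
    p = params.lumped_constant * w_i * (g + params.degradation_rate)
    if params.saturation_g_half > 0:
        mult = synthesis_rate_multiplier(g, params.saturation_g_half)
        if mult == 0.0:
            # g = 0 limit: required fraction diverges; report inf rather than divide.
            return math.inf if p > 0 else 0.0
        p = p / mult
    if p > 1:
        warnings.warn(f"predicted fraction {p:.3g} exceeds 1; check parameters")
    return p
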