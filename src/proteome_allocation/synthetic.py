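"""Synthetic multi-condition proteomics data with known ground truth.

Three generators cover the pipeline's null and positive controls:

* :func:`simulate_from_model` — forward simulation of the affinity model
  itself (fractions from affinity competition, growth rates from the
  biosynthetic share), with multiplicative measurement noise.
* :func:`simulate_half_coordinated` — the benchmark data set in which a
  known share of proteins lies exactly on one normalized line versus
  growth rate and the rest are flat, plus 25% multiplicative noise.
* :func:`shuffle_dataset` — the permutation null: every protein's row is
  independently shuffled across conditions.

:func:`example_model` builds an affinity model whose forward simulation
has the shape of published *E. coli* data sets: ~1,200 proteins, 20
conditions, growth rates spanning 0.12–0.66 h⁻¹, a constant-affinity
(coordinated) subset including the biosynthetic sector, and
condition-regulated proteins that are induced under slow growth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_model import AffinityModel, doubling_time, growth_rate_from_doubling, proteome_fractions
from .datasets import NoiseSpec, ProteomicsDataset
from .errors import ModelInvalidError

__all__ = [
    "simulate_from_model",
    "simulate_half_coordinated",
    "shuffle_dataset",
    "example_model",
    "default_growth_rates",
]


def _noise_factors(rng: np.random.Generator, shape, cv: float) -> np.ndarray:
    """Multiplicative noise ``max(0, N(1, cv))`` — truncation avoids negative mass."""
    if cv == 0:
        return np.ones(shape)
    return np.maximum(0.0, rng.normal(1.0, cv, size=shape))


def simulate_from_model(model: AffinityModel, noise: NoiseSpec = NoiseSpec(cv=0.0)) -> ProteomicsDataset:
    """Forward-simulate a proteomics data set from an affinity model.

    Noise-free fractions are the affinity-competition fractions per
    condition; growth rates come from the biosynthetic-share doubling
    time. Measurement noise is applied multiplicatively per entry and each
    column is then re-expressed as a fraction of its measured total — the
    normalization inherent to relative (fraction-of-proteome)
    quantification — so columns always sum to 1. At ``cv = 0`` the output
    equals the model fractions exactly.
    """
    rng = np.random.default_rng(noise.seed)
    cols = {}
    rates = {}
    for cond in model.condition_ids:
        cols[cond] = proteome_fractions(model, cond)
        rates[cond] = growth_rate_from_doubling(doubling_time(model, cond))
    clean = pd.DataFrame(cols)[model.condition_ids]
    noisy = clean * _noise_factors(rng, clean.shape, noise.cv)
    if noise.cv > 0:
        noisy = noisy / noisy.sum(axis=0)
    is_bio = clean.index.isin(model.biosynthesis_ids)
    const = np.isclose(model.affinities.values, model.affinities.values[:, :1]).all(axis=1)
    protein_meta = pd.DataFrame(
        {
            "functional_group": np.where(is_bio, "biosynthesis", "other"),
            "is_ribosomal": is_bio,
            "true_class": np.where(const, "constant_affinity", "regulated"),
        },
        index=clean.index,
    )
    return ProteomicsDataset(
        noisy,
        pd.Series(rates)[model.condition_ids],
        protein_meta=protein_meta,
        provenance={"generator": "simulate_from_model", "cv": noise.cv, "seed": noise.seed},
    )


def simulate_half_coordinated(
    n_proteins: int = 1200,
    growth_rates: pd.Series | None = None,
    slope: float = 1.0,
    intercept: float = 0.5,
    coordinated_share: float = 0.5,
    noise: NoiseSpec = NoiseSpec(cv=0.25),
    mean_fractions: pd.Series | None = None,
    total_fraction: float = 0.6,
) -> ProteomicsDataset:
    """Benchmark data set with a known coordinated subset.

    A coordinated protein's expected fraction is
    ``mean_fraction_i * (slope * g + intercept)`` — i.e. all coordinated
    proteins share one normalized line versus growth rate — while an
    uncoordinated protein sits at ``mean_fraction_i`` in every condition.
    Multiplicative noise ``max(0, N(1, cv))`` is applied entry-wise.

    By default per-protein mean fractions are drawn log-uniformly over
    10⁻⁵–10⁻² and rescaled so the largest expected column total equals
    ``total_fraction`` (the proteome coverage of the emulated data);
    ``protein_meta['true_class']`` records the ground truth.
    """
    if not 0 <= coordinated_share <= 1:
        raise ValueError("coordinated_share must lie in [0, 1]")
    rng = np.random.default_rng(noise.seed)
    if growth_rates is None:
        growth_rates = default_growth_rates()
    growth_rates = pd.Series(growth_rates, dtype=float)
    line = slope * growth_rates.values + intercept
    if (line <= 0).any():
        raise ValueError("slope * g + intercept must be positive over the growth-rate range")

    protein_ids = [f"P{i:04d}" for i in range(n_proteins)]
    if mean_fractions is None:
        mean_fractions = pd.Series(
            np.exp(rng.uniform(np.log(1e-5), np.log(1e-2), n_proteins)), index=protein_ids
        )
    else:
        mean_fractions = pd.Series(mean_fractions, dtype=float)
        protein_ids = list(mean_fractions.index)
    if (mean_fractions <= 0).any():
        raise ValueError("mean fractions must be positive")

    n_coord = int(round(coordinated_share * len(protein_ids)))
    coord = np.zeros(len(protein_ids), dtype=bool)
    coord[:n_coord] = True

    expected = np.outer(mean_fractions.values, np.ones(len(growth_rates)))
    expected[coord] = np.outer(mean_fractions.values[coord], line)
    # rescale to the target proteome coverage so columns remain valid fractions
    scale = total_fraction / expected.sum(axis=0).max()
    expected *= scale

    values = expected * _noise_factors(rng, expected.shape, noise.cv)
    fractions = pd.DataFrame(values, index=protein_ids, columns=growth_rates.index)
    protein_meta = pd.DataFrame(
        {
            "functional_group": "synthetic",
            "is_ribosomal": False,
            "true_class": np.where(coord, "coordinated", "uncoordinated"),
        },
        index=protein_ids,
    )
    return ProteomicsDataset(
        fractions,
        growth_rates,
        protein_meta=protein_meta,
        provenance={
            "generator": "simulate_half_coordinated",
            "slope": slope,
            "intercept": intercept,
            "coordinated_share": coordinated_share,
            "cv": noise.cv,
            "seed": noise.seed,
        },
    )


def shuffle_dataset(data: ProteomicsDataset, seed: int = 0) -> ProteomicsDataset:
    """Permutation null: independently permute each protein's row across conditions.

    Growth rates and all metadata are unchanged; each row keeps its
    multiset of values, so per-protein means and variances survive while
    any relation to growth rate is destroyed.
    """
    if data.n_conditions < 2:
        raise ValueError("need at least 2 conditions to shuffle")
    rng = np.random.default_rng(seed)
    values = data.fractions.values.copy()
    for i in range(values.shape[0]):
        values[i] = values[i, rng.permutation(values.shape[1])]
    out = data.copy()
    out.fractions = pd.DataFrame(values, index=data.fractions.index, columns=data.fractions.columns)
    out.provenance = dict(data.provenance, shuffled_with_seed=seed)
    return out


def default_growth_rates(n_conditions: int = 20, low: float = 0.12, high: float = 0.66) -> pd.Series:
    """Evenly spaced growth-rate grid over the span of the emulated data sets."""
    return pd.Series(
        np.linspace(low, high, n_conditions),
        index=[f"C{i:02d}" for i in range(n_conditions)],
    )


def example_model(
    n_genes: int = 1200,
    n_conditions: int = 20,
    constant_share: float = 0.5,
    biosynthesis_share: float = 0.05,
    t_b: float | None = None,
    growth_rates: pd.Series | None = None,
    seed: int = 0,
) -> AffinityModel:
    """Affinity model whose forward simulation resembles the published data sets.

    Half the genes (including the biosynthetic sector) keep constant
    affinities; the other half are condition-regulated proteins induced
    progressively under harsher (slower) conditions. Per-condition totals
    of the regulated set are solved so that the growth rates land exactly
    on the requested grid (default 0.12–0.66 h⁻¹ over 20 conditions).
    ``t_b`` defaults to the value that places the fastest condition at the
    top of the grid while regulated proteins still hold a positive share.
    """
    rng = np.random.default_rng(seed)
    if growth_rates is None:
        growth_rates = default_growth_rates(n_conditions)
    growth_rates = pd.Series(growth_rates, dtype=float)
    conditions = list(growth_rates.index)

    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    base = np.exp(rng.uniform(np.log(1e-5), np.log(1e-2), n_genes))
    n_const = int(round(constant_share * n_genes))
    n_bio = max(1, int(round(biosynthesis_share * n_genes)))
    if n_bio > n_const:
        raise ValueError("biosynthesis genes must fit inside the constant-affinity set")
    bio_ids = gene_ids[:n_bio]
    const_mask = np.zeros(n_genes, dtype=bool)
    const_mask[:n_const] = True

    w_const = base[const_mask].sum()
    w_b = base[:n_bio].sum()
    ln2 = np.log(2.0)
    g = growth_rates.values
    if t_b is None:
        # fastest condition: regulated set holds 10% of total affinity
        t_b = ln2 * w_b / (g.max() * w_const / 0.9)
    # per-condition total affinity required to hit each growth rate exactly
    total = ln2 * w_b / (t_b * g)
    var_total = total - w_const
    if (var_total <= 0).any():
        raise ModelInvalidError("t_b too large: regulated share non-positive at fast growth")

    table = np.tile(base[:, None], (1, len(conditions)))
    var_base = base[~const_mask]
    # regulated genes share one induction profile; scale to the solved totals
    table[~const_mask] = np.outer(var_base / var_base.sum(), var_total)
    aff = pd.DataFrame(table, index=gene_ids, columns=conditions)
    return AffinityModel(aff, bio_ids, t_b)
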