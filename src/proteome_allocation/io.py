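"""Readers and writers for the tab-separated data-set trio.

A data set on disk is three TSV files: the fractions matrix (protein-id
first column, condition-id header, empty cells = missing), a condition
metadata table (condition_id, growth_rate in h⁻¹, is_exponential, medium,
control_type) and an optional protein metadata table (protein_id,
functional_group, is_ribosomal, optionally true_class). UTF-8, "."
decimal, header row mandatory.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ProteomicsDataset

__all__ = ["read_dataset", "write_dataset"]


def read_dataset(fractions_path, conditions_path, proteins_path=None) -> ProteomicsDataset:
    """Load and validate a data set from its TSV trio.

    Conditions present in the matrix but absent from the metadata (or
    vice versa), duplicate ids and non-numeric fractions are hard errors;
    empty cells parse as missing, not zero.
    """
    fractions = pd.read_csv(fractions_path, sep="\t", index_col=0, float_precision="round_trip")
    if fractions.index.has_duplicates:
        dups = fractions.index[fractions.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate protein ids in {fractions_path}: {dups}")
    try:
        fractions = fractions.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric fraction value in {fractions_path}: {exc}") from exc

    cond = pd.read_csv(conditions_path, sep="\t", index_col=0, float_precision="round_trip")
    if cond.index.has_duplicates:
        raise ValueError(f"duplicate condition ids in {conditions_path}")
    unknown = [c for c in fractions.columns if c not in cond.index]
    if unknown:
        raise ValueError(f"conditions in matrix missing from metadata: {unknown}")
    cond = cond.loc[list(fractions.columns)]
    if "growth_rate" not in cond.columns:
        raise ValueError(f"{conditions_path} must carry a growth_rate column")
    growth_rates = cond["growth_rate"].astype(float)
    meta_cols = {}
    meta_cols["is_exponential"] = (
        cond["is_exponential"].astype(bool) if "is_exponential" in cond.columns else True
    )
    meta_cols["medium"] = cond.get("medium", pd.Series("unspecified", index=cond.index))
    meta_cols["control_type"] = cond.get("control_type", pd.Series("batch", index=cond.index))
    condition_meta = pd.DataFrame(meta_cols, index=cond.index)

    protein_meta = None
    if proteins_path is not None:
        prot = pd.read_csv(proteins_path, sep="\t", index_col=0)
        if prot.index.has_duplicates:
            raise ValueError(f"duplicate protein ids in {proteins_path}")
        missing = [p for p in fractions.index if p not in prot.index]
        if missing:
            raise ValueError(f"proteins in matrix missing from metadata: {missing[:5]}")
        protein_meta = prot.loc[list(fractions.index)]
        if "is_ribosomal" in protein_meta.columns:
            protein_meta["is_ribosomal"] = protein_meta["is_ribosomal"].astype(bool)

    return ProteomicsDataset(
        fractions,
        growth_rates,
        condition_meta,
        protein_meta,
        provenance={"fractions_path": str(fractions_path)},
    )


def write_dataset(data: ProteomicsDataset, out_dir, prefix: str = "dataset") -> dict[str, Path]:
    """Write the TSV trio; round-trips bit-exactly through :func:`read_dataset`."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fractions": out_dir / f"{prefix}_fractions.tsv",
        "conditions": out_dir / f"{prefix}_conditions.tsv",
        "proteins": out_dir / f"{prefix}_proteins.tsv",
    }
    frame = data.fractions.copy()
    frame.index.name = "protein_id"
    frame.to_csv(paths["fractions"], sep="\t")

    cond = data.condition_meta.copy()
    cond.insert(0, "growth_rate", data.growth_rates)
    cond.index.name = "condition_id"
    cond.to_csv(paths["conditions"], sep="\t")

    prot = data.protein_meta.copy()
    prot.index.name = "protein_id"
    prot.to_csv(paths["proteins"], sep="\t")
    return paths
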