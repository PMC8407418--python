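"""Absolute abundance: cells per gram of soil from relative abundance.

Two census models are exposed:

Model A (``cell_fraction``)
    cells/g = cell_fraction x N_total, with N_total the assumed total
    microbial cell density of soil (default 1e9 cells/g, the standard
    order-of-magnitude estimate). This is the default model: a lineage at a
    community fraction of 1e-7 of 1e9 cells/g is 100 cells/g, i.e. 1e-5 % of
    cells.

Model B (``dna_mass``)
    genome copies/g = (DNA yield per gram x base_fraction) /
    (genome_length x mass_per_bp), with mass_per_bp = 650 g/mol/bp divided
    by Avogadro's number = 1.079e-21 g/bp. Reported as cells/g under a
    one-genome-copy-per-cell assumption.

Both models are linear in abundance. Estimates below one cell per gram are
reported as-is with a ``sub_unity`` flag, never rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

#: grams per base pair of double-stranded DNA (650 g/mol/bp over Avogadro)
MASS_PER_BP_G = 1.079e-21

NG_PER_G = 1e9


@dataclass(frozen=True)
class CensusParameters:
    total_cells_per_gram: float = 1e9
    dna_yield_ng_per_gram: float | None = None
    mass_per_bp_g: float = MASS_PER_BP_G
    model: str = "cell_fraction"

    def __post_init__(self) -> None:
        if self.total_cells_per_gram <= 0:
            raise ValueError("total_cells_per_gram must be positive")
        if self.mass_per_bp_g <= 0:
            raise ValueError("mass_per_bp_g must be positive")
        if self.dna_yield_ng_per_gram is not None and self.dna_yield_ng_per_gram <= 0:
            raise ValueError("dna_yield_ng_per_gram must be positive when set")
        if self.model not in {"cell_fraction", "dna_mass"}:
            raise ValueError(f"unknown census model {self.model!r}")


@dataclass(frozen=True)
class CensusEstimate:
    bin_id: str
    cells_per_gram: float
    percent_of_community: float
    model: str
    parameters: CensusParameters = field(repr=False, default=CensusParameters())

    @property
    def sub_unity(self) -> bool:
        return self.cells_per_gram < 1.0


def cells_per_gram_cellfraction(
    cell_fraction: float,
    params: CensusParameters | None = None,
    bin_id: str = "",
) -> CensusEstimate:
    """Model A: cells/g = cell_fraction x N_total; percent = 100 x fraction."""
    params = params or CensusParameters()
    if not 0.0 <= cell_fraction <= 1.0:
        raise ValueError(f"cell_fraction outside [0, 1]: {cell_fraction}")
    cells = cell_fraction * params.total_cells_per_gram
    return CensusEstimate(bin_id, cells, cell_fraction * 100.0, "cell_fraction", params)


def percent_of_community(cells_per_gram: float, n_total: float) -> float:
    """Percent of the whole community that ``cells_per_gram`` represents."""
    if cells_per_gram < 0 or n_total < 0:
        raise ValueError("inputs must be non-negative")
    if n_total == 0:
        raise ValueError("n_total must be positive")
    return 100.0 * cells_per_gram / n_total


def cells_per_gram_dnamass(
    base_fraction: float,
    genome_length_bp: float,
    params: CensusParameters,
    bin_id: str = "",
) -> CensusEstimate:
    """Model B: genome copies/g from the DNA mass attributable to the genome."""
    if not 0.0 <= base_fraction <= 1.0:
        raise ValueError(f"base_fraction outside [0, 1]: {base_fraction}")
    if genome_length_bp <= 0:
        raise ValueError("genome_length_bp must be positive")
    if params.dna_yield_ng_per_gram is None:
        raise ValueError("the dna_mass model requires dna_yield_ng_per_gram")
    yield_g = params.dna_yield_ng_per_gram / NG_PER_G
    cells = (yield_g * base_fraction) / (genome_length_bp * params.mass_per_bp_g)
    percent = percent_of_community(cells, params.total_cells_per_gram)
    return CensusEstimate(bin_id, cells, percent, "dna_mass", params)


def census_table(
    abundance: Mapping[str, float] | pd.Series,
    params: CensusParameters | None = None,
    genome_lengths: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Apply the configured census model to a per-bin abundance series."""
    params = params or CensusParameters()
    abundance = pd.Series(abundance, dtype=float)
    rows = []
    for bin_id, frac in abundance.items():
        if params.model == "cell_fraction":
            est = cells_per_gram_cellfraction(float(frac), params, str(bin_id))
        else:
            if genome_lengths is None or bin_id not in genome_lengths:
                raise ValueError(f"dna_mass model needs a genome length for {bin_id}")
            est = cells_per_gram_dnamass(
                float(frac), float(genome_lengths[bin_id]), params, str(bin_id)
            )
        rows.append(
            (est.bin_id, est.model, est.cells_per_gram, est.percent_of_community,
             est.sub_unity)
        )
    return pd.DataFrame(
        rows,
        columns=["bin_id", "model", "cells_per_gram", "percent_of_community",
                 "sub_unity"],
    ).set_index("bin_id")
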