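"""Concentrate-over-bulk enrichment factors with detection-limit handling.

The enrichment factor E of a unit (scaffold or bin) is its relative
abundance in the concentrate sample divided by its relative abundance in the
bulk sample. Rare organisms are routinely at zero observed bulk abundance,
so zeros are the common case and are reported honestly: E then becomes a
*lower bound* computed against an explicit detection floor (by default the
base fraction a single read would contribute), flagged as such and never
silently averaged into summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class UndefinedEnrichmentError(ValueError):
    """Both abundances are zero; no enrichment factor is defined."""


@dataclass(frozen=True)
class EnrichmentResult:
    unit_id: str
    E: float
    ra_concentrate: float
    ra_bulk: float
    bulk_below_detection: bool
    floor_used: float | None = None

    def __post_init__(self) -> None:
        if self.bulk_below_detection and self.floor_used is None:
            raise ValueError("a lower-bound result must record the floor used")


def enrichment_factor(
    ra_concentrate: float,
    ra_bulk: float,
    detection_floor: float,
    unit_id: str = "",
) -> EnrichmentResult:
    """E = ra_concentrate / ra_bulk; zero bulk gives a flagged lower bound.

    ``detection_floor`` is the smallest bulk abundance the sample could have
    detected (see :func:`default_detection_floor`); it replaces a zero bulk
    denominator so the result is a conservative lower bound on E.
    """
    if not (0.0 <= ra_concentrate <= 1.0) or not (0.0 <= ra_bulk <= 1.0):
        raise ValueError("relative abundances must lie in [0, 1]")
    if detection_floor <= 0:
        raise ValueError(f"detection_floor must be positive, got {detection_floor}")
    if ra_concentrate == 0.0 and ra_bulk == 0.0:
        raise UndefinedEnrichmentError(
            f"unit {unit_id or '<unnamed>'}: both abundances are zero"
        )
    if ra_bulk > 0.0:
        return EnrichmentResult(unit_id, ra_concentrate / ra_bulk,
                                ra_concentrate, ra_bulk, False, None)
    return EnrichmentResult(unit_id, ra_concentrate / detection_floor,
                            ra_concentrate, ra_bulk, True, detection_floor)


def default_detection_floor(total_mapped_bases_bulk: float, read_length: float) -> float:
    """Base fraction a single mapped read contributes to the bulk sample."""
    if total_mapped_bases_bulk <= 0 or read_length <= 0:
        raise ValueError("total mapped bases and read length must be positive")
    return read_length / total_mapped_bases_bulk


def enrichment_table(
    bulk: Mapping[str, float] | pd.Series,
    concentrate: Mapping[str, float] | pd.Series,
    detection_floor: float,
) -> pd.DataFrame:
    """Per-unit enrichment for units present in either abundance table.

    Units absent from a table count as zero abundance there; units at zero in
    both are dropped (no enrichment is defined for them).
    """
    bulk = pd.Series(bulk, dtype=float)
    concentrate = pd.Series(concentrate, dtype=float)
    units = bulk.index.union(concentrate.index)
    rows = []
    for unit in units:
        rb = float(bulk.get(unit, 0.0))
        rc = float(concentrate.get(unit, 0.0))
        if rb == 0.0 and rc == 0.0:
            continue
        res = enrichment_factor(rc, rb, detection_floor, unit_id=str(unit))
        rows.append(
            (res.unit_id, res.ra_bulk, res.ra_concentrate, res.E,
             res.bulk_below_detection, res.floor_used)
        )
    return pd.DataFrame(
        rows,
        columns=["unit_id", "ra_bulk", "ra_concentrate", "E", "is_lower_bound", "floor"],
    ).set_index("unit_id")


def summarize_enrichment(
    results: Iterable[EnrichmentResult],
    bin_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-bin medians and quartiles over finite E values.

    Lower-bound results are counted (``n_lower_bound``) but never averaged
    into the order statistics; a bin with only lower bounds is flagged
    ``lower_bound_only`` with NaN summary statistics.
    """
    groups: dict[str, list[EnrichmentResult]] = {}
    for res in results:
        bin_id = bin_of.get(res.unit_id, res.unit_id) if bin_of else res.unit_id
        groups.setdefault(bin_id, []).append(res)
    if not groups:
        raise ValueError("need at least one enrichment result")
    rows = []
    for bin_id in sorted(groups):
        members = groups[bin_id]
        finite = [r.E for r in members if not r.bulk_below_detection]
        n_lb = sum(r.bulk_below_detection for r in members)
        if finite:
            med = float(np.median(finite))
            q1, q3 = (float(q) for q in np.percentile(finite, [25, 75]))
        else:
            med = q1 = q3 = math.nan
        rows.append((bin_id, med, q1, q3, len(members), n_lb, not finite))
    return pd.DataFrame(
        rows,
        columns=["bin_id", "median_E", "q1_E", "q3_E", "n", "n_lower_bound",
                 "lower_bound_only"],
    ).set_index("bin_id")


def results_from_table(df: pd.DataFrame) -> list[EnrichmentResult]:
    """Rehydrate :class:`EnrichmentResult` rows from :func:`enrichment_table` output."""
    out = []
    for unit_id, row in df.iterrows():
        out.append(
            EnrichmentResult(
                str(unit_id), float(row["E"]), float(row["ra_concentrate"]),
                float(row["ra_bulk"]), bool(row["is_lower_bound"]),
                None if pd.isna(row["floor"]) else float(row["floor"]),
            )
        )
    return out
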