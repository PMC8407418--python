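"""Per-scaffold depth/breadth profiles and relative-abundance tables.

Depth is the mean read depth over *all* positions of a scaffold (positions
absent from the depth file count as zero). Breadth is the fraction of
positions covered at or above ``breadth_min_depth``. Two relative-abundance
normalisations are kept explicit:

``base_fraction``
    depth x length of the unit over the sample total — the fraction of
    sequenced bases attributable to the unit. Used for scaffold-level
    enrichment factors.
``cell_fraction``
    length-weighted mean depth of a bin over the sum across bins — a proxy
    for the fraction of cells, since one cell contributes one genome copy's
    worth of depth regardless of genome size. Used for the cell census.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ScaffoldProfile:
    """Coverage summary for one scaffold in one sample."""

    scaffold_id: str
    sample_id: str
    length_bp: int
    mean_depth: float
    breadth: float

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError(f"breadth outside [0, 1]: {self.breadth}")
        if self.mean_depth == 0.0 and self.breadth != 0.0:
            raise ValueError("zero mean depth implies zero breadth")

    @property
    def covered_bp(self) -> float:
        return self.breadth * self.length_bp

    @property
    def base_units(self) -> float:
        """depth x length — the scaffold's share of sequenced bases."""
        return self.mean_depth * self.length_bp


def profile_scaffold(
    depth_records: tuple[np.ndarray, np.ndarray] | Iterable[tuple[int, int]],
    scaffold_id: str,
    length_bp: int,
    sample_id: str = "sample",
    breadth_min_depth: int = 1,
) -> ScaffoldProfile:
    """Summarise depth records (1-based position, depth) for one scaffold.

    Records may omit zero-depth positions or list them explicitly; both
    dialects give identical profiles. Out-of-range or duplicated positions
    raise ``ValueError`` naming the scaffold and position.
    """
    if length_bp <= 0:
        raise ValueError(f"length_bp must be positive, got {length_bp}")
    if isinstance(depth_records, tuple) and len(depth_records) == 2:
        pos, depth = depth_records
    else:
        rows = list(depth_records)
        if rows:
            pos, depth = (np.asarray(x, dtype=np.int64) for x in zip(*rows))
        else:
            pos = depth = np.empty(0, dtype=np.int64)
    pos = np.asarray(pos, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    if pos.size:
        bad = (pos < 1) | (pos > length_bp)
        if bad.any():
            p = int(pos[bad][0])
            raise ValueError(
                f"position {p} outside scaffold {scaffold_id} (length {length_bp})"
            )
        uniq, counts = np.unique(pos, return_counts=True)
        if (counts > 1).any():
            p = int(uniq[counts > 1][0])
            raise ValueError(f"duplicate position {p} on scaffold {scaffold_id}")
        if (depth < 0).any():
            raise ValueError(f"negative depth on scaffold {scaffold_id}")
    mean_depth = float(depth.sum()) / length_bp
    covered = int((depth >= breadth_min_depth).sum())
    return ScaffoldProfile(
        scaffold_id=scaffold_id,
        sample_id=sample_id,
        length_bp=length_bp,
        mean_depth=mean_depth,
        breadth=covered / length_bp,
    )


def profile_from_vector(
    vec: np.ndarray,
    scaffold_id: str,
    sample_id: str = "sample",
    breadth_min_depth: int = 1,
) -> ScaffoldProfile:
    """Profile a dense per-base depth vector (index 0 is position 1)."""
    vec = np.asarray(vec)
    return ScaffoldProfile(
        scaffold_id=scaffold_id,
        sample_id=sample_id,
        length_bp=len(vec),
        mean_depth=float(vec.mean()),
        breadth=float((vec >= breadth_min_depth).mean()),
    )


def profile_sample(
    depth_table: Mapping[str, tuple[np.ndarray, np.ndarray]],
    lengths: Mapping[str, int],
    sample_id: str,
    breadth_min_depth: int = 1,
) -> list[ScaffoldProfile]:
    """Profile every scaffold in ``lengths``; scaffolds absent from the depth
    table get zero depth. Depth records for scaffolds with no known length
    raise ``KeyError`` (the depth file alone cannot define lengths)."""
    unknown = set(depth_table) - set(lengths)
    if unknown:
        raise KeyError(f"depth records for scaffolds of unknown length: {sorted(unknown)[:5]}")
    empty = (np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64))
    return [
        profile_scaffold(
            depth_table.get(scaf, empty), scaf, length, sample_id, breadth_min_depth
        )
        for scaf, length in lengths.items()
    ]


def relative_abundance(
    profiles: Sequence[ScaffoldProfile],
    unit: str = "scaffold",
) -> pd.DataFrame:
    """Base-fraction relative abundances for one sample.

    Returns a DataFrame indexed by unit id with columns ``base_fraction``
    and ``undefined``. An all-zero sample yields NaN fractions with the
    undefined flag set, never 0/0.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    samples = {p.sample_id for p in profiles}
    if len(samples) > 1:
        raise ValueError(f"profiles mix samples: {sorted(samples)}")
    if unit != "scaffold":
        raise ValueError("unit must be 'scaffold' here; use aggregate_bins for bins")
    ids = [p.scaffold_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scaffold ids in profiles")
    base_units = np.array([p.base_units for p in profiles], dtype=float)
    total = base_units.sum()
    if total == 0:
        frac = np.full(len(profiles), np.nan)
        undefined = True
    else:
        frac = base_units / total
        undefined = False
    return pd.DataFrame(
        {"base_fraction": frac, "undefined": undefined},
        index=pd.Index(ids, name="scaffold_id"),
    )


def aggregate_bins(
    profiles: Sequence[ScaffoldProfile],
    bin_membership: Mapping[str, str],
    lengths: Mapping[str, int] | None = None,
    sample_id: str | None = None,
) -> tuple[list[ScaffoldProfile], pd.DataFrame]:
    """Length-weighted aggregation of scaffold profiles to genome bins.

    Scaffolds in the membership map but missing from ``profiles`` are treated
    as zero-depth; their lengths must then come from ``lengths``. Returns the
    per-bin profiles (bin id in the scaffold_id slot) and a DataFrame with
    per-bin ``mean_depth``, ``breadth``, ``base_fraction`` and
    ``cell_fraction``.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    samples = {p.sample_id for p in profiles}
    if len(samples) > 1:
        raise ValueError(f"profiles mix samples: {sorted(samples)}")
    sample = sample_id or samples.pop()
    by_scaffold = {p.scaffold_id: p for p in profiles}

    bins: dict[str, list[ScaffoldProfile]] = {}
    for scaf, bin_id in bin_membership.items():
        prof = by_scaffold.get(scaf)
        if prof is None:
            if lengths is None or scaf not in lengths:
                raise KeyError(
                    f"scaffold {scaf} in bin {bin_id} has no profile and no stated length"
                )
            prof = ScaffoldProfile(scaf, sample, lengths[scaf], 0.0, 0.0)
        bins.setdefault(bin_id, []).append(prof)

    bin_profiles: list[ScaffoldProfile] = []
    rows = []
    for bin_id in sorted(bins):
        members = bins[bin_id]
        total_len = sum(p.length_bp for p in members)
        mean_depth = sum(p.base_units for p in members) / total_len
        breadth = sum(p.covered_bp for p in members) / total_len
        bin_profiles.append(
            ScaffoldProfile(bin_id, sample, total_len, mean_depth, breadth)
        )
        rows.append((bin_id, total_len, mean_depth, breadth))

    df = pd.DataFrame(
        rows, columns=["bin_id", "length_bp", "mean_depth", "breadth"]
    ).set_index("bin_id")
    depth_total = df["mean_depth"].sum()
    base_total = (df["mean_depth"] * df["length_bp"]).sum()
    df["base_fraction"] = (
        df["mean_depth"] * df["length_bp"] / base_total if base_total > 0 else np.nan
    )
    df["cell_fraction"] = df["mean_depth"] / depth_total if depth_total > 0 else np.nan
    df["undefined"] = depth_total == 0
    return bin_profiles, df


def write_profiles_tsv(path, profiles: Sequence[ScaffoldProfile]) -> None:
    with open(path, "w") as fh:
        fh.write("# depth TSVs are 1-based; breadth = fraction of positions at depth >= threshold\n")
        fh.write("scaffold_id\tsample_id\tlength_bp\tmean_depth\tbreadth\n")
        for p in profiles:
            fh.write(
                f"{p.scaffold_id}\t{p.sample_id}\t{p.length_bp}\t{p.mean_depth:.10g}\t{p.breadth:.10g}\n"
            )


def read_profiles_tsv(path) -> list[ScaffoldProfile]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ScaffoldProfile(
            str(r.scaffold_id), str(r.sample_id), int(r.length_bp),
            float(r.mean_depth), float(r.breadth),
        )
        for r in df.itertuples()
    ]
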