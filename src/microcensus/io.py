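"""Readers and writers for the plain-text formats the pipeline exchanges.

Conventions: depth TSVs follow samtools-depth (scaffold, 1-based position,
depth; zero-depth positions may be omitted). GFF3 coordinates are 1-based
inclusive. All internal position arrays are 0-based half-open.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO


class FormatError(ValueError):
    """A file violated the expected schema; message carries the line number."""


@dataclass(frozen=True)
class Gene:
    """A flat gene annotation (GFF3-style, 1-based inclusive coordinates)."""

    scaffold: str
    start: int
    end: int
    strand: str
    label: str | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid gene span {self.start}..{self.end} on {self.scaffold}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_depth_tsv(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read a samtools-depth-style TSV into per-scaffold position/depth arrays.

    Returns a mapping scaffold -> (positions_1based, depths). Positions are
    returned as given; validation against scaffold lengths happens in
    :func:`microcensus.coverage.profile_scaffold`.
    """
    positions: dict[str, list[int]] = {}
    depths: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            scaf, pos_s, depth_s = parts[0], parts[1], parts[2]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from None
            positions.setdefault(scaf, []).append(pos)
            depths.setdefault(scaf, []).append(depth)
    return {
        scaf: (np.asarray(positions[scaf], dtype=np.int64),
               np.asarray(depths[scaf], dtype=np.int64))
        for scaf in positions
    }


def write_depth_tsv(
    path: str | Path,
    profiles: Mapping[str, np.ndarray],
    omit_zeros: bool = True,
) -> None:
    """Write per-base depth vectors as a depth TSV (positions 1-based)."""
    with open(path, "w") as fh:
        for scaf, vec in profiles.items():
            vec = np.asarray(vec)
            if omit_zeros:
                idx = np.nonzero(vec)[0]
            else:
                idx = np.arange(len(vec))
            for i in idx:
                fh.write(f"{scaf}\t{i + 1}\t{int(vec[i])}\n")


def read_lengths(path: str | Path) -> dict[str, int]:
    """Scaffold lengths from a two-column TSV or a FASTA file (by extension)."""
    path = Path(path)
    if path.suffix.lower() in {".fa", ".fasta", ".fna"}:
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                lengths[parts[0]] = int(parts[1])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer length {parts[1]!r}") from None
    return lengths


def write_lengths(path: str | Path, lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("# scaffold_id\tlength_bp\n")
        for scaf, length in lengths.items():
            fh.write(f"{scaf}\t{length}\n")


def read_bins(path: str | Path) -> dict[str, str]:
    """Scaffold -> bin membership TSV; a scaffold in two bins is an error."""
    membership: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            scaf, bin_id = parts[0], parts[1]
            if scaf in membership and membership[scaf] != bin_id:
                raise FormatError(
                    f"{path}:{lineno}: scaffold {scaf} assigned to two bins "
                    f"({membership[scaf]}, {bin_id})"
                )
            membership[scaf] = bin_id
    return membership


def write_bins(path: str | Path, membership: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("# scaffold_id\tbin_id\n")
        for scaf, bin_id in membership.items():
            fh.write(f"{scaf}\t{bin_id}\n")


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# --- GFF3 ------------------------------------------------------------------

_GFF_COLS = 9


def read_gff3(path: str | Path) -> list[Gene]:
    """Parse flat gene features from GFF3; label comes from gene= then product=."""
    genes: list[Gene] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLS:
                raise FormatError(f"{path}:{lineno}: expected {_GFF_COLS} columns")
            scaf, _source, ftype, start_s, end_s, _score, strand, _phase, attr_s = parts
            if ftype not in {"gene", "CDS"}:
                continue
            attrs: dict[str, str] = {}
            for item in attr_s.split(";"):
                if not item:
                    continue
                key, _, value = item.partition("=")
                attrs[key.strip()] = urllib.parse.unquote(value.strip())
            label = attrs.get("gene") or attrs.get("product")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            genes.append(Gene(scaf, start, end, strand, label=label, attributes=attrs))
    return genes


def write_gff3(path: str | Path, genes: Iterable[Gene]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in enumerate(genes, 1):
            attrs = dict(g.attributes)
            attrs.setdefault("ID", f"gene_{i}")
            if g.label is not None:
                attrs.setdefault("gene", g.label)
            attr_s = ";".join(
                f"{k}={urllib.parse.quote(v, safe=' _.:-')}" for k, v in attrs.items()
            )
            fh.write(
                f"{g.scaffold}\tmicrocensus\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attr_s}\n"
            )
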