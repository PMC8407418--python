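"""In-silico PCR: IUPAC primer matching and amplicon detectability.

A primer position matches a subject base when the base belongs to the
primer code's expansion; an ambiguous subject code (other than N) matches
when the two expansions intersect; a subject N never matches — the
conservative convention for detectability claims. A sequence is detectable
by a pair when a forward-primer site and a downstream reverse-primer site
(reverse-complement matched) co-occur on the same strand with at most k
mismatches each and a product length — inclusive of both primer
footprints — inside the pair's range. Detectability is strand-symmetric:
both orientations of the template are examined.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}


def _mask(code: str) -> int:
    return sum(_BITS[b] for b in IUPAC[code])


_PRIMER_MASK = {c: _mask(c) for c in IUPAC}
# subject N matches nothing; other subject ambiguity codes match on overlap
_SUBJECT_MASK = {c: (0 if c == "N" else _mask(c)) for c in IUPAC}


def _encode(seq: str, table: Mapping[str, int], what: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq.upper()):
        m = table.get(ch)
        if m is None:
            raise ValueError(f"invalid {what} character {ch!r} at offset {i}")
        out[i] = m
    return out


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str
    max_mismatches: int = 0
    product_length_range: tuple[int, int] = (200, 600)

    def __post_init__(self) -> None:
        for primer in (self.forward, self.reverse):
            if not primer:
                raise ValueError("primers must be non-empty")
            _encode(primer, _PRIMER_MASK, "primer")
        lo, hi = self.product_length_range
        if lo > hi:
            raise ValueError("product length range min must be <= max")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")


@dataclass(frozen=True)
class PrimerHit:
    position: int  # 0-based start on the subject's plus strand
    strand: str  # '+': primer matches plus strand; '-': primer anneals minus strand
    mismatches: int


@dataclass(frozen=True)
class DetectabilityRecord:
    seq_id: str
    detectable: bool
    strand: str | None = None  # template strand carrying the amplicon
    forward_position: int | None = None
    forward_mismatches: int | None = None
    reverse_position: int | None = None
    reverse_mismatches: int | None = None
    product_length: int | None = None


@dataclass(frozen=True)
class DetectabilityReport:
    n_sequences: int
    n_undetectable: int
    records: tuple[DetectabilityRecord, ...]

    @property
    def fraction_undetectable(self) -> float:
        return self.n_undetectable / self.n_sequences


def _scan(subject: np.ndarray, primer: np.ndarray, k: int, anchor3: int,
          three_prime_at_end: bool) -> list[tuple[int, int]]:
    """All (position, mismatches) with mismatches <= k; optionally require an
    exact match over the `anchor3` primer bases at the 3' end."""
    m = len(primer)
    if len(subject) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(subject, m)
    mismatch = (windows & primer) == 0
    counts = mismatch.sum(axis=1)
    ok = counts <= k
    if anchor3 > 0:
        a = min(anchor3, m)
        region = mismatch[:, -a:] if three_prime_at_end else mismatch[:, :a]
        ok &= ~region.any(axis=1)
    return [(int(i), int(counts[i])) for i in np.nonzero(ok)[0]]


def find_primer_sites(
    sequence: str,
    primer: str,
    k: int = 0,
    three_prime_anchor: int = 0,
) -> list[PrimerHit]:
    """All primer binding sites on either strand with <= k mismatches.

    Positions are 0-based starts of the primer footprint on the plus strand;
    hits are sorted by (mismatches, position). ``three_prime_anchor`` > 0
    requires that many 3'-terminal primer bases to match exactly.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    subject = _encode(sequence, _SUBJECT_MASK, "subject")
    fwd = _encode(primer, _PRIMER_MASK, "primer")
    # a minus-strand annealing site appears on the plus strand as the
    # reverse complement of the primer; its 3' end is the window start
    rc = _encode(reverse_complement(primer), _PRIMER_MASK, "primer")
    hits = [
        PrimerHit(pos, "+", mm)
        for pos, mm in _scan(subject, fwd, k, three_prime_anchor, True)
    ] + [
        PrimerHit(pos, "-", mm)
        for pos, mm in _scan(subject, rc, k, three_prime_anchor, False)
    ]
    return sorted(hits, key=lambda h: (h.mismatches, h.position, h.strand))


def _assess_one_orientation(
    sequence: str, pair: PrimerPair, k: int, anchor: int
) -> tuple[int, int, int, int, int] | None:
    """Best (total_mm, fwd_pos, fwd_mm, rev_pos, rev_mm) for the amplicon on
    the plus strand of `sequence`, or None."""
    fwd_hits = [h for h in find_primer_sites(sequence, pair.forward, k, anchor)
                if h.strand == "+"]
    rev_hits = [h for h in find_primer_sites(sequence, pair.reverse, k, anchor)
                if h.strand == "-"]
    if not fwd_hits or not rev_hits:
        return None
    lo, hi = pair.product_length_range
    rev_len = len(pair.reverse)
    best = None
    for fh in fwd_hits:
        for rh in rev_hits:
            product = rh.position + rev_len - fh.position
            if rh.position < fh.position or not (lo <= product <= hi):
                continue
            cand = (fh.mismatches + rh.mismatches, fh.position,
                    fh.mismatches, rh.position, rh.mismatches)
            if best is None or cand < best:
                best = cand
    return best


def assess_detectability(
    sequence: str,
    pair: PrimerPair,
    seq_id: str = "",
    k: int | None = None,
    three_prime_anchor: int = 0,
) -> DetectabilityRecord:
    """Is the sequence amplifiable by the pair? Checks both template strands
    and reports the minimal-mismatch qualifying site pair."""
    k = pair.max_mismatches if k is None else k
    plus = _assess_one_orientation(sequence, pair, k, three_prime_anchor)
    minus = _assess_one_orientation(
        reverse_complement(sequence), pair, k, three_prime_anchor
    )
    if plus is None and minus is None:
        return DetectabilityRecord(seq_id, False)
    if minus is None or (plus is not None and plus <= minus):
        strand, best = "+", plus
    else:
        strand, best = "-", minus
    total_mm, fpos, fmm, rpos, rmm = best
    product = rpos + len(pair.reverse) - fpos
    return DetectabilityRecord(seq_id, True, strand, fpos, fmm, rpos, rmm, product)


def summarize_detectability(
    records: Sequence[DetectabilityRecord],
) -> DetectabilityReport:
    if not records:
        raise ValueError("need at least one record")
    n_undet = sum(not r.detectable for r in records)
    return DetectabilityReport(len(records), n_undet, tuple(records))


def screen_sequences(
    sequences: Mapping[str, str],
    pairs: Iterable[PrimerPair],
    k: int | None = None,
    three_prime_anchor: int = 0,
) -> pd.DataFrame:
    """Detectability of every sequence against every pair, as a tidy table."""
    rows = []
    for pair in pairs:
        for seq_id, seq in sequences.items():
            rec = assess_detectability(seq, pair, seq_id, k, three_prime_anchor)
            rows.append(
                (pair.name, rec.seq_id, rec.detectable, rec.strand,
                 rec.forward_position, rec.forward_mismatches,
                 rec.reverse_position, rec.reverse_mismatches, rec.product_length)
            )
    return pd.DataFrame(
        rows,
        columns=["pair", "seq_id", "detectable", "strand", "fwd_pos", "fwd_mm",
                 "rev_pos", "rev_mm", "product_length"],
    )


def load_primer_pairs(path: str | Path | None = None) -> list[PrimerPair]:
    """Primer pairs from a TSV (name/forward/reverse/max_mismatches/min/max);
    default: the packaged example pairs."""
    if path is None:
        text = (resources.files("microcensus") / "data" / "primer_pairs.tsv").read_text()
    else:
        text = Path(path).read_text()
    pairs = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise ValueError(f"primer TSV line {lineno}: expected 6 columns")
        name, fwd, rev, k_s, lo_s, hi_s = (p.strip() for p in parts)
        pairs.append(
            PrimerPair(name, fwd, rev, int(k_s), (int(lo_s), int(hi_s)))
        )
    return pairs
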