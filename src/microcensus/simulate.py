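"""Synthetic paired bulk/concentrate communities with known ground truth.

The simulator emulates the rare-biosphere structure the analysis chain
assumes: a community of genomes with log-normal cell abundances, a
designated "ultrasmall" subset that a 0.2-um filtration step enriches
100-1,000-fold in a concentrate sample relative to bulk soil, and per-base
Poisson read depth (so expected breadth follows the Lander-Waterman form
1 - e^(-c) at mean depth c). Optional planting utilities generate 16S-like
sequences with controlled primer-site mismatches, cyo-operon gene layouts,
and single-copy-gene / metabolic-marker hit tables, all with the planted
truth recorded for round-trip testing.

Composition model: genomes draw log-normal cell abundances, the ultrasmall
subset is down-weighted into the rare regime, and the planted
fold-enrichment acts on *relative abundance* (base fraction — depth x
length over the sample total), because that is the quantity read mapping
measures and the enrichment factor is defined on: concentrate base
fractions are bulk x planted fold for ultrasmall genomes and bulk x capture
fraction for everything else. Cell fractions follow by dividing base
fractions by genome length and renormalising. By default the ultrasmall
down-weighting is *solved* so that the concentrate base-fraction weights
already sum to one — then every genome's realised concentrate/bulk
abundance ratio equals its planted enrichment exactly. Passing an explicit
``rarity_factor`` instead fixes the down-weight and renormalises the
concentrate, in which case the realised enrichment (also recorded) differs
from the planted target by the common renormalisation constant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from . import io as mio
from .io import Gene
from .metabolic import MarkerPanel
from .primers import IUPAC, PrimerPair
from .qc import SCGSet

SAMPLES = ("bulk", "concentrate")


class InvalidSpecError(ValueError):
    """The community specification violates its invariants."""


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of a synthetic paired bulk/concentrate community.

    Defaults give a desk-scale study: 50 genomes of 50-150 kb (scaled-down
    stand-ins for Mb genomes), 5 ultrasmall genomes enriched 100-1,000x,
    and sequencing effort placing ultrasmall genomes below 1x in bulk and
    in the tens-of-fold range in the concentrate.
    """

    n_genomes: int = 50
    genome_length_bp: tuple[int, int] = (50_000, 150_000)
    abundance_lognormal_mu: float = 0.0
    abundance_lognormal_sigma: float = 1.0
    n_ultrasmall: int = 5
    enrichment_range: tuple[float, float] = (100.0, 1000.0)
    seq_bases_bulk: float = 2e8
    seq_bases_concentrate: float = 2e7
    concentrate_capture_of_large: float = 0.0
    rarity_factor: float | None = None
    scaffolds_per_genome: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise InvalidSpecError("n_genomes must be >= 1")
        if not (0 <= self.n_ultrasmall <= self.n_genomes):
            raise InvalidSpecError(
                f"n_ultrasmall ({self.n_ultrasmall}) must lie in [0, n_genomes]"
            )
        lo, hi = self.genome_length_bp
        if lo <= 0 or hi < lo:
            raise InvalidSpecError(f"invalid genome length range {self.genome_length_bp}")
        elo, ehi = self.enrichment_range
        if elo < 1 or ehi < elo:
            raise InvalidSpecError(f"invalid enrichment range {self.enrichment_range}")
        if self.seq_bases_bulk <= 0 or self.seq_bases_concentrate <= 0:
            raise InvalidSpecError("sequencing effort must be positive")
        if not 0.0 <= self.concentrate_capture_of_large <= 1.0:
            raise InvalidSpecError("concentrate_capture_of_large must lie in [0, 1]")
        if self.abundance_lognormal_sigma <= 0:
            raise InvalidSpecError("abundance_lognormal_sigma must be > 0")
        if self.rarity_factor is not None and self.rarity_factor <= 0:
            raise InvalidSpecError("rarity_factor must be positive when set")
        if self.scaffolds_per_genome < 1:
            raise InvalidSpecError("scaffolds_per_genome must be >= 1")
        if self.n_ultrasmall == 0 and self.concentrate_capture_of_large == 0.0:
            raise InvalidSpecError(
                "concentrate sample would be empty: no ultrasmall genomes and "
                "concentrate_capture_of_large = 0"
            )


@dataclass(frozen=True)
class GenomeTruth:
    genome_id: str
    length_bp: int
    is_ultrasmall: bool
    cell_fraction_bulk: float
    cell_fraction_concentrate: float
    base_fraction_bulk: float = 0.0
    base_fraction_concentrate: float = 0.0
    planted_enrichment: float | None = None
    realized_enrichment: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.cell_fraction_bulk <= 1.0:
            raise ValueError("cell_fraction_bulk outside [0, 1]")
        if self.is_ultrasmall != (self.planted_enrichment is not None):
            raise ValueError("planted_enrichment present iff is_ultrasmall")


@dataclass(frozen=True)
class Community:
    spec: CommunitySpec
    genomes: tuple[GenomeTruth, ...]
    calibrated: bool = True

    def cell_fractions(self, sample_id: str) -> dict[str, float]:
        if sample_id == "bulk":
            return {g.genome_id: g.cell_fraction_bulk for g in self.genomes}
        if sample_id == "concentrate":
            return {g.genome_id: g.cell_fraction_concentrate for g in self.genomes}
        raise KeyError(f"unknown sample {sample_id!r}; expected one of {SAMPLES}")

    @property
    def ultrasmall(self) -> tuple[GenomeTruth, ...]:
        return tuple(g for g in self.genomes if g.is_ultrasmall)


def build_community(spec: CommunitySpec) -> Community:
    """Draw a community satisfying the spec; deterministic under its seed."""
    rng = np.random.default_rng(spec.seed)
    n, n_us = spec.n_genomes, spec.n_ultrasmall
    lo, hi = spec.genome_length_bp
    lengths = rng.integers(lo, hi + 1, size=n)
    raw = rng.lognormal(spec.abundance_lognormal_mu, spec.abundance_lognormal_sigma, n)
    elo, ehi = spec.enrichment_range
    enrich = np.exp(rng.uniform(np.log(elo), np.log(ehi), size=n_us))
    capture = spec.concentrate_capture_of_large

    is_us = np.zeros(n, dtype=bool)
    is_us[:n_us] = True
    # base weights: cell abundance x genome length, the read-mapping scale
    base_raw = raw * lengths
    u_us, u_large = base_raw[:n_us], base_raw[n_us:]

    calibrated = False
    rarity = spec.rarity_factor
    if rarity is None and 0 < n_us < n and capture < 1.0:
        denom = float(np.sum(u_us * (enrich - 1.0)))
        if denom > 0:
            # solve the ultrasmall down-weight so the concentrate
            # base-fraction weights sum to exactly 1 (realised == planted)
            rarity = float(u_large.sum()) * (1.0 - capture) / denom
            calibrated = True
    if rarity is None:
        rarity = 1e-4  # fixed down-weight; concentrate gets renormalised

    weights = base_raw.copy()
    weights[:n_us] *= rarity
    base_bulk = weights / weights.sum()

    conc_w = np.where(is_us, 0.0, base_bulk * capture)
    conc_w[:n_us] = base_bulk[:n_us] * enrich
    z = conc_w.sum()
    if z <= 0:
        raise InvalidSpecError("concentrate sample has zero total weight")
    base_conc = conc_w / z

    cells_bulk = base_bulk / lengths
    cells_bulk /= cells_bulk.sum()
    cells_conc = base_conc / lengths
    cells_conc /= cells_conc.sum()

    genomes = []
    width = len(str(n))
    for i in range(n):
        gid = f"genome_{i + 1:0{width}d}"
        planted = float(enrich[i]) if i < n_us else None
        realized = float(base_conc[i] / base_bulk[i]) if base_bulk[i] > 0 else None
        genomes.append(
            GenomeTruth(
                genome_id=gid,
                length_bp=int(lengths[i]),
                is_ultrasmall=bool(is_us[i]),
                cell_fraction_bulk=float(cells_bulk[i]),
                cell_fraction_concentrate=float(cells_conc[i]),
                base_fraction_bulk=float(base_bulk[i]),
                base_fraction_concentrate=float(base_conc[i]),
                planted_enrichment=planted,
                realized_enrichment=realized if is_us[i] or capture > 0 else None,
            )
        )
    return Community(spec=spec, genomes=tuple(genomes), calibrated=calibrated)


def expected_depth(
    community: Community, sample_id: str, seq_bases: float | None = None
) -> dict[str, float]:
    """Expected mean depth per genome: depth_g = p_g S / sum_h p_h L_h."""
    if seq_bases is None:
        seq_bases = (
            community.spec.seq_bases_bulk
            if sample_id == "bulk"
            else community.spec.seq_bases_concentrate
        )
    if seq_bases <= 0:
        raise ValueError("seq_bases must be positive")
    fractions = community.cell_fractions(sample_id)
    total = sum(
        fractions[g.genome_id] * g.length_bp for g in community.genomes
    )
    if total == 0:
        raise ValueError(f"sample {sample_id!r} has no cells")
    return {
        g.genome_id: fractions[g.genome_id] * seq_bases / total
        for g in community.genomes
    }


def seq_bases_for_min_depth(
    community: Community,
    sample_id: str,
    target_depth: float,
    genome_ids: Sequence[str] | None = None,
) -> float:
    """Sequencing effort (bp) at which every listed genome (default: the
    ultrasmall subset) reaches at least ``target_depth`` mean coverage."""
    if target_depth <= 0:
        raise ValueError("target_depth must be positive")
    per_base = expected_depth(community, sample_id, seq_bases=1.0)
    ids = list(genome_ids) if genome_ids else [g.genome_id for g in community.ultrasmall]
    if not ids:
        raise ValueError("no genomes to target")
    slowest = min(per_base[g] for g in ids)
    if slowest <= 0:
        raise ValueError("a targeted genome has zero abundance in this sample")
    return target_depth / slowest


def simulate_depth_profile(
    length_bp: int,
    expected_depth: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Independent per-base Poisson depth at the given mean coverage."""
    if expected_depth < 0:
        raise ValueError(f"expected_depth must be >= 0, got {expected_depth}")
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    return rng.poisson(expected_depth, size=length_bp)


# --- 16S planting ----------------------------------------------------------


@dataclass(frozen=True)
class Planted16S:
    sequence: str
    forward_mismatches: int
    detectable: bool
    forward_start: int  # 0-based start of the (mutated) forward primer site
    reverse_start: int  # 0-based start of the reverse primer annealing site
    product_length: int


def _realize(primer: str, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC[c])[rng.integers(len(IUPAC[c]))] for c in primer)


def plant_16s_with_primer_sites(
    primer_pair: PrimerPair,
    mutate_forward_mismatches: int = 0,
    seed: int | None = None,
    product_length: int = 292,
    flank: int = 60,
    screen_threshold: int = 0,
    rng: np.random.Generator | None = None,
) -> Planted16S:
    """A 16S-like sequence carrying the primer pair with a controlled number
    of substitutions inside the forward-primer site.

    The amplicon (inclusive of both primer footprints) has the requested
    product length; the truth flag marks the sequence detectable iff the
    planted mismatch count is at most ``screen_threshold``. Substitutions
    are guaranteed mismatches: each replaces the realised base with one
    outside the primer code's IUPAC expansion.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    m = mutate_forward_mismatches
    fwd, rev = primer_pair.forward, primer_pair.reverse
    if m < 0 or m > len(fwd):
        raise ValueError(f"mismatch count {m} outside [0, {len(fwd)}]")
    if product_length < len(fwd) + len(rev):
        raise ValueError(
            f"product length {product_length} shorter than combined primers "
            f"({len(fwd) + len(rev)} bp)"
        )
    mutable = [i for i, c in enumerate(fwd) if len(IUPAC[c]) < 4]
    if m > len(mutable):
        raise ValueError(
            f"cannot plant {m} guaranteed mismatches: only {len(mutable)} "
            "forward-primer positions have a non-degenerate complement"
        )
    fwd_site = list(_realize(fwd, rng))
    for i in rng.choice(len(mutable), size=m, replace=False):
        pos = mutable[int(i)]
        options = sorted(set("ACGT") - IUPAC[fwd[pos]])
        fwd_site[pos] = options[rng.integers(len(options))]
    rev_site = reverse_complement(_realize(rev, rng))

    insert_len = product_length - len(fwd) - len(rev)
    bases = np.array(list("ACGT"))
    insert = "".join(rng.choice(bases, size=insert_len))
    left = "".join(rng.choice(bases, size=flank))
    right = "".join(rng.choice(bases, size=flank))
    seq = left + "".join(fwd_site) + insert + rev_site + right
    return Planted16S(
        sequence=seq,
        forward_mismatches=m,
        detectable=m <= screen_threshold,
        forward_start=len(left),
        reverse_start=len(left) + len(fwd) + insert_len,
        product_length=product_length,
    )


# --- operon planting -------------------------------------------------------

OPERON_LAYOUTS = ("reference", "inserted_orf", "reordered", "fragmented", "partial")

#: plausible cyo subunit gene lengths (bp), cyoA..cyoE
_CYO_LENGTHS = {"cyoA": 945, "cyoB": 1992, "cyoC": 615, "cyoD": 330, "cyoE": 891}
_REFERENCE_ORDER = ("cyoA", "cyoB", "cyoC", "cyoD", "cyoE")


def _lay_genes(
    labels: Sequence[str | None],
    scaffold: str,
    strand: str,
    start: int,
    rng: np.random.Generator,
) -> list[Gene]:
    spans = []
    pos = start
    for label in labels:
        length = _CYO_LENGTHS.get(label, int(rng.integers(300, 900)))
        spans.append((pos, pos + length - 1))
        pos = spans[-1][1] + 1 + int(rng.integers(5, 51))
    if strand == "-":
        total_end = spans[-1][1]
        spans = [
            (start + (total_end - e), start + (total_end - s)) for s, e in spans
        ][::-1]
        labels = list(labels)[::-1]
    return [
        Gene(scaffold, s, e, strand,
             label=(label if label is not None else "oxidoreductase"))
        for (s, e), label in zip(spans, labels)
    ]


def plant_operon(
    layout: str,
    seed: int | None = None,
    scaffold_id: str = "scaffold_op",
    strand: str = "+",
    start: int = 101,
    rng: np.random.Generator | None = None,
) -> list[Gene]:
    """Ordered, strand-consistent cyo-cluster annotations for a layout.

    ``reference`` is the E. coli K-12 order cyoA..cyoE; ``inserted_orf``
    adds one non-model ORF inside the cluster; ``reordered`` is a
    non-identity permutation; ``fragmented`` splits the cluster across two
    scaffolds; ``partial`` is a proper prefix or suffix.
    """
    if layout not in OPERON_LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {OPERON_LAYOUTS}")
    if rng is None:
        rng = np.random.default_rng(seed)
    ref = list(_REFERENCE_ORDER)
    if layout == "reference":
        return _lay_genes(ref, scaffold_id, strand, start, rng)
    if layout == "inserted_orf":
        at = int(rng.integers(1, len(ref)))
        return _lay_genes(ref[:at] + [None] + ref[at:], scaffold_id, strand, start, rng)
    if layout == "reordered":
        order = ref[:]
        while order == ref:
            order = [ref[i] for i in rng.permutation(len(ref))]
        return _lay_genes(order, scaffold_id, strand, start, rng)
    if layout == "fragmented":
        cut = int(rng.integers(1, len(ref)))
        first = _lay_genes(ref[:cut], f"{scaffold_id}_frag1", strand, start, rng)
        second = _lay_genes(ref[cut:], f"{scaffold_id}_frag2", strand, start, rng)
        return first + second
    # partial: proper prefix or suffix of length 1..4
    keep = int(rng.integers(1, len(ref)))
    labels = ref[:keep] if rng.integers(2) == 0 else ref[-keep:]
    return _lay_genes(labels, scaffold_id, strand, start, rng)


# --- QC / metabolic planting ----------------------------------------------


def plant_scg_hits(
    scg_set: SCGSet,
    n_present: int,
    n_duplicated: int,
    rng: np.random.Generator,
) -> tuple[list[str], float, float]:
    """Gene hits realising an exact completeness/contamination pair.

    Returns (hits, completeness %, contamination %) where ``n_present`` set
    genes appear and ``n_duplicated`` of those appear twice.
    """
    if not 0 <= n_duplicated <= n_present <= len(scg_set):
        raise ValueError("need 0 <= n_duplicated <= n_present <= |set|")
    order = rng.permutation(len(scg_set))
    present = [scg_set.genes[i] for i in order[:n_present]]
    hits = present + present[:n_duplicated]
    return (
        hits,
        100.0 * n_present / len(scg_set),
        100.0 * n_duplicated / len(scg_set),
    )


def plant_metabolic_hits(
    panel: MarkerPanel,
    rng: np.random.Generator,
    marker_prob: float = 0.5,
) -> tuple[list[str], dict[str, bool], dict[str, int]]:
    """Hits realising a random presence/absence truth over a marker panel.

    Returns (hits, marker truth flags, pathway member-present counts).
    Identifiers shared between a marker alias list and a pathway definition
    (e.g. sdhA, both an ETC marker and a TCA member) are never planted, so
    each planted truth is recoverable independently.
    """
    pathway_members = {m for members in panel.pathways.values() for m in members}
    alias_union = {a for aliases in panel.markers.values() for a in aliases}
    hits: list[str] = []
    marker_truth: dict[str, bool] = {}
    for name, aliases in panel.markers.items():
        present = bool(rng.random() < marker_prob)
        marker_truth[name] = present
        if present:
            alias_list = sorted(aliases - pathway_members) or sorted(aliases)
            hits.append(alias_list[int(rng.integers(len(alias_list)))])
    pathway_truth: dict[str, int] = {}
    for name, members in panel.pathways.items():
        member_list = sorted(members - alias_union)
        k = int(rng.integers(0, len(member_list) + 1))
        pathway_truth[name] = k
        hits.extend(
            member_list[i] for i in rng.choice(len(member_list), size=k, replace=False)
        )
    return hits, marker_truth, pathway_truth


# --- dataset emission ------------------------------------------------------


def split_scaffolds(community: Community) -> dict[str, tuple[str, int]]:
    """Scaffold id -> (genome id, scaffold length); genomes are split into
    spec.scaffolds_per_genome near-equal pieces."""
    k = community.spec.scaffolds_per_genome
    out: dict[str, tuple[str, int]] = {}
    for g in community.genomes:
        base, extra = divmod(g.length_bp, k)
        for i in range(k):
            out[f"{g.genome_id}_s{i + 1}"] = (g.genome_id, base + (1 if i < extra else 0))
    return out


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def write_dataset(
    community: Community,
    outdir: str | Path,
    include_fasta: bool = False,
    primer_pair: PrimerPair | None = None,
    scg_set: SCGSet | None = None,
    panel: MarkerPanel | None = None,
) -> dict:
    """Write the full synthetic dataset and its truth JSON; returns the truth.

    Files: lengths.tsv, bins.tsv, depth_bulk.tsv / depth_concentrate.tsv
    (1-based samtools-depth dialect, zero positions omitted), truth.json,
    16s.fasta, operons.gff3, gene_hits.tsv, and optionally genomes.fasta.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = community.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))

    scaffolds = split_scaffolds(community)
    mio.write_lengths(outdir / "lengths.tsv", {s: L for s, (_, L) in scaffolds.items()})
    mio.write_bins(outdir / "bins.tsv", {s: g for s, (g, _) in scaffolds.items()})

    for sample in SAMPLES:
        depths = expected_depth(community, sample)
        vectors = {
            scaf: simulate_depth_profile(L, depths[gid], rng=rng)
            for scaf, (gid, L) in scaffolds.items()
        }
        mio.write_depth_tsv(outdir / f"depth_{sample}.tsv", vectors, omit_zeros=True)

    truth: dict = {
        "spec": dataclasses.asdict(spec),
        "calibrated": community.calibrated,
        "genomes": [dataclasses.asdict(g) for g in community.genomes],
    }

    # 16S with planted forward-primer mismatches, cycling 0..3
    from .primers import load_primer_pairs

    pair = primer_pair or load_primer_pairs()[0]
    sixteen_s: dict[str, str] = {}
    truth["sixteen_s"] = {"primer_pair": pair.name, "records": []}
    targets = community.ultrasmall or community.genomes
    for i, g in enumerate(targets):
        m = i % 4
        planted = plant_16s_with_primer_sites(pair, m, rng=rng)
        name = f"{g.genome_id}_16S"
        sixteen_s[name] = planted.sequence
        truth["sixteen_s"]["records"].append(
            {"seq_id": name, "forward_mismatches": m,
             "detectable_at_k0": planted.detectable}
        )
    mio.write_fasta(outdir / "16s.fasta", sixteen_s)

    # operon layouts, cycling through all five
    genes: list[Gene] = []
    truth["operons"] = []
    for i, g in enumerate(targets):
        layout = OPERON_LAYOUTS[i % len(OPERON_LAYOUTS)]
        strand = "+" if i % 2 == 0 else "-"
        planted_genes = plant_operon(
            layout, scaffold_id=f"{g.genome_id}_op", strand=strand, rng=rng
        )
        genes.extend(planted_genes)
        truth["operons"].append({"genome_id": g.genome_id, "layout": layout,
                                 "strand": strand})
    mio.write_gff3(outdir / "operons.gff3", genes)

    # SCG + metabolic gene hits per genome
    from .qc import load_scg_set
    from .metabolic import default_panel

    scg = scg_set or load_scg_set()
    pnl = panel or default_panel()
    truth["qc"] = []
    truth["metabolic"] = []
    with open(outdir / "gene_hits.tsv", "w") as fh:
        fh.write("# bin_id\tgene_id\n")
        for g in community.genomes:
            n_present = int(rng.integers(len(scg) // 2, len(scg) + 1))
            n_dup = int(rng.integers(0, max(n_present // 5, 1)))
            hits, comp, cont = plant_scg_hits(scg, n_present, n_dup, rng)
            truth["qc"].append(
                {"bin_id": g.genome_id, "completeness": comp, "contamination": cont}
            )
            met_hits, marker_truth, pathway_truth = plant_metabolic_hits(pnl, rng)
            truth["metabolic"].append(
                {"bin_id": g.genome_id, "markers": marker_truth,
                 "pathways": pathway_truth}
            )
            for h in hits + met_hits:
                fh.write(f"{g.genome_id}\t{h}\n")

    if include_fasta:
        mio.write_fasta(
            outdir / "genomes.fasta",
            {scaf: random_sequence(L, rng) for scaf, (_, L) in scaffolds.items()},
        )

    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
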