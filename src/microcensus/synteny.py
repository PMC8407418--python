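"""Operon gene-order synteny against a reference model.

Candidate clusters of cytochrome bo3 ubiquinol oxidase genes (cyoA-cyoE by
default) are extracted from flat annotations, put in transcriptional order,
and classified by gene-order agreement with the reference operon (E. coli
K-12 order). Order conservation is scored as the longest common subsequence
(LCS) of gene labels with the reference, divided by the reference length —
a gene-order comparison, not a sequence alignment.

Classes: ``identical`` (full reference order, nothing inserted),
``identical_with_insertion`` (full order with >=1 unlabeled ORF inside, as
seen for the oxidoreductase ORF carried inside several CPR loci),
``partial`` (a proper ordered subset, e.g. an assembly-truncated locus),
``rearranged`` (>=2 shared genes out of reference order), ``fragmented``
(reference genes split across clusters/scaffolds — assigned at genome
level), ``absent``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io import Gene

CLASSES = (
    "identical", "identical_with_insertion", "partial", "rearranged",
    "fragmented", "absent",
)


@dataclass(frozen=True)
class OperonModel:
    name: str = "cyo"
    genes: tuple[str, ...] = ("cyoA", "cyoB", "cyoC", "cyoD", "cyoE")
    max_intergenic_gap_bp: int = 500

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("reference gene list must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("reference gene labels must be unique")
        if self.max_intergenic_gap_bp < 0:
            raise ValueError("max_intergenic_gap_bp must be >= 0")


@dataclass(frozen=True)
class Cluster:
    """Genes of one candidate locus, in transcriptional order."""

    scaffold_id: str
    genes: tuple[Gene, ...]
    labels: tuple[str | None, ...]  # model label or None per gene
    strand_consistent: bool

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SyntenyComparison:
    scaffold_id: str
    classification: str
    order_score: float
    insertions: int
    strand_consistent: bool
    labels: tuple[str | None, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.classification not in CLASSES:
            raise ValueError(f"unknown classification {self.classification!r}")


def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Annotation-product synonym -> model label map (case-folded keys)."""
    if path is None:
        text = (resources.files("microcensus") / "data" / "cyo_synonyms.tsv").read_text()
    else:
        text = Path(path).read_text()
    synonyms: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"synonym TSV line {lineno}: expected 2 columns")
        synonyms[parts[0].strip().casefold()] = parts[1].strip()
    return synonyms


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Longest common subsequence length (dynamic programming)."""
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0]
        for j, y in enumerate(b, 1):
            cur.append(prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def _model_label(gene: Gene, model: OperonModel, synonyms: Mapping[str, str]) -> str | None:
    if gene.label is None:
        return None
    label = synonyms.get(gene.label.casefold(), gene.label)
    by_fold = {g.casefold(): g for g in model.genes}
    return by_fold.get(label.casefold())


def extract_clusters(
    annotations: Iterable[Gene],
    model: OperonModel | None = None,
    synonyms: Mapping[str, str] | None = None,
) -> list[Cluster]:
    """Group annotations into candidate operon clusters.

    Same-scaffold genes are chained while successive intergenic gaps stay
    within ``model.max_intergenic_gap_bp``; a chain containing at least one
    model gene is trimmed to the span between its first and last model gene,
    keeping unlabeled ORFs that lie inside. Clusters whose genes all sit on
    the minus strand are reported in transcriptional (reversed coordinate)
    order.
    """
    model = model or OperonModel()
    synonyms = load_synonyms() if synonyms is None else synonyms
    by_scaffold: dict[str, list[Gene]] = {}
    seen: set[tuple[str, int, int, str | None]] = set()
    for g in annotations:
        key = (g.scaffold, g.start, g.end, g.label)
        if key in seen:
            raise ValueError(
                f"duplicate annotation {g.label!r} at {g.scaffold}:{g.start}-{g.end}"
            )
        seen.add(key)
        by_scaffold.setdefault(g.scaffold, []).append(g)

    clusters: list[Cluster] = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(by_scaffold[scaffold], key=lambda g: (g.start, g.end))
        chains: list[list[Gene]] = []
        for g in genes:
            if chains and g.start - chains[-1][-1].end - 1 <= model.max_intergenic_gap_bp:
                chains[-1].append(g)
            else:
                chains.append([g])
        for chain in chains:
            idx = [
                i for i, g in enumerate(chain)
                if _model_label(g, model, synonyms) is not None
            ]
            if not idx:
                continue
            members = chain[idx[0] : idx[-1] + 1]
            strands = {g.strand for g in members}
            if strands == {"-"}:
                members = members[::-1]
            clusters.append(
                Cluster(
                    scaffold_id=scaffold,
                    genes=tuple(members),
                    labels=tuple(_model_label(g, model, synonyms) for g in members),
                    strand_consistent=len(strands) == 1,
                )
            )
    return clusters


def _classify_labels(
    labels: Sequence[str | None], model: OperonModel
) -> tuple[str, float, int]:
    ref = list(model.genes)
    labeled = [l for l in labels if l is not None]
    insertions = sum(
        1 for l in labels[_first(labels) : _last(labels) + 1] if l is None
    ) if labeled else len(labels)
    lcs = lcs_length(labeled, ref)
    ref_counts = Counter(ref)
    lab_counts = Counter(labeled)
    overlap = sum(min(lab_counts[g], ref_counts[g]) for g in ref_counts)
    score = lcs / len(ref)
    if overlap == 0:
        return "absent", 0.0, insertions
    if labeled == ref:
        cls = "identical" if insertions == 0 else "identical_with_insertion"
        return cls, score, insertions
    if lcs < overlap:
        return "rearranged", score, insertions
    return "partial", score, insertions


def _first(labels: Sequence[str | None]) -> int:
    return next(i for i, l in enumerate(labels) if l is not None)


def _last(labels: Sequence[str | None]) -> int:
    return len(labels) - 1 - _first(labels[::-1])


def classify_cluster(cluster: Cluster, model: OperonModel | None = None) -> SyntenyComparison:
    """Classify one extracted cluster against the reference gene order."""
    model = model or OperonModel()
    if not cluster.genes:
        raise ValueError("empty cluster")
    cls, score, insertions = _classify_labels(cluster.labels, model)
    return SyntenyComparison(
        scaffold_id=cluster.scaffold_id,
        classification=cls,
        order_score=score,
        insertions=insertions,
        strand_consistent=cluster.strand_consistent,
        labels=cluster.labels,
    )


def classify_genome(
    clusters: Sequence[Cluster], model: OperonModel | None = None
) -> SyntenyComparison:
    """Genome-level verdict over all of a genome's candidate clusters.

    One cluster classifies as itself; reference genes split across two or
    more clusters yield ``fragmented`` (order scored over the concatenation
    of the clusters' labels, clusters in scaffold/coordinate order).
    """
    model = model or OperonModel()
    with_model = [c for c in clusters if any(l is not None for l in c.labels)]
    if not with_model:
        return SyntenyComparison("*", "absent", 0.0, 0, True)
    if len(with_model) == 1:
        return classify_cluster(with_model[0], model)
    ordered = sorted(with_model, key=lambda c: (c.scaffold_id, c.genes[0].start))
    labels: list[str | None] = []
    for c in ordered:
        labels.extend(c.labels)
    labeled = [l for l in labels if l is not None]
    score = lcs_length(labeled, list(model.genes)) / len(model.genes)
    return SyntenyComparison(
        scaffold_id=",".join(c.scaffold_id for c in ordered),
        classification="fragmented",
        order_score=score,
        insertions=sum(sum(1 for l in c.labels if l is None) for c in ordered),
        strand_consistent=all(c.strand_consistent for c in ordered),
        labels=tuple(labels),
    )


def render_diagram(cluster: Cluster) -> str:
    """One-line text synteny diagram of a cluster in transcriptional order."""
    parts = [
        (l if l is not None else f"[{g.label or 'ORF'}]")
        for g, l in zip(cluster.genes, cluster.labels)
    ]
    strand = cluster.genes[0].strand if cluster.strand_consistent else "+/-"
    return f"{cluster.scaffold_id} ({strand}): " + " > ".join(parts)


def comparisons_table(comparisons: Sequence[SyntenyComparison]):
    import pandas as pd

    return pd.DataFrame(
        [
            (c.scaffold_id, c.classification, c.order_score, c.insertions,
             c.strand_consistent,
             " > ".join(l or "[ORF]" for l in c.labels))
            for c in comparisons
        ],
        columns=["scaffold_id", "classification", "order_score", "insertions",
                 "strand_consistent", "gene_order"],
    )
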