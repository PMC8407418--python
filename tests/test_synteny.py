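"""Operon cluster extraction and gene-order classification."""

from itertools import combinations

import pytest

from microcensus import OperonModel, classify_cluster, extract_clusters
from microcensus.io import Gene
from microcensus.simulate import OPERON_LAYOUTS, plant_operon
from microcensus.synteny import (
    Cluster,
    classify_genome,
    lcs_length,
    load_synonyms,
    render_diagram,
)

REF = ("cyoA", "cyoB", "cyoC", "cyoD", "cyoE")


def _genes(labels, scaffold="s1", strand="+", gap=50, start=1, length=300):
    genes, pos = [], start
    for label in labels:
        genes.append(Gene(scaffold, pos, pos + length - 1, strand, label=label))
        pos += length + gap
    return genes


class TestExtractClusters:
    def test_contiguous_plus_strand_cluster(self):
        clusters = extract_clusters(_genes(REF))
        assert len(clusters) == 1
        assert clusters[0].labels == REF
        assert clusters[0].strand_consistent

    def test_minus_strand_reported_in_transcriptional_order(self):
        # coordinates ascending A..E but on the minus strand: transcription
        # reads E..A, so a minus-strand operon laid E..A in coordinates
        # comes back as A..E
        clusters = extract_clusters(_genes(REF[::-1], strand="-"))
        assert clusters[0].labels == REF

    def test_large_gap_splits_cluster(self):
        genes = _genes(REF[:3]) + _genes(REF[3:], start=20_000)
        clusters = extract_clusters(genes)
        assert [c.labels for c in clusters] == [REF[:3], REF[3:]]

    def test_unlabeled_orf_between_model_genes_is_kept(self):
        genes = _genes(["cyoA", "cyoB", "oxidoreductase", "cyoC", "cyoD", "cyoE"])
        clusters = extract_clusters(genes)
        assert clusters[0].labels == ("cyoA", "cyoB", None, "cyoC", "cyoD", "cyoE")

    def test_flanking_non_model_genes_trimmed(self):
        genes = _genes(["recA", *REF, "gyrB"])
        clusters = extract_clusters(genes)
        assert clusters[0].labels == REF

    def test_product_synonyms_mapped(self):
        labels = ["cytochrome o ubiquinol oxidase subunit II", "heme O synthase"]
        clusters = extract_clusters(_genes(labels), synonyms=load_synonyms())
        assert clusters[0].labels == ("cyoA", "cyoE")

    def test_duplicate_annotation_rejected(self):
        g = Gene("s1", 1, 300, "+", label="cyoA")
        with pytest.raises(ValueError, match="duplicate"):
            extract_clusters([g, g])


class TestClassifyCluster:
    def _cluster(self, labels):
        clusters = extract_clusters(_genes(labels))
        assert len(clusters) == 1
        return clusters[0]

    def test_reference_is_identical_score_one(self):
        res = classify_cluster(self._cluster(list(REF)))
        assert res.classification == "identical"
        assert res.order_score == 1.0
        assert res.insertions == 0

    def test_inserted_orf(self):
        res = classify_cluster(
            self._cluster(["cyoA", "cyoB", "oxidoreductase", "cyoC", "cyoD", "cyoE"])
        )
        assert res.classification == "identical_with_insertion"
        assert res.insertions == 1
        assert res.order_score == 1.0

    def test_partial_prefix(self):
        res = classify_cluster(self._cluster(["cyoA", "cyoB", "cyoC", "cyoD"]))
        assert res.classification == "partial"
        assert res.order_score == pytest.approx(0.8)

    def test_full_reversal_is_rearranged(self):
        res = classify_cluster(self._cluster(list(REF[::-1])))
        assert res.classification == "rearranged"
        assert res.order_score == pytest.approx(0.2)

    def test_two_swapped_genes_rearranged(self):
        res = classify_cluster(self._cluster(["cyoB", "cyoA"]))
        assert res.classification == "rearranged"

    def test_single_shared_gene_is_partial_not_rearranged(self):
        res = classify_cluster(self._cluster(["cyoC"]))
        assert res.classification == "partial"

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster(Cluster("s", (), (), True))


def test_strand_invariance_under_scaffold_reverse_complement():
    """Flipping a whole scaffold (coordinates mirrored, strands toggled)
    leaves every classification unchanged."""
    for layout in OPERON_LAYOUTS:
        genes = plant_operon(layout, seed=17)
        span = max(g.end for g in genes) + 100
        flipped = [
            Gene(g.scaffold, span - g.end + 1, span - g.start + 1,
                 "-" if g.strand == "+" else "+", label=g.label)
            for g in genes
        ]
        direct = classify_genome(extract_clusters(genes))
        mirrored = classify_genome(extract_clusters(flipped))
        assert direct.classification == mirrored.classification
        assert direct.order_score == mirrored.order_score


@pytest.mark.parametrize("layout,expected", [
    ("reference", "identical"),
    ("inserted_orf", "identical_with_insertion"),
    ("reordered", "rearranged"),
    ("fragmented", "fragmented"),
    ("partial", "partial"),
])
@pytest.mark.parametrize("seed", range(20))
def test_planted_layouts_map_to_intended_class(layout, expected, seed):
    genes = plant_operon(layout, seed=seed, strand="+" if seed % 2 else "-")
    res = classify_genome(extract_clusters(genes))
    assert res.classification == expected


def _brute_force_lcs(a, b):
    """Longest common subsequence by subsequence enumeration (oracle)."""
    best = 0
    for r in range(len(a), 0, -1):
        for idx in combinations(range(len(a)), r):
            sub = [a[i] for i in idx]
            it = iter(b)
            if all(x in it for x in sub):
                best = max(best, r)
        if best == r:
            break
    return best


@pytest.mark.parametrize("seed", range(30))
def test_order_score_matches_brute_force_lcs(seed):
    """DP order score equals exhaustive-subsequence LCS for <=6-gene clusters."""
    import numpy as np

    rng = np.random.default_rng(seed)
    pool = list(REF) + ["orfX"]
    labels = [pool[i] for i in rng.integers(0, len(pool), size=rng.integers(1, 7))]
    model = OperonModel()
    labeled = [l for l in labels if l in REF]
    assert lcs_length(labeled, list(model.genes)) == _brute_force_lcs(
        labeled, list(model.genes)
    )


def test_render_diagram_shows_transcriptional_order():
    genes = plant_operon("inserted_orf", seed=4)
    cluster = extract_clusters(genes)[0]
    text = render_diagram(cluster)
    assert "cyoA" in text and ">" in text and "[oxidoreductase]" in text
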