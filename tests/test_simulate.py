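"""Synthetic-community simulator: composition, depth model, planting."""

import dataclasses
import math

import numpy as np
import pytest

from microcensus import (
    Community,
    CommunitySpec,
    GenomeTruth,
    build_community,
    expected_depth,
    plant_16s_with_primer_sites,
    plant_operon,
    simulate_depth_profile,
)
from microcensus.simulate import (
    InvalidSpecError,
    OPERON_LAYOUTS,
    seq_bases_for_min_depth,
    split_scaffolds,
)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_genomes": 5, "n_ultrasmall": 6},
        {"n_genomes": 0},
        {"genome_length_bp": (0, 100)},
        {"genome_length_bp": (100, 50)},
        {"enrichment_range": (0.5, 10)},
        {"enrichment_range": (100, 10)},
        {"seq_bases_bulk": 0},
        {"concentrate_capture_of_large": 1.5},
        {"abundance_lognormal_sigma": 0.0},
        {"n_ultrasmall": 0, "concentrate_capture_of_large": 0.0},
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(InvalidSpecError):
        CommunitySpec(**kwargs)


def test_single_genome_fraction_is_one():
    com = build_community(CommunitySpec(n_genomes=1, n_ultrasmall=1, seed=3))
    assert com.genomes[0].cell_fraction_bulk == 1.0
    assert com.genomes[0].cell_fraction_concentrate == 1.0


def test_seeded_determinism():
    spec = CommunitySpec(n_genomes=10, n_ultrasmall=2, seed=7)
    assert build_community(spec) == build_community(spec)


@pytest.mark.parametrize("seed", [0, 1, 99])
def test_fractions_sum_to_one_and_enrichments_in_range(seed):
    spec = CommunitySpec(n_genomes=20, n_ultrasmall=4, seed=seed)
    com = build_community(spec)
    assert math.isclose(sum(g.cell_fraction_bulk for g in com.genomes), 1.0,
                        abs_tol=1e-9)
    assert math.isclose(sum(g.cell_fraction_concentrate for g in com.genomes),
                        1.0, abs_tol=1e-9)
    lo, hi = spec.enrichment_range
    for g in com.ultrasmall:
        assert lo <= g.planted_enrichment <= hi
        # calibrated composition: the realised abundance ratio IS the planted fold
        assert math.isclose(g.realized_enrichment, g.planted_enrichment,
                            rel_tol=1e-9)
    for g in com.genomes:
        assert g.is_ultrasmall == (g.planted_enrichment is not None)


def test_fixed_rarity_mode_renormalizes():
    spec = CommunitySpec(n_genomes=20, n_ultrasmall=4, rarity_factor=1e-4, seed=5)
    com = build_community(spec)
    assert not com.calibrated
    assert math.isclose(sum(g.cell_fraction_concentrate for g in com.genomes),
                        1.0, abs_tol=1e-9)
    # all realized enrichments share the renormalisation constant
    ratios = [g.realized_enrichment / g.planted_enrichment for g in com.ultrasmall]
    assert np.allclose(ratios, ratios[0])


def _manual_community(fractions, lengths):
    spec = CommunitySpec(n_genomes=len(fractions), n_ultrasmall=1, seed=0)
    genomes = tuple(
        GenomeTruth(f"g{i}", L, False, f, f)
        for i, (f, L) in enumerate(zip(fractions, lengths))
    )
    return Community(spec=spec, genomes=genomes)


def test_expected_depth_single_genome():
    com = _manual_community([1.0], [10**6])
    assert expected_depth(com, "bulk", 10**7) == {"g0": 10.0}


def test_expected_depth_two_genomes_weighted():
    # 0.5 * 8e6 / (0.5*1e6 + 0.5*3e6) = 2.0 for both genomes
    com = _manual_community([0.5, 0.5], [10**6, 3 * 10**6])
    depths = expected_depth(com, "bulk", 8 * 10**6)
    assert depths == {"g0": 2.0, "g1": 2.0}


@pytest.mark.parametrize("seed", [11, 12])
def test_expected_depth_conserves_sequencing_effort(seed):
    com = build_community(CommunitySpec(n_genomes=15, n_ultrasmall=3, seed=seed))
    for sample, total in (("bulk", com.spec.seq_bases_bulk),
                          ("concentrate", com.spec.seq_bases_concentrate)):
        depths = expected_depth(com, sample)
        got = sum(depths[g.genome_id] * g.length_bp for g in com.genomes)
        assert math.isclose(got, total, rel_tol=1e-6)


def test_expected_depth_unknown_sample():
    com = build_community(CommunitySpec(n_genomes=3, n_ultrasmall=1, seed=0))
    with pytest.raises(KeyError):
        expected_depth(com, "filtrate")


def test_seq_bases_helper_reaches_target_depth():
    com = build_community(CommunitySpec(n_genomes=10, n_ultrasmall=2, seed=4))
    s = seq_bases_for_min_depth(com, "bulk", 2.0)
    depths = expected_depth(com, "bulk", s)
    assert min(depths[g.genome_id] for g in com.ultrasmall) == pytest.approx(2.0)


def test_depth_profile_zero_rate_is_all_zero():
    vec = simulate_depth_profile(1000, 0.0, seed=1)
    assert not vec.any()


def test_depth_profile_mean_matches_rate():
    vec = simulate_depth_profile(10**5, 10.0, seed=2)
    se = math.sqrt(10.0 / 10**5)
    assert abs(vec.mean() - 10.0) < 3 * se


def test_depth_profile_negative_rate_rejected():
    with pytest.raises(ValueError):
        simulate_depth_profile(100, -1.0)


@pytest.mark.parametrize("c", [0.1, 0.5, 1.0, 2.0, 5.0])
def test_breadth_follows_lander_waterman(c):
    """Observed breadth tracks 1 - e^(-c) within 3 binomial standard errors."""
    length = 10**5
    vec = simulate_depth_profile(length, c, seed=int(c * 10))
    p = 1.0 - math.exp(-c)
    se = math.sqrt(p * (1 - p) / length)
    assert abs((vec > 0).mean() - p) < 3 * se


def test_scaffold_split_preserves_genome_lengths():
    com = build_community(CommunitySpec(n_genomes=6, n_ultrasmall=2, seed=9,
                                        scaffolds_per_genome=4))
    scaffolds = split_scaffolds(com)
    totals = {}
    for _, (gid, length) in scaffolds.items():
        totals[gid] = totals.get(gid, 0) + length
    assert totals == {g.genome_id: g.length_bp for g in com.genomes}


# --- 16S planting ---------------------------------------------------------


def test_plant_16s_zero_mismatch_detectable_and_verbatim(primer_pair):
    planted = plant_16s_with_primer_sites(primer_pair, 0, seed=8)
    assert planted.detectable
    from microcensus import find_primer_sites

    hits = find_primer_sites(planted.sequence, primer_pair.forward, k=0)
    assert any(h.mismatches == 0 and h.strand == "+" for h in hits)


def test_plant_16s_full_mutation_is_undetectable(primer_pair):
    n_mutable = sum(
        1 for c in primer_pair.forward if c not in "N"
    )
    planted = plant_16s_with_primer_sites(primer_pair, n_mutable, seed=8)
    assert not planted.detectable
    assert planted.forward_mismatches == n_mutable


def test_plant_16s_product_too_short_rejected(primer_pair):
    too_short = len(primer_pair.forward) + len(primer_pair.reverse) - 1
    with pytest.raises(ValueError):
        plant_16s_with_primer_sites(primer_pair, 0, seed=1,
                                    product_length=too_short)


def test_plant_16s_mismatch_count_bounds(primer_pair):
    with pytest.raises(ValueError):
        plant_16s_with_primer_sites(primer_pair, len(primer_pair.forward) + 1,
                                    seed=1)


# --- operon planting ------------------------------------------------------


def test_plant_operon_reference_order():
    genes = plant_operon("reference", seed=1)
    assert [g.label for g in genes] == ["cyoA", "cyoB", "cyoC", "cyoD", "cyoE"]


def test_plant_operon_partial_is_strict_sublist():
    ref = ["cyoA", "cyoB", "cyoC", "cyoD", "cyoE"]
    for seed in range(10):
        labels = [g.label for g in plant_operon("partial", seed=seed)]
        assert 0 < len(labels) < len(ref)
        joined = ",".join(ref)
        assert ",".join(labels) in joined


def test_plant_operon_reordered_same_multiset_different_order():
    ref = ["cyoA", "cyoB", "cyoC", "cyoD", "cyoE"]
    labels = [g.label for g in plant_operon("reordered", seed=2)]
    assert sorted(labels) == sorted(ref) and labels != ref


def test_plant_operon_unknown_layout():
    with pytest.raises(ValueError):
        plant_operon("inverted")


@pytest.mark.parametrize("layout", OPERON_LAYOUTS)
def test_plant_operon_minus_strand_is_strand_consistent(layout):
    genes = plant_operon(layout, seed=3, strand="-")
    assert {g.strand for g in genes} == {"-"}
    for scaffold in {g.scaffold for g in genes}:
        spans = [(g.start, g.end) for g in genes if g.scaffold == scaffold]
        assert all(s <= e for s, e in spans)


def test_truth_serialization_roundtrip(tmp_path, small_community):
    from microcensus.simulate import write_dataset
    import json

    truth = write_dataset(small_community, tmp_path)
    on_disk = json.loads((tmp_path / "truth.json").read_text())
    assert on_disk == json.loads(json.dumps(truth))
    spec_dict = json.loads(json.dumps(dataclasses.asdict(small_community.spec)))
    assert spec_dict == on_disk["spec"]
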