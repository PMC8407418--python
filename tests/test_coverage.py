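"""Depth/breadth profiles, abundance normalisation, bin aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microcensus import (
    CommunitySpec,
    ScaffoldProfile,
    aggregate_bins,
    build_community,
    expected_depth,
    profile_scaffold,
    relative_abundance,
)
from microcensus.coverage import profile_from_vector
from microcensus.simulate import simulate_depth_profile, split_scaffolds


class TestProfileScaffold:
    def test_no_records_gives_zero_profile(self):
        p = profile_scaffold([], "s1", 100)
        assert (p.mean_depth, p.breadth) == (0.0, 0.0)

    def test_uniform_depth(self):
        records = [(i, 5) for i in range(1, 101)]
        p = profile_scaffold(records, "s1", 100)
        assert (p.mean_depth, p.breadth) == (5.0, 1.0)

    def test_half_covered(self):
        # depth 4 over positions 1-50 of 100 bp: mean 2.0, breadth 0.5
        records = [(i, 4) for i in range(1, 51)]
        p = profile_scaffold(records, "s1", 100)
        assert (p.mean_depth, p.breadth) == (2.0, 0.5)

    def test_breadth_min_depth_threshold(self):
        records = [(1, 1), (2, 3), (3, 3)]
        p = profile_scaffold(records, "s1", 10, breadth_min_depth=2)
        assert p.breadth == 0.2

    def test_position_out_of_range_names_scaffold_and_position(self):
        with pytest.raises(ValueError, match=r"101.*scaffold_x|scaffold_x.*101"):
            profile_scaffold([(101, 2)], "scaffold_x", 100)

    def test_duplicate_position_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            profile_scaffold([(5, 1), (5, 2)], "s1", 100)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            profile_scaffold([], "s1", 0)

    @given(
        st.lists(
            st.tuples(st.integers(1, 200), st.integers(0, 30)),
            unique_by=lambda t: t[0],
            max_size=60,
        ),
        st.permutations(range(3)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_and_zero_listing_invariance(self, records, _perm):
        """Shuffled records and explicit zero rows change nothing."""
        base = profile_scaffold(records, "s", 200)
        shuffled = profile_scaffold(records[::-1], "s", 200)
        present = {pos for pos, _ in records}
        padded = records + [(pos, 0) for pos in range(1, 201) if pos not in present]
        explicit = profile_scaffold(padded, "s", 200)
        assert base == shuffled == explicit


class TestRelativeAbundance:
    def test_single_scaffold_is_one(self):
        p = profile_scaffold([(1, 3)], "s1", 10)
        assert relative_abundance([p])["base_fraction"].iloc[0] == 1.0

    def test_depth_times_length_weighting(self):
        # (depth 3, L=100) and (depth 1, L=300): 300 base-units each -> 0.5/0.5
        a = ScaffoldProfile("a", "s", 100, 3.0, 1.0)
        b = ScaffoldProfile("b", "s", 300, 1.0, 1.0)
        table = relative_abundance([a, b])
        assert np.allclose(table["base_fraction"], [0.5, 0.5])

    def test_symmetry_three_equal_units(self):
        profiles = [ScaffoldProfile(f"s{i}", "s", 100, 2.0, 1.0) for i in range(3)]
        assert np.allclose(relative_abundance(profiles)["base_fraction"], 1 / 3)

    def test_mixed_samples_rejected(self):
        a = ScaffoldProfile("a", "bulk", 100, 1.0, 1.0)
        b = ScaffoldProfile("b", "concentrate", 100, 1.0, 1.0)
        with pytest.raises(ValueError, match="mix"):
            relative_abundance([a, b])

    def test_all_zero_sample_flagged_undefined(self):
        profiles = [ScaffoldProfile(f"s{i}", "s", 100, 0.0, 0.0) for i in range(2)]
        table = relative_abundance(profiles)
        assert table["undefined"].all()
        assert table["base_fraction"].isna().all()


class TestAggregateBins:
    def test_single_scaffold_bin_equals_scaffold(self):
        p = profile_scaffold([(i, 2) for i in range(1, 51)], "s1", 100)
        bin_profiles, table = aggregate_bins([p], {"s1": "b1"})
        assert bin_profiles[0].mean_depth == p.mean_depth
        assert bin_profiles[0].breadth == p.breadth

    def test_length_weighted_mean_and_breadth(self):
        full = ScaffoldProfile("s1", "s", 100, 10.0, 1.0)
        empty = ScaffoldProfile("s2", "s", 100, 0.0, 0.0)
        bin_profiles, _ = aggregate_bins([full, empty], {"s1": "b", "s2": "b"})
        assert bin_profiles[0].mean_depth == 5.0
        assert bin_profiles[0].breadth == 0.5

    def test_equal_depth_bins_split_cell_fraction(self):
        p1 = ScaffoldProfile("s1", "s", 100, 4.0, 1.0)
        p2 = ScaffoldProfile("s2", "s", 400, 4.0, 1.0)
        _, table = aggregate_bins([p1, p2], {"s1": "b1", "s2": "b2"})
        assert np.allclose(table["cell_fraction"], 0.5)
        # base fractions differ because lengths differ
        assert np.allclose(table["base_fraction"], [0.2, 0.8])

    def test_missing_scaffold_needs_stated_length(self):
        p = ScaffoldProfile("s1", "s", 100, 1.0, 1.0)
        with pytest.raises(KeyError, match="s2"):
            aggregate_bins([p], {"s1": "b", "s2": "b"})
        _, table = aggregate_bins([p], {"s1": "b", "s2": "b"}, lengths={"s2": 300})
        assert table.loc["b", "mean_depth"] == pytest.approx(100 / 400)

    def test_abundance_flavors_sum_to_one(self):
        rng = np.random.default_rng(0)
        profiles = [
            ScaffoldProfile(f"s{i}", "s", int(rng.integers(50, 500)),
                            float(rng.uniform(0, 20)), 0.0)
            for i in range(12)
        ]
        profiles = [
            ScaffoldProfile(p.scaffold_id, p.sample_id, p.length_bp, p.mean_depth,
                            0.5 if p.mean_depth > 0 else 0.0)
            for p in profiles
        ]
        membership = {f"s{i}": f"b{i % 4}" for i in range(12)}
        _, table = aggregate_bins(profiles, membership)
        assert math.isclose(table["base_fraction"].sum(), 1.0, abs_tol=1e-9)
        assert math.isclose(table["cell_fraction"].sum(), 1.0, abs_tol=1e-9)


def test_cell_fraction_recovery_at_high_depth():
    """At >=20x depth for every genome, estimated bin cell fractions land
    within 5% of the planted fractions."""
    spec = CommunitySpec(
        n_genomes=8, n_ultrasmall=2, genome_length_bp=(20_000, 40_000), seed=13
    )
    com = build_community(spec)
    from microcensus.simulate import seq_bases_for_min_depth

    seq_bases = seq_bases_for_min_depth(
        com, "bulk", 20.0, [g.genome_id for g in com.genomes]
    )
    depths = expected_depth(com, "bulk", seq_bases)
    rng = np.random.default_rng(77)
    scaffolds = split_scaffolds(com)
    profiles = [
        profile_from_vector(
            simulate_depth_profile(L, depths[gid], rng=rng), scaf, "bulk"
        )
        for scaf, (gid, L) in scaffolds.items()
    ]
    membership = {scaf: gid for scaf, (gid, _) in scaffolds.items()}
    _, table = aggregate_bins(profiles, membership)
    for g in com.genomes:
        est = table.loc[g.genome_id, "cell_fraction"]
        assert abs(est - g.cell_fraction_bulk) / g.cell_fraction_bulk < 0.05
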