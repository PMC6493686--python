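"""Interval model, I/O round-trips, and the overlap/stitch/nearest engines."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sescape.intervals import (
    ChromSizes,
    CountMatrix,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    ParseError,
    RegionSet,
    ValidationError,
    nearest_tss,
    overlap,
    read_regions,
    stitch,
    write_regions,
)
from conftest import random_regions, region_set


class TestInvariants:
    def test_interval_rejects_degenerate_coordinates(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 100)

    def test_regionset_bounds_checked_against_genome(self, genome):
        with pytest.raises(ValidationError):
            region_set([("chr2", 0, 600_000)], chromsizes=genome)
        with pytest.raises(ValidationError):
            region_set([("chrUn", 0, 100)], chromsizes=genome)

    def test_chromsizes_rejects_bad_lengths(self):
        with pytest.raises(ValidationError):
            ChromSizes({"chr1": 0})

    def test_gene_tss_must_sit_in_body(self):
        with pytest.raises(ValidationError):
            GeneModel("g", "chr1", "+", 999,
                      GenomicInterval("chr1", 1_000, 2_000))


class TestIO:
    def test_bed_roundtrip_is_exact(self, tmp_path, genome):
        rng = np.random.default_rng(0)
        rs = random_regions(rng, 200, max_pos=400_000, chromsizes=genome)
        path = tmp_path / "x.bed"
        write_regions(rs, path)
        back = read_regions(path, "bed", chromsizes=genome)
        assert np.array_equal(rs.starts, back.starts)
        assert np.array_equal(rs.ends, back.ends)
        assert list(rs.chroms) == list(back.chroms)

    def test_bed_line_parses_half_open(self, tmp_path):
        p = tmp_path / "one.bed"
        p.write_text("chr1\t100\t200\tpk1\n")
        rs = read_regions(p, "bed")
        iv = rs[0]
        assert (iv.chrom, iv.start, iv.end, iv.name) == ("chr1", 100, 200, "pk1")

    def test_inverted_coordinates_raise_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(ParseError, match=":2"):
            read_regions(p, "bed")

    def test_narrowpeak_carries_signal_value_and_needs_10_columns(self, tmp_path):
        p = tmp_path / "x.narrowPeak"
        p.write_text("chr1\t10\t50\tpk\t0\t.\t7.25\t-1\t-1\t-1\n")
        rs = read_regions(p, "narrowPeak")
        assert rs.scores[0] == pytest.approx(7.25)
        p.write_text("chr1\t10\t50\tpk\n")
        with pytest.raises(ParseError, match="10 columns"):
            read_regions(p, "narrowPeak")

    def test_snp_table_converts_1based_to_width1(self, tmp_path):
        p = tmp_path / "snps.tsv"
        p.write_text("chr1\t1000\trs1\tCVD\n")
        rs = read_regions(p, "snp_table")
        assert (rs.starts[0], rs.ends[0]) == (999, 1000)


class TestOverlap:
    def test_basic_hit_and_half_open_abutment(self):
        q = region_set([("chr1", 100, 200)])
        assert overlap(q, region_set([("chr1", 150, 300)])).flags[0]
        assert not overlap(q, region_set([("chr1", 200, 300)])).flags[0]

    def test_min_bp_threshold(self):
        q = region_set([("chr1", 100, 200)])
        s = region_set([("chr1", 150, 300)])
        assert overlap(q, s, min_bp=50).flags[0]
        assert not overlap(q, s, min_bp=51).flags[0]

    def test_self_overlap_is_total(self):
        rng = np.random.default_rng(1)
        rs = random_regions(rng, 1000)
        assert overlap(rs, rs).fraction() == 1.0

    def test_existence_is_symmetric(self):
        rng = np.random.default_rng(2)
        a = random_regions(rng, 300)
        b = random_regions(rng, 300)
        any_ab = overlap(a, b).n_overlapping > 0
        any_ba = overlap(b, a).n_overlapping > 0
        assert any_ab == any_ba
        # and per-pair: every hit in a->b appears as b->a
        hits_ab = {(i, j) for i, h in enumerate(overlap(a, b).hits) for j in h}
        hits_ba = {(i, j) for j, h in enumerate(overlap(b, a).hits) for i in h}
        assert hits_ab == hits_ba

    def test_mismatched_universes_rejected(self, genome):
        other = ChromSizes({"chrX": 1_000})
        a = region_set([("chr1", 0, 10)], chromsizes=genome)
        b = region_set([("chrX", 0, 10)], chromsizes=other)
        with pytest.raises(ValidationError):
            overlap(a, b)


def brute_force_stitch(rs: RegionSet, max_gap: int):
    """Oracle: pairwise gap graph + connected components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(rs)))
    for i in range(len(rs)):
        for j in range(i + 1, len(rs)):
            if rs.chroms[i] != rs.chroms[j]:
                continue
            gap = max(rs.starts[i], rs.starts[j]) - min(rs.ends[i], rs.ends[j])
            if gap <= max_gap:
                g.add_edge(i, j)
    spans = set()
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        spans.add(
            (
                rs.chroms[comp[0]],
                int(min(rs.starts[c] for c in comp)),
                int(max(rs.ends[c] for c in comp)),
                frozenset(comp),
            )
        )
    return spans


class TestStitch:
    def test_merges_within_gap(self):
        rs = region_set([("chr1", 100, 200), ("chr1", 300, 400)])
        out = stitch(rs, 12_500)
        assert len(out.regions) == 1
        assert (out.regions.starts[0], out.regions.ends[0]) == (100, 400)
        assert out.constituents[0].size == 2

    def test_gap_boundary_is_inclusive(self):
        near = region_set([("chr1", 100, 200), ("chr1", 12_700, 12_800)])
        assert len(stitch(near, 12_500).regions) == 1  # gap == 12500
        far = region_set([("chr1", 100, 200), ("chr1", 12_701, 12_800)])
        assert len(stitch(far, 12_500).regions) == 2   # gap == 12501

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            rs = random_regions(rng, 60, max_pos=50_000, max_width=3_000)
            gap = int(rng.integers(0, 10_000))
            out = stitch(rs, gap)
            got = {
                (out.regions.chroms[i], int(out.regions.starts[i]),
                 int(out.regions.ends[i]), frozenset(out.constituents[i]))
                for i in range(len(out.regions))
            }
            assert got == brute_force_stitch(rs, gap)

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        rs = random_regions(rng, 200, max_pos=100_000)
        once = stitch(rs, 5_000).regions
        twice = stitch(once, 5_000).regions
        assert np.array_equal(once.starts, twice.starts)
        assert np.array_equal(once.ends, twice.ends)

    def test_zero_gap_merges_only_touching(self):
        rs = region_set(
            [("chr1", 0, 100), ("chr1", 100, 200), ("chr1", 201, 300)]
        )
        out = stitch(rs, 0)
        assert len(out.regions) == 2

    def test_covers_every_input_base(self):
        rng = np.random.default_rng(4)
        rs = random_regions(rng, 150, max_pos=80_000)
        out = stitch(rs, 0)
        cover = overlap(rs, out.regions)
        assert cover.flags.all()
        for i in range(len(rs)):
            assert cover.overlap_bp[i].sum() >= rs.widths[i]

    def test_does_not_bridge_chromosomes(self):
        rs = region_set([("chr1", 0, 900_000), ("chr2", 100, 200),
                         ("chr2", 50_000, 50_100)])
        out = stitch(rs, 1_000)
        assert len(out.regions) == 3


class TestNearestTSS:
    GENES = [
        GeneModel("gA", "chr1", "+", 5_000, GenomicInterval("chr1", 5_000, 8_000)),
        GeneModel("gB", "chr1", "-", 50_000,
                  GenomicInterval("chr1", 45_000, 50_001)),
    ]

    def test_signed_distance_plus_strand(self):
        rs = region_set([("chr1", 6_000, 8_000)])
        out = nearest_tss(rs, self.GENES)
        assert out["gene_id"][0] == "gA"
        assert out["distance"][0] == 2_000

    def test_midpoint_on_tss_gives_zero(self):
        rs = region_set([("chr1", 4_000, 6_000)])
        assert nearest_tss(rs, self.GENES)["distance"][0] == 0

    def test_minus_strand_flips_sign(self):
        rs = region_set([("chr1", 51_000, 53_000)])  # midpoint 52000 > tss
        out = nearest_tss(rs, self.GENES)
        assert out["gene_id"][0] == "gB"
        assert out["distance"][0] == -2_000

    def test_unassigned_on_geneless_chromosome(self):
        rs = region_set([("chr2", 0, 1_000)])
        assert nearest_tss(rs, self.GENES)["gene_id"][0] == "unassigned"

    def test_tie_breaks_to_smallest_gene_id(self):
        genes = [
            GeneModel("zz", "chr1", "+", 900,
                      GenomicInterval("chr1", 900, 2_000)),
            GeneModel("aa", "chr1", "+", 1_100,
                      GenomicInterval("chr1", 1_100, 2_000)),
        ]
        rs = region_set([("chr1", 500, 1_500)])  # midpoint 1000, both 100 away
        assert nearest_tss(rs, genes)["gene_id"][0] == "aa"

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(5)
        genes = []
        for i in range(50):
            chrom = rng.choice(["chr1", "chr2"])
            tss = int(rng.integers(0, 400_000))
            genes.append(
                GeneModel(f"g{i:02d}", chrom, "+", tss,
                          GenomicInterval(chrom, tss, tss + 1_000))
            )
        rs = random_regions(rng, 200, max_pos=400_000)
        out = nearest_tss(rs, genes)
        for i in range(len(rs)):
            mid = rs.midpoints[i]
            same = [g for g in genes if g.chrom == rs.chroms[i]]
            best = min(same, key=lambda g: (abs(mid - g.tss), g.gene_id))
            assert out["gene_id"][i] == best.gene_id
            assert out["abs_distance"][i] == abs(mid - best.tss)


class TestCountMatrix:
    def test_dimension_and_conservation_checks(self, genome):
        rs = region_set([("chr1", 0, 1_000), ("chr1", 5_000, 6_000)],
                        chromsizes=genome)
        with pytest.raises(ValidationError):
            CountMatrix(rs, np.ones((3, 1)), np.array([100]))
        with pytest.raises(ValidationError):
            CountMatrix(rs, np.array([[60], [50]]), np.array([100]))

    def test_rpm_scaling(self, genome):
        rs = region_set([("chr1", 0, 1_000)], chromsizes=genome)
        cm = CountMatrix(rs, np.array([[100]]), np.array([1_000_000]))
        assert cm.rpm()[0, 0] == pytest.approx(100.0)
        assert cm.rpm_per_bp()[0, 0] == pytest.approx(0.1)

    def test_recount_exact_for_containing_spans(self, genome):
        rs = region_set([("chr1", 0, 1_000), ("chr1", 2_000, 3_000)],
                        chromsizes=genome)
        cm = CountMatrix(rs, np.array([[40], [60]]), np.array([1_000_000]))
        spans = region_set([("chr1", 0, 3_000)], chromsizes=genome)
        assert cm.recount(spans).counts[0, 0] == 100

    def test_recount_splits_partial_overlap_uniformly(self, genome):
        rs = region_set([("chr1", 0, 1_000)], chromsizes=genome)
        cm = CountMatrix(rs, np.array([[100]]), np.array([1_000_000]))
        spans = region_set([("chr1", 0, 500)], chromsizes=genome)
        assert cm.recount(spans).counts[0, 0] == 50


class TestCoverageTrack:
    def test_mean_over_step_function(self, genome):
        rs = region_set([("chr1", 0, 100), ("chr1", 200, 300)],
                        chromsizes=genome)
        tr = CoverageTrack.from_values(rs, np.array([2.0, 4.0]), genome)
        assert tr.mean("chr1", 0, 100) == pytest.approx(2.0)
        assert tr.mean("chr1", 0, 400) == pytest.approx((200 + 400) / 400)
        assert tr.mean("chr1", 100, 200) == 0.0

    def test_bedgraph_roundtrip(self, tmp_path, genome):
        rs = region_set([("chr1", 10, 20), ("chr2", 0, 5)], chromsizes=genome)
        tr = CoverageTrack.from_values(rs, np.array([1.5, 3.0]), genome)
        p = tmp_path / "x.bedgraph"
        tr.to_bedgraph(p)
        back = CoverageTrack.from_bedgraph(p, genome)
        assert back.mean("chr1", 10, 20) == pytest.approx(1.5)
        assert back.mean("chr2", 0, 5) == pytest.approx(3.0)


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
        min_size=1, max_size=30,
    ),
    st.integers(0, 2_000),
)
def test_stitch_output_is_disjoint_and_gap_separated(pairs, gap):
    """Property: stitched regions never overlap and are > gap apart."""
    rs = region_set([("chr1", s, s + w) for s, w in pairs])
    out = stitch(rs, gap).regions
    starts, ends = out.starts, out.ends
    order = np.argsort(starts)
    assert all(
        starts[order[i + 1]] - ends[order[i]] > gap
        for i in range(len(out) - 1)
    )
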