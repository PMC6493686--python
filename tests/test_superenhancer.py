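"""Quantification, knee cutoff, SE calling, and co-occupancy statistics."""

import numpy as np
import pandas as pd
import pytest

from sescape.annotate import define_elements
from sescape.intervals import ChromSizes, CountMatrix, CoverageTrack, overlap
from sescape.simulate import SyntheticConfig, generate
from sescape.stats import rank_sum
from sescape.superenhancer import (
    binding_fraction,
    call_superenhancers,
    diagonal_distance_cutoff,
    metaprofile,
    occupancy_correlation,
    quantify,
    rank_cutoff,
    se_precision_recall,
)
from conftest import region_set


def catalog_of(ds):
    return define_elements(
        ds.peaks["H3K27ac"], ds.peaks["H3K4me1"], ds.peaks["H3K4me3"],
        ds.peaks["H3K27me3"], genes=ds.genes,
    )


def call_of(ds, mark="H3K27ac"):
    return call_superenhancers(
        catalog_of(ds).active_enhancers, ds.counts[mark]["ctl"],
        ds.counts["input"]["ctl"], ds.genes, ranking_mark=mark,
    )


class TestQuantify:
    CS = ChromSizes({"chr1": 100_000})

    def _cm(self, count, lib=1_000_000):
        spans = region_set([("chr1", 0, 1_000)], chromsizes=self.CS)
        return spans, CountMatrix(spans, np.array([[count]]), np.array([lib]))

    def test_rpm_per_bp_arithmetic(self):
        spans, cm = self._cm(100)
        assert quantify(spans, cm)[0] == pytest.approx(0.1)

    def test_equal_treatment_and_control_cancel(self):
        spans, cm = self._cm(100)
        assert quantify(spans, cm, cm)[0] == 0.0

    def test_excess_control_floors_at_zero(self):
        spans, t = self._cm(10)
        _, c = self._cm(100)
        assert quantify(spans, t, c)[0] == 0.0


class TestRankCutoff:
    def test_single_outlier_is_the_only_se(self):
        cutoff, order = rank_cutoff(np.array([1, 1, 1, 1, 10.0]))
        assert cutoff == 3           # SE = ranks > 3, i.e. the outlier alone

    def test_constant_signal_calls_nothing(self):
        with pytest.warns(UserWarning):
            cutoff, _ = rank_cutoff(np.full(10, 3.0))
        assert cutoff == 9

    def test_linear_curve_calls_nothing(self):
        with pytest.warns(UserWarning):
            cutoff, _ = rank_cutoff(np.arange(10, dtype=float))
        assert cutoff == 9

    def test_agrees_with_diagonal_oracle_on_convex_curves(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            n = int(rng.integers(10, 400))
            power = rng.uniform(1.2, 8.0)
            scale = rng.uniform(0.5, 50.0)
            y = scale * np.linspace(0, 1, n) ** power
            assert abs(rank_cutoff(y)[0] - diagonal_distance_cutoff(y)) <= 1

    def test_too_few_entities_rejected(self):
        with pytest.raises(ValueError):
            rank_cutoff(np.array([1.0, 2.0]))


class TestCallSE:
    def test_worked_example_recovers_both_planted_clusters(self, tiny_dataset):
        call = call_of(tiny_dataset)
        assert call.n_se == 2
        p, r = se_precision_recall(call, tiny_dataset.truth.planted_se)
        assert (p, r) == (1.0, 1.0)
        # all SE signals >= all TE signals, ranks partition the entities
        tab = call.table
        assert tab.loc[tab["is_se"], "signal"].min() >= \
            tab.loc[~tab["is_se"], "signal"].max()
        assert tab["is_se"].sum() + (~tab["is_se"]).sum() == len(tab)

    def test_se_genes_match_hand_assignment(self, tiny_dataset):
        call = call_of(tiny_dataset)
        se = call.table[call.table["is_se"]].sort_values("start")
        assert list(se["gene_id"]) == ["gA", "gB"]

    def test_zero_gap_keeps_singletons_apart(self, tiny_dataset):
        cat = catalog_of(tiny_dataset)
        call = call_superenhancers(
            cat.active_enhancers, tiny_dataset.counts["H3K27ac"]["ctl"],
            tiny_dataset.counts["input"]["ctl"], tiny_dataset.genes,
            stitch_gap=0,
        )
        assert len(call.table) == len(cat.active_enhancers)

    def test_library_scale_invariance(self, tiny_dataset):
        ds = tiny_dataset
        cat = catalog_of(ds)
        base = ds.counts["H3K27ac"]["ctl"]
        scaled_treat = CountMatrix(base.regions, base.counts,
                                   base.library_sizes * 10)
        inp = ds.counts["input"]["ctl"]
        scaled_inp = CountMatrix(inp.regions, inp.counts,
                                 inp.library_sizes * 10)
        a = call_superenhancers(cat.active_enhancers, base, inp, ds.genes)
        b = call_superenhancers(cat.active_enhancers, scaled_treat,
                                scaled_inp, ds.genes)
        assert a.table["is_se"].equals(b.table["is_se"])
        assert a.cutoff_rank == b.cutoff_rank

    def test_planted_recovery_across_seeds(self):
        ps, rs = [], []
        for seed in range(1, 6):
            ds = generate(SyntheticConfig(seed=seed))
            p, r = se_precision_recall(call_of(ds), ds.truth.planted_se)
            ps.append(p)
            rs.append(r)
        assert np.mean(ps) >= 0.9 and np.mean(rs) >= 0.9

    def test_tf_ranking_recovers_bound_clusters(self, fixture_dataset):
        ds = fixture_dataset
        call_tf = call_of(ds, mark="TF")
        bound = [n for n, v in ds.truth.tf_bound.items()
                 if n.startswith("cluster") and v]
        tdf = ds.truth.planted_se.df
        bound_spans = ds.truth.planted_se.subset(
            tdf["name"].isin(bound).to_numpy()
        )
        assert overlap(bound_spans, call_tf.se_regions()).fraction() >= 0.9
        # agreement with the activating-mark call on the planted clusters
        call_k27 = call_of(ds)
        k27_hit = overlap(ds.truth.planted_se, call_k27.se_regions()).flags
        tf_hit = overlap(ds.truth.planted_se, call_tf.se_regions()).flags
        both = (k27_hit & tf_hit).sum()
        either = (k27_hit | tf_hit).sum()
        assert both / either >= 0.8

    def test_se_genes_express_higher_than_te_genes(self, fixture_dataset):
        ds = fixture_dataset
        call = call_of(ds)
        expr = dict(zip(ds.expression["gene_id"], ds.expression["expression"]))
        tab = call.table
        se_e = [expr[g] for g in tab.loc[tab["is_se"], "gene_id"] if g in expr]
        te_e = [expr[g] for g in tab.loc[~tab["is_se"], "gene_id"]
                if g in expr]
        res = rank_sum(se_e, te_e, sided="greater")
        assert res.p_value < 0.01


class TestBindingFraction:
    def test_blanket_tf_coverage_is_uninformative(self, genome):
        se = region_set([("chr1", 0, 1_000), ("chr1", 5_000, 6_000)],
                        chromsizes=genome)
        te = region_set([("chr1", 10_000, 11_000), ("chr1", 20_000, 21_000)],
                        chromsizes=genome)
        blanket = region_set([("chr1", 0, 900_000)], chromsizes=genome)
        f_se, f_te, test = binding_fraction(se, te, blanket)
        assert (f_se, f_te, test.p_value) == (1.0, 1.0, 1.0)

    def test_no_tf_peaks(self, genome):
        se = region_set([("chr1", 0, 1_000)], chromsizes=genome)
        te = region_set([("chr1", 10_000, 11_000)], chromsizes=genome)
        f_se, f_te, test = binding_fraction(se, te, region_set([]))
        assert (f_se, f_te, test.p_value) == (0.0, 0.0, 1.0)

    def test_empty_category_rejected(self, genome):
        se = region_set([("chr1", 0, 1_000)], chromsizes=genome)
        with pytest.raises(ValueError):
            binding_fraction(se, region_set([]), se)


class TestOccupancyCorrelation:
    def test_doubled_counts_correlate_perfectly(self, genome):
        rng = np.random.default_rng(21)
        starts = np.arange(10) * 10_000
        se = region_set([("chr1", int(s), int(s + 1_000)) for s in starts],
                        chromsizes=genome)
        c = rng.integers(50, 500, size=(10, 1))
        a = CountMatrix(se, c, np.array([1_000_000]))
        b = CountMatrix(se, 2 * c, np.array([2_000_000]))
        r, _ = occupancy_correlation(se, a, b)
        assert r == pytest.approx(1.0)

    def test_independent_counts_uncorrelated(self, genome):
        rng = np.random.default_rng(22)
        n = 500
        starts = np.arange(n) * 1_500
        se = region_set([("chr1", int(s), int(s + 1_000)) for s in starts],
                        chromsizes=genome)
        a = CountMatrix(se, rng.poisson(100, (n, 1)), np.array([1_000_000]))
        b = CountMatrix(se, rng.poisson(100, (n, 1)), np.array([1_000_000]))
        r, _ = occupancy_correlation(se, a, b)
        assert abs(r) < 0.15

    def test_shared_planted_strength_correlates(self, fixture_dataset):
        ds = fixture_dataset
        call = call_of(ds)
        r, _ = occupancy_correlation(
            call.se_regions(), ds.counts["TF"]["ctl"],
            ds.counts["H3K27ac"]["ctl"],
        )
        assert r > 0.6


class TestMetaprofile:
    CS = ChromSizes({"chr1": 100_000})

    def test_uniform_coverage_gives_flat_profile(self):
        cov = CoverageTrack.from_values(
            region_set([("chr1", 0, 100_000)], chromsizes=self.CS),
            np.array([2.5]), self.CS,
        )
        regions = region_set([("chr1", 40_000, 42_000),
                              ("chr1", 60_000, 62_000)], chromsizes=self.CS)
        prof = metaprofile(regions, cov, flank=5_000, n_bins=20)
        assert np.allclose(prof["mean_signal"], 2.5)
        assert (prof["n_regions"] == 2).all()

    def test_triangular_coverage_peaks_centrally(self):
        # staircase triangle over [48000, 52000): values rise to the center
        steps = [1, 2, 3, 4, 5, 5, 4, 3, 2, 1]
        rows = [("chr1", 48_000 + 400 * k, 48_000 + 400 * (k + 1))
                for k in range(10)]
        cov = CoverageTrack.from_values(
            region_set(rows, chromsizes=self.CS),
            np.array(steps, dtype=float), self.CS,
        )
        regions = region_set([("chr1", 49_000, 51_000)], chromsizes=self.CS)
        prof = metaprofile(regions, cov, flank=4_000, n_bins=16)
        sig = prof["mean_signal"].to_numpy()
        assert sig.argmax() in (7, 8)
        assert np.allclose(sig, sig[::-1], atol=1e-9)

    def test_flank_beyond_chromosome_clips_not_errors(self):
        cov = CoverageTrack.from_values(
            region_set([("chr1", 0, 100_000)], chromsizes=self.CS),
            np.array([1.0]), self.CS,
        )
        regions = region_set([("chr1", 1_000, 2_000)], chromsizes=self.CS)
        prof = metaprofile(regions, cov, flank=200_000, n_bins=10)
        assert prof["n_regions"].iloc[0] == 0   # fully off-chromosome bin
        assert prof["n_regions"].iloc[5] == 1
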