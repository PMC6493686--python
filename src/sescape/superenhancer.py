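"""Stitched super-enhancer calling and SE-level co-occupancy statistics.

The procedure: drop promoter-proximal enhancers, concatenate the rest
whenever the intervening gap is at most 12.5 kb, quantify each stitched
entity as input-subtracted rpm/bp over its full span, rank ascending, and
cut the ranked curve where its tangent slope first reaches 1 after both
axes are scaled to [0, 1] (the classic hockey-stick knee). Everything above
the cutoff is a super-enhancer; the ranking signal can be any mark
(activating histone mark, TF, cofactor).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import (
    CountMatrix,
    CoverageTrack,
    GeneModel,
    RegionSet,
    nearest_tss,
    overlap,
    stitch,
)
from .stats import TestResult, fisher_exact, pearson

__all__ = [
    "SECallResult",
    "quantify",
    "rank_cutoff",
    "call_superenhancers",
    "binding_fraction",
    "occupancy_correlation",
    "metaprofile",
    "se_precision_recall",
]


def quantify(
    spans: RegionSet,
    treatment: CountMatrix,
    control: CountMatrix | None = None,
) -> np.ndarray:
    """Input-subtracted signal per span in rpm/bp, floored at zero.

    Both matrices are re-counted over the spans (reads uniform within their
    source regions), samples pooled, then
    ``treatment_rpm/width - control_rpm/width`` with negative values set to
    0. ``control=None`` skips the subtraction.
    """
    widths = spans.widths.astype(float)
    if (widths <= 0).any():
        raise ValueError("zero-width span")
    t = treatment.recount(spans)
    t_counts, t_lib = t.pooled()
    if t_lib <= 0:
        raise ValueError("zero treatment library size")
    signal = t_counts / (t_lib / 1e6) / widths
    if control is not None:
        c = control.recount(spans)
        c_counts, c_lib = c.pooled()
        if c_lib <= 0:
            raise ValueError("zero control library size")
        signal = signal - c_counts / (c_lib / 1e6) / widths
    return np.maximum(signal, 0.0)


def rank_cutoff(signals: np.ndarray) -> tuple[int, np.ndarray]:
    """Knee of the ascending ranked-signal curve.

    Ranks and signals are rescaled to [0, 1]; the cutoff is the smallest
    rank from which the tangent slope of the curve exceeds 1 and stays
    above. The slope is measured on the lower convex envelope, so the rule
    is robust to counting noise; for convex curves it coincides with the
    point of maximum vertical distance below the diagonal. Entities with
    rank strictly above the cutoff are super-enhancers.

    Returns ``(cutoff_rank, order)`` where ``order`` sorts the input
    ascending by signal (stable).
    """
    signals = np.asarray(signals, dtype=float)
    n = signals.size
    if n < 3:
        raise ValueError("need at least 3 entities to place a cutoff")
    if not np.isfinite(signals).all():
        raise ValueError("non-finite signal")
    order = np.argsort(signals, kind="mergesort")
    s = signals[order]
    if s[0] == s[-1]:
        warnings.warn("constant signal vector: no super-enhancers called")
        return n - 1, order
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    # tangent slope measured on the lower convex envelope of the curve, so
    # it is nondecreasing and "first exceeds 1, stays above" is well posed
    # even when counting noise wiggles the raw increments
    hull = [0]
    for i in range(1, n):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            if (y[i1] - y[i0]) * (x[i] - x[i0]) >= (y[i] - y[i0]) * (
                x[i1] - x[i0]
            ):
                hull.pop()
            else:
                break
        hull.append(i)
    cutoff = None
    for a, b in zip(hull[:-1], hull[1:]):
        if (y[b] - y[a]) / (x[b] - x[a]) > 1.0:
            cutoff = a
            break
    if cutoff is None:    # slope never rises above 1 (e.g. linear curve)
        warnings.warn("ranked curve never exceeds unit slope; no SE called")
        return n - 1, order
    # the crossing point itself stays typical; SE are strictly above it
    return cutoff, order


def diagonal_distance_cutoff(signals: np.ndarray) -> int:
    """Oracle knee: rank maximizing x - y on the rescaled ascending curve."""
    signals = np.asarray(signals, dtype=float)
    order = np.argsort(signals, kind="mergesort")
    s = signals[order]
    n = s.size
    if s[0] == s[-1]:
        return n - 1
    x = np.arange(n) / (n - 1)
    y = (s - s[0]) / (s[-1] - s[0])
    return int(np.argmax(x - y))


@dataclass
class SECallResult:
    """Ranked stitched entities with the SE/TE cutoff.

    ``table`` rows are ordered by ascending rank and carry span coordinates,
    constituent count, signal (rpm/bp), rank, ``is_se``, and the assigned
    gene. ``constituents[i]`` are the input-enhancer indices of the entity
    at rank i.
    """

    table: pd.DataFrame
    constituents: list[np.ndarray]
    cutoff_rank: int
    ranking_mark: str
    chromsizes: object = None

    @property
    def n_se(self) -> int:
        return int(self.table["is_se"].sum())

    def _subset(self, mask) -> RegionSet:
        df = self.table.loc[mask, ["chrom", "start", "end", "name"]].copy()
        df["score"] = self.table.loc[mask, "signal"]
        df["strand"] = "."
        return RegionSet(df.reset_index(drop=True), chromsizes=self.chromsizes)

    def se_regions(self) -> RegionSet:
        return self._subset(self.table["is_se"].to_numpy())

    def te_regions(self) -> RegionSet:
        return self._subset(~self.table["is_se"].to_numpy())

    def spans(self) -> RegionSet:
        return self._subset(np.ones(len(self.table), dtype=bool))


def call_superenhancers(
    enhancers: RegionSet,
    ranking_counts: CountMatrix,
    input_counts: CountMatrix | None,
    genes: list[GeneModel],
    stitch_gap: int = 12_500,
    promoter_exclusion: int = 2_000,
    ranking_mark: str = "H3K27ac",
) -> SECallResult:
    """Full stitched-entity calling pipeline on an enhancer catalog.

    Promoter-proximal enhancers (midpoint within ``promoter_exclusion`` of a
    TSS) are removed before stitching; signal is re-counted over each
    stitched span (not summed over constituents); ties in signal rank break
    by genomic position, so the call is deterministic.
    """
    if len(enhancers) == 0:
        raise ValueError("empty enhancer catalog")
    keep = np.ones(len(enhancers), dtype=bool)
    if genes and promoter_exclusion > 0:
        d = nearest_tss(enhancers, genes)["abs_distance"].to_numpy()
        keep &= ~np.where(np.isnan(d), False, d <= promoter_exclusion)
    distal = enhancers.subset(keep).sorted()
    stitched = stitch(distal, max_gap=stitch_gap)
    n = len(stitched.regions)
    if n < 3:
        raise ValueError(f"only {n} stitched entities; need at least 3")
    signal = quantify(stitched.regions, ranking_counts, input_counts)
    cutoff, order = rank_cutoff(signal)
    spans = stitched.regions
    assign = nearest_tss(spans, genes) if genes else None
    rows = []
    constituents = []
    for rank, idx in enumerate(order):
        rows.append(
            {
                "chrom": spans.chroms[idx],
                "start": int(spans.starts[idx]),
                "end": int(spans.ends[idx]),
                "name": f"entity_{rank:05d}",
                "n_constituents": int(stitched.constituents[idx].size),
                "signal": float(signal[idx]),
                "rank": rank,
                "is_se": rank > cutoff,
                "gene_id": assign["gene_id"].iloc[idx] if assign is not None
                else "unassigned",
                "tss_distance": float(assign["distance"].iloc[idx])
                if assign is not None else np.nan,
            }
        )
        constituents.append(stitched.constituents[idx])
    table = pd.DataFrame(rows)
    return SECallResult(
        table=table, constituents=constituents, cutoff_rank=cutoff,
        ranking_mark=ranking_mark, chromsizes=enhancers.chromsizes,
    )


def binding_fraction(
    se: RegionSet,
    te: RegionSet,
    tf_peaks: RegionSet,
) -> tuple[float, float, TestResult]:
    """Fraction of SE and TE entities bound (>= 1 bp) by a TF, with Fisher p."""
    if len(se) == 0 or len(te) == 0:
        raise ValueError("empty SE or TE category")
    se_bound = int(overlap(se, tf_peaks).n_overlapping) if len(tf_peaks) else 0
    te_bound = int(overlap(te, tf_peaks).n_overlapping) if len(tf_peaks) else 0
    frac_se = se_bound / len(se)
    frac_te = te_bound / len(te)
    if se_bound + te_bound == 0 or \
            (se_bound == len(se) and te_bound == len(te)):
        # degenerate: identical margins give p = 1 without calling Fisher
        test = TestResult(1.0, 1.0, "two", "fisher_exact")
    else:
        test = fisher_exact(
            (se_bound, len(se) - se_bound, te_bound, len(te) - te_bound),
            sided="two",
        )
    return frac_se, frac_te, test


def occupancy_correlation(
    se: RegionSet,
    counts_a: CountMatrix,
    counts_b: CountMatrix,
    pseudocount: float = 1.0,
) -> tuple[float, TestResult]:
    """Pearson r between two marks' mean SE signal, log2 scale.

    Per SE: pooled rpm/bp for each mark, then ``log2(x + pseudocount)``.
    """
    if len(se) < 3:
        raise ValueError("need at least 3 super-enhancers")
    widths = se.widths.astype(float)
    sig = []
    for cm in (counts_a, counts_b):
        rc = cm.recount(se)
        counts, lib = rc.pooled()
        sig.append(np.log2(counts / (lib / 1e6) / widths + pseudocount))
    return pearson(sig[0], sig[1])


def metaprofile(
    regions: RegionSet,
    coverage: CoverageTrack,
    flank: int = 5_000,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Mean coverage on a common bin grid centered on region centers.

    Each region contributes its coverage over ``[center - flank,
    center + flank)`` split into ``n_bins``; bins clipped away by a
    chromosome edge simply do not contribute (per-bin contributing-region
    counts are reported).
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    edges = np.linspace(-flank, flank, n_bins + 1)
    total = np.zeros(n_bins)
    n_contrib = np.zeros(n_bins, dtype=int)
    for i in range(len(regions)):
        chrom = regions.chroms[i]
        center = regions.midpoints[i]
        chrom_len = (
            coverage.chromsizes[chrom] if chrom in coverage.chromsizes else None
        )
        for b in range(n_bins):
            lo = center + edges[b]
            hi = center + edges[b + 1]
            if hi <= 0 or (chrom_len is not None and lo >= chrom_len):
                continue
            lo_c = max(lo, 0)
            hi_c = min(hi, chrom_len) if chrom_len is not None else hi
            if hi_c <= lo_c:
                continue
            total[b] += coverage.mean(chrom, lo_c, hi_c)
            n_contrib[b] += 1
    mean = np.divide(total, n_contrib, out=np.full(n_bins, np.nan),
                     where=n_contrib > 0)
    centers = (edges[:-1] + edges[1:]) / 2
    return pd.DataFrame(
        {"offset": centers, "mean_signal": mean, "n_regions": n_contrib}
    )


def se_precision_recall(call: SECallResult, truth_se: RegionSet) -> tuple[float, float]:
    """Precision and recall of called SE spans against planted SE spans.

    A called SE counts as true when it overlaps (>= 1 bp) a planted span;
    a planted span is recovered when some called SE overlaps it.
    """
    called = call.se_regions()
    if len(called) == 0:
        return float("nan"), 0.0
    if len(truth_se) == 0:
        return 0.0, float("nan")
    precision = overlap(called, truth_se).fraction()
    recall = overlap(truth_se, called).fraction()
    return float(precision), float(recall)
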