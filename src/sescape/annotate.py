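"""Chromatin-element classification from histone-mark co-occupancy.

Element definitions follow the standard two-mark logic: active enhancers are
H3K4me1 peaks also carrying H3K27ac (away from promoters), poised enhancers
are H3K4me1 with H3K27me3 instead, and active promoters are H3K4me3 peaks
with H3K27ac. Element coordinates are anchored on the defining mark's peak
(H3K4me1 for enhancers, H3K4me3 for promoters); the intersection is
available as an alternative anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import ChromSizes, GeneModel, RegionSet, overlap, nearest_tss
from .stats import TestResult, hypergeom_overlap

__all__ = [
    "ElementCatalog",
    "define_elements",
    "classify_vs_tss",
    "feature_association",
    "compare_peak_sets",
]


@dataclass
class ElementCatalog:
    active_enhancers: RegionSet
    poised_enhancers: RegionSet
    active_promoters: RegionSet
    provenance: dict[str, str]


def _tss_proximal(regions: RegionSet, genes: list[GeneModel],
                  halfwidth: int) -> np.ndarray:
    """True where the region midpoint lies within +/- halfwidth of any TSS."""
    if not genes or len(regions) == 0:
        return np.zeros(len(regions), dtype=bool)
    assign = nearest_tss(regions, genes)
    d = assign["abs_distance"].to_numpy()
    return np.where(np.isnan(d), False, d <= halfwidth)


def define_elements(
    h3k27ac: RegionSet,
    h3k4me1: RegionSet,
    h3k4me3: RegionSet,
    h3k27me3: RegionSet,
    genes: list[GeneModel] | None = None,
    promoter_halfwidth: int = 2_000,
    anchor: str = "defining_mark",
) -> ElementCatalog:
    """Build the element catalog from the four mark peak sets.

    An H3K4me1 peak overlapping both H3K27ac and H3K27me3 counts as active,
    not poised (the activating mark wins). When ``genes`` is given, active
    enhancers within ``promoter_halfwidth`` of a TSS are dropped.
    """
    if anchor not in ("defining_mark", "intersection"):
        raise ValueError("anchor must be 'defining_mark' or 'intersection'")
    for rs, mark in ((h3k27ac, "H3K27ac"), (h3k4me1, "H3K4me1")):
        if len(rs) == 0:
            warnings.warn(f"empty {mark} peak set: catalog will be empty")
    with_k27ac = overlap(h3k4me1, h3k27ac).flags
    with_k27me3 = overlap(h3k4me1, h3k27me3).flags
    active_mask = with_k27ac.copy()
    if genes:
        active_mask &= ~_tss_proximal(h3k4me1, genes, promoter_halfwidth)
    poised_mask = with_k27me3 & ~with_k27ac
    prom_mask = overlap(h3k4me3, h3k27ac).flags

    def _anchored(anchor_set: RegionSet, mask: np.ndarray,
                  other: RegionSet) -> RegionSet:
        out = anchor_set.subset(mask)
        if anchor == "intersection" and len(out):
            ov = overlap(out, other)
            starts = out.starts.copy()
            ends = out.ends.copy()
            for i in range(len(out)):
                if ov.hits[i].size:
                    starts[i] = max(starts[i], other.starts[ov.hits[i]].min())
                    ends[i] = min(ends[i], other.ends[ov.hits[i]].max())
            df = out.df.copy()
            df["start"], df["end"] = starts, ends
            out = RegionSet(df, chromsizes=out.chromsizes, label=out.label)
        return out

    catalog = ElementCatalog(
        active_enhancers=_anchored(h3k4me1, active_mask, h3k27ac),
        poised_enhancers=_anchored(h3k4me1, poised_mask, h3k27me3),
        active_promoters=_anchored(h3k4me3, prom_mask, h3k27ac),
        provenance={
            "active_enhancers": "H3K4me1 & H3K27ac, promoter-distal",
            "poised_enhancers": "H3K4me1 & H3K27me3, not H3K27ac",
            "active_promoters": "H3K4me3 & H3K27ac",
            "anchor": anchor,
        },
    )
    return catalog


def classify_vs_tss(
    peaks: RegionSet,
    genes: list[GeneModel],
    promoter_halfwidth: int = 2_000,
) -> pd.DataFrame:
    """Label each peak promoter / intragenic / intergenic by its midpoint.

    Priority promoter > intragenic > intergenic; the labels partition the
    set. Returns ``label``, ``gene_id`` (nearest TSS), ``distance``.
    """
    if not genes:
        raise ValueError("need at least one gene")
    assign = nearest_tss(peaks, genes)
    labels = np.full(len(peaks), "intergenic", dtype=object)
    mids = peaks.midpoints
    chroms = peaks.chroms
    body_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in genes:
        body_by_chrom.setdefault(g.chrom, ([], []))
        body_by_chrom[g.chrom][0].append(g.body.start)
        body_by_chrom[g.chrom][1].append(g.body.end)
    body_by_chrom = {
        c: (np.array(s), np.array(e)) for c, (s, e) in body_by_chrom.items()
    }
    for i in range(len(peaks)):
        d = assign["abs_distance"].iloc[i]
        if not np.isnan(d) and d <= promoter_halfwidth:
            labels[i] = "promoter"
            continue
        bodies = body_by_chrom.get(chroms[i])
        if bodies is not None and (
            (bodies[0] <= mids[i]) & (mids[i] < bodies[1])
        ).any():
            labels[i] = "intragenic"
    out = assign.copy()
    out.insert(0, "label", labels)
    return out


def feature_association(
    peaks: RegionSet,
    catalog: ElementCatalog,
    chromsizes: ChromSizes,
    segmentation,
    n_random: int,
    seed: int,
) -> pd.DataFrame:
    """Observed peak counts per element class vs matched-random expectation.

    The random expectation repeats the same overlap count on ``n_random``
    chromosome- and size-matched shuffles of the peaks restricted to
    permissive chromatin (see :func:`sescape.snp_enrichment.shuffle_matched`).
    """
    from .snp_enrichment import shuffle_matched  # circular at module level

    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    classes = {
        "active_enhancers": catalog.active_enhancers,
        "poised_enhancers": catalog.poised_enhancers,
        "active_promoters": catalog.active_promoters,
    }
    shuffles = shuffle_matched(peaks, segmentation, chromsizes, seed=seed,
                               n_perm=n_random)
    rows = []
    for name, subject in classes.items():
        observed = overlap(peaks, subject).n_overlapping if len(subject) else 0
        rand = np.array(
            [
                overlap(sh, subject).n_overlapping if len(subject) else 0
                for sh in shuffles
            ],
            dtype=float,
        )
        expected = float(rand.mean())
        fold = observed / expected if expected > 0 else np.inf
        rows.append((name, observed, expected, fold))
    return pd.DataFrame(
        rows, columns=["element_class", "observed", "expected_random", "fold"]
    )


def compare_peak_sets(
    set_a: RegionSet,
    set_b: RegionSet,
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    tss_window: int = 1_000,
) -> dict:
    """Shared vs unique binding sites between two cell types.

    Shared means >= 1 bp reciprocal overlap. Reports the shared fraction of
    each set, the fraction of shared and unique sites within
    ``+/-tss_window`` of a TSS, and a hypergeometric test on the overlap of
    nearest-TSS-assigned genes (universe = union of both annotations).
    """
    flags_a = overlap(set_a, set_b).flags
    flags_b = overlap(set_b, set_a).flags

    def _tss_frac(rs: RegionSet, mask: np.ndarray,
                  genes: list[GeneModel]) -> float:
        if mask.sum() == 0 or not genes:
            return float("nan")
        sub = rs.subset(mask)
        return float(_tss_proximal(sub, genes, tss_window).mean())

    genes_a_ids = (
        set(nearest_tss(set_a, genes_a)["gene_id"]) - {"unassigned"}
        if len(set_a) and genes_a else set()
    )
    genes_b_ids = (
        set(nearest_tss(set_b, genes_b)["gene_id"]) - {"unassigned"}
        if len(set_b) and genes_b else set()
    )
    universe = {g.gene_id for g in genes_a} | {g.gene_id for g in genes_b}
    k = len(genes_a_ids & genes_b_ids)
    gene_test: TestResult = hypergeom_overlap(
        k, len(genes_a_ids), len(genes_b_ids), max(len(universe), 1)
    )
    return {
        "shared_fraction_a": float(flags_a.mean()) if len(set_a) else 0.0,
        "shared_fraction_b": float(flags_b.mean()) if len(set_b) else 0.0,
        "shared_tss_fraction_a": _tss_frac(set_a, flags_a, genes_a),
        "unique_tss_fraction_a": _tss_frac(set_a, ~flags_a, genes_a),
        "shared_tss_fraction_b": _tss_frac(set_b, flags_b, genes_b),
        "unique_tss_fraction_b": _tss_frac(set_b, ~flags_b, genes_b),
        "gene_overlap_k": k,
        "gene_overlap_test": gene_test,
    }
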