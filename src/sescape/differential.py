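"""Two-condition differential enrichment at regions and super-enhancers.

The statistic is an exact conditional binomial rate-ratio test on pooled
counts: given a region's total ``t = a + b`` reads across the two
conditions, the knockdown count ``a`` is Binomial(t, L_kd/(L_kd + L_ctl))
under no change, and the two-sided p doubles the smaller tail (capped at
1). The effect size is ``log2((kd_rpm + psi)/(ctl_rpm + psi))`` with a
pseudocount on the rpm scale. Regions are classed loss / gain / unchanged
by the volcano thresholds |log2FC| >= 1 and -log10(p) >= 4; super-enhancer
spans use the milder |log2FC| >= 0.58 (fold change 1.5) with the same p
threshold and classes decreased / increased / constant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .intervals import CountMatrix, GeneModel, RegionSet, nearest_tss
from .stats import kruskal_wallis, rank_sum

__all__ = [
    "differential_regions",
    "differential_superenhancers",
    "integrate_expression",
    "cofactor_occupancy_change",
]

_LN10 = np.log(10.0)


def _conditional_binomial(a, b, lib_kd, lib_ctl):
    """Two-sided exact conditional test, returned as -log10(p) (stable)."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    t = a + b
    q = lib_kd / (lib_kd + lib_ctl)
    log_lower = sps.binom.logcdf(a, t, q)
    log_upper = sps.binom.logsf(a - 1, t, q)
    logp = np.log(2.0) + np.minimum(log_lower, log_upper)
    logp = np.minimum(logp, 0.0)
    neg_log10 = -logp / _LN10
    return np.exp(logp), neg_log10


def differential_regions(
    ctl: CountMatrix,
    kd: CountMatrix,
    fc_thresh: float = 1.0,
    p_thresh: float = 4.0,
    pseudocount: float = 1.0,
    labels: tuple[str, str, str] = ("loss", "gain", "unchanged"),
) -> pd.DataFrame:
    """Per-region differential table with loss / gain / unchanged classes.

    Samples within each condition are pooled (counts and library sizes
    summed). Thresholds: ``klass = loss`` iff ``log2fc <= -fc_thresh`` and
    ``neg_log10_p >= p_thresh``; gain symmetric; otherwise unchanged.
    """
    if len(ctl.regions) != len(kd.regions) or not np.array_equal(
        ctl.regions.starts, kd.regions.starts
    ):
        raise ValueError("control and knockdown matrices cover different regions")
    a, lib_kd = kd.pooled()
    b, lib_ctl = ctl.pooled()
    if lib_kd <= 0 or lib_ctl <= 0:
        raise ValueError("zero library size")
    rpm_kd = a / (lib_kd / 1e6)
    rpm_ctl = b / (lib_ctl / 1e6)
    log2fc = np.log2((rpm_kd + pseudocount) / (rpm_ctl + pseudocount))
    p, neg_log10_p = _conditional_binomial(a, b, lib_kd, lib_ctl)
    lo, hi, mid = labels
    klass = np.full(len(a), mid, dtype=object)
    sig = neg_log10_p >= p_thresh
    klass[(log2fc <= -fc_thresh) & sig] = lo
    klass[(log2fc >= fc_thresh) & sig] = hi
    df = ctl.regions.df[["chrom", "start", "end", "name"]].copy()
    df["count_ctl"] = b
    df["count_kd"] = a
    df["log2fc"] = log2fc
    df["p_value"] = p
    df["neg_log10_p"] = neg_log10_p
    df["klass"] = klass
    return df


def differential_superenhancers(
    se_call,
    ctl: CountMatrix,
    kd: CountMatrix,
    fc_thresh: float = 0.58,
    p_thresh: float = 4.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Differential table over the called SE spans.

    Same statistic as :func:`differential_regions`, classes
    decreased / increased / constant at |log2FC| >= 0.58 (FC 1.5).
    """
    spans = se_call.se_regions()
    if len(spans) == 0:
        raise ValueError("no super-enhancers in the call")
    ctl_se = ctl.recount(spans)
    kd_se = kd.recount(spans)
    return differential_regions(
        ctl_se, kd_se, fc_thresh=fc_thresh, p_thresh=p_thresh,
        pseudocount=pseudocount,
        labels=("decreased", "increased", "constant"),
    )


def integrate_expression(
    records: pd.DataFrame,
    expression: pd.DataFrame,
    genes: list[GeneModel],
    fc_column: str = "log2fc",
) -> dict:
    """Expression fold-change distributions per differential class.

    Each region is assigned to its nearest-TSS gene; the gene's expression
    ``log2fc`` is grouped by the region class. Returns the per-class
    distributions plus a Kruskal-Wallis omnibus test and pairwise two-sided
    rank-sum post hoc tests. Classes with no assignable gene are skipped
    (and listed under ``skipped``).
    """
    regions = RegionSet(records[["chrom", "start", "end", "name"]].copy())
    assign = nearest_tss(regions, genes)
    expr_map = dict(zip(expression["gene_id"], expression[fc_column]))
    groups: dict[str, list[float]] = {}
    for klass, gid in zip(records["klass"], assign["gene_id"]):
        if gid in expr_map:
            groups.setdefault(klass, []).append(float(expr_map[gid]))
    skipped = [k for k, v in groups.items() if len(v) == 0]
    groups = {k: np.array(v) for k, v in groups.items() if len(v) > 0}
    for k in set(records["klass"]) - set(groups):
        skipped.append(k)
        warnings.warn(f"class {k!r} has no assignable genes; skipped")
    result = {"groups": groups, "skipped": sorted(set(skipped))}
    if len(groups) >= 2:
        result["kruskal_wallis"] = kruskal_wallis(list(groups.values()))
        pairwise = {}
        names = sorted(groups)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairwise[(names[i], names[j])] = rank_sum(
                    groups[names[i]], groups[names[j]], sided="two"
                )
        result["pairwise"] = pairwise
    return result


def cofactor_occupancy_change(
    cof_ctl: CountMatrix,
    cof_kd: CountMatrix,
    region_classes: pd.Series | np.ndarray,
    pseudocount: float = 1.0,
) -> dict:
    """Cofactor occupancy log2FC grouped by the (histone-mark) region class.

    ``region_classes`` must align row-for-row with the cofactor matrices.
    Returns per-class log2FC arrays and pairwise two-sided rank-sum tests;
    empty classes are skipped with a warning.
    """
    klass = np.asarray(region_classes, dtype=object)
    if len(klass) != len(cof_ctl.regions):
        raise ValueError("class vector does not match cofactor regions")
    a, lib_kd = cof_kd.pooled()
    b, lib_ctl = cof_ctl.pooled()
    log2fc = np.log2(
        (a / (lib_kd / 1e6) + pseudocount) / (b / (lib_ctl / 1e6) + pseudocount)
    )
    groups = {
        k: log2fc[klass == k] for k in pd.unique(klass)
    }
    empty = [k for k, v in groups.items() if v.size == 0]
    for k in empty:
        warnings.warn(f"class {k!r} empty; comparison skipped")
    groups = {k: v for k, v in groups.items() if v.size > 0}
    result: dict = {"groups": groups, "skipped": empty}
    pairwise = {}
    names = sorted(groups)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = rank_sum(
                groups[names[i]], groups[names[j]], sided="two"
            )
    result["pairwise"] = pairwise
    return result
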