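"""Synthetic chromatin landscapes with planted ground truth.

The generator emulates the input side of an endothelial ChIP-seq study:
histone-mark and TF peak sets, per-region read counts for two conditions
(control and knockdown), a chromatin-state segmentation, gene models with
expression, and GWAS-style SNP catalogs. Everything is planted, so every
downstream stage can be scored against a :class:`TruthSet`.

Signal model
------------
Each region carries a latent strength ``s ~ Gamma(shape, 1/shape)`` (mean 1,
shape 5 by default — the standard negative-binomial account of ChIP-seq
overdispersion). Expected reads are ``base_rate_per_bp * width * multiplier
* s`` and observed counts are Poisson around that mean, independently per
condition, so the two conditions share the biological strength and differ
only by planted fold changes plus counting noise. Planted super-enhancer
constituents get a ``se_multiplier`` (default 5x) over singleton enhancers,
which is what puts the knee in the ranked-signal curve.

TF binding is Bernoulli per *entity* (per planted cluster or per singleton);
a bound cluster places a TF peak on every constituent. Trait SNPs are
rejection-placed with a relative risk inside planted super-enhancer spans
versus the rest of permissive chromatin; repressed segments carry no peaks
and no SNPs by construction.
"""

from __future__ import annotations


from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import (
    ChromSizes,
    CountMatrix,
    GeneModel,
    GenomicInterval,
    RegionSet,
    nearest_tss,
    write_chrom_sizes,
    write_gene_table,
    write_regions,
    read_chrom_sizes,
    read_gene_table,
    read_regions,
)

__all__ = [
    "SyntheticConfig",
    "TruthSet",
    "SyntheticDataset",
    "generate",
    "worked_example",
    "load_dataset",
]

_GENE_PAD = 1_000  # bp kept free around a gene body for its promoter peaks


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic landscape.

    Defaults are the conditions the acceptance properties are stated at:
    ~25 planted super-enhancer clusters among ~250 singleton enhancers on a
    30 Mb genome, 5x constituent signal, entity-level TF binding
    probabilities 0.9 (SE) / 0.3 (TE), knockdown effect |log2FC| = 1.5, and
    a single trait with relative risk 5 inside planted SE spans.
    """

    seed: int = 7
    n_chroms: int = 3
    chrom_length: int = 10_000_000
    n_genes: int = 300
    gene_body_range: tuple[int, int] = (5_000, 30_000)
    n_enhancer_clusters: int = 25
    cluster_size: tuple[int, int] = (3, 6)
    within_cluster_gap: tuple[int, int] = (200, 2_000)
    n_singleton_enhancers: int = 250
    n_poised_enhancers: int = 40
    enhancer_width: tuple[int, int] = (800, 2_000)
    entity_spacing: tuple[int, int] = (13_000, 18_000)
    # signal model
    gamma_shape: float = 5.0
    base_rate_per_bp: float = 0.05
    se_multiplier: float = 5.0
    # per-cluster boost on top of se_multiplier: log-uniform over
    # [1, 10**spread], giving the ranked curve the orders-of-magnitude
    # dynamic range real hockey plots show; 0 = strict uniform multiplier
    se_multiplier_log10_spread: float = 1.0
    med1_rate_factor: float = 0.5
    tf_rate_factor: float = 1.0
    tf_background_factor: float = 0.02
    input_rate_factor: float = 0.04
    mark_noise_shape: float = 10.0   # extra per-mark Gamma noise (MED1, TF)
    library_size: int = 2_000_000
    promoter_h3k27ac_fraction: float = 0.7
    # TF binding (per entity)
    tf_bind_prob_se: float = 0.9
    tf_bind_prob_te: float = 0.3
    # differential planting
    fraction_loss: float = 0.15
    fraction_gain: float = 0.05
    effect_log2fc: float = 1.5
    cluster_loss_fraction: float = 0.25
    # expression coupling
    expr_mean_se: float = 7.0
    expr_mean_te: float = 5.0
    expr_mean_other: float = 4.0
    expr_sd: float = 1.0
    expr_fc_effect: float = 1.2
    expr_fc_sd: float = 0.4
    expr_fc_null_sd: float = 0.25
    # SNP catalog
    snp_background_per_mb: float = 100.0
    n_trait_snps: int = 200
    trait_rr: float = 5.0
    n_null_traits: int = 9
    # chromatin states
    repressed_fraction: float = 0.3
    state_block: int = 100_000

    def validate(self) -> None:
        for p in (
            self.tf_bind_prob_se, self.tf_bind_prob_te,
            self.fraction_loss, self.fraction_gain,
            self.cluster_loss_fraction, self.repressed_fraction,
            self.promoter_h3k27ac_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if not np.isfinite(self.effect_log2fc):
            raise ValueError("effect_log2fc must be finite")
        if self.trait_rr <= 0:
            raise ValueError("trait_rr must be positive")


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside the synthetic data."""

    planted_se: RegionSet                 # cluster spans, named cluster_<id>
    loss_region_names: list[str]
    gain_region_names: list[str]
    decreased_cluster_names: list[str]    # clusters planted to lose signal
    tf_bound: dict[str, bool]             # per entity (cluster or singleton)
    trait_rr: dict[str, float]

    def loss_set(self) -> set[str]:
        return set(self.loss_region_names)

    def gain_set(self) -> set[str]:
        return set(self.gain_region_names)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig | None
    chromsizes: ChromSizes
    genes: list[GeneModel]
    peaks: dict[str, RegionSet]           # mark -> peak set
    counts: dict[str, dict[str, CountMatrix]]  # mark -> condition -> matrix
    expression: pd.DataFrame              # gene_id, expression, log2fc
    segmentation: RegionSet               # name column holds the state label
    snps: pd.DataFrame                    # chrom, pos (1-based), rsid, trait
    truth: TruthSet

    def write(self, outdir) -> None:
        out = Path(outdir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        (out / "counts").mkdir(exist_ok=True)
        (out / "truth").mkdir(exist_ok=True)
        write_chrom_sizes(self.chromsizes, out / "chrom.sizes")
        write_gene_table(self.genes, out / "genes.tsv")
        for mark, rs in self.peaks.items():
            write_regions(rs, out / "peaks" / f"{mark}.bed")
        for mark, conds in self.counts.items():
            for cond, cm in conds.items():
                cm.to_tsv(out / "counts" / f"{mark}_{cond}.counts.tsv")
        with open(out / "expression.tsv", "w") as fh:
            fh.write("# gene_id\texpression\tlog2fc\n")
            for row in self.expression.itertuples(index=False):
                fh.write(f"{row.gene_id}\t{row.expression:.6f}\t{row.log2fc:.6f}\n")
        write_regions(self.segmentation, out / "segmentation.bed")
        with open(out / "snps.tsv", "w") as fh:
            fh.write("# chrom\tpos_1based\trsid\ttrait\n")
            for row in self.snps.itertuples(index=False):
                fh.write(f"{row.chrom}\t{row.pos}\t{row.rsid}\t{row.trait}\n")
        write_regions(self.truth.planted_se, out / "truth" / "planted_se.bed")
        with open(out / "truth" / "regions.tsv", "w") as fh:
            fh.write("# name\ttruth\n")
            for n in self.truth.loss_region_names:
                fh.write(f"{n}\tloss\n")
            for n in self.truth.gain_region_names:
                fh.write(f"{n}\tgain\n")
            for n in self.truth.decreased_cluster_names:
                fh.write(f"{n}\tdecreased_cluster\n")
            for n, b in self.truth.tf_bound.items():
                fh.write(f"{n}\t{'bound' if b else 'unbound'}\n")
        with open(out / "truth" / "traits.tsv", "w") as fh:
            fh.write("# trait\trelative_risk\n")
            for t, rr in self.truth.trait_rr.items():
                fh.write(f"{t}\t{rr}\n")
        if self.config is not None:
            with open(out / "config.yaml", "w") as fh:
                yaml.safe_dump(asdict(self.config), fh, sort_keys=True)

    def permissive_territory(self) -> RegionSet:
        mask = self.segmentation.df["name"] == "permissive"
        return self.segmentation.subset(mask.to_numpy())


# ---------------------------------------------------------------------------
# placement


def _segmentation(cfg: SyntheticConfig, rng) -> tuple[RegionSet, ChromSizes]:
    chromsizes = ChromSizes(
        [(f"chr{i + 1}", cfg.chrom_length) for i in range(cfg.n_chroms)]
    )
    rows = []
    for chrom in chromsizes:
        n_blocks = cfg.chrom_length // cfg.state_block
        repressed = rng.random(n_blocks) < cfg.repressed_fraction
        state = np.where(repressed, "repressed", "permissive")
        # merge runs of equal state
        start = 0
        for i in range(n_blocks):
            end_of_run = i == n_blocks - 1 or state[i + 1] != state[i]
            if end_of_run:
                hi = (i + 1) * cfg.state_block
                if i == n_blocks - 1:
                    hi = cfg.chrom_length
                rows.append((chrom, start, hi, state[i], np.nan, "."))
                start = hi
    seg = RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end", "name",
                                    "score", "strand"]),
        chromsizes=chromsizes,
        label="chromatin_states",
    )
    return seg, chromsizes


def _place_entities(cfg: SyntheticConfig, seg: RegionSet, rng):
    """Greedy sequential placement of shuffled entities into permissive runs.

    Entities never cross a repressed block and keep >= entity_spacing bp of
    clear ground between each other, which is above the 12.5 kb stitching
    gap — so distinct entities never stitch together.
    """
    entities: list[dict] = []
    for i in range(cfg.n_genes):
        body = int(rng.integers(cfg.gene_body_range[0],
                                cfg.gene_body_range[1] + 1))
        entities.append(
            {"kind": "gene", "id": i, "width": body + 2 * _GENE_PAD,
             "body": body,
             "strand": "+" if rng.random() < 0.5 else "-"}
        )
    for c in range(cfg.n_enhancer_clusters):
        k = int(rng.integers(cfg.cluster_size[0], cfg.cluster_size[1] + 1))
        widths = rng.integers(cfg.enhancer_width[0],
                              cfg.enhancer_width[1] + 1, size=k)
        gaps = rng.integers(cfg.within_cluster_gap[0],
                            cfg.within_cluster_gap[1] + 1, size=max(k - 1, 0))
        entities.append(
            {"kind": "cluster", "id": c, "widths": widths, "gaps": gaps,
             "width": int(widths.sum() + gaps.sum())}
        )
    for i in range(cfg.n_singleton_enhancers):
        w = int(rng.integers(cfg.enhancer_width[0], cfg.enhancer_width[1] + 1))
        entities.append({"kind": "singleton", "id": i, "width": w})
    for i in range(cfg.n_poised_enhancers):
        w = int(rng.integers(cfg.enhancer_width[0], cfg.enhancer_width[1] + 1))
        entities.append({"kind": "poised", "id": i, "width": w})
    order = rng.permutation(len(entities))
    queue = [entities[i] for i in order]

    placed = []
    qi = 0
    perm = seg.df[seg.df["name"] == "permissive"]
    for row in perm.itertuples(index=False):
        pos = row.start + int(rng.integers(500, 2_000))
        while qi < len(queue):
            ent = queue[qi]
            if pos + ent["width"] > row.end - 500:
                break
            placed.append({**ent, "chrom": row.chrom, "start": pos})
            pos += ent["width"] + int(
                rng.integers(cfg.entity_spacing[0], cfg.entity_spacing[1] + 1)
            )
            qi += 1
        if qi == len(queue):
            break
    if qi < len(queue):
        raise ValueError(
            f"genome too small: {len(queue) - qi} entities could not be "
            "placed in permissive territory"
        )
    return placed


def _region_df(rows):
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]
    )


def _gamma_poisson(rng, mean, shape):
    """NB counts: Poisson around a Gamma(shape, mean/shape) rate."""
    mean = np.asarray(mean, dtype=float)
    lam = rng.gamma(shape, mean / shape)
    return rng.poisson(lam)


def generate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate a full synthetic landscape with planted truth.

    Deterministic given ``config.seed``: the same config yields
    byte-identical files from :meth:`SyntheticDataset.write`.
    """
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    seg, chromsizes = _segmentation(cfg, rng)
    placed = _place_entities(cfg, seg, rng)

    genes: list[GeneModel] = []
    enh_rows = []           # individual enhancer regions
    enh_meta = []           # kind, cluster_id, entity name
    poised_rows = []
    cluster_spans: dict[int, tuple[str, int, int]] = {}
    for ent in placed:
        chrom, start = ent["chrom"], ent["start"]
        if ent["kind"] == "gene":
            body_start = start + _GENE_PAD
            body_end = body_start + ent["body"]
            tss = body_start if ent["strand"] == "+" else body_end - 1
            genes.append(
                GeneModel(
                    f"gene_{ent['id']:04d}", chrom, ent["strand"], tss,
                    GenomicInterval(chrom, body_start, body_end,
                                    strand=ent["strand"]),
                )
            )
        elif ent["kind"] == "cluster":
            pos = start
            for j, w in enumerate(ent["widths"]):
                name = f"enh_c{ent['id']:03d}_{j}"
                enh_rows.append((chrom, pos, pos + int(w), name, np.nan, "."))
                enh_meta.append(("cluster", ent["id"], name))
                pos += int(w)
                if j < len(ent["gaps"]):
                    pos += int(ent["gaps"][j])
            cluster_spans[ent["id"]] = (chrom, start, pos)
        elif ent["kind"] == "singleton":
            name = f"enh_s{ent['id']:04d}"
            enh_rows.append(
                (chrom, start, start + ent["width"], name, np.nan, ".")
            )
            enh_meta.append(("singleton", -1, name))
        else:  # poised
            poised_rows.append(
                (chrom, start, start + ent["width"],
                 f"poised_{ent['id']:03d}", np.nan, ".")
            )

    enh = RegionSet(_region_df(enh_rows), chromsizes=chromsizes,
                    label="enhancers")
    kinds = np.array([m[0] for m in enh_meta])
    cluster_ids = np.array([m[1] for m in enh_meta])
    enh_names = np.array([m[2] for m in enh_meta], dtype=object)
    is_cluster = kinds == "cluster"

    # --- TF binding: Bernoulli per entity -----------------------------------
    bound_cluster = {
        c: bool(rng.random() < cfg.tf_bind_prob_se) for c in sorted(cluster_spans)
    }
    tf_bound_region = np.zeros(len(enh), dtype=bool)
    tf_bound_entity: dict[str, bool] = {}
    for i in range(len(enh)):
        if is_cluster[i]:
            tf_bound_region[i] = bound_cluster[cluster_ids[i]]
        else:
            tf_bound_region[i] = bool(rng.random() < cfg.tf_bind_prob_te)
            tf_bound_entity[enh_names[i]] = bool(tf_bound_region[i])
    for c, b in bound_cluster.items():
        tf_bound_entity[f"cluster_{c:03d}"] = b

    # --- differential planting ----------------------------------------------
    n_loss_clusters = int(round(cfg.cluster_loss_fraction
                                * cfg.n_enhancer_clusters))
    loss_clusters = sorted(
        rng.choice(sorted(cluster_spans), size=n_loss_clusters, replace=False)
    ) if n_loss_clusters else []
    loss_mask = np.isin(cluster_ids, loss_clusters) & is_cluster
    n_loss_target = int(round(cfg.fraction_loss * len(enh)))
    singles = np.flatnonzero(~is_cluster & ~loss_mask)
    extra = max(0, n_loss_target - int(loss_mask.sum()))
    if extra > len(singles):
        raise ValueError("fraction_loss too large for the enhancer count")
    pick = rng.choice(singles, size=extra, replace=False)
    loss_mask[pick] = True
    remaining = np.flatnonzero(~is_cluster & ~loss_mask)
    n_gain = int(round(cfg.fraction_gain * len(enh)))
    if n_gain > len(remaining):
        raise ValueError("fraction_gain too large for the enhancer count")
    gain_mask = np.zeros(len(enh), dtype=bool)
    gain_mask[rng.choice(remaining, size=n_gain, replace=False)] = True

    # --- peak sets -----------------------------------------------------------
    pad = 200
    h3k4me1_rows = [
        (r.chrom, max(0, r.start - pad), r.end + pad, f"k4me1_{r.name}",
         np.nan, ".")
        for r in enh.df.itertuples(index=False)
    ] + [
        (c, s, e, f"k4me1_{n}", np.nan, ".")
        for c, s, e, n, _sc, _st in poised_rows
    ]
    h3k27me3_rows = [
        (c, s, e, f"k27me3_{n}", np.nan, ".") for c, s, e, n, _sc, _st
        in poised_rows
    ]
    promoter_rows = []
    prom_k27_rows = []
    for g in genes:
        lo, hi = max(0, g.tss - 500), g.tss + 500
        promoter_rows.append((g.chrom, lo, hi, f"k4me3_{g.gene_id}", np.nan, "."))
        if rng.random() < cfg.promoter_h3k27ac_fraction:
            prom_k27_rows.append(
                (g.chrom, lo, hi, f"prom_{g.gene_id}", np.nan, ".")
            )
    tf_rows = []
    for i in np.flatnonzero(tf_bound_region):
        mid = (enh.starts[i] + enh.ends[i]) // 2
        tf_rows.append(
            (enh.chroms[i], int(mid - 200), int(mid + 200),
             f"tf_{enh_names[i]}", np.nan, ".")
        )
    med1_rows = [
        (enh.chroms[i], int(enh.starts[i]), int(enh.ends[i]),
         f"med1_{enh_names[i]}", np.nan, ".")
        for i in np.flatnonzero(is_cluster | tf_bound_region)
    ]

    # the H3K27ac "bound regions" list drives all count matrices
    k27_rows = list(enh.df.itertuples(index=False, name=None)) + prom_k27_rows
    k27_regions = RegionSet(_region_df(k27_rows), chromsizes=chromsizes,
                            label="H3K27ac_regions")
    n_enh = len(enh)
    n_k27 = len(k27_regions)
    is_promoter_region = np.zeros(n_k27, dtype=bool)
    is_promoter_region[n_enh:] = True

    peaks = {
        "H3K27ac": k27_regions,
        "H3K4me1": RegionSet(_region_df(h3k4me1_rows), chromsizes=chromsizes,
                             label="H3K4me1"),
        "H3K4me3": RegionSet(_region_df(promoter_rows), chromsizes=chromsizes,
                             label="H3K4me3"),
        "H3K27me3": RegionSet(_region_df(h3k27me3_rows), chromsizes=chromsizes,
                              label="H3K27me3"),
        "TF": RegionSet(_region_df(tf_rows), chromsizes=chromsizes, label="TF"),
        "MED1": RegionSet(_region_df(med1_rows), chromsizes=chromsizes,
                          label="MED1"),
    }

    # --- counts --------------------------------------------------------------
    widths = k27_regions.widths.astype(float)
    strength = rng.gamma(cfg.gamma_shape, 1.0 / cfg.gamma_shape, size=n_k27)
    cluster_mult = {
        c: cfg.se_multiplier
        * 10.0 ** rng.uniform(0.0, cfg.se_multiplier_log10_spread)
        for c in sorted(cluster_spans)
    }
    multiplier = np.ones(n_k27)
    for i in np.flatnonzero(is_cluster):
        multiplier[i] = cluster_mult[cluster_ids[i]]
    base_mean = cfg.base_rate_per_bp * widths * multiplier * strength
    loss_all = np.zeros(n_k27, dtype=bool)
    gain_all = np.zeros(n_k27, dtype=bool)
    loss_all[:n_enh] = loss_mask
    gain_all[:n_enh] = gain_mask
    kd_factor = np.ones(n_k27)
    kd_factor[loss_all] = 2.0 ** (-cfg.effect_log2fc)
    kd_factor[gain_all] = 2.0 ** (cfg.effect_log2fc)

    lib = np.array([cfg.library_size])

    def _cm(mean):
        return CountMatrix(k27_regions, rng.poisson(mean)[:, None], lib)

    med1_noise = rng.gamma(cfg.mark_noise_shape, 1.0 / cfg.mark_noise_shape,
                           size=n_k27)
    med1_mean = cfg.med1_rate_factor * base_mean * med1_noise
    tf_noise = rng.gamma(cfg.mark_noise_shape, 1.0 / cfg.mark_noise_shape,
                         size=n_k27)
    tf_bound_all = np.zeros(n_k27, dtype=bool)
    tf_bound_all[:n_enh] = tf_bound_region
    tf_mean = np.where(
        tf_bound_all,
        cfg.tf_rate_factor * base_mean * tf_noise,
        cfg.tf_background_factor * cfg.base_rate_per_bp * widths,
    )
    input_mean = cfg.input_rate_factor * cfg.base_rate_per_bp * widths

    counts = {
        "H3K27ac": {"ctl": _cm(base_mean), "kd": _cm(base_mean * kd_factor)},
        "MED1": {"ctl": _cm(med1_mean), "kd": _cm(med1_mean * kd_factor)},
        "TF": {"ctl": _cm(tf_mean)},
        "input": {"ctl": _cm(input_mean)},
    }

    # --- truth ---------------------------------------------------------------
    se_rows = [
        (c, s, e, f"cluster_{cid:03d}", np.nan, ".")
        for cid, (c, s, e) in sorted(cluster_spans.items())
    ]
    planted_se = RegionSet(_region_df(se_rows), chromsizes=chromsizes,
                           label="planted_se")
    truth = TruthSet(
        planted_se=planted_se,
        loss_region_names=sorted(enh_names[loss_mask]),
        gain_region_names=sorted(enh_names[gain_mask]),
        decreased_cluster_names=[f"cluster_{c:03d}" for c in loss_clusters],
        tf_bound=tf_bound_entity,
        trait_rr={},
    )

    # --- expression ----------------------------------------------------------
    se_gene_ids = set(nearest_tss(planted_se, genes)["gene_id"]) - {"unassigned"}
    singles_rs = enh.subset(~is_cluster)
    te_gene_ids = (
        set(nearest_tss(singles_rs, genes)["gene_id"]) - {"unassigned"}
        - se_gene_ids
    )
    loss_rs = k27_regions.subset(loss_all)
    gain_rs = k27_regions.subset(gain_all)
    loss_genes = set(nearest_tss(loss_rs, genes)["gene_id"]) if len(loss_rs) \
        else set()
    gain_genes = (
        set(nearest_tss(gain_rs, genes)["gene_id"]) if len(gain_rs) else set()
    ) - loss_genes
    expr_rows = []
    for g in genes:
        if g.gene_id in se_gene_ids:
            mu = cfg.expr_mean_se
        elif g.gene_id in te_gene_ids:
            mu = cfg.expr_mean_te
        else:
            mu = cfg.expr_mean_other
        expr = rng.normal(mu, cfg.expr_sd)
        if g.gene_id in loss_genes:
            fc = rng.normal(-cfg.expr_fc_effect, cfg.expr_fc_sd)
        elif g.gene_id in gain_genes:
            fc = rng.normal(cfg.expr_fc_effect, cfg.expr_fc_sd)
        else:
            fc = rng.normal(0.0, cfg.expr_fc_null_sd)
        expr_rows.append((g.gene_id, expr, fc))
    expression = pd.DataFrame(expr_rows,
                              columns=["gene_id", "expression", "log2fc"])

    # --- SNPs ----------------------------------------------------------------
    perm_df = seg.df[seg.df["name"] == "permissive"]
    perm_starts = perm_df["start"].to_numpy()
    perm_lens = (perm_df["end"] - perm_df["start"]).to_numpy()
    perm_chroms = perm_df["chrom"].to_numpy()
    perm_total = int(perm_lens.sum())

    def _uniform_positions(n, starts, lens, chroms_arr):
        cum = np.concatenate([[0], np.cumsum(lens)])
        offs = rng.integers(0, cum[-1], size=n)
        seg_i = np.searchsorted(cum, offs, side="right") - 1
        pos0 = starts[seg_i] + (offs - cum[seg_i])
        return chroms_arr[seg_i], pos0

    snp_rows = []
    n_bg = int(rng.poisson(cfg.snp_background_per_mb * perm_total / 1e6))
    c_arr, p_arr = _uniform_positions(n_bg, perm_starts, perm_lens, perm_chroms)
    for i in range(n_bg):
        snp_rows.append((c_arr[i], int(p_arr[i]) + 1, f"bg{i:06d}", "background"))

    se_df = planted_se.df
    se_starts = se_df["start"].to_numpy()
    se_lens = (se_df["end"] - se_df["start"]).to_numpy()
    se_chroms_arr = se_df["chrom"].to_numpy()
    # strata must be exclusive (SE vs permissive-minus-SE); otherwise the
    # mixture is not uniform at relative risk 1
    out_chroms, out_starts, out_lens = [], [], []
    for pc, ps, pl in zip(perm_chroms, perm_starts, perm_lens):
        cuts = [(ps, ps + pl)]
        on_chrom = np.flatnonzero(se_chroms_arr == pc)
        for k in on_chrom:
            s, e = int(se_starts[k]), int(se_starts[k] + se_lens[k])
            nxt = []
            for lo, hi in cuts:
                if e <= lo or s >= hi:
                    nxt.append((lo, hi))
                    continue
                if lo < s:
                    nxt.append((lo, s))
                if e < hi:
                    nxt.append((e, hi))
            cuts = nxt
        for lo, hi in cuts:
            out_chroms.append(pc)
            out_starts.append(lo)
            out_lens.append(hi - lo)
    out_chroms = np.array(out_chroms, dtype=object)
    out_starts = np.array(out_starts, dtype=np.int64)
    out_lens = np.array(out_lens, dtype=np.int64)
    f_se = se_lens.sum() / perm_total
    p_in_se = cfg.trait_rr * f_se / (cfg.trait_rr * f_se + (1 - f_se))
    trait_rr_map = {"CVD": cfg.trait_rr}
    inside = rng.random(cfg.n_trait_snps) < p_in_se
    n_in = int(inside.sum())
    ci, pi = _uniform_positions(n_in, se_starts, se_lens, se_chroms_arr)
    co, po = _uniform_positions(cfg.n_trait_snps - n_in, out_starts,
                                out_lens, out_chroms)
    j_in = j_out = 0
    for i in range(cfg.n_trait_snps):
        if inside[i]:
            snp_rows.append((ci[j_in], int(pi[j_in]) + 1, f"cvd{i:04d}", "CVD"))
            j_in += 1
        else:
            snp_rows.append((co[j_out], int(po[j_out]) + 1, f"cvd{i:04d}", "CVD"))
            j_out += 1
    for t in range(cfg.n_null_traits):
        trait = f"trait_null_{t}"
        trait_rr_map[trait] = 1.0
        c_arr, p_arr = _uniform_positions(cfg.n_trait_snps, perm_starts,
                                          perm_lens, perm_chroms)
        for i in range(cfg.n_trait_snps):
            snp_rows.append(
                (c_arr[i], int(p_arr[i]) + 1, f"t{t}_{i:04d}", trait)
            )
    truth.trait_rr = trait_rr_map
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "rsid", "trait"])

    return SyntheticDataset(
        config=cfg, chromsizes=chromsizes, genes=genes, peaks=peaks,
        counts=counts, expression=expression, segmentation=seg, snps=snps,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# worked example: hand-enumerable miniature, no randomness


def worked_example() -> SyntheticDataset:
    """Deterministic miniature landscape whose every downstream number is
    enumerable by hand.

    One 200 kb chromosome, 12 enhancers (two 3-constituent clusters A and B
    plus six singletons), four genes, one trait. Cluster A and singleton s0
    are planted losses (counts scaled by 2^-1.5 and 1/4); singleton s5 is a
    planted gain (4x).
    """
    chromsizes = ChromSizes([("chrS", 200_000)])
    seg = RegionSet(
        _region_df(
            [
                ("chrS", 0, 180_000, "permissive", np.nan, "."),
                ("chrS", 180_000, 200_000, "repressed", np.nan, "."),
            ]
        ),
        chromsizes=chromsizes,
        label="chromatin_states",
    )
    genes = [
        GeneModel("gA", "chrS", "+", 5_000,
                  GenomicInterval("chrS", 5_000, 9_000, strand="+")),
        GeneModel("gB", "chrS", "+", 45_000,
                  GenomicInterval("chrS", 45_000, 48_000, strand="+")),
        GeneModel("gC", "chrS", "-", 100_000,
                  GenomicInterval("chrS", 96_000, 100_001, strand="-")),
        GeneModel("gD", "chrS", "+", 140_000,
                  GenomicInterval("chrS", 140_000, 146_000, strand="+")),
    ]
    # cluster A: 3 x 1 kb constituents, gaps 1 kb -> span [10000, 15000)
    # cluster B: 3 x 1.5 kb constituents, gaps 1.5 kb -> span [50000, 57500)
    enh_rows = [
        ("chrS", 10_000, 11_000, "enh_cA_0", np.nan, "."),
        ("chrS", 12_000, 13_000, "enh_cA_1", np.nan, "."),
        ("chrS", 14_000, 15_000, "enh_cA_2", np.nan, "."),
        ("chrS", 50_000, 51_500, "enh_cB_0", np.nan, "."),
        ("chrS", 53_000, 54_500, "enh_cB_1", np.nan, "."),
        ("chrS", 56_000, 57_500, "enh_cB_2", np.nan, "."),
        ("chrS", 90_000, 91_000, "enh_s0", np.nan, "."),
        ("chrS", 105_000, 106_000, "enh_s1", np.nan, "."),
        ("chrS", 120_000, 121_000, "enh_s2", np.nan, "."),
        ("chrS", 135_000, 136_000, "enh_s3", np.nan, "."),
        ("chrS", 150_000, 151_000, "enh_s4", np.nan, "."),
        ("chrS", 165_000, 166_000, "enh_s5", np.nan, "."),
    ]
    prom_k27 = [
        ("chrS", 4_500, 5_500, "prom_gA", np.nan, "."),
        ("chrS", 44_500, 45_500, "prom_gB", np.nan, "."),
        ("chrS", 99_500, 100_500, "prom_gC", np.nan, "."),
    ]
    k27_regions = RegionSet(_region_df(enh_rows + prom_k27),
                            chromsizes=chromsizes, label="H3K27ac_regions")
    k4me1 = RegionSet(
        _region_df(
            [(c, s - 200, e + 200, f"k4me1_{n}", np.nan, ".")
             for c, s, e, n, _x, _y in enh_rows]
            + [("chrS", 170_000, 171_000, "k4me1_poised_0", np.nan, ".")]
        ),
        chromsizes=chromsizes, label="H3K4me1",
    )
    k4me3 = RegionSet(
        _region_df(
            [("chrS", g.tss - 500, g.tss + 500, f"k4me3_{g.gene_id}",
              np.nan, ".") for g in genes]
        ),
        chromsizes=chromsizes, label="H3K4me3",
    )
    k27me3 = RegionSet(
        _region_df([("chrS", 170_000, 171_000, "k27me3_poised_0", np.nan, ".")]),
        chromsizes=chromsizes, label="H3K27me3",
    )
    # clusters A and B bound; singletons s1 and s3 bound (2/6)
    tf_rows = []
    bound_names = {"enh_cA_0", "enh_cA_1", "enh_cA_2",
                   "enh_cB_0", "enh_cB_1", "enh_cB_2", "enh_s1", "enh_s3"}
    for c, s, e, n, _x, _y in enh_rows:
        if n in bound_names:
            mid = (s + e) // 2
            tf_rows.append((c, mid - 200, mid + 200, f"tf_{n}", np.nan, "."))
    tf = RegionSet(_region_df(tf_rows), chromsizes=chromsizes, label="TF")
    med1 = RegionSet(
        _region_df([(c, s, e, f"med1_{n}", np.nan, ".")
                    for c, s, e, n, _x, _y in enh_rows[:6]]),
        chromsizes=chromsizes, label="MED1",
    )
    lib = np.array([1_000_000])
    k27_ctl = np.array([500, 500, 500, 1500, 1500, 1500,
                        40, 50, 60, 70, 80, 90, 100, 100, 100])
    # planted: cluster A scaled by 2^-1.5 (-> 177), s0 by 1/4, s5 by 4
    k27_kd = np.array([177, 177, 177, 1500, 1500, 1500,
                       10, 50, 60, 70, 80, 360, 100, 100, 100])
    med1_ctl = k27_ctl // 2
    med1_kd = k27_kd // 2
    tf_counts = np.array([250, 250, 250, 250, 250, 250,
                          0, 20, 0, 20, 0, 0, 0, 0, 0])
    input_counts = np.full(15, 5)
    counts = {
        "H3K27ac": {
            "ctl": CountMatrix(k27_regions, k27_ctl[:, None], lib),
            "kd": CountMatrix(k27_regions, k27_kd[:, None], lib),
        },
        "MED1": {
            "ctl": CountMatrix(k27_regions, med1_ctl[:, None], lib),
            "kd": CountMatrix(k27_regions, med1_kd[:, None], lib),
        },
        "TF": {"ctl": CountMatrix(k27_regions, tf_counts[:, None], lib)},
        "input": {"ctl": CountMatrix(k27_regions, input_counts[:, None], lib)},
    }
    planted_se = RegionSet(
        _region_df(
            [
                ("chrS", 10_000, 15_000, "cluster_A", np.nan, "."),
                ("chrS", 50_000, 57_500, "cluster_B", np.nan, "."),
            ]
        ),
        chromsizes=chromsizes, label="planted_se",
    )
    truth = TruthSet(
        planted_se=planted_se,
        loss_region_names=["enh_cA_0", "enh_cA_1", "enh_cA_2", "enh_s0"],
        gain_region_names=["enh_s5"],
        decreased_cluster_names=["cluster_A"],
        tf_bound={"cluster_A": True, "cluster_B": True,
                  "enh_s0": False, "enh_s1": True, "enh_s2": False,
                  "enh_s3": True, "enh_s4": False, "enh_s5": False},
        trait_rr={"CVD": 5.0, "trait_null_0": 1.0},
    )
    expression = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD"],
            "expression": [8.0, 7.0, 3.0, 4.0],
            "log2fc": [-1.4, 0.1, 0.0, 0.2],
        }
    )
    # trait CVD: 6 of 8 SNPs inside the planted SE spans
    cvd = [10_501, 12_501, 14_201, 50_501, 53_501, 56_501, 70_001, 130_001]
    null_trait = [20_001 + 13_000 * i for i in range(8)]
    bg_in_se = [11_001, 12_901, 51_001, 57_001]
    bg_out = [60_001 + 1_200 * i for i in range(96)]
    snp_rows = (
        [("chrS", p, f"cvd{i}", "CVD") for i, p in enumerate(cvd)]
        + [("chrS", p, f"nul{i}", "trait_null_0")
           for i, p in enumerate(null_trait)]
        + [("chrS", p, f"bg{i}", "background")
           for i, p in enumerate(bg_in_se + bg_out)]
    )
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "rsid", "trait"])
    peaks = {"H3K27ac": k27_regions, "H3K4me1": k4me1, "H3K4me3": k4me3,
             "H3K27me3": k27me3, "TF": tf, "MED1": med1}
    return SyntheticDataset(
        config=None, chromsizes=chromsizes, genes=genes, peaks=peaks,
        counts=counts, expression=expression, segmentation=seg, snps=snps,
        truth=truth,
    )


def load_dataset(indir) -> SyntheticDataset:
    """Read a dataset directory written by :meth:`SyntheticDataset.write`."""
    ind = Path(indir)
    chromsizes = read_chrom_sizes(ind / "chrom.sizes")
    genes = read_gene_table(ind / "genes.tsv", chromsizes=chromsizes)
    peaks = {}
    for path in sorted((ind / "peaks").glob("*.bed")):
        peaks[path.stem] = read_regions(path, "bed", chromsizes=chromsizes,
                                        label=path.stem)
    counts: dict[str, dict[str, CountMatrix]] = {}
    for path in sorted((ind / "counts").glob("*.counts.tsv")):
        mark, cond = path.name[: -len(".counts.tsv")].rsplit("_", 1)
        counts.setdefault(mark, {})[cond] = CountMatrix.from_tsv(
            path, chromsizes=chromsizes
        )
    expression = pd.read_csv(
        ind / "expression.tsv", sep="\t", comment=None, skiprows=1,
        names=["gene_id", "expression", "log2fc"],
    )
    seg = read_regions(ind / "segmentation.bed", "bed", chromsizes=chromsizes,
                       label="chromatin_states")
    snps = pd.read_csv(
        ind / "snps.tsv", sep="\t", skiprows=1,
        names=["chrom", "pos", "rsid", "trait"],
    )
    planted_se = read_regions(ind / "truth" / "planted_se.bed", "bed",
                              chromsizes=chromsizes, label="planted_se")
    loss, gain, decreased = [], [], []
    bound: dict[str, bool] = {}
    with open(ind / "truth" / "regions.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            name, klass = line.rstrip("\n").split("\t")
            if klass == "loss":
                loss.append(name)
            elif klass == "gain":
                gain.append(name)
            elif klass == "decreased_cluster":
                decreased.append(name)
            else:
                bound[name] = klass == "bound"
    trait_rr = {}
    with open(ind / "truth" / "traits.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            t, rr = line.rstrip("\n").split("\t")
            trait_rr[t] = float(rr)
    cfg = None
    if (ind / "config.yaml").exists():
        with open(ind / "config.yaml") as fh:
            cfg = SyntheticConfig(**yaml.safe_load(fh))
    truth = TruthSet(planted_se, loss, gain, decreased, bound, trait_rr)
    return SyntheticDataset(
        config=cfg, chromsizes=chromsizes, genes=genes, peaks=peaks,
        counts=counts, expression=expression, segmentation=seg, snps=snps,
        truth=truth,
    )
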