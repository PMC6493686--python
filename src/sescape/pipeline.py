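"""End-to-end orchestration: annotate -> call-se -> diff -> snp-enrich.

Stages communicate only through files in the run directory, so any stage
can be re-run on its own; a fixed config plus fixed inputs yields
byte-identical outputs (every table header records the tool version, a
config hash, and the seed — never a timestamp).
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, asdict, fields
from pathlib import Path


import pandas as pd
import yaml

from . import __version__
from .annotate import classify_vs_tss, define_elements, feature_association
from .differential import (
    cofactor_occupancy_change,
    differential_regions,
    differential_superenhancers,
    integrate_expression,
)
from .intervals import write_regions
from .simulate import SyntheticConfig, SyntheticDataset, generate, load_dataset
from .snp_enrichment import (
    Segmentation,
    TraitSNPSet,
    shuffle_matched,
    trait_class_scan,
)
from .superenhancer import (
    binding_fraction,
    call_superenhancers,
    occupancy_correlation,
)

__all__ = ["PipelineConfig", "PipelineError", "run_all", "make_synthetic"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    input_dir: str = ""
    output_dir: str = "run_out"
    seed: int = 0
    stitch_gap: int = 12_500
    promoter_exclusion: int = 2_000
    promoter_halfwidth: int = 2_000
    tss_window: int = 1_000
    fc_thresh: float = 1.0
    se_fc_thresh: float = 0.58
    p_thresh: float = 4.0
    pseudocount: float = 1.0
    n_random: int = 20
    n_perm: int = 200
    snp_mode: str = "background_snps"

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so the same
        analysis into a different directory hashes identically)."""
        params = {
            k: v for k, v in asdict(self).items()
            if k not in ("input_dir", "output_dir")
        }
        blob = yaml.safe_dump(params, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(cfg: PipelineConfig) -> str:
    return (
        f"# sescape v{__version__} config_hash={cfg.config_hash()} "
        f"seed={cfg.seed}\n"
    )


def _write_table(df: pd.DataFrame, path, cfg: PipelineConfig) -> None:
    with io.StringIO() as buf:
        buf.write(_header(cfg))
        df.to_csv(buf, sep="\t", index=False, float_format="%.6g")
        text = buf.getvalue()
    with open(path, "w") as fh:
        fh.write(text)


def stage_annotate(ds: SyntheticDataset, cfg: PipelineConfig, out: Path) -> dict:
    catalog = define_elements(
        ds.peaks["H3K27ac"], ds.peaks["H3K4me1"], ds.peaks["H3K4me3"],
        ds.peaks["H3K27me3"], genes=ds.genes,
        promoter_halfwidth=cfg.promoter_halfwidth,
    )
    for name, rs in (
        ("active_enhancers", catalog.active_enhancers),
        ("poised_enhancers", catalog.poised_enhancers),
        ("active_promoters", catalog.active_promoters),
    ):
        write_regions(rs, out / f"{name}.bed")
    tf = ds.peaks.get("TF")
    summary_rows = [
        ("active_enhancers", len(catalog.active_enhancers)),
        ("poised_enhancers", len(catalog.poised_enhancers)),
        ("active_promoters", len(catalog.active_promoters)),
    ]
    if tf is not None and len(tf) and ds.genes:
        labels = classify_vs_tss(tf, ds.genes,
                                 promoter_halfwidth=cfg.promoter_halfwidth)
        table = pd.concat(
            [tf.df[["chrom", "start", "end", "name"]], labels], axis=1
        )
        _write_table(table, out / "tf_peaks_vs_tss.tsv", cfg)
        for lab, n in labels["label"].value_counts().sort_index().items():
            summary_rows.append((f"tf_{lab}", int(n)))
        assoc = feature_association(
            tf, catalog, ds.chromsizes, ds.segmentation,
            n_random=cfg.n_random, seed=cfg.seed,
        )
        _write_table(assoc, out / "tf_feature_association.tsv", cfg)
    summary = pd.DataFrame(summary_rows, columns=["item", "count"])
    _write_table(summary, out / "annotate_summary.tsv", cfg)
    return {"catalog": catalog, "summary": summary}


def stage_call_se(ds: SyntheticDataset, cfg: PipelineConfig, out: Path,
                  catalog) -> dict:
    input_cm = ds.counts.get("input", {}).get("ctl")
    calls = {}
    for mark in ("H3K27ac", "TF"):
        if mark not in ds.counts:
            continue
        call = call_superenhancers(
            catalog.active_enhancers, ds.counts[mark]["ctl"], input_cm,
            ds.genes, stitch_gap=cfg.stitch_gap,
            promoter_exclusion=cfg.promoter_exclusion, ranking_mark=mark,
        )
        calls[mark] = call
        _write_table(call.table, out / f"entities_{mark}.tsv", cfg)
        hockey = call.table[["rank", "signal", "is_se"]]
        _write_table(hockey, out / f"hockey_{mark}.tsv", cfg)
        write_regions(call.se_regions(), out / f"se_{mark}.bed")
    stats_rows = []
    primary = calls.get("H3K27ac")
    tf_peaks = ds.peaks.get("TF")
    if primary is not None and tf_peaks is not None and len(tf_peaks):
        frac_se, frac_te, test = binding_fraction(
            primary.se_regions(), primary.te_regions(), tf_peaks
        )
        stats_rows += [
            ("tf_bound_fraction_se", frac_se),
            ("tf_bound_fraction_te", frac_te),
            ("tf_binding_fisher_p", test.p_value),
        ]
        if "TF" in ds.counts and primary.n_se >= 3:
            r, rtest = occupancy_correlation(
                primary.se_regions(), ds.counts["TF"]["ctl"],
                ds.counts["H3K27ac"]["ctl"],
            )
            stats_rows += [("tf_h3k27ac_log2_pearson_r", r),
                           ("tf_h3k27ac_pearson_p", rtest.p_value)]
    if stats_rows:
        _write_table(
            pd.DataFrame(stats_rows, columns=["statistic", "value"]),
            out / "se_binding_stats.tsv", cfg,
        )
    return {"calls": calls}


def stage_diff(ds: SyntheticDataset, cfg: PipelineConfig, out: Path,
               se_call) -> dict:
    ctl = ds.counts["H3K27ac"]["ctl"]
    kd = ds.counts["H3K27ac"]["kd"]
    volcano = differential_regions(
        ctl, kd, fc_thresh=cfg.fc_thresh, p_thresh=cfg.p_thresh,
        pseudocount=cfg.pseudocount,
    )
    _write_table(volcano, out / "differential_regions.tsv", cfg)
    counts = volcano["klass"].value_counts().sort_index()
    summary_rows = [(f"regions_{k}", int(v)) for k, v in counts.items()]
    if ds.genes and len(ds.expression):
        expr = integrate_expression(volcano, ds.expression, ds.genes)
        for (a, b), t in expr.get("pairwise", {}).items():
            summary_rows.append((f"expr_ranksum_{a}_vs_{b}_p", t.p_value))
        if "kruskal_wallis" in expr:
            summary_rows.append(
                ("expr_kruskal_p", expr["kruskal_wallis"].p_value)
            )
    if "MED1" in ds.counts and "kd" in ds.counts["MED1"]:
        cof = cofactor_occupancy_change(
            ds.counts["MED1"]["ctl"], ds.counts["MED1"]["kd"],
            volcano["klass"], pseudocount=cfg.pseudocount,
        )
        for (a, b), t in cof["pairwise"].items():
            summary_rows.append((f"med1_ranksum_{a}_vs_{b}_p", t.p_value))
    diff_se = None
    if se_call is not None and se_call.n_se > 0:
        diff_se = differential_superenhancers(
            se_call, ctl, kd, fc_thresh=cfg.se_fc_thresh,
            p_thresh=cfg.p_thresh, pseudocount=cfg.pseudocount,
        )
        _write_table(diff_se, out / "differential_se.tsv", cfg)
        for k, v in diff_se["klass"].value_counts().sort_index().items():
            summary_rows.append((f"se_{k}", int(v)))
    summary = pd.DataFrame(summary_rows, columns=["item", "value"])
    _write_table(summary, out / "diff_summary.tsv", cfg)
    return {"volcano": volcano, "diff_se": diff_se, "summary": summary}


def stage_snp_enrich(ds: SyntheticDataset, cfg: PipelineConfig, out: Path,
                     se_call) -> dict:
    if se_call is None or se_call.n_se == 0:
        raise ValueError("no super-enhancers to test")
    seg = Segmentation(ds.segmentation, ds.chromsizes)
    regions = se_call.se_regions()
    traits = sorted(t for t in ds.snps["trait"].unique() if t != "background")
    trait_sets = [
        TraitSNPSet.from_table(ds.snps, t, chromsizes=ds.chromsizes)
        for t in traits
    ]
    background = None
    permutations = None
    if cfg.snp_mode == "background_snps":
        background = TraitSNPSet.from_table(ds.snps, "background",
                                            chromsizes=ds.chromsizes)
    else:
        permutations = shuffle_matched(
            regions, seg, ds.chromsizes, seed=cfg.seed, n_perm=cfg.n_perm
        )
    scan = trait_class_scan(trait_sets, regions, background=background,
                            permutations=permutations, mode=cfg.snp_mode)
    _write_table(scan, out / "snp_enrichment.tsv", cfg)
    return {"scan": scan}


_STAGES = ("annotate", "call-se", "diff", "snp-enrich")


def run_all(config: PipelineConfig, stages=_STAGES) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "resolved_config.yaml", "w") as fh:
        fh.write(_header(config))
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    log_lines = []

    def _log(msg: str) -> None:
        log_lines.append(msg)

    try:
        ds = load_dataset(config.input_dir)
    except Exception as exc:
        raise PipelineError(f"stage input: cannot load dataset: {exc}") from exc
    state: dict = {"catalog": None, "calls": {}}
    report_rows = []
    for stage in stages:
        try:
            if stage == "annotate":
                res = stage_annotate(ds, config, out)
                state["catalog"] = res["catalog"]
                for row in res["summary"].itertuples(index=False):
                    report_rows.append((stage, row.item, row.count))
            elif stage == "call-se":
                if state["catalog"] is None:
                    res = stage_annotate(ds, config, out)
                    state["catalog"] = res["catalog"]
                res = stage_call_se(ds, config, out, state["catalog"])
                state["calls"] = res["calls"]
                for mark, call in res["calls"].items():
                    report_rows.append(
                        (stage, f"entities_{mark}", len(call.table))
                    )
                    report_rows.append((stage, f"se_{mark}", call.n_se))
            elif stage == "diff":
                res = stage_diff(ds, config, out,
                                 state["calls"].get("H3K27ac"))
                for row in res["summary"].itertuples(index=False):
                    report_rows.append((stage, row.item, row.value))
            elif stage == "snp-enrich":
                res = stage_snp_enrich(ds, config, out,
                                       state["calls"].get("H3K27ac"))
                top = res["scan"].iloc[0]
                report_rows.append((stage, "n_traits", len(res["scan"])))
                report_rows.append((stage, "top_trait", top["trait"]))
                report_rows.append((stage, "top_trait_p", top["binomial_p"]))
            else:
                raise ValueError(f"unknown stage {stage!r}")
            _log(f"stage {stage}: ok")
        except Exception as exc:
            _log(f"stage {stage}: FAILED: {exc}")
            with open(out / "run.log", "w") as fh:
                fh.write(_header(config))
                fh.write("\n".join(log_lines) + "\n")
            raise PipelineError(f"stage {stage} failed: {exc}") from exc
    report = pd.DataFrame(report_rows, columns=["stage", "item", "value"])
    _write_table(report, out / "report.tsv", config)
    with open(out / "run.log", "w") as fh:
        fh.write(_header(config))
        fh.write("\n".join(log_lines) + "\n")
    return out


def make_synthetic(config: SyntheticConfig, outdir) -> Path:
    """Generate a synthetic dataset directory with truth and provenance."""
    ds = generate(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ds.write(out)
    return out
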