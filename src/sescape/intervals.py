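"""Genomic interval data model, text-format I/O, and the overlap/stitch engine.

All coordinates are 0-based half-open (BED convention). SNP tables supply
1-based positions which are converted to width-1 intervals ``[p-1, p)`` on
read. Interval sets are backed by :class:`pandas.DataFrame` columns
(``chrom``, ``start``, ``end``, ``name``, ``score``, ``strand``) and are
validated against a governing :class:`ChromSizes`.

The engines here are plain numpy sweeps: every set this package handles is
desk-scale (thousands of regions), and the stitching/overlap semantics are
load-bearing enough that they are written out explicitly and oracle-tested
rather than delegated.
"""

from __future__ import annotations

import io
from collections.abc import Iterator, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "ChromSizes",
    "RegionSet",
    "GeneModel",
    "CountMatrix",
    "CoverageTrack",
    "OverlapResult",
    "overlap",
    "stitch",
    "nearest_tss",
    "read_regions",
    "write_regions",
    "read_chrom_sizes",
    "write_chrom_sizes",
    "read_gene_table",
    "write_gene_table",
    "ValidationError",
    "ParseError",
]


class ValidationError(ValueError):
    """An interval or matrix violates a structural invariant."""


class ParseError(ValueError):
    """A text input line does not parse under the declared dialect."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class ChromSizes(Mapping):
    """Ordered mapping chromosome name -> length in bp."""

    def __init__(self, sizes: Mapping[str, int] | list[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names")
        for name, length in items:
            if int(length) <= 0:
                raise ValidationError(f"chromosome {name} has non-positive length")
        self._sizes: dict[str, int] = {n: int(v) for n, v in items}

    def __getitem__(self, key: str) -> int:
        return self._sizes[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __repr__(self) -> str:
        return f"ChromSizes({self._sizes!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def total_length(self) -> int:
        return sum(self._sizes.values())


@dataclass(frozen=True)
class GeneModel:
    """Gene with an annotated TSS; body spans the transcribed interval."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: GenomicInterval

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if not (self.body.start <= self.tss < self.body.end):
            raise ValidationError(f"gene {self.gene_id}: TSS outside gene body")
        if self.body.chrom != self.chrom:
            raise ValidationError(f"gene {self.gene_id}: body on wrong chromosome")


_REGION_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class RegionSet:
    """An ordered collection of validated genomic intervals.

    Parameters
    ----------
    df
        Frame with at least ``chrom``, ``start``, ``end``; optional ``name``,
        ``score``, ``strand`` columns are filled with defaults.
    chromsizes
        Governing genome; when given, every interval is bounds-checked.
    label
        Provenance tag (e.g. the mark or stage that produced the set).
    """

    def __init__(
        self,
        df: pd.DataFrame,
        chromsizes: ChromSizes | None = None,
        label: str = "",
        validate: bool = True,
    ):
        df = df.copy()
        for col, default in (("name", ""), ("score", np.nan), ("strand", ".")):
            if col not in df.columns:
                df[col] = default
        df = df[_REGION_COLUMNS].reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["chrom"] = df["chrom"].astype(str)
        self.df = df
        self.chromsizes = chromsizes
        self.label = label
        # cached coordinate arrays; hot loops (overlap, shuffling) hit these
        self._chroms = df["chrom"].to_numpy()
        self._starts = df["start"].to_numpy()
        self._ends = df["end"].to_numpy()
        if validate:
            self._validate()

    def _validate(self) -> None:
        df = self.df
        bad = df["start"] < 0
        bad |= df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"invalid interval at row {i}: "
                f"{df.loc[i, 'chrom']}:{df.loc[i, 'start']}-{df.loc[i, 'end']}"
            )
        if self.chromsizes is not None:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.chromsizes:
                    raise ValidationError(f"chromosome {chrom} not in chrom sizes")
                if (sub["end"] > self.chromsizes[chrom]).any():
                    raise ValidationError(
                        f"interval beyond end of {chrom} "
                        f"(length {self.chromsizes[chrom]})"
                    )

    @classmethod
    def from_intervals(
        cls,
        intervals: list[GenomicInterval],
        chromsizes: ChromSizes | None = None,
        label: str = "",
    ) -> "RegionSet":
        df = pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in intervals],
                "start": [iv.start for iv in intervals],
                "end": [iv.end for iv in intervals],
                "name": [iv.name or "" for iv in intervals],
                "strand": [iv.strand for iv in intervals],
            }
        )
        if not intervals:
            df = pd.DataFrame(columns=_REGION_COLUMNS)
        return cls(df, chromsizes=chromsizes, label=label)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self.df.itertuples(index=False):
            yield GenomicInterval(
                row.chrom, int(row.start), int(row.end),
                strand=row.strand, name=row.name or None,
            )

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self.df.iloc[i]
        return GenomicInterval(
            row["chrom"], int(row["start"]), int(row["end"]),
            strand=row["strand"], name=row["name"] or None,
        )

    @property
    def starts(self) -> np.ndarray:
        return self._starts

    @property
    def ends(self) -> np.ndarray:
        return self._ends

    @property
    def chroms(self) -> np.ndarray:
        return self._chroms

    @property
    def widths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    @property
    def names(self) -> np.ndarray:
        return self.df["name"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.df["score"].to_numpy()

    def sorted(self) -> "RegionSet":
        df = self.df.sort_values(
            ["chrom", "start", "end"], kind="mergesort"
        ).reset_index(drop=True)
        return RegionSet(df, chromsizes=self.chromsizes, label=self.label)

    def subset(self, mask_or_idx) -> "RegionSet":
        df = self.df.loc[mask_or_idx].reset_index(drop=True)
        return RegionSet(df, chromsizes=self.chromsizes, label=self.label)

    def total_bp(self) -> int:
        """Total covered bp after merging overlaps."""
        if len(self) == 0:
            return 0
        merged = stitch(self, max_gap=0).regions
        return int(merged.widths.sum())


@dataclass
class OverlapResult:
    """Per-query overlap flags and matched subject indices."""

    flags: np.ndarray            # bool, per query
    hits: list[np.ndarray]       # per query, subject row indices
    overlap_bp: list[np.ndarray]  # per query, shared bp with each hit

    @property
    def n_overlapping(self) -> int:
        return int(self.flags.sum())

    def fraction(self) -> float:
        return float(self.flags.mean()) if len(self.flags) else float("nan")


def _check_same_universe(a: RegionSet, b: RegionSet) -> None:
    if (
        a.chromsizes is not None
        and b.chromsizes is not None
        and a.chromsizes != b.chromsizes
    ):
        raise ValidationError("region sets belong to different chromosome universes")


def overlap(query: RegionSet, subject: RegionSet, min_bp: int = 1) -> OverlapResult:
    """Flag each query interval sharing at least ``min_bp`` bases with a subject.

    Half-open semantics: abutting intervals (``q.end == s.start``) share zero
    bases and do not overlap.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    _check_same_universe(query, subject)
    nq = len(query)
    flags = np.zeros(nq, dtype=bool)
    hits: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(nq)]
    bps: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(nq)]
    sub_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    s_chroms = subject.chroms
    s_starts, s_ends = subject.starts, subject.ends
    for chrom in np.unique(s_chroms):
        idx = np.flatnonzero(s_chroms == chrom)
        order = np.argsort(s_starts[idx], kind="mergesort")
        idx = idx[order]
        sub_by_chrom[chrom] = (s_starts[idx], s_ends[idx], idx)
    q_chroms, q_starts, q_ends = query.chroms, query.starts, query.ends
    for i in range(nq):
        entry = sub_by_chrom.get(q_chroms[i])
        if entry is None:
            continue
        ss, se, sidx = entry
        # candidates must start early enough to reach min_bp before q end
        hi = int(np.searchsorted(ss, q_ends[i] - min_bp, side="right"))
        if hi == 0:
            continue
        ov = np.minimum(q_ends[i], se[:hi]) - np.maximum(q_starts[i], ss[:hi])
        keep = np.flatnonzero(ov >= min_bp)
        if keep.size:
            flags[i] = True
            hits[i] = sidx[keep]
            bps[i] = ov[keep]
    return OverlapResult(flags=flags, hits=hits, overlap_bp=bps)


@dataclass
class StitchResult:
    """Merged regions plus, per merged region, the input row indices."""

    regions: RegionSet
    constituents: list[np.ndarray]


def stitch(regions: RegionSet, max_gap: int) -> StitchResult:
    """Merge intervals whose intervening gap is at most ``max_gap`` bp.

    The gap between two sorted intervals is ``next.start - prev.end``
    (intervening bases); overlapping or touching intervals have gap <= 0 and
    always merge. Merging is transitive; each output region spans min start
    to max end of its constituents and records their input indices.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    n = len(regions)
    if n == 0:
        return StitchResult(
            regions=RegionSet(
                pd.DataFrame(columns=_REGION_COLUMNS),
                chromsizes=regions.chromsizes,
                label=regions.label,
            ),
            constituents=[],
        )
    df = regions.df
    order = np.lexsort((df["end"].to_numpy(), df["start"].to_numpy(),
                        df["chrom"].to_numpy()))
    chroms = df["chrom"].to_numpy()[order]
    starts = df["start"].to_numpy()[order]
    ends = df["end"].to_numpy()[order]
    new_chrom = np.empty(n, dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chroms[1:] != chroms[:-1]
    # running max of ends, restarted at each chromosome
    running_end = np.empty(n, dtype=np.int64)
    for lo, hi in zip(
        np.flatnonzero(new_chrom),
        np.append(np.flatnonzero(new_chrom)[1:], n),
    ):
        running_end[lo:hi] = np.maximum.accumulate(ends[lo:hi])
    gap_break = np.empty(n, dtype=bool)
    gap_break[0] = True
    gap_break[1:] = starts[1:] - running_end[:-1] > max_gap
    group = np.cumsum(new_chrom | gap_break) - 1
    out_rows = []
    constituents = []
    for g in range(group[-1] + 1):
        member = np.flatnonzero(group == g)
        out_rows.append(
            (
                chroms[member[0]],
                int(starts[member].min()),
                int(ends[member].max()),
                f"stitched_{g}",
                float(member.size),
                ".",
            )
        )
        constituents.append(np.sort(order[member]))
    out = pd.DataFrame(out_rows, columns=_REGION_COLUMNS)
    return StitchResult(
        regions=RegionSet(out, chromsizes=regions.chromsizes, label=regions.label),
        constituents=constituents,
    )


def nearest_tss(
    regions: RegionSet,
    genes: list[GeneModel],
    anchor: str = "midpoint",
) -> pd.DataFrame:
    """Assign each region to the gene with the nearest TSS on its chromosome.

    Distance is anchor-to-TSS; the signed distance is ``anchor - tss`` for
    plus-strand genes and negated for minus-strand genes, so positive values
    are downstream of the TSS in the gene's orientation. Ties on absolute
    distance break to the lexicographically smallest gene_id. Regions on a
    chromosome with no gene get gene_id ``"unassigned"`` and NaN distance.

    Returns a frame with ``gene_id``, ``distance`` (signed), ``abs_distance``.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if anchor not in ("midpoint", "edge"):
        raise ValueError("anchor must be 'midpoint' or 'edge'")
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    gene_ids = np.empty(len(regions), dtype=object)
    dist = np.full(len(regions), np.nan)
    chroms = regions.chroms
    mids = regions.midpoints
    starts, ends = regions.starts, regions.ends
    for chrom, glist in by_chrom.items():
        mask = np.flatnonzero(chroms == chrom)
        if mask.size == 0:
            continue
        tss = np.array([g.tss for g in glist])
        gid = np.array([g.gene_id for g in glist], dtype=object)
        gstrand = np.array([g.strand for g in glist])
        if anchor == "midpoint":
            raw = mids[mask][:, None] - tss[None, :]
            absd = np.abs(raw)
        else:
            # nearest-edge: zero if the TSS falls inside the region
            left = starts[mask][:, None] - tss[None, :]
            right = tss[None, :] - (ends[mask][:, None] - 1)
            absd = np.maximum(0, np.maximum(left, right))
            raw = np.where(mids[mask][:, None] >= tss[None, :], absd, -absd)
        # tie-break: minimal |distance|, then smallest gene_id
        gid_rank = np.argsort(np.argsort(gid, kind="mergesort"))
        key = absd * len(glist) + gid_rank[None, :]
        best = np.argmin(key, axis=1)
        rows = np.arange(mask.size)
        signed = raw[rows, best].astype(float)
        flip = gstrand[best] == "-"
        signed[flip] = -signed[flip]
        gene_ids[mask] = gid[best]
        dist[mask] = signed
    unassigned = np.array([g is None for g in gene_ids])
    gene_ids[unassigned] = "unassigned"
    return pd.DataFrame(
        {"gene_id": gene_ids, "distance": dist, "abs_distance": np.abs(dist)}
    )


# ---------------------------------------------------------------------------
# text-format I/O (all outputs tab-separated; data headers start with '#')


def read_chrom_sizes(path) -> ChromSizes:
    items = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'name\\tlength'")
            try:
                items.append((parts[0], int(parts[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {parts[1]!r}") from exc
    return ChromSizes(items)


def write_chrom_sizes(chromsizes: ChromSizes, path) -> None:
    with open(path, "w") as fh:
        for name in chromsizes:
            fh.write(f"{name}\t{chromsizes[name]}\n")


def _parse_bed_line(parts: list[str], lineno: int, path) -> tuple:
    if len(parts) < 3:
        raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
    try:
        start, end = int(parts[1]), int(parts[2])
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    if start >= end or start < 0:
        raise ParseError(
            f"{path}:{lineno}: invalid interval {parts[0]}:{start}-{end}"
        )
    name = parts[3] if len(parts) > 3 else ""
    score = float(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else np.nan
    strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "."
    return parts[0], start, end, name, score, strand


def read_regions(
    path,
    format: str = "bed",
    chromsizes: ChromSizes | None = None,
    label: str = "",
) -> RegionSet:
    """Read a BED, narrowPeak, or SNP-table file into a validated RegionSet.

    narrowPeak rows carry ``signalValue`` (column 7) as the region score.
    SNP tables are ``chrom<TAB>pos_1based<TAB>rsid<TAB>trait``; positions
    become width-1 intervals ``[p-1, p)`` with the trait stored in ``score``-
    free ``name`` as ``rsid|trait``.
    """
    if format not in ("bed", "narrowPeak", "snp_table"):
        raise ValueError(f"unknown format {format!r}")
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if format == "bed":
                rows.append(_parse_bed_line(parts, lineno, path))
            elif format == "narrowPeak":
                if len(parts) != 10:
                    raise ParseError(
                        f"{path}:{lineno}: narrowPeak needs 10 columns, "
                        f"got {len(parts)}"
                    )
                chrom, start, end, name, _score, strand = _parse_bed_line(
                    parts, lineno, path
                )
                rows.append((chrom, start, end, name, float(parts[6]), strand))
            else:  # snp_table
                if len(parts) < 2:
                    raise ParseError(f"{path}:{lineno}: SNP table needs >= 2 columns")
                try:
                    pos = int(parts[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad position") from exc
                if pos < 1:
                    raise ParseError(f"{path}:{lineno}: 1-based position must be >= 1")
                rsid = parts[2] if len(parts) > 2 else f"snp{lineno}"
                trait = parts[3] if len(parts) > 3 else ""
                rows.append((parts[0], pos - 1, pos, f"{rsid}|{trait}", np.nan, "."))
    df = pd.DataFrame(rows, columns=_REGION_COLUMNS)
    return RegionSet(df, chromsizes=chromsizes, label=label or str(path))


def write_regions(regions: RegionSet, path, format: str = "bed") -> None:
    df = regions.df
    with open(path, "w") as fh:
        if format == "bed":
            for row in df.itertuples(index=False):
                score = "." if np.isnan(row.score) else f"{row.score:g}"
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name or '.'}"
                    f"\t{score}\t{row.strand}\n"
                )
        elif format == "narrowPeak":
            for row in df.itertuples(index=False):
                sig = 0.0 if np.isnan(row.score) else row.score
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name or '.'}"
                    f"\t0\t{row.strand}\t{sig:g}\t-1\t-1\t-1\n"
                )
        else:
            raise ValueError(f"unknown format {format!r}")


def read_gene_table(path, chromsizes: ChromSizes | None = None) -> list[GeneModel]:
    """Read genes from ``gene_id chrom strand tss body_start body_end`` TSV."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: gene table needs 6 columns")
            gene_id, chrom, strand = parts[0], parts[1], parts[2]
            tss, bstart, bend = int(parts[3]), int(parts[4]), int(parts[5])
            genes.append(
                GeneModel(
                    gene_id, chrom, strand, tss,
                    GenomicInterval(chrom, bstart, bend, strand=strand),
                )
            )
    if chromsizes is not None:
        for g in genes:
            if g.chrom not in chromsizes or g.body.end > chromsizes[g.chrom]:
                raise ValidationError(f"gene {g.gene_id} outside chromosome bounds")
    return genes


def write_gene_table(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_id\tchrom\tstrand\ttss\tbody_start\tbody_end\n")
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}"
                f"\t{g.body.start}\t{g.body.end}\n"
            )


# ---------------------------------------------------------------------------
# counts


class CountMatrix:
    """Per-region read counts across samples, with library sizes.

    ``counts`` is ``(n_regions, n_samples)`` nonnegative integers;
    ``library_sizes`` are total mapped reads per sample and must be at least
    the column sums (reads fall elsewhere in the genome too).
    """

    def __init__(
        self,
        regions: RegionSet,
        counts: np.ndarray,
        library_sizes: np.ndarray,
        samples: list[str] | None = None,
    ):
        counts = np.asarray(counts)
        if counts.ndim == 1:
            counts = counts[:, None]
        library_sizes = np.asarray(library_sizes, dtype=np.int64).ravel()
        if counts.shape[0] != len(regions):
            raise ValidationError("counts rows != number of regions")
        if counts.shape[1] != library_sizes.size:
            raise ValidationError("counts columns != number of library sizes")
        if (counts < 0).any():
            raise ValidationError("negative counts")
        if (library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if (counts.sum(axis=0) > library_sizes).any():
            raise ValidationError("column sum exceeds library size")
        self.regions = regions
        self.counts = counts.astype(np.int64)
        self.library_sizes = library_sizes
        self.samples = samples or [f"s{i}" for i in range(counts.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def pooled(self) -> tuple[np.ndarray, int]:
        """Pool all samples: (per-region summed counts, summed library size)."""
        return self.counts.sum(axis=1), int(self.library_sizes.sum())

    def rpm(self) -> np.ndarray:
        """Reads per million mapped reads, per region x sample."""
        return self.counts / (self.library_sizes[None, :] / 1e6)

    def rpm_per_bp(self) -> np.ndarray:
        return self.rpm() / self.regions.widths[:, None]

    def recount(self, spans: RegionSet) -> "CountMatrix":
        """Re-aggregate counts over new spans.

        Reads are modelled as uniform within their source region, so a span
        receives ``count * (shared bp / region width)`` from each overlapping
        region, rounded to the nearest integer. Spans fully containing their
        source regions (the stitched-entity case) recover exact sums.
        """
        ov = overlap(spans, self.regions, min_bp=1)
        out = np.zeros((len(spans), self.n_samples), dtype=float)
        widths = self.regions.widths
        for i in range(len(spans)):
            if ov.hits[i].size:
                frac = ov.overlap_bp[i] / widths[ov.hits[i]]
                out[i] = frac @ self.counts[ov.hits[i]]
        return CountMatrix(
            spans, np.rint(out).astype(np.int64), self.library_sizes, self.samples
        )

    def to_tsv(self, path) -> None:
        libs = ",".join(
            f"{s}={l}" for s, l in zip(self.samples, self.library_sizes)
        )
        with io.StringIO() as buf:
            buf.write(f"# library_sizes: {libs}\n")
            buf.write(
                "# chrom\tstart\tend\tname\t" + "\t".join(self.samples) + "\n"
            )
            df = self.regions.df
            for i, row in enumerate(df.itertuples(index=False)):
                vals = "\t".join(str(int(v)) for v in self.counts[i])
                buf.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.name or '.'}\t{vals}\n"
                )
            text = buf.getvalue()
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def from_tsv(cls, path, chromsizes: ChromSizes | None = None) -> "CountMatrix":
        samples: list[str] = []
        libs: list[int] = []
        rows = []
        counts = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if line.startswith("# library_sizes:"):
                    for item in line.split(":", 1)[1].strip().split(","):
                        s, l = item.split("=")
                        samples.append(s.strip())
                        libs.append(int(l))
                    continue
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 4 + len(samples):
                    raise ParseError(f"{path}:{lineno}: short row")
                rows.append((parts[0], int(parts[1]), int(parts[2]), parts[3],
                             np.nan, "."))
                counts.append([int(v) for v in parts[4:4 + len(samples)]])
        regions = RegionSet(
            pd.DataFrame(rows, columns=_REGION_COLUMNS), chromsizes=chromsizes
        )
        return cls(regions, np.array(counts), np.array(libs), samples)


class CoverageTrack:
    """Piecewise-constant per-bp coverage (bedGraph semantics).

    Stored per chromosome as breakpoints ``b_0 < ... < b_k`` with values on
    ``[b_i, b_{i+1})``; positions outside all segments have value 0.
    """

    def __init__(self, chromsizes: ChromSizes):
        self.chromsizes = chromsizes
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def from_values(
        cls,
        regions: RegionSet,
        values: np.ndarray,
        chromsizes: ChromSizes,
    ) -> "CoverageTrack":
        """Build a track assigning each (non-overlapping) region a constant value."""
        track = cls(chromsizes)
        values = np.asarray(values, dtype=float)
        chroms = regions.chroms
        for chrom in np.unique(chroms):
            idx = np.flatnonzero(chroms == chrom)
            order = np.argsort(regions.starts[idx], kind="mergesort")
            idx = idx[order]
            starts = regions.starts[idx]
            ends = regions.ends[idx]
            if (starts[1:] < ends[:-1]).any():
                raise ValidationError("overlapping regions in coverage track")
            bp = np.empty(2 * idx.size + 1, dtype=np.int64)
            val = np.zeros(2 * idx.size + 1, dtype=float)
            bp[0] = 0
            bp[1::2] = starts
            bp[2::2] = ends
            val[1::2] = values[idx]
            # bp may contain duplicate positions (touching regions, start at
            # 0); zero-width segments contribute nothing to the integral
            track._chrom[chrom] = track._finalize(bp, val, chromsizes[chrom])
        return track

    @staticmethod
    def _finalize(bp: np.ndarray, val: np.ndarray, chrom_len: int):
        # append terminal zero segment to chromosome end
        bp_full = np.append(bp, chrom_len)
        widths = np.diff(bp_full)
        cum = np.concatenate([[0.0], np.cumsum(val * widths)])
        return bp_full, val, cum

    def _lookup(self, chrom: str):
        if chrom not in self._chrom:
            # all-zero chromosome
            return (
                np.array([0, self.chromsizes[chrom]]),
                np.zeros(1),
                np.array([0.0, 0.0]),
            )
        return self._chrom[chrom]

    def integral(self, chrom: str, start: float, end: float) -> float:
        """Integral of coverage over [start, end), clipped to the chromosome."""
        bp, val, cum = self._lookup(chrom)
        start = max(0.0, min(start, bp[-1]))
        end = max(0.0, min(end, bp[-1]))
        if end <= start:
            return 0.0

        def cum_at(x: float) -> float:
            i = int(np.searchsorted(bp, x, side="right")) - 1
            i = min(i, val.size - 1)
            return float(cum[i] + val[i] * (x - bp[i]))

        return cum_at(end) - cum_at(start)

    def mean(self, chrom: str, start: float, end: float) -> float:
        if end <= start:
            return 0.0
        return self.integral(chrom, start, end) / (end - start)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, (bp, val, _cum) in self._chrom.items():
                for i in range(val.size):
                    if val[i] != 0 and bp[i + 1] > bp[i]:
                        fh.write(f"{chrom}\t{bp[i]}\t{bp[i + 1]}\t{val[i]:g}\n")

    @classmethod
    def from_bedgraph(cls, path, chromsizes: ChromSizes) -> "CoverageTrack":
        regions = []
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: bedGraph needs 4 columns")
                regions.append((parts[0], int(parts[1]), int(parts[2]), "",
                                np.nan, "."))
                values.append(float(parts[3]))
        rs = RegionSet(
            pd.DataFrame(regions, columns=_REGION_COLUMNS), chromsizes=chromsizes
        )
        return cls.from_values(rs, np.array(values), chromsizes)
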