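"""Genomic interval model, standard-format I/O, and interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)`` (BED convention).
Interval collections are plain :class:`pandas.DataFrame` objects with at
least the columns ``chrom``, ``start``, ``end`` and optionally ``name`` and
``strand``; this keeps them trivially serialisable and lets downstream code
use ordinary pandas idioms. Overlap queries are backed by
:mod:`intervaltree`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeSpec",
    "SignalTrack",
    "read_bed",
    "write_bed",
    "read_bedpe",
    "write_bedpe",
    "read_genes",
    "write_genes",
    "intersect",
    "overlaps_any",
    "merge_overlapping",
    "shuffle_intervals",
    "promoters_from_genes",
    "define_enhancers",
    "define_insulators",
    "count_overlaps",
    "aggregate_signal_profile",
    "annotate_peak_location",
]

INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "strand"]
PEAK_CATEGORIES = ["promoter", "insulator", "gene_body", "intergenic"]


class BedFormatError(ValueError):
    """Raised for malformed BED/BEDPE records (carries the line number)."""


@dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths in base pairs."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chroms]

    def length(self, chrom: str) -> int:
        for name, length in self.chroms:
            if name == chrom:
                return length
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.names

    def as_dict(self) -> dict[str, int]:
        return dict(self.chroms)


@dataclass
class SignalTrack:
    """Fixed-bin non-negative signal over a genome (bedGraph-compatible)."""

    genome: GenomeSpec
    bin_size: int
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.genome.chroms:
            n = -(-length // self.bin_size)
            if chrom not in self.values:
                self.values[chrom] = np.zeros(n)
            elif len(self.values[chrom]) != n:
                raise ValueError(
                    f"{chrom}: expected {n} bins, got {len(self.values[chrom])}"
                )

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.genome.chroms:
                vals = self.values[chrom]
                for i, v in enumerate(vals):
                    start = i * self.bin_size
                    end = min(start + self.bin_size, length)
                    fh.write(f"{chrom}\t{start}\t{end}\t{v:g}\n")

    @classmethod
    def from_bedgraph(cls, path: str | Path, genome: GenomeSpec, bin_size: int) -> "SignalTrack":
        track = cls(genome=genome, bin_size=bin_size)
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
        for chrom, sub in df.groupby("chrom"):
            idx = (sub["start"] // bin_size).to_numpy()
            track.values[str(chrom)][idx] = sub["value"].to_numpy()
        return track


def _as_frame(records: Iterable[Sequence], n_loaded: int | None = None) -> pd.DataFrame:
    df = pd.DataFrame(records, columns=INTERVAL_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def make_intervals(chroms, starts, ends, names=None, strands=None) -> pd.DataFrame:
    """Assemble an interval frame from parallel columns."""
    n = len(starts)
    df = pd.DataFrame({
        "chrom": chroms,
        "start": np.asarray(starts, dtype=np.int64),
        "end": np.asarray(ends, dtype=np.int64),
        "name": names if names is not None else [f"iv{i}" for i in range(n)],
        "strand": strands if strands is not None else ["."] * n,
    })
    if (df["start"] >= df["end"]).any():
        raise ValueError("intervals require start < end")
    return df


def read_bed(path: str | Path, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Read BED3/BED6 into an interval frame, in file order.

    Records with ``start >= end`` raise :class:`BedFormatError` with the
    offending line number; unknown chromosomes are an error only when a
    *genome* is supplied.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedFormatError(f"line {lineno}: fewer than 3 columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            if genome is not None:
                if chrom not in genome:
                    raise BedFormatError(f"line {lineno}: unknown chromosome {chrom!r}")
                if end > genome.length(chrom):
                    raise BedFormatError(f"line {lineno}: end beyond chromosome")
            name = parts[3] if len(parts) > 3 else f"iv{lineno}"
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            rows.append((chrom, start, end, name, strand))
    return _as_frame(rows)


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    """Write BED6 (score column written as 0)."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, "name", ".")
            strand = getattr(row, "strand", ".")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\t0\t{strand}\n")


BEDPE_CORE = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]


def read_bedpe(path: str | Path) -> pd.DataFrame:
    """Read BEDPE; anchors are canonicalised so anchor1 <= anchor2.

    Extra columns beyond the first six are preserved under the names in the
    optional ``#``-prefixed header line, else as ``extra_<i>``.
    """
    rows, extra_names = [], None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                header = line[1:].split("\t")
                if len(header) > 6:
                    extra_names = header[6:]
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise BedFormatError(f"line {lineno}: fewer than 6 columns")
            try:
                rec = (parts[0], int(parts[1]), int(parts[2]),
                       parts[3], int(parts[4]), int(parts[5]))
            except ValueError as exc:
                raise BedFormatError(f"line {lineno}: non-integer coordinate") from exc
            if rec[1] >= rec[2] or rec[4] >= rec[5]:
                raise BedFormatError(f"line {lineno}: invalid anchor interval")
            rows.append(rec + tuple(parts[6:]))
    n_extra = max((len(r) - 6 for r in rows), default=0)
    if extra_names is None:
        extra_names = [f"extra_{i}" for i in range(n_extra)]
    rows = [r + ("",) * (6 + n_extra - len(r)) for r in rows]
    df = pd.DataFrame(rows, columns=BEDPE_CORE + extra_names[:n_extra])
    # canonical order: anchor1 <= anchor2 by (chrom, start)
    flip = (df["chrom1"] > df["chrom2"]) | (
        (df["chrom1"] == df["chrom2"]) & (df["start1"] > df["start2"])
    )
    for a, b in (("chrom1", "chrom2"), ("start1", "start2"), ("end1", "end2")):
        df.loc[flip, [a, b]] = df.loc[flip, [b, a]].to_numpy()
    for col in ("start1", "end1", "start2", "end2"):
        df[col] = df[col].astype(np.int64)
    df["intra"] = df["chrom1"] == df["chrom2"]
    return df


def write_bedpe(pairs: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in pairs.columns if c != "intra"]
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        pairs[cols].to_csv(fh, sep="\t", header=False, index=False)


GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


def read_genes(path: str | Path) -> pd.DataFrame:
    """Read gene models from TSV with header ``chrom start end strand gene_id``."""
    df = pd.read_csv(path, sep="\t")
    missing = set(GENE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    df = df[GENE_COLUMNS].copy()
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"])
    return df


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    genes[GENE_COLUMNS].to_csv(path, sep="\t", index=False)


def _trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (s, e, i) for i, s, e in zip(sub.index, sub["start"], sub["end"])
        )
    return trees


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All overlapping pairs between two interval sets, with overlap length.

    Half-open semantics: ``[x, b)`` and ``[b, y)`` do not overlap.
    """
    trees = _trees(b)
    rows = []
    for ia, chrom, s, e in zip(a.index, a["chrom"], a["start"], a["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(s, e):
            rows.append((ia, hit.data, min(e, hit.end) - max(s, hit.begin)))
    return pd.DataFrame(rows, columns=["index_a", "index_b", "overlap"])


def overlaps_any(a: pd.DataFrame, b: pd.DataFrame) -> np.ndarray:
    """Boolean per row of *a*: overlaps at least one interval of *b*."""
    trees = _trees(b)
    out = np.zeros(len(a), dtype=bool)
    for k, (chrom, s, e) in enumerate(zip(a["chrom"], a["start"], a["end"])):
        tree = trees.get(chrom)
        out[k] = tree is not None and bool(tree.overlap(s, e))
    return out


def merge_overlapping(a: pd.DataFrame) -> pd.DataFrame:
    """Minimal sorted set of disjoint intervals covering the input."""
    rows = []
    for chrom in sorted(a["chrom"].unique()):
        sub = a[a["chrom"] == chrom].sort_values("start")
        cur_s = cur_e = None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return make_intervals(*zip(*rows)) if rows else make_intervals([], [], [])


def shuffle_intervals(a: pd.DataFrame, genome: GenomeSpec,
                      seed: int | np.random.Generator) -> pd.DataFrame:
    """Re-place each interval uniformly at random within its own chromosome.

    Lengths are preserved, overlaps among shuffled intervals are permitted,
    and the result is deterministic for a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lengths = (a["end"] - a["start"]).to_numpy()
    chrom_len = np.array([genome.length(c) for c in a["chrom"]])
    if (lengths > chrom_len).any():
        raise ValueError("interval longer than its chromosome")
    new_start = (rng.random(len(a)) * (chrom_len - lengths + 1)).astype(np.int64)
    out = a.copy()
    out["start"] = new_start
    out["end"] = new_start + lengths
    return out


def promoters_from_genes(genes: pd.DataFrame, upstream: int = 3000,
                         genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Strictly-upstream promoter windows from TSSs, clipped to chromosome bounds.

    Plus strand: ``[tss - upstream, tss)``; minus strand: ``[tss, tss + upstream)``.
    """
    if upstream <= 0:
        raise ValueError("upstream must be positive")
    tss = np.where(genes["strand"] == "+", genes["start"], genes["end"]).astype(np.int64)
    plus = (genes["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss)
    end = np.where(plus, tss, tss + upstream)
    start = np.maximum(start, 0)
    if genome is not None:
        lim = np.array([genome.length(c) for c in genes["chrom"]])
        end = np.minimum(end, lim)
    keep = start < end  # a fully-clipped window has no extent left
    return make_intervals(genes["chrom"].to_numpy()[keep], start[keep], end[keep],
                          names=genes["gene_id"].to_numpy()[keep],
                          strands=genes["strand"].to_numpy()[keep])


def define_enhancers(h3k27ac: pd.DataFrame, promoters: pd.DataFrame) -> pd.DataFrame:
    """Enhancers: H3K27ac peaks that do not overlap any promoter."""
    keep = ~overlaps_any(h3k27ac, promoters) if len(promoters) else np.ones(len(h3k27ac), bool)
    return h3k27ac[keep].reset_index(drop=True)


def define_insulators(ctcf_peaks: pd.DataFrame, cohesin_anchors: pd.DataFrame) -> pd.DataFrame:
    """Insulators: CTCF peaks that overlap at least one cohesin (SMC1) anchor."""
    if len(cohesin_anchors) == 0:
        return ctcf_peaks.iloc[0:0].reset_index(drop=True)
    return ctcf_peaks[overlaps_any(ctcf_peaks, cohesin_anchors)].reset_index(drop=True)


def count_overlaps(queries: pd.DataFrame, targets: pd.DataFrame) -> np.ndarray:
    """Number of query intervals overlapping each target (multi-counting allowed)."""
    counts = np.zeros(len(targets), dtype=np.int64)
    trees = _trees(targets)
    pos_map = {idx: k for k, idx in enumerate(targets.index)}
    for chrom, s, e in zip(queries["chrom"], queries["start"], queries["end"]):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for hit in tree.overlap(s, e):
            counts[pos_map[hit.data]] += 1
    return counts


def aggregate_signal_profile(track: SignalTrack, regions: pd.DataFrame,
                             flank: int) -> np.ndarray:
    """Mean binned signal over ±flank around region centers.

    Regions whose window would run off the chromosome are dropped.
    """
    if len(regions) == 0:
        raise ValueError("no regions to profile")
    if flank % track.bin_size != 0:
        raise ValueError("flank must be a multiple of the track bin size")
    f = flank // track.bin_size
    windows = []
    for chrom, s, e in zip(regions["chrom"], regions["start"], regions["end"]):
        vals = track.values[chrom]
        c = ((s + e) // 2) // track.bin_size
        if c - f < 0 or c + f >= len(vals):
            continue
        windows.append(vals[c - f:c + f + 1])
    if not windows:
        raise ValueError("all regions truncated at chromosome edges")
    return np.mean(windows, axis=0)


def annotate_peak_location(peaks: pd.DataFrame, genes: pd.DataFrame,
                           promoters: pd.DataFrame,
                           insulators: pd.DataFrame) -> tuple[pd.Series, dict[str, float]]:
    """Assign each peak one category by its center point.

    Precedence: promoter > insulator > gene body > intergenic. Returns the
    per-peak labels and the category fractions (which sum to 1).
    """
    centers = make_intervals(
        peaks["chrom"].to_numpy(),
        (peaks["start"] + peaks["end"]) // 2,
        (peaks["start"] + peaks["end"]) // 2 + 1,
    )
    gene_iv = make_intervals(genes["chrom"].to_numpy(), genes["start"].to_numpy(),
                             genes["end"].to_numpy()) if len(genes) else genes
    in_prom = overlaps_any(centers, promoters) if len(promoters) else np.zeros(len(peaks), bool)
    in_ins = overlaps_any(centers, insulators) if len(insulators) else np.zeros(len(peaks), bool)
    in_gene = overlaps_any(centers, gene_iv) if len(genes) else np.zeros(len(peaks), bool)
    labels = np.where(in_prom, "promoter",
                      np.where(in_ins, "insulator",
                               np.where(in_gene, "gene_body", "intergenic")))
    labels = pd.Series(labels, index=peaks.index, name="category")
    n = max(len(peaks), 1)
    fractions = {cat: float((labels == cat).sum()) / n for cat in PEAK_CATEGORIES}
    return labels, fractions
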