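"""Genomic signal tracks: I/O, normalization, fragment pileups, window scoring.

Tracks are dense per-chromosome float vectors at 1 bp resolution with
NaN as the missing-data sentinel.  Two scales are distinguished:
``linear`` (nonnegative occupancy) and ``log2_ratio`` (fold enrichment
over input or over the genome average).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .annotation import GenomeAnnotation, PromoterFrame, TranscriptModel

MONO_NUC_MIN, MONO_NUC_MAX = 120, 180


class TrackError(ValueError):
    """Malformed track file or inconsistent track operation."""


@dataclass
class OccupancyTrack:
    """Per-chromosome base-pair signal with a declared scale."""

    data: dict[str, np.ndarray]
    scale: str = "linear"  # {"linear", "log2_ratio"}
    label: str = ""

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2_ratio"):
            raise TrackError(f"unknown scale {self.scale!r}")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.data.items()}

    def defined_values(self) -> np.ndarray:
        """All non-missing values genome-wide, concatenated."""
        parts = [v[~np.isnan(v)] for v in self.data.values()]
        return np.concatenate(parts) if parts else np.array([])


@dataclass
class FragmentSet:
    """Paired-end fragments as (chrom, start, end), 0-based half-open."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("fragment field lengths differ")
        if len(self.starts) and not np.all(self.starts < self.ends):
            raise ValueError("fragment with start >= end")

    def __len__(self) -> int:
        return len(self.starts)

    def length_filter(self, min_len: int = MONO_NUC_MIN, max_len: int = MONO_NUC_MAX) -> "FragmentSet":
        """Keep mono-nucleosome-sized fragments (default 120-180 bp)."""
        lengths = self.ends - self.starts
        keep = (lengths >= min_len) & (lengths <= max_len)
        return FragmentSet(self.chroms[keep], self.starts[keep], self.ends[keep])


def read_fragments(path) -> FragmentSet:
    """Read fragments from BED3 (extra columns ignored)."""
    chroms, starts, ends = [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            if len(f) < 3:
                raise TrackError(f"{path}: line {lineno}: expected >=3 BED fields")
            chroms.append(f[0])
            starts.append(int(f[1]))
            ends.append(int(f[2]))
    return FragmentSet(
        np.array(chroms, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


def write_fragments(fragments: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for c, s, e in zip(fragments.chroms, fragments.starts, fragments.ends):
            fh.write(f"{c}\t{s}\t{e}\n")


@dataclass
class WindowMatrix:
    """Genes x TSS-anchored windows, with a validity mask.

    Rows align 1:1 with ``gene_ids``; column ``i`` covers oriented
    offsets ``[-flank + i*window, -flank + (i+1)*window)``.  Masked
    cells hold NaN in ``scores`` and False in ``mask``.
    """

    gene_ids: list[str]
    scores: np.ndarray
    mask: np.ndarray
    frame: PromoterFrame = field(default_factory=PromoterFrame)
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.scores.shape != (len(self.gene_ids), self.frame.n_windows):
            raise ValueError("scores shape does not match gene list / frame")
        if self.mask.shape != self.scores.shape:
            raise ValueError("mask shape does not match scores")
        self.scores = np.where(self.mask, self.scores, np.nan)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, gene_id: str) -> np.ndarray:
        return self.scores[self.gene_ids.index(gene_id)]

    def same_frame(self, other: "WindowMatrix") -> bool:
        return self.frame == other.frame and self.gene_ids == other.gene_ids

    def to_tsv(self, path) -> None:
        """TSV with header = oriented window start offsets."""
        offsets = self.frame.window_offsets()
        with open(path, "w") as fh:
            fh.write("gene_id\t" + "\t".join(str(o) for o in offsets) + "\n")
            for gid, row, m in zip(self.gene_ids, self.scores, self.mask):
                cells = [f"{v:.6g}" if ok else "NA" for v, ok in zip(row, m)]
                fh.write(gid + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path, scale: str = "linear") -> "WindowMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            offsets = np.array([int(x) for x in header[1:]])
            gene_ids, rows = [], []
            for line in fh:
                f = line.rstrip("\n").split("\t")
                gene_ids.append(f[0])
                rows.append([np.nan if x == "NA" else float(x) for x in f[1:]])
        window = int(offsets[1] - offsets[0]) if len(offsets) > 1 else 50
        frame = PromoterFrame(flank=-int(offsets[0]), window=window)
        scores = np.array(rows, dtype=float)
        return cls(gene_ids, scores, ~np.isnan(scores), frame, scale)


# ---------------------------------------------------------------------------
# Track I/O

def read_track(path, format: str, chrom_sizes: Mapping[str, int],
               scale: str = "linear", label: str = "") -> OccupancyTrack:
    """Read a bedGraph or fixedStep-wiggle track into a dense NaN-gapped vector.

    bedGraph coordinates are 0-based half-open, wiggle 1-based.
    Overlapping bedGraph intervals and out-of-range coordinates are
    hard errors (with line numbers).
    """
    data = {c: np.full(n, np.nan) for c, n in chrom_sizes.items()}
    fmt = format.lower()
    with open(path) as fh:
        if fmt == "bedgraph":
            covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_sizes.items()}
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t") if "\t" in line else line.split()
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
                if chrom not in data:
                    raise TrackError(f"{path}: line {lineno}: unknown chromosome {chrom}")
                if start < 0 or end > chrom_sizes[chrom]:
                    raise TrackError(
                        f"{path}: line {lineno}: interval [{start},{end}) exceeds "
                        f"{chrom} size {chrom_sizes[chrom]}")
                if covered[chrom][start:end].any():
                    raise TrackError(f"{path}: line {lineno}: overlapping bedGraph interval")
                covered[chrom][start:end] = True
                data[chrom][start:end] = value
        elif fmt in ("wiggle", "wig", "fixedstep"):
            chrom, pos, step, span = None, 0, 1, 1
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                if line.startswith("fixedStep"):
                    kv = dict(p.split("=") for p in line.split()[1:])
                    chrom = kv["chrom"]
                    if chrom not in data:
                        raise TrackError(f"{path}: line {lineno}: unknown chromosome {chrom}")
                    pos = int(kv["start"]) - 1  # wiggle is 1-based
                    step = int(kv.get("step", 1))
                    span = int(kv.get("span", 1))
                    continue
                if chrom is None:
                    raise TrackError(f"{path}: line {lineno}: value before fixedStep header")
                if pos + span > chrom_sizes[chrom]:
                    raise TrackError(f"{path}: line {lineno}: position beyond {chrom} size")
                data[chrom][pos:pos + span] = float(line)
                pos += step
        else:
            raise ValueError(f"unsupported track format {format!r}")
    return OccupancyTrack(data, scale=scale, label=label)


def write_track(track: OccupancyTrack, path) -> None:
    """Write as bedGraph, merging runs of equal value; gaps are omitted."""
    with open(path, "w") as fh:
        for chrom, values in track.data.items():
            n = len(values)
            i = 0
            while i < n:
                if np.isnan(values[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and values[j] == values[i] and not np.isnan(values[j]):
                    j += 1
                fh.write(f"{chrom}\t{i}\t{j}\t{values[i]:.10g}\n")
                i = j


# ---------------------------------------------------------------------------
# Fragment -> occupancy

def midpoint_occupancy(fragments: FragmentSet, chrom_sizes: Mapping[str, int],
                       smoothing_bw: float = 20.0,
                       length_filter: bool = True) -> OccupancyTrack:
    """Nucleosome dyad density from fragment midpoints.

    Each fragment contributes unit mass at floor((start+end)/2); a
    Gaussian kernel of bandwidth ``smoothing_bw`` (bp, SD) is then
    applied with edge truncation renormalized so total mass is
    conserved.  ``smoothing_bw=0`` gives the raw midpoint histogram.
    """
    if length_filter:
        fragments = fragments.length_filter()
    if len(fragments) == 0:
        warnings.warn("empty fragment set: returning all-zero track")
        return OccupancyTrack({c: np.zeros(n) for c, n in chrom_sizes.items()},
                              scale="linear", label="midpoint_occupancy")
    data = {}
    mids = (fragments.starts + fragments.ends) // 2
    for chrom, size in chrom_sizes.items():
        sel = fragments.chroms == chrom
        hist = np.bincount(mids[sel], minlength=size).astype(float)
        if len(hist) > size:
            raise TrackError(f"fragment midpoint beyond {chrom} size {size}")
        if smoothing_bw > 0:
            mass = hist.sum()
            hist = gaussian_filter1d(hist, sigma=smoothing_bw, mode="constant")
            got = hist.sum()
            if got > 0:
                hist *= mass / got  # renormalize edge truncation
        data[chrom] = hist
    return OccupancyTrack(data, scale="linear", label="midpoint_occupancy")


# ---------------------------------------------------------------------------
# Normalization

def quantile_normalize(vectors: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Classic quantile normalization across equal-length vectors.

    After the transform every vector has identical sorted values: the
    across-vector mean of order statistics.  Ties within a vector get
    the mean of their tied target values.  Missing values are not
    supported.
    """
    arrays = [np.asarray(v, dtype=float) for v in vectors]
    if len(arrays) < 2:
        raise ValueError("quantile normalization needs >=2 vectors")
    n = len(arrays[0])
    for a in arrays:
        if len(a) != n:
            raise ValueError("vectors must have equal length")
        if np.isnan(a).any():
            raise ValueError("missing values not supported")
    target = np.mean([np.sort(a) for a in arrays], axis=0)
    out = []
    for a in arrays:
        order = np.argsort(a, kind="stable")
        ranked = np.empty(n)
        ranked[order] = target
        # ties -> mean of tied target values
        uniq, inv, counts = np.unique(a, return_inverse=True, return_counts=True)
        if len(uniq) < n:
            sums = np.bincount(inv, weights=ranked)
            ranked = (sums / counts)[inv]
        out.append(ranked)
    return out


def normalize_to_genome_mean(track: OccupancyTrack) -> OccupancyTrack:
    """Linear occupancy -> log2 relative to the genome-wide mean.

    output = log2((x + eps) / (mean + eps)) with eps = 0.1 * mean, so
    empty positions stay bounded; the genome mean of 2**output is ~1.
    """
    if track.scale != "linear":
        raise TrackError("input track must be linear-scale")
    defined = track.defined_values()
    if defined.size == 0 or defined.sum() <= 0:
        raise TrackError("all-zero or empty track cannot be mean-normalized")
    mean = defined.mean()
    eps = 0.1 * mean
    data = {c: np.log2((v + eps) / (mean + eps)) for c, v in track.data.items()}
    return OccupancyTrack(data, scale="log2_ratio",
                          label=f"{track.label} (log2/genome-mean)")


# ---------------------------------------------------------------------------
# Window scoring

def score_windows(track: OccupancyTrack, annotation: GenomeAnnotation,
                  frame: PromoterFrame | None = None,
                  mask: Mapping[str, np.ndarray] | None = None,
                  max_missing_frac: float = 0.5) -> WindowMatrix:
    """Score promoter windows: mean of defined track values per window.

    Column order is gene-oriented (column 0 = most upstream), so
    minus-strand genes read their genomic footprint right-to-left.  A
    cell is masked if neighbor-masked, off-chromosome, or more than
    ``max_missing_frac`` of its bases are missing.
    """
    frame = frame or PromoterFrame()
    n_genes, n_win = len(annotation), frame.n_windows
    scores = np.full((n_genes, n_win), np.nan)
    valid = np.zeros((n_genes, n_win), dtype=bool)
    for gi, gene in enumerate(annotation):
        if gene.chrom not in track.data:
            warnings.warn(f"{gene.id}: chromosome {gene.chrom} absent from track")
            continue
        values = track.data[gene.chrom]
        size = len(values)
        gene_mask = mask[gene.id] if mask is not None else np.ones(n_win, bool)
        bounds = frame.window_bounds(gene)
        for w in range(n_win):
            if not gene_mask[w]:
                continue
            ws, we = bounds[w]
            if ws < 0 or we > size:
                continue
            chunk = values[ws:we]
            defined = ~np.isnan(chunk)
            if defined.sum() < (1.0 - max_missing_frac) * len(chunk):
                continue
            scores[gi, w] = chunk[defined].mean()
            valid[gi, w] = True
    return WindowMatrix(list(annotation.ids), scores, valid, frame, track.scale)
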