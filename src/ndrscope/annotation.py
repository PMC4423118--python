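"""Transcript models and TSS-anchored promoter coordinate frames.

All internal coordinates are 0-based half-open; conversion from 1-based
formats (GFF3) happens only at the parse boundary.  The transcription
start site (TSS) is the 5' end of the transcript on its own strand, so
for a minus-strand gene ``tss > tes``.

Window offsets are *oriented*: negative offsets are upstream of
transcription regardless of strand, which makes "a shift toward the
NDR" mean the same thing for every gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

GENE_CLASSES = ("coding", "ncRNA", "tRNA")


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent transcript annotations."""


@dataclass(frozen=True)
class TranscriptModel:
    """One gene/transcript anchored at its TSS.

    ``tss`` and ``tes`` are 0-based; for a plus-strand gene the span is
    ``[tss, tes)`` and for a minus-strand gene ``[tes, tss)`` with the
    TSS being the (exclusive-end - 1 ... conceptually the 5' base).
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    gene_class: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.id}: unknown strand {self.strand!r}")
        if self.tss == self.tes:
            raise AnnotationError(f"{self.id}: zero-length transcript")
        if self.strand == "+" and not self.tss < self.tes:
            raise AnnotationError(f"{self.id}: plus-strand transcript needs tss < tes")
        if self.strand == "-" and not self.tes < self.tss:
            raise AnnotationError(f"{self.id}: minus-strand transcript needs tes < tss")
        if not self.chrom:
            raise AnnotationError(f"{self.id}: empty chromosome name")
        if self.gene_class not in GENE_CLASSES:
            raise AnnotationError(f"{self.id}: unknown gene_class {self.gene_class!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Genomic footprint [start, end), strand-independent.

        For a minus-strand gene the TSS base itself (the rightmost
        transcribed base) is included, so the footprint is
        ``[tes, tss + 1)``.
        """
        return (self.tss, self.tes) if self.strand == "+" else (self.tes, self.tss + 1)

    def oriented_offset(self, genomic_position: int) -> int:
        """Signed offset of a genomic position relative to the TSS.

        Negative = upstream of transcription on this gene's strand.
        """
        if self.strand == "+":
            return genomic_position - self.tss
        return self.tss - genomic_position

    def genomic_position(self, oriented_offset: int) -> int:
        """Inverse of :meth:`oriented_offset`."""
        if self.strand == "+":
            return self.tss + oriented_offset
        return self.tss - oriented_offset


@dataclass(frozen=True)
class PromoterFrame:
    """Fixed TSS-anchored window grid shared by all genes.

    Window ``i`` covers oriented offsets ``[-flank + i*window,
    -flank + (i+1)*window)``; with the defaults (flank 800, window 50)
    that is 32 windows spanning +/-800 bp around the TSS.
    """

    flank: int = 800
    window: int = 50

    def __post_init__(self) -> None:
        if self.flank <= 0 or self.window <= 0:
            raise ValueError("flank and window must be positive")
        if (2 * self.flank) % self.window:
            raise ValueError("2*flank must be a multiple of the window size")

    @property
    def n_windows(self) -> int:
        return 2 * self.flank // self.window

    def window_offsets(self) -> np.ndarray:
        """Oriented start offset of each window."""
        return -self.flank + self.window * np.arange(self.n_windows)

    def window_bounds(self, gene: TranscriptModel) -> np.ndarray:
        """Genomic [start, end) of each window, in gene-oriented window order.

        Column ``i`` always corresponds to oriented offsets
        ``[-flank + i*window, ...)``; for minus-strand genes the genomic
        footprint of column ``i`` therefore lies to the right of the TSS.
        """
        starts = self.window_offsets()
        bounds = np.empty((self.n_windows, 2), dtype=np.int64)
        if gene.strand == "+":
            bounds[:, 0] = gene.tss + starts
            bounds[:, 1] = gene.tss + starts + self.window
        else:
            # oriented [a, a+w) maps to genomic (tss-a-w, tss-a] -> half-open
            # [tss-a-w+1, tss-a+1)
            bounds[:, 0] = gene.tss - starts - self.window + 1
            bounds[:, 1] = gene.tss - starts + 1
        return bounds


@dataclass
class GenomeAnnotation:
    """Ordered transcript collection plus chromosome sizes."""

    transcripts: list[TranscriptModel] = field(default_factory=list)
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for t in self.transcripts:
            if t.id in seen:
                raise AnnotationError(f"duplicate transcript id {t.id!r}")
            seen.add(t.id)
            if t.chrom not in self.chrom_sizes:
                raise AnnotationError(f"{t.id}: chromosome {t.chrom!r} not in chrom_sizes")
            lo, hi = t.span
            if lo < 0 or hi > self.chrom_sizes[t.chrom]:
                raise AnnotationError(
                    f"{t.id}: span [{lo},{hi}) outside chromosome {t.chrom} "
                    f"of size {self.chrom_sizes[t.chrom]}"
                )

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    def by_chrom(self, chrom: str) -> list[TranscriptModel]:
        """Transcripts on one chromosome, sorted by span start."""
        return sorted(
            (t for t in self.transcripts if t.chrom == chrom),
            key=lambda t: t.span,
        )


def oriented_offsets(gene: TranscriptModel, genomic_position: int) -> int:
    """Functional alias for :meth:`TranscriptModel.oriented_offset`."""
    return gene.oriented_offset(genomic_position)


_BED_CLASS_KEY = "gene_class="


def _parse_bed6(lines: Iterable[str]) -> list[TranscriptModel]:
    out = []
    errors = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 6:
            errors.append(f"line {lineno}: expected 6 BED fields, got {len(fields)}")
            continue
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            errors.append(f"line {lineno}: non-integer coordinates")
            continue
        if strand not in ("+", "-"):
            raise AnnotationError(f"line {lineno}: unknown strand {strand!r}")
        gene_class = "coding"
        for extra in fields[6:]:
            if extra.startswith(_BED_CLASS_KEY):
                gene_class = extra[len(_BED_CLASS_KEY):]
        tss, tes = (start, end) if strand == "+" else (end - 1, start)
        try:
            out.append(TranscriptModel(name, chrom, strand, tss, tes, gene_class))
        except AnnotationError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise AnnotationError("; ".join(errors))
    return out


def _parse_gff3(lines: Iterable[str]) -> list[TranscriptModel]:
    out = []
    errors = []
    for lineno, raw in enumerate(lines, 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            errors.append(f"line {lineno}: expected 9 GFF3 columns, got {len(fields)}")
            continue
        chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields[:9]
        if ftype not in ("gene", "transcript", "mRNA", "ncRNA", "tRNA"):
            continue
        if strand not in ("+", "-"):
            raise AnnotationError(f"line {lineno}: unknown strand {strand!r}")
        attr = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        name = attr.get("ID") or attr.get("Name")
        if not name:
            errors.append(f"line {lineno}: missing ID attribute")
            continue
        gene_class = attr.get("gene_class", "tRNA" if ftype == "tRNA" else
                              "ncRNA" if ftype == "ncRNA" else "coding")
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            errors.append(f"line {lineno}: non-integer coordinates")
            continue
        # GFF3 is 1-based inclusive: [start, end] -> 0-based [start-1, end)
        start0, end0 = start - 1, end
        tss, tes = (start0, end0) if strand == "+" else (end0 - 1, start0)
        try:
            out.append(TranscriptModel(name, chrom, strand, tss, tes, gene_class))
        except AnnotationError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise AnnotationError("; ".join(errors))
    return out


def load_annotation(path, format: str, chrom_sizes: Mapping[str, int]) -> GenomeAnnotation:
    """Load transcript models from BED6 or GFF3.

    BED is 0-based half-open; GFF3 1-based inclusive.  The TSS is
    derived strand-aware (5' end of the transcript on its strand).
    Records violating invariants are rejected with line numbers.
    """
    fmt = format.upper()
    with open(path) as fh:
        lines = fh.readlines()
    if fmt in ("BED", "BED6"):
        transcripts = _parse_bed6(lines)
    elif fmt == "GFF3":
        transcripts = _parse_gff3(lines)
    else:
        raise ValueError(f"unsupported annotation format {format!r}")
    return GenomeAnnotation(transcripts, dict(chrom_sizes))


def write_annotation(annotation: GenomeAnnotation, path) -> None:
    """Write BED6 (+ gene_class in column 7) round-trippable by load_annotation."""
    with open(path, "w") as fh:
        for t in annotation:
            start, end = t.span
            fh.write(
                f"{t.chrom}\t{start}\t{end}\t{t.id}\t0\t{t.strand}"
                f"\t{_BED_CLASS_KEY}{t.gene_class}\n"
            )


def write_chrom_sizes(chrom_sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom, size in chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            chrom, size = line.split("\t")[:2]
            sizes[chrom] = int(size)
    return sizes


def neighbor_mask(
    annotation: GenomeAnnotation, frame: PromoterFrame | None = None
) -> dict[str, np.ndarray]:
    """Per-gene boolean validity vector over promoter windows.

    Window ``w`` of gene ``g`` is invalid (False) iff its genomic
    footprint overlaps, by at least 1 bp, the transcript span of any
    *other* transcript, or extends past a chromosome end.  Masking uses
    the full span of neighbours (TSS to TES), a conservative reading of
    "windows overlapping neighboring genes are excluded".
    """
    frame = frame or PromoterFrame()
    masks: dict[str, np.ndarray] = {}
    # Per-chromosome sorted span arrays for interval queries.
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for chrom in annotation.chrom_sizes:
        genes = annotation.by_chrom(chrom)
        if genes:
            starts = np.array([g.span[0] for g in genes])
            ends = np.array([g.span[1] for g in genes])
            by_chrom[chrom] = (starts, ends, [g.id for g in genes])
    for gene in annotation:
        bounds = frame.window_bounds(gene)
        valid = np.ones(frame.n_windows, dtype=bool)
        size = annotation.chrom_sizes[gene.chrom]
        valid &= (bounds[:, 0] >= 0) & (bounds[:, 1] <= size)
        starts, ends, ids = by_chrom[gene.chrom]
        for w in range(frame.n_windows):
            ws, we = bounds[w]
            hits = (starts < we) & (ends > ws)
            for j in np.nonzero(hits)[0]:
                if ids[j] != gene.id:
                    valid[w] = False
                    break
        masks[gene.id] = valid
    return masks


def write_mask(masks: Mapping[str, np.ndarray], path) -> None:
    """Mask as TSV: gene_id, window_index, valid (0/1)."""
    with open(path, "w") as fh:
        fh.write("gene_id\twindow_index\tvalid\n")
        for gene_id, valid in masks.items():
            for w, v in enumerate(valid):
                fh.write(f"{gene_id}\t{w}\t{int(v)}\n")
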