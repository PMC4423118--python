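"""End-to-end convenience chain over a synthetic or real cohort directory.

Ties the modules together: fragments -> dyad occupancy -> log2
genome-mean normalization -> promoter window matrices (neighbor
masked) -> mutant/WT ratio matrix -> k-means clusters -> per-gene NDR
geometry and genotype effects.  Every step is also available
individually; this module exists so the CLI and validation studies run
one code path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .annotation import (GenomeAnnotation, PromoterFrame, load_annotation,
                         neighbor_mask, read_chrom_sizes)
from .architecture import architecture_report
from .profiles import kmeans_profiles, ratio_matrix
from .tracks import (WindowMatrix, midpoint_occupancy,
                     normalize_to_genome_mean, read_fragments, score_windows)

GENOTYPES = ("WT", "rsc", "isw1", "rsc_isw1")


def isolated_genes(annotation: GenomeAnnotation,
                   min_tss_distance: int = 1700) -> set[str]:
    """Genes whose TSS is at least ``min_tss_distance`` from any other TSS.

    Composite (cohort-mean) profiles are computed over these genes so
    that a promoter's flank carries only its own chromatin: closely
    spaced (e.g. divergent) gene pairs share intergenic nucleosomes,
    which is real but confounds comparison to single-promoter models.
    """
    by_chrom: dict[str, list[tuple[str, int]]] = {}
    for t in annotation:
        by_chrom.setdefault(t.chrom, []).append((t.id, t.tss))
    out = set()
    for pairs in by_chrom.values():
        for gid, tss in pairs:
            if all(gid == g2 or abs(tss - t2) >= min_tss_distance
                   for g2, t2 in pairs):
                out.add(gid)
    return out


def composite_log2_profile(linear_matrix: WindowMatrix, genes: list[str],
                           genome_mean: float) -> np.ndarray:
    """Cohort-mean occupancy of a gene set, log2 vs the genome mean.

    Averages the *linear* window scores across genes first and takes
    log2 after (with the pipeline's 0.1 x mean pseudocount), so the
    composite converges to the noiseless profile as genes accumulate
    instead of inheriting the per-gene log-of-small-count bias.
    """
    idx = [linear_matrix.gene_ids.index(g) for g in genes]
    mean = np.nanmean(linear_matrix.scores[idx], axis=0)
    eps = 0.1 * genome_mean
    return np.log2((mean + eps) / (genome_mean + eps))


def load_cohort_annotation(cohort_dir) -> tuple[GenomeAnnotation, dict]:
    d = Path(cohort_dir)
    sizes = read_chrom_sizes(d / "chrom.sizes")
    annotation = load_annotation(d / "genes.bed", "BED6", sizes)
    return annotation, sizes


def genotype_matrices(cohort_dir, genotype: str, annotation: GenomeAnnotation,
                      frame: PromoterFrame, mask,
                      smoothing_bw: float = 20.0) -> tuple[WindowMatrix, WindowMatrix]:
    """Fragments of one genotype -> (linear, log2-vs-genome-mean) window matrices.

    The linear matrix feeds mutant/WT ratio construction; the log2
    matrix feeds NDR geometry and promoter classification.
    """
    frags = read_fragments(Path(cohort_dir) / f"fragments_{genotype}.bed")
    occ = midpoint_occupancy(frags, annotation.chrom_sizes, smoothing_bw)
    linear = score_windows(occ, annotation, frame, mask)
    rel = normalize_to_genome_mean(occ)
    log2m = score_windows(rel, annotation, frame, mask)
    return linear, log2m


def run_pipeline(cohort_dir, genotypes=GENOTYPES, k: int = 6, seed: int = 0,
                 frame: PromoterFrame | None = None) -> dict:
    """Full analysis of a cohort directory; returns a dict of results.

    Keys: ``annotation``, ``mask``, ``matrices`` (genotype ->
    WindowMatrix), ``ratio`` (rsc/WT), ``clusters``, ``reports``
    (per-gene ArchitectureReport list for rsc vs WT, with the double
    mutant when present).
    """
    frame = frame or PromoterFrame()
    annotation, _ = load_cohort_annotation(cohort_dir)
    mask = neighbor_mask(annotation, frame)
    linear, matrices = {}, {}
    for g in genotypes:
        linear[g], matrices[g] = genotype_matrices(cohort_dir, g, annotation,
                                                   frame, mask)
    result = {"annotation": annotation, "mask": mask,
              "matrices": matrices, "linear": linear}
    if "WT" in matrices and "rsc" in matrices:
        result["ratio"] = ratio_matrix(linear["rsc"], linear["WT"])
        result["clusters"] = kmeans_profiles(result["ratio"], k=k, seed=seed)
        double = matrices.get("rsc_isw1")
        result["reports"] = architecture_report(matrices["WT"], matrices["rsc"],
                                                double)
    return result
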