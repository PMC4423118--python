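import numpy as np
import pytest

from ndrscope.annotation import GenomeAnnotation, PromoterFrame, TranscriptModel


@pytest.fixture
def frame():
    return PromoterFrame()  # flank 800, window 50 -> 32 windows


@pytest.fixture
def lone_gene_annotation():
    """One plus-strand gene far from any chromosome end."""
    gene = TranscriptModel("g1", "chrI", "+", 5000, 6500)
    return GenomeAnnotation([gene], {"chrI": 20000})


def random_annotation(rng: np.random.Generator, n_genes: int = 10,
                      chrom_size: int = 50000) -> GenomeAnnotation:
    """Random non-identical gene layout on one chromosome (overlaps allowed)."""
    transcripts = []
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_size - 3000))
        length = int(rng.integers(300, 2500))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            tss, tes = start, start + length
        else:
            tss, tes = start + length - 1, start
        transcripts.append(TranscriptModel(f"g{i}", "chrI", strand, tss, tes))
    return GenomeAnnotation(transcripts, {"chrI": chrom_size})


def random_track_values(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.0, 5.0, size=size)
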