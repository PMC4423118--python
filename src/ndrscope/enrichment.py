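"""Remodeler-enriched promoter calling, motif scanning, permutation tests.

Promoter occupancy calls use an empirical null built by circular
per-chromosome shifts of the ChIP track (or a matched control track),
with Benjamini-Hochberg control of the FDR.  Sequence-element
enrichment in promoter classes is tested by random permutation of gene
labels; gene-set intersections by hypergeometric tail or permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Default yeast consensi: TATA box, Reb1 and Rsc3 binding sites, and
# poly(A) tracts that disfavour nucleosome formation.
DEFAULT_MOTIFS: tuple["MotifSpec", ...] = None  # filled after class def


@dataclass(frozen=True)
class MotifSpec:
    """IUPAC consensus motif with a scan mode."""

    name: str
    pattern: str
    both_strands: bool = True
    count_mode: str = "presence"  # {"presence", "count"}

    def __post_init__(self) -> None:
        bad = set(self.pattern.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"{self.name}: non-IUPAC characters {bad}")
        if self.count_mode not in ("presence", "count"):
            raise ValueError(f"{self.name}: unknown count_mode {self.count_mode!r}")


DEFAULT_MOTIFS = (
    MotifSpec("TATA", "TATAWAWR"),
    MotifSpec("Reb1", "TTACCCG"),
    MotifSpec("Rsc3", "CGCGC"),
    MotifSpec("polyA", "AAAAA", count_mode="count"),
)


@dataclass
class EnrichmentResult:
    """One enrichment/depletion test outcome."""

    category: str
    name: str
    observed: float
    null_mean: float
    null_sd: float
    n_permutations: int
    p_value: float
    direction: str  # {"enriched", "depleted"}

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("empirical p must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Occupancy calling

def call_enriched_promoters(chip_scores: Mapping[str, float],
                            null_scores: np.ndarray,
                            fdr: float = 0.01) -> tuple[set[str], dict[str, float]]:
    """Call promoters whose TSS score exceeds an empirical null at the FDR.

    ``null_scores`` is the pooled null score distribution (from
    :func:`circular_null_scores` or from scoring a matched control
    track).  Per-gene one-sided empirical p-values (plus-one rule) get
    Benjamini-Hochberg correction; genes with q <= fdr are returned.
    Calls are monotone in ``fdr``.
    """
    null_scores = np.asarray(null_scores, dtype=float)
    null_scores = null_scores[np.isfinite(null_scores)]
    if null_scores.size < 100:
        raise ValueError("null distribution too small (<100 scores): unstable")
    genes = [g for g, v in chip_scores.items() if np.isfinite(v)]
    obs = np.array([chip_scores[g] for g in genes])
    sorted_null = np.sort(null_scores)
    # #{null >= obs} via right-side search on the sorted null
    ge = null_scores.size - np.searchsorted(sorted_null, obs, side="left")
    pvals = (1.0 + ge) / (null_scores.size + 1.0)
    reject, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")[0:4]
    qmap = dict(zip(genes, qvals))
    called = {g for g, q in qmap.items() if q <= fdr}
    return called, qmap


def circular_null_scores(track, annotation, frame=None, mask=None,
                         n_shifts: int = 25, seed: int = 0,
                         statistic: str = "mean") -> np.ndarray:
    """Pooled null TSS scores from circular per-chromosome track shifts.

    Each draw rolls every chromosome's signal by an independent random
    offset and rescores all promoters, destroying gene-track alignment
    while preserving the signal's marginal distribution and
    autocorrelation.  Pooled over genes, ``n_shifts`` draws give
    n_genes x n_shifts null scores (>= 1000 for a default cohort).
    """
    from .profiles import tss_score
    from .tracks import OccupancyTrack, score_windows

    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_shifts):
        shifted = OccupancyTrack(
            {c: np.roll(v, int(rng.integers(1, len(v))))
             for c, v in track.data.items()},
            scale=track.scale, label=track.label)
        mat = score_windows(shifted, annotation, frame, mask)
        vals = np.fromiter(
            (v for v in tss_score(mat, statistic).values() if np.isfinite(v)),
            dtype=float)
        pooled.append(vals)
    return np.concatenate(pooled)


# ---------------------------------------------------------------------------
# Motif scanning

def _matches_at(seq: str, pattern: str, i: int) -> bool:
    for j, p in enumerate(pattern):
        c = seq[i + j]
        if c == "N" or c not in IUPAC[p]:
            return False
    return True


def _scan_strand(seq: str, pattern: str, count_mode: str) -> int:
    n, m = len(seq), len(pattern)
    hits, i = 0, 0
    while i <= n - m:
        if _matches_at(seq, pattern, i):
            hits += 1
            if count_mode == "presence":
                return 1
            # non-overlapping maximal matches: extend through the run
            i += m
            if pattern == len(pattern) * pattern[0]:
                # homopolymer-like pattern: swallow the rest of the run
                while i < n and seq[i] != "N" and seq[i] in IUPAC[pattern[0]]:
                    i += 1
        else:
            i += 1
    return hits


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def scan_motifs(sequences: Mapping[str, str],
                motifs: Iterable[MotifSpec] = DEFAULT_MOTIFS) -> dict[str, dict[str, float]]:
    """Per-gene, per-motif statistic table from exact IUPAC matching.

    Presence motifs give 0/1; count motifs the number of
    non-overlapping maximal matches.  ``N`` never matches.  Both
    strands are scanned when the motif says so, and a site is never
    double-counted across strands for presence motifs.
    """
    table: dict[str, dict[str, float]] = {}
    for gene, seq in sequences.items():
        seq = seq.upper()
        row: dict[str, float] = {}
        for m in motifs:
            pat = m.pattern.upper()
            hits = _scan_strand(seq, pat, m.count_mode)
            if m.both_strands and not (m.count_mode == "presence" and hits):
                hits += _scan_strand(reverse_complement(seq), pat, m.count_mode)
            row[m.name] = float(min(hits, 1) if m.count_mode == "presence" else hits)
        table[gene] = row
    return table


def read_fasta(path) -> dict[str, str]:
    """Plain FASTA reader (id = first token of the header)."""
    seqs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Permutation tests

def _null_means(values: np.ndarray, k: int, n_permutations: int,
                rng: np.random.Generator,
                max_block: int = 20_000_000) -> np.ndarray:
    """Means of ``k``-subsets drawn without replacement, batched.

    Sampling without replacement is realized by rank-k selection on
    uniform random keys, vectorized over permutations.
    """
    n = len(values)
    out = np.empty(n_permutations)
    batch = max(1, min(n_permutations, max_block // max(n, 1)))
    done = 0
    while done < n_permutations:
        b = min(batch, n_permutations - done)
        keys = rng.random((b, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        out[done:done + b] = values[idx].mean(axis=1)
        done += b
    return out


def permutation_enrichment(statistic_per_gene: Mapping[str, float],
                           category: set[str], background: set[str],
                           n_permutations: int = 10_000,
                           seed: int = 0, tail: str = "enriched",
                           name: str = "", category_name: str = "") -> EnrichmentResult:
    """One-sided permutation test of a category's mean statistic.

    The null resamples |category| genes from the background without
    replacement ``n_permutations`` times; p uses the plus-one rule on
    the stated ``tail`` ("enriched": null >= observed, "depleted":
    null <= observed).  The tail is fixed a priori — not chosen from
    the observed direction — so null p-values are uniform; the
    ``direction`` field reports the observed sign separately.
    """
    if not category:
        raise ValueError("empty category")
    if not category <= background:
        raise ValueError("category must be a subset of the background")
    if tail not in ("enriched", "depleted"):
        raise ValueError(f"unknown tail {tail!r}")
    rng = np.random.default_rng(seed)
    bg = sorted(background)
    stats_arr = np.array([statistic_per_gene[g] for g in bg])
    cat_mask = np.fromiter((g in category for g in bg), dtype=bool)
    observed = float(stats_arr[cat_mask].mean())
    k = int(cat_mask.sum())
    nulls = _null_means(stats_arr, k, n_permutations, rng)
    null_mean = float(nulls.mean())
    direction = "enriched" if observed >= null_mean else "depleted"
    if tail == "enriched":
        extreme = int((nulls >= observed).sum())
    else:
        extreme = int((nulls <= observed).sum())
    p = (1.0 + extreme) / (n_permutations + 1.0)
    return EnrichmentResult(category_name, name, observed, null_mean,
                            float(nulls.std()), n_permutations, p, direction)


def gene_set_intersection_test(set_a: set[str], set_b: set[str],
                               universe: set[str],
                               method: str = "hypergeometric",
                               n_permutations: int = 10_000,
                               seed: int = 0,
                               tail: str = "enrichment") -> EnrichmentResult:
    """Significance of |A intersect B| against random draws from the universe.

    ``hypergeometric`` gives the exact tail; ``permutation`` shuffles
    set_b's labels.  ``tail`` selects the enrichment (overlap >= obs)
    or depletion (overlap <= obs) test.
    """
    if not universe:
        raise ValueError("empty universe")
    if not (set_a <= universe and set_b <= universe):
        raise ValueError("sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    obs = len(set_a & set_b)
    if method == "hypergeometric":
        if tail == "enrichment":
            p = float(hypergeom.sf(obs - 1, N, K, n))
        else:
            p = float(hypergeom.cdf(obs, N, K, n))
        p = min(max(p, np.finfo(float).tiny), 1.0)
        mean = K * n / N
        # degenerate draws (n = 0 or n = N) have zero variance
        sd = (float(np.sqrt(hypergeom.var(N, K, n)))
              if 0 < n < N else 0.0)
        nperm = 0
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        uni = sorted(universe)
        a_mask = np.fromiter((g in set_a for g in uni), dtype=bool)
        if n == 0:
            nulls = np.zeros(n_permutations)
        else:
            nulls = np.rint(_null_means(a_mask.astype(float), n,
                                        n_permutations, rng) * n)
        if tail == "enrichment":
            extreme = int((nulls >= obs).sum())
        else:
            extreme = int((nulls <= obs).sum())
        p = (1.0 + extreme) / (n_permutations + 1.0)
        mean, sd, nperm = float(nulls.mean()), float(nulls.std()), n_permutations
    else:
        raise ValueError(f"unknown method {method!r}")
    direction = "enriched" if obs >= mean else "depleted"
    return EnrichmentResult("intersection", f"{method}:{tail}", float(obs),
                            mean, sd, nperm, p, direction)


def write_enrichment_results(results: Iterable[EnrichmentResult], path) -> None:
    cols = ["category", "name", "observed", "null_mean", "null_sd",
            "n_permutations", "p_value", "direction"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write(f"{r.category}\t{r.name}\t{r.observed:.6g}\t"
                     f"{r.null_mean:.6g}\t{r.null_sd:.6g}\t{r.n_permutations}\t"
                     f"{r.p_value:.6g}\t{r.direction}\n")
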