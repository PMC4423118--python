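"""Promoter ratio profiles, k-means classification, and TSS scoring.

The central object is a genes x windows matrix of log2(mutant /
wild-type) occupancy.  Promoters are grouped by profile with a masked
k-means: distances are squared Euclidean over each gene's valid
windows, rescaled by (total windows / valid windows) so sparsely
covered promoters are comparable to fully covered ones without
imputing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .tracks import WindowMatrix


@dataclass
class ClusterResult:
    """k-means output: assignments, centroids, run metadata.

    ``assignments`` maps gene id -> cluster id (0-based); genes set
    aside for insufficient valid windows map to -1.  Cluster ids are
    ordered by descending mean centroid value over the NDR zone
    (oriented [-150, +50)), so cluster 0 always has the strongest NDR
    gain; the numbering is thus stable across seeds.
    """

    k: int
    assignments: dict[str, int]
    centroids: np.ndarray
    inertia: float
    seed: int
    restarts: int
    unclustered: list[str] = field(default_factory=list)

    def members(self, cluster: int) -> list[str]:
        return [g for g, c in self.assignments.items() if c == cluster]

    def labels_for(self, gene_ids: list[str]) -> np.ndarray:
        return np.array([self.assignments.get(g, -1) for g in gene_ids])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tcluster\n")
            for g, c in self.assignments.items():
                fh.write(f"{g}\t{c}\n")


def ratio_matrix(mutant: WindowMatrix, wildtype: WindowMatrix) -> WindowMatrix:
    """Per-window log2(mutant / wild-type) with joint masking.

    Pseudocount eps = 0.1 x the genome-mean window score, pooled over
    both inputs so the transform is exactly antisymmetric under
    swapping mutant and wild type; cells valid only where both inputs
    are valid.
    """
    if not mutant.same_frame(wildtype):
        raise ValueError("mutant and wildtype matrices have different frames/genes")
    if mutant.scale != "linear" or wildtype.scale != "linear":
        raise ValueError("ratio_matrix expects linear-scale window matrices")
    pooled = np.concatenate([wildtype.scores[wildtype.mask],
                             mutant.scores[mutant.mask]])
    if pooled.size == 0:
        raise ValueError("no valid cells in the input matrices")
    eps = 0.1 * pooled.mean()
    joint = mutant.mask & wildtype.mask
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.log2((mutant.scores + eps) / (wildtype.scores + eps))
    return WindowMatrix(mutant.gene_ids, np.where(joint, ratio, np.nan),
                        joint, mutant.frame, scale="log2_ratio")


# ---------------------------------------------------------------------------
# Masked k-means

def _masked_sq_distances(X: np.ndarray, valid: np.ndarray,
                         centroids: np.ndarray) -> np.ndarray:
    """(n, k) squared distances over valid windows, scaled by total/valid."""
    n, p = X.shape
    Xz = np.where(valid, X, 0.0)
    d = np.empty((n, len(centroids)))
    for j, c in enumerate(centroids):
        diff = (Xz - c) ** 2
        d[:, j] = np.where(valid, diff, 0.0).sum(axis=1)
    scale = p / valid.sum(axis=1)
    return d * scale[:, None]


def _centroid_update(X: np.ndarray, valid: np.ndarray, labels: np.ndarray,
                     k: int, prev: np.ndarray) -> np.ndarray:
    cents = prev.copy()
    for j in range(k):
        sel = labels == j
        if not sel.any():
            continue
        counts = valid[sel].sum(axis=0)
        sums = np.where(valid[sel], X[sel], 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            col = sums / counts
        cents[j] = np.where(counts > 0, col, prev[j])
    return cents


def _kmeans_once(X: np.ndarray, valid: np.ndarray, k: int,
                 rng: np.random.Generator, max_iter: int = 300,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray, float]:
    n = len(X)
    # k-means++ seeding on the masked distance
    first = int(rng.integers(n))
    cent_rows = [first]
    cents = np.where(valid[[first]], X[[first]], 0.0)
    while len(cent_rows) < k:
        d = _masked_sq_distances(X, valid, cents).min(axis=1)
        total = d.sum()
        if total <= 0:
            choice = int(rng.integers(n))
        else:
            choice = int(rng.choice(n, p=d / total))
        cent_rows.append(choice)
        cents = np.vstack([cents, np.where(valid[choice], X[choice], 0.0)])
    labels = np.full(n, -1)
    prev_inertia = np.inf
    for _ in range(max_iter):
        d = _masked_sq_distances(X, valid, cents)
        labels = d.argmin(axis=1)
        inertia = float(d[np.arange(n), labels].sum())
        assert inertia <= prev_inertia + 1e-6 * max(1.0, prev_inertia), \
            "k-means inertia increased"
        cents = _centroid_update(X, valid, labels, k, cents)
        if prev_inertia - inertia <= tol * max(1.0, prev_inertia):
            prev_inertia = inertia
            break
        prev_inertia = inertia
    d = _masked_sq_distances(X, valid, cents)
    labels = d.argmin(axis=1)
    inertia = float(d[np.arange(n), labels].sum())
    return labels, cents, inertia


def kmeans_profiles(matrix: WindowMatrix, k: int = 6, seed: int = 0,
                    restarts: int = 20,
                    min_valid_frac: float = 0.5) -> ClusterResult:
    """Cluster promoter profiles with Lloyd's algorithm, k-means++ seeded.

    Genes with fewer than ``min_valid_frac`` valid windows are set
    aside as unclustered.  The best of ``restarts`` runs by inertia is
    returned (ties by lowest run index); deterministic given ``seed``.
    """
    frac = matrix.mask.mean(axis=1)
    keep = frac >= min_valid_frac
    kept_ids = [g for g, ok in zip(matrix.gene_ids, keep) if ok]
    unclustered = [g for g, ok in zip(matrix.gene_ids, keep) if not ok]
    X, valid = matrix.scores[keep], matrix.mask[keep]
    if k > len(kept_ids):
        raise ValueError(f"k={k} exceeds {len(kept_ids)} clusterable genes")
    best = None
    root = np.random.default_rng(seed)
    for _ in range(restarts):
        run_rng = np.random.default_rng(root.integers(2**31))
        labels, cents, inertia = _kmeans_once(X, valid, k, run_rng)
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, cents, inertia)
    labels, cents, inertia = best
    # order clusters by descending mean centroid over the NDR zone [-150,+50)
    offsets = matrix.frame.window_offsets()
    zone = (offsets >= -150) & (offsets < 50)
    if not zone.any():
        zone = np.ones_like(offsets, dtype=bool)
    order = np.argsort(-cents[:, zone].mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    cents = cents[order]
    assignments = dict(zip(kept_ids, (int(c) for c in labels)))
    for g in unclustered:
        assignments[g] = -1
    return ClusterResult(k, assignments, cents, inertia, seed, restarts, unclustered)


def cluster_mean_profiles(matrix: WindowMatrix, clusters: ClusterResult,
                          n_boot: int = 1000, seed: int = 0,
                          min_genes: int = 10) -> dict[int, dict]:
    """Per-cluster mean profile with a 95% bootstrap band.

    Returns, per cluster id, ``mean`` (per window, over valid member
    cells), ``lo``/``hi`` (2.5/97.5 percentiles over ``n_boot`` gene
    resamples), ``n_genes``, and ``low_support`` flags for windows with
    fewer than ``min_genes`` contributing genes.
    """
    rng = np.random.default_rng(seed)
    idx = {g: i for i, g in enumerate(matrix.gene_ids)}
    out: dict[int, dict] = {}
    for c in range(clusters.k):
        rows = [idx[g] for g in clusters.members(c)]
        if not rows:
            raise ValueError(f"cluster {c} is empty")
        X = matrix.scores[rows]
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(X, axis=0)
        support = (~np.isnan(X)).sum(axis=0)
        boots = np.empty((n_boot, X.shape[1]))
        for b in range(n_boot):
            sample = X[rng.integers(len(rows), size=len(rows))]
            with np.errstate(invalid="ignore"):
                boots[b] = np.nanmean(sample, axis=0)
        lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
        out[c] = {"mean": mean, "lo": lo, "hi": hi, "n_genes": len(rows),
                  "low_support": support < min_genes}
    return out


def tss_score(matrix: WindowMatrix, statistic: str = "mean",
              half_width: int = 250) -> dict[str, float]:
    """Per-gene scalar over windows intersecting [-half_width, +half_width).

    ``statistic`` is ``mean`` or ``max`` over valid windows in range;
    genes with no valid window in range get NaN.
    """
    if half_width > matrix.frame.flank:
        raise ValueError("half_width exceeds the frame flank")
    if statistic not in ("mean", "max"):
        raise ValueError(f"unknown statistic {statistic!r}")
    starts = matrix.frame.window_offsets()
    ends = starts + matrix.frame.window
    in_range = (starts < half_width) & (ends > -half_width)
    scores: dict[str, float] = {}
    for g, row, m in zip(matrix.gene_ids, matrix.scores, matrix.mask):
        vals = row[in_range & m]
        if vals.size == 0:
            scores[g] = float("nan")
        elif statistic == "mean":
            scores[g] = float(vals.mean())
        else:
            scores[g] = float(vals.max())
    return scores


def correlate_assays(scores_a: dict[str, float],
                     scores_b: dict[str, float]) -> dict:
    """Pearson r and least-squares line on genes defined in both assays."""
    common = [g for g in scores_a
              if g in scores_b
              and np.isfinite(scores_a[g]) and np.isfinite(scores_b[g])]
    if len(common) < 3:
        raise ValueError("need >=3 genes defined in both score sets")
    a = np.array([scores_a[g] for g in common])
    b = np.array([scores_b[g] for g in common])
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return {"r": float("nan"), "n": len(common),
                "slope": float("nan"), "intercept": float("nan"),
                "defined": False}
    r, _ = stats.pearsonr(a, b)
    fit = stats.linregress(a, b)
    return {"r": float(r), "n": len(common), "slope": float(fit.slope),
            "intercept": float(fit.intercept), "defined": True}
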