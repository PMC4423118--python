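# Methods

`ndrscope` quantifies promoter chromatin around transcription start
sites (TSSs): how nucleosome occupancy and chromatin-remodeler binding
are organized at promoters, how that organization changes when a
remodeler is removed, and how those changes relate to promoter sequence
elements and transcription. This note documents the models, estimators,
defaults, and known limitations.

## Coordinate conventions

All internal coordinates are 0-based, half-open; conversions from
1-based formats (GFF3, wiggle) happen only at parse boundaries. Every
promoter quantity is expressed in *oriented* offsets relative to the
TSS: negative = upstream of transcription on the gene's own strand, so
"a shift toward the NDR" is a negative number for plus- and
minus-strand genes alike. For minus-strand transcripts the TSS is the
rightmost transcribed base and the genomic footprint is
`[tes, tss + 1)`.

## TSS window frames and neighbor masking

Occupancy is scored in fixed windows tiling ±`flank` bp around the TSS
(defaults: flank 800, window 50, hence 32 windows; 20 bp windows are
appropriate for sequencing-resolution data and are a config
parameter). The window score is the mean of defined base-pair values —
mean rather than sum so scores are comparable across window sizes. A
window is masked when (a) it overlaps, by at least 1 bp, the transcript
span of any other gene ("neighbor masking"; the full TSS-to-TES span is
used because any transcribed neighbor contaminates the signal), (b) it
extends past a chromosome end, or (c) more than half of its bases carry
no data. Masked cells propagate as missing through every downstream
statistic; nothing is imputed.

## From fragments to occupancy

Paired-end mono-nucleosome fragments (length filter 120–180 bp, the
standard MNase mono-nucleosome band) are reduced to their midpoints,
which approximate nucleosome dyads. The midpoint histogram is smoothed
with a Gaussian kernel (default bandwidth 20 bp SD — narrow enough to
preserve single-nucleosome peaks, wide enough to suppress base-pair
shot noise), renormalized so total mass equals the fragment count.
Occupancy is put on an interpretable scale as
`log2((x + eps) / (mean + eps))` with `eps = 0.1 * mean`, i.e. log2
relative to the genome average; the pseudocount bounds the transform at
empty positions (floor −log2(11) ≈ −3.46) without distorting typical
signal (< 0.07 log2 at 2× the mean).

Mutant/wild-type ratio matrices are built from linear window scores as
`log2((m + eps)/(w + eps))` with `eps = 0.1 ×` the pooled genome-mean
window score. Pooling both genotypes into `eps` makes the transform
exactly antisymmetric under swapping the genotypes.

## Promoter clustering

Promoters are grouped by their ratio profiles with k-means (default
k = 6, 20 restarts, k-means++ seeding, deterministic given the seed).
Masked windows are handled by distance scaling, not imputation: the
squared Euclidean distance over a gene's valid windows is multiplied by
(total windows / valid windows), an unbiased estimate of the
full-profile distance under a missing-at-random view. Genes with fewer
than 50% valid windows are set aside as "unclustered" but still receive
all per-gene scores. Cluster ids are ordered by descending mean
centroid over the NDR zone (oriented [−150, +50)), so cluster 0 is
always "strongest occupancy gain at the NDR" and the numbering is
stable across seeds. Per-run inertia is asserted non-increasing across
Lloyd iterations.

Cluster mean profiles carry 95% bootstrap bands (1000 gene resamples by
default); windows supported by fewer than 10 genes are flagged.

## NDR detection

The nucleosome-depleted region is called on the wild-type log2 profile
inside the search zone (oriented [−350, +50)) with a two-threshold
(hysteresis) rule: candidate intervals are maximal runs of windows
below θ/2, and a candidate qualifies if it contains at least 100 bp of
windows below θ (default θ = −0.5 log2; 100 bp = 2 windows at the
default width). Single sub-θ windows — nucleosome linkers, shot noise —
never qualify. If no run qualifies, an integrated fallback accepts a
contiguous ~150 bp span whose *mean* is below θ and which contains at
least two sub-θ/2 windows; integration is robust to one noisy window,
while a linker (≤ ~80 bp wide after smoothing) cannot drag a 150 bp
mean below θ. Depth is the distance from the genome-mean reference
down to the profile minimum in the interval. θ and the minimum length
are config-exposed; the defaults were calibrated on the synthetic
generator such that planted open promoters are detected and flat or
phased-but-undepleted profiles are not.

## +1 nucleosome and shift

The +1 nucleosome is the argmax of a cubic-spline interpolation of the
profile on a 10 bp grid (50 bp windows cannot otherwise resolve tens of
bp), searched downstream of the detected NDR end within oriented
[0, +300); zone-boundary maxima without an interior peak are rejected.
The mutant peak is then searched within ±82.5 bp (half the 165 bp
nucleosome repeat) of the wild-type peak, so both genotypes report the
same nucleosome — unconstrained argmax can lock onto the +2 in one
genotype and the +1 in the other, corrupting the shift by one repeat
length. `shift = mut_position − wt_position` (negative = upstream,
toward the NDR).

## Fill-in, suppression, classification

* **Fill-in** = mean of (mutant − wild type) log2 occupancy over the
  NDR windows; positive = the NDR gains nucleosomes. Cohort-level
  fill-in is estimated on *composite* profiles — linear window scores
  averaged over genes first, log2 second — restricted to isolated genes
  (no other TSS within 1700 bp). Averaging before the log avoids the
  concave-transform bias of per-gene log2 at near-zero counts, and
  isolation excludes promoters whose flanks carry a neighbor's
  chromatin; so estimated, the composite converges to the model's
  fragments→∞ limit (verified to ±0.07 log2 at default cohort size).
* **Suppression index** = 1 − effect_double / effect_single, computed
  per metric (fill-in and shift separately), defined only when the
  single-mutant effect clears a floor (0.3 log2 for fill, 20 bp for
  shift) below which the ratio is unstable. The shift-based index is
  linear in the planted suppression; the fill-based index is not
  (log2 compresses the fill fraction), so recovery of a planted
  suppression level is assessed on the shift metric.
* **Open/closed classification**: structure_score = NDR depth (0 if
  absent) + phasing amplitude, where phasing amplitude is the peak
  |autocorrelation| of the mean-subtracted, spline-resampled profile at
  lags 140–220 bp over the gene-body zone [+50, +750). A promoter is
  open iff an NDR is present and the score reaches τ = 0.8. The call is
  undefined when over half the phasing zone is masked.

## Occupancy calling at a target FDR

Per-gene ChIP TSS scores (mean over windows intersecting ±250 bp) are
compared to an empirical null built by circular per-chromosome shifts
of the track (each shift rolls every chromosome by an independent
random offset, preserving the signal's marginal distribution and
autocorrelation while destroying gene alignment) or by scoring a
matched control track. One-sided empirical p-values (plus-one rule)
receive Benjamini–Hochberg correction; genes with q ≤ FDR are called.
Calls are monotone in the FDR level by construction.

## Sequence elements and permutation tests

Motifs are exact IUPAC consensus matches; defaults: TATA box
`TATAWAWR`, Reb1 `TTACCCG`, Rsc3 `CGCGC` (presence, both strands), and
poly(A) = runs of ≥5 consecutive A on either strand (count of maximal
runs). `N` never matches. The scan region defaults to oriented
[−500, +50).

Category enrichment is tested by permutation: the observed category
mean is compared to means of equal-size gene draws from the background
without replacement (≥1000 draws; the implementation vectorizes the
draws). The tested tail is fixed a priori (enrichment by default,
depletion selectable); the observed direction is reported separately.
With an adaptive tail, null p-values would concentrate on (0, 0.5]; with
the fixed tail they are uniform, which the test suite verifies by
Kolmogorov–Smirnov. Empirical p-values use the plus-one rule and are
never zero. Gene-set intersections are tested both hypergeometrically
(exact tail) and by label permutation; the two agree within Monte-Carlo
error and cross-check each other.

## Expression (tiled-array) module

Probe intensities are divided, per replicate, by the median of the
non-hybridizing control probes (exactly 1 after scaling; idempotent and
invariant to rescaling a replicate). Gene level = median over the
gene's sense probes within a replicate (robust to single failing
probes), then mean over replicates; antisense likewise. Genotype
ratios are log2 ratios of these replicate-averaged levels — a single
well-defined level per gene/genotype — rather than means of
per-replicate ratios. The suppressed-gene screen selects genes at
least 1.5-fold down in the single mutant (log2 ≤ −0.585) whose double
mutant recovers at least half of the deficit in log2 space; both
thresholds are explicit parameters.

## The synthetic cohort generator

The generator emits everything the pipeline consumes — BED6 annotation,
chromosome sizes, promoter FASTA, per-genotype fragment BED3, a ChIP
bedGraph, probe TSVs — plus a JSON record of every planted parameter.
Fragments are simulated at the read level (midpoint = sampled dyad,
length ~ Normal(147, 10) clipped to [120, 180]) so the entire
tracks → profiles → architecture chain is exercised under MNase-style
multinomial sampling noise.

Dyad mixture per promoter (oriented bp): −1 nucleosome N(−220, 20) and
+1 N(+60, 20) at unit weight; gene-body nucleosomes at +60 + 165k
(k = 1..4) with SD growing 5 bp and weight decaying ×0.8 per step; an
upstream array at −220 − 165k mirrors the body decay so the promoter
flank is covered the way real chromatin is — without it every promoter
would show a spurious deep "NDR" in the empty upstream flank. The NDR
zone [−180, −20) carries a uniform baseline: 0.05 nucleosome
equivalents for open promoters, 0.6 for closed. Closed promoters apply
a per-gene uniform phase offset in [0, 165) to the *entire* landscape,
baseline zone included — each closed promoter has definite structure,
the cohort has no consensus; shifting the components but not the zone
would tear a genuine hole at large phases and contradict the planted
class.

Genotype effects: remodeler-loss ("rsc") raises the open-promoter NDR
baseline from b to b + f(1−b) (default f = 0.6) and translates the +1
and body components by s (default −40 bp); ISW1 loss moves body
components by −10 bp; the double mutant applies f(1−σ) and s(1−σ)
(default σ = 0.5), making σ the planted suppression. 165 bp repeat and
147 bp fragment mode are the canonical yeast values; all are config
fields.

Layout: 50 genes per chromosome, ~4 kb mean gaps (minimum 2×flank +
100 so unmasked promoters exist); 10% of gaps are 500 bp to exercise
neighbor masking. Genes are at least 1 kb so a promoter's array (which
reaches ~0.9 kb from the TSS) never spills past its own transcript,
and close-spaced pairs are forced into tandem orientation: a divergent
pair sharing a 500 bp gap would superimpose two promoters' chromatin on
the same DNA, and no estimator could recover either gene's planted
geometry from their sum. (Real divergent promoters do share NDRs; the
pipeline makes no special provision for them, and composite statistics
use isolated genes.)

Promoter sequences are built on a background of doubled C/G blocks —
no A/T at all and no ≥4 bp C/G alternation, hence no spurious match to
any default motif — with elements planted at class-specific rates:
Reb1/Rsc3 sites and poly(A) runs inside open NDRs, TATA boxes near
−100 in closed promoters. Planted counts recorded in the truth file
are obtained by re-scanning the emitted sequence, so collisions between
planted elements cannot desynchronize truth and data. The ChIP track
multiplies a 500 bp promoter window by 4 (closed) or 2 (open) in linear
scale — closed promoters carry the most remodeler — plus N(0, 0.15)
log2 noise; a sparse mode instead plants +2 log2 at a random 10% of
promoters for FDR calibration studies. Probe tables give each gene 8
sense and 8 antisense probes across 3 replicates with 0.15 log2
per-replicate noise, 61 zebrafish-style non-hybridizing controls (odd
count, so the scaled control median is exactly 1), class-wise planted
expression effects (−1 log2 for coding/ncRNA, 0 for tRNA), and 15
"restored" genes (−1 log2 in the single mutant, 90% recovered in the
double) for the suppression screen.

What the generator does *not* emulate: sequence-determined nucleosome
energetics, replication or transcription dynamics, MNase sequence bias,
array probe-response curves, or read-level error models. Passing tests
therefore demonstrate that the estimators recover planted effects from
realistic sampling noise at realistic effect sizes — not that real
chromatin satisfies the model.

## Problem sizes and determinism

The validation cohort is 300 genes × 200 fragments/gene × 4 genotypes,
the size at which all recovery bands quoted in the test suite hold
(shift ±10 bp, composite fill-in ±0.15 log2 of the analytic limit,
shift-suppression median ±0.1, classification accuracy ≥ 0.95 —
measured 0.977–0.997 across seeds). Every stochastic step takes an
explicit seed; the full CLI chain is byte-reproducible, which the test
suite checks by running it twice and comparing files.

## Known limitations

* The NDR detector assumes the promoter flank is covered by signal;
  on assays with large no-data gaps the ≥50% missing rule masks
  windows, and heavily masked promoters return "unevaluable".
* The +1 tracker assumes the mutant peak stays within half a repeat
  length of the wild-type peak; shifts larger than ~82 bp would be
  aliased.
* Per-gene fill-in retains the log-of-small-counts bias at low
  coverage; use the composite estimator for cohort-level claims.
* Closed promoters are modeled as phase-randomized open promoters with
  a high NDR baseline; real unstructured promoters are more
  heterogeneous than a single phase parameter.
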