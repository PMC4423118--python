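# ndrscope

Promoter chromatin analysis around transcription start sites: nucleosome
occupancy profiling, NDR (nucleosome-depleted region) geometry, promoter
classification by response to chromatin-remodeler loss, FDR-controlled
remodeler-occupancy calling, permutation tests for promoter sequence
elements, and tiled-array expression ratios — together with a synthetic
chromatin generator that plants ground truth for every quantity the
pipeline estimates.

## The problem

Yeast promoters come in two architectures. *Open* (structured)
promoters show a stereotyped organization: a nucleosome-depleted region
just upstream of the TSS flanked by positioned −1 and +1 nucleosomes,
with a phased array (≈165 bp repeat) running into the gene body.
*Closed* (unstructured) promoters lack consensus positioning relative
to the TSS and are typically TATA-containing and highly regulated.
ATP-dependent remodelers act antagonistically on this organization:
RSC-type remodelers keep the NDR open, while ISW1-type spacing
remodelers fill it in and reposition the +1. Removing one remodeler
therefore shifts promoter chromatin; removing both partially restores
it. `ndrscope` turns those observations into per-gene, per-genotype
numbers:

* **window matrices** — occupancy scored in 50 bp windows, ±800 bp
  around each TSS, gene-oriented, with windows overlapping neighboring
  genes excluded;
* **ratio profiles and k-means clusters** — promoters grouped by their
  log2(mutant/wild-type) occupancy profile (default k = 6);
* **NDR calls** — interval, depth (log2 below genome mean), and
  presence, via a hysteresis run detector (θ = −0.5, ≥100 bp);
* **+1 shift** — spline-interpolated peak displacement at 10 bp
  resolution (negative = toward the NDR);
* **fill-in** — mean occupancy gain over the NDR (log2);
* **suppression index** — 1 − effect_double/effect_single per metric;
* **open/closed calls** — NDR depth + phasing autocorrelation ≥ τ;
* **occupancy calls at a target FDR** — empirical circular-shift null +
  Benjamini–Hochberg;
* **sequence-element enrichment** — exact IUPAC scans (TATA, Reb1,
  Rsc3, poly(A)) tested by label permutation, plus hypergeometric /
  permutation gene-set intersection tests;
* **expression summaries** — control-probe-scaled intensities, per-gene
  sense/antisense levels, class-wise log2 ratio distributions, and a
  screen for genes whose expression loss is suppressed in a double
  mutant.

See `docs/methods.md` for the estimators, defaults, and the synthetic
model.

## Worked example

Generate a synthetic cohort with planted effects (NDR fill fraction
0.6, +1 shift −40 bp, double-mutant suppression 0.5), run the analysis
chain, and read the recovered numbers:

```python
from ndrscope import SyntheticConfig, generate_cohort
from ndrscope.pipeline import run_pipeline
import numpy as np

cfg = SyntheticConfig(n_genes=300, fragments_per_gene=200, seed=11)
truth = generate_cohort(cfg, "cohort/")
res = run_pipeline("cohort/", k=6, seed=17)

reports = {r.gene_id: r for r in res["reports"]}
open_genes = [g for g, a in truth.architecture.items() if a == "open"]
shifts = [reports[g].shift_bp for g in open_genes
          if np.isfinite(reports[g].shift_bp)]
sup = [reports[g].suppression_shift for g in open_genes
       if np.isfinite(reports[g].suppression_shift)]
calls = {g: r.promoter_class for g, r in reports.items()
         if r.promoter_class != "undefined"}
acc = np.mean([calls[g] == truth.architecture[g] for g in calls])
print(f"mean +1 shift      {np.mean(shifts):+.1f} bp")
print(f"median suppression {np.median(sup):.2f}")
print(f"class accuracy     {acc:.3f}")
```

Output:

```
mean +1 shift      -42.2 bp
median suppression 0.50
class accuracy     0.997
```

The planted −40 bp upstream shift of the +1 nucleosome is recovered as
a cohort mean of −42.2 bp; the planted suppression σ = 0.5 (the double
mutant shows half the single-mutant shift) is recovered exactly as the
median shift-based suppression index; and 99.7% of promoters are assigned
their planted open/closed class from wild-type occupancy alone.

The same steps are available from the shell:

```bash
ndrscope simulate --seed 11 --out cohort/
ndrscope score --track occ.bedgraph --genes cohort/genes.bed \
    --chrom-sizes cohort/chrom.sizes --out matrix.tsv
ndrscope cluster --ratio ratio.tsv --k 6 --seed 17 --out clusters.tsv
ndrscope ndr --wt wt.tsv --mut mut.tsv --out architecture.tsv
ndrscope enrich --fasta cohort/promoters.fa --clusters clusters.tsv \
    --perms 10000 --seed 7 --out enrichment.tsv
```

## Layout

```
src/ndrscope/
  annotation.py    transcript models, promoter frames, neighbor masks
  tracks.py        bedGraph/wiggle/fragment I/O, pileups, normalization,
                   window scoring
  profiles.py      ratio matrices, masked k-means, TSS scores, correlation
  architecture.py  NDR calls, +1 shifts, fill-in, suppression, open/closed
  enrichment.py    FDR occupancy calls, motif scans, permutation tests
  expression.py    control scaling, gene levels, class ratios, screen
  synthetic.py     cohort generator with planted ground truth
  pipeline.py      end-to-end chain over a cohort directory
  cli.py           `ndrscope` command-line entry points
```
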