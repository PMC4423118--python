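"""Synthetic chromatin cohorts with planted, recorded ground truth.

The generator emits everything the pipeline consumes — annotation,
promoter sequences, per-genotype nucleosome fragments, remodeler ChIP
tracks, probe intensities — from an explicit dyad mixture model, and
records every planted parameter so downstream estimates can be scored
against truth.

Dyad model (oriented offsets relative to the TSS):

* open (structured) promoter — Gaussian dyad components at -1
  (mu=-220, sd=20) and +1 (mu=+60, sd=20), then phased gene-body peaks
  at +60+165k (k=1..4) whose sd grows 5 bp per step and weight decays
  x0.8; the NDR zone [-180,-20) carries a small uniform baseline
  (default 0.05 of a nucleosome's weight).
* closed (unstructured) promoter — the same number of components but
  with a per-gene uniform random phase offset in [0,165), and an NDR
  baseline of 0.6: each gene has structure, the cohort has no
  consensus.

Genotypes: loss of RSC raises the open-promoter NDR baseline from b to
b + f(1-b) and translates the +1-and-downstream components upstream by
``shift_bp``; loss of ISW1 translates gene-body components (k>=1) by a
small body shift; the double mutant applies f(1-sigma) and
shift*(1-sigma), i.e. ``sigma`` is the planted suppression.

Fragments are mono-nucleosome sized (Normal(147,10) clipped to
[120,180]) with the sampled dyad as midpoint, so the full
tracks->profiles->architecture chain sees MNase-style sampling noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotation import (GenomeAnnotation, PromoterFrame, TranscriptModel,
                         write_annotation, write_chrom_sizes)
from .enrichment import DEFAULT_MOTIFS, reverse_complement
from .tracks import FragmentSet, write_fragments, write_track, OccupancyTrack

GENOTYPES = ("WT", "rsc", "isw1", "rsc_isw1")


@dataclass
class SyntheticConfig:
    """Planted study conditions for one synthetic cohort."""

    n_genes: int = 300
    fraction_open: float = 0.5
    genes_per_chrom: int = 50
    spacing_mean: int = 4000          # intergenic gap, most genes unmasked
    spacing_close_frac: float = 0.1   # fraction with short gaps (masking path)
    spacing_close: int = 500
    gene_length_mean: int = 1500
    fragments_per_gene: int = 200
    fragment_length_mean: float = 147.0
    fragment_length_sd: float = 10.0
    seed: int = 0
    # genotype effects
    fill_fraction: float = 0.6        # f: rsc NDR fill
    shift_bp: float = -40.0           # s: rsc +1/body shift (upstream)
    isw1_body_shift: float = -10.0
    suppression: float = 0.5          # sigma: double-mutant restoration
    # dyad model
    ndr_zone: tuple[float, float] = (-180.0, -20.0)
    ndr_baseline_open: float = 0.05
    ndr_baseline_closed: float = 0.6
    minus_one_mu: float = -220.0
    plus_one_mu: float = 60.0
    nuc_sd: float = 20.0
    phasing_period: float = 165.0
    n_body_nucs: int = 4
    n_upstream_nucs: int = 4
    body_weight_decay: float = 0.8
    body_sd_step: float = 5.0
    # ChIP
    chip_closed_multiplier: float = 4.0   # linear occupancy boost at closed promoters
    chip_open_multiplier: float = 2.0
    chip_noise_sd: float = 0.15           # log2 units
    chip_enriched_fraction: float = 0.0   # extra planted calls (0 = architecture-driven)
    # motif placement probabilities / rates
    motif_rates_open: dict = field(default_factory=lambda: {
        "TATA": 0.2, "Reb1": 0.6, "Rsc3": 0.6, "polyA": 3.0})
    motif_rates_closed: dict = field(default_factory=lambda: {
        "TATA": 0.8, "Reb1": 0.1, "Rsc3": 0.1, "polyA": 0.5})
    # expression
    n_expr_genes: int = 150
    probes_per_gene: int = 8
    n_control_probes: int = 61   # odd: the scaled control median is exactly 1
    n_replicates: int = 3
    expr_noise_sd: float = 0.15           # log2 units
    expr_class_effect: dict = field(default_factory=lambda: {
        "coding": -1.0, "ncRNA": -1.0, "tRNA": 0.0})
    n_restored_genes: int = 15
    restored_down_log2: float = -1.0
    restored_recovery: float = 0.9        # fraction of deficit recovered
    flank: int = 800
    window: int = 50

    def __post_init__(self) -> None:
        for name, p in (("fraction_open", self.fraction_open),
                        ("fill_fraction", self.fill_fraction),
                        ("suppression", self.suppression),
                        ("spacing_close_frac", self.spacing_close_frac)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.n_genes <= 0 or self.fragments_per_gene <= 0:
            raise ValueError("n_genes and fragments_per_gene must be positive")
        if self.spacing_mean < 2 * self.flank and self.spacing_close_frac < 1.0:
            raise ValueError("spacing_mean must leave room for unmasked promoters")


@dataclass
class GroundTruth:
    """Everything planted, per gene, for downstream recovery scoring."""

    config: dict
    architecture: dict[str, str]               # gene -> open/closed
    ndr_interval: dict[str, tuple[float, float]]
    plus_one: dict[str, dict[str, float]]      # gene -> genotype -> oriented pos
    fill_fraction: dict[str, float]
    shift_bp: dict[str, float]
    suppression: dict[str, float]
    chip_enriched: list[str]
    motif_counts: dict[str, dict[str, int]]
    expression_effect: dict[str, dict[str, float]]  # gene -> genotype -> log2 vs WT
    restored_genes: list[str]

    def to_json(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["ndr_interval"] = {k: tuple(v) for k, v in d["ndr_interval"].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Dyad mixture model

def dyad_components(cfg: SyntheticConfig, architecture: str, genotype: str,
                    phase_offset: float = 0.0) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """(means, sds, weights, ndr_baseline) of the dyad mixture, oriented bp.

    ``phase_offset`` shifts every component for closed promoters
    (per-gene random phase).  Genotype effects translate the +1 and
    body components and raise the NDR baseline as documented in the
    module docstring.
    """
    f = {"WT": 0.0, "isw1": 0.0,
         "rsc": cfg.fill_fraction,
         "rsc_isw1": cfg.fill_fraction * (1.0 - cfg.suppression)}[genotype]
    s = {"WT": 0.0, "isw1": 0.0,
         "rsc": cfg.shift_bp,
         "rsc_isw1": cfg.shift_bp * (1.0 - cfg.suppression)}[genotype]
    body = cfg.isw1_body_shift if genotype in ("isw1",) else 0.0

    means = [cfg.minus_one_mu, cfg.plus_one_mu + s]
    sds = [cfg.nuc_sd, cfg.nuc_sd]
    weights = [1.0, 1.0]
    for k in range(1, cfg.n_body_nucs + 1):
        means.append(cfg.plus_one_mu + k * cfg.phasing_period + s + body)
        sds.append(cfg.nuc_sd + cfg.body_sd_step * k)
        weights.append(cfg.body_weight_decay ** k)
    # upstream array continuing past the -1 (the neighbouring chromatin),
    # so the promoter flank is covered the way real MNase maps are and
    # the planted NDR is the only depleted interval; unaffected by the
    # genotype shifts, which act from the +1 downstream.
    for k in range(1, cfg.n_upstream_nucs + 1):
        means.append(cfg.minus_one_mu - k * cfg.phasing_period)
        sds.append(cfg.nuc_sd + cfg.body_sd_step * k)
        weights.append(cfg.body_weight_decay ** k)
    means = np.array(means) + phase_offset
    base = cfg.ndr_baseline_open if architecture == "open" else cfg.ndr_baseline_closed
    baseline = base + f * (1.0 - base) if architecture == "open" else base
    # the baseline zone translates with the phase so an unstructured
    # promoter is the whole landscape shifted, with no fixed hole
    zone = (cfg.ndr_zone[0] + phase_offset, cfg.ndr_zone[1] + phase_offset)
    return means, np.array(sds), np.array(weights), baseline, zone


def sample_dyads(cfg: SyntheticConfig, architecture: str, genotype: str,
                 phase_offset: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``n`` oriented dyad offsets from the mixture."""
    means, sds, weights, baseline, zone = dyad_components(cfg, architecture,
                                                          genotype, phase_offset)
    lo, hi = zone
    # NDR baseline acts as one uniform pseudo-component over the NDR zone
    w = np.concatenate([weights, [baseline]])
    w = w / w.sum()
    comp = rng.choice(len(w), size=n, p=w)
    out = np.empty(n)
    is_nuc = comp < len(means)
    out[is_nuc] = rng.normal(means[comp[is_nuc]], sds[comp[is_nuc]])
    out[~is_nuc] = rng.uniform(lo, hi, size=(~is_nuc).sum())
    return out


def expected_profile(cfg: SyntheticConfig, architecture: str, genotype: str,
                     offsets: np.ndarray, phase_offset: float = 0.0) -> np.ndarray:
    """Noiseless dyad density (fragments -> infinity limit) at given offsets."""
    means, sds, weights, baseline, zone = dyad_components(cfg, architecture,
                                                          genotype, phase_offset)
    lo, hi = zone
    dens = np.zeros_like(offsets, dtype=float)
    for m, sd, w in zip(means, sds, weights):
        dens += w * np.exp(-0.5 * ((offsets - m) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    dens += baseline * ((offsets >= lo) & (offsets < hi)) / (hi - lo)
    return dens / (np.array(weights).sum() + baseline)


def expected_window_profile(cfg: SyntheticConfig, architecture: str,
                            genotype: str, frame: PromoterFrame,
                            genome_mean: float, smoothing_bw: float = 20.0,
                            phase_offset: float = 0.0) -> np.ndarray:
    """Noiseless pipeline-scale window profile (fragments -> infinity).

    Evaluates the dyad density on a 1 bp grid, applies the same
    Gaussian smoothing and log2-relative-to-genome-mean transform the
    fragment pipeline applies (``genome_mean`` in fragments/bp, e.g.
    n_genes x fragments_per_gene / genome size), and averages into the
    frame's windows.  This is the closed-form limit the sampled
    cohort's estimates converge to.
    """
    from scipy.ndimage import gaussian_filter1d

    pad = 400
    grid = np.arange(-frame.flank - pad, frame.flank + pad, dtype=float)
    dens = expected_profile(cfg, architecture, genotype, grid, phase_offset)
    dens = dens * cfg.fragments_per_gene
    if smoothing_bw > 0:
        dens = gaussian_filter1d(dens, sigma=smoothing_bw, mode="nearest")
    eps = 0.1 * genome_mean
    rel = np.log2((dens + eps) / (genome_mean + eps))
    out = np.empty(frame.n_windows)
    for w, start in enumerate(frame.window_offsets()):
        i = int(start + frame.flank + pad)
        out[w] = rel[i:i + frame.window].mean()
    return out


# ---------------------------------------------------------------------------
# Sequence planting

_BASES = np.array(list("ACGT"))


def _random_sequence(n: int, rng: np.random.Generator) -> list[str]:
    return list(_BASES[rng.integers(4, size=n)])


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    from .enrichment import IUPAC
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern.upper())


def plant_promoter_sequence(cfg: SyntheticConfig, architecture: str,
                            rng: np.random.Generator,
                            region: tuple[int, int] = (-500, 50)) -> tuple[str, dict[str, int]]:
    """Random promoter sequence with elements planted at the class rates.

    Presence motifs (TATA, Reb1, Rsc3) are planted 0/1 by a Bernoulli
    draw; polyA plants a Poisson number of >=5 bp A-runs.  Open
    promoters get their Reb1/Rsc3/polyA elements inside the NDR,
    TATA-rich closed promoters get the TATA near the canonical -100
    position.  Returned counts are recomputed by scanning, so they
    match what any scanner sees (collisions included).
    """
    from .enrichment import scan_motifs

    rates = cfg.motif_rates_open if architecture == "open" else cfg.motif_rates_closed
    length = region[1] - region[0]
    # background of doubled C/G blocks: contains no A/T (so no spurious
    # polyA runs or TATA boxes) and no >=4 bp C/G alternation (so no
    # spurious Rsc3 sites); isolated sprinkled bases cannot create either
    blocks = rng.choice(["CC", "GG"], size=length // 2 + 1)
    seq = list("".join(blocks))[:length]
    for i in range(0, length, 7):
        seq[i] = str(_BASES[rng.integers(4)])
        if seq[i] == "A" and i > 0 and seq[i - 1] == "A":
            seq[i] = "C"

    def place(sub: str, zone: tuple[int, int]) -> None:
        lo = zone[0] - region[0]
        hi = zone[1] - region[0] - len(sub)
        if hi <= lo:
            return
        pos = int(rng.integers(lo, hi))
        seq[pos:pos + len(sub)] = list(sub)

    ndr_zone = (int(cfg.ndr_zone[0]), int(cfg.ndr_zone[1]))
    for m in DEFAULT_MOTIFS:
        rate = rates.get(m.name, 0.0)
        if m.count_mode == "presence":
            if rng.random() < rate:
                zone = ndr_zone if m.name in ("Reb1", "Rsc3") else (-150, -50)
                place(_instantiate(m.pattern, rng), zone)
        else:
            for _ in range(rng.poisson(rate)):
                run = "A" * int(rng.integers(5, 9))
                place(run, (region[0] + 10, region[1] - 10))
    sequence = "".join(seq)
    counts = {k: int(v) for k, v in scan_motifs({"x": sequence})["x"].items()}
    return sequence, counts


# ---------------------------------------------------------------------------
# Cohort generation

def _layout_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> GenomeAnnotation:
    """Gene layout with mostly wide intergenic gaps plus planted close pairs.

    Genes are >= 1 kb so a promoter's nucleosome array (reaching ~0.9 kb
    from the TSS) never spills past its own transcript into a
    neighbour's promoter.  Close-spaced pairs (which exercise the
    neighbor-masking path) are forced into tandem orientation: a
    divergent pair sharing a short gap would superimpose two promoters'
    chromatin on the same DNA and make the planted per-gene truth
    unrecoverable in principle.
    """
    transcripts = []
    chrom_sizes = {}
    gi = 0
    chrom_idx = 0
    while gi < cfg.n_genes:
        chrom_idx += 1
        chrom = f"chr{chrom_idx}"
        pos = cfg.flank + 200
        n_here = min(cfg.genes_per_chrom, cfg.n_genes - gi)
        prev_strand, prev_gap_short = "+", False
        for _ in range(n_here):
            length = int(rng.normal(cfg.gene_length_mean, 200))
            length = max(length, 1000)
            strand = "+" if rng.random() < 0.5 else "-"
            if prev_gap_short and prev_strand == "-":
                strand = "-"  # keep close pairs tandem
            if strand == "+":
                tss, tes = pos, pos + length
            else:
                tss, tes = pos + length - 1, pos
            transcripts.append(TranscriptModel(f"g{gi:04d}", chrom, strand,
                                               tss, tes, "coding"))
            gi += 1
            prev_gap_short = rng.random() < cfg.spacing_close_frac
            if prev_gap_short:
                gap = cfg.spacing_close
            else:
                gap = int(rng.normal(cfg.spacing_mean, cfg.spacing_mean / 8))
                gap = max(gap, 2 * cfg.flank + 100)
            prev_strand = strand
            pos += length + gap
        chrom_sizes[chrom] = pos + cfg.flank + 200
    return GenomeAnnotation(transcripts, chrom_sizes)


def generate_cohort(cfg: SyntheticConfig, out_dir) -> GroundTruth:
    """Emit a full synthetic cohort to ``out_dir`` and return its truth.

    Files written: genes.bed, chrom.sizes, promoters.fa, fragments
    BED3 per genotype, chip.bedgraph (log2 enrichment), probes_* TSV
    per genotype, and truth.json.  Byte-deterministic given cfg.seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    annotation = _layout_genes(cfg, rng)
    write_annotation(annotation, out / "genes.bed")
    write_chrom_sizes(annotation.chrom_sizes, out / "chrom.sizes")

    n_open = int(round(cfg.fraction_open * cfg.n_genes))
    arch_labels = ["open"] * n_open + ["closed"] * (cfg.n_genes - n_open)
    rng.shuffle(arch_labels)
    genes = list(annotation)
    architecture = {g.id: a for g, a in zip(genes, arch_labels)}
    phase = {g.id: (float(rng.uniform(0, cfg.phasing_period))
                    if architecture[g.id] == "closed" else 0.0)
             for g in genes}

    # --- fragments per genotype
    frag_rng = np.random.default_rng(rng.integers(2**31))
    plus_one_truth: dict[str, dict[str, float]] = {g.id: {} for g in genes}
    for genotype in GENOTYPES:
        chroms, starts, ends = [], [], []
        for g in genes:
            offs = sample_dyads(cfg, architecture[g.id], genotype, phase[g.id],
                                cfg.fragments_per_gene, frag_rng)
            lengths = np.clip(frag_rng.normal(cfg.fragment_length_mean,
                                              cfg.fragment_length_sd,
                                              size=len(offs)),
                              120, 180).round().astype(int)
            mids = np.array([g.genomic_position(int(round(o))) for o in offs])
            size = annotation.chrom_sizes[g.chrom]
            mids = np.clip(mids, 100, size - 101)
            fs = mids - lengths // 2
            fe = fs + lengths
            chroms.extend([g.chrom] * len(offs))
            starts.extend(fs.tolist())
            ends.extend(fe.tolist())
            means = dyad_components(cfg, architecture[g.id], genotype,
                                    phase[g.id])[0]
            plus_one_truth[g.id][genotype] = float(means[1])
        frags = FragmentSet(np.array(chroms, dtype=object),
                            np.array(starts), np.array(ends))
        write_fragments(frags, out / f"fragments_{genotype}.bed")

    # --- ChIP track (log2 enrichment over input).
    # Default mode boosts every promoter with closed > open, matching the
    # observation that unstructured promoters carry the most remodeler;
    # chip_enriched_fraction > 0 switches to a sparse planted-call mode
    # (that fraction of genes gets +2 log2 at the promoter, rest nothing),
    # the regime used for FDR calibration studies.
    chip_rng = np.random.default_rng(rng.integers(2**31))
    chip = {c: np.ones(n) for c, n in annotation.chrom_sizes.items()}
    enriched = []
    if cfg.chip_enriched_fraction > 0:
        n_enriched = int(round(cfg.chip_enriched_fraction * cfg.n_genes))
        picks = chip_rng.choice(len(genes), size=n_enriched, replace=False)
        gene_mult = {genes[i].id: 4.0 for i in picks}  # +2 log2
    else:
        gene_mult = {g.id: (cfg.chip_closed_multiplier
                            if architecture[g.id] == "closed"
                            else cfg.chip_open_multiplier) for g in genes}
    for g in genes:
        mult = gene_mult.get(g.id, 1.0)
        if mult <= 1.0:
            continue
        span_lo = min(g.genomic_position(-250), g.genomic_position(249))
        span_lo = max(span_lo, 0)
        span_hi = min(span_lo + 500, annotation.chrom_sizes[g.chrom])
        chip[g.chrom][span_lo:span_hi] *= mult
        enriched.append(g.id)
    for c in chip:
        noise = chip_rng.normal(0.0, cfg.chip_noise_sd, size=len(chip[c]))
        chip[c] = np.log2(chip[c]) + noise
    write_track(OccupancyTrack(chip, scale="log2_ratio", label="chip"),
                out / "chip.bedgraph")

    # --- promoter sequences with planted motifs
    seq_rng = np.random.default_rng(rng.integers(2**31))
    seqs, motif_counts = {}, {}
    for g in genes:
        s, counts = plant_promoter_sequence(cfg, architecture[g.id], seq_rng)
        seqs[g.id] = s
        motif_counts[g.id] = counts
    from .enrichment import write_fasta
    write_fasta(seqs, out / "promoters.fa")

    # --- expression probe tables
    expr_rng = np.random.default_rng(rng.integers(2**31))
    expr_genes = [g.id for g in genes[:cfg.n_expr_genes]]
    classes = {}
    for i, gid in enumerate(expr_genes):
        classes[gid] = ("tRNA" if i % 10 == 9 else
                        "ncRNA" if i % 10 == 8 else "coding")
    restored = [g for g in expr_genes if classes[g] == "coding"][:cfg.n_restored_genes]
    effects: dict[str, dict[str, float]] = {}
    for gid in expr_genes:
        base_effect = cfg.expr_class_effect.get(classes[gid], 0.0)
        eff = {"WT": 0.0}
        if gid in restored:
            eff["rsc"] = cfg.restored_down_log2
            eff["rsc_isw1"] = cfg.restored_down_log2 * (1.0 - cfg.restored_recovery)
        else:
            eff["rsc"] = base_effect
            eff["rsc_isw1"] = base_effect
        eff["isw1"] = 0.0
        effects[gid] = eff
    base_level = {gid: float(expr_rng.lognormal(5.0, 0.5)) for gid in expr_genes}
    import pandas as pd
    for genotype in GENOTYPES:
        rows = []
        for gid in expr_genes:
            level = base_level[gid] * 2.0 ** effects[gid].get(genotype, 0.0)
            for p in range(cfg.probes_per_gene):
                for strand, frac in (("sense", 1.0), ("antisense", 0.15)):
                    row = {"probe_id": f"{gid}_p{p}_{strand[0]}",
                           "gene_id": gid, "control": False, "strand": strand}
                    for r in range(cfg.n_replicates):
                        noise = 2.0 ** expr_rng.normal(0.0, cfg.expr_noise_sd)
                        row[f"rep{r+1}"] = level * frac * noise
                    rows.append(row)
        for p in range(cfg.n_control_probes):
            row = {"probe_id": f"ctrl_{p}", "gene_id": "", "control": True,
                   "strand": "sense"}
            for r in range(cfg.n_replicates):
                row[f"rep{r+1}"] = float(expr_rng.lognormal(3.0, 0.3))
            rows.append(row)
        df = pd.DataFrame(rows)
        df["control"] = df["control"].astype(int)
        df.to_csv(out / f"probes_{genotype}.tsv", sep="\t", index=False)

    truth = GroundTruth(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(cfg).items()},
        architecture=architecture,
        ndr_interval={g.id: (cfg.ndr_zone[0], cfg.ndr_zone[1]) for g in genes
                      if architecture[g.id] == "open"},
        plus_one=plus_one_truth,
        fill_fraction={g.id: (cfg.fill_fraction if architecture[g.id] == "open"
                              else 0.0) for g in genes},
        shift_bp={g.id: cfg.shift_bp for g in genes},
        suppression={g.id: cfg.suppression for g in genes},
        chip_enriched=enriched,
        motif_counts=motif_counts,
        expression_effect=effects,
        restored_genes=restored,
    )
    truth.to_json(out / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# Recovery scoring

def truth_report(truth: GroundTruth, estimates: dict) -> dict:
    """Bias/RMSE/accuracy of pipeline estimates against planted truth.

    ``estimates`` may carry any of: ``shift_bp``, ``fill_in``,
    ``suppression`` (per-gene dicts), ``promoter_class`` (per-gene
    open/closed), ``chip_called`` (set of gene ids).  Metrics are
    computed over the intersection with the truth's gene universe;
    a disjoint universe is a hard error.
    """
    report: dict = {}
    universe = set(truth.architecture)

    def common(d: dict) -> list[str]:
        genes = [g for g in d if g in universe and np.isfinite(d[g])]
        if d and not set(d) & universe:
            raise ValueError("estimate universe disjoint from truth")
        return genes

    if "shift_bp" in estimates:
        d = estimates["shift_bp"]
        genes = [g for g in common(d) if truth.architecture[g] == "open"]
        if genes:
            err = np.array([d[g] - truth.shift_bp[g] for g in genes])
            report["shift"] = {"bias": float(err.mean()),
                               "rmse": float(np.sqrt((err ** 2).mean())),
                               "n": len(genes)}
    if "fill_in" in estimates:
        d = estimates["fill_in"]
        genes = [g for g in common(d) if truth.architecture[g] == "open"]
        if genes:
            vals = np.array([d[g] for g in genes])
            report["fill_in"] = {"mean": float(vals.mean()), "n": len(genes)}
    if "suppression" in estimates:
        d = estimates["suppression"]
        genes = common(d)
        if genes:
            vals = np.array([d[g] for g in genes])
            report["suppression"] = {"median": float(np.median(vals)),
                                     "n": len(genes)}
    if "promoter_class" in estimates:
        d = estimates["promoter_class"]
        genes = [g for g in d if g in universe and d[g] in ("open", "closed")]
        if genes:
            correct = sum(d[g] == truth.architecture[g] for g in genes)
            report["classification"] = {"accuracy": correct / len(genes),
                                        "n": len(genes)}
    if "chip_called" in estimates:
        called = set(estimates["chip_called"]) & universe
        true_set = set(truth.chip_enriched)
        tp = len(called & true_set)
        report["chip_calls"] = {
            "precision": tp / len(called) if called else float("nan"),
            "recall": tp / len(true_set) if true_set else float("nan"),
            "n_called": len(called)}
    return report
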