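"""Tiled-array expression quantification with non-hybridizing controls.

Probe intensities are scaled per replicate to the median of the
control (non-hybridizing, foreign-sequence) probes, summarized per
gene by the median over sense probes and averaged over replicates,
then compared between genotypes as log2 ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProbeTable:
    """Probe-level intensities: probe_id, gene_id/control, strand, replicates.

    ``frame`` columns: probe_id, gene_id (empty for controls), control
    (bool), strand ({sense, antisense}), rep1..repN (nonnegative floats).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "gene_id", "control", "strand"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"probe table missing columns {missing}")
        if not self.rep_columns:
            raise ValueError("probe table has no replicate columns")
        if not self.frame["control"].any():
            raise ValueError("at least one control probe is required")
        noncontrol = self.frame[~self.frame["control"]]
        if (noncontrol["gene_id"].astype(str).str.len() == 0).any():
            raise ValueError("non-control probe without a gene_id")

    @property
    def rep_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c.startswith("rep")]

    @classmethod
    def from_tsv(cls, path) -> "ProbeTable":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        df["gene_id"] = df["gene_id"].fillna("")
        df["control"] = df["control"].astype(bool)
        return cls(df)

    def to_tsv(self, path) -> None:
        df = self.frame.copy()
        df["control"] = df["control"].astype(int)
        df.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionSummary:
    """Per-gene expression levels for one genotype."""

    genotype: str
    sense: dict[str, float] = field(default_factory=dict)
    antisense: dict[str, float] = field(default_factory=dict)
    gene_class: dict[str, str] = field(default_factory=dict)


def scale_to_controls(table: ProbeTable) -> ProbeTable:
    """Divide each replicate by its control-probe median intensity.

    After scaling, the control median is exactly 1 per replicate.
    Idempotent, and invariant to rescaling a replicate's raw
    intensities by any positive constant.
    """
    df = table.frame.copy()
    controls = df["control"].to_numpy()
    for col in table.rep_columns:
        med = float(df.loc[controls, col].median())
        if med <= 0:
            raise ValueError(f"{col}: control-probe median is not positive")
        df[col] = df[col] / med
    return ProbeTable(df)


def gene_expression(table: ProbeTable, genotype: str,
                    gene_classes: dict[str, str] | None = None) -> ExpressionSummary:
    """Per-gene levels: median over probes per replicate, mean over replicates.

    Sense and antisense strands are summarized separately.  Genes with
    zero probes are absent from the output (logged as a warning).
    """
    df = table.frame[~table.frame["control"]]
    summary = ExpressionSummary(genotype)
    reps = table.rep_columns
    for strand, store in (("sense", summary.sense), ("antisense", summary.antisense)):
        sub = df[df["strand"] == strand]
        if sub.empty:
            continue
        med = sub.groupby("gene_id")[reps].median()
        for gene, row in med.iterrows():
            store[str(gene)] = float(row.mean())
    missing = set(df["gene_id"]) - set(summary.sense)
    if missing:
        warnings.warn(f"{len(missing)} genes have no sense probes: "
                      f"{sorted(missing)[:5]}...")
    if gene_classes:
        summary.gene_class = {g: gene_classes.get(g, "coding") for g in summary.sense}
    return summary


def log2_ratios(mutant: ExpressionSummary, wildtype: ExpressionSummary) -> dict[str, float]:
    """Per-gene log2(mut/wt) sense ratios; genes lacking either value skipped."""
    out: dict[str, float] = {}
    for g, wt in wildtype.sense.items():
        mut = mutant.sense.get(g)
        if mut is None or not (wt > 0):
            continue
        out[g] = float(np.log2(mut / wt)) if mut > 0 else float("-inf")
    return out


def class_ratio_summary(mutant: ExpressionSummary, wildtype: ExpressionSummary,
                        classes: dict[str, str]) -> pd.DataFrame:
    """Five-number summary of log2(mut/wt) per gene class.

    Returns a DataFrame indexed by class with columns n, min, q1,
    median, q3, max, n_skipped.  Genes lacking either genotype's value
    are skipped and counted.
    """
    ratios = log2_ratios(mutant, wildtype)
    rows = []
    universe = set(wildtype.sense) | set(mutant.sense)
    for cls in sorted(set(classes.values())):
        members = [g for g in universe if classes.get(g) == cls]
        vals = np.array([ratios[g] for g in members if g in ratios
                         and np.isfinite(ratios[g])])
        skipped = len(members) - len(vals)
        if vals.size == 0:
            rows.append({"gene_class": cls, "n": 0, "min": np.nan, "q1": np.nan,
                         "median": np.nan, "q3": np.nan, "max": np.nan,
                         "n_skipped": skipped})
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"gene_class": cls, "n": len(vals), "min": float(vals.min()),
                     "q1": float(q1), "median": float(med), "q3": float(q3),
                     "max": float(vals.max()), "n_skipped": skipped})
    return pd.DataFrame(rows).set_index("gene_class")


def suppressed_gene_screen(wt: ExpressionSummary, single_mut: ExpressionSummary,
                           double_mut: ExpressionSummary,
                           down_threshold: float = 0.585,
                           restore_fraction: float = 0.5) -> list[str]:
    """Genes down in the single mutant and partially restored in the double.

    A gene is selected iff log2(single/wt) <= -down_threshold (default
    0.585, i.e. 1.5-fold down) and the double mutant recovers at least
    ``restore_fraction`` of the single-mutant deficit in log2 space.
    """
    single_r = log2_ratios(single_mut, wt)
    double_r = log2_ratios(double_mut, wt)
    selected = []
    for g, s in single_r.items():
        d = double_r.get(g)
        if d is None or not np.isfinite(s) or not np.isfinite(d):
            continue
        if s <= -down_threshold and (d - s) >= restore_fraction * abs(s):
            selected.append(g)
    return sorted(selected)


def write_expression_summary(summary: ExpressionSummary,
                             ratios: dict[str, float] | None, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tgenotype\tsense\tantisense\tlog2_ratio_vs_wt\tgene_class\n")
        for g in sorted(summary.sense):
            anti = summary.antisense.get(g, float("nan"))
            ratio = (ratios or {}).get(g, float("nan"))
            cls = summary.gene_class.get(g, "coding")
            fh.write(f"{g}\t{summary.genotype}\t{summary.sense[g]:.6g}\t"
                     f"{anti:.6g}\t{ratio:.6g}\t{cls}\n")
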