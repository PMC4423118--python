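"""Promoter chromatin geometry: NDR calls, +1 shifts, fill-in, suppression.

All positions are oriented bp offsets relative to the TSS (negative =
upstream of transcription), so "a shift toward the NDR" is negative for
every gene regardless of strand.  Profiles are expected in log2
occupancy relative to the genome average, one value per promoter
window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.interpolate import CubicSpline

from .annotation import PromoterFrame
from .tracks import WindowMatrix

NDR_SEARCH_ZONE = (-350, 50)
PLUS_ONE_ZONE = (0, 300)
PHASING_ZONE = (50, 750)
NDR_THRESHOLD = -0.5       # log2 units below genome mean
NDR_MIN_BP = 100           # minimum NDR length (2 windows at the 50 bp default)
STRUCTURE_TAU = 0.8
FILL_FLOOR = 0.3           # log2 units
SHIFT_FLOOR = 20.0         # bp


@dataclass
class NDRCall:
    """Nucleosome-depleted region of one promoter (oriented coordinates)."""

    gene_id: str
    present: bool
    ndr_start: float = float("nan")
    ndr_end: float = float("nan")
    depth: float = float("nan")
    unevaluable: bool = False


@dataclass
class ArchitectureReport:
    """Per-gene geometry and genotype-effect summary."""

    gene_id: str
    ndr: NDRCall
    plus_one_pos_wt: float = float("nan")
    plus_one_pos_mut: float = float("nan")
    shift_bp: float = float("nan")
    fill_in: float = float("nan")
    suppression_fill: float = float("nan")
    suppression_shift: float = float("nan")
    promoter_class: str = "undefined"
    structure_score: float = float("nan")


def _zone_selector(frame: PromoterFrame, zone: tuple[int, int]) -> np.ndarray:
    starts = frame.window_offsets()
    ends = starts + frame.window
    return (starts < zone[1]) & (ends > zone[0])


def detect_ndr(wt_profile: np.ndarray, frame: PromoterFrame,
               gene_id: str = "", search_zone: tuple[int, int] = NDR_SEARCH_ZONE,
               threshold: float = NDR_THRESHOLD,
               min_windows: int | None = None) -> NDRCall:
    """Call the NDR as the longest sub-threshold run in the search zone.

    The NDR is the longest contiguous run of valid windows with value
    below ``threshold`` (log2 relative to genome mean); it is called
    present iff the run spans at least ``min_windows`` windows
    (default: enough windows to cover ~100 bp, i.e. 2 at the 50 bp
    default window, so inter-nucleosome linkers never qualify).  Depth
    is the distance from the genome-mean reference (0) down to the
    profile minimum within the run.
    """
    if min_windows is None:
        min_windows = max(2, int(np.ceil(NDR_MIN_BP / frame.window)))
    weak = threshold / 2.0  # hysteresis: extent threshold
    sel = _zone_selector(frame, search_zone)
    starts = frame.window_offsets()
    idx = np.nonzero(sel)[0]
    vals = wt_profile[idx]
    if np.isnan(vals).all():
        return NDRCall(gene_id, present=False, unevaluable=True)
    below_weak = np.isfinite(vals) & (vals < weak)
    below_core = np.isfinite(vals) & (vals < threshold)
    # candidate = maximal runs under the weak threshold; a candidate
    # qualifies if it carries >= min_windows core windows (so single
    # linker dips and isolated noisy windows never do)
    best = None  # (n_core, start, length)
    i = 0
    while i < len(vals):
        if not below_weak[i]:
            i += 1
            continue
        j = i
        while j < len(vals) and below_weak[j]:
            j += 1
        n_core = int(below_core[i:j].sum())
        if best is None or n_core > best[0] or (n_core == best[0] and j - i > best[2]):
            best = (n_core, i, j - i)
        i = j
    if best is not None and best[0] >= min_windows:
        _, start, length = best
        run = idx[start:start + length]
        depth = -float(np.nanmin(vals[start:start + length]))
        return NDRCall(gene_id, present=True,
                       ndr_start=float(starts[run[0]]),
                       ndr_end=float(starts[run[-1]] + frame.window),
                       depth=depth)
    # integrated fallback: a contiguous ~150 bp span whose *mean* is
    # sub-threshold is depleted even if one window fluctuates above it;
    # a nucleosome linker cannot span 150 bp, so closed promoters are
    # not rescued by this path
    span = max(min_windows + 1, int(np.ceil(1.5 * NDR_MIN_BP / frame.window)))
    best_mean, best_start = np.inf, -1
    for i in range(len(vals) - span + 1):
        chunk = vals[i:i + span]
        if np.isnan(chunk).any() or below_weak[i:i + span].sum() < 2:
            continue  # a lone linker dip is not depletion
        m = float(chunk.mean())
        if m < best_mean:
            best_mean, best_start = m, i
    if best_mean < threshold:
        run = idx[best_start:best_start + span]
        depth = -float(np.nanmin(vals[best_start:best_start + span]))
        return NDRCall(gene_id, present=True,
                       ndr_start=float(starts[run[0]]),
                       ndr_end=float(starts[run[-1]] + frame.window),
                       depth=depth)
    return NDRCall(gene_id, present=False)


def _interpolated_peak(profile: np.ndarray, frame: PromoterFrame,
                       zone: tuple[float, float], grid_bp: float = 10.0) -> float:
    """Argmax of a cubic-spline interpolation of the profile at window centers."""
    centers = frame.window_offsets() + frame.window / 2.0
    ok = np.isfinite(profile)
    if ok.sum() < 4:
        return float("nan")
    spline = CubicSpline(centers[ok], profile[ok])
    lo = max(zone[0], centers[ok][0])
    hi = min(zone[1], centers[ok][-1])
    if hi <= lo:
        return float("nan")
    # grid aligned to multiples of grid_bp so equal profiles in shifted
    # search zones localize to identical positions
    grid = np.arange(np.ceil(lo / grid_bp) * grid_bp, hi + 1e-9, grid_bp)
    if grid.size < 3:
        return float("nan")
    y = spline(grid)
    # require an interior local maximum, not a zone-boundary runaway
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        peaks = [j for j in range(1, len(y) - 1)
                 if y[j] >= y[j - 1] and y[j] >= y[j + 1]]
        if not peaks:
            return float("nan")
        i = max(peaks, key=lambda j: y[j])
    return float(grid[i])


def plus_one_position(profile: np.ndarray, frame: PromoterFrame,
                      ndr: NDRCall | None = None,
                      search_zone: tuple[int, int] = PLUS_ONE_ZONE) -> float:
    """Locate the +1 nucleosome peak at 10 bp resolution.

    The search starts downstream of the detected NDR end (if an NDR is
    present and ends inside the zone), avoiding lock-on to the -1 peak.
    """
    lo, hi = search_zone
    if ndr is not None and ndr.present and np.isfinite(ndr.ndr_end):
        lo = max(lo, ndr.ndr_end)
    return _interpolated_peak(profile, frame, (lo, hi))


def plus_one_shift(wt_profile: np.ndarray, mut_profile: np.ndarray,
                   frame: PromoterFrame, ndr: NDRCall | None = None,
                   search_zone: tuple[int, int] = PLUS_ONE_ZONE,
                   track_halfwidth: float = 82.5) -> float:
    """Signed +1 nucleosome displacement, mutant minus wild type.

    The wild-type peak is located first (argmax downstream of the NDR
    end); the mutant peak is then searched within half a phasing
    period (``track_halfwidth``) of it, so both genotypes report the
    same nucleosome rather than hopping between +1 and +2.  Negative
    values are upstream shifts, toward the NDR.  NaN when no peak can
    be located for either genotype.
    """
    wt_pos = plus_one_position(wt_profile, frame, ndr, search_zone)
    if not np.isfinite(wt_pos):
        return float("nan")
    mut_zone = (wt_pos - track_halfwidth, wt_pos + track_halfwidth)
    mut_pos = _interpolated_peak(mut_profile, frame, mut_zone)
    return mut_pos - wt_pos


def fill_in_score(wt_profile: np.ndarray, mut_profile: np.ndarray,
                  frame: PromoterFrame, ndr: NDRCall) -> float:
    """Mean occupancy gain (mut - wt, log2) over the NDR windows.

    Positive = the mutant fills the NDR.  Undefined when the NDR is
    absent.
    """
    if not ndr.present:
        return float("nan")
    starts = frame.window_offsets()
    ends = starts + frame.window
    sel = (starts < ndr.ndr_end) & (ends > ndr.ndr_start)
    diff = mut_profile[sel] - wt_profile[sel]
    diff = diff[np.isfinite(diff)]
    return float(diff.mean()) if diff.size else float("nan")


def suppression_index(effect_single: float, effect_double: float,
                      floor: float) -> float:
    """1 - double/single: 0 = no suppression, 1 = full restoration.

    NaN (gene skipped) when the single-mutant effect is below ``floor``
    in magnitude, where the ratio is unstable.  Invariant under common
    rescaling of both effects.
    """
    if not np.isfinite(effect_single) or abs(effect_single) < floor:
        return float("nan")
    if not np.isfinite(effect_double):
        return float("nan")
    return 1.0 - effect_double / effect_single


def phasing_amplitude(profile: np.ndarray, frame: PromoterFrame,
                      zone: tuple[int, int] = PHASING_ZONE,
                      lag_range: tuple[int, int] = (140, 220)) -> float:
    """Peak autocorrelation of the mean-subtracted profile at nucleosomal lags.

    The profile over the phasing zone is spline-resampled to a 10 bp
    grid; the normalized autocorrelation is evaluated at lags 140-220
    bp and its maximum magnitude returned.  Strongly phased arrays
    (period ~165 bp) give values near 1, unstructured promoters near 0.
    """
    centers = frame.window_offsets() + frame.window / 2.0
    sel = (centers >= zone[0]) & (centers < zone[1])
    vals = profile[sel]
    cen = centers[sel]
    ok = np.isfinite(vals)
    if ok.sum() < 4:
        return float("nan")
    grid = np.arange(cen[ok][0], cen[ok][-1] + 1e-9, 10.0)
    y = CubicSpline(cen[ok], vals[ok])(grid)
    y = y - y.mean()
    denom = float((y ** 2).sum())
    if denom <= 0:
        return 0.0
    best = 0.0
    for lag_bp in range(lag_range[0], lag_range[1] + 1, 10):
        lag = lag_bp // 10
        if lag >= len(y):
            break
        ac = float((y[:-lag] * y[lag:]).sum()) / denom
        best = max(best, abs(ac))
    return best


def classify_promoter(wt_profile: np.ndarray, frame: PromoterFrame,
                      ndr: NDRCall,
                      phasing_zone: tuple[int, int] = PHASING_ZONE,
                      tau: float = STRUCTURE_TAU) -> tuple[str, float]:
    """Open (structured) vs closed (unstructured) promoter call.

    structure_score = NDR depth (0 if absent) + phasing amplitude;
    open iff an NDR is present and the score reaches ``tau``.
    Undefined when over half of the phasing zone is masked.
    """
    sel = _zone_selector(frame, phasing_zone)
    if np.isnan(wt_profile[sel]).mean() > 0.5:
        return "undefined", float("nan")
    amp = phasing_amplitude(wt_profile, frame, phasing_zone)
    depth = ndr.depth if ndr.present else 0.0
    score = depth + (amp if np.isfinite(amp) else 0.0)
    label = "open" if (ndr.present and score >= tau) else "closed"
    return label, float(score)


def architecture_report(wt: WindowMatrix, mut: WindowMatrix,
                        double: WindowMatrix | None = None,
                        fill_floor: float = FILL_FLOOR,
                        shift_floor: float = SHIFT_FLOOR) -> list[ArchitectureReport]:
    """Full per-gene geometry/effect table for a mutant (and optional double).

    ``wt``/``mut``/``double`` are window matrices in log2-relative-to-
    genome-mean scale over the same frame and gene list.
    """
    if not wt.same_frame(mut) or (double is not None and not wt.same_frame(double)):
        raise ValueError("matrices must share frame and gene list")
    reports = []
    for i, gene_id in enumerate(wt.gene_ids):
        wt_p, mut_p = wt.scores[i], mut.scores[i]
        ndr = detect_ndr(wt_p, wt.frame, gene_id)
        rep = ArchitectureReport(gene_id, ndr)
        rep.promoter_class, rep.structure_score = classify_promoter(wt_p, wt.frame, ndr)
        rep.plus_one_pos_wt = plus_one_position(wt_p, wt.frame, ndr)
        rep.shift_bp = plus_one_shift(wt_p, mut_p, wt.frame, ndr)
        rep.plus_one_pos_mut = rep.plus_one_pos_wt + rep.shift_bp
        rep.fill_in = fill_in_score(wt_p, mut_p, wt.frame, ndr)
        if double is not None:
            dbl_p = double.scores[i]
            fill_dbl = fill_in_score(wt_p, dbl_p, wt.frame, ndr)
            shift_dbl = plus_one_shift(wt_p, dbl_p, wt.frame, ndr)
            rep.suppression_fill = suppression_index(rep.fill_in, fill_dbl, fill_floor)
            rep.suppression_shift = suppression_index(rep.shift_bp, shift_dbl, shift_floor)
        reports.append(rep)
    return reports


def write_reports(reports: list[ArchitectureReport], path) -> None:
    cols = ["gene_id", "ndr_present", "ndr_start", "ndr_end", "ndr_depth",
            "plus_one_wt", "plus_one_mut", "shift_bp", "fill_in",
            "suppression_fill", "suppression_shift", "promoter_class",
            "structure_score"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in reports:
            row = [r.gene_id, str(int(r.ndr.present)),
                   f"{r.ndr.ndr_start:.6g}", f"{r.ndr.ndr_end:.6g}",
                   f"{r.ndr.depth:.6g}", f"{r.plus_one_pos_wt:.6g}",
                   f"{r.plus_one_pos_mut:.6g}", f"{r.shift_bp:.6g}",
                   f"{r.fill_in:.6g}", f"{r.suppression_fill:.6g}",
                   f"{r.suppression_shift:.6g}", r.promoter_class,
                   f"{r.structure_score:.6g}"]
            fh.write("\t".join(row) + "\n")
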