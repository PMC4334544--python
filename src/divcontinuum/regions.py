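"""Delimitation of divergent regions of exceptional differentiation.

Adjacent outlier windows are merged into candidate regions; each candidate's
border is then refined to 1 kb resolution by walking outward from the locus
of maximal divergence in 1 kb bins and contrasting each bin's mean site F_ST
to the genome-wide average through the barrier strength

    b = [f / (1 - f)] / [F / (1 - F)]

(the ratio of local to genome-wide effective-migration odds; b = 1 exactly
at the genome-wide average). A side's margin is set at the inner edge of the
first of two consecutive bins with b strictly below 1; empty bins count as
below. Refined regions overlapping each other are merged, and regions whose
accessible fraction is below 50% are discarded.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DivergentRegion

__all__ = [
    "merge_adjacent",
    "barrier_strength",
    "refine_boundaries",
    "coverage_filter",
    "build_regions",
]

log = logging.getLogger(__name__)

#: refinement bin width (bp); regions are reported on this grid
BIN = 1000
#: hard cap on the outward walk per side, in bp
MAX_EXTENSION = 500_000


def merge_adjacent(outlier_windows: pd.DataFrame) -> list[tuple[str, int, int]]:
    """Merge maximal runs of boundary-sharing outlier windows per chromosome.

    Input needs chrom/start/end columns, sorted by (chrom, start); returns
    (chrom, start, end) candidates. Singleton outliers stay single-window
    candidates.
    """
    cands: list[tuple[str, int, int]] = []
    for chrom, sub in outlier_windows.groupby("chrom", sort=False):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise ValueError("outlier windows must be sorted and unique")
        cur_s, cur_e = None, None
        for s, e in zip(starts, ends):
            if cur_e is not None and s == cur_e:
                cur_e = e
            else:
                if cur_s is not None:
                    cands.append((chrom, int(cur_s), int(cur_e)))
                cur_s, cur_e = s, e
        if cur_s is not None:
            cands.append((chrom, int(cur_s), int(cur_e)))
    return cands


def barrier_strength(bin_fst: float, genome_fst: float) -> float:
    """Barrier strength b of a 1 kb bin relative to the genome-wide average.

    Returns +inf for a fully differentiated bin (F_ST = 1), treated as b > 1.
    An alternative plain-ratio definition is available via
    ``barrier_strength_ratio``.
    """
    if not 0 < genome_fst < 1:
        raise ValueError("genome_fst must lie in (0, 1)")
    if bin_fst >= 1:
        return float("inf")
    bin_fst = max(float(bin_fst), 0.0)
    return (bin_fst / (1.0 - bin_fst)) / (genome_fst / (1.0 - genome_fst))


def barrier_strength_ratio(bin_fst: float, genome_fst: float) -> float:
    """Plain-ratio variant b = bin_fst / genome_fst."""
    if not 0 < genome_fst < 1:
        raise ValueError("genome_fst must lie in (0, 1)")
    return float(bin_fst) / genome_fst


@dataclass
class SiteProfile:
    """Per-chromosome retained site positions (0-based) and F_ST values."""

    pos: np.ndarray
    fst: np.ndarray

    def bin_mean(self, bin_start: int) -> float:
        lo = np.searchsorted(self.pos, bin_start, side="left")
        hi = np.searchsorted(self.pos, bin_start + BIN, side="left")
        if hi == lo:
            return float("nan")  # empty bin
        return float(np.mean(self.fst[lo:hi]))


def _walk(profile: SiteProfile, peak_bin: int, direction: int, genome_fst: float,
          chrom_length: int, b_func) -> int:
    """Walk outward from the peak bin; return the margin (bp) on this side.

    ``direction`` is -1 (left) or +1 (right). The margin is the inner edge
    of the first of two consecutive bins with b < 1 (empty bins count as
    below); with no stop, the walk is clamped to the chromosome bounds or
    the maximum extension, whichever comes first.
    """
    below_streak = 0
    first_below = None  # bin start of the first bin of a potential stopping pair
    step = 0
    max_steps = MAX_EXTENSION // BIN
    while step < max_steps:
        step += 1
        bstart = peak_bin + direction * step * BIN
        if bstart < 0 or bstart >= chrom_length:
            break
        m = profile.bin_mean(bstart)
        below = True if np.isnan(m) else (b_func(m, genome_fst) < 1.0)
        if below:
            if below_streak == 0:
                first_below = bstart
            below_streak += 1
            if below_streak == 2:
                # inner edge of the first below-bin of the pair
                return first_below + BIN if direction < 0 else first_below
        else:
            below_streak = 0
    # no stopping pair: clamp to the furthest examined bin's outer edge
    outer = peak_bin + direction * step * BIN
    if direction < 0:
        return max(outer, 0)
    return min(outer + BIN, _grid_floor(chrom_length))


def _grid_floor(x: int) -> int:
    return (x // BIN) * BIN


def refine_boundaries(candidate: tuple[str, int, int], profile: SiteProfile,
                      genome_fst: float, chrom_length: int,
                      use_ratio: bool = False) -> DivergentRegion | None:
    """Refine one candidate's borders with the barrier-strength walk.

    ``profile`` holds the chromosome's retained per-site F_ST (0-based
    positions). The peak is the position of the maximal per-site F_ST inside
    the candidate (ties broken leftmost); the peak's own 1 kb bin is always
    retained. Returns None (with a logged reason) when the candidate holds
    no retained site.
    """
    chrom, start, end = candidate
    lo = np.searchsorted(profile.pos, start, side="left")
    hi = np.searchsorted(profile.pos, end, side="left")
    if hi == lo:
        log.warning("candidate %s:%d-%d dropped: no retained sites", chrom, start, end)
        return None
    seg_fst = profile.fst[lo:hi]
    peak_pos = int(profile.pos[lo + int(np.argmax(seg_fst))])
    peak_bin = _grid_floor(peak_pos)
    b_func = barrier_strength_ratio if use_ratio else barrier_strength

    left = _walk(profile, peak_bin, -1, genome_fst, chrom_length, b_func)
    right = _walk(profile, peak_bin, +1, genome_fst, chrom_length, b_func)
    left = min(left, peak_bin)
    right = max(right, peak_bin + BIN)

    r_lo = np.searchsorted(profile.pos, left, side="left")
    r_hi = np.searchsorted(profile.pos, right, side="left")
    mean_fst = float(np.mean(profile.fst[r_lo:r_hi]))
    return DivergentRegion(chrom=chrom, start=int(left), end=int(right),
                           peak_pos=peak_pos, mean_fst=mean_fst)


def coverage_filter(region: DivergentRegion, mask: pd.DataFrame) -> bool:
    """Keep a region iff accessible bp spans at least 50% of its length."""
    sub = mask[mask["chrom"] == region.chrom]
    acc = 0
    for s, e in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
        acc += max(0, min(int(e), region.end) - max(int(s), region.start))
    frac = acc / (region.end - region.start)
    region.coverage_fraction = float(frac)
    return frac >= 0.5


def _merge_overlapping(regions: list[DivergentRegion]) -> list[DivergentRegion]:
    """Merge refined regions that overlap (regions are maximal by construction)."""
    out: list[DivergentRegion] = []
    for reg in sorted(regions, key=lambda r: (r.chrom, r.start)):
        if out and out[-1].chrom == reg.chrom and reg.start < out[-1].end:
            prev = out[-1]
            keep_peak = prev if prev.mean_fst >= reg.mean_fst else reg
            merged = DivergentRegion(
                chrom=prev.chrom, start=prev.start, end=max(prev.end, reg.end),
                peak_pos=keep_peak.peak_pos,
                mean_fst=max(prev.mean_fst, reg.mean_fst),
            )
            out[-1] = merged
        else:
            out.append(reg)
    return out


def build_regions(scan: pd.DataFrame, site_profiles: dict[str, SiteProfile],
                  genome_fst: float, chrom_lengths: dict[str, int],
                  mask: pd.DataFrame | None = None,
                  use_ratio: bool = False) -> list[DivergentRegion]:
    """End-to-end region building from a scanned window table.

    ``scan`` is the output of :func:`divcontinuum.outliers.scan_windows`;
    ``site_profiles`` maps chromosome to its retained-site F_ST profile
    (build with :func:`site_profiles_from_matrices` in the pipeline module).
    """
    outl = scan[scan["final_flag"]].sort_values(["chrom", "start"])
    cands = merge_adjacent(outl)
    regions = []
    for cand in cands:
        prof = site_profiles.get(cand[0])
        if prof is None:
            continue
        reg = refine_boundaries(cand, prof, genome_fst, chrom_lengths[cand[0]],
                                use_ratio=use_ratio)
        if reg is not None:
            regions.append(reg)
    regions = _merge_overlapping(regions)
    if mask is not None:
        regions = [r for r in regions if coverage_filter(r, mask)]
    return regions
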