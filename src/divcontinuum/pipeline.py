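"""Orchestration of the five-stage analysis: windowed statistics, outlier
scan, region delimitation, classification and summary reporting.

`run_pair` is the in-memory engine used by both the CLI and the test
fixtures; `run_pipeline` adds file I/O around it.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import io as _io
from . import outliers as _outliers
from . import popgen as _popgen
from . import regions as _regions
from .datatypes import DivergentRegion, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = ["PairResult", "run_pair", "run_pipeline", "retained_site_fst",
           "site_profiles_from_windows"]


def retained_site_fst(pop1: GenotypeMatrix, pop2: GenotypeMatrix,
                      maf_threshold: float | None = 0.25):
    """Per-site WC F_ST at the sites passing the pooled-MAF filter.

    Returns (chrom, pos0, fst) arrays in genome order; sites where the
    estimator is undefined are dropped along with their positions.
    """
    c1, n1 = pop1.alt_counts(), pop1.called_alleles()
    c2, n2 = pop2.alt_counts(), pop2.called_alleles()
    keep = np.ones(pop1.n_sites, dtype=bool)
    if maf_threshold is not None:
        keep = _popgen.maf_filter_pair(c1, n1, c2, n2, maf_threshold)
    fst = _popgen.site_fst_wc_vector(c1, n1, c2, n2)
    keep &= ~np.isnan(fst)
    return pop1.chrom[keep], pop1.pos[keep] - 1, fst[keep]


def site_profiles_from_windows(chrom, pos0, fst) -> dict[str, _regions.SiteProfile]:
    """Group retained per-site F_ST into per-chromosome profiles."""
    profiles = {}
    for c in pd.unique(pd.Series(chrom)):
        on_c = chrom == c
        profiles[str(c)] = _regions.SiteProfile(pos=pos0[on_c], fst=fst[on_c])
    return profiles


@dataclass
class PairResult:
    """Bundle of everything the pipeline derives for one population pair."""

    windows: pd.DataFrame            # 10 kb scan table with outlier flags
    windows_100kb: pd.DataFrame      # 100 kb table (T_D thresholds source)
    regions: list[DivergentRegion]
    thresholds: _classify.CategoryThresholds | None
    genome_fst: float                # genome-wide mean of retained site F_ST
    summary: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pair(pop1: GenotypeMatrix, pop2: GenotypeMatrix, mask: pd.DataFrame,
             chrom_lengths: dict[str, int], window_size: int = 10_000,
             maf_threshold: float = 0.25, q: float = 0.01,
             fdr_level: float = 0.01, n_perm: int = 10_000,
             seed: int | None = None, classifier_mode: str = "per-pop",
             classify_regions: bool = True) -> PairResult:
    """Scan one population pair end to end.

    Stages: 10 kb window statistics -> empirical + permutation outlier scan
    -> adjacent-window merge and barrier-strength border refinement (against
    the genome-wide mean retained-site F_ST) -> 50% accessibility filter ->
    Tajima's-D classification against 100 kb genome-wide thresholds.
    """
    win = _popgen.window_stats(pop1, pop2, mask, chrom_lengths,
                               window_size=window_size,
                               maf_threshold=maf_threshold)
    chrom_s, pos0_s, fst_s = retained_site_fst(pop1, pop2, maf_threshold)
    log.info("scan: %d retained sites, %d windows", len(fst_s), len(win))

    scan = _outliers.scan_windows(win, fst_s, q=q, fdr_level=fdr_level,
                                  n_perm=n_perm, seed=seed)
    genome_fst = float(np.mean(fst_s))
    # border refinement reads the *unfiltered* polymorphic-site profile: the
    # pooled-MAF cut belongs to the scan, and inside a sweep it thins sites
    # so strongly that 1 kb bins go empty and the walk would stop early
    chrom_a, pos0_a, fst_a = retained_site_fst(pop1, pop2, None)
    profiles = site_profiles_from_windows(chrom_a, pos0_a, fst_a)
    genome_fst_all = float(np.mean(fst_a))
    regions = _regions.build_regions(scan, profiles, genome_fst_all,
                                     chrom_lengths, mask=mask)
    log.info("regions: %d final outlier windows -> %d refined regions",
             int(scan["final_flag"].sum()), len(regions))

    win100 = _popgen.window_stats(pop1, pop2, mask, chrom_lengths,
                                  window_size=100_000,
                                  maf_threshold=maf_threshold)
    thresholds = None
    if classify_regions and regions:
        try:
            thresholds = _classify.compute_thresholds(
                win100["td_pop1"].to_numpy(), win100["td_pop2"].to_numpy(),
                mode=classifier_mode)
        except ValueError as exc:
            # genome too small for stable genome-wide quantiles: keep the
            # regions but leave them uncategorised
            log.warning("classification skipped: %s", exc)
        else:
            regions = _classify.classify_regions(regions, pop1, pop2, thresholds)
    summary = _classify.summarize_categories({"pair": regions})
    return PairResult(windows=scan, windows_100kb=win100, regions=regions,
                      thresholds=thresholds, genome_fst=genome_fst,
                      summary=summary)


def run_pipeline(vcf_path, popmap_path, mask_path, chrom_lengths: dict[str, int],
                 out_dir, pop_order: tuple[str, str] | None = None,
                 seed: int = 0, **scan_kwargs) -> PairResult:
    """File-based pipeline: read inputs, run the pair scan, write reports.

    Writes windows.tsv, outliers.bed, regions.bed, regions.tsv and
    summary.tsv under ``out_dir``; every file carries the seed and a config
    hash in its header comment. Deterministic for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    popmap = _io.read_popmap(popmap_path)
    mask = _io.read_bed(mask_path)
    pops = _io.read_vcf(vcf_path, popmap, mask)
    if pop_order is None:
        pop_order = tuple(sorted(pops))  # type: ignore[assignment]
    if len(pops) != 2:
        raise ValueError(f"expected exactly 2 populations, got {sorted(pops)}")
    pop1, pop2 = pops[pop_order[0]], pops[pop_order[1]]

    cfg = dict(vcf=str(vcf_path), popmap=str(popmap_path), mask=str(mask_path),
               chrom_lengths=chrom_lengths, seed=seed, **scan_kwargs)
    h = _io.config_hash(cfg)
    result = run_pair(pop1, pop2, mask, chrom_lengths, seed=seed, **scan_kwargs)

    _io.write_table(result.windows, out / "windows.tsv", seed, h)
    outl = result.windows[result.windows["final_flag"]]
    _io.write_table(outl[["chrom", "start", "end", "fst"]],
                    out / "outliers.tsv", seed, h)
    _io.write_regions_bed(result.regions, out / "regions.bed", seed, h)
    region_cols = ["chrom", "start", "end", "peak_pos", "mean_fst",
                   "size_kb", "coverage", "category"]
    _io.write_table(pd.DataFrame(
        [[r.chrom, r.start, r.end, r.peak_pos, r.mean_fst, r.size_kb,
          r.coverage_fraction, r.category or "NA"] for r in result.regions],
        columns=region_cols), out / "regions.tsv", seed, h)
    _io.write_table(result.summary, out / "summary.tsv", seed, h)
    return result
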