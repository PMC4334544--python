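"""Classification of divergent regions by Tajima's-D selection signatures.

Each region's Tajima's D in the two populations (computed over the region's
exact refined extent) is contrasted to genome-wide 5% / 95% quantile
thresholds of the 100 kb-window T_D distribution of the respective
population:

- both below the 5% quantile        -> background selection
- below it only in the lake (pop1)  -> adaptation in the lake
- below it only in the river (pop2) -> adaptation in the river
- both inside [5%, 95%]             -> reduced gene flow (neutral spectrum)
- anything else (an upper-tail T_D) -> unclassified

Thresholds are population-specific by default; a shared mode pools the two
populations' window distributions before taking quantiles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import DivergentRegion, GenotypeMatrix, REGION_CATEGORIES
from .popgen import _pi_site, tajimas_d

__all__ = [
    "CategoryThresholds",
    "compute_thresholds",
    "classify_region",
    "classify_regions",
    "region_tajimas_d",
    "summarize_categories",
    "category_percentages",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryThresholds:
    """Genome-wide T_D quantile thresholds per population."""

    q05_pop1: float
    q95_pop1: float
    q05_pop2: float
    q95_pop2: float

    def __post_init__(self) -> None:
        if self.q05_pop1 > self.q95_pop1 or self.q05_pop2 > self.q95_pop2:
            raise ValueError("q05 must not exceed q95")


def compute_thresholds(td_pop1: np.ndarray, td_pop2: np.ndarray,
                       mode: str = "per-pop") -> CategoryThresholds:
    """5% and 95% empirical quantiles of genome-wide 100 kb-window T_D.

    ``mode='shared'`` pools both populations' windows and applies the same
    thresholds to both. Requires >= 100 non-missing windows per population.
    """
    t1 = np.asarray(td_pop1, dtype=float)
    t2 = np.asarray(td_pop2, dtype=float)
    t1, t2 = t1[~np.isnan(t1)], t2[~np.isnan(t2)]
    if t1.size < 100 or t2.size < 100:
        raise ValueError("need at least 100 non-missing windows per population")
    if mode == "per-pop":
        lo1, hi1 = np.quantile(t1, [0.05, 0.95])
        lo2, hi2 = np.quantile(t2, [0.05, 0.95])
    elif mode == "shared":
        pooled = np.concatenate([t1, t2])
        lo1, hi1 = np.quantile(pooled, [0.05, 0.95])
        lo2, hi2 = lo1, hi1
    else:
        raise ValueError("mode must be 'per-pop' or 'shared'")
    return CategoryThresholds(float(lo1), float(hi1), float(lo2), float(hi2))


def classify_region(td_lake: float, td_river: float,
                    thresholds: CategoryThresholds) -> str:
    """Assign one of the four evolutionary categories (or 'unclassified')."""
    if np.isnan(td_lake) or np.isnan(td_river):
        log.warning("missing T_D (lake=%s river=%s): unclassified", td_lake, td_river)
        return "unclassified"
    low_lake = td_lake < thresholds.q05_pop1
    low_river = td_river < thresholds.q05_pop2
    mid_lake = thresholds.q05_pop1 <= td_lake <= thresholds.q95_pop1
    mid_river = thresholds.q05_pop2 <= td_river <= thresholds.q95_pop2
    if low_lake and low_river:
        return "background_selection"
    if low_lake:
        return "adaptation_lake"
    if low_river:
        return "adaptation_river"
    if mid_lake and mid_river:
        return "reduced_gene_flow"
    return "unclassified"


def region_tajimas_d(pop: GenotypeMatrix, chrom: str, start: int, end: int,
                     min_s: int = 3) -> float:
    """Tajima's D over an exact region extent for one population."""
    sel = (pop.chrom == chrom) & (pop.pos - 1 >= start) & (pop.pos - 1 < end)
    c = pop.alt_counts()[sel]
    n = pop.called_alleles()[sel]
    seg = (c > 0) & (c < n)
    s = int(seg.sum())
    k_hat = float(np.nansum(_pi_site(c, n)))
    return tajimas_d(s, k_hat, 2 * pop.n_individuals, min_s=min_s)


def classify_regions(regions: list[DivergentRegion], pop1: GenotypeMatrix,
                     pop2: GenotypeMatrix, thresholds: CategoryThresholds
                     ) -> list[DivergentRegion]:
    """Attach a category (and return the regions) using exact-extent T_D."""
    for reg in regions:
        td1 = region_tajimas_d(pop1, reg.chrom, reg.start, reg.end)
        td2 = region_tajimas_d(pop2, reg.chrom, reg.start, reg.end)
        reg.category = classify_region(td1, td2, thresholds)
    return regions


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def summarize_categories(regions_by_pair: dict[str, list[DivergentRegion]]
                         ) -> pd.DataFrame:
    """Per-pair summary: region counts per category, sizes and mean F_ST.

    Returns one row per pair with columns n_regions, mean_fst,
    mean_size_kb, max_size_kb, sum_size_kb and one count column per
    category. Empty input gives an empty frame.
    """
    rows = []
    for pair, regions in regions_by_pair.items():
        if regions:
            sizes = np.array([r.size_kb for r in regions])
            row = {
                "pair": pair,
                "n_regions": len(regions),
                "mean_fst": float(np.mean([r.mean_fst for r in regions])),
                "mean_size_kb": float(sizes.mean()),
                "max_size_kb": int(sizes.max()),
                "sum_size_kb": int(sizes.sum()),
            }
        else:
            row = {"pair": pair, "n_regions": 0, "mean_fst": float("nan"),
                   "mean_size_kb": float("nan"), "max_size_kb": 0, "sum_size_kb": 0}
        for cat in REGION_CATEGORIES:
            row[f"n_{cat}"] = sum(r.category == cat for r in regions)
        rows.append(row)
    return pd.DataFrame(rows)


def category_percentages(counts: pd.DataFrame,
                         totals: pd.Series | None = None) -> dict[str, object]:
    """Aggregate category shares from a per-pair category-count table.

    ``counts`` has pairs as columns and categories as the index (the layout
    of a published per-pair summary table); entries are region counts per
    category. ``totals`` gives each pair's total region count — it can
    exceed the category column sum when some regions fall outside every
    rule (unclassified); when omitted the column sums are used. Aggregate
    percentages are each category's sum over pairs divided by the total
    region count, rounded half-up to whole percent; per-pair percentages
    are also returned so ranges can be read off.
    """
    if totals is None:
        totals = counts.sum(axis=0)
    totals = totals.reindex(counts.columns)
    if (totals < counts.sum(axis=0)).any():
        raise ValueError("per-pair totals cannot be below the category sums")
    total = int(totals.sum())
    if total == 0:
        return {"total_regions": 0, "aggregate_pct": {}, "per_pair_pct": {}}
    agg = {str(cat): _round_half_up(100.0 * counts.loc[cat].sum() / total)
           for cat in counts.index}
    per_pair = {}
    for cat in counts.index:
        per_pair[str(cat)] = {
            str(pair): _round_half_up(100.0 * counts.loc[cat, pair]
                                      / totals[pair])
            for pair in counts.columns
        }
    return {"total_regions": total, "aggregate_pct": agg, "per_pair_pct": per_pair}
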