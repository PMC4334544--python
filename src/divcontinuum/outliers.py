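"""Outlier-window detection: empirical top-quantile cut intersected with a
site-permutation test under FDR control.

The permutation null shuffles the retained per-site F_ST values across the
genome, recomputes window means, and compares each observed window mean to
permuted means of windows holding the same number of variable sites (pooled
across permutation replicates; nearest site-count bin when the exact count
has too few null draws). Final outliers are the intersection of the two
approaches.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "empirical_top_quantile",
    "permutation_null",
    "bh_fdr",
    "final_outliers",
    "scan_windows",
]

#: minimum pooled null draws before falling back to the nearest site-count bin
_MIN_NULL_DRAWS = 200


def empirical_top_quantile(window_fst: np.ndarray, q: float = 0.01) -> np.ndarray:
    """Flag windows with F_ST strictly above the (1-q) empirical quantile.

    The quantile is computed over non-missing windows with linear (type-7)
    interpolation. Requires at least 100 non-missing windows.
    """
    x = np.asarray(window_fst, dtype=float)
    good = ~np.isnan(x)
    if good.sum() == 0:
        raise ValueError("all windows missing")
    if good.sum() < 100:
        raise ValueError("need at least 100 non-missing windows")
    cut = np.quantile(x[good], 1.0 - q)
    flags = np.zeros(x.shape, dtype=bool)
    flags[good] = x[good] > cut
    return flags


def permutation_null(site_fst: np.ndarray, window_site_counts: np.ndarray,
                     observed_means: np.ndarray, n_perm: int = 10_000,
                     seed: int | None = None,
                     min_null_draws: int = _MIN_NULL_DRAWS) -> np.ndarray:
    """Permutation p-values for observed window mean F_ST.

    ``site_fst`` are the retained per-site values genome-wide (in any
    order); ``window_site_counts`` gives each window's number of retained
    sites, and ``observed_means`` the corresponding observed means. For each
    permutation the site values are shuffled and re-averaged into blocks of
    the same window site counts; a window's null distribution pools, across
    all permutations, the permuted means of windows with the same site count,
    widening the count bin symmetrically until it holds at least
    ``min_null_draws`` pooled draws (rare site counts would otherwise floor
    the attainable p above any FDR-corrected threshold). p-values use the
    add-one estimator p = (1 + #null >= observed) / (1 + #draws); windows
    with zero sites get NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = np.asarray(site_fst, dtype=float)
    values = values[~np.isnan(values)]
    counts = np.asarray(window_site_counts, dtype=np.int64)
    obs = np.asarray(observed_means, dtype=float)
    if counts.shape != obs.shape:
        raise ValueError("window_site_counts and observed_means length mismatch")
    if counts.sum() != values.size:
        raise ValueError("window site counts must partition the site values")

    rng = np.random.default_rng(seed)
    nonzero = counts > 0
    cnz = counts[nonzero]
    edges = np.concatenate([[0], np.cumsum(cnz)])[:-1]

    # null means per permutation, grouped by site count
    uniq = np.unique(cnz)
    null_by_count: dict[int, list[np.ndarray]] = {int(k): [] for k in uniq}
    # canonicalise input order so the null (hence p) is a function of the
    # multiset of site values alone
    work = np.sort(values)
    for _ in range(n_perm):
        rng.shuffle(work)
        sums = np.add.reduceat(work, edges)
        means = sums / cnz
        for k in uniq:
            null_by_count[int(k)].append(means[cnz == k])
    pooled = {k: np.sort(np.concatenate(v)) for k, v in null_by_count.items()}

    avail = sorted(pooled)
    sizes = {k: pooled[k].size for k in pooled}
    cache: dict[int, np.ndarray] = {}

    def draws_for(k: int) -> np.ndarray:
        if k in cache:
            return cache[k]
        # widen the count bin symmetrically (by count distance, ties toward
        # the smaller count) until it holds enough pooled draws
        order = sorted(avail, key=lambda kk: (abs(kk - k), kk))
        chosen, total = [], 0
        for kk in order:
            chosen.append(kk)
            total += sizes[kk]
            if total >= min_null_draws:
                break
        null = np.sort(np.concatenate([pooled[kk] for kk in chosen]))
        cache[k] = null
        return null

    p = np.full(counts.shape, np.nan)
    for i in np.flatnonzero(nonzero):
        null = draws_for(int(counts[i]))
        n_ge = null.size - np.searchsorted(null, obs[i], side="left")
        p[i] = (1.0 + n_ge) / (1.0 + null.size)
    return p


def bh_fdr(p_values: np.ndarray, level: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: returns (q_values, flags at q <= level).

    Missing p-values propagate to missing q and are never flagged.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    good = ~np.isnan(p)
    if np.any((p[good] <= 0) | (p[good] > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    q = np.full(p.shape, np.nan)
    pg = p[good]
    m = pg.size
    if m:
        order = np.argsort(pg, kind="stable")
        ranked = pg[order] * m / np.arange(1, m + 1)
        qs = np.minimum.accumulate(ranked[::-1])[::-1]
        qq = np.empty(m)
        qq[order] = np.minimum(qs, 1.0)
        q[good] = qq
    flags = np.zeros(p.shape, dtype=bool)
    flags[good] = q[good] <= level
    return q, flags


def final_outliers(empirical_flags: np.ndarray, fdr_flags: np.ndarray) -> np.ndarray:
    """Windows significant under both the empirical cut and the FDR test."""
    a = np.asarray(empirical_flags, dtype=bool)
    b = np.asarray(fdr_flags, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("flag vectors must have equal length")
    return a & b


def scan_windows(windows: pd.DataFrame, site_fst: np.ndarray,
                 q: float = 0.01, fdr_level: float = 0.01,
                 n_perm: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Run the full outlier scan over a window table.

    ``windows`` needs columns chrom/start/end/fst/n_snps_fst in genome order
    matching the concatenation order of ``site_fst`` (the retained per-site
    values). Returns the table with empirical_flag, perm_p, q_value and
    final_flag columns appended.
    """
    out = windows.copy()
    emp = empirical_top_quantile(out["fst"].to_numpy(), q)
    # the null pool per window must resolve p below the BH step-up threshold
    # fdr_level*k/m around the rank k where true outliers sit (divergent
    # regions span multiple windows; k=10 is the scan's resolution target) —
    # wider pools would distort the count-conditional null, coarser ones
    # would floor p above any attainable threshold
    m = int(out["fst"].notna().sum())
    min_draws = max(_MIN_NULL_DRAWS, int(np.ceil(2 * m / (10 * fdr_level))))
    p = permutation_null(site_fst, out["n_snps_fst"].to_numpy(),
                         out["fst"].to_numpy(), n_perm=n_perm, seed=seed,
                         min_null_draws=min_draws)
    qv, fdr_flags = bh_fdr(p, fdr_level)
    out["empirical_flag"] = emp
    out["perm_p"] = p
    out["q_value"] = qv
    out["final_flag"] = final_outliers(emp, fdr_flags)
    return out
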