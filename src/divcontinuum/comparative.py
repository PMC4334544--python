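"""Cross-pair and ecological comparative statistics.

Covers the shared-outlier permutation test, between-pair F_ST correlations,
region-versus-genome Mann-Whitney contrasts with Bonferroni correction,
recombination-map filtering and mutation-rate normalisation, parasite
community metrics (Shannon diversity and quantitative Jaccard on
fourth-root-transformed counts), geodetic distances, and the partial Mantel
test for isolation-by-adaptation.
"""
from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shared_outlier_test",
    "fst_correlation",
    "region_vs_genome_contrast",
    "rho_filter_and_normalize",
    "shannon_diversity",
    "community_distance",
    "geodetic_distance",
    "partial_mantel",
]

EARTH_RADIUS_KM = 6371.0088
#: adjacent-SNP rho values above this are linkage-breakdown artifacts
RHO_ARTIFACT_CUTOFF = 100.0


def shared_outlier_test(outlier_sets: list[np.ndarray], n_windows: int,
                        n_perm: int = 10_000, seed: int | None = None
                        ) -> tuple[int, float, float]:
    """Permutation test for outlier windows shared between population pairs.

    Each element of ``outlier_sets`` is a boolean vector over a common
    window universe of size ``n_windows``. Observed statistic: windows
    flagged in at least two sets. Null: each set's flag count scattered
    uniformly over the universe. Returns (observed, null mean, one-tailed
    add-one p).
    """
    if len(outlier_sets) < 2:
        raise ValueError("need at least two outlier sets")
    sets = [np.asarray(s, dtype=bool) for s in outlier_sets]
    if any(s.shape != (n_windows,) for s in sets):
        raise ValueError("all sets must cover the same window universe")
    observed = int((np.sum(sets, axis=0) >= 2).sum())

    rng = np.random.default_rng(seed)
    ks = [int(s.sum()) for s in sets]
    null = np.empty(n_perm, dtype=np.int64)
    hits = np.zeros(n_windows, dtype=np.int8)
    for i in range(n_perm):
        hits[:] = 0
        for k in ks:
            hits[rng.choice(n_windows, size=k, replace=False)] += 1
        null[i] = int((hits >= 2).sum())
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return observed, float(null.mean()), float(p)


def fst_correlation(fst_a: np.ndarray, fst_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of matched window F_ST between two pairs.

    Missing windows (NaN in either vector) are dropped; needs >= 3 complete
    pairs.
    """
    a = np.asarray(fst_a, dtype=float)
    b = np.asarray(fst_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("window vectors must be matched")
    good = ~(np.isnan(a) | np.isnan(b))
    if good.sum() < 3:
        raise ValueError("need at least 3 complete window pairs")
    r, p = stats.pearsonr(a[good], b[good])
    return float(r), float(p)


def region_vs_genome_contrast(values_in_regions, values_genomewide,
                              n_tests: int = 10, alpha: float = 0.05
                              ) -> tuple[float, float, bool]:
    """Two-sided Mann-Whitney U contrast of region values vs the genome.

    Uses the exact null for small tie-free samples and the normal
    approximation with tie correction otherwise; significance is judged at
    the Bonferroni-corrected level alpha / n_tests (0.005 by default, for a
    family of ten population-level tests).
    """
    x = np.asarray(values_in_regions, dtype=float)
    y = np.asarray(values_genomewide, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    threshold = alpha / n_tests
    return float(res.statistic), float(res.pvalue), bool(res.pvalue < threshold)


def rho_filter_and_normalize(rho_intervals: pd.DataFrame, theta: float,
                             windows: pd.DataFrame | None = None) -> pd.DataFrame:
    """Filter linkage-breakdown artifacts and normalise rho by theta.

    ``rho_intervals`` has chrom/start/end/rho columns (per adjacent-SNP
    interval). Intervals with rho > 100 are dropped; survivors are averaged
    per window (``windows`` needs chrom/start/end; when None the filtered
    intervals are returned) and divided by the population mutation rate
    ``theta``. Windows with no surviving interval get NaN.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    kept = rho_intervals[rho_intervals["rho"] <= RHO_ARTIFACT_CUTOFF].copy()
    if windows is None:
        kept["rho_over_theta"] = kept["rho"] / theta
        return kept
    out = windows.copy()
    means = np.full(len(out), np.nan)
    for i, (chrom, start, end) in enumerate(
            zip(out["chrom"], out["start"], out["end"])):
        sub = kept[(kept["chrom"] == chrom) & (kept["start"] < end)
                   & (kept["end"] > start)]
        if len(sub):
            means[i] = sub["rho"].mean() / theta
    out["rho_over_theta"] = means
    return out


def shannon_diversity(counts, transform_root: float = 4.0) -> float:
    """Shannon diversity H of one host's parasite counts.

    Counts are root-transformed (fourth root by default) before computing
    H = -sum p_i ln p_i over taxa with positive transformed abundance; an
    all-zero host returns 0 by convention.
    """
    x = np.asarray(counts, dtype=float)
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    t = x ** (1.0 / transform_root)
    t = t[t > 0]
    if t.size == 0:
        return 0.0
    p = t / t.sum()
    return float(-(p * np.log(p)).sum())


def community_distance(counts_by_population: pd.DataFrame,
                       transform_root: float = 4.0,
                       binary: bool = False) -> pd.DataFrame:
    """Pairwise community dissimilarity between populations.

    ``counts_by_population`` is taxa x populations (counts already summed
    over individuals). Counts are fourth-root transformed; the distance is
    the quantitative Jaccard (Ruzicka) 1 - sum min / sum max, or the binary
    Jaccard on presence/absence when ``binary``.
    """
    t = counts_by_population.to_numpy(dtype=float) ** (1.0 / transform_root)
    if binary:
        t = (t > 0).astype(float)
    pops = list(counts_by_population.columns)
    n = len(pops)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mx = np.maximum(t[:, i], t[:, j]).sum()
        mn = np.minimum(t[:, i], t[:, j]).sum()
        d[i, j] = d[j, i] = 1.0 - (mn / mx if mx > 0 else 1.0)
    return pd.DataFrame(d, index=pops, columns=pops)


def geodetic_distance(gps_a: tuple[float, float], gps_b: tuple[float, float]) -> float:
    """Great-circle (haversine) distance in km between (lat, lon) points."""
    for lat, lon in (gps_a, gps_b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError("coordinates out of range")
    la1, lo1, la2, lo2 = map(math.radians, (*gps_a, *gps_b))
    h = (math.sin((la2 - la1) / 2) ** 2
         + math.cos(la1) * math.cos(la2) * math.sin((lo2 - lo1) / 2) ** 2)
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _offdiag(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _partial_r(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    rab = np.corrcoef(a, b)[0, 1]
    rac = np.corrcoef(a, c)[0, 1]
    rbc = np.corrcoef(b, c)[0, 1]
    return (rab - rac * rbc) / math.sqrt((1 - rac**2) * (1 - rbc**2))


def _partial_r_rows(rows: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Partial correlation of each row of ``rows`` with b, controlling c."""
    bz = (b - b.mean()) / b.std()
    cz = (c - c.mean()) / c.std()
    az = rows - rows.mean(axis=1, keepdims=True)
    az /= az.std(axis=1, keepdims=True)
    m = rows.shape[1]
    rab = az @ bz / m
    rac = az @ cz / m
    rbc = float(bz @ cz / m)
    return (rab - rac * rbc) / np.sqrt((1 - rac**2) * (1 - rbc**2))


def partial_mantel(genetic: np.ndarray, ecological: np.ndarray,
                   geographic: np.ndarray, n_perm: int = 9_999,
                   seed: int | None = None, tail: str = "greater",
                   exact_max_n: int = 8) -> tuple[float, float]:
    """Partial Mantel test of genetic vs ecological distance given geography.

    The statistic is the partial Pearson correlation of the upper-triangle
    entries; significance comes from permuting the row/column labels of the
    genetic matrix. With ``n <= exact_max_n`` populations all n! label
    permutations are enumerated exactly (p = fraction of permutations at
    least as extreme, identity included); otherwise ``n_perm`` random
    permutations with the add-one estimator. ``tail`` is 'greater'
    (default, directional hypothesis) or 'two-sided'.
    """
    g = np.asarray(genetic, dtype=float)
    e = np.asarray(ecological, dtype=float)
    d = np.asarray(geographic, dtype=float)
    n = g.shape[0]
    if n < 4:
        raise ValueError("need at least 4 populations")
    for m in (g, e, d):
        if m.shape != (n, n) or not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
            raise ValueError("matrices must be square, symmetric, zero-diagonal "
                             "and equally sized")
    ev, dv = _offdiag(e), _offdiag(d)
    r_obs = _partial_r(_offdiag(g), ev, dv)

    iu = np.triu_indices(n, k=1)
    if n <= exact_max_n:
        perms = np.array(list(itertools.permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rows = g[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = _partial_r_rows(rows, ev, dv)
    hits = (np.abs(r_perm) >= abs(r_obs) - 1e-12 if tail == "two-sided"
            else r_perm >= r_obs - 1e-12).sum()
    if n <= exact_max_n:
        return float(r_obs), float(hits / len(perms))
    return float(r_obs), float((1.0 + hits) / (1.0 + n_perm))
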