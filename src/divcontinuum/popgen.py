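"""Per-site and windowed population-genetic estimators.

Implements the two-population Weir & Cockerham (1984) F_ST variance-components
estimator on allele counts, nucleotide diversity (pi), Watterson's theta,
Tajima's D, absolute divergence D_xy, minor-allele-frequency filtering for the
F_ST scan, non-overlapping window construction, and leave-one-out jackknife
uncertainty for window F_ST.

Diversity statistics are normalised by the number of *accessible* base pairs
in each window, not the nominal window length, so windows with partial
sequence accessibility are comparable.
"""
from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = [
    "site_fst_wc",
    "site_fst_wc_vector",
    "wc_components_vector",
    "genome_fst_wc",
    "maf_filter_pair",
    "tajimas_d",
    "tajima_constants",
    "window_stats",
    "jackknife_window_fst",
]


# ---------------------------------------------------------------------------
# per-site estimators
# ---------------------------------------------------------------------------

def wc_components_vector(c1, n1, c2, n2):
    """Weir & Cockerham (1984) per-site variance components for two populations.

    Parameters are alternate-allele counts ``c`` and called allele numbers
    ``n`` per site (haplotype/allele samples; the haploid ANOVA form:
    among- vs within-population mean squares with the n_c correction for
    unequal sample sizes). Returns (numerator, denominator) arrays with
    theta-hat = num / den per site; both are NaN where the pooled site is
    monomorphic or either sample has fewer than 2 alleles.
    """
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise ValueError("sample sizes must be positive")

    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = c1 / n1, c2 / n2
        nt = n1 + n2
        pbar = (c1 + c2) / nt
        # among-population mean square (r = 2 populations)
        msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
        # within-population mean square
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - 2)
        nc = nt - (n1**2 + n2**2) / nt
        num = msp - msg
        den = msp + (nc - 1) * msg
    bad = ~valid | (pbar <= 0) | (pbar >= 1)
    num = np.where(bad, np.nan, num)
    den = np.where(bad, np.nan, den)
    return num, den


def site_fst_wc_vector(c1, n1, c2, n2):
    """Vectorised per-site Weir-Cockerham theta-hat (NaN where undefined)."""
    num, den = wc_components_vector(c1, n1, c2, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def genome_fst_wc(pop1: GenotypeMatrix, pop2: GenotypeMatrix) -> float:
    """Genome-wide Weir-Cockerham F_ST as the ratio of summed variance
    components over all polymorphic sites (the conventional multi-locus
    estimate; contrast with the unweighted window means used in the scan).
    """
    num, den = wc_components_vector(pop1.alt_counts(), pop1.called_alleles(),
                                    pop2.alt_counts(), pop2.called_alleles())
    return float(np.nansum(num) / np.nansum(den))


def site_fst_wc(c1: int, n1: int, c2: int, n2: int) -> float:
    """Weir-Cockerham F_ST at a single biallelic site (may be negative)."""
    return float(site_fst_wc_vector([c1], [n1], [c2], [n2])[0])


def maf_filter_pair(c1, n1, c2, n2, threshold: float = 0.25) -> np.ndarray:
    """Boolean mask of sites whose *pooled* minor-allele frequency >= threshold.

    Applied to the F_ST scan input only; diversity statistics are computed on
    the unfiltered sites.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    n = np.asarray(n1, dtype=float) + np.asarray(n2, dtype=float)
    f = (c1 + c2) / n
    maf = np.minimum(f, 1.0 - f)
    return maf >= threshold


def tajima_constants(n: int) -> dict[str, float]:
    """Standard a1, a2, b1, b2, c1, c2, e1, e2 for sample size n (alleles)."""
    if n < 2:
        raise ValueError("need n >= 2 alleles")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(s: int, k_hat: float, n: int, min_s: int = 3) -> float:
    """Tajima's D from the segregating-site count and mean pairwise differences.

    Returns NaN when S < ``min_s`` (the normalising variance is unstable for
    very few segregating sites).
    """
    if s < min_s:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    return float((k_hat - s / c["a1"]) / np.sqrt(var))


def _pi_site(c: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-site heterozygosity 2c(n-c)/(n(n-1)), the per-site term of pi."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * c * (n - c) / (n * (n - 1.0))
    return np.where(n >= 2, out, np.nan)


def _dxy_site(c1, n1, c2, n2) -> np.ndarray:
    p1 = np.asarray(c1, dtype=float) / np.asarray(n1, dtype=float)
    p2 = np.asarray(c2, dtype=float) / np.asarray(n2, dtype=float)
    return p1 * (1 - p2) + p2 * (1 - p1)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _accessible_per_window(mask: pd.DataFrame, chrom: str, n_windows: int,
                           window_size: int) -> np.ndarray:
    """Accessible bp in each window of one chromosome from a BED-style mask."""
    acc = np.zeros(n_windows, dtype=np.int64)
    sub = mask[mask["chrom"] == chrom]
    for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
        w0 = int(start) // window_size
        w1 = (int(end) - 1) // window_size
        for w in range(max(w0, 0), min(w1, n_windows - 1) + 1):
            lo = max(int(start), w * window_size)
            hi = min(int(end), (w + 1) * window_size)
            if hi > lo:
                acc[w] += hi - lo
    return acc


def window_stats(pop1: GenotypeMatrix, pop2: GenotypeMatrix, mask: pd.DataFrame,
                 chrom_lengths: dict[str, int], window_size: int = 10_000,
                 maf_threshold: float | None = 0.25,
                 min_s_tajima: int = 3, fst_mode: str = "mean") -> pd.DataFrame:
    """Windowed statistics for a population pair.

    Both matrices must describe the same sites in the same order. Windows
    tile each chromosome from position 0 in non-overlapping blocks of
    ``window_size``. The window F_ST is the unweighted mean of per-site
    Weir-Cockerham estimates over the sites passing the pooled MAF filter
    (``maf_threshold=None`` disables the filter); pi, Watterson's theta and
    D_xy are per accessible bp; Tajima's D uses the window's segregating-site
    count and mean pairwise differences.

    Statistics are NaN (missing, not zero) where a window has no accessible
    sequence; Tajima's D is missing where S < ``min_s_tajima``.
    ``fst_mode='ratio'`` switches the window F_ST from the unweighted mean
    of per-site estimates (the default) to the ratio of summed
    variance components.
    """
    if pop1.n_sites != pop2.n_sites or np.any(pop1.pos != pop2.pos):
        raise ValueError("the two populations must share one site list")
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if fst_mode not in ("mean", "ratio"):
        raise ValueError("fst_mode must be 'mean' or 'ratio'")

    c1, n1 = pop1.alt_counts(), pop1.called_alleles()
    c2, n2 = pop2.alt_counts(), pop2.called_alleles()
    wc_num, wc_den = wc_components_vector(c1, n1, c2, n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = wc_num / wc_den
    if maf_threshold is not None:
        retained = maf_filter_pair(c1, n1, c2, n2, maf_threshold)
        fst = np.where(retained, fst, np.nan)
        wc_num = np.where(retained, wc_num, np.nan)
        wc_den = np.where(retained, wc_den, np.nan)
    pi1 = _pi_site(c1, n1)
    pi2 = _pi_site(c2, n2)
    dxy = _dxy_site(c1, n1, c2, n2)
    seg1 = (c1 > 0) & (c1 < n1)
    seg2 = (c2 > 0) & (c2 < n2)

    nhap1 = 2 * pop1.n_individuals
    nhap2 = 2 * pop2.n_individuals

    rows = []
    for chrom, length in chrom_lengths.items():
        nwin = -(-length // window_size)
        on_chrom = pop1.chrom == chrom
        widx = (pop1.pos[on_chrom] - 1) // window_size
        acc = _accessible_per_window(mask, chrom, nwin, window_size)

        def wsum(values):
            v = np.asarray(values, dtype=float)[on_chrom]
            good = ~np.isnan(v)
            return (np.bincount(widx[good], weights=v[good], minlength=nwin),
                    np.bincount(widx[good], minlength=nwin))

        fst_sum, fst_n = wsum(fst)
        if fst_mode == "ratio":
            num_sum, _ = wsum(wc_num)
            den_sum, _ = wsum(wc_den)
        pi1_sum, _ = wsum(pi1)
        pi2_sum, _ = wsum(pi2)
        dxy_sum, _ = wsum(dxy)
        s1 = np.bincount(widx[seg1[on_chrom]], minlength=nwin)
        s2 = np.bincount(widx[seg2[on_chrom]], minlength=nwin)
        n_snps = np.bincount(widx, minlength=nwin)

        with np.errstate(divide="ignore", invalid="ignore"):
            if fst_mode == "ratio":
                mean_fst = np.where(fst_n > 0, num_sum / den_sum, np.nan)
            else:
                mean_fst = np.where(fst_n > 0, fst_sum / np.maximum(fst_n, 1),
                                    np.nan)
            accf = np.where(acc > 0, acc, np.nan).astype(float)
            pi1_w = pi1_sum / accf
            pi2_w = pi2_sum / accf
            dxy_w = dxy_sum / accf
            a1_1 = tajima_constants(nhap1)["a1"]
            a1_2 = tajima_constants(nhap2)["a1"]
            th1_w = s1 / a1_1 / accf
            th2_w = s2 / a1_2 / accf

        td1 = np.array([tajimas_d(int(s), k, nhap1, min_s_tajima)
                        for s, k in zip(s1, pi1_sum)])
        td2 = np.array([tajimas_d(int(s), k, nhap2, min_s_tajima)
                        for s, k in zip(s2, pi2_sum)])
        inaccessible = acc == 0
        for arr in (mean_fst, pi1_w, pi2_w, dxy_w, th1_w, th2_w, td1, td2):
            arr[inaccessible] = np.nan

        starts = np.arange(nwin, dtype=np.int64) * window_size
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": starts,
            "end": np.minimum(starts + window_size, length),
            "n_snps": n_snps,
            "n_snps_fst": fst_n,
            "n_accessible_bp": acc,
            "fst": mean_fst,
            "pi_pop1": pi1_w, "pi_pop2": pi2_w,
            "theta_pop1": th1_w, "theta_pop2": th2_w,
            "td_pop1": td1, "td_pop2": td2,
            "dxy": dxy_w,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def jackknife_window_fst(pop1: GenotypeMatrix, pop2: GenotypeMatrix,
                         chrom: str, start: int, end: int,
                         maf_threshold: float | None = 0.25) -> tuple[float, float]:
    """Leave-one-individual-out-per-population jackknife of a window's F_ST.

    Every (i, j) pair of left-out individuals (one per population) is
    enumerated; the window mean F_ST is recomputed from the reduced allele
    counts at the sites retained by the pooled-MAF filter on the full data.
    Returns the mean of the replicate estimates and the width of their
    central 95% interval (NaN, NaN when the window is monomorphic).
    """
    if pop1.n_individuals < 3 or pop2.n_individuals < 3:
        raise ValueError("need at least 3 individuals per population")
    in_win = (pop1.chrom == chrom) & (pop1.pos - 1 >= start) & (pop1.pos - 1 < end)
    g1 = pop1.genotypes[in_win]
    g2 = pop2.genotypes[in_win]
    c1f = np.where(g1 >= 0, g1, 0).sum(axis=1)
    c2f = np.where(g2 >= 0, g2, 0).sum(axis=1)
    n1f = 2 * (g1 >= 0).sum(axis=1)
    n2f = 2 * (g2 >= 0).sum(axis=1)
    keep = np.ones(len(c1f), dtype=bool)
    if maf_threshold is not None:
        keep = maf_filter_pair(c1f, n1f, c2f, n2f, maf_threshold)
    g1, g2 = g1[keep], g2[keep]
    if g1.shape[0] == 0:
        return float("nan"), float("nan")

    estimates = []
    for i, j in product(range(pop1.n_individuals), range(pop2.n_individuals)):
        h1 = np.delete(g1, i, axis=1)
        h2 = np.delete(g2, j, axis=1)
        c1 = np.where(h1 >= 0, h1, 0).sum(axis=1)
        c2 = np.where(h2 >= 0, h2, 0).sum(axis=1)
        n1 = 2 * (h1 >= 0).sum(axis=1)
        n2 = 2 * (h2 >= 0).sum(axis=1)
        vals = site_fst_wc_vector(c1, n1, c2, n2)
        if np.all(np.isnan(vals)):
            continue
        estimates.append(float(np.nanmean(vals)))
    if not estimates:
        return float("nan"), float("nan")
    est = np.array(estimates)
    lo, hi = np.quantile(est, [0.025, 0.975])
    return float(est.mean()), float(hi - lo)
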