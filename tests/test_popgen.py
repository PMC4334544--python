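"""Estimator unit tests against brute-force oracles.

The oracles deliberately take a different computational route from the
library: the F_ST oracle builds the explicit 0/1 allele vectors and runs a
one-way ANOVA from first principles; pi and D_xy oracles enumerate allele
pairs; the Tajima oracle recomputes every constant from scratch.
"""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import divcontinuum as dc
from divcontinuum import popgen


def random_site_instance(rng, max_sites=50):
    """Random biallelic allele-count instance for oracle-equivalence tests."""
    n_sites = rng.integers(1, max_sites + 1)
    n1 = int(rng.integers(2, 13)) * 2
    n2 = int(rng.integers(2, 13)) * 2
    c1 = rng.integers(0, n1 + 1, size=n_sites)
    c2 = rng.integers(0, n2 + 1, size=n_sites)
    # ensure at least one pooled-polymorphic site
    c1[0] = max(1, min(n1 - 1, int(c1[0])))
    return c1, n1, c2, n2


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def fst_anova_oracle(c1, n1, c2, n2):
    """WC theta-hat from explicit allele vectors via one-way ANOVA sums of
    squares (haploid individuals = alleles)."""
    pooled = c1 + c2
    if pooled == 0 or pooled == n1 + n2:
        return float("nan")
    groups = [np.array([1.0] * c + [0.0] * (n - c))
              for c, n in ((c1, n1), (c2, n2))]
    r = len(groups)
    nt = sum(len(g) for g in groups)
    grand = sum(g.sum() for g in groups) / nt
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msa = ss_between / (r - 1)
    msw = ss_within / (nt - r)
    n0 = (nt - sum(len(g) ** 2 for g in groups) / nt) / (r - 1)
    return (msa - msw) / (msa + (n0 - 1) * msw)


def pi_pairs_oracle(c, n):
    """Mean pairwise difference at one site by enumerating allele pairs."""
    alleles = [1] * c + [0] * (n - c)
    diffs = sum(a != b for a, b in itertools.combinations(alleles, 2))
    return diffs / (n * (n - 1) / 2)


def dxy_pairs_oracle(c1, n1, c2, n2):
    """Mean between-population difference by enumerating cross pairs."""
    a1 = [1] * c1 + [0] * (n1 - c1)
    a2 = [1] * c2 + [0] * (n2 - c2)
    return sum(x != y for x in a1 for y in a2) / (n1 * n2)


def tajima_oracle(s, k_hat, n):
    """Tajima's D recomputed from scratch (published constants)."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k_hat - s / a1) / np.sqrt(e1 * s + e2 * s * (s - 1))


def watterson_oracle(s, n, acc_bp):
    return s / sum(1.0 / i for i in range(1, n)) / acc_bp


# ---------------------------------------------------------------------------
# site F_ST
# ---------------------------------------------------------------------------

def test_site_fst_fixed_difference_is_one():
    assert dc.site_fst_wc(12, 12, 0, 12) == pytest.approx(1.0)


def test_site_fst_identical_frequencies_nonpositive():
    assert dc.site_fst_wc(6, 12, 6, 12) <= 0


def test_site_fst_matches_textbook_oracle():
    # the spec-level worked case plus a batch of random sites
    assert dc.site_fst_wc(10, 12, 2, 12) == pytest.approx(
        fst_anova_oracle(10, 12, 2, 12), abs=1e-12)
    rng = np.random.default_rng(0)
    for _ in range(200):
        n1, n2 = 2 * rng.integers(1, 13, size=2) + 2
        c1 = int(rng.integers(0, n1 + 1))
        c2 = int(rng.integers(0, n2 + 1))
        got = dc.site_fst_wc(c1, int(n1), c2, int(n2))
        want = fst_anova_oracle(c1, int(n1), c2, int(n2))
        if np.isnan(want):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-12)


def test_site_fst_zero_sample_size_errors():
    with pytest.raises(ValueError):
        dc.site_fst_wc(0, 0, 3, 12)


@given(c1=st.integers(0, 12), c2=st.integers(0, 12))
@settings(deadline=None, max_examples=60)
def test_site_fst_symmetric_and_label_invariant(c1, c2):
    """Swapping populations or relabelling ref/alt leaves theta-hat unchanged."""
    a = dc.site_fst_wc(c1, 12, c2, 12)
    b = dc.site_fst_wc(c2, 12, c1, 12)
    c = dc.site_fst_wc(12 - c1, 12, 12 - c2, 12)
    if np.isnan(a):
        assert np.isnan(b) and np.isnan(c)
    else:
        assert a == pytest.approx(b, abs=1e-12)
        assert a == pytest.approx(c, abs=1e-12)


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def test_maf_filter_thresholds():
    # pooled MAF 0.30 retained, 0.10 removed, boundary value retained
    keep = popgen.maf_filter_pair([7, 2, 6], [12, 12, 12], [1, 1, 0], [12, 12, 12],
                                  threshold=0.25)
    # pooled frequencies: 8/24=0.333, 3/24=0.125, 6/24=0.25
    assert list(keep) == [True, False, True]
    with pytest.raises(ValueError):
        popgen.maf_filter_pair([1], [12], [1], [12], threshold=0.7)


def test_maf_filter_matches_enumeration():
    rng = np.random.default_rng(1)
    c1 = rng.integers(0, 13, size=1000)
    c2 = rng.integers(0, 13, size=1000)
    keep = popgen.maf_filter_pair(c1, np.full(1000, 12), c2, np.full(1000, 12))
    brute = np.array([min((a + b) / 24, 1 - (a + b) / 24) >= 0.25
                      for a, b in zip(c1, c2)])
    assert np.array_equal(keep, brute)


# ---------------------------------------------------------------------------
# the five-estimator oracle equivalence battery
# ---------------------------------------------------------------------------

def test_all_estimators_match_brute_force_on_random_instances():
    """Site F_ST, pi, Watterson's theta, Tajima's D and D_xy agree with
    independent brute-force implementations to 1e-10 on random instances."""
    rng = np.random.default_rng(42)
    for _ in range(300):
        c1v, n1, c2v, n2 = random_site_instance(rng, max_sites=50)
        n_sites = len(c1v)
        acc_bp = 10_000

        fst = popgen.site_fst_wc_vector(c1v, np.full(n_sites, n1),
                                        c2v, np.full(n_sites, n2))
        pi1 = popgen._pi_site(c1v, np.full(n_sites, n1))
        dxy = popgen._dxy_site(c1v, np.full(n_sites, n1),
                               c2v, np.full(n_sites, n2))
        for i in range(n_sites):
            want = fst_anova_oracle(int(c1v[i]), n1, int(c2v[i]), n2)
            if np.isnan(want):
                assert np.isnan(fst[i])
            else:
                assert abs(fst[i] - want) < 1e-10
            assert abs(pi1[i] - pi_pairs_oracle(int(c1v[i]), n1)) < 1e-10
            assert abs(dxy[i] - dxy_pairs_oracle(int(c1v[i]), n1,
                                                 int(c2v[i]), n2)) < 1e-10

        s1 = int(np.sum((c1v > 0) & (c1v < n1)))
        k1 = float(np.sum([pi_pairs_oracle(int(c), n1) for c in c1v]))
        theta_impl = s1 / popgen.tajima_constants(n1)["a1"] / acc_bp
        assert abs(theta_impl - watterson_oracle(s1, n1, acc_bp)) < 1e-10
        if s1 >= 3:
            assert abs(popgen.tajimas_d(s1, k1, n1)
                       - tajima_oracle(s1, k1, n1)) < 1e-10


def test_tajimas_d_constructed_case_and_low_s():
    # n=10 haplotypes, S=16, mean pairwise differences 3.888...
    d = popgen.tajimas_d(16, 3.8888888888888888, 10)
    assert d == pytest.approx(tajima_oracle(16, 3.8888888888888888, 10), abs=1e-10)
    assert np.isnan(popgen.tajimas_d(2, 0.5, 10))  # S < 3 -> missing


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def _matrix_from_counts(chrom, pos, counts, n_hap):
    """Deterministic diploid matrix realising given alt counts per site."""
    geno = np.zeros((len(pos), n_hap // 2), dtype=np.int8)
    for i, c in enumerate(counts):
        hap = np.array([1] * c + [0] * (n_hap - c), dtype=np.int8)
        geno[i] = hap[0::2] + hap[1::2]
    return dc.GenotypeMatrix(np.array([chrom] * len(pos), dtype=object),
                             np.array(pos), geno)


def _full_mask(chrom_lengths):
    import pandas as pd
    return pd.DataFrame([(c, 0, l) for c, l in chrom_lengths.items()],
                        columns=["chrom", "start", "end"])


def test_window_with_no_snps_has_zero_pi_missing_td():
    lengths = {"chr1": 20_000}
    p1 = _matrix_from_counts("chr1", [15_001], [6], 12)  # window 2 only
    p2 = _matrix_from_counts("chr1", [15_001], [6], 12)
    win = popgen.window_stats(p1, p2, _full_mask(lengths), lengths,
                              window_size=10_000, maf_threshold=None)
    empty = win.iloc[0]
    assert empty["n_snps"] == 0
    assert empty["pi_pop1"] == 0.0 and np.isnan(empty["td_pop1"])


def test_dxy_single_fixed_difference():
    lengths = {"chr1": 10_000}
    p1 = _matrix_from_counts("chr1", [5_001], [12], 12)
    p2 = _matrix_from_counts("chr1", [5_001], [0], 12)
    win = popgen.window_stats(p1, p2, _full_mask(lengths), lengths,
                              window_size=10_000, maf_threshold=None)
    assert win.iloc[0]["dxy"] == pytest.approx(1.0 / 10_000)
    assert win.iloc[0]["fst"] == pytest.approx(1.0)


def test_window_statistics_normalised_by_accessible_not_nominal():
    import pandas as pd
    lengths = {"chr1": 10_000}
    mask = pd.DataFrame([("chr1", 0, 5_000)], columns=["chrom", "start", "end"])
    p1 = _matrix_from_counts("chr1", [1_001], [12], 12)
    p2 = _matrix_from_counts("chr1", [1_001], [0], 12)
    win = popgen.window_stats(p1, p2, mask, lengths, window_size=10_000,
                              maf_threshold=None)
    assert win.iloc[0]["n_accessible_bp"] == 5_000
    assert win.iloc[0]["dxy"] == pytest.approx(1.0 / 5_000)


def test_window_mean_invariant_to_site_order():
    rng = np.random.default_rng(3)
    lengths = {"chr1": 10_000}
    pos = np.sort(rng.choice(np.arange(1, 10_001), size=30, replace=False))
    counts1 = rng.integers(1, 12, size=30)
    counts2 = rng.integers(1, 12, size=30)
    a = popgen.window_stats(_matrix_from_counts("chr1", pos, counts1, 12),
                            _matrix_from_counts("chr1", pos, counts2, 12),
                            _full_mask(lengths), lengths, maf_threshold=None)
    # same multiset of (pos, counts) presented in a different generation order
    order = rng.permutation(30)
    pos2, c1o, c2o = pos[order], counts1[order], counts2[order]
    resort = np.argsort(pos2)
    b = popgen.window_stats(
        _matrix_from_counts("chr1", pos2[resort], c1o[resort], 12),
        _matrix_from_counts("chr1", pos2[resort], c2o[resort], 12),
        _full_mask(lengths), lengths, maf_threshold=None)
    assert a["fst"].iloc[0] == pytest.approx(b["fst"].iloc[0], abs=1e-12)


def test_ratio_mode_differs_and_matches_component_sums():
    rng = np.random.default_rng(4)
    lengths = {"chr1": 10_000}
    pos = np.sort(rng.choice(np.arange(1, 10_001), size=40, replace=False))
    c1 = rng.integers(0, 13, size=40)
    c2 = rng.integers(0, 13, size=40)
    c1[0] = 6
    m1 = _matrix_from_counts("chr1", pos, c1, 12)
    m2 = _matrix_from_counts("chr1", pos, c2, 12)
    win = popgen.window_stats(m1, m2, _full_mask(lengths), lengths,
                              maf_threshold=None, fst_mode="ratio")
    num, den = popgen.wc_components_vector(c1, np.full(40, 12), c2, np.full(40, 12))
    assert win["fst"].iloc[0] == pytest.approx(np.nansum(num) / np.nansum(den))


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------

def test_jackknife_enumeration_oracle():
    """Mean over all 6x6 leave-one-out pairs equals explicit enumeration."""
    rng = np.random.default_rng(9)
    pos = np.sort(rng.choice(np.arange(1, 10_001), size=20, replace=False))
    g1 = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
    g2 = rng.integers(0, 3, size=(20, 6)).astype(np.int8)
    p1 = dc.GenotypeMatrix(np.array(["chr1"] * 20, dtype=object), pos, g1)
    p2 = dc.GenotypeMatrix(np.array(["chr1"] * 20, dtype=object), pos, g2)
    mean, width = popgen.jackknife_window_fst(p1, p2, "chr1", 0, 10_000,
                                              maf_threshold=None)

    vals = []
    for i in range(6):
        for j in range(6):
            h1 = np.delete(g1, i, axis=1)
            h2 = np.delete(g2, j, axis=1)
            site_vals = [fst_anova_oracle(int(h1[s].sum()), 10,
                                          int(h2[s].sum()), 10)
                         for s in range(20)]
            vals.append(np.nanmean(site_vals))
    assert mean == pytest.approx(np.mean(vals), abs=1e-10)
    assert width >= 0


def test_jackknife_identical_individuals_zero_width():
    pos = np.array([101, 202, 303])
    g1 = np.tile(np.array([[2], [0], [2]], dtype=np.int8), (1, 6))
    g2 = np.tile(np.array([[0], [2], [0]], dtype=np.int8), (1, 6))
    p1 = dc.GenotypeMatrix(np.array(["chr1"] * 3, dtype=object), pos, g1)
    p2 = dc.GenotypeMatrix(np.array(["chr1"] * 3, dtype=object), pos, g2)
    mean, width = popgen.jackknife_window_fst(p1, p2, "chr1", 0, 1_000)
    assert mean == pytest.approx(1.0) and width == pytest.approx(0.0)


def test_jackknife_monomorphic_window_missing_and_few_individuals_error():
    pos = np.array([101])
    g = np.zeros((1, 6), dtype=np.int8)
    g2 = np.zeros((1, 6), dtype=np.int8)
    p1 = dc.GenotypeMatrix(np.array(["chr1"], dtype=object), pos, g)
    p2 = dc.GenotypeMatrix(np.array(["chr1"], dtype=object), pos, g2)
    mean, width = popgen.jackknife_window_fst(p1, p2, "chr1", 0, 1_000,
                                              maf_threshold=None)
    assert np.isnan(mean)
    small = dc.GenotypeMatrix(np.array(["chr1"], dtype=object), pos,
                              np.zeros((1, 2), dtype=np.int8))
    with pytest.raises(ValueError):
        popgen.jackknife_window_fst(small, p2, "chr1", 0, 1_000)


# ---------------------------------------------------------------------------
# genome-wide estimator
# ---------------------------------------------------------------------------

def test_background_fst_ordering_recovered():
    """Higher simulated background divergence gives higher genome-wide F_ST
    (the continuum ordering), and the multi-locus estimate tracks the
    generating parameter."""
    means = []
    for f in (0.10, 0.28):
        vals = []
        for seed in range(3):
            cfg = dc.SimulationConfig(seed=seed, chrom_lengths={"chr1": 1_000_000},
                                      background_fst=f, accessible_fraction=1.0)
            p1, p2, _ = dc.simulate_pair(cfg)
            vals.append(popgen.genome_fst_wc(p1, p2))
        means.append(np.mean(vals))
    assert means[0] < means[1]
    assert means[0] == pytest.approx(0.10, abs=0.04)
    assert means[1] == pytest.approx(0.28, abs=0.04)
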