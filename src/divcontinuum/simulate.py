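"""Two-population genotype simulator with planted selection signatures.

The generator is phenomenological, not a coalescent: background sites draw an
ancestral frequency from a truncated Beta(0.5, 0.5) "standing variation"
spectrum and per-population frequencies from the Balding-Nichols beta with
F equal to the background F_ST; haplotype alleles are then sampled
binomially and paired at random into diploids. Planted regions modify this
recipe to produce the four windowed signatures a divergence scan reads:

- ``reduced_gene_flow``: a strength-dependent fraction of the region's sites
  draws an independent ancestral frequency per population, so window F_ST
  rises while each population's site-frequency spectrum stays neutral-like
  (Tajima's D unaffected).
- ``sweep_pop1`` / ``sweep_pop2``: in the swept population the segregating
  sites are thinned and the survivors pushed to extreme frequencies (most
  sites fixed for the swept allele, the rest near-singletons), giving a
  strongly negative Tajima's D in that population only and elevated F_ST;
  the other population is untouched.
- ``background_selection``: the sweep treatment applied to both populations
  independently (diversity loss and rare-allele excess in both).

Sites monomorphic across the pooled pair are not emitted, and sites are only
placed inside the accessible mask. All randomness descends from
``config.seed`` through named seed streams, so output is byte-reproducible
and the accessibility mask can be regenerated independently of the
genotypes.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import (
    GenotypeMatrix,
    SimulationConfig,
    TruthTable,
)

__all__ = ["simulate_pair", "simulated_mask", "write_truth_bed", "read_truth_bed"]

#: base fraction of swept-population sites left segregating at strength 4
_SWEEP_KEEP = 0.35
#: maximum copies of the non-swept allele at a surviving segregating site
_SWEEP_MAX_MINOR = 2
#: accessible intervals are drawn on this block grid
_MASK_BLOCK = 50_000
#: candidate sites drawn per expected within-population segregating site;
#: compensates sites that come out monomorphic within a population (or in the
#: pooled pair, which are dropped) under the default spectrum, so the realized
#: per-population segregating density matches ``snp_density``
_CANDIDATE_FACTOR = 1.75

# stream tags keeping the mask reproducible without replaying genotype draws
_MASK_STREAM, _SITE_STREAM, _PAIRING_STREAM = 0, 1, 2


def _stream(seed: int, chrom_index: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, chrom_index, tag]))


def _accessible_intervals(rng: np.random.Generator, length: int,
                          fraction: float,
                          force_spans: list[tuple[int, int]] = ()
                          ) -> list[tuple[int, int]]:
    """Random accessible intervals covering ~fraction of one chromosome.

    Tiles the chromosome in 50 kb blocks, keeps each with the target
    probability; adjacent kept blocks merge into one interval. Blocks
    overlapping ``force_spans`` (the planted regions) are always kept, so
    ground truth is observable by construction.
    """
    n_blocks = -(-length // _MASK_BLOCK)
    if fraction >= 1.0:
        return [(0, length)]
    kept = rng.random(n_blocks) < fraction
    for s, e in force_spans:
        kept[s // _MASK_BLOCK: (e - 1) // _MASK_BLOCK + 1] = True
    intervals: list[tuple[int, int]] = []
    for i in np.flatnonzero(kept):
        s, e = i * _MASK_BLOCK, min((i + 1) * _MASK_BLOCK, length)
        if intervals and intervals[-1][1] == s:
            intervals[-1] = (intervals[-1][0], e)
        else:
            intervals.append((s, e))
    return intervals


def _balding_nichols(rng: np.random.Generator, p: np.ndarray,
                     fst: float) -> np.ndarray:
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def _apply_sweep(rng: np.random.Generator, counts: np.ndarray, p_anc: np.ndarray,
                 in_region: np.ndarray, n_hap: int, strength: float) -> None:
    """Overwrite allele counts inside a swept region, in place.

    Each site either becomes fixed for the allele carried by the swept
    haplotype, or stays segregating at an extreme frequency (1 or 2 copies
    of the minor allele, modelling new mutations on the swept background).
    The segregating fraction shrinks as ``strength`` grows.
    """
    idx = np.flatnonzero(in_region)
    if idx.size == 0:
        return
    keep_frac = min(1.0, _SWEEP_KEEP * 4.0 / max(strength, 1e-9))
    swept_allele = (rng.random(idx.size) < p_anc[idx]).astype(np.int64)
    seg = rng.random(idx.size) < keep_frac
    minor = rng.integers(1, _SWEEP_MAX_MINOR + 1, size=idx.size)
    fixed_count = swept_allele * n_hap
    seg_count = np.where(swept_allele == 1, n_hap - minor, minor)
    counts[idx] = np.where(seg, seg_count, fixed_count)


def simulate_pair(config: SimulationConfig) -> tuple[GenotypeMatrix, GenotypeMatrix, TruthTable]:
    """Simulate a parapatric population pair plus ground truth.

    Returns the two populations' genotype matrices (identical site lists)
    and a :class:`TruthTable` mirroring the planted regions. The matching
    accessibility mask comes from :func:`simulated_mask`.
    """
    n_hap = config.n_haplotypes_per_pop
    n_ind = n_hap // 2

    chroms, positions = [], []
    counts1, counts2 = [], []
    for ci, (chrom, length) in enumerate(config.chrom_lengths.items()):
        forced = [(r.start, r.end) for r in config.regions if r.chrom == chrom]
        intervals = _accessible_intervals(
            _stream(config.seed, ci, _MASK_STREAM), length,
            config.accessible_fraction, forced)
        rng = _stream(config.seed, ci, _SITE_STREAM)

        # candidate sites: Poisson-many, uniform along the chromosome,
        # kept only where accessible
        n_cand = rng.poisson(_CANDIDATE_FACTOR * config.snp_density
                             * length / 1000.0)
        pos = np.sort(rng.choice(length, size=min(n_cand, length), replace=False))
        acc = np.zeros(len(pos), dtype=bool)
        for s, e in intervals:
            acc |= (pos >= s) & (pos < e)
        pos = pos[acc]

        p_anc = np.clip(rng.beta(0.5, 0.5, size=len(pos)), 0.02, 0.98)
        p1 = _balding_nichols(rng, p_anc, config.background_fst)
        p2 = _balding_nichols(rng, p_anc, config.background_fst)

        for reg in (r for r in config.regions if r.chrom == chrom):
            if reg.category == "reduced_gene_flow":
                # decouple a strength-dependent fraction of the region's
                # sites: each population draws an independent frequency from
                # the neutral ancestral spectrum, so window F_ST rises while
                # each population's site-frequency spectrum stays the
                # background's (Tajima's D unaffected)
                in_reg = np.flatnonzero((pos >= reg.start) & (pos < reg.end))
                w = min(1.0, config.background_fst * reg.strength)
                decouple = in_reg[rng.random(in_reg.size) < w]
                for p in (p1, p2):
                    fresh = np.clip(rng.beta(0.5, 0.5, size=decouple.size),
                                    0.02, 0.98)
                    p[decouple] = _balding_nichols(rng, fresh,
                                                   config.background_fst)

        c1 = rng.binomial(n_hap, p1)
        c2 = rng.binomial(n_hap, p2)

        for reg in (r for r in config.regions if r.chrom == chrom):
            in_reg = (pos >= reg.start) & (pos < reg.end)
            if reg.category in ("sweep_pop1", "background_selection"):
                _apply_sweep(rng, c1, p_anc, in_reg, n_hap, reg.strength)
            if reg.category in ("sweep_pop2", "background_selection"):
                _apply_sweep(rng, c2, p_anc, in_reg, n_hap, reg.strength)

        poly = ~(((c1 == 0) & (c2 == 0)) | ((c1 == n_hap) & (c2 == n_hap)))
        chroms.append(np.full(int(poly.sum()), chrom, dtype=object))
        positions.append(pos[poly] + 1)  # 1-based
        counts1.append(c1[poly])
        counts2.append(c2[poly])

    empty_i = np.array([], dtype=np.int64)
    chrom_arr = np.concatenate(chroms) if chroms else np.array([], dtype=object)
    pos_arr = np.concatenate(positions) if positions else empty_i
    c1 = np.concatenate(counts1) if counts1 else empty_i
    c2 = np.concatenate(counts2) if counts2 else empty_i

    pair_rng = _stream(config.seed, 0, _PAIRING_STREAM)
    pop1 = GenotypeMatrix(chrom_arr, pos_arr,
                          _counts_to_genotypes(pair_rng, c1, n_hap),
                          [f"pop1_ind{i}" for i in range(n_ind)])
    pop2 = GenotypeMatrix(chrom_arr, pos_arr,
                          _counts_to_genotypes(pair_rng, c2, n_hap),
                          [f"pop2_ind{i}" for i in range(n_ind)])
    truth = TruthTable([(r.chrom, r.start, r.end, r.category)
                        for r in config.regions])
    return pop1, pop2, truth


def _counts_to_genotypes(rng: np.random.Generator, counts: np.ndarray,
                         n_hap: int) -> np.ndarray:
    """Scatter each site's alternate alleles over random haplotypes, then
    pair consecutive haplotypes into diploid individuals."""
    n_sites = len(counts)
    if n_sites == 0:
        return np.zeros((0, n_hap // 2), dtype=np.int8)
    # rank a uniform draw per haplotype; the `counts` smallest ranks carry
    # the alternate allele
    u = rng.random((n_sites, n_hap))
    ranks = np.argsort(np.argsort(u, axis=1), axis=1)
    hap = (ranks < counts[:, None]).astype(np.int8)
    return hap[:, 0::2] + hap[:, 1::2]


def simulated_mask(config: SimulationConfig) -> pd.DataFrame:
    """The accessibility mask matching :func:`simulate_pair` for this config."""
    rows = []
    for ci, (chrom, length) in enumerate(config.chrom_lengths.items()):
        forced = [(r.start, r.end) for r in config.regions if r.chrom == chrom]
        intervals = _accessible_intervals(
            _stream(config.seed, ci, _MASK_STREAM), length,
            config.accessible_fraction, forced)
        rows.extend((chrom, s, e) for s, e in intervals)
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def write_truth_bed(truth: TruthTable, path) -> None:
    """Write planted-region ground truth as BED6 (category in the name column)."""
    with open(path, "w") as fh:
        for chrom, start, end, category in truth:
            fh.write(f"{chrom}\t{start}\t{end}\t{category}\t0\t.\n")


def read_truth_bed(path) -> TruthTable:
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append((f[0], int(f[1]), int(f[2]), f[3]))
    return TruthTable(records)
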