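# Methods

`divcontinuum` implements a genome-scan workflow for pairs of recently
diverged, parapatric populations: windowed divergence and diversity
statistics, detection of outlier windows of exceptional differentiation,
delimitation of divergent regions at 1 kb resolution, classification of
those regions by their site-frequency-spectrum signature, and a set of
cross-pair and ecological comparative statistics. A two-population
simulator with plantable selection signatures makes every stage testable
against known truth.

## Estimators

**Site F_ST.** The Weir & Cockerham (1984) variance-components estimator
for two populations, applied to allele (haplotype) samples: with per-site
allele frequencies p̂₁, p̂₂ on n₁, n₂ called alleles, the estimator is
θ̂ = (MSP − MSG) / (MSP + (n_c − 1)·MSG), where MSP and MSG are the among-
and within-population mean squares and n_c the usual correction for unequal
sample sizes. θ̂ can be negative at undifferentiated sites; negative values
are kept in window means (clamping would bias them upward). Sites that are
monomorphic across the pooled pair are undefined (missing). The genome-wide
F_ST quoted for a pair is the conventional multi-locus ratio of summed
variance components (`genome_fst_wc`), which recovers the simulator's
generating F; the *scan* aggregates windows as the unweighted mean of
per-site estimates, with a ratio-of-sums mode behind `fst_mode="ratio"`.

**MAF filter.** The F_ST scan input keeps sites whose pooled minor-allele
frequency is ≥ 0.25 (threshold inclusive). Low-MAF polymorphism carries
little information about differentiation and dilutes window means. The
filter applies only to the scan; π, Watterson's Θ, Tajima's D and D_xy use
all sites.

**Windows.** Non-overlapping windows (10 kb for the scan, 100 kb for
classifier thresholds) tile each chromosome from position 0; coordinates
are 0-based half-open internally, 1-based only in VCF I/O. π, Θ and D_xy
are divided by the window's *accessible* base pairs (from the mask BED),
not the nominal window length. Windows with no accessible sequence have
all statistics missing (never zero). Tajima's D uses the window's
segregating-site count and summed per-site heterozygosity with the
standard constants; it is reported missing for S < 3, where the variance
normalisation is unstable. The per-site sample size is the number of
called alleles at that site (no imputation); the D constants use the
population's nominal haplotype count.

**Jackknife.** Window-F_ST uncertainty is assessed by removing one
individual from each population in every combination (6×6 = 36 replicates
at the default design), recomputing the window mean over the sites
retained by the full-data MAF filter, and reporting the replicate mean and
central 95% interval width.

## Outlier scan

A window is a final outlier when it passes **both** filters:

1. **Empirical cut** — window F_ST strictly above the top-1% quantile
   (linear/type-7 interpolation, so results are bit-reproducible) of the
   non-missing windows.
2. **Permutation test with FDR control** — per-site F_ST values are
   shuffled genome-wide and re-averaged into blocks matching each window's
   retained-site count. A window's null pools, across permutation
   replicates, the permuted means of windows with the same site count;
   the count bin widens symmetrically until it holds enough draws to
   resolve p below the Benjamini–Hochberg threshold near rank 10
   (divergent regions span many windows, so true signals enter the
   step-up in groups; without the widening, a window with a rare site
   count has an attainable-p floor above every BH threshold and could
   never be significant at desk-scale permutation counts). p-values use
   the add-one estimator; Benjamini–Hochberg at FDR 0.01 flags windows.

The default permutation count is 10,000 in the CLI (raise `--nperm` for
final runs; 1,000,000 matches the original design). Because the smallest
attainable p is ~1/(pooled draws), FDR 0.01 on ~2,000 windows needs at
least ~1,000 permutations to resolve significance at all; single isolated
outlier windows remain hard to confirm at desk scale, which is
conservative.

## Divergent regions

Adjacent (boundary-sharing) final outlier windows merge into candidate
regions. Within each candidate, the retained site of maximal F_ST seeds an
outward walk in 1 kb bins (absolute grid, ties broken leftmost). Each
bin's mean site F_ST f is contrasted to the genome-wide mean F̄ through
the barrier strength

    b = [f/(1−f)] / [F̄/(1−F̄)],

the ratio of local to genome-wide effective-migration odds; b = 1 exactly
at the genome-wide average, and a plain-ratio variant is available behind
a flag. A side's margin sits at the inner edge of the first of **two
consecutive** bins with b strictly below 1; empty bins count as below
(no evidence of elevated divergence); b exactly 1 does not stop the walk,
which is otherwise capped at 500 kb per side and clamped to chromosome
bounds. The walk reads the *unfiltered* polymorphic-site profile — the
pooled-MAF cut belongs to the scan, and inside a sweep it removes so many
sites that 1 kb bins go empty and the walk would stop prematurely.
Overlapping refined regions merge; regions whose accessible fraction is
below 50% are discarded (boundary inclusive). Region sizes are reported
to the nearest 1 kb.

## Classification

Genome-wide 5% and 95% quantiles of the 100 kb-window Tajima's D
distribution are computed per population (a `shared` mode pools the two
populations — a robustness check that changes absolute counts only
mildly). Each region's T_D, computed over its exact refined extent, is
compared to the thresholds of its population:

| lake T_D | river T_D | category |
|---|---|---|
| < q05 | < q05 | background selection |
| < q05 | ≥ q05 | adaptation (lake) |
| ≥ q05 | < q05 | adaptation (river) |
| in [q05, q95] | in [q05, q95] | reduced gene flow |
| otherwise (an upper-tail value) | | unclassified |

Missing region T_D (S < 3 in either population) yields `unclassified`
with a logged reason. The explicit fifth outcome reflects that the four
rules are not exhaustive: upper-tail T_D values match none of them.
Aggregate category percentages divide each category's summed count by the
total region count and round half-up to whole percents.

## Comparative statistics

- **Shared outliers:** observed windows flagged in ≥ 2 pairs versus a null
  that scatters each pair's flag count uniformly over the common window
  universe (one-tailed add-one p). The null mean converges to the
  hypergeometric expectation.
- **Between-pair correlation:** Pearson r over matched non-missing
  windows.
- **Region-vs-genome contrasts** (T_D, ρ/Θ): two-sided Mann–Whitney U
  (exact for small tie-free samples, normal approximation with tie
  correction otherwise), judged at the Bonferroni level α/m (0.005 for
  the default family of ten population-level tests).
- **Recombination map:** adjacent-SNP ρ values above 100 are discarded as
  linkage-breakdown artifacts, the rest averaged per window or region and
  divided by the population's Θ.
- **Parasite ecology:** Shannon diversity per fish and quantitative
  Jaccard (Ružička) distance between populations, both on fourth-root
  transformed counts (a binary-Jaccard flag exists); geodetic distances
  are haversine great circles (R = 6371.0088 km; ellipsoidal corrections
  are irrelevant at this precision).
- **Isolation-by-adaptation:** partial Mantel correlation of genetic and
  ecological distances controlling geography (Pearson on upper-triangle
  entries), permuting the genetic matrix's labels; all n! permutations
  are enumerated exactly for n ≤ 8 populations (a 10-population design has
  few enough labels that random permutation sets would be needlessly
  noisy), one-tailed by default.

## Simulator

The generator is phenomenological and desk-scale; it is **not** a
coalescent and makes no claim to match any specific demography.

- **Background:** ancestral frequencies from Beta(0.5, 0.5) truncated to
  [0.02, 0.98] (a standing-variation-like spectrum without a coalescent
  dependency); population frequencies from the Balding–Nichols beta with
  F = `background_fst`; allele counts binomial on 12 haplotypes per
  population (the sequencing design being emulated), paired at random
  into diploids. Pooled-monomorphic sites are dropped; the candidate-site
  rate is calibrated (factor 1.75) so the realized *per-population
  segregating* density matches `snp_density` (default 5/kb, inside the
  3–10/kb range of the data being emulated).
- **Accessibility:** random 50 kb blocks kept with probability
  `accessible_fraction` (default 0.8, close to the ~78% accessible
  fraction typical of a stringently filtered assembly); planted regions
  are always accessible — ground truth must be observable for recovery
  experiments to be meaningful.
- **Reduced gene flow:** a strength-dependent fraction
  w = min(1, background_fst × strength) of the region's sites draw an
  *independent* ancestral frequency per population. This raises F_ST
  without touching either population's marginal site-frequency spectrum —
  exactly the neutral-spectrum/high-divergence signature the classifier
  reads. (Inflating the Balding–Nichols F instead would skew the SFS
  toward rare alleles and masquerade as selection.)
- **Sweeps:** inside `sweep_popX` regions the swept population's sites are
  either fixed for the allele the swept haplotype carried or left
  segregating at 1–2 copies (new mutations on the swept background); the
  segregating fraction shrinks with strength. This thins diversity and
  drives T_D strongly negative in the swept population only, while
  fixation against the other population's intermediate frequencies
  elevates F_ST. `background_selection` applies the same treatment to
  both populations independently.

**What the simulator does not capture:** linkage disequilibrium and
recombination structure (sites are independent), demographic
non-equilibrium, mutation-rate variation, genotyping error and missing
data. Consequently region-extent T_D is noisier relative to 100 kb-window
thresholds than in real data, where LD smooths local statistics — the
validation experiments therefore plant 100 kb regions (within the
empirical size range of divergent regions and equal to the threshold
window scale) so region and threshold statistics rest on comparable site
numbers. Passing recovery tests demonstrate the pipeline's logic is
correct and calibrated under these conditions, not that real-data power
equals the simulated power.

## Validation experiments and problem sizes

`divcontinuum.validation` backs both the test suite and
`scripts/acceptance.py`:

- **Null calibration:** no-signal simulations on a 20 Mb chromosome
  (~2,000 10 kb windows) with 1,000 permutations; reports the mean
  realized false-discovery proportion of final calls (all calls are false
  under the null) and the empirically flagged fraction (≈ 1% by
  construction).
- **Planted recovery:** one strong region (strength 6) per signature per
  replicate on a 2 × 20 Mb genome with 2,000 permutations; reports
  detection rate, label accuracy among detected regions, and median
  truth-overlap Jaccard.

## Numerical choices and degenerate inputs

- Quantiles everywhere use numpy's default linear (type-7) interpolation.
- Peak ties break leftmost; region grids are absolute 1 kb.
- The permutation null canonicalises site order (sorting before the
  seeded shuffle) so p-values are a pure function of the value multiset.
- Percent aggregation rounds half-up (floor(x + 0.5)); banker's rounding
  would drop exact .5 shares by one point.
- Empty inputs raise `ValueError` early (empty p-vectors, undersized
  samples, < 4 Mantel populations, < 100 windows for quantile thresholds
  — pipelines on genomes too small for stable thresholds keep their
  regions unclassified with a logged warning).
- All randomness flows through named, seeded generator streams; rerunning
  any stage with the same seed is byte-identical.

## Known limitations

- Window F_ST as an unweighted mean of per-site estimates is downward
  biased relative to the ratio-of-sums multi-locus estimator (~0.065 vs
  0.10 at a generating F of 0.10 under the default design); the scan is
  internally consistent because the empirical cut, permutation null and
  barrier baseline all use the same aggregation.
- Isolated single-window outliers cannot reach FDR-0.01 significance at
  desk-scale permutation counts (the attainable-p floor); the original
  million-permutation design does not have this limit.
- D_xy is computed and reported but deliberately not used for region
  calling (absolute divergence is unreliable for nascent populations).
- No LD-aware statistics; recombination maps are consumed, never
  estimated.
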