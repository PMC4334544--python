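"""Core in-memory containers shared across the pipeline.

Coordinate conventions: genotype positions are 1-based (as in VCF); all
intervals (windows, masks, regions) are 0-based half-open (as in BED).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: the four signature types the simulator can plant, in the truth table's vocabulary
PLANTED_CATEGORIES = (
    "sweep_pop1",
    "sweep_pop2",
    "background_selection",
    "reduced_gene_flow",
)

#: classifier output vocabulary (pop1 = lake, pop2 = river by pipeline convention)
REGION_CATEGORIES = (
    "background_selection",
    "adaptation_lake",
    "adaptation_river",
    "reduced_gene_flow",
    "unclassified",
)

#: mapping from planted truth labels to the classifier's labels
TRUTH_TO_CLASSIFIER = {
    "sweep_pop1": "adaptation_lake",
    "sweep_pop2": "adaptation_river",
    "background_selection": "background_selection",
    "reduced_gene_flow": "reduced_gene_flow",
}


@dataclass
class GenotypeMatrix:
    """Biallelic diploid genotypes for one population.

    Attributes
    ----------
    chrom : array of str, one per site
    pos : array of int, 1-based positions, strictly increasing within chrom
    genotypes : (n_sites, n_individuals) int8, alternate-allele dosage 0/1/2,
        -1 for a missing call
    samples : sample names, one per individual
    """

    chrom: np.ndarray
    pos: np.ndarray
    genotypes: np.ndarray
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2 or self.genotypes.shape[0] != self.pos.shape[0]:
            raise ValueError("genotypes must be (n_sites, n_individuals)")
        if not self.samples:
            self.samples = [f"ind{i}" for i in range(self.genotypes.shape[1])]
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.shape[0])

    @property
    def n_individuals(self) -> int:
        return int(self.genotypes.shape[1])

    def alt_counts(self) -> np.ndarray:
        """Alternate-allele count per site over called genotypes."""
        g = self.genotypes
        return np.where(g >= 0, g, 0).sum(axis=1).astype(np.int64)

    def called_alleles(self) -> np.ndarray:
        """Number of successfully called alleles per site (2 x called genotypes)."""
        return (2 * (self.genotypes >= 0).sum(axis=1)).astype(np.int64)

    def drop_individual(self, index: int) -> "GenotypeMatrix":
        keep = [i for i in range(self.n_individuals) if i != index]
        return GenotypeMatrix(
            self.chrom, self.pos, self.genotypes[:, keep],
            [self.samples[i] for i in keep],
        )

    def subset_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.chrom[keep], self.pos[keep], self.genotypes[keep], list(self.samples)
        )


@dataclass(frozen=True)
class PlantedRegion:
    """A region carrying one of the four molecular signatures."""

    chrom: str
    start: int
    end: int
    category: str
    strength: float = 4.0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.category not in PLANTED_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.strength <= 0:
            raise ValueError("strength must be positive")


@dataclass
class SimulationConfig:
    """Study-design parameters for the two-population simulator.

    Defaults mirror the sequencing design being emulated: six diploid
    genomes (12 haplotypes) per population, 3-10 segregating sites per kb
    and genome-wide background divergence in the 0.1-0.3 range.
    """

    seed: int = 0
    n_haplotypes_per_pop: int = 12
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000})
    snp_density: float = 5.0  # expected segregating sites per kb per population
    background_fst: float = 0.15
    accessible_fraction: float = 0.8
    regions: list[PlantedRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_haplotypes_per_pop < 2 or self.n_haplotypes_per_pop % 2:
            raise ValueError("need an even number of haplotypes >= 2")
        if any(l <= 0 for l in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        if not 0 < self.background_fst < 1:
            raise ValueError("background_fst must lie in (0, 1)")
        if not 0 < self.accessible_fraction <= 1:
            raise ValueError("accessible_fraction must lie in (0, 1]")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be positive")
        by_chrom: dict[str, list[PlantedRegion]] = {}
        for r in self.regions:
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"region on unknown chromosome {r.chrom}")
            if r.end > self.chrom_lengths[r.chrom]:
                raise ValueError("planted region exceeds chromosome bounds")
            by_chrom.setdefault(r.chrom, []).append(r)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.start)
            for a, b in zip(regs, regs[1:]):
                if b.start < a.end:
                    raise ValueError("planted regions overlap")


class TruthTable:
    """Ground truth for planted regions, one record per region."""

    def __init__(self, records: Sequence[tuple[str, int, int, str]]):
        self.records = [tuple(r) for r in records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, TruthTable) and self.records == other.records

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=["chrom", "start", "end", "category"])


@dataclass
class DivergentRegion:
    """A merged and border-refined region of exceptional differentiation."""

    chrom: str
    start: int
    end: int
    peak_pos: int
    mean_fst: float
    coverage_fraction: float = 1.0
    category: str | None = None

    @property
    def size_kb(self) -> int:
        return int(round((self.end - self.start) / 1000))

    def __post_init__(self) -> None:
        if self.end - self.start < 1000 or (self.end - self.start) % 1000:
            raise ValueError("region length must be a positive multiple of 1 kb")
        if not self.start <= self.peak_pos < self.end:
            raise ValueError("peak must lie inside the region")
        if not 0 <= self.coverage_fraction <= 1:
            raise ValueError("coverage_fraction must lie in [0, 1]")
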