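"""File formats: VCF, sample-population maps, BED masks, GFF/BED gene
annotations, and the TSV tables the pipeline writes.

Coordinate conventions follow the formats themselves: VCF positions are
1-based, all BED intervals 0-based half-open. Output tables carry a header
comment with the package version, seed and config hash so reruns are
traceable and byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import DivergentRegion, GenotypeMatrix

__all__ = [
    "write_vcf",
    "read_vcf",
    "read_popmap",
    "write_popmap",
    "read_bed",
    "write_bed",
    "read_gene_annotations",
    "intersect_genes",
    "write_table",
    "write_regions_bed",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_CODES = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(pops: dict[str, GenotypeMatrix], path,
              chrom_lengths: dict[str, int] | None = None) -> None:
    """Write one VCFv4.2 with all populations' samples (GT only, A/T alleles)."""
    mats = list(pops.values())
    first = mats[0]
    for m in mats[1:]:
        if m.n_sites != first.n_sites or np.any(m.pos != first.pos):
            raise ValueError("all populations must share one site list")
    samples = [s for m in mats for s in m.samples]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divcontinuum\n")
        if chrom_lengths:
            for c, l in chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={l}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for i in range(first.n_sites):
            gts = "\t".join(_GT_CODES[int(g)] for m in mats
                            for g in m.genotypes[i])
            fh.write(f"{first.chrom[i]}\t{first.pos[i]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path, popmap: dict[str, str],
             mask: pd.DataFrame | None = None) -> dict[str, GenotypeMatrix]:
    """Load biallelic SNPs from a VCF into per-population genotype matrices.

    ``popmap`` maps sample name to population label. Indels, multi-allelic
    records and sites outside the accessibility ``mask`` are dropped. Raises
    if a popmap sample is absent from the VCF.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    missing = set(popmap) - set(vcf.samples)
    if missing:
        raise ValueError(f"popmap samples missing from VCF: {sorted(missing)}")
    col_of = {s: i for i, s in enumerate(vcf.samples)}
    pops: dict[str, list[str]] = {}
    for sample, pop in popmap.items():
        pops.setdefault(pop, []).append(sample)

    chroms, poss, rows = [], [], []
    for lineno, var in enumerate(vcf, start=1):
        if not var.is_snp or len(var.ALT) != 1:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(np.asarray(var.gt_types, dtype=np.int8))
    chrom = np.array(chroms, dtype=object)
    pos = np.array(poss, dtype=np.int64)
    geno = (np.vstack(rows) if rows
            else np.zeros((0, len(vcf.samples)), dtype=np.int8))
    # cyvcf2 gts012: 0/1/2 dosage, 3 = unknown
    geno = np.where(geno == 3, -1, geno).astype(np.int8)

    if mask is not None and len(pos):
        keep = np.zeros(len(pos), dtype=bool)
        for c, sub in mask.groupby("chrom"):
            on_c = chrom == c
            p0 = pos[on_c] - 1
            inside = np.zeros(p0.shape, dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                inside |= (p0 >= s) & (p0 < e)
            keep[on_c] = inside
        chrom, pos, geno = chrom[keep], pos[keep], geno[keep]

    out = {}
    for pop, samples in pops.items():
        cols = [col_of[s] for s in samples]
        out[pop] = GenotypeMatrix(chrom, pos, geno[:, cols], list(samples))
    return out


# ---------------------------------------------------------------------------
# sidecar tables
# ---------------------------------------------------------------------------

def read_popmap(path) -> dict[str, str]:
    """Two-column TSV: sample <tab> population."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return dict(zip(df["sample"], df["population"]))


def write_popmap(popmap: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in popmap.items():
            fh.write(f"{sample}\t{pop}\n")


def read_bed(path) -> pd.DataFrame:
    """BED3(+): chrom, start, end (extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"],
                     dtype={"chrom": str, "start": np.int64, "end": np.int64})
    return df


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False,
                                                index=False)


def read_gene_annotations(path) -> pd.DataFrame:
    """Gene intervals from a GFF3 or BED file, as 0-based half-open frames.

    GFF3 (1-based closed) rows of type 'gene' are converted; for BED all
    rows are taken, using column 4 as the gene name when present.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                name = next((kv.split("=", 1)[1] for kv in f[8].split(";")
                             if kv.startswith(("ID=", "Name="))), f[8])
                rows.append((f[0], int(f[3]) - 1, int(f[4]), name))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.assign(name="gene")
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    if "name" not in df:
        df["name"] = [f"gene{i}" for i in range(len(df))]
    return df


def intersect_genes(regions: list[DivergentRegion],
                    genes: pd.DataFrame) -> list[list[str]]:
    """Gene names overlapping each region by >= 1 bp (half-open intervals)."""
    out = []
    for reg in regions:
        sub = genes[(genes["chrom"] == reg.chrom)
                    & (genes["start"] < reg.end)
                    & (genes["end"] > reg.start)]
        out.append(list(sub["name"]))
    return out


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _header_comment(seed, cfg_hash) -> str:
    from . import __version__

    return f"# divcontinuum v{__version__} | seed={seed} | config={cfg_hash}\n"


def write_table(df: pd.DataFrame, path, seed=None, cfg_hash="-") -> None:
    """TSV with a fixed column order and a provenance header comment."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, cfg_hash))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_regions_bed(regions: list[DivergentRegion], path,
                      seed=None, cfg_hash="-") -> None:
    """Regions as BED6, category (or '.') in the name column, F_ST as score."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed, cfg_hash))
        for r in regions:
            name = r.category or "."
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t"
                     f"{r.mean_fst:.4f}\t.\n")
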