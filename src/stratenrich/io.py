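"""Core containers and readers/writers for the plain-text study formats.

The pipeline exchanges data through four standard formats: VCF 4.2 with
GT-only calls for genotypes, a TSV sample table, BED4 for gene bodies and
GMT for gene sets.  Internally all coordinates are 1-based inclusive (the
VCF convention); BED output is converted to 0-based half-open on write and
back on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: sentinel for a missing genotype call in the dosage matrix
MISSING: int = -1

_GT_STRINGS = np.array(["./.", "0/0", "0/1", "1/1"])

SAMPLE_COLUMNS = ["sample_id", "status", "stratum", "subpop"]
STRATA = ("control", "MLI_LA", "ILI", "unclassified")


@dataclass
class GenotypeMatrix:
    """Samples x variants additive dosage matrix with {0,1,2,-1} entries."""

    dosages: np.ndarray
    sample_ids: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix shape inconsistent with id lists")
        bad = (self.dosages < MISSING) | (self.dosages > 2)
        if bad.any():
            raise ValueError("dosages must lie in {0,1,2} or -1 for missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def sample_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([lookup[s] for s in ids], dtype=int)

    def variant_index(self, ids: Iterable[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_ids)}
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(ids)
        return GenotypeMatrix(self.dosages[idx], self.sample_ids[idx], self.variant_ids)

    def subset_variants(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.variant_index(ids)
        return GenotypeMatrix(self.dosages[:, idx], self.sample_ids, self.variant_ids[idx])

    def alt_freq(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing calls."""
        d = self.dosages
        obs = d != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def variant_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)


@dataclass(frozen=True)
class GeneSet:
    """A named gene set; subcomplexes carry the parent pathway's name."""

    name: str
    genes: tuple
    parent: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicated gene ids")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(path: str | os.PathLike, genotypes: GenotypeMatrix, variants: pd.DataFrame) -> None:
    """Write a minimal GT-only VCF 4.2; missing calls become "./."."""
    v = variants.set_index("variant_id").loc[list(genotypes.variant_ids)]
    gt = _GT_STRINGS[genotypes.dosages.T + 1]  # variants x samples
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, genotypes.sample_ids))
            + "\n"
        )
        chroms = v["chrom"].to_numpy()
        poss = v["pos"].to_numpy()
        refs = v["ref"].to_numpy()
        alts = v["alt"].to_numpy()
        ids = v.index.to_numpy()
        for i in range(len(v)):
            fh.write(
                f"{chroms[i]}\t{poss[i]}\t{ids[i]}\t{refs[i]}\t{alts[i]}\t.\t.\t.\tGT\t"
                + "\t".join(gt[i])
                + "\n"
            )


def read_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read a GT-only VCF into a dosage matrix and a variant table."""
    from cyvcf2 import VCF

    reader = VCF(str(path), gts012=True)
    samples = np.asarray(reader.samples, dtype=object)
    rows, records = [], []
    for rec in reader:
        gt = rec.gt_types.astype(np.int8)  # 0/1/2 dosage, 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
        records.append(
            (rec.ID, rec.CHROM, rec.POS, rec.REF, rec.ALT[0] if rec.ALT else ".")
        )
    reader.close()
    variants = pd.DataFrame(records, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    dosages = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(dosages, samples, variants["variant_id"].to_numpy()), variants


# ---------------------------------------------------------------------------
# sample table / BED / GMT / generic TSV


def write_samples(path: str | os.PathLike, samples: pd.DataFrame) -> None:
    samples.loc[:, SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    return df


def write_bed(path: str | os.PathLike, genes: pd.DataFrame) -> None:
    """Genes held 1-based inclusive internally; BED is 0-based half-open."""
    out = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"].astype(int) - 1,
            "end": genes["end"].astype(int),
            "name": genes["gene_id"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"], dtype={0: str},
    )
    return pd.DataFrame(
        {
            "gene_id": df["name"],
            "chrom": df["chrom"],
            "start": df["start"].astype(int) + 1,
            "end": df["end"].astype(int),
        }
    )


def write_gmt(path: str | os.PathLike, gene_sets: Sequence[GeneSet]) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = gs.description or (f"parent={gs.parent}" if gs.parent else ".")
            fh.write("\t".join([gs.name, desc, *map(str, gs.genes)]) + "\n")


def read_gmt(path: str | os.PathLike) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], tuple(parts[2:])
            parent = desc.removeprefix("parent=") if desc.startswith("parent=") else None
            sets.append(GeneSet(name=name, genes=genes, parent=parent, description=desc))
    return sets
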