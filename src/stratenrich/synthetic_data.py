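"""Synthetic case/control cohorts with LD-blocked genotypes and planted signal.

The generator emulates the substrate of a small-vessel-disease style GWAS:
a cohort of controls plus two radiologic case strata (an MLI/LA-like stratum
A and an ILI-like stratum B), biallelic SNPs laid out in gene-centric blocks
on synthetic autosomes, within-gene linkage disequilibrium, mild population
structure, random missingness, and a focal pathway in which a subset of
genes carries causal variants whose effect is expressed only when sampling
stratum-A cases.

Haplotype model
---------------
Each gene block draws, per haplotype, a latent AR(1) Gaussian vector with
lag-one correlation ``ld_rho`` (independent across genes), thresholded at
the allele-frequency quantile to a binary haplotype; the two haplotypes of
an individual are independent, so genotypes are in Hardy-Weinberg
equilibrium within each subpopulation.  Population structure follows the
Balding-Nichols model: with ``structure_shift`` = F > 0, each of two
subpopulations draws its allele frequency from Beta(p(1-F)/F, (1-p)(1-F)/F).

Phenotype model
---------------
Disease status follows a logistic liability: log-odds = alpha + log(OR) per
alternate allele at each causal SNP, with the intercept alpha solved so the
population prevalence equals ``baseline_prevalence``.  Stratum-A cases are
ascertained by accept/reject sampling against this liability; stratum-B
cases, unclassified cases and controls are population draws with no genetic
effect, mirroring a pathway signal confined to one radiologic subtype.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from .io import (
    MISSING,
    GeneSet,
    GenotypeMatrix,
    read_bed,
    read_gmt,
    read_samples,
    read_vcf,
    write_bed,
    write_gmt,
    write_samples,
    write_vcf,
)

GENES_PER_CHROMOSOME = 1_000

_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_PLAIN_PAIRS = [("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"), ("C", "A"), ("G", "A")]

PATHWAY_NAME = "pathway"
N_SUBCOMPLEXES = 5


class InsufficientPoolError(RuntimeError):
    """Raised when a candidate pool cannot satisfy the requested stratum counts."""


@dataclass
class SimulationConfig:
    n_controls: int = 600
    n_cases_stratumA: int = 300
    n_cases_stratumB: int = 300
    n_cases_unclassified: int = 0
    n_genes: int = 2_000
    snps_per_gene: int | tuple[int, int] = 5
    gene_span_bp: int = 10_000
    intergene_gap_bp: int = 30_000
    ld_rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    pathway_size: int = 20
    n_causal_genes: int = 10
    causal_snps_per_gene: int = 1
    causal_or: float = 2.0
    baseline_prevalence: float = 0.1
    missing_rate: float = 0.01
    structure_shift: float = 0.0
    ambiguous_fraction: float = 0.05
    diff_missing_rate: float = 0.0
    diff_missing_fraction: float = 0.0
    n_duplicate_samples: int = 0
    seed: int = 0

    def snp_count_range(self) -> tuple[int, int]:
        if isinstance(self.snps_per_gene, int):
            return self.snps_per_gene, self.snps_per_gene
        lo, hi = self.snps_per_gene
        return int(lo), int(hi)

    def validate(self) -> None:
        if self.n_controls <= 0:
            raise ValueError("n_controls must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if min(self.n_cases_stratumA, self.n_cases_stratumB, self.n_cases_unclassified) < 0:
            raise ValueError("case counts must be non-negative")
        lo, hi = self.snp_count_range()
        if lo < 1 or hi < lo:
            raise ValueError("snps_per_gene must be a positive count or (lo, hi) range")
        if hi > self.gene_span_bp:
            raise ValueError("more SNPs per gene than base pairs in the gene span")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must lie in [0, 1)")
        mlo, mhi = self.maf_range
        if not (0.0 < mlo <= mhi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (self.n_causal_genes <= self.pathway_size <= self.n_genes):
            raise ValueError("need n_causal_genes <= pathway_size <= n_genes")
        if self.causal_or < 1.0:
            raise ValueError("causal_or must be >= 1")
        if not (0.0 <= self.baseline_prevalence <= 1.0):
            raise ValueError("baseline_prevalence must be a probability")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.structure_shift < 0.0 or self.structure_shift >= 1.0:
            raise ValueError("structure_shift must lie in [0, 1)")
        if self.causal_snps_per_gene < 1:
            raise ValueError("causal_snps_per_gene must be >= 1")


@dataclass
class Truth:
    """Planted causal structure of a synthetic study."""

    causal_genes: tuple
    causal_snps: tuple
    effects: pd.Series  # per-SNP log odds ratio, indexed by variant id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": list(self.effects.index),
                "beta": self.effects.to_numpy(),
                "odds_ratio": np.exp(self.effects.to_numpy()),
            }
        )


@dataclass
class SyntheticStudy:
    genotypes: GenotypeMatrix
    variants: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame
    gene_sets: list[GeneSet]
    truth: Truth
    config: SimulationConfig | None = None


@dataclass
class _Plan:
    """Frozen randomised layout: variants, genes, sets and causal effects."""

    variants: pd.DataFrame  # variant_id chrom pos ref alt gene_index maf ambiguous
    genes: pd.DataFrame  # gene_id chrom start end
    gene_sets: list[GeneSet]
    truth: Truth
    subpop_freqs: np.ndarray | None  # (2, n_variants) or None when unstructured
    gene_slices: list[slice]


# ---------------------------------------------------------------------------
# layout


def _make_plan(config: SimulationConfig, rng: np.random.Generator) -> _Plan:
    lo, hi = config.snp_count_range()
    counts = rng.integers(lo, hi + 1, size=config.n_genes) if hi > lo else np.full(config.n_genes, lo)

    gene_rows, var_rows, gene_slices = [], [], []
    period = config.gene_span_bp + config.intergene_gap_bp
    offset = 0
    for g in range(config.n_genes):
        chrom = f"chr{g // GENES_PER_CHROMOSOME + 1}"
        within = g % GENES_PER_CHROMOSOME
        start = 1 + within * period
        end = start + config.gene_span_bp - 1
        gene_id = f"G{g + 1:05d}"
        gene_rows.append((gene_id, chrom, start, end))
        pos = np.sort(rng.choice(config.gene_span_bp, size=counts[g], replace=False)) + start
        gene_slices.append(slice(offset, offset + counts[g]))
        for j, p in enumerate(pos):
            var_rows.append((f"{gene_id}_snp{j + 1}", chrom, int(p), g))
        offset += counts[g]

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos", "gene_index"])
    n_var = len(variants)
    variants["maf"] = rng.uniform(config.maf_range[0], config.maf_range[1], size=n_var)

    # focal pathway, disjoint subcomplexes, causal genes and SNP effects
    pathway_idx = np.sort(rng.choice(config.n_genes, size=config.pathway_size, replace=False))
    pathway_genes = genes["gene_id"].to_numpy()[pathway_idx]
    causal_gene_idx = np.sort(rng.choice(pathway_idx, size=config.n_causal_genes, replace=False))
    causal_genes = genes["gene_id"].to_numpy()[causal_gene_idx]

    causal_snps, betas = [], []
    beta = math.log(config.causal_or)
    for gi in causal_gene_idx:
        sl = gene_slices[gi]
        n_here = min(config.causal_snps_per_gene, sl.stop - sl.start)
        # spread causal SNPs across the block: adjacent picks would be nearly
        # redundant under the AR(1) LD and carry little extra signal
        chosen = sl.start + np.unique(
            np.round(np.linspace(0, sl.stop - sl.start - 1, n_here)).astype(int)
        )
        for c in np.sort(chosen):
            causal_snps.append(variants["variant_id"].iat[int(c)])
            betas.append(beta)
    effects = pd.Series(betas, index=causal_snps, dtype=float, name="beta")

    # strand-ambiguous alleles exercise the QC filter; never on causal SNPs
    ambiguous = np.zeros(n_var, dtype=bool)
    causal_mask = variants["variant_id"].isin(causal_snps).to_numpy()
    eligible = np.flatnonzero(~causal_mask)
    n_amb = int(round(config.ambiguous_fraction * n_var))
    if n_amb > 0 and len(eligible) > 0:
        ambiguous[rng.choice(eligible, size=min(n_amb, len(eligible)), replace=False)] = True
    variants["ambiguous"] = ambiguous
    refs = np.empty(n_var, dtype=object)
    alts = np.empty(n_var, dtype=object)
    amb_choice = rng.integers(0, len(_AMBIGUOUS_PAIRS), size=n_var)
    plain_choice = rng.integers(0, len(_PLAIN_PAIRS), size=n_var)
    for i in range(n_var):
        refs[i], alts[i] = (
            _AMBIGUOUS_PAIRS[amb_choice[i]] if ambiguous[i] else _PLAIN_PAIRS[plain_choice[i]]
        )
    variants["ref"] = refs
    variants["alt"] = alts
    variants = variants[
        ["variant_id", "chrom", "pos", "ref", "alt", "gene_index", "maf", "ambiguous"]
    ]

    subpop_freqs = None
    if config.structure_shift > 0:
        F = config.structure_shift
        p = variants["maf"].to_numpy()
        a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
        subpop_freqs = np.clip(rng.beta(a, b, size=(2, n_var)), 1e-4, 1 - 1e-4)

    gene_sets = [GeneSet(PATHWAY_NAME, tuple(pathway_genes), description="focal pathway")]
    n_sub = min(N_SUBCOMPLEXES, config.pathway_size)
    for s in range(n_sub):
        members = tuple(pathway_genes[s::n_sub])
        if members:
            gene_sets.append(GeneSet(f"subcomplex{s + 1}", members, parent=PATHWAY_NAME))

    truth = Truth(tuple(causal_genes), tuple(causal_snps), effects)
    return _Plan(variants, genes, gene_sets, truth, subpop_freqs, gene_slices)


# ---------------------------------------------------------------------------
# genotype drawing


def _draw_complete(
    plan: _Plan, n: int, rng: np.random.Generator, subpop: np.ndarray, ld_rho: float
) -> np.ndarray:
    """Complete (no-missing) dosages for n individuals via the AR(1) copula."""
    n_var = len(plan.variants)
    maf = plan.variants["maf"].to_numpy()
    out = np.empty((n, n_var), dtype=np.int8)
    root = math.sqrt(1.0 - ld_rho * ld_rho)
    for sl in plan.gene_slices:
        k = sl.stop - sl.start
        z = np.empty((2 * n, k))
        z[:, 0] = rng.standard_normal(2 * n)
        for j in range(1, k):
            z[:, j] = ld_rho * z[:, j - 1] + root * rng.standard_normal(2 * n)
        if plan.subpop_freqs is None:
            thresh = np.broadcast_to(ndtri(maf[sl]), (2 * n, k))
        else:
            thresh = ndtri(plan.subpop_freqs[:, sl])[np.repeat(subpop, 2)]
        hap = (z < thresh).astype(np.int8)
        out[:, sl] = hap[0::2] + hap[1::2]
    return out


def simulate_genotypes(
    config: SimulationConfig,
    n_individuals: int | None = None,
    rng: np.random.Generator | None = None,
    plan: _Plan | None = None,
    subpop: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw a population sample of genotypes (the pipeline's raw substrate).

    Returns the dosage matrix (with MCAR missingness already applied at
    ``config.missing_rate``), the variant table and the gene annotation.
    """
    config.validate()
    if n_individuals is None:
        n_individuals = (
            config.n_controls
            + config.n_cases_stratumA
            + config.n_cases_stratumB
            + config.n_cases_unclassified
        )
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if plan is None:
        plan = _make_plan(config, rng)
    if subpop is None:
        subpop = (
            rng.integers(0, 2, size=n_individuals)
            if config.structure_shift > 0
            else np.zeros(n_individuals, dtype=int)
        )
    dos = _draw_complete(plan, n_individuals, rng, subpop, config.ld_rho)
    if config.missing_rate > 0:
        dos[rng.random(dos.shape) < config.missing_rate] = MISSING
    ids = np.array([f"ind_{i + 1:06d}" for i in range(n_individuals)], dtype=object)
    gm = GenotypeMatrix(dos, ids, plan.variants["variant_id"].to_numpy())
    return gm, plan.variants.copy(), plan.genes.copy()


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    if prevalence <= 0.0 or prevalence >= 1.0:
        return math.inf if prevalence >= 1.0 else -math.inf

    def f(a: float) -> float:
        return float(np.mean(expit(a + scores))) - prevalence

    return brentq(f, -40.0, 40.0)


def assign_phenotypes(
    genotypes: GenotypeMatrix,
    effects: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign strata over a candidate pool of genotype rows.

    The first rows become controls, stratum-B cases and unclassified cases
    (population draws, no genetic effect); the remaining rows are candidates
    for stratum-A cases, accepted with the logistic liability probability.
    The returned table carries a ``pool_row`` column mapping each selected
    sample back to its genotype row.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_base = config.n_controls + config.n_cases_stratumB + config.n_cases_unclassified
    n_a = config.n_cases_stratumA
    if genotypes.n_samples < n_base + n_a:
        raise InsufficientPoolError(
            f"pool of {genotypes.n_samples} cannot provide {n_base + n_a} samples"
        )
    if n_a > 0 and config.baseline_prevalence <= 0.0:
        raise ValueError("cannot sample cases at baseline_prevalence = 0")

    rows: list[tuple[str, str, str, int]] = []
    cursor = 0
    for stratum, status, count, prefix in (
        ("control", "control", config.n_controls, "ctrl"),
        ("ILI", "case", config.n_cases_stratumB, "ili"),
        ("unclassified", "case", config.n_cases_unclassified, "uncl"),
    ):
        for i in range(count):
            rows.append((f"{prefix}_{i + 1:05d}", status, stratum, cursor))
            cursor += 1

    if n_a > 0:
        candidates = np.arange(cursor, genotypes.n_samples)
        genetic = len(effects) > 0 and effects.abs().max() > 0
        if genetic:
            idx = genotypes.variant_index(effects.index)
            # liability uses the true genotype; an (unusual) missing call counts 0
            g = np.maximum(genotypes.dosages[:, idx], 0).astype(float)
            score = g @ effects.to_numpy()
            alpha = _solve_intercept(score, config.baseline_prevalence)
            accept = rng.random(len(candidates)) < expit(alpha + score[candidates])
            accepted = candidates[accept]
        else:
            accepted = candidates  # constant acceptance: take rows in order
        if len(accepted) < n_a:
            raise InsufficientPoolError(
                f"only {len(accepted)} stratum-A cases accepted from the pool, need {n_a}"
            )
        for i, r in enumerate(accepted[:n_a]):
            rows.append((f"mlila_{i + 1:05d}", "case", "MLI_LA", int(r)))

    df = pd.DataFrame(rows, columns=["sample_id", "status", "stratum", "pool_row"])
    df["subpop"] = "pop0"
    order = {"control": 0, "MLI_LA": 1, "ILI": 2, "unclassified": 3}
    df = df.sort_values(
        by=["stratum", "sample_id"], key=lambda s: s.map(order) if s.name == "stratum" else s
    ).reset_index(drop=True)
    return df[["sample_id", "status", "stratum", "subpop", "pool_row"]]


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete reproducible study: genotypes, annotations, truth."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_plan, r_geno, r_pheno, r_miss = (np.random.default_rng(c) for c in ss.spawn(4))
    plan = _make_plan(config, r_plan)

    n_base = config.n_controls + config.n_cases_stratumB + config.n_cases_unclassified
    n_a = config.n_cases_stratumA
    genetic = len(plan.truth.effects) > 0 and config.causal_or > 1.0 and n_a > 0
    pool_a = n_a if not genetic else int(math.ceil(n_a / config.baseline_prevalence * 1.4)) + 100

    samples = dosages = subpop = None
    for attempt in range(8):
        pool_n = n_base + pool_a
        rg = np.random.default_rng(r_geno.spawn(1)[0])
        sp = (
            rg.integers(0, 2, size=pool_n)
            if config.structure_shift > 0
            else np.zeros(pool_n, dtype=int)
        )
        dos = _draw_complete(plan, pool_n, rg, sp, config.ld_rho)
        pool = GenotypeMatrix(
            dos,
            np.array([f"pool_{i}" for i in range(pool_n)], dtype=object),
            plan.variants["variant_id"].to_numpy(),
        )
        try:
            samples = assign_phenotypes(pool, plan.truth.effects, config, r_pheno)
            dosages, subpop = dos, sp
            break
        except InsufficientPoolError:
            pool_a *= 2
    if samples is None:
        raise InsufficientPoolError("could not satisfy stratum counts; raise the pool bound")

    rows = samples["pool_row"].to_numpy()
    dos = dosages[rows].copy()
    samples = samples.copy()
    samples["subpop"] = np.array([f"pop{s}" for s in subpop[rows]], dtype=object)

    # optional exact-duplicate controls (exercise the relatedness filter)
    if config.n_duplicate_samples > 0:
        ctrl_rows = np.flatnonzero(samples["stratum"].to_numpy() == "control")
        take = ctrl_rows[: config.n_duplicate_samples]
        dup = samples.iloc[take].copy()
        dup["sample_id"] = dup["sample_id"] + "_dup"
        samples = pd.concat([samples, dup], ignore_index=True)
        dos = np.vstack([dos, dos[take]])

    if config.missing_rate > 0:
        dos[r_miss.random(dos.shape) < config.missing_rate] = MISSING
    if config.diff_missing_rate > 0 and config.diff_missing_fraction > 0:
        n_var = dos.shape[1]
        n_aff = max(1, int(round(config.diff_missing_fraction * n_var)))
        cols = r_miss.choice(n_var, size=n_aff, replace=False)
        case_rows = np.flatnonzero(samples["status"].to_numpy() == "case")
        extra = r_miss.random((len(case_rows), n_aff)) < config.diff_missing_rate
        block = dos[np.ix_(case_rows, cols)]
        block[extra] = MISSING
        dos[np.ix_(case_rows, cols)] = block

    gm = GenotypeMatrix(
        dos, samples["sample_id"].to_numpy(), plan.variants["variant_id"].to_numpy()
    )
    return SyntheticStudy(
        genotypes=gm,
        variants=plan.variants.copy(),
        samples=samples.drop(columns=["pool_row"]),
        genes=plan.genes.copy(),
        gene_sets=list(plan.gene_sets),
        truth=plan.truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# on-disk round trip


def write_study(study: SyntheticStudy, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write genotypes.vcf, samples.tsv, genes.bed, genesets.gmt and truth.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "samples": out / "samples.tsv",
        "bed": out / "genes.bed",
        "gmt": out / "genesets.gmt",
        "truth": out / "truth.tsv",
    }
    write_vcf(paths["vcf"], study.genotypes, study.variants)
    write_samples(paths["samples"], study.samples)
    write_bed(paths["bed"], study.genes)
    write_gmt(paths["gmt"], study.gene_sets)
    study.truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths


def read_study(in_dir: str | os.PathLike) -> SyntheticStudy:
    """Load a study written by :func:`write_study` (truth optional)."""
    d = Path(in_dir)
    gm, variants = read_vcf(d / "genotypes.vcf")
    samples = read_samples(d / "samples.tsv")
    genes = read_bed(d / "genes.bed")
    gene_sets = read_gmt(d / "genesets.gmt")
    truth_path = d / "truth.tsv"
    if truth_path.exists():
        tf = pd.read_csv(truth_path, sep="\t")
        effects = pd.Series(tf["beta"].to_numpy(), index=tf["variant_id"], name="beta")
        gene_of = {v: v.rsplit("_snp", 1)[0] for v in effects.index}
        truth = Truth(tuple(sorted(set(gene_of.values()))), tuple(effects.index), effects)
    else:
        truth = Truth((), (), pd.Series(dtype=float))
    return SyntheticStudy(gm, variants, samples, genes, gene_sets, truth)
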