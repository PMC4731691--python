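"""Variant and sample quality control for case/control genotype matrices.

Implements the standard exome-array GWAS filter battery: per-variant MAF,
call-rate, Hardy-Weinberg (exact test in controls), strand-ambiguity and
differential-missingness filters; per-sample call-rate, heterozygosity and
relatedness (method-of-moments pi-hat) filters; greedy LD pruning; and the
iterative EIGENSTRAT-style principal-component ancestry-outlier removal
whose final PCs feed the association stage as covariates.

Filter conventions (all strict inequalities): exclude variants with
MAF < 0.01, missingness > 3%, HWE p < 1e-6 in controls, A/T-or-C/G alleles,
or differential missingness p < 0.05; exclude samples with missingness > 3%,
|heterozygosity z| above a cutoff (default 3 SD), or pi-hat > 0.1875 with
another retained sample; remove PC outliers beyond 6 SD on either of the
first two components over up to 8 iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import fisher_exact

from .io import MISSING, GenotypeMatrix

@dataclass
class QCThresholds:
    maf_min: float = 0.01
    variant_miss_max: float = 0.03
    hwe_min_p: float = 1e-6
    diffmiss_alpha: float = 0.05
    drop_ambiguous: bool = True
    sample_miss_max: float = 0.03
    het_sd: float = 3.0
    pihat_max: float = 0.1875
    pihat_min_overlap: int = 100
    pc_sd: float = 6.0
    pc_iterations: int = 8
    ld_window_snps: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.2


@dataclass
class SampleQCReport:
    table: pd.DataFrame  # sample_id, missing_rate, het_rate, het_z, removed_reason
    flagged_pairs: pd.DataFrame  # sample_i, sample_j, pihat
    retained: list


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Levene-Haldane exact test of Hardy-Weinberg proportions.

    Given the observed genotype counts, conditions on the allele counts and
    sums the probabilities of all heterozygote counts (of matching parity)
    no more probable than the observed one.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("all genotype counts are zero")
    rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    if rare == 0:
        return 1.0  # monomorphic: a single achievable configuration
    common = 2 * n - rare
    hets = np.arange(rare % 2, rare + 1, 2)
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        gammaln(n + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(hets + 1)
        - gammaln(n_common_hom + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1)
        + gammaln(common + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC


def variant_qc(
    genotypes: GenotypeMatrix,
    variants: pd.DataFrame,
    samples: pd.DataFrame | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Apply all per-variant filters; a variant failing any filter is excluded.

    Returns the annotated variant table (one verdict column per filter plus
    ``pass_qc``) and the genotype matrix restricted to passing variants.
    """
    th = thresholds or QCThresholds()
    v = variants.set_index("variant_id").loc[list(genotypes.variant_ids)].reset_index()
    d = genotypes.dosages
    obs = d != MISSING

    freq = genotypes.alt_freq()
    maf = np.minimum(freq, 1.0 - freq)
    miss = genotypes.variant_missing_rate()

    status = None
    if samples is not None:
        status = (
            samples.set_index("sample_id")
            .loc[list(genotypes.sample_ids), "status"]
            .to_numpy()
        )

    hwe_p = np.full(genotypes.n_variants, np.nan)
    if status is None or not (status == "control").any():
        raise ValueError(
            "HWE-in-controls filter requires a sample table with control samples"
        )
    ctrl = status == "control"
    dc = d[ctrl]
    oc = obs[ctrl]
    n_het = ((dc == 1) & oc).sum(axis=0)
    n_hom_alt = ((dc == 2) & oc).sum(axis=0)
    n_hom_ref = ((dc == 0) & oc).sum(axis=0)
    for j in range(genotypes.n_variants):
        if n_hom_ref[j] + n_het[j] + n_hom_alt[j] > 0:
            hwe_p[j] = hwe_exact_test(int(n_hom_ref[j]), int(n_het[j]), int(n_hom_alt[j]))

    case = status == "case"
    diff_p = np.ones(genotypes.n_variants)
    n_case, n_ctrl = int(case.sum()), int(ctrl.sum())
    miss_case = (~obs[case]).sum(axis=0)
    miss_ctrl = (~obs[ctrl]).sum(axis=0)
    for j in range(genotypes.n_variants):
        mc, mt = int(miss_case[j]), int(miss_ctrl[j])
        if mc + mt == 0:
            continue
        table = [[mc, n_case - mc], [mt, n_ctrl - mt]]
        diff_p[j] = fisher_exact(table, alternative="two-sided")[1]

    ambiguous = v["ambiguous"].to_numpy(dtype=bool) if "ambiguous" in v else _is_ambiguous(v)

    fail_maf = maf < th.maf_min
    fail_miss = miss > th.variant_miss_max
    fail_hwe = hwe_p < th.hwe_min_p
    fail_amb = ambiguous & th.drop_ambiguous
    fail_diff = diff_p < th.diffmiss_alpha
    passed = ~(fail_maf | fail_miss | fail_hwe | fail_amb | fail_diff)

    report = v.assign(
        maf=maf,
        missing_rate=miss,
        hwe_p_controls=hwe_p,
        diffmiss_p=diff_p,
        ambiguous=ambiguous,
        fail_maf=fail_maf,
        fail_missing=fail_miss,
        fail_hwe=fail_hwe,
        fail_ambiguous=fail_amb,
        fail_diffmiss=fail_diff,
        pass_qc=passed,
    )
    kept = genotypes.variant_ids[passed]
    return report, genotypes.subset_variants(list(kept))


def _is_ambiguous(variants: pd.DataFrame) -> np.ndarray:
    pairs = set(map(tuple, (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))))
    return np.array(
        [(r, a) in pairs for r, a in zip(variants["ref"], variants["alt"])], dtype=bool
    )


# ---------------------------------------------------------------------------
# relatedness


def _ibd_expectations(p: np.ndarray) -> tuple[np.ndarray, ...]:
    q = 1.0 - p
    e0 = 2.0 * p**2 * q**2
    e1_ibd0 = 4.0 * p**3 * q + 4.0 * p * q**3
    e2_ibd0 = 1.0 - e0 - e1_ibd0
    e1_ibd1 = 2.0 * p * q
    e2_ibd1 = 1.0 - e1_ibd1
    return e0, e1_ibd0, e2_ibd0, e1_ibd1, e2_ibd1


def pihat_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments pi-hat for every sample pair (PLINK-style).

    IBS class counts come from one-hot dosage products; the IBD mixture is
    solved by moments against the no-IBD expectations implied by the sample
    allele frequencies, restricted per pair to jointly observed polymorphic
    variants.  Returns an (n, n) matrix with ones on the diagonal.
    """
    d = genotypes.dosages
    freq = genotypes.alt_freq()
    poly = (freq > 0.0) & (freq < 1.0) & ~np.isnan(freq)
    d = d[:, poly]
    p = freq[poly]
    obs = (d != MISSING).astype(np.float32)
    a0 = ((d == 0)).astype(np.float32)
    a1 = ((d == 1)).astype(np.float32)
    a2 = ((d == 2)).astype(np.float32)

    ibs2 = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    ibs0 = a0 @ a2.T + a2 @ a0.T
    total = obs @ obs.T
    ibs1 = total - ibs2 - ibs0

    e0, e1_0, e2_0, e1_1, e2_1 = (e.astype(np.float32) for e in _ibd_expectations(p))
    s0 = (obs * e0) @ obs.T
    s1_0 = (obs * e1_0) @ obs.T
    s2_0 = (obs * e2_0) @ obs.T
    s1_1 = (obs * e1_1) @ obs.T
    s2_1 = (obs * e2_1) @ obs.T

    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = np.where(s0 > 0, ibs0 / s0, 0.0)
        p1 = np.where(s1_1 > 0, (ibs1 - p0 * s1_0) / s1_1, 0.0)
        p2 = np.where(total > 0, (ibs2 - p0 * s2_0 - p1 * s2_1) / total, 0.0)
    # only the combined estimate is truncated; clipping the components
    # individually would bias unrelated pairs upward
    pihat = np.clip(p2 + 0.5 * p1, 0.0, 1.0).astype(np.float64)
    np.fill_diagonal(pihat, 1.0)
    return pihat


def estimate_pihat(
    genotypes: GenotypeMatrix,
    sample_i: str,
    sample_j: str,
    min_overlap: int = 100,
) -> float:
    """Pi-hat for one sample pair; allele frequencies from the full matrix."""
    i, j = genotypes.sample_index([sample_i, sample_j])
    d = genotypes.dosages
    freq = genotypes.alt_freq()
    poly = (freq > 0.0) & (freq < 1.0) & ~np.isnan(freq)
    gi, gj, p = d[i, poly], d[j, poly], freq[poly]
    both = (gi != MISSING) & (gj != MISSING)
    if both.sum() < min_overlap:
        raise ValueError(
            f"only {int(both.sum())} overlapping non-missing variants; need {min_overlap}"
        )
    gi, gj, p = gi[both], gj[both], p[both]
    ibs = 2 - np.abs(gi.astype(int) - gj.astype(int))
    n0 = float((ibs == 0).sum())
    n1 = float((ibs == 1).sum())
    n2 = float((ibs == 2).sum())
    e0, e1_0, e2_0, e1_1, e2_1 = _ibd_expectations(p)
    p0 = n0 / e0.sum() if e0.sum() > 0 else 0.0
    p1 = (n1 - p0 * e1_0.sum()) / e1_1.sum() if e1_1.sum() > 0 else 0.0
    p2 = (n2 - p0 * e2_0.sum() - p1 * e2_1.sum()) / len(p)
    return float(min(1.0, max(0.0, p2 + 0.5 * p1)))


# ---------------------------------------------------------------------------
# sample QC


def sample_qc(
    genotypes: GenotypeMatrix,
    thresholds: QCThresholds | None = None,
    pihat_variant_ids: list | None = None,
) -> SampleQCReport:
    """Missingness -> heterozygosity -> relatedness sample filters, in order.

    For a related pair the member with higher missingness is removed (ties
    broken by removing the lexicographically later id).  Each removed sample
    carries exactly one primary reason.
    """
    th = thresholds or QCThresholds()
    if genotypes.n_samples == 0:
        raise ValueError("empty genotype matrix")
    ids = genotypes.sample_ids
    d = genotypes.dosages
    obs = d != MISSING
    miss = genotypes.sample_missing_rate()
    reason = np.full(len(ids), "none", dtype=object)

    reason[miss > th.sample_miss_max] = "missingness"
    alive = reason == "none"

    n_obs = obs.sum(axis=1)
    het = np.where(n_obs > 0, (d == 1).sum(axis=1) / np.maximum(n_obs, 1), np.nan)
    het_z = np.full(len(ids), np.nan)
    if alive.sum() >= 2:
        mu = het[alive].mean()
        sd = het[alive].std(ddof=1)
        if sd > 0:
            het_z[alive] = (het[alive] - mu) / sd
            reason[alive & (np.abs(het_z) > th.het_sd)] = "heterozygosity"
    alive = reason == "none"

    pair_rows = []
    alive_idx = np.flatnonzero(alive)
    if len(alive_idx) >= 2:
        sub = GenotypeMatrix(d[alive_idx], ids[alive_idx], genotypes.variant_ids)
        if pihat_variant_ids is not None:
            sub = sub.subset_variants(pihat_variant_ids)
        pm = pihat_matrix(sub)
        iu, ju = np.triu_indices(len(alive_idx), k=1)
        hot = pm[iu, ju] > th.pihat_max
        flagged = [
            (alive_idx[a], alive_idx[b], pm[a, b])
            for a, b in zip(iu[hot], ju[hot])
        ]
        pair_rows = [(ids[a], ids[b], ph) for a, b, ph in flagged]
        # greedy removal, highest pi-hat first
        flagged.sort(key=lambda t: (-t[2], ids[t[0]], ids[t[1]]))
        for a, b, _ in flagged:
            if reason[a] != "none" or reason[b] != "none":
                continue
            if miss[a] > miss[b]:
                drop = a
            elif miss[b] > miss[a]:
                drop = b
            else:
                drop = a if ids[a] > ids[b] else b
            reason[drop] = "relatedness"

    table = pd.DataFrame(
        {
            "sample_id": ids,
            "missing_rate": miss,
            "het_rate": het,
            "het_z": het_z,
            "removed_reason": reason,
        }
    )
    pairs = pd.DataFrame(pair_rows, columns=["sample_i", "sample_j", "pihat"])
    retained = [s for s, r in zip(ids, reason) if r == "none"]
    return SampleQCReport(table=table, flagged_pairs=pairs, retained=retained)


# ---------------------------------------------------------------------------
# LD pruning


def ld_prune(
    genotypes: GenotypeMatrix,
    window_snps: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
    variants: pd.DataFrame | None = None,
    exclude_regions: list[tuple[str, int, int]] | None = None,
) -> list:
    """Sliding-window greedy LD pruning; keeps the earlier-position member.

    ``exclude_regions`` (chrom, start, end; 1-based inclusive) drops
    variants in long-range-LD intervals before pruning.
    """
    if not (window_snps >= step >= 1):
        raise ValueError("need window_snps >= step >= 1")
    ids = genotypes.variant_ids
    order = np.arange(len(ids))
    keep = np.ones(len(ids), dtype=bool)
    if variants is not None:
        v = variants.set_index("variant_id").loc[list(ids)]
        order = np.lexsort((v["pos"].to_numpy(), v["chrom"].to_numpy()))
        if exclude_regions:
            chrom = v["chrom"].to_numpy()
            pos = v["pos"].to_numpy()
            for c, s, e in exclude_regions:
                keep &= ~((chrom == c) & (pos >= s) & (pos <= e))

    d = genotypes.dosages.astype(np.float64)
    mask = d >= 0
    d[~mask] = np.nan
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean, d)
    sd = d.std(axis=0)
    keep &= sd > 0  # monomorphic columns carry no pruning information
    z = (d - d.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    z /= np.sqrt(d.shape[0])

    for w0 in range(0, len(order), step):
        widx = order[w0 : w0 + window_snps]
        widx = widx[keep[widx]]
        if len(widx) < 2:
            continue
        r = z[:, widx].T @ z[:, widx]
        r2 = r * r
        for a in range(len(widx)):
            if not keep[widx[a]]:
                continue
            for b in range(a + 1, len(widx)):
                if keep[widx[b]] and r2[a, b] > r2_max:
                    keep[widx[b]] = False
        if w0 + window_snps >= len(order):
            break
    return [ids[i] for i in order if keep[i]]


# ---------------------------------------------------------------------------
# PCA ancestry outliers


def _standardized(genotypes: GenotypeMatrix, rows: np.ndarray) -> np.ndarray:
    """EIGENSTRAT standardization: centre by 2p, scale by sqrt(2p(1-p))."""
    d = genotypes.dosages[rows].astype(np.float64)
    obs = d >= 0
    d[~obs] = np.nan
    p = np.nanmean(d, axis=0) / 2.0
    informative = (p > 0) & (p < 1) & ~np.isnan(p)
    d = d[:, informative]
    p = p[informative]
    z = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return np.where(np.isnan(z), 0.0, z)


def pc_outlier_removal(
    genotypes: GenotypeMatrix,
    n_iterations: int = 8,
    sd_cutoff: float = 6.0,
    n_pcs: int = 2,
) -> tuple[list, pd.DataFrame]:
    """Iterative PCA outlier removal on the first two principal components.

    Each iteration recomputes PCs on the retained samples and removes any
    sample more than ``sd_cutoff`` standard deviations from the mean on PC1
    or PC2; stops early once an iteration removes nobody.  Returns the
    retained sample ids and their final PCs (recomputed after removal).
    """
    if n_pcs < 2:
        raise ValueError("n_pcs must be >= 2")
    ids = genotypes.sample_ids
    rows = np.arange(len(ids))
    for _ in range(max(1, n_iterations)):
        if len(rows) < n_pcs + 1:
            raise ValueError("fewer retained samples than n_pcs + 1")
        z = _standardized(genotypes, rows)
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        pcs = u[:, :n_pcs] * s[:n_pcs]
        lead = pcs[:, :2]
        dev = np.abs(lead - lead.mean(axis=0)) / lead.std(axis=0, ddof=1)
        outlier = (dev > sd_cutoff).any(axis=1)
        if not outlier.any():
            break
        rows = rows[~outlier]
    if len(rows) < n_pcs + 1:
        raise ValueError("fewer retained samples than n_pcs + 1")
    z = _standardized(genotypes, rows)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    table = pd.DataFrame(pcs, columns=[f"PC{k + 1}" for k in range(n_pcs)])
    table.insert(0, "sample_id", ids[rows])
    return [ids[i] for i in rows], table
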