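"""Per-SNP case/control association via the logistic score test.

Each SNP is tested with a 1-df score test of the additive dosage term in a
logistic model whose null (covariates only, first two ancestry PCs by
default) is fitted by IRLS.  Samples with a missing call are dropped for
that SNP only, and the null model is refitted on the SNP's observed-sample
subset, so every statistic depends solely on samples with observed dosage.
With an intercept-only null the statistic reduces exactly to the
Cochran-Armitage trend chi-square.

SNPs that are monomorphic in the analysis subset, or leave fewer than two
cases or two controls after the missing-call drop, are reported untestable
rather than assigned a zero statistic, and are excluded from downstream
gene sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2 as chi2_dist

from .io import MISSING, GenotypeMatrix

CHI2_MEDIAN_1DF = 0.4549364231195724  # chi2(1) median, for genomic inflation

_SELECTORS = {
    "all_cases": ("MLI_LA", "ILI", "unclassified"),
    "MLI_LA": ("MLI_LA",),
    "ILI": ("ILI",),
}


@dataclass
class AssociationRecord:
    variant_id: str
    n_used: int
    chi2: float | None
    p: float | None
    effect_direction: int
    testable: bool


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10) -> np.ndarray:
    """Plain Newton/IRLS logistic fit; small fixed design, used for null models."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        mu = np.clip(expit(X @ beta), 1e-12, 1.0 - 1e-12)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        hess[np.diag_indices_from(hess)] += 1e-12
        delta = np.linalg.solve(hess, grad)
        beta += delta
        if np.max(np.abs(delta)) < tol:
            break
    return beta


def _batched_null_mu(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, beta0: np.ndarray,
    max_iter: int = 50, tol: float = 1e-9,
) -> np.ndarray:
    """Fitted null probabilities for many masked-sample logistic nulls at once.

    ``mask`` is (n, m): column j's null model uses only rows where mask is
    True.  Returns mu of shape (n, m); entries outside the mask are
    meaningless and must be re-masked by the caller.
    """
    n, c = X.shape
    m = mask.shape[1]
    beta = np.tile(beta0, (m, 1))
    msk = mask.astype(np.float64)
    for _ in range(max_iter):
        eta = X @ beta.T  # (n, m)
        mu = np.clip(expit(eta), 1e-12, 1.0 - 1e-12)
        w = mu * (1.0 - mu) * msk
        grad = X.T @ ((y[:, None] - mu) * msk)  # (c, m)
        hess = np.einsum("ni,nm,nj->mij", X, w, X, optimize=True)
        hess[:, np.arange(c), np.arange(c)] += 1e-12
        delta = np.linalg.solve(hess, grad.T[:, :, None])[:, :, 0]  # (m, c)
        beta += delta
        if np.max(np.abs(delta)) < tol:
            break
    return np.clip(expit(X @ beta.T), 1e-12, 1.0 - 1e-12)


def logistic_score_scan(
    G: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None,
    chunk: int = 2048,
) -> pd.DataFrame:
    """Score-test chi2 for every column of ``G`` (int dosages, -1 missing).

    The covariate matrix should not contain an intercept; one is added.
    Returns a frame with n_used, chi2, p, effect_direction and testable.
    """
    G = np.asarray(G)
    y = np.asarray(y, dtype=np.float64)
    n = len(y)
    if covariates is None or covariates.size == 0:
        X = np.ones((n, 1))
    else:
        X = np.column_stack([np.ones(n), np.asarray(covariates, dtype=np.float64)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix (with intercept) is rank deficient")
    beta0 = _irls(X, y)

    m = G.shape[1]
    out_n = np.zeros(m, dtype=int)
    out_chi2 = np.full(m, np.nan)
    out_p = np.full(m, np.nan)
    out_dir = np.zeros(m, dtype=int)
    out_ok = np.zeros(m, dtype=bool)

    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        g = G[:, lo:hi].astype(np.float64)
        mask = g != MISSING
        g = np.where(mask, g, 0.0)
        msk = mask.astype(np.float64)

        n_used = mask.sum(axis=0)
        n_case = (msk * y[:, None]).sum(axis=0)
        n_ctrl = n_used - n_case
        gmean = g.sum(axis=0) / np.maximum(n_used, 1)
        gvar = (msk * (g - gmean) ** 2).sum(axis=0)
        testable = (n_case >= 2) & (n_ctrl >= 2) & (gvar > 0)

        complete = mask.all(axis=0)
        mu = np.full_like(g, 0.5)  # placeholder for untestable columns
        if complete.any():
            mu0 = np.clip(expit(X @ beta0), 1e-12, 1.0 - 1e-12)
            mu[:, complete] = mu0[:, None]
        todo = ~complete & testable
        if todo.any():
            mu[:, todo] = _batched_null_mu(X, y, mask[:, todo], beta0)

        w = mu * (1.0 - mu) * msk
        U = (g * (y[:, None] - mu) * msk).sum(axis=0)
        a = (w * g * g).sum(axis=0)
        C = np.einsum("nm,nc->mc", w * g, X, optimize=True)
        H = np.einsum("ni,nm,nj->mij", X, w, X, optimize=True)
        H[:, np.arange(X.shape[1]), np.arange(X.shape[1])] += 1e-12
        t = np.linalg.solve(H, C[:, :, None])[:, :, 0]
        V = a - (C * t).sum(axis=1)

        ok = testable & (V > 1e-12)
        chi2 = np.where(ok, U * U / np.maximum(V, 1e-300), np.nan)
        sl = slice(lo, hi)
        out_n[sl] = n_used
        out_chi2[sl] = chi2
        out_p[sl] = np.where(ok, chi2_dist.sf(chi2, df=1), np.nan)
        out_dir[sl] = np.sign(U).astype(int)
        out_ok[sl] = ok

    return pd.DataFrame(
        {
            "n_used": out_n,
            "chi2": out_chi2,
            "p": out_p,
            "effect_direction": out_dir,
            "testable": out_ok,
        }
    )


def score_test(
    dosages: np.ndarray, status: np.ndarray, covariates: np.ndarray | None = None,
    variant_id: str = "snp",
) -> AssociationRecord:
    """Score test for a single SNP; see :func:`logistic_score_scan`."""
    res = logistic_score_scan(np.asarray(dosages).reshape(-1, 1), status, covariates)
    row = res.iloc[0]
    return AssociationRecord(
        variant_id=variant_id,
        n_used=int(row["n_used"]),
        chi2=float(row["chi2"]) if row["testable"] else None,
        p=float(row["p"]) if row["testable"] else None,
        effect_direction=int(row["effect_direction"]),
        testable=bool(row["testable"]),
    )


def genome_scan(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    pcs: pd.DataFrame,
    stratum_selector: str = "all_cases",
    n_pcs_used: int = 2,
) -> tuple[pd.DataFrame, list]:
    """Per-variant score tests for one case stratum (plus all controls).

    ``pcs`` is the table from PC outlier removal; only samples present there
    (i.e. post-QC) enter the design.  Returns the association table for
    testable variants and the list of untestable variant ids.
    """
    if stratum_selector not in _SELECTORS:
        raise ValueError(f"unknown stratum selector {stratum_selector!r}")
    case_strata = _SELECTORS[stratum_selector]
    info = samples.set_index("sample_id")
    pc_ids = [s for s in pcs["sample_id"] if s in info.index]
    strata = info.loc[pc_ids, "stratum"]
    use = [s for s in pc_ids if strata[s] == "control" or strata[s] in case_strata]
    y = (info.loc[use, "status"] == "case").to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError(f"no cases selected for stratum {stratum_selector!r}")
    if (1 - y).sum() == 0:
        raise ValueError("no controls available")

    pc_mat = pcs.set_index("sample_id").loc[use].to_numpy(dtype=float)[:, :n_pcs_used]
    rows = genotypes.sample_index(use)
    res = logistic_score_scan(genotypes.dosages[rows], y, pc_mat)
    res.insert(0, "variant_id", genotypes.variant_ids)
    testable = res[res["testable"]].drop(columns="testable").reset_index(drop=True)
    untestable = list(res.loc[~res["testable"], "variant_id"])
    return testable, untestable


def genomic_inflation(chi2: np.ndarray) -> float:
    """Genomic inflation factor: median chi2 over the chi2(1) median."""
    return float(np.nanmedian(np.asarray(chi2, dtype=float)) / CHI2_MEDIAN_1DF)
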