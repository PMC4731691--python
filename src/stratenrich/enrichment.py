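"""Gene-set enrichment by top-percentile permutation and a GSEA running sum.

The percentile test counts how many genes of a focal set fall in the top
q% of the gene universe ranked by gene-level p-value, then compares that
count against random gene sets of the same size drawn uniformly from the
universe.  Because random sets are matched on count only, the permutation
null is exactly hypergeometric -- a property the test suite exploits as a
closed-form oracle.  Permutations start at 1,000 and are escalated to
10,000 whenever the initial empirical p falls below 0.05.

The GSEA variant ranks genes by -log10 of their gene p-value and walks a
weighted running sum (hits increment by their normalised score weight,
misses decrement by 1/(N-k)); its enrichment score is the maximum
deviation from zero, and significance comes from the same random-set null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSet

PERCENTILES = (1.0, 5.0, 10.0)
_PERM_CHUNK = 2_000


@dataclass
class EnrichmentResult:
    set_name: str
    test: str  # pct1 / pct5 / pct10 / gsea
    universe_size: int
    set_size: int  # after intersection with the universe
    cut_size: int | None  # m for percentile tests, None for gsea
    observed: float  # top-m member count, or enrichment score
    n_perm: int
    n_as_extreme: int
    p_empirical: float
    escalated: bool = False
    stratum: str = ""

    def to_row(self) -> dict:
        return {
            "set": self.set_name,
            "stratum": self.stratum,
            "test": self.test,
            "N": self.universe_size,
            "k": self.set_size,
            "m": self.cut_size if self.cut_size is not None else "",
            "observed": self.observed,
            "n_perm": self.n_perm,
            "n_as_extreme": self.n_as_extreme,
            "p_empirical": self.p_empirical,
            "escalated": self.escalated,
        }


def _ranked_universe(gene_results: pd.DataFrame) -> pd.DataFrame:
    """Genes ranked by ascending p, ties by larger observed sum then id."""
    df = gene_results.copy()
    df["_neg_sum"] = -df["observed_sum"].to_numpy(dtype=float)
    df = df.sort_values(["p_empirical", "_neg_sum", "gene_id"], kind="mergesort")
    return df.drop(columns="_neg_sum").reset_index(drop=True)


def percentile_cut(n_universe: int, q: float) -> int:
    if not (0.0 < q < 100.0):
        raise ValueError("percentile must lie in (0, 100)")
    return max(1, int(round(q * n_universe / 100.0)))


def top_percentile_membership(gene_results: pd.DataFrame, q: float) -> set:
    """Ids of the genes in the top q% of the universe (deterministic ties)."""
    if len(gene_results) == 0:
        raise ValueError("empty gene universe")
    ranked = _ranked_universe(gene_results)
    m = percentile_cut(len(ranked), q)
    return set(ranked["gene_id"].iloc[:m])


def _random_set_counts(
    rng: np.random.Generator, n_perm: int, n_universe: int, k: int, top_mask: np.ndarray
) -> np.ndarray:
    """Top-m member counts of random k-subsets of the universe, vectorised."""
    counts = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(_PERM_CHUNK, n_perm - done)
        keys = rng.random((b, n_universe))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        counts[done : done + b] = top_mask[idx].sum(axis=1)
        done += b
    return counts


def percentile_enrichment_test(
    gene_results: pd.DataFrame,
    gene_set: GeneSet,
    q: float,
    n_perm_initial: int = 1_000,
    n_perm_escalated: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of focal-set membership in the top q% of genes.

    Each permutation draws k genes uniformly without replacement from the
    universe and counts how many land in the same top-m set; the p-value is
    the proportion of permutations with a count at least the observed one.
    If the initial p (1,000 draws) is below 0.05 the test reruns at 10,000
    draws with a fresh derived seed and the escalated result is reported.
    """
    ranked = _ranked_universe(gene_results)
    universe = ranked["gene_id"].to_numpy()
    n_universe = len(universe)
    members = set(gene_set.genes) & set(universe)
    k = len(members)
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} is empty after intersection")
    if k > n_universe:
        raise ValueError("gene set larger than the universe")
    m = percentile_cut(n_universe, q)
    top_mask = np.zeros(n_universe, dtype=bool)
    top_mask[:m] = True  # ranked order: first m rows are the top percentile
    observed = int(sum(top_mask[i] for i, g in enumerate(universe) if g in members))

    ss = np.random.SeedSequence(seed)
    child_initial, child_escalated = ss.spawn(2)
    counts = _random_set_counts(
        np.random.default_rng(child_initial), n_perm_initial, n_universe, k, top_mask
    )
    n_extreme = int((counts >= observed).sum())
    p = n_extreme / n_perm_initial
    escalated = False
    n_perm = n_perm_initial
    if p < 0.05:
        counts = _random_set_counts(
            np.random.default_rng(child_escalated), n_perm_escalated, n_universe, k, top_mask
        )
        n_extreme = int((counts >= observed).sum())
        n_perm = n_perm_escalated
        p = n_extreme / n_perm_escalated
        escalated = True
    return EnrichmentResult(
        set_name=gene_set.name,
        test=f"pct{q:g}",
        universe_size=n_universe,
        set_size=k,
        cut_size=m,
        observed=observed,
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        p_empirical=p,
        escalated=escalated,
    )


# ---------------------------------------------------------------------------
# GSEA


def _gene_scores(ranked: pd.DataFrame) -> np.ndarray:
    """-log10 gene p-values; empirical zeros get half their resolution."""
    p = ranked["p_empirical"].to_numpy(dtype=float)
    if "n_sims" in ranked.columns:
        floor = 0.5 / ranked["n_sims"].to_numpy(dtype=float)
    else:
        pos = p[p > 0]
        floor = np.full_like(p, (pos.min() / 2.0) if len(pos) else 1e-16)
    return -np.log10(np.maximum(p, floor))


def _running_sum_es(hits: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    """Signed max-deviation enrichment score for each row of a hit matrix."""
    n = hits.shape[1]
    w_hit = hits * weights
    denom = w_hit.sum(axis=1, keepdims=True)
    inc = np.divide(w_hit, denom, out=np.zeros_like(w_hit), where=denom > 0)
    inc -= (1.0 - hits) / (n - k)
    run = np.cumsum(inc, axis=1)
    arg = np.argmax(np.abs(run), axis=1)
    return run[np.arange(len(run)), arg]


def gsea_test(
    gene_results: pd.DataFrame,
    gene_set: GeneSet,
    n_perm: int = 1_000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Weighted running-sum enrichment over the full gene ranking.

    Null enrichment scores come from random same-size gene sets (scores
    fixed, membership permuted); the p-value is the proportion of null
    scores at least the observed one.
    """
    ranked = _ranked_universe(gene_results)
    universe = ranked["gene_id"].to_numpy()
    n_universe = len(universe)
    members = set(gene_set.genes) & set(universe)
    k = len(members)
    if k == 0:
        raise ValueError(f"gene set {gene_set.name!r} is empty after intersection")
    if k >= n_universe:
        raise ValueError("gene set must be a strict subset of the universe")

    scores = _gene_scores(ranked)
    weights = np.abs(scores) ** weight_exponent
    hit = np.isin(universe, list(members)).astype(np.float64)
    observed = float(_running_sum_es(hit[None, :], weights, k)[0])

    rng = np.random.default_rng(seed)
    n_extreme = 0
    done = 0
    while done < n_perm:
        b = min(_PERM_CHUNK, n_perm - done)
        keys = rng.random((b, n_universe))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null_hits = np.zeros((b, n_universe))
        null_hits[np.repeat(np.arange(b), k), idx.ravel()] = 1.0
        es = _running_sum_es(null_hits, weights, k)
        n_extreme += int((es >= observed).sum())
        done += b
    p = n_extreme / n_perm
    return EnrichmentResult(
        set_name=gene_set.name,
        test="gsea",
        universe_size=n_universe,
        set_size=k,
        cut_size=None,
        observed=observed,
        n_perm=n_perm,
        n_as_extreme=n_extreme,
        p_empirical=p,
    )


def subcomplex_scan(
    gene_results: pd.DataFrame,
    subcomplexes: list[GeneSet],
    q_list=PERCENTILES,
    n_perm_initial: int = 1_000,
    n_perm_escalated: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Percentile tests per subcomplex and percentile; raw p-values, no
    multiplicity adjustment (follow-up scans are reported descriptively)."""
    universe = set(gene_results["gene_id"])
    rows = []
    for si, gs in enumerate(sorted(subcomplexes, key=lambda g: g.name)):
        if not set(gs.genes) & universe:
            warnings.warn(f"subcomplex {gs.name!r} has no genes in the universe; skipped")
            continue
        for qi, q in enumerate(q_list):
            res = percentile_enrichment_test(
                gene_results,
                gs,
                q,
                n_perm_initial=n_perm_initial,
                n_perm_escalated=n_perm_escalated,
                seed=int(np.random.SeedSequence([seed, si, qi]).generate_state(1)[0] % (2**31)),
            )
            rows.append(res.to_row())
    return pd.DataFrame(rows)
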