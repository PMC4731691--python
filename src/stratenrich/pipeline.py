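"""End-to-end stratified enrichment study: QC -> association -> gene tests
-> pathway enrichment, run for three phenotype contrasts.

The study design mirrors a lacunar-stroke style subtype analysis: every
contrast compares one case stratum (all cases, the MLI/LA-like stratum, or
the ILI-like stratum) against the shared controls.  Each contrast runs four
enrichment tests on the focal pathway (top 1%, 5% and 10% percentile
permutation tests plus GSEA), giving a fixed 12-cell report evaluated
against a Bonferroni-corrected threshold alpha/12 = 0.0042 at the default
family-wise level of 0.05.  Subcomplex scans run as a follow-up only in
strata whose top-1% pathway test is significant.

Every stochastic stage draws from a child seed derived deterministically
from the master seed, so a study is exactly reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .association import genome_scan, genomic_inflation
from .enrichment import (
    EnrichmentResult,
    gsea_test,
    percentile_enrichment_test,
    subcomplex_scan,
)
from .gene_level import gene_scan, map_snps_to_genes
from .io import GeneSet
from .qc import QCThresholds, ld_prune, pc_outlier_removal, sample_qc, variant_qc
from .synthetic_data import PATHWAY_NAME, SimulationConfig, SyntheticStudy, simulate_study

CONTRASTS = ("all", "MLI_LA", "ILI")
TESTS = ("pct1", "pct5", "pct10", "gsea")
_SELECTOR_OF = {"all": "all_cases", "MLI_LA": "MLI_LA", "ILI": "ILI"}


class BonferroniThreshold(NamedTuple):
    threshold: float
    rounded: float


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 12) -> BonferroniThreshold:
    """Per-test threshold alpha/n_tests, with its 4-decimal rounding."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    full = alpha / n_tests
    return BonferroniThreshold(full, round(full, 4))


@dataclass
class PipelineConfig:
    qc: QCThresholds = field(default_factory=QCThresholds)
    window_kb: float = 50.0
    vegas_sims: int = 1_000
    vegas_max_sims: int = 100_000
    q_list: tuple = (1.0, 5.0, 10.0)
    n_perm: int = 1_000
    n_perm_escalated: int = 10_000
    alpha: float = 0.05
    n_tests: int = 12
    n_pcs: int = 2
    gsea_weight: float = 1.0
    force_subcomplexes: bool = False
    long_range_ld_regions: tuple = ()


@dataclass
class StudyReport:
    cells: dict  # (stratum, test) -> EnrichmentResult; exactly 12 cells
    alpha: float
    alpha_star: float
    alpha_star_rounded: float
    significant: dict  # (stratum, test) -> bool
    subcomplexes: dict  # stratum -> DataFrame (only strata followed up)
    gene_results: dict  # stratum -> DataFrame
    provenance: dict

    def cell(self, stratum: str, test: str) -> EnrichmentResult:
        return self.cells[(stratum, test)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_row() for r in self.cells.values()])


def _child_seed(master: int, *codes: int) -> int:
    return int(np.random.SeedSequence([int(master), *map(int, codes)]).generate_state(1)[0] % (2**31))


def _pathway_set(gene_sets: list[GeneSet]) -> GeneSet:
    for gs in gene_sets:
        if gs.parent is None and gs.name == PATHWAY_NAME:
            return gs
    for gs in gene_sets:
        if gs.parent is None:
            return gs
    raise ValueError("no parent pathway gene set found")


def run_study(
    study: SyntheticStudy | SimulationConfig,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> StudyReport:
    """Run the full stratified enrichment analysis and fill the 12-cell report.

    ``study`` is either an assembled study (simulated or loaded from disk)
    or a :class:`SimulationConfig`, in which case the cohort is generated
    first.  Any stage failure is re-raised with the stage and stratum named.
    """
    cfg = config or PipelineConfig()
    if isinstance(study, SimulationConfig):
        study = simulate_study(study)

    prov: dict = {"seed": seed, "n_samples_raw": study.genotypes.n_samples,
                  "n_variants_raw": study.genotypes.n_variants}

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    variant_report, gm = stage(
        "variant_qc", variant_qc, study.genotypes, study.variants, study.samples, cfg.qc
    )
    prov["n_variants_pass"] = gm.n_variants

    pruned = stage(
        "ld_prune", ld_prune, gm, cfg.qc.ld_window_snps, cfg.qc.ld_step, cfg.qc.ld_r2_max,
        variants=study.variants, exclude_regions=list(cfg.long_range_ld_regions),
    )
    prov["n_variants_pruned"] = len(pruned)

    sqc = stage("sample_qc", sample_qc, gm, cfg.qc, pruned)
    gm = gm.subset_samples(sqc.retained)
    prov["n_samples_pass"] = gm.n_samples

    retained, pcs = stage(
        "pc_outlier_removal", pc_outlier_removal, gm.subset_variants(pruned),
        cfg.qc.pc_iterations, cfg.qc.pc_sd, max(2, cfg.n_pcs),
    )
    gm = gm.subset_samples(retained)
    prov["n_samples_final"] = gm.n_samples
    samples = study.samples[study.samples["sample_id"].isin(retained)].reset_index(drop=True)
    prov["n_cases_final"] = {
        s: int((samples["stratum"] == s).sum()) for s in ("MLI_LA", "ILI", "unclassified")
    }
    prov["n_controls_final"] = int((samples["stratum"] == "control").sum())

    post_variants = study.variants[
        study.variants["variant_id"].isin(list(gm.variant_ids))
    ].reset_index(drop=True)
    windows, empty_genes = stage(
        "map_snps_to_genes", map_snps_to_genes, post_variants, study.genes, cfg.window_kb
    )
    prov["n_genes_without_snps"] = len(empty_genes)

    alpha_full, alpha_round = bonferroni_threshold(cfg.alpha, cfg.n_tests)
    pathway = _pathway_set(study.gene_sets)
    subsets = [gs for gs in study.gene_sets if gs.parent == pathway.name]

    cells: dict = {}
    significant: dict = {}
    sub_tables: dict = {}
    gene_tables: dict = {}
    prov["universe_size"] = {}
    prov["lambda_gc"] = {}

    for ci, contrast in enumerate(CONTRASTS):
        selector = _SELECTOR_OF[contrast]
        strata = ("control",) + (
            ("MLI_LA", "ILI", "unclassified") if contrast == "all" else (contrast,)
        )
        sel_samples = samples[samples["stratum"].isin(strata)]
        if (sel_samples["status"] == "case").sum() == 0:
            raise RuntimeError(f"pipeline stage 'genome_scan' [{contrast}]: empty stratum")
        assoc, untestable = stage(
            f"genome_scan[{contrast}]", genome_scan, gm, samples, pcs, selector, cfg.n_pcs
        )
        prov["lambda_gc"][contrast] = genomic_inflation(assoc["chi2"].to_numpy())

        gm_contrast = gm.subset_samples(list(sel_samples["sample_id"]))
        genes_df = stage(
            f"gene_scan[{contrast}]", gene_scan, assoc, windows, gm_contrast,
            cfg.vegas_sims, _child_seed(seed, 1, ci), cfg.vegas_max_sims,
        )
        gene_tables[contrast] = genes_df
        prov["universe_size"][contrast] = len(genes_df)

        for qi, q in enumerate(cfg.q_list):
            res = stage(
                f"percentile_enrichment[{contrast},q={q:g}]",
                percentile_enrichment_test, genes_df, pathway, q,
                cfg.n_perm, cfg.n_perm_escalated, _child_seed(seed, 2, ci, qi),
            )
            res.stratum = contrast
            cells[(contrast, f"pct{q:g}")] = res
        res = stage(
            f"gsea[{contrast}]", gsea_test, genes_df, pathway,
            cfg.n_perm, _child_seed(seed, 3, ci), cfg.gsea_weight,
        )
        res.stratum = contrast
        cells[(contrast, "gsea")] = res

        for test in TESTS:
            significant[(contrast, test)] = cells[(contrast, test)].p_empirical < alpha_full

        if subsets and (significant[(contrast, "pct1")] or cfg.force_subcomplexes):
            sub_tables[contrast] = stage(
                f"subcomplex_scan[{contrast}]", subcomplex_scan, genes_df, subsets,
                cfg.q_list, cfg.n_perm, cfg.n_perm_escalated, _child_seed(seed, 4, ci),
            )
            sub_tables[contrast]["stratum"] = contrast

    prov["variant_qc_fail_counts"] = {
        c: int(variant_report[c].sum())
        for c in ("fail_maf", "fail_missing", "fail_hwe", "fail_ambiguous", "fail_diffmiss")
    }
    prov["sample_removed_reasons"] = (
        sqc.table[sqc.table["removed_reason"] != "none"]["removed_reason"]
        .value_counts().to_dict()
    )
    prov["n_pc_outliers"] = prov["n_samples_pass"] - prov["n_samples_final"]

    return StudyReport(
        cells=cells,
        alpha=cfg.alpha,
        alpha_star=alpha_full,
        alpha_star_rounded=alpha_round,
        significant=significant,
        subcomplexes=sub_tables,
        gene_results=gene_tables,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# report output


def format_report_table(report: StudyReport) -> str:
    """Human-readable 12-cell table (tests as rows, contrasts as columns)."""
    lines = [f"Pathway enrichment (threshold p < {report.alpha_star_rounded:g})", ""]
    header = f"{'test':<8}" + "".join(f"{c:>14}" for c in CONTRASTS)
    lines.append(header)
    lines.append("-" * len(header))
    for test in TESTS:
        row = f"{test:<8}"
        for c in CONTRASTS:
            res = report.cells[(c, test)]
            mark = "*" if report.significant[(c, test)] else ""
            row += f"{res.p_empirical:>13.4g}{mark or ' '}"
        lines.append(row)
    return "\n".join(lines) + "\n"


def write_report(report: StudyReport, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / "enrichment.tsv", sep="\t", index=False)
    for stratum, df in report.gene_results.items():
        df.to_csv(out / f"genes_{stratum}.tsv", sep="\t", index=False)
    for stratum, df in report.subcomplexes.items():
        df.to_csv(out / f"subcomplexes_{stratum}.tsv", sep="\t", index=False)
    payload = {
        "alpha": report.alpha,
        "alpha_star": report.alpha_star,
        "alpha_star_rounded": report.alpha_star_rounded,
        "significant": {f"{s}:{t}": bool(v) for (s, t), v in report.significant.items()},
        "provenance": report.provenance,
    }
    (out / "report.json").write_text(json.dumps(payload, indent=2, default=str))
    (out / "table.txt").write_text(format_report_table(report))
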