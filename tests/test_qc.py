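"""QC filters against enumeration oracles and constructed fixtures."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from stratenrich import (
    SimulationConfig,
    estimate_pihat,
    hwe_exact_test,
    ld_prune,
    pc_outlier_removal,
    sample_qc,
    simulate_study,
    variant_qc,
)

from conftest import make_genotypes


def hwe_enumeration_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact-rational Levene-Haldane enumeration, independent of the package."""
    n = n_hom_ref + n_het + n_hom_alt
    na = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    nA = 2 * n - na
    if na == 0:
        return 1.0
    probs = {}
    for h in range(na % 2, na + 1, 2):
        n_rare = (na - h) // 2
        n_common = n - h - n_rare
        probs[h] = (
            Fraction(factorial(n), factorial(n_rare) * factorial(h) * factorial(n_common))
            * Fraction(2**h)
            * Fraction(factorial(na) * factorial(nA), factorial(2 * n))
        )
    obs = probs[n_het]
    return float(min(Fraction(1), sum(p for p in probs.values() if p <= obs)))


class TestHweExactTest:
    def test_monomorphic_site_is_certain(self):
        assert hwe_exact_test(100, 0, 0) == 1.0

    @pytest.mark.parametrize("counts", [(10, 5, 10), (0, 100, 0), (50, 21, 3), (1, 1, 1)])
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            hwe_enumeration_oracle(*counts), abs=1e-12
        )

    def test_random_sweep_matches_oracle(self, rng):
        for _ in range(60):
            counts = tuple(int(x) for x in rng.integers(0, 67, size=3))
            if sum(counts) == 0:
                continue
            assert hwe_exact_test(*counts) == pytest.approx(
                hwe_enumeration_oracle(*counts), abs=1e-12
            )

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)


def _hwe_column(n: int, p: float) -> np.ndarray:
    """Deterministic dosage column with exact HWE-proportion counts."""
    n_aa = int(round(n * p * p))
    n_het = int(round(n * 2 * p * (1 - p)))
    n_ref = n - n_aa - n_het
    return np.repeat([0, 1, 2], [n_ref, n_het, n_aa]).astype(np.int8)


def _qc_fixture():
    """10 variants over 200 cases + 200 controls; one designed failure each."""
    n = 400
    half = n // 2  # first half cases, second half controls

    def balanced(p):  # same HWE-exact composition in both halves
        return np.concatenate([_hwe_column(half, p), _hwe_column(half, p)])

    cols = {}
    cols["v_maf"] = np.zeros(n, np.int8)
    cols["v_maf"][0] = 1  # maf 1/800 < 0.01
    cols["v_miss"] = balanced(0.4)
    miss_idx = np.concatenate([np.arange(0, 200, 30), 200 + np.arange(0, 180, 30)])
    cols["v_miss"][miss_idx] = -1  # 13 missing = 3.25% > 3%, balanced across status
    cols["v_hwe"] = np.concatenate(
        [_hwe_column(half, 0.5), np.repeat([0, 2], [100, 100])]
    ).astype(np.int8)  # controls: no hets at maf 0.5
    cols["v_amb"] = balanced(0.4)  # will be written as A/T
    cols["v_diffmiss"] = balanced(0.4)
    cols["v_diffmiss"][:12] = -1  # 12 missing, all cases: 3% overall, p<0.05
    cols["v_boundary"] = np.zeros(n, np.int8)
    cols["v_boundary"][:4] = 1
    cols["v_boundary"][200:204] = 1  # maf exactly 8/800 = 0.01: retained
    for i in range(4):
        col = balanced(0.3 + 0.05 * i)
        cols[f"v_pass{i + 1}"] = np.concatenate(
            [np.roll(col[:half], i * 7), np.roll(col[half:], i * 7)]
        )

    d = np.column_stack(list(cols.values()))
    ids = list(cols.keys())
    gm = make_genotypes(d)
    gm.variant_ids = np.array(ids, dtype=object)
    variants = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "chr1",
            "pos": np.arange(1, len(ids) + 1) * 1000,
            "ref": ["A"] * len(ids),
            "alt": ["T" if v == "v_amb" else "C" for v in ids],
        }
    )
    variants["ambiguous"] = variants["alt"] == "T"
    samples = pd.DataFrame(
        {
            "sample_id": list(gm.sample_ids),
            "status": ["case"] * half + ["control"] * half,
            "stratum": ["MLI_LA"] * half + ["control"] * half,
            "subpop": "pop0",
        }
    )
    return gm, variants, samples


class TestVariantQC:
    def test_each_designed_failure_is_labelled(self):
        gm, variants, samples = _qc_fixture()
        report, filtered = variant_qc(gm, variants, samples)
        verdict = report.set_index("variant_id")
        assert bool(verdict.loc["v_maf", "fail_maf"])
        assert bool(verdict.loc["v_miss", "fail_missing"])
        assert bool(verdict.loc["v_hwe", "fail_hwe"])
        assert bool(verdict.loc["v_amb", "fail_ambiguous"])
        assert bool(verdict.loc["v_diffmiss", "fail_diffmiss"])
        for c in ("fail_maf", "fail_missing", "fail_hwe", "fail_ambiguous", "fail_diffmiss"):
            assert int(verdict[c].sum()) == 1, c
        assert filtered.n_variants == 5
        assert "v_boundary" in filtered.variant_ids  # maf exactly 0.01 retained

    def test_all_pass_fixture_is_identity(self):
        gm, variants, samples = _qc_fixture()
        keep = [v for v in gm.variant_ids if v.startswith("v_pass") or v == "v_boundary"]
        sub = gm.subset_variants(keep)
        report, filtered = variant_qc(sub, variants, samples)
        assert report["pass_qc"].all()
        np.testing.assert_array_equal(filtered.dosages, sub.dosages)

    def test_idempotent_on_own_output(self):
        gm, variants, samples = _qc_fixture()
        _, once = variant_qc(gm, variants, samples)
        report2, twice = variant_qc(once, variants, samples)
        assert report2["pass_qc"].all()
        np.testing.assert_array_equal(twice.dosages, once.dosages)

    def test_requires_controls_for_hwe_filter(self):
        gm, variants, samples = _qc_fixture()
        samples = samples.assign(status="case", stratum="MLI_LA")
        with pytest.raises(ValueError, match="HWE"):
            variant_qc(gm, variants, samples)


class TestPihat:
    @staticmethod
    def _binomial_gm(rng, n, m, dup_of=None):
        p = rng.uniform(0.2, 0.5, m)
        d = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        if dup_of is not None:
            d[-1] = d[dup_of]
        return make_genotypes(d), p

    def test_duplicate_pair_near_one_across_snp_counts(self, rng):
        prev = 0.0
        for m in (500, 2_000, 10_000):
            gm, _ = self._binomial_gm(np.random.default_rng(4), 30, m, dup_of=0)
            ph = estimate_pihat(gm, gm.sample_ids[0], gm.sample_ids[-1])
            assert ph >= max(0.95, prev - 1e-9)
            prev = ph

    def test_unrelated_pair_near_zero(self, rng):
        gm, _ = self._binomial_gm(rng, 40, 1_000)
        assert estimate_pihat(gm, "s1", "s2") < 0.12

    def test_one_shared_haplotype_matches_counting_oracle(self):
        r = np.random.default_rng(12)
        m = 2_000
        p = r.uniform(0.3, 0.5, m)
        shared = (r.random(m) < p).astype(np.int8)
        own = (r.random((8, m)) < p).astype(np.int8)
        d = np.vstack([shared + own[i] for i in range(8)])
        gm = make_genotypes(d)
        got = estimate_pihat(gm, "s1", "s2")

        # oracle: recompute the moments estimator by direct counting
        freq = d.mean(axis=0) / 2.0
        q = 1 - freq
        gi, gj = d[0].astype(int), d[1].astype(int)
        ibs = 2 - np.abs(gi - gj)
        n0, n1, n2 = [(ibs == k).sum() for k in (0, 1, 2)]
        e0 = (2 * freq**2 * q**2).sum()
        e1_0 = (4 * freq**3 * q + 4 * freq * q**3).sum()
        e2_0 = m - e0 - e1_0
        e1_1 = (2 * freq * q).sum()
        e2_1 = m - e1_1
        p0 = n0 / e0
        p1 = (n1 - p0 * e1_0) / e1_1
        p2 = (n2 - p0 * e2_0 - p1 * e2_1) / m
        want = min(1.0, max(0.0, p2 + 0.5 * p1))
        assert got == pytest.approx(want, abs=1e-9)
        assert 0.3 < got < 0.7  # one shared haplotype ~ pi-hat 1/2

    def test_insufficient_overlap_rejected(self):
        gm = make_genotypes(np.ones((2, 50), np.int8))
        with pytest.raises(ValueError, match="overlap"):
            estimate_pihat(gm, "s1", "s2")


class TestSampleQC:
    def test_clean_cohort_no_removals(self):
        r = np.random.default_rng(6)
        d = r.binomial(2, 0.3, size=(40, 800)).astype(np.int8)
        report = sample_qc(make_genotypes(d))
        assert report.retained == list(make_genotypes(d).sample_ids)

    def test_high_missingness_sample_removed_first(self):
        r = np.random.default_rng(6)
        d = r.binomial(2, 0.3, size=(40, 800)).astype(np.int8)
        d[3, r.random(800) < 0.10] = -1
        report = sample_qc(make_genotypes(d))
        removed = report.table[report.table["removed_reason"] != "none"]
        assert list(removed["sample_id"]) == ["s4"]
        assert list(removed["removed_reason"]) == ["missingness"]

    def test_duplicated_sample_loses_one_member(self):
        cfg = SimulationConfig(
            n_controls=40, n_cases_stratumA=0, n_cases_stratumB=0,
            n_genes=400, snps_per_gene=4, ld_rho=0.0, pathway_size=4,
            n_causal_genes=0, causal_or=1.0, missing_rate=0.0,
            n_duplicate_samples=1, seed=9,
        )
        study = simulate_study(cfg)
        report = sample_qc(study.genotypes)
        related = report.table[report.table["removed_reason"] == "relatedness"]
        assert len(related) == 1
        assert related["sample_id"].iloc[0].startswith("ctrl_00001")


class TestLdPrune:
    def test_identical_columns_keep_one(self, rng):
        c = rng.binomial(2, 0.4, 100).astype(np.int8)
        gm = make_genotypes(np.column_stack([c, c]))
        assert ld_prune(gm, window_snps=5, step=1) == ["v1"]

    def test_independent_columns_all_kept(self, rng):
        d = rng.binomial(2, 0.4, size=(500, 10)).astype(np.int8)
        gm = make_genotypes(d)
        assert len(ld_prune(gm, window_snps=5, step=2, r2_max=0.2)) == 10

    def test_matches_brute_force_greedy_oracle(self, rng):
        base = rng.binomial(2, 0.5, 200).astype(np.int8)
        noisy = base.copy()
        flip = rng.random(200) < 0.2
        noisy[flip] = rng.integers(0, 3, int(flip.sum()))
        cols = np.column_stack(
            [base, base, noisy, rng.binomial(2, 0.3, 200), rng.binomial(2, 0.3, 200)]
        ).astype(np.int8)
        gm = make_genotypes(cols)
        got = ld_prune(gm, window_snps=5, step=5, r2_max=0.2)

        r2 = np.corrcoef(cols.T) ** 2
        keep = [True] * 5
        for a in range(5):
            if not keep[a]:
                continue
            for b in range(a + 1, 5):
                if keep[b] and r2[a, b] > 0.2:
                    keep[b] = False
        want = [f"v{i + 1}" for i in range(5) if keep[i]]
        assert got == want

    def test_exclusion_regions_drop_variants(self, rng):
        d = rng.binomial(2, 0.4, size=(100, 4)).astype(np.int8)
        gm = make_genotypes(d)
        variants = pd.DataFrame(
            {"variant_id": list(gm.variant_ids), "chrom": "chr1",
             "pos": [100, 200, 5000, 6000]}
        )
        kept = ld_prune(gm, 5, 1, 0.99, variants=variants,
                        exclude_regions=[("chr1", 1, 300)])
        assert set(kept) == {"v3", "v4"}


class TestPCOutliers:
    # the outlier fraction must stay below ~1/37 or a 6-SD rule cannot fire:
    # for fraction f the standardised deviation of a far cluster is sqrt((1-f)/f)
    @staticmethod
    def _cohort_with_outliers(n_main=295, n_out=5, m=400, seed=3):
        r = np.random.default_rng(seed)
        p = r.uniform(0.2, 0.8, m)
        d_main = r.binomial(2, p, size=(n_main, m))
        shifted = np.clip(p + np.where(p < 0.5, 0.45, -0.45), 0.02, 0.98)
        d_out = r.binomial(2, shifted, size=(n_out, m))
        return make_genotypes(np.vstack([d_main, d_out]).astype(np.int8))

    def test_homogeneous_cohort_all_retained(self, rng):
        d = rng.binomial(2, 0.3, size=(60, 300)).astype(np.int8)
        gm = make_genotypes(d)
        retained, pcs = pc_outlier_removal(gm, sd_cutoff=6.0)
        assert retained == list(gm.sample_ids)
        assert list(pcs.columns) == ["sample_id", "PC1", "PC2"]

    def test_shifted_subpopulation_removed_matches_eigen_oracle(self):
        gm = self._cohort_with_outliers()
        retained, _ = pc_outlier_removal(gm, n_iterations=8, sd_cutoff=6.0)
        expected_removed = {f"s{i}" for i in range(296, 301)}
        assert set(gm.sample_ids) - set(retained) == expected_removed

        # oracle: independent eigendecomposition of the GRM + the 6-SD rule
        d = gm.dosages.astype(float)
        p = d.mean(axis=0) / 2
        ok = (p > 0) & (p < 1)
        z = (d[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        vals, vecs = np.linalg.eigh(z @ z.T)
        lead = vecs[:, ::-1][:, :2] * np.sqrt(np.maximum(vals[::-1][:2], 0))
        dev = np.abs(lead - lead.mean(0)) / lead.std(0, ddof=1)
        oracle_removed = {gm.sample_ids[i] for i in np.flatnonzero((dev > 6).any(1))}
        assert oracle_removed == expected_removed

    def test_deterministic_up_to_sign(self):
        gm = self._cohort_with_outliers(seed=11)
        r1, pcs1 = pc_outlier_removal(gm)
        r2, pcs2 = pc_outlier_removal(gm)
        assert r1 == r2
        for c in ("PC1", "PC2"):
            a, b = pcs1[c].to_numpy(), pcs2[c].to_numpy()
            assert np.allclose(a, b) or np.allclose(a, -b)

    def test_too_few_samples_rejected(self):
        gm = make_genotypes(np.array([[0, 1, 2], [1, 1, 0]], np.int8))
        with pytest.raises(ValueError, match="n_pcs"):
            pc_outlier_removal(gm)
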