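"""SNP QC, GRM, LMM and LD-multiplicity checks against oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biotypeflow import genetics


def brute_force_hwe(n_het, n_hom_rare, n_hom_common):
    """Exact HWE p by direct enumeration with exact rational-free probs."""
    n = n_het + n_hom_rare + n_hom_common
    rare = min(2 * n_hom_rare + n_het, 2 * n_hom_common + n_het)
    from math import comb

    def weight(h):
        r = (rare - h) // 2
        c = n - h - r
        # multinomial count of genotype configurations times 2^het
        from math import factorial
        return 2**h / (factorial(r) * factorial(h) * factorial(c))

    hs = list(range(rare % 2, rare + 1, 2))
    ws = np.array([weight(h) for h in hs])
    ws = ws / ws.sum()
    obs = ws[hs.index(n_het)]
    return float(ws[ws <= obs * (1 + 1e-12)].sum())


class TestHweExact:
    @pytest.mark.parametrize(
        "het,hom_r,hom_c",
        [(50, 25, 25), (10, 1, 39), (0, 5, 45), (21, 10, 19), (3, 0, 47)],
    )
    def test_matches_enumeration_oracle(self, het, hom_r, hom_c):
        assert genetics.hwe_exact_pvalue(het, hom_r, hom_c) == pytest.approx(
            brute_force_hwe(het, hom_r, hom_c), abs=1e-9
        )

    def test_perfect_hwe_counts_have_high_p(self):
        assert genetics.hwe_exact_pvalue(50, 25, 25) >= 0.5

    def test_extreme_disequilibrium_has_tiny_p(self):
        # all heterozygotes missing despite intermediate allele frequency
        assert genetics.hwe_exact_pvalue(0, 50, 50) < 1e-7


class TestMaf:
    def test_monomorphic_is_zero(self):
        assert genetics.maf(np.zeros(40)) == 0.0

    def test_balanced_counts_give_half(self):
        d = np.array([0] * 30 + [1] * 40 + [2] * 30, dtype=float)
        assert genetics.maf(d) == pytest.approx(0.5)

    def test_folding_above_half(self):
        d = np.array([0] * 9 + [1] * 42 + [2] * 49, dtype=float)
        assert genetics.maf(d) == pytest.approx(0.3)

    def test_missing_excluded_from_denominator(self):
        d = np.array([1.0, 0.0, np.nan, np.nan])
        assert genetics.maf(d) == pytest.approx(0.25)


def _panel(dosages, pops=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return genetics.GenotypePanel(
        dosages=dosages,
        snp_ids=np.array([f"rs{j}" for j in range(m)]),
        chrom=np.array(["1"] * m) if chrom is None else np.asarray(chrom),
        pos=np.arange(1, m + 1) * 100,
        populations=np.array(["EA"] * n) if pops is None else np.asarray(pops),
    )


class TestSnpQc:
    def test_low_call_rate_removed(self, rng):
        good = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        bad = good.copy()
        bad[:10] = np.nan
        panel = _panel(np.hstack([good, bad]))
        kept, flags = genetics.snp_qc(panel)
        assert list(flags["pass_call_rate"]) == [True, False]
        assert kept.n_snps == 1

    def test_hwe_conforming_snp_retained(self):
        d = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=float)[:, None]
        panel = _panel(np.hstack([d, d]))
        kept, flags = genetics.snp_qc(panel)
        assert flags["pass_hwe"].all() and kept.n_snps == 2

    def test_low_maf_in_one_population_removed(self, rng):
        # minor-allele count 4 in a 60-subject population: MAF 0.033 < 0.05
        pops = np.array(["EA"] * 60 + ["AA"] * 60)
        common = rng.binomial(2, 0.3, size=(120, 1)).astype(float)
        rare = common.copy()
        rare[:60] = 0.0
        rare[:4, 0] = 1.0
        panel = _panel(np.hstack([common, rare]), pops=pops)
        kept, flags = genetics.snp_qc(panel)
        assert list(flags["pass_maf"]) == [True, False]

    def test_all_removed_raises_with_counts(self):
        d = np.full((50, 2), np.nan)
        d[:10] = 1.0
        with pytest.raises(ValueError, match="call-rate"):
            genetics.snp_qc(_panel(d))

    def test_rule_order_independence(self, rng):
        """Applying each rule as a standalone filter, in any order, agrees."""
        n = 80
        d = rng.binomial(2, rng.uniform(0.05, 0.5, 30), size=(n, 30)).astype(float)
        d[rng.random((n, 30)) < 0.04] = np.nan
        panel = _panel(d)
        _, flags = genetics.snp_qc(panel)
        joint = flags["retained"].to_numpy()
        sequential = flags["pass_call_rate"] & flags["pass_hwe"] & flags["pass_maf"]
        assert np.array_equal(joint, sequential.to_numpy())


class TestGrm:
    def test_duplicated_subject_matches_diagonal(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 300), size=(40, 300)).astype(float)
        d[1] = d[0]
        k = genetics.compute_grm(_panel(d))
        assert k[0, 1] == pytest.approx(k[0, 0], abs=1e-10)

    def test_unrelated_offdiagonals_small(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 5000), size=(60, 5000)).astype(float)
        k = genetics.compute_grm(_panel(d))
        off = np.abs(k[np.triu_indices(60, 1)])
        assert np.percentile(off, 95) < 0.1

    def test_allele_flip_invariance(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 400), size=(30, 400)).astype(float)
        k1 = genetics.compute_grm(_panel(d))
        k2 = genetics.compute_grm(_panel(2.0 - d))
        np.testing.assert_allclose(k1, k2, atol=1e-10)

    def test_twin_entries_in_synthetic_cohort(self, small_cohort):
        k = genetics.compute_grm(small_cohort.genotypes)
        for a, b, kind in small_cohort.truth.kinship_pairs:
            if kind == "MZ":
                assert abs(k[a, b] - k[a, a]) < 0.1
            else:
                assert 0.25 < k[a, b] < 0.75


class TestLmmWald:
    def test_identity_grm_reduces_to_ols(self, rng):
        n = 150
        w = np.column_stack([np.ones(n), rng.standard_normal(n), rng.integers(0, 2, n)])
        x = rng.binomial(2, 0.3, n).astype(float)
        y = w @ [1.0, 0.5, -0.3] + 0.4 * x + rng.standard_normal(n)
        beta, se, p = genetics.lmm_wald(y, x, w, np.eye(n))
        design = np.column_stack([w, x])
        bh, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ bh
        s2 = resid @ resid / (n - design.shape[1])
        se_ols = np.sqrt(s2 * np.linalg.inv(design.T @ design)[-1, -1])
        p_ols = stats.chi2.sf((bh[-1] / se_ols) ** 2, 1)
        assert beta == pytest.approx(bh[-1], rel=1e-6)
        assert se == pytest.approx(se_ols, rel=1e-6)
        assert p == pytest.approx(p_ols, rel=1e-6)

    def test_null_type_i_error_calibrated(self, rng):
        n, m = 300, 400
        mafs = rng.uniform(0.1, 0.5, m)
        d = rng.binomial(2, mafs, size=(n, m)).astype(float)
        panel = _panel(d)
        grm = genetics.compute_grm(panel)
        w = np.column_stack([np.ones(n), rng.standard_normal(n)])
        y = rng.standard_normal(n)
        table = genetics.association_scan(y, panel, w, grm)
        rate = (table["p"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_relatedness_effect_recovery(self, rng):
        """Planted SNP effect is covered at ~2 SE under twin relatedness."""
        hits = 0
        for _ in range(5):
            n, m = 200, 400
            mafs = rng.uniform(0.1, 0.5, m)
            d = rng.binomial(2, mafs, size=(n, m)).astype(float)
            d[1::10] = d[::10][: len(d[1::10])]  # duplicate rows: MZ-like pairs
            panel = _panel(d)
            grm = genetics.compute_grm(panel)
            u = rng.multivariate_normal(np.zeros(n), 0.5 * grm + 1e-6 * np.eye(n))
            x = d[:, 7]
            y = 0.5 * x + u + 0.7 * rng.standard_normal(n)
            beta, se, _ = genetics.lmm_wald(y, x, np.ones((n, 1)), grm)
            hits += abs(beta - 0.5) < 2 * se
        assert hits >= 4

    def test_singular_covariates_named(self, rng):
        age = rng.uniform(22, 36, 50)
        with pytest.raises(ValueError, match="age2"):
            w = np.column_stack([np.ones(50), age, 2 * age])
            genetics._check_full_rank(w, ["intercept", "age", "age2"])


class TestLdBlocks:
    def test_independent_snps_mostly_singletons(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 200), size=(300, 200)).astype(float)
        blocks = genetics.ld_blocks(_panel(d))
        assert blocks.n_independent >= 0.95 * 200

    def test_exact_copies_form_one_block(self, rng):
        base = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        d = np.hstack([base] * 10)
        blocks = genetics.ld_blocks(_panel(d))
        assert blocks.n_independent == 1

    def test_blocks_never_span_chromosomes(self, rng):
        base = rng.binomial(2, 0.3, size=(100, 1)).astype(float)
        d = np.hstack([base] * 6)
        chrom = np.array(["1"] * 3 + ["2"] * 3)
        blocks = genetics.ld_blocks(_panel(d, chrom=chrom))
        assert blocks.n_independent == 2
        for start, stop in blocks.blocks:
            assert len(set(chrom[start:stop])) == 1


class TestLdAdjustedBonferroni:
    def test_single_block_is_plain_alpha(self):
        bs = genetics.LDBlockSet(blocks=((0, 3),), n_snps=3)
        sig = genetics.ld_adjusted_bonferroni(np.array([0.04, 0.06, 0.2]), bs)
        assert list(sig) == [True, False, False]

    def test_published_consistency_m_1420(self):
        # p = 3.52e-5 stays significant whenever m <= alpha/p = 1420
        bs = genetics.LDBlockSet(blocks=tuple((j, j + 1) for j in range(1420)), n_snps=1420)
        assert genetics.ld_adjusted_bonferroni(np.array([3.52e-5]), bs)[0]
        bs2 = genetics.LDBlockSet(blocks=tuple((j, j + 1) for j in range(1421)), n_snps=1421)
        assert not genetics.ld_adjusted_bonferroni(np.array([3.52e-5]), bs2)[0]

    def test_nothing_significant_gives_empty_set(self):
        bs = genetics.LDBlockSet(blocks=((0, 1), (1, 2)), n_snps=2)
        assert not genetics.ld_adjusted_bonferroni(np.array([0.5, 0.9]), bs).any()


def test_hwe_pvalues_approximately_uniform_in_generator(rng):
    """Non-causal generator SNPs pass a KS uniformity check of exact HWE p."""
    from biotypeflow import synthetic

    cfg = synthetic.CohortConfig(
        n_train=500, n_validation=50, n_replication=50, n_roi=3, n_signal_fc=0,
        n_snps=200, mz_pairs=0, dz_pairs=0, seed=99,
    )
    c = synthetic.generate_cohort(cfg)
    pvals = []
    for j in range(c.genotypes.n_snps):
        if j == c.truth.causal_snp_index:
            continue
        het, hr, hc = genetics.genotype_counts(c.genotypes.dosages[:, j])
        # mid-p: the conservative exact p is discretely super-uniform by
        # construction, which a KS test would flag even under perfect HWE
        pvals.append(genetics.hwe_exact_pvalue(het, hr, hc, midp=True))
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
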