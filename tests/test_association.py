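"""QTL engine tests: OLS t-tests against an independent oracle,
effective-test counting, FDR procedures, pruning and scan filters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from qtlmed.association import (
    bh_fdr,
    cis_scan,
    effective_tests,
    fit_qtl,
    hierarchical_egene_fdr,
    ld_prune,
    trans_scan,
)


def ols_oracle(y, design, term):
    """Textbook OLS t-test, coded independently of the engine."""
    xtx_inv = np.linalg.inv(design.T @ design)
    beta = xtx_inv @ design.T @ y
    resid = y - design @ beta
    df = len(y) - design.shape[1]
    s2 = resid @ resid / df
    se = np.sqrt(s2 * xtx_inv[term, term])
    t = beta[term] / se
    return beta[term], se, 2 * stats.t.sf(abs(t), df)


class TestFitQtl:
    def test_perfect_association(self, rng):
        x = np.repeat([0.0, 1.0, 2.0], 7) + rng.normal(0, 1e-6, 21)
        res = fit_qtl(x.copy(), x)
        assert res.beta == pytest.approx(1.0, abs=1e-6)
        assert res.p_nominal < 1e-30

    def test_matches_independent_ols_oracle(self, rng):
        y = rng.normal(size=100)
        x = rng.normal(size=100)
        cov = rng.normal(size=(100, 3))
        res = fit_qtl(y, x, cov)
        design = np.hstack([np.ones((100, 1)), cov, x[:, None]])
        beta, se, p = ols_oracle(y, design, term=4)
        assert res.beta == pytest.approx(beta, abs=1e-10)
        assert res.se == pytest.approx(se, abs=1e-10)
        assert res.p_nominal == pytest.approx(p, abs=1e-10)

    def test_monomorphic_variant_degenerate(self, rng):
        res = fit_qtl(rng.normal(size=30), np.ones(30))
        assert res.degenerate
        assert res.p_nominal == 1.0

    def test_conditioning_on_self_degenerate(self, rng):
        x = rng.binomial(2, 0.5, 50).astype(float)
        res = fit_qtl(rng.normal(size=50), x, extra_conditioning=x)
        assert res.degenerate

    def test_null_p_values_uniform(self, rng):
        ps = []
        for _ in range(400):
            ps.append(fit_qtl(rng.normal(size=40),
                              rng.binomial(2, 0.5, 40).astype(float)).p_nominal)
        stat = stats.kstest(ps, "uniform").pvalue
        assert stat > 0.01


class TestEffectiveTests:
    def test_identical_columns_one_test(self, rng):
        col = rng.binomial(2, 0.5, 60).astype(float)
        assert effective_tests(np.tile(col[:, None], 5)) == 1

    def test_uncorrelated_columns_full_count(self, rng):
        g = rng.binomial(2, 0.5, size=(5000, 5)).astype(float)
        assert effective_tests(g) == 5

    def test_two_columns_r_half(self):
        # correlation 0.5 -> eigenvalues 1.5, 0.5; top-1 explains 75% < 99%
        n = 40_000
        rng = np.random.default_rng(0)
        a = rng.normal(size=n)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=n)
        assert effective_tests(np.column_stack([a, b])) == 2


class TestBhFdr:
    def test_all_equal(self):
        q, _ = bh_fdr(np.full(10, 0.2))
        np.testing.assert_allclose(q, 0.2)

    def test_brute_force_step_up_example(self):
        q, _ = bh_fdr(np.array([0.001, 0.01, 0.1, 0.8]))
        np.testing.assert_allclose(q, [0.004, 0.02, 0.13333333, 0.8], atol=1e-8)

    def test_trans_level_ten_percent(self):
        _, flags = bh_fdr(np.array([0.04, 0.09, 0.5]), level=0.10)
        # q-values 0.12, 0.135, 0.5 -> nothing passes; at p=0.03 it would
        _, flags2 = bh_fdr(np.array([0.03, 0.05, 0.5]), level=0.10)
        assert flags2[0] and flags2[1] and not flags2[2]

    def test_empirical_fdr_controlled(self, rng):
        # mixture simulations: BH at 5% keeps empirical FDR below 7%
        fdps = []
        for _ in range(200):
            p_null = rng.uniform(size=80)
            p_alt = rng.beta(0.05, 8, size=20)
            p = np.concatenate([p_null, p_alt])
            _, rej = bh_fdr(p, 0.05)
            n_false = rej[:80].sum()
            fdps.append(n_false / max(rej.sum(), 1))
        assert np.mean(fdps) <= 0.07

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))


class TestHierarchicalEgeneFdr:
    def test_single_gene_single_variant(self):
        res = pd.DataFrame({"variant_id": ["v"], "feature_id": ["g"],
                            "p_nominal": [0.04], "beta": [1.0]})
        table = hierarchical_egene_fdr(res, {"g": 1})
        assert table["q_global"].iloc[0] == pytest.approx(0.04)
        assert bool(table["egene"].iloc[0])

    def test_local_adjustment_can_remove_egene(self):
        res = pd.DataFrame({"variant_id": ["v"], "feature_id": ["g"],
                            "p_nominal": [0.04], "beta": [1.0]})
        table = hierarchical_egene_fdr(res, {"g": 2})
        assert table["p_local"].iloc[0] == pytest.approx(0.08)
        assert not bool(table["egene"].iloc[0])

    def test_bh_across_top_snps(self):
        res = pd.DataFrame({
            "variant_id": ["a", "b", "c"],
            "feature_id": ["g1", "g2", "g3"],
            "p_nominal": [0.01, 0.02, 0.9],
            "beta": [1.0, 1.0, 1.0],
        })
        table = hierarchical_egene_fdr(res, {g: 1 for g in ("g1", "g2", "g3")})
        got = table.set_index("feature_id")["q_global"]
        assert got["g1"] == pytest.approx(0.03)
        assert got["g2"] == pytest.approx(0.03)
        assert got["g3"] == pytest.approx(0.9)


class TestLdPrune:
    def test_identical_adjacent_removed(self, rng):
        col = rng.binomial(2, 0.5, 50).astype(float)
        kept = ld_prune(np.column_stack([col, col]))
        np.testing.assert_array_equal(kept, [0])

    def test_uncorrelated_all_retained(self, rng):
        g = rng.binomial(2, 0.5, size=(500, 5)).astype(float)
        kept = ld_prune(g)
        assert len(kept) == 5

    def test_three_variant_example(self, rng):
        # r2(0,1)=0.9, r2(0,2)~0, r2(1,2)~0 -> keep {0, 2}
        n = 5000
        a = rng.normal(size=n)
        b = np.sqrt(0.9) * a + np.sqrt(0.1) * rng.normal(size=n)
        c = rng.normal(size=n)
        kept = ld_prune(np.column_stack([a, b, c]))
        np.testing.assert_array_equal(kept, [0, 2])


class TestTransScan:
    @pytest.fixture
    def scan_inputs(self, rng):
        n = 150
        genotypes = pd.DataFrame({
            "v_near": rng.binomial(2, 0.5, n).astype(float),
            "v_far": rng.binomial(2, 0.5, n).astype(float),
            "v_rare": rng.binomial(2, 0.01, n).astype(float),
        })
        variant_meta = pd.DataFrame({
            "variant_id": ["v_near", "v_far", "v_rare"],
            "chrom": ["chr1", "chr1", "chr1"],
            "pos": [500_000, 5_000_000, 5_000_100],
        })
        expression = pd.DataFrame({
            "gene_distal": rng.normal(size=n),
            "gene_pseudo": rng.normal(size=n),
        })
        gene_meta = pd.DataFrame({
            "gene_id": ["gene_distal", "gene_pseudo"],
            "chrom": ["chr1", "chr2"],
            "tss": [100, 100],
            "is_pseudogene": [False, True],
        })
        return genotypes, variant_meta, expression, gene_meta

    def test_distance_and_pseudogene_filters(self, scan_inputs):
        genotypes, vmeta, expr, gmeta = scan_inputs
        table = trans_scan(genotypes, vmeta, expr, gmeta, prune=False,
                           maf_min=0.025)
        pairs = set(zip(table["variant_id"], table["feature_id"]))
        # v_near is 0.5 Mb from gene_distal TSS on the same chromosome: excluded
        assert ("v_near", "gene_distal") not in pairs
        assert ("v_far", "gene_distal") in pairs
        # pseudogene excluded everywhere
        assert not any(f == "gene_pseudo" for _, f in pairs)
        # MAF 0.01 variant excluded by the 0.025 floor
        assert not any(v == "v_rare" for v, _ in pairs)

    def test_crossmap_boundary_strictly_greater(self, scan_inputs):
        genotypes, vmeta, expr, gmeta = scan_inputs
        crossmap_at_5 = pd.DataFrame({"gene_a": ["up"], "gene_b": ["gene_distal"],
                                      "log2_crossmap": [5.0]})
        table = trans_scan(genotypes, vmeta, expr, gmeta, prune=False,
                           crossmap=crossmap_at_5,
                           variant_gene_cis={"v_far": "up"})
        # value exactly 5 is retained (rule is strictly greater than 5)
        assert ("v_far", "gene_distal") in set(zip(table["variant_id"],
                                                   table["feature_id"]))
        crossmap_above = pd.DataFrame({"gene_a": ["up"], "gene_b": ["gene_distal"],
                                       "log2_crossmap": [10.2]})
        table2 = trans_scan(genotypes, vmeta, expr, gmeta, prune=False,
                            crossmap=crossmap_above,
                            variant_gene_cis={"v_far": "up"})
        assert ("v_far", "gene_distal") not in set(zip(table2["variant_id"],
                                                       table2["feature_id"]))


class TestCisScan:
    def test_recovers_planted_association(self, rng):
        n = 200
        x = rng.binomial(2, 0.5, n).astype(float)
        y = 0.8 * x + rng.normal(size=n)
        genotypes = pd.DataFrame({"v1": x})
        vmeta = pd.DataFrame({"variant_id": ["v1"], "chrom": ["chr1"], "pos": [1000]})
        pheno = pd.DataFrame({"g1": y})
        fmeta = pd.DataFrame({"feature_id": ["g1"], "chrom": ["chr1"], "tss": [5000]})
        table = cis_scan(genotypes, vmeta, pheno, fmeta)
        assert len(table) == 1
        assert table["p_nominal"].iloc[0] < 1e-6
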