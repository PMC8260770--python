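import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import bh_stepup_oracle, ols_slope_oracle
from speqtl.eqtl_mapping import (
    SkippedTest, bh_adjust, call_eqtls, classify_pair, eqtls_from_frame,
    eqtls_to_frame, significant_records,
)
from speqtl.eqtl_mapping import test_association as run_association
from speqtl.spatial_pairs import find_spatial_pairs
from speqtl.synthetic_data import SimConfig, simulate_dataset


class TestAssociation:
    def test_planted_slope_recovered(self, rng):
        # oracle: slope by the normal equations, independent of scipy
        dosage = rng.integers(0, 3, size=200).astype(float)
        expr = 5.0 + 1.0 * dosage + rng.normal(0, 0.1, size=200)
        res = run_association(dosage, expr)
        assert 0.95 <= res.beta <= 1.05
        assert res.beta == pytest.approx(ols_slope_oracle(dosage, expr))
        assert res.p < 1e-10

    def test_constant_expression_skipped(self, rng):
        dosage = rng.integers(0, 3, size=50).astype(float)
        with pytest.raises(SkippedTest) as exc:
            run_association(dosage, np.full(50, 3.0))
        assert exc.value.reason == "zero_expr_variance"

    def test_monomorphic_snp_skipped(self, rng):
        with pytest.raises(SkippedTest) as exc:
            run_association(np.zeros(50), rng.normal(size=50))
        assert exc.value.reason == "zero_dosage_variance"

    def test_missing_dropped_pairwise(self, rng):
        dosage = rng.integers(0, 3, size=100).astype(float)
        expr = 2.0 * dosage + rng.normal(0, 0.1, size=100)
        dosage[:5] = np.nan
        expr[5:10] = np.nan
        res = run_association(dosage, expr)
        assert res.n == 90

    def test_too_few_samples(self):
        with pytest.raises(SkippedTest) as exc:
            run_association([0, 1, 2], [1.0, 2.0, 3.0])
        assert exc.value.reason == "too_few_samples"

    def test_null_pvalues_uniform(self):
        """Under no association, the t-test p-values are U(0,1)."""
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(1000):
            dosage = rng.integers(0, 3, size=200).astype(float)
            expr = rng.normal(size=200)
            pvals.append(run_association(dosage, expr).p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001


class TestClassifyPair:
    def test_distance_over_1mb_is_trans_intra(self):
        assert classify_pair("chr1", 500_000, "chr1", 1_600_000) == \
            ("trans_intra", 1_100_000)

    def test_cross_chromosome(self):
        assert classify_pair("chr1", 0, "chr2", 0) == ("trans_inter", None)

    def test_exactly_1mb_is_cis(self):
        assert classify_pair("chr1", 0, "chr1", 1_000_000) == \
            ("cis", 1_000_000)

    def test_partition_is_exhaustive(self, rng):
        for _ in range(200):
            cls, dist = classify_pair(
                f"chr{rng.integers(2)}", int(rng.integers(3_000_000)),
                f"chr{rng.integers(2)}", int(rng.integers(3_000_000)))
            assert cls in ("cis", "trans_intra", "trans_inter")
            assert (dist is None) == (cls == "trans_inter")


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3]), [0.3])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1,
                    max_size=40))
    def test_matches_stepup_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), bh_stepup_oracle(pvals),
                                   atol=1e-12)

    def test_permutation_equivariance(self, rng):
        p = rng.uniform(1e-6, 1, size=50)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(1e-6, 1, size=100)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestCallEqtls:
    def test_empty_inputs(self):
        assert call_eqtls([], {}, {}, [], []) == []

    def test_planted_recovery_and_signs(self, small_dataset):
        """>= 18/20 planted triples significant; recovered signs all match."""
        ds = small_dataset
        pairs, seen = [], set()
        for trait in ds.snp_sets:
            for p in find_spatial_pairs(ds.snp_sets[trait], ds.genes,
                                        ds.fragment_map, ds.contacts):
                if (p.rsid, p.gene_id) not in seen:
                    seen.add((p.rsid, p.gene_id))
                    pairs.append(p)
        records = call_eqtls(pairs, ds.genotypes, ds.expression,
                             ds.snps, ds.genes)
        sig = {(r.rsid, r.gene_id, r.tissue): r
               for r in significant_records(records)}
        recovered = [e for e in ds.truth.eqtls
                     if (e.rsid, e.gene_id, e.tissue) in sig]
        assert len(recovered) >= 18
        for e in recovered:
            assert np.sign(sig[(e.rsid, e.gene_id, e.tissue)].afc) == \
                np.sign(e.afc)

    def test_planted_class_agrees_with_truth(self, small_dataset):
        ds = small_dataset
        pairs = []
        for trait in ds.snp_sets:
            pairs.extend(find_spatial_pairs(ds.snp_sets[trait], ds.genes,
                                            ds.fragment_map, ds.contacts))
        records = call_eqtls(pairs, ds.genotypes, ds.expression,
                             ds.snps, ds.genes)
        by_key = {(r.rsid, r.gene_id): r.eqtl_class for r in records}
        for e in ds.truth.eqtls:
            if (e.rsid, e.gene_id) in by_key:
                assert by_key[(e.rsid, e.gene_id)] == e.eqtl_class

    def test_sign_recovery_improves_with_n(self):
        """sign(aFC) recovery rate at n=200 is >= the rate at n=50."""
        rates = {}
        for n in (50, 200):
            config = SimConfig(
                seed=5, n_chroms=2, chrom_length=400_000, n_genes=30,
                n_snps_per_trait=30, n_identical_snps=4, n_tissues=1,
                samples_per_tissue=n, n_planted_cis=12, n_planted_trans=4,
                n_shared_egenes=2, afc_effect=0.15, noise_sd=1.0,
                n_coloc_loci_per_flag=0,
            )
            ds = simulate_dataset(config)
            pairs = []
            for trait in ds.snp_sets:
                pairs.extend(find_spatial_pairs(
                    ds.snp_sets[trait], ds.genes, ds.fragment_map, ds.contacts))
            records = call_eqtls(pairs, ds.genotypes, ds.expression,
                                 ds.snps, ds.genes)
            by_key = {(r.rsid, r.gene_id, r.tissue): r for r in records}
            hits = [
                np.sign(by_key[(e.rsid, e.gene_id, e.tissue)].afc) ==
                np.sign(e.afc)
                for e in ds.truth.eqtls
                if (e.rsid, e.gene_id, e.tissue) in by_key
            ]
            rates[n] = np.mean(hits)
        assert rates[200] >= rates[50]

    def test_fdr_scope_per_tissue(self, small_dataset):
        ds = small_dataset
        pairs = find_spatial_pairs(ds.snp_sets["trait1"], ds.genes,
                                   ds.fragment_map, ds.contacts)
        per_tissue = call_eqtls(pairs, ds.genotypes, ds.expression,
                                ds.snps, ds.genes, fdr_scope="per-tissue")
        assert all(r.fdr >= r.p for r in per_tissue)
        with pytest.raises(ValueError):
            call_eqtls(pairs, ds.genotypes, ds.expression, ds.snps, ds.genes,
                       fdr_scope="bogus")

    def test_afc_sign_equals_beta_sign(self, small_dataset):
        ds = small_dataset
        pairs = find_spatial_pairs(ds.snp_sets["trait1"], ds.genes,
                                   ds.fragment_map, ds.contacts)
        for r in call_eqtls(pairs, ds.genotypes, ds.expression,
                            ds.snps, ds.genes):
            assert np.sign(r.afc) == np.sign(r.beta)
            assert r.fdr >= r.p


def test_eqtl_frame_round_trip(small_dataset):
    ds = small_dataset
    pairs = find_spatial_pairs(ds.snp_sets["trait1"], ds.genes,
                               ds.fragment_map, ds.contacts)
    records = call_eqtls(pairs, ds.genotypes, ds.expression, ds.snps, ds.genes)
    back = eqtls_from_frame(eqtls_to_frame(records))
    assert back == records
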