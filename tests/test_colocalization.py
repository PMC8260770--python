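import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from speqtl.colocalization import (
    ColocPriors, ColocResult, coloc_decision, coloc_posteriors, compute_labf,
    extract_window, harmonize_tracks, run_coloc, select_lowest_p_pairs,
)
from speqtl.synthetic_data import simulate_coloc_locus

PAPER_PRIORS = ColocPriors(p1=1e-4, p2=1e-4, p12=5e-5)


def posterior_oracle(labf1, labf2, p1, p2, p12):
    """Independent hand evaluation with plain math, no log-sum-exp tricks.

    Only usable when the ABFs are small enough not to overflow.
    """
    l1 = math.fsum(math.exp(v) for v in labf1)
    l2 = math.fsum(math.exp(v) for v in labf2)
    l12 = math.fsum(math.exp(a + b) for a, b in zip(labf1, labf2))
    s = [1.0, p1 * l1, p2 * l2, p1 * p2 * max(l1 * l2 - l12, 0.0), p12 * l12]
    total = math.fsum(s)
    return [v / total for v in s]


class TestLabf:
    def test_zero_z_half_shrinkage(self):
        # r = w/(w+v) = 0.5 when w = se^2, so labf = 0.5*log(0.5)
        rec = compute_labf(beta=0.0, se=0.3, w=0.09)
        assert rec.r == pytest.approx(0.5)
        assert rec.labf == pytest.approx(0.5 * math.log(0.5), abs=1e-12)

    def test_vanishing_prior_variance(self):
        assert compute_labf(0.5, 0.1, w=1e-300).labf == pytest.approx(0.0, abs=1e-10)

    def test_high_precision_oracle(self):
        # sympy evaluates the same formula at 50 digits
        import sympy

        z, se, w = 8, sympy.Rational(1, 10), sympy.Rational(225, 10000)
        v = se ** 2
        r = w / (w + v)
        expected = float((sympy.log(1 - r) + r * z ** 2) / 2)
        got = compute_labf(beta=8 * 0.1, se=0.1, w=0.0225).labf
        assert got == pytest.approx(expected, rel=1e-12)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            compute_labf(0.1, 0.0, 0.04)


class TestPriors:
    def test_validation(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=0.0)
        with pytest.raises(ValueError):
            ColocPriors(p1=0.5, p2=0.5, p12=0.5)
        with pytest.raises(ValueError):
            ColocPriors(w_quant=-1.0)

    def test_trait_type_selects_variance(self):
        pri = ColocPriors()
        assert pri.w_for("case_control") == pytest.approx(0.04)
        assert pri.w_for("quantitative") == pytest.approx(0.0225)


class TestPosteriors:
    def test_single_snp_pp3_exactly_zero(self):
        res = coloc_posteriors([3.0], [2.0], ["rs1"], PAPER_PRIORS)
        assert res.pp3 == 0.0

    def test_flat_labf_matches_hand_oracle(self):
        labf = [0.0] * 50
        res = coloc_posteriors(labf, labf, [f"rs{i}" for i in range(50)],
                               PAPER_PRIORS)
        expected = posterior_oracle(labf, labf, 1e-4, 1e-4, 5e-5)
        np.testing.assert_allclose(res.posteriors, expected, atol=1e-12)
        assert res.pp0 > 0.9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(-5, 30), st.floats(-5, 30)),
                    min_size=1, max_size=30))
    def test_normalization_and_swap_symmetry(self, labfs):
        labf1 = [a for a, _ in labfs]
        labf2 = [b for _, b in labfs]
        rsids = [f"rs{i}" for i in range(len(labfs))]
        res = coloc_posteriors(labf1, labf2, rsids, PAPER_PRIORS)
        swapped = coloc_posteriors(labf2, labf1, rsids, PAPER_PRIORS)
        assert abs(res.posteriors.sum() - 1.0) < 1e-9
        assert res.pp0 == pytest.approx(swapped.pp0, abs=1e-9)
        assert res.pp1 == pytest.approx(swapped.pp2, abs=1e-9)
        assert res.pp2 == pytest.approx(swapped.pp1, abs=1e-9)
        assert res.pp3 == pytest.approx(swapped.pp3, abs=1e-9)
        assert res.pp4 == pytest.approx(swapped.pp4, abs=1e-9)

    def test_matches_oracle_on_moderate_values(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 20))
            labf1 = rng.uniform(-3, 10, size=n)
            labf2 = rng.uniform(-3, 10, size=n)
            res = coloc_posteriors(labf1, labf2,
                                   [f"rs{i}" for i in range(n)], PAPER_PRIORS)
            expected = posterior_oracle(list(labf1), list(labf2),
                                        1e-4, 1e-4, 5e-5)
            np.testing.assert_allclose(res.posteriors, expected, atol=1e-10)

    def test_pp4_monotone_in_p12(self, rng):
        labf1 = rng.uniform(-2, 12, size=30)
        labf2 = rng.uniform(-2, 12, size=30)
        rsids = [f"rs{i}" for i in range(30)]
        last = -1.0
        for p12 in (1e-6, 1e-5, 5e-5, 1e-4, 5e-4):
            pp4 = coloc_posteriors(labf1, labf2, rsids,
                                   ColocPriors(p12=p12)).pp4
            assert pp4 >= last
            last = pp4

    def test_empty_locus_rejected(self):
        with pytest.raises(ValueError, match="no_common_snps"):
            coloc_posteriors([], [], [], PAPER_PRIORS)


class TestDecision:
    def _res(self, pp3, pp4):
        return ColocResult("L", "rs1", 10, 0.0, 0.0, 0.0, pp3, pp4, "rs1")

    def test_ratio_rule(self):
        assert coloc_decision(self._res(0.10, 0.90))
        assert not coloc_decision(self._res(0.50, 0.50))

    def test_zero_pp3_infinite_ratio(self):
        assert coloc_decision(self._res(0.0, 0.995))

    def test_sum_threshold(self):
        assert not coloc_decision(self._res(0.0, 0.50))


class TestExtractWindow:
    def _track(self, positions):
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(len(positions))],
            "chrom": "chr1", "pos": positions,
        })

    def test_lead_only(self):
        win = extract_window(self._track([100]), "rs0")
        assert len(win) == 1

    def test_boundary_inclusive(self):
        win = extract_window(self._track([0, 200_000, 200_001]), "rs0")
        assert list(win["rsid"]) == ["rs0", "rs1"]

    def test_matches_brute_force_filter(self, rng):
        positions = sorted(rng.integers(0, 2_000_000, size=200).tolist())
        track = self._track(positions)
        lead = "rs100"
        win = extract_window(track, lead, window=150_000)
        lead_pos = positions[100]
        expected = [f"rs{i}" for i, p in enumerate(positions)
                    if abs(p - lead_pos) <= 150_000]
        assert list(win["rsid"]) == expected

    def test_missing_lead(self):
        with pytest.raises(KeyError):
            extract_window(self._track([1, 2]), "rs99")


class TestHarmonization:
    def test_flipped_alleles_flip_beta(self):
        t1 = pd.DataFrame({"rsid": ["rs1"], "ref": ["A"], "alt": ["G"],
                           "beta": [0.5], "se": [0.1]})
        t2 = pd.DataFrame({"rsid": ["rs1"], "ref": ["G"], "alt": ["A"],
                           "beta": [0.5], "se": [0.1]})
        merged = harmonize_tracks(t1, t2)
        assert merged["beta_2"].iloc[0] == pytest.approx(-0.5)

    def test_ambiguous_snps_dropped(self):
        t1 = pd.DataFrame({"rsid": ["rs1", "rs2"], "ref": ["A", "C"],
                           "alt": ["T", "A"], "beta": [0.5, 0.2],
                           "se": [0.1, 0.1]})
        merged = harmonize_tracks(t1, t1.copy())
        assert list(merged["rsid"]) == ["rs2"]


class TestSimulatedLoci:
    def test_shared_causal_recovers_pp4(self):
        """Median PP4 > 0.9 over shared-causal loci; < 0.5 over distinct."""
        rng = np.random.default_rng(31)
        pp4 = {"shared_causal": [], "distinct_causal": []}
        for flag in pp4:
            for _ in range(30):
                sim = simulate_coloc_locus(flag, n_snps=50, rng=rng)
                res = run_coloc(sim.track1, sim.track2,
                                sim.track1.loc[sim.track1["p"].idxmin(), "rsid"])
                pp4[flag].append(res.pp4)
        assert np.median(pp4["shared_causal"]) > 0.9
        assert np.median(pp4["distinct_causal"]) < 0.5

    def test_shared_candidate_is_planted_causal(self):
        rng = np.random.default_rng(8)
        sim = simulate_coloc_locus("shared_causal", n_snps=40, rng=rng)
        res = run_coloc(sim.track1, sim.track2, sim.causal_trait1)
        assert res.shared_causal_candidate == sim.causal_trait1


def test_select_lowest_p_pairs(small_dataset):
    from speqtl.eqtl_mapping import call_eqtls
    from speqtl.spatial_pairs import find_spatial_pairs

    ds = small_dataset
    pairs = find_spatial_pairs(ds.snp_sets["trait1"], ds.genes,
                               ds.fragment_map, ds.contacts)
    records = call_eqtls(pairs, ds.genotypes, ds.expression, ds.snps, ds.genes)
    best = select_lowest_p_pairs(records)
    for rsid, rec in best.items():
        assert rec.p == min(r.p for r in records if r.rsid == rsid)
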