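"""Fst / pi / XP-CLR statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from panelforge import simdata, sweepscan


def brute_force_hudson(ka, na, kb, nb):
    """Direct arithmetic evaluation of the Hudson window estimator."""
    num = den = 0.0
    for k1, n1, k2, n2 in zip(ka, na, kb, nb):
        pa, pb = k1 / n1, k2 / n2
        num += (pa - pb) ** 2 - pa * (1 - pa) / (n1 - 1) - pb * (1 - pb) / (n2 - 1)
        den += pa * (1 - pb) + pb * (1 - pa)
    return num / den


class TestFst:
    def test_hand_set_window_matches_brute_force(self):
        ka = [5, 10, 0, 18, 7]
        kb = [15, 3, 2, 1, 7]
        na = nb = [20] * 5
        got = sweepscan.windowed_fst(ka, na, kb, nb)
        assert got == pytest.approx(brute_force_hudson(ka, na, kb, nb), abs=1e-12)

    def test_no_differentiation_near_zero(self):
        rng = np.random.default_rng(0)
        k = rng.integers(1, 40, 200)
        n = 40
        fst = sweepscan.windowed_fst(k, [n] * 200, k, [n] * 200)
        # identical sample frequencies sit at the unbiased estimator's
        # sampling correction, -1/(n-1)
        assert abs(fst) <= 1 / (n - 1) + 1e-12
        # sites fixed identically in both populations contribute exactly 0
        num, den, _ = sweepscan.site_fst_hudson([0, 40], [n, n], [0, 40], [n, n])
        assert num.tolist() == [0.0, 0.0] and den.tolist() == [0.0, 0.0]

    def test_fixed_difference_approaches_one(self):
        fst = sweepscan.windowed_fst([1000], [1000], [0], [1000])
        assert fst == pytest.approx(1.0, abs=1e-3)

    def test_low_count_sites_skipped(self):
        num, den, valid = sweepscan.site_fst_hudson([1, 5], [1, 20], [0, 3], [4, 20])
        assert valid.tolist() == [False, True]
        assert num[0] == 0 and den[0] == 0

    def test_allele_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        ka, kb = rng.integers(0, 30, 50), rng.integers(0, 30, 50)
        na = nb = np.full(50, 30)
        a = sweepscan.windowed_fst(ka, na, kb, nb)
        b = sweepscan.windowed_fst(na - ka, na, nb - kb, nb)
        assert a == pytest.approx(b, abs=1e-12)

    def test_concatenation_is_weighted_combination(self):
        rng = np.random.default_rng(2)
        ka, kb = rng.integers(0, 30, 40), rng.integers(0, 30, 40)
        na = nb = np.full(40, 30)
        whole = sweepscan.windowed_fst(ka, na, kb, nb)
        parts = []
        for sl in (slice(0, 25), slice(25, 40)):
            n, d, _ = sweepscan.site_fst_hudson(ka[sl], na[sl], kb[sl], nb[sl])
            parts.append((n.sum(), d.sum()))
        combined = sum(p[0] for p in parts) / sum(p[1] for p in parts)
        assert whole == pytest.approx(combined, abs=1e-12)
        lo = min(p[0] / p[1] for p in parts)
        hi = max(p[0] / p[1] for p in parts)
        assert lo - 1e-12 <= whole <= hi + 1e-12

    def test_weir_cockerham_close_to_hudson_at_equal_n(self):
        geno, truth = _small_bn(seed=5)
        ka, na, kb, nb = sweepscan.pop_allele_counts(
            geno, truth.pop_of_sample, "pop1", "pop2"
        )
        h = sweepscan.windowed_fst(ka, na, kb, nb, "hudson")
        w = sweepscan.windowed_fst(ka, na, kb, nb, "weir-cockerham")
        assert h == pytest.approx(w, abs=0.01)


def _small_bn(seed, n_loci=2000, f=0.1):
    cfg = simdata.PopulationSimConfig(
        n_loci=n_loci, samples_per_pop=(30, 30), target_fst=f, seed=seed
    )
    return simdata.simulate_populations(cfg)


class TestPi:
    def test_monomorphic_window_is_zero(self):
        assert sweepscan.nucleotide_diversity([0, 50], [50, 50], 1000) == 0.0

    def test_single_het_pair_value(self):
        # two chromosomes differing at one site: per-site contribution 1.0
        assert sweepscan.nucleotide_diversity([1], [2], 1.0) == pytest.approx(1.0)

    def test_equals_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(3)
        n_hap, n_sites = 50, 30
        haplotypes = rng.integers(0, 2, size=(n_hap, n_sites))
        k = haplotypes.sum(axis=0)
        window_bp = 5000
        got = sweepscan.nucleotide_diversity(k, np.full(n_sites, n_hap), window_bp)
        diffs = [
            (haplotypes[i] != haplotypes[j]).sum()
            for i, j in itertools.combinations(range(n_hap), 2)
        ]
        expected = np.mean(diffs) / window_bp
        assert got == pytest.approx(expected, abs=1e-10)

    def test_zero_window_length_rejected(self):
        with pytest.raises(ValueError, match="window length"):
            sweepscan.nucleotide_diversity([1], [10], 0)


class TestXpclr:
    def test_identical_frequencies_score_near_zero(self):
        # no differentiation at all: omega estimated on the same data,
        # any s > 0 only moves the model away from the observations
        geno, truth = _small_bn(seed=8, f=0.0)
        ka, na, kb, nb = sweepscan.pop_allele_counts(
            geno, truth.pop_of_sample, "pop1", "pop2"
        )
        omega = sweepscan.estimate_omega(ka, na, kb, nb)
        score = sweepscan.xpclr_score(ka[:200], na[:200], kb[:200], nb[:200], omega)
        assert 0 <= score < 1.0

    def test_drifted_null_bias_small_per_site(self):
        # under pure drift (no sweep) the mixture alternative may fit the
        # misspecified tails slightly better; the per-site gain must stay
        # far below a sweep signal
        geno, truth = _small_bn(seed=8)
        ka, na, kb, nb = sweepscan.pop_allele_counts(
            geno, truth.pop_of_sample, "pop1", "pop2"
        )
        omega = sweepscan.estimate_omega(ka, na, kb, nb)
        score = sweepscan.xpclr_score(ka[:200], na[:200], kb[:200], nb[:200], omega)
        assert 0 <= score / 200 < 0.1

    def test_quadrature_matches_dense_integration(self):
        # single site: compare the Gauss-Legendre likelihood to dense
        # numeric integration of the same integrand
        p_ref, kb, nb, omega, s = 0.35, 11, 40, 0.08, 1.5
        for s_val in (0.0, s):
            ll = sweepscan.xpclr_site_loglik(
                np.array([p_ref]),
                np.array([kb]),
                np.array([nb]),
                omega,
                s_val,
                np.array([True]),
            )[0]
            expo = 1.0 / (1.0 + s_val)
            mean = p_ref**expo
            sd = np.sqrt(omega * p_ref * (1 - p_ref))
            q = np.linspace(0, 1, 200_001)
            dens = np.exp(-0.5 * ((q - mean) / sd) ** 2)
            dens /= integrate.trapezoid(dens, q)
            lik = integrate.trapezoid(dens * stats.binom.pmf(kb, nb, q), q)
            assert ll == pytest.approx(np.log(lik), rel=1e-6)

    def test_grid_without_null_rejected(self):
        with pytest.raises(ValueError, match="s=0"):
            sweepscan.xpclr_score([1], [10], [2], [10], 0.1, s_grid=(1.0, 2.0))

    def test_monotone_in_sweep_strength(self):
        geno, truth = _small_bn(seed=13, n_loci=4000)
        region = ("chr1", 1_000_000, 1_400_000)
        scores = []
        for strength in (0.0, 2.0, 8.0):
            g, t = simdata.simulate_sweep_region(geno, truth, region, strength, seed=5)
            ka, na, kb, nb = sweepscan.pop_allele_counts(
                g, t.pop_of_sample, "pop1", "pop2"
            )
            omega = sweepscan.estimate_omega(ka, na, kb, nb)
            inside = (
                (g.loci["chrom"] == "chr1")
                & (g.loci["pos"] - 1 >= region[1])
                & (g.loci["pos"] - 1 < region[2])
            ).to_numpy()
            scores.append(
                sweepscan.xpclr_score(ka[inside], na[inside], kb[inside], nb[inside], omega)
            )
        assert scores[0] < scores[1] < scores[2]


class TestWindowStats:
    @pytest.fixture(scope="class")
    @staticmethod
    def swept_stats():
        geno, truth = _small_bn(seed=21, n_loci=6000)
        g, t = simdata.simulate_sweep_region(
            geno, truth, ("chr1", 2_000_000, 2_300_000), 5.0, seed=1
        )
        stats_df = sweepscan.window_stats(g, t.pop_of_sample, "pop1", "pop2")
        return stats_df

    def test_window_scheme_and_invariants(self, swept_stats):
        st = swept_stats
        assert (st["end"] > st["start"]).all()
        assert (st["n_snps"] >= 5).all()
        assert (st["xpclr"] >= 0).all()
        assert (st[["pi_a", "pi_b"]] >= 0).all().all()

    def test_sample_order_invariance(self):
        geno, truth = _small_bn(seed=30, n_loci=1000)
        perm = np.random.default_rng(0).permutation(geno.n_samples)
        shuffled = geno.subset_samples(perm)
        a = sweepscan.window_stats(geno, truth.pop_of_sample, "pop1", "pop2")
        b = sweepscan.window_stats(shuffled, truth.pop_of_sample, "pop1", "pop2")
        pd.testing.assert_frame_equal(a, b)

    def test_select_regions_recovers_sweep(self, swept_stats):
        regions = sweepscan.select_sweep_regions(swept_stats)
        hit = regions[
            (regions["chrom"] == "chr1")
            & (regions["end"] > 2_000_000)
            & (regions["start"] < 2_300_000)
        ]
        assert len(hit) >= 1

    def test_select_regions_degenerate_union(self, swept_stats):
        all_windows = sweepscan.select_sweep_regions(
            swept_stats, q_fst=1e-9, q_pi=1e-9, q_xpclr=1e-9, combine="union"
        )
        # every window selected -> one merged region per chromosome
        assert len(all_windows) == swept_stats["chrom"].nunique()

    def test_select_regions_input_validation(self, swept_stats):
        with pytest.raises(ValueError, match="no windows"):
            sweepscan.select_sweep_regions(swept_stats.iloc[0:0])
        with pytest.raises(ValueError, match="quantile"):
            sweepscan.select_sweep_regions(swept_stats, q_fst=1.5)
        with pytest.raises(ValueError, match="combination"):
            sweepscan.select_sweep_regions(swept_stats, combine="all-of-them")
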