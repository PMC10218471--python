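"""Ground-truth recovery and determinism of the synthetic-data generators."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelforge import simdata, sweepscan
from panelforge.variants import MISSING, read_vcf


class TestSimulatePopulations:
    def test_zero_fst_shares_frequencies(self):
        cfg = simdata.PopulationSimConfig(
            n_loci=50, samples_per_pop=(5, 5), target_fst=0.0, seed=1
        )
        _, truth = simdata.simulate_populations(cfg)
        np.testing.assert_array_equal(truth.freqs[0], truth.freqs[1])

    def test_deterministic_under_seed(self):
        cfg = simdata.PopulationSimConfig(n_loci=200, samples_per_pop=(8, 8), seed=42)
        g1, t1 = simdata.simulate_populations(cfg)
        g2, t2 = simdata.simulate_populations(cfg)
        np.testing.assert_array_equal(g1.calls, g2.calls)
        pd.testing.assert_frame_equal(g1.loci, g2.loci)
        np.testing.assert_array_equal(t1.freqs, t2.freqs)

    def test_fst_recovery(self, two_pop_sim):
        geno, truth = two_pop_sim
        ka, na, kb, nb = sweepscan.pop_allele_counts(
            geno, truth.pop_of_sample, "pop1", "pop2"
        )
        fst = sweepscan.windowed_fst(ka, na, kb, nb)
        assert fst == pytest.approx(0.1, abs=0.02)

    def test_positions_strictly_increasing(self, two_pop_sim):
        geno, _ = two_pop_sim
        for _, grp in geno.loci.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].nunique() == len(grp)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simdata.simulate_populations(simdata.PopulationSimConfig(n_loci=0))
        with pytest.raises(ValueError):
            simdata.simulate_populations(
                simdata.PopulationSimConfig(samples_per_pop=(0, 5))
            )
        with pytest.raises(ValueError):
            simdata.simulate_populations(
                simdata.PopulationSimConfig(target_fst=1.0)
            )


class TestSweepOverlay:
    REGION = ("chr1", 2_000_000, 2_500_000)

    def test_strength_zero_is_identity(self, two_pop_sim):
        geno, truth = two_pop_sim
        out, t2 = simdata.simulate_sweep_region(geno, truth, self.REGION, 0.0)
        np.testing.assert_array_equal(out.calls, geno.calls)
        np.testing.assert_array_equal(t2.freqs, truth.freqs)

    def test_sweep_reduces_pi_and_raises_fst(self, two_pop_sim):
        geno, truth = two_pop_sim
        out, t2 = simdata.simulate_sweep_region(geno, truth, self.REGION, 5.0, seed=3)
        chrom, start, end = self.REGION
        inside = (
            (out.loci["chrom"] == chrom)
            & (out.loci["pos"] - 1 >= start)
            & (out.loci["pos"] - 1 < end)
        ).to_numpy()
        idx_b = t2.pop_index("pop2")
        kb, nb = out.allele_counts(idx_b)
        ka, na = out.allele_counts(t2.pop_index("pop1"))
        pi_in = sweepscan.nucleotide_diversity(kb[inside], nb[inside], end - start)
        # same number of sites on an equal-length neutral stretch
        outside = ~inside & (out.loci["chrom"] == chrom).to_numpy()
        pi_out = sweepscan.nucleotide_diversity(
            kb[outside], nb[outside], outside.sum() / inside.sum() * (end - start)
        )
        assert pi_in < pi_out
        fst_in = sweepscan.windowed_fst(ka[inside], na[inside], kb[inside], nb[inside])
        fst_out = sweepscan.windowed_fst(ka[outside], na[outside], kb[outside], nb[outside])
        assert fst_in > fst_out
        # untouched outside the region
        np.testing.assert_array_equal(out.calls[:, ~inside], geno.calls[:, ~inside])

    def test_whole_genome_region_warns(self, two_pop_sim):
        geno, truth = two_pop_sim
        lengths = geno.chrom_lengths
        # single-chromosome input covering everything
        sel = (geno.loci["chrom"] == "chr1").to_numpy()
        sub = geno.subset_loci(sel)
        t_sub = simdata.PopulationTruth(
            truth.freqs[:, sel], truth.pop_of_sample, truth.pop_labels, truth.config
        )
        with pytest.warns(UserWarning, match="every simulated locus"):
            out, _ = simdata.simulate_sweep_region(
                sub, t_sub, ("chr1", 0, lengths["chr1"]), 1.0
            )
        assert out.n_loci == sub.n_loci

    def test_region_outside_coordinates_rejected(self, two_pop_sim):
        geno, truth = two_pop_sim
        with pytest.raises(ValueError, match="outside|chromosome"):
            simdata.simulate_sweep_region(geno, truth, ("chr9", 0, 1000), 1.0)
        with pytest.raises(ValueError, match="outside"):
            simdata.simulate_sweep_region(
                geno, truth, ("chr1", 50_000_000, 60_000_000), 1.0
            )


class TestBreedingValues:
    @pytest.fixture(scope="class")
    @staticmethod
    def geno1000():
        cfg = simdata.PopulationSimConfig(
            n_populations=1, samples_per_pop=(1000,), n_loci=800, target_fst=0.0, seed=7
        )
        return simdata.simulate_populations(cfg)[0]

    def test_noiseless_limit_ebv_equals_tbv(self, geno1000):
        cfg = simdata.BreedingSimConfig(
            h2=1 - 1e-9, n_causal=50, reliability_law=1 - 1e-9, seed=1
        )
        ebv, truth = simdata.simulate_breeding_values(geno1000, cfg)
        np.testing.assert_allclose(ebv["ebv"], truth["tbv"], atol=1e-3)

    def test_heritability_realised(self, geno1000):
        sub = geno1000.subset_samples(np.arange(500))
        cfg = simdata.BreedingSimConfig(h2=0.3, n_causal=100, seed=2)
        _, truth = simdata.simulate_breeding_values(sub, cfg)
        ratio = truth["tbv"].var() / truth["phenotype"].var()
        assert ratio == pytest.approx(0.3, abs=0.05)

    def test_reliability_calibration(self, geno1000):
        cfg = simdata.BreedingSimConfig(h2=0.3, n_causal=100, reliability_law=0.64, seed=3)
        ebv, truth = simdata.simulate_breeding_values(geno1000, cfg)
        r2 = np.corrcoef(ebv["ebv"], truth["tbv"])[0, 1] ** 2
        assert r2 == pytest.approx(0.64, abs=0.05)

    def test_bad_h2_rejected(self, geno1000):
        with pytest.raises(ValueError, match="h2"):
            simdata.simulate_breeding_values(
                geno1000, simdata.BreedingSimConfig(h2=1.5)
            )


class TestCaptureExperiment:
    @pytest.fixture(scope="class")
    @staticmethod
    def truth_geno():
        cfg = simdata.PopulationSimConfig(
            n_populations=1, samples_per_pop=(40,), n_loci=2_000, target_fst=0.0, seed=9
        )
        return simdata.simulate_populations(cfg)[0]

    def test_error_free_limit_is_exact_copy(self, truth_geno):
        cfg = simdata.CaptureSimConfig(ado_prob=0.0, dropout_prob=0.0, seed=1)
        res = simdata.simulate_capture_experiment(truth_geno, truth_geno.loci, cfg)
        np.testing.assert_array_equal(res.gbts.calls, truth_geno.calls)

    def test_ado_count_within_binomial_interval(self, truth_geno):
        cfg = simdata.CaptureSimConfig(ado_prob=0.1, dropout_prob=0.0, seed=2)
        res = simdata.simulate_capture_experiment(truth_geno, truth_geno.loci, cfg)
        het = truth_geno.calls == 1
        n_het = int(het.sum())
        assert n_het > 4000
        hom_now = het & np.isin(res.gbts.calls, (0, 2))
        lo, hi = stats.binom.interval(0.99, n_het, 0.1)
        assert lo <= hom_now.sum() <= hi
        # ADO resolves to either homozygote, roughly evenly
        frac2 = res.gbts.calls[hom_now].mean() / 2
        assert 0.4 < frac2 < 0.6

    def test_depth_anchors_match_configured_decay(self, truth_geno):
        cfg = simdata.CaptureSimConfig(seed=3)
        res = simdata.simulate_capture_experiment(truth_geno, truth_geno.loci, cfg)
        prof = res.flank.groupby(res.flank["offset"].abs())["depth"].mean()
        assert prof.loc[0] == pytest.approx(91, rel=0.05)
        assert prof.loc[100] == pytest.approx(60, rel=0.05)
        assert prof.loc[250] == pytest.approx(26, rel=0.05)
        # monotone non-increasing decay in expectation
        factors = simdata.flank_decay_factor(np.arange(0, 501, 25), cfg)
        assert (np.diff(factors) <= 1e-12).all()

    def test_unknown_panel_locus_named_in_error(self, truth_geno):
        bad = pd.DataFrame({"chrom": ["chr1"], "pos": [999_999_999]})
        with pytest.raises(ValueError, match="chr1:999999999"):
            simdata.simulate_capture_experiment(
                truth_geno, bad, simdata.CaptureSimConfig()
            )

    def test_dropout_zeroes_depth_and_call(self, truth_geno):
        cfg = simdata.CaptureSimConfig(ado_prob=0.0, dropout_prob=0.3, seed=4)
        res = simdata.simulate_capture_experiment(truth_geno, truth_geno.loci, cfg)
        dropped = res.gbts.calls.T == MISSING
        assert dropped.mean() == pytest.approx(0.3, abs=0.02)
        assert (res.depths.to_numpy()[dropped] == 0).all()


class TestFixtureSet:
    @pytest.fixture(scope="class")
    @staticmethod
    def fixture_set(tmp_path_factory):
        out = tmp_path_factory.mktemp("fx")
        cfg = simdata.PopulationSimConfig(
            n_loci=400, samples_per_pop=(10, 10), seed=5
        )
        return simdata.write_fixture_set(out, pop_cfg=cfg), out

    def test_truth_vcf_round_trips(self, fixture_set):
        result, _ = fixture_set
        back = read_vcf(result["paths"]["truth_vcf"])
        np.testing.assert_array_equal(back.calls, result["geno"].calls)

    def test_stable_digests_across_runs(self, fixture_set, tmp_path):
        import hashlib

        result, outdir = fixture_set
        cfg = simdata.PopulationSimConfig(n_loci=400, samples_per_pop=(10, 10), seed=5)
        again = simdata.write_fixture_set(tmp_path, pop_cfg=cfg)

        def digest(p):
            return hashlib.sha256(p.read_bytes()).hexdigest()

        for name in ("truth_vcf", "gbts_vcf", "depth_tsv", "qtl_bed", "ebv_tsv"):
            assert digest(result["paths"][name]) == digest(again["paths"][name])

    def test_empty_panel_fails_before_writing(self, tmp_path):
        cfg = simdata.PopulationSimConfig(n_loci=50, samples_per_pop=(4, 4), seed=6)
        target = tmp_path / "nothing"
        empty = pd.DataFrame(columns=["chrom", "pos", "ref", "alt"])
        with pytest.raises(ValueError, match="empty panel"):
            simdata.write_fixture_set(target, pop_cfg=cfg, panel_loci=empty)
        assert not target.exists()
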