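"""End-to-end orchestration: simulate -> filter -> sweep scan -> GWAS ->
panel assembly -> capture QC.

This is the driver used by the numbered analysis scripts, the smoke
test, and the acceptance script. Every step delegates to the module that
owns the computation; this file only wires them together and collects
summary metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import captureqc, gwas, panelbuild, simdata, sweepscan
from .variants import GenotypeMatrix, filter_sites

logger = logging.getLogger(__name__)


def simulate_validation_cohort(
    truth: simdata.PopulationTruth,
    geno: GenotypeMatrix,
    samples_per_pop: tuple,
    seed: int,
) -> GenotypeMatrix:
    """Fresh diploids drawn at the same loci/frequencies as ``truth``.

    Emulates genotyping additional animals from the same breeds with the
    designed panel's truth genotypes known.
    """
    rng = np.random.default_rng(seed)
    calls = []
    samples = []
    for k, n_k in enumerate(samples_per_pop):
        calls.append(
            rng.binomial(2, truth.freqs[k], size=(n_k, truth.freqs.shape[1])).astype(
                np.int8
            )
        )
        samples.extend(
            f"val_{truth.pop_labels[k]}_s{i + 1:03d}" for i in range(n_k)
        )
    return GenotypeMatrix(
        samples, geno.loci.copy(), np.vstack(calls), geno.chrom_lengths
    )


@dataclass
class PipelineConfig:
    """Problem sizes and thresholds for one end-to-end run.

    The default scale (110 discovery animals in two breed groups, 40k
    loci on two 10 Mb chromosomes, an 8k-locus panel validated on 200
    fresh animals) keeps a full run to a few minutes on one CPU while
    preserving the density relationships of the full-genome design.
    """

    seed: int = 1
    n_loci: int = 40_000
    samples_per_pop: tuple = (68, 42)
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000}
    )
    target_fst: float = 0.1
    sweep_region: tuple = ("chr1", 2_400_000, 2_700_000)
    sweep_strength: float = 5.0
    h2: float = 0.3
    n_causal: int = 100
    panel_k: int = 8_000
    target_spacing: int = 2_500
    n_validation: tuple = (120, 80)
    capture: simdata.CaptureSimConfig = field(default_factory=simdata.CaptureSimConfig)
    scan: sweepscan.ScanConfig = field(default_factory=sweepscan.ScanConfig)
    deregress_c: float = 0.1


def run_pipeline(cfg: PipelineConfig, outdir=None) -> dict:
    """Run the whole design-and-validation pipeline on synthetic data.

    Returns a dict of intermediate objects and summary metrics; when
    ``outdir`` is given, tables are written there as TSV.
    """
    rng_seed = cfg.seed

    # 1. simulate the discovery cohort with a known swept region
    pop_cfg = simdata.PopulationSimConfig(
        samples_per_pop=cfg.samples_per_pop,
        n_loci=cfg.n_loci,
        chrom_lengths=dict(cfg.chrom_lengths),
        target_fst=cfg.target_fst,
        seed=rng_seed,
    )
    geno0, truth0 = simdata.simulate_populations(pop_cfg)
    geno, truth = simdata.simulate_sweep_region(
        geno0, truth0, cfg.sweep_region, cfg.sweep_strength, seed=rng_seed + 1
    )
    ebv_table, breeding_truth = simdata.simulate_breeding_values(
        geno, simdata.BreedingSimConfig(h2=cfg.h2, n_causal=cfg.n_causal, seed=rng_seed + 2)
    )
    qtl = simdata.simulate_qtl_regions(cfg.chrom_lengths, seed=rng_seed + 3)

    # 2. site filtering (the simulator emits no failing INFO annotations,
    #    so the hard-filter pass is a no-op here; MAF/missingness apply)
    filtered = filter_sites(geno, max_miss=0.1, min_maf=0.05)
    logger.info("filtered %d -> %d loci", geno.n_loci, filtered.n_loci)

    # 3. sweep scan: pop1 (reference) vs pop2 (test)
    stats = sweepscan.window_stats(
        filtered, truth.pop_of_sample, "pop1", "pop2", cfg.scan
    )
    regions = sweepscan.select_sweep_regions(stats)
    sweep_loci = panelbuild.overlap_qtl(
        filtered.loci.assign(maf=filtered.maf()),
        regions.assign(trait_tag="sweep"),
    ).drop(columns="trait_tags")

    # 4. GWAS on de-regressed EBVs
    debv = gwas.deregress_table(ebv_table, h2=cfg.h2, c=cfg.deregress_c)
    grm = gwas.build_grm(filtered)
    fit = gwas.fit_null_reml(debv["debv"].to_numpy(), grm)
    assoc = gwas.single_marker_scan(debv["debv"].to_numpy(), filtered, fit)
    _, suggestive = gwas.significance_lines()
    gwas_hits = filtered.loci.loc[(assoc["p"] < suggestive).to_numpy()]

    # 4b. validation-style GWAS on a major-gene trait (single causal locus
    #     of large effect, the coat-color situation), same mixed model
    rng = np.random.default_rng(rng_seed + 6)
    causal_major = int(rng.integers(filtered.n_loci))
    x_major = gwas.imputed_dosage(filtered)[:, causal_major]
    if x_major.std() == 0:  # extremely unlikely after MAF filtering
        causal_major = int(np.argmax(filtered.maf()))
        x_major = gwas.imputed_dosage(filtered)[:, causal_major]
    y_major = x_major + rng.normal(
        0, np.sqrt(x_major.var() * 0.8 / 0.2), filtered.n_samples
    )
    fit_major = gwas.fit_null_reml(y_major, grm)
    assoc_major = gwas.single_marker_scan(y_major, filtered, fit_major)
    major_top = int(assoc_major["p"].idxmin())

    # 5. panel assembly
    pool = filtered.loci.assign(maf=filtered.maf())
    qtl_loci = panelbuild.overlap_qtl(pool, qtl)
    panel = panelbuild.assemble_panel(
        sweep_loci,
        qtl_loci,
        gwas_hits,
        pool,
        k=cfg.panel_k,
        target_spacing=cfg.target_spacing,
        chrom_lengths=cfg.chrom_lengths,
    )
    density = panelbuild.density_report(panel)

    # 6. validation: capture the panel on a fresh cohort
    val_truth_geno = simulate_validation_cohort(
        truth, geno, cfg.n_validation, seed=rng_seed + 4
    )
    capture = simdata.simulate_capture_experiment(
        val_truth_geno,
        panel.loci,
        simdata.CaptureSimConfig(**{**vars(cfg.capture), "seed": rng_seed + 5}),
    )
    rates = captureqc.detection_rates(capture.depths)
    profile = captureqc.flank_profile(capture.flank)
    maf_frac, maf_vals, _ = captureqc.captured_maf_spectrum(capture.gbts)
    conc = captureqc.concordance_summary(capture.gbts, capture.truth_panel)

    # summary metrics
    ka, na, kb, nb = sweepscan.pop_allele_counts(
        geno0, truth0.pop_of_sample, "pop1", "pop2"
    )
    fst_overall = sweepscan.windowed_fst(ka, na, kb, nb)
    chrom_s, start_s, end_s = cfg.sweep_region
    hit_sweep = regions[
        (regions["chrom"] == chrom_s)
        & (regions["end"] > start_s - cfg.scan.window)
        & (regions["start"] < end_s + cfg.scan.window)
    ]
    major_recovered = major_top == causal_major

    result = {
        "geno": geno,
        "truth": truth,
        "filtered": filtered,
        "stats": stats,
        "regions": regions,
        "debv": debv,
        "assoc": assoc,
        "assoc_major": assoc_major,
        "panel": panel,
        "density": density,
        "capture": capture,
        "detection": rates,
        "flank_profile": profile,
        "concordance": conc,
        "metrics": {
            "n_loci_raw": geno.n_loci,
            "n_loci_filtered": filtered.n_loci,
            "fst_estimate": fst_overall,
            "sweep_recovered": float(len(hit_sweep) > 0),
            "major_locus_top_hit": float(major_recovered),
            "major_locus_min_p": float(assoc_major["p"].min()),
            "gwas_lambda_gc": gwas.genomic_inflation(assoc["p"].to_numpy()),
            "debv_tbv_slope": float(
                np.polyfit(breeding_truth["tbv"], debv["debv"], 1)[0]
            ),
            "panel_size": panel.size,
            "frac_gaps_le_100kb": density["frac_le_100kb"],
            "dp0_percent": 100 * rates.loc["mean", "dp0"],
            "dp5_percent": 100 * rates.loc["mean", "dp5"],
            "dp20_percent": 100 * rates.loc["mean", "dp20"],
            "depth_on_target": profile.depth_at[0],
            "depth_100bp": profile.depth_at[100],
            "depth_250bp": profile.depth_at[250],
            "captured_maf_gt_0.05_percent": 100 * maf_frac,
            "concordance_percent": 100 * conc.concordance,
            "gbts_attributed_percent": 100 * conc.gbts_attributed_share,
        },
    }
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stats.to_csv(outdir / "sweep_windows.tsv", sep="\t", index=False)
        regions.to_csv(outdir / "sweep_regions.bed", sep="\t", index=False, header=False)
        debv.to_csv(outdir / "debv.tsv", sep="\t", index=False)
        assoc.to_csv(outdir / "assoc.tsv", sep="\t", index=False)
        assoc_major.to_csv(outdir / "assoc_major_locus.tsv", sep="\t", index=False)
        panel.loci.to_csv(outdir / "panel.tsv", sep="\t", index=False)
        rates.to_csv(outdir / "detection_rates.tsv", sep="\t")
        profile.profile.to_csv(outdir / "flank_profile.tsv", sep="\t", index=False)
        conc.counts.to_csv(outdir / "concordance_counts.tsv", sep="\t")
        pd.Series(result["metrics"]).to_csv(outdir / "metrics.tsv", sep="\t")
    return result
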