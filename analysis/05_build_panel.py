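#!/usr/bin/env python
"""Stage 5 — assemble the uniform-density panel.

Merges the three candidate sources (sweep-region loci, QTL-overlap loci,
GWAS hits) with priority gwas > qtl > sweep, gap-fills from the filtered
pool to the target spacing, and emits the exact-K panel with a spacing
report and histogram.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from panelforge import panelbuild, plots
from panelforge.variants import read_vcf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--k", type=int, default=8_000)
    ap.add_argument("--spacing", type=int, default=2_500)
    args = ap.parse_args()
    data = args.workdir / "data"

    geno = read_vcf(data / "filtered.vcf")
    pool = geno.loci.assign(maf=geno.maf())
    with open(data / "config.json") as fh:
        chrom_lengths = {
            k: int(v) for k, v in json.load(fh)["population"]["chrom_lengths"].items()
        }

    sweep_bed = pd.read_csv(
        args.workdir / "sweep_regions.bed", sep="\t", header=None,
        names=["chrom", "start", "end"],
    ).assign(trait_tag="sweep")
    sweep_loci = panelbuild.overlap_qtl(pool, sweep_bed).drop(columns="trait_tags")
    qtl_bed = pd.read_csv(
        data / "qtl.bed", sep="\t", header=None,
        names=["chrom", "start", "end", "trait_tag"],
    )
    qtl_loci = panelbuild.overlap_qtl(pool, qtl_bed)
    hits = pd.read_csv(args.workdir / "gwas_hits.tsv", sep="\t")
    gwas_loci = pool.merge(hits[["chrom", "pos"]], on=["chrom", "pos"])

    panel = panelbuild.assemble_panel(
        sweep_loci, qtl_loci, gwas_loci, pool,
        k=args.k, target_spacing=args.spacing, chrom_lengths=chrom_lengths,
    )
    panel.loci.to_csv(args.workdir / "panel.tsv", sep="\t", index=False)
    rep = panelbuild.density_report(panel)
    plots.gap_histogram(rep["gaps"], args.workdir / "panel_spacing.png")

    by_source = panel.loci["source"].value_counts()
    print(f"panel of {panel.size} loci (target {args.k}):")
    print(by_source.to_string())
    print(f"{100 * rep['frac_le_100kb']:.2f}% of adjacent gaps <= 100 kb")
    print(f"max gap per chromosome: {rep['max_gap_per_chrom']}")


if __name__ == "__main__":
    main()
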