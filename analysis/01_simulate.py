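#!/usr/bin/env python
"""Stage 1 — simulate the discovery data for panel design.

Generates a two-breed-group discovery cohort (68 + 42 diploids, the
resequencing cohort size), overlays a known selective sweep on the test
group, simulates EBVs with reliabilities and trait-tagged QTL intervals,
and writes everything in standard formats (VCF / TSV / BED) under
<workdir>/data. These files are the single source the later stages read,
so the whole analysis reproduces from this script's output.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from panelforge import simdata
from panelforge.variants import write_vcf

SWEEP_REGION = ("chr1", 2_400_000, 2_700_000)
SWEEP_STRENGTH = 5.0


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results/analysis"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-loci", type=int, default=40_000)
    args = ap.parse_args()
    data = args.workdir / "data"
    data.mkdir(parents=True, exist_ok=True)

    pop_cfg = simdata.PopulationSimConfig(n_loci=args.n_loci, seed=args.seed)
    geno, truth = simdata.simulate_populations(pop_cfg)
    geno, truth = simdata.simulate_sweep_region(
        geno, truth, SWEEP_REGION, SWEEP_STRENGTH, seed=args.seed + 1
    )
    ebv, breeding_truth = simdata.simulate_breeding_values(
        geno, simdata.BreedingSimConfig(seed=args.seed + 2)
    )
    qtl = simdata.simulate_qtl_regions(pop_cfg.chrom_lengths, seed=args.seed + 3)

    write_vcf(geno, data / "truth.vcf")
    ebv.to_csv(data / "ebv.tsv", sep="\t", index=False)
    breeding_truth.to_csv(data / "breeding_truth.tsv", sep="\t", index=False)
    qtl.to_csv(data / "qtl.bed", sep="\t", header=False, index=False)
    truth.pop_of_sample.rename("population").to_csv(
        data / "populations.tsv", sep="\t", index_label="id"
    )
    with open(data / "config.json", "w") as fh:
        json.dump(
            {
                "population": asdict(pop_cfg),
                "sweep_region": SWEEP_REGION,
                "sweep_strength": SWEEP_STRENGTH,
                "seed": args.seed,
            },
            fh,
            indent=2,
            default=str,
        )

    print(f"discovery cohort: {geno.n_samples} animals, {geno.n_loci} loci")
    print(f"sweep positive control at {SWEEP_REGION} (strength {SWEEP_STRENGTH})")
    print(f"wrote {sorted(p.name for p in data.iterdir())} under {data}")


if __name__ == "__main__":
    main()
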