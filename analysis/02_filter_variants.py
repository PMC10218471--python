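#!/usr/bin/env python
"""Stage 2 — site-level filtering of the discovery variants.

Applies the GATK-style hard filters (no-op on the simulated data, which
carries no failing annotations) and the panel-design site filters:
missing rate < 0.1 and minor allele frequency >= 0.05. Writes
filtered.vcf and a one-line filtering summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from panelforge.variants import filter_sites, hard_filter_info, read_vcf, write_vcf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--workdir", type=Path, default=Path("results/analysis"))
    args = ap.parse_args()
    data = args.workdir / "data"

    geno = read_vcf(data / "truth.vcf")
    n_raw = geno.n_loci
    geno = geno.subset_loci(~hard_filter_info(geno))
    n_hard = geno.n_loci
    geno = filter_sites(geno, max_miss=0.1, min_maf=0.05)
    write_vcf(geno, data / "filtered.vcf")

    summary = pd.DataFrame(
        [{"raw": n_raw, "after_hard_filters": n_hard, "after_site_filters": geno.n_loci}]
    )
    summary.to_csv(args.workdir / "filtering_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"kept {geno.n_loci}/{n_raw} loci -> {data / 'filtered.vcf'}")


if __name__ == "__main__":
    main()
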