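"""Validation metrics for targeted-capture (GBTS) genotyping runs.

Covers the four QC blocks of a panel validation: per-sample detection
rates at depth thresholds (dp0 / dp5 / dp20), the flank depth-decay
profile, the captured minor-allele-frequency spectrum, and genotype
concordance between GBTS calls and a whole-genome-sequencing truth set.

Discordance taxonomy (per locus x sample, dosage codes 0/1/2, -1 missing):

=============  ====================================================
concordant     equal non-missing calls
gbts_miss      GBTS no-call, WGS called
wgs_miss       WGS no-call, GBTS called
gbts_hom       GBTS homozygous where WGS saw a heterozygote
wgs_hom        GBTS heterozygous where WGS saw a homozygote
opposite_hom   hom-ref on one platform, hom-alt on the other
=============  ====================================================

Pairs missing on both platforms are excluded from the denominator. The
``gbts_miss + gbts_hom`` share of discordant pairs is the
GBTS-attributed error fraction (the classes explained by capture/PCR
artifacts such as allele drop-out).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

CATEGORIES = (
    "concordant",
    "gbts_miss",
    "wgs_miss",
    "gbts_hom",
    "wgs_hom",
    "opposite_hom",
)


# ------------------------------------------------------------ detection rate

def detection_rates(depths: pd.DataFrame, thresholds=(1, 5, 20)) -> pd.DataFrame:
    """Fraction of targets detected per sample at each depth threshold.

    For threshold ``t`` the rate is the fraction of targets with depth
    >= t, except t = 1 which is reported as ``dp0`` (depth strictly > 0)
    so the dp0/dp5/dp20 family is coherent. The row ``mean`` averages
    over samples; columns are named by threshold regardless of the input
    order.
    """
    vals = depths.to_numpy(dtype=float)
    if vals.size == 0:
        raise ValueError("empty depth matrix")
    if (vals < 0).any():
        raise ValueError("negative depth encountered")
    out = {}
    for t in sorted(thresholds):
        if t <= 1:
            rate = (vals > 0).mean(axis=0)
            name = "dp0"
        else:
            rate = (vals >= t).mean(axis=0)
            name = f"dp{t}"
        out[name] = rate
    table = pd.DataFrame(out, index=depths.columns)
    table.loc["mean"] = table.mean(axis=0)
    return table


# ------------------------------------------------------------- flank profile

@dataclass
class FlankProfile:
    """Mean depth vs |offset| with a fitted piecewise-exponential decay."""

    profile: pd.DataFrame  # columns: offset (>=0, pooled), mean_depth, n
    depth_at: dict  # fitted/empirical depth at 0, 100, 250 bp
    rate_near: float  # decay rate per bp on [0, 100]
    rate_far: float  # decay rate per bp beyond 100


def flank_profile(flank: pd.DataFrame, breakpoint: int = 100) -> FlankProfile:
    """Pool symmetric offsets and fit the two-segment exponential decay.

    ``flank`` is a long table with columns ``offset`` (bp, signed) and
    ``depth``. Depth means are computed per |offset| bin; the two decay
    rates come from least squares on log mean depth within [0, breakpoint]
    and beyond.
    """
    if not (flank["offset"] == 0).any():
        raise ValueError("no on-target (offset 0) depths present")
    pooled = flank.assign(offset=flank["offset"].abs())
    prof = (
        pooled.groupby("offset")["depth"]
        .agg(mean_depth="mean", n="size")
        .reset_index()
        .sort_values("offset")
    )
    off = prof["offset"].to_numpy(dtype=float)
    mu = np.maximum(prof["mean_depth"].to_numpy(dtype=float), 1e-9)

    def seg_rate(mask):
        if mask.sum() < 2:
            return 0.0
        coeff = np.polyfit(off[mask], np.log(mu[mask]), 1)
        return float(-coeff[0])

    rate_near = seg_rate(off <= breakpoint)
    rate_far = seg_rate(off >= breakpoint)

    def empirical(target):
        j = int(np.argmin(np.abs(off - target)))
        return float(mu[j])

    depth_at = {0: empirical(0), 100: empirical(100), 250: empirical(250)}
    return FlankProfile(
        profile=prof, depth_at=depth_at, rate_near=rate_near, rate_far=rate_far
    )


# -------------------------------------------------------------- MAF spectrum

def captured_maf_spectrum(gbts: GenotypeMatrix, maf_threshold: float = 0.05):
    """Per-locus MAF of the captured calls and the informative fraction.

    Returns ``(fraction_above, maf_array, histogram)`` where
    ``fraction_above`` is the share of loci with MAF strictly above
    ``maf_threshold`` (among loci with any called genotype).
    """
    if gbts.n_samples < 2:
        raise ValueError("MAF spectrum needs at least 2 samples")
    maf = gbts.maf()
    maf = maf[~np.isnan(maf)]
    frac = float((maf > maf_threshold).mean())
    hist = np.histogram(maf, bins=np.linspace(0, 0.5, 11))
    return frac, maf, hist


# -------------------------------------------------------------- concordance

def classify_genotype_pair(gbts_call: int, wgs_call: int) -> str | None:
    """Category of one (GBTS, WGS) genotype pair; None if both missing.

    Calls are alt dosages 0/1/2 with -1 for no-call.
    """
    for c in (gbts_call, wgs_call):
        if c not in (0, 1, 2, MISSING):
            raise ValueError(f"unknown genotype code {c!r}")
    g, w = gbts_call, wgs_call
    if g == MISSING and w == MISSING:
        return None
    if g == MISSING:
        return "gbts_miss"
    if w == MISSING:
        return "wgs_miss"
    if g == w:
        return "concordant"
    if g != 1 and w == 1:
        return "gbts_hom"
    if g == 1 and w != 1:
        return "wgs_hom"
    return "opposite_hom"


@dataclass
class ConcordanceTable:
    """Aggregate GBTS-vs-WGS comparison results."""

    counts: pd.Series  # per category
    n_compared: int
    concordance: float  # pooled over all compared pairs
    concordance_per_sample: pd.Series
    concordance_sample_mean: float
    discordant_shares: pd.Series  # per category among discordant
    gbts_attributed_share: float  # (gbts_miss + gbts_hom) / discordant


def concordance_summary(
    gbts: GenotypeMatrix, wgs: GenotypeMatrix, loci_subset: pd.DataFrame | None = None
) -> ConcordanceTable:
    """Classify every shared sample x locus pair and aggregate.

    Loci are matched by (chrom, pos), samples by id; ``loci_subset``
    (chrom, pos) restricts the comparison. Pooled and per-sample-mean
    concordance are both reported since either aggregation is defensible.
    """
    common_samples = [s for s in gbts.samples if s in set(wgs.samples)]
    if not common_samples:
        raise ValueError("no shared samples between call sets")
    key_g = gbts.locus_key()
    key_w = wgs.locus_key()
    shared = key_g.intersection(key_w)
    if loci_subset is not None:
        want = pd.Index(
            loci_subset["chrom"].astype(str) + ":" + loci_subset["pos"].astype(str)
        )
        shared = shared.intersection(want)
    if len(shared) == 0:
        raise ValueError("no shared loci between call sets")

    gi = pd.Series(np.arange(len(key_g)), index=key_g).loc[shared].to_numpy()
    wi = pd.Series(np.arange(len(key_w)), index=key_w).loc[shared].to_numpy()
    gs = [gbts.samples.index(s) for s in common_samples]
    ws = [wgs.samples.index(s) for s in common_samples]
    a = gbts.calls[np.ix_(gs, gi)]
    b = wgs.calls[np.ix_(ws, wi)]

    both_missing = (a == MISSING) & (b == MISSING)
    cat = np.full(a.shape, "", dtype=object)
    cat[(a == MISSING) & (b != MISSING)] = "gbts_miss"
    cat[(b == MISSING) & (a != MISSING)] = "wgs_miss"
    called = (a != MISSING) & (b != MISSING)
    cat[called & (a == b)] = "concordant"
    cat[called & (a != 1) & (b == 1)] = "gbts_hom"
    cat[called & (a == 1) & (b != 1)] = "wgs_hom"
    cat[called & (a != b) & (a != 1) & (b != 1)] = "opposite_hom"

    compared = ~both_missing
    counts = pd.Series(
        {c: int(((cat == c) & compared).sum()) for c in CATEGORIES}, name="count"
    )
    n_comp = int(compared.sum())
    conc_per_sample = pd.Series(
        [
            (cat[i] == "concordant").sum() / max(compared[i].sum(), 1)
            for i in range(len(common_samples))
        ],
        index=common_samples,
    )
    n_disc = n_comp - counts["concordant"]
    shares = (
        counts.drop("concordant") / n_disc
        if n_disc > 0
        else counts.drop("concordant") * np.nan
    )
    gbts_share = (
        float((counts["gbts_miss"] + counts["gbts_hom"]) / n_disc) if n_disc else np.nan
    )
    return ConcordanceTable(
        counts=counts,
        n_compared=n_comp,
        concordance=counts["concordant"] / n_comp,
        concordance_per_sample=conc_per_sample,
        concordance_sample_mean=float(conc_per_sample.mean()),
        discordant_shares=shares,
        gbts_attributed_share=gbts_share,
    )


def estimate_ado_rate(table: ConcordanceTable, n_het_truth: int) -> float:
    """Allele-drop-out rate implied by the gbts_hom count.

    Each ADO event turns one WGS heterozygote into a GBTS homozygote, so
    gbts_hom / heterozygous-truth-calls is a consistent estimator of the
    per-heterozygote ADO probability.
    """
    if n_het_truth <= 0:
        raise ValueError("need a positive heterozygous-truth count")
    return float(table.counts["gbts_hom"] / n_het_truth)
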