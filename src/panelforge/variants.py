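"""Genotype containers, VCF I/O, and site-level filtering.

The central in-memory object is :class:`GenotypeMatrix`: samples x loci
alt-allele dosages in {0, 1, 2} with -1 for a missing call, plus a locus
table carrying CHROM/POS/REF/ALT and the GATK-style hard-filter
annotations (QD, QUAL, SOR, MQ, FS, MQRankSum, ReadPosRankSum) when
present.

Coordinates: VCF positions are 1-based; BED interchange elsewhere in the
package is 0-based half-open. Conversions live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: INFO keys recognised for GATK-style hard filtering. QUAL is a VCF
#: column, not an INFO key, but participates in the same rule set.
HARD_FILTER_KEYS = ("QD", "QUAL", "SOR", "MQ", "FS", "MQRankSum", "ReadPosRankSum")

#: Default GATK SNP hard filters: a locus FAILS if any rule fires.
DEFAULT_HARD_FILTERS = (
    ("QD", "<", 2.0),
    ("QUAL", "<", 30.0),
    ("SOR", ">", 3.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 60.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)

#: Key aliases seen in the wild.
INFO_ALIASES = {"MORankSum": "MQRankSum"}


class VcfFormatError(ValueError):
    """Raised for malformed or unsupported VCF content."""


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with alt-dosage coding.

    Parameters
    ----------
    samples
        Sample identifiers, one per row of ``calls``.
    loci
        Locus table with at least columns ``chrom, pos, ref, alt``
        (``pos`` 1-based). May carry annotation columns (QD, QUAL, ...).
    calls
        ``(n_samples, n_loci)`` int8 array of alt-allele dosages;
        ``-1`` encodes a missing genotype.
    chrom_lengths
        Optional chromosome sizes in bp, used when writing VCF contig
        headers and when windowing.
    """

    samples: list[str]
    loci: pd.DataFrame
    calls: np.ndarray
    chrom_lengths: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x loci)")
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        self.loci = self.loci.reset_index(drop=True)
        self._check_sorted()

    def _check_sorted(self) -> None:
        chrom = self.loci["chrom"].to_numpy()
        pos = self.loci["pos"].to_numpy()
        seen: set[str] = set()
        prev_chrom = None
        for i in range(len(chrom)):
            c = chrom[i]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"loci not grouped by chromosome: {c!r} reappears")
                seen.add(c)
                prev_chrom = c
            elif pos[i] <= pos[i - 1]:
                raise ValueError(
                    f"positions not strictly increasing on {c!r} at index {i} "
                    f"({pos[i - 1]} -> {pos[i]})"
                )

    # ------------------------------------------------------------------ shape
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            list(self.samples),
            self.loci.copy(),
            self.calls.copy(),
            dict(self.chrom_lengths) if self.chrom_lengths else None,
        )

    # ------------------------------------------------------------- statistics
    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """Per-locus (alt allele count, called chromosome count).

        Restricted to ``sample_idx`` rows when given. Missing genotypes
        contribute to neither count.
        """
        g = self.calls if sample_idx is None else self.calls[sample_idx]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0).astype(np.int64)
        n_chrom = 2 * called.sum(axis=0).astype(np.int64)
        return alt, n_chrom

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        alt, n = self.allele_counts(sample_idx)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per locus, in [0, 0.5]; NaN if uncalled.

        Computed from integer counts as min(alt, n-alt)/n so loci at an
        exact threshold boundary (e.g. 1/20 vs 0.05) compare cleanly.
        """
        alt, n = self.allele_counts()
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, np.minimum(alt, n - alt) / np.maximum(n, 1), np.nan)

    def miss(self) -> np.ndarray:
        """Missing-genotype rate per locus, in [0, 1]."""
        return (self.calls == MISSING).mean(axis=0)

    # --------------------------------------------------------------- indexing
    def subset_loci(self, mask_or_idx) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            list(self.samples),
            self.loci.iloc[idx].reset_index(drop=True),
            self.calls[:, idx],
            dict(self.chrom_lengths) if self.chrom_lengths else None,
        )

    def subset_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx],
            self.loci.copy(),
            self.calls[idx],
            dict(self.chrom_lengths) if self.chrom_lengths else None,
        )

    def locus_key(self) -> pd.Index:
        return pd.Index(
            self.loci["chrom"].astype(str) + ":" + self.loci["pos"].astype(str)
        )


# ---------------------------------------------------------------------- I/O

_GT_WRITE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a minimal VCFv4.2 with diploid GT and hard-filter annotations."""
    info_cols = [k for k in HARD_FILTER_KEYS if k != "QUAL" and k in geno.loci.columns]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panelforge\n")
        if geno.chrom_lengths:
            for c, ln in geno.chrom_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        else:
            for c in dict.fromkeys(geno.loci["chrom"]):
                fh.write(f"##contig=<ID={c}>\n")
        for k in info_cols:
            fh.write(
                f'##INFO=<ID={k},Number=1,Type=Float,Description="{k} annotation">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        quals = (
            geno.loci["QUAL"].to_numpy()
            if "QUAL" in geno.loci.columns
            else np.full(geno.n_loci, np.nan)
        )
        info_mat = {k: geno.loci[k].to_numpy() for k in info_cols}
        for j in range(geno.n_loci):
            row = geno.loci.iloc[j]
            qual = quals[j]
            qual_s = "." if np.isnan(qual) else f"{qual:g}"
            parts = [
                f"{k}={info_mat[k][j]:g}" for k in info_cols if not np.isnan(info_mat[k][j])
            ]
            info_s = ";".join(parts) if parts else "."
            gts = "\t".join(_GT_WRITE[int(g)] for g in geno.calls[:, j])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t{row['alt']}\t"
                f"{qual_s}\tPASS\t{info_s}\tGT\t{gts}\n"
            )


def read_vcf(path, multiallelic: str = "error") -> GenotypeMatrix:
    """Read a VCFv4.2 with diploid GT into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path
        VCF (optionally bgzipped) path.
    multiallelic
        ``"error"`` (default) rejects records with >1 ALT allele;
        ``"drop"`` silently skips them.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("error", "drop"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom_lengths: dict[str, int] = {}
    try:
        seqlens = vcf.seqlens
    except AttributeError:  # header contigs without length
        seqlens = []
    for c, ln in zip(vcf.seqnames, seqlens or []):
        if ln:
            chrom_lengths[c] = int(ln)

    rows = []
    calls = []
    prev = None
    for var in vcf:
        if len(var.ALT) != 1:
            if multiallelic == "error":
                raise VcfFormatError(
                    f"multiallelic record at {var.CHROM}:{var.POS} "
                    f"(ALT={','.join(var.ALT)}); splitting is disabled"
                )
            continue
        key = (var.CHROM, var.POS)
        if prev is not None and prev[0] == key[0] and key[1] <= prev[1]:
            raise VcfFormatError(f"unsorted VCF at {var.CHROM}:{var.POS}")
        prev = key
        gts = var.genotypes  # [[a, b, phased], ...]
        if gts and len(gts[0]) != 3:
            raise VcfFormatError(
                f"non-diploid GT at {var.CHROM}:{var.POS} (ploidy {len(gts[0]) - 1})"
            )
        col = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(gts):
            a, b = g[0], g[1]
            col[i] = MISSING if (a < 0 or b < 0) else (a > 0) + (b > 0)
        rec = {
            "chrom": var.CHROM,
            "pos": var.POS,
            "ref": var.REF,
            "alt": var.ALT[0],
            "QUAL": np.nan if var.QUAL is None else float(var.QUAL),
        }
        for k in HARD_FILTER_KEYS:
            if k == "QUAL":
                continue
            v = var.INFO.get(k)
            if v is None:
                v = var.INFO.get(
                    next((a for a, t in INFO_ALIASES.items() if t == k), "")
                )
            if v is not None:
                rec[k] = float(v)
        rows.append(rec)
        calls.append(col)
    vcf.close()
    if not rows:
        raise VcfFormatError(f"no biallelic SNP records in {path}")
    loci = pd.DataFrame(rows)
    return GenotypeMatrix(
        samples,
        loci,
        np.array(calls, dtype=np.int8).T,
        chrom_lengths or None,
    )


# ------------------------------------------------------------------ filters

_OPS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


def hard_filter_info(geno: GenotypeMatrix, rules=DEFAULT_HARD_FILTERS) -> np.ndarray:
    """Boolean mask of loci FAILING any hard-filter rule.

    Rules are ``(key, op, threshold)`` triples with GATK semantics: a
    locus fails if any rule fires. A locus with the annotation absent
    (NaN) passes that rule, as GATK does; this is logged once per key.
    """
    fail = np.zeros(geno.n_loci, dtype=bool)
    for key, op, thr in rules:
        key = INFO_ALIASES.get(key, key)
        if op not in _OPS:
            raise ValueError(f"unknown operator {op!r} in hard filter rule")
        if key not in geno.loci.columns:
            logger.info("hard filter: annotation %s absent everywhere; rule skipped", key)
            continue
        vals = geno.loci[key].to_numpy(dtype=float)
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            logger.info(
                "hard filter: %d loci lack %s; they pass that rule", n_missing, key
            )
        with np.errstate(invalid="ignore"):
            fail |= np.where(np.isnan(vals), False, _OPS[op](vals, thr))
    return fail


def filter_sites(
    geno: GenotypeMatrix,
    max_miss: float = 0.1,
    min_maf: float = 0.05,
    keep_chroms=None,
) -> GenotypeMatrix:
    """Site-level filtering as done ahead of panel design.

    Removes loci with missing rate ``>= max_miss`` (inclusive bound) or
    minor allele frequency ``< min_maf`` (strict, so maf == min_maf
    survives), recomputing both from the call matrix. When
    ``keep_chroms`` is given, loci on other chromosomes/contigs are
    dropped too.
    """
    if not (0 <= max_miss <= 1 and 0 <= min_maf <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    if keep_chroms is not None:
        keep_chroms = set(keep_chroms)
        if not keep_chroms:
            raise ValueError("keep_chroms must be None or non-empty")
    miss = geno.miss()
    maf = geno.maf()
    keep = (miss < max_miss) & ~(np.nan_to_num(maf, nan=-1.0) < min_maf)
    if keep_chroms is not None:
        keep &= geno.loci["chrom"].isin(keep_chroms).to_numpy()
    return geno.subset_loci(keep)
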