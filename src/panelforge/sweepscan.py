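"""Windowed selective-sweep statistics between two breed groups.

Three per-window statistics are computed over fixed sliding windows
(default 50 kb, 25 kb step, >= 5 SNPs):

* Hudson Fst as a ratio of averages, sum(num)/sum(den), with the
  unbiased per-site numerator and denominator (Weir–Cockerham per-site
  components are available as a config switch for parity with vcftools);
* nucleotide diversity pi per bp for each population, from the unbiased
  per-site heterozygosity n/(n-1) * 2 p (1-p), and the log2 ratio
  pi_a/pi_b (large when diversity is lost in the test population);
* an XP-CLR-style composite log-likelihood ratio: drift of the test
  population's latent allele frequency away from the reference frequency
  is modelled as a truncated Normal with variance omega * p (1 - p)
  (omega estimated genome-wide by method of moments), observed counts
  are binomial given the latent frequency (integrated by Gauss–Legendre
  quadrature), and selection with intensity s moves the favored allele
  via p -> p**(1/(1+s)), with the likelihood averaged over both possible
  orientations of the favored allele (nested in the null at s = 0); the
  score is the window's log-likelihood ratio maximised over a grid of s
  that includes 0, hence >= 0.

Sweep regions are windows passing a combination (default: 2-of-3 vote at
the 99th percentile) of the three statistics, merged when adjacent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_S_GRID = (0.0, 0.1, 0.25, 0.5, 1.0, 2.0, 5.0, 10.0)


# -------------------------------------------------------------- per-site Fst

def site_fst_hudson(ka, na, kb, nb):
    """Hudson per-site Fst components (numerator, denominator, valid mask).

    num = (pa - pb)^2 - pa(1-pa)/(na-1) - pb(1-pb)/(nb-1)
    den = pa(1-pb) + pb(1-pa)

    Sites with fewer than 2 observed chromosomes in either population are
    flagged invalid (mask False) and should be skipped; the caller reports
    the count. Windowed Fst is sum(num)/sum(den) over valid sites.
    """
    ka, na, kb, nb = (np.asarray(v, dtype=float) for v in (ka, na, kb, nb))
    valid = (na >= 2) & (nb >= 2)
    na_ = np.where(valid, na, 2.0)
    nb_ = np.where(valid, nb, 2.0)
    pa = ka / na_
    pb = kb / nb_
    num = (pa - pb) ** 2 - pa * (1 - pa) / (na_ - 1) - pb * (1 - pb) / (nb_ - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return np.where(valid, num, 0.0), np.where(valid, den, 0.0), valid


def site_fst_wc(ka, na, kb, nb):
    """Weir–Cockerham (1984) per-site variance components (a, a+b+c) for
    two populations, haploid-count parameterisation, returned like the
    Hudson components so windows combine as a ratio of averages."""
    ka, na, kb, nb = (np.asarray(v, dtype=float) for v in (ka, na, kb, nb))
    valid = (na >= 2) & (nb >= 2)
    na_ = np.where(valid, na, 2.0)
    nb_ = np.where(valid, nb, 2.0)
    r = 2.0
    n_bar = (na_ + nb_) / r
    nc = (na_ + nb_ - (na_**2 + nb_**2) / (na_ + nb_)) / (r - 1)
    pa = ka / na_
    pb = kb / nb_
    p_bar = (ka + kb) / (na_ + nb_)
    s2 = (na_ * (pa - p_bar) ** 2 + nb_ * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (na_ * 2 * pa * (1 - pa) * na_ / np.maximum(na_ - 1, 1)
             + nb_ * 2 * pb * (1 - pb) * nb_ / np.maximum(nb_ - 1, 1)) / (r * n_bar)
    # Weir-Cockerham with individuals = chromosomes (no within-ind term):
    a = n_bar / nc * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1))
    b = n_bar / (n_bar - 1) * (p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
    c = h_bar / 2
    num = a
    den = a + b + c
    return np.where(valid, num, 0.0), np.where(valid, den, 0.0), valid


FST_ESTIMATORS = {"hudson": site_fst_hudson, "weir-cockerham": site_fst_wc}


def windowed_fst(ka, na, kb, nb, estimator: str = "hudson") -> float:
    """Ratio-of-averages Fst over a set of sites."""
    num, den, valid = FST_ESTIMATORS[estimator](ka, na, kb, nb)
    n_skip = int((~valid).sum())
    if n_skip:
        logger.debug("fst: skipped %d sites with <2 chromosomes", n_skip)
    d = den.sum()
    return float(num.sum() / d) if d > 0 else np.nan


# ------------------------------------------------------------------------ pi

def nucleotide_diversity(k, n, window_bp: float) -> float:
    """Nucleotide diversity per bp over a window.

    Per-site unbiased heterozygosity n/(n-1) * 2 p (1-p) (equal to the
    mean pairwise difference k(n-k)/C(n,2)), summed over sites and
    divided by the window length in bp.
    """
    if window_bp <= 0:
        raise ValueError("window length must be positive")
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    ok = n >= 2
    n_ = np.where(ok, n, 2.0)
    p = k / n_
    per_site = np.where(ok, n_ / (n_ - 1.0) * 2.0 * p * (1.0 - p), 0.0)
    return float(per_site.sum() / window_bp)


# -------------------------------------------------------------------- XP-CLR

def estimate_omega(ka, na, kb, nb) -> float:
    """Genome-wide method-of-moments drift variance multiplier.

    Solves E[(pb_hat - pa_hat)^2] = omega * pa(1-pa) + sampling noise for
    omega, averaged over all polymorphic sites; floored at 1e-4.
    """
    ka, na, kb, nb = (np.asarray(v, dtype=float) for v in (ka, na, kb, nb))
    ok = (na >= 2) & (nb >= 2)
    pa = ka[ok] / na[ok]
    pb = kb[ok] / nb[ok]
    het_a = pa * (1 - pa)
    poly = het_a > 0
    pa, pb = pa[poly], pb[poly]
    na_, nb_ = na[ok][poly], nb[ok][poly]
    het_a = het_a[poly]
    resid = (pb - pa) ** 2 - pa * (1 - pa) / na_ - pb * (1 - pb) / nb_
    omega = float(np.sum(resid) / np.sum(het_a))
    return max(omega, 1e-4)


def _quad_nodes(n_nodes: int = 256):
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    return 0.5 * (x + 1.0), 0.5 * w  # mapped to [0, 1]


def xpclr_site_loglik(
    p_ref: np.ndarray,
    kb: np.ndarray,
    nb: np.ndarray,
    omega: float,
    s: float,
    favored_is_alt: np.ndarray,
    n_nodes: int = 256,
) -> np.ndarray:
    """Per-site composite log-likelihood under selection intensity s.

    The latent test-population frequency q has a truncated-Normal density
    centred on the drifted/selected reference frequency with variance
    omega * p_ref (1 - p_ref); the observed alt count kb of nb
    chromosomes is Binomial(nb, q), integrated over q by Gauss–Legendre
    quadrature on [0, 1] (density renormalised on the truncation).
    Selection acts on the favored allele: its frequency is mapped
    p -> p**(1/(1+s)).
    """
    p_ref = np.asarray(p_ref, dtype=float)
    kb = np.asarray(kb, dtype=float)
    nb = np.asarray(nb, dtype=float)
    q_nodes, w = _quad_nodes(n_nodes)

    expo = 1.0 / (1.0 + s)
    mean_alt = np.where(favored_is_alt, p_ref**expo, 1.0 - (1.0 - p_ref) ** expo)
    var = omega * p_ref * (1.0 - p_ref)
    sd = np.sqrt(np.maximum(var, 1e-12))

    zz = (q_nodes[None, :] - mean_alt[:, None]) / sd[:, None]
    dens = np.exp(-0.5 * zz * zz)  # unnormalised; constants cancel on renorm
    norm = dens @ w
    dens = dens / np.maximum(norm[:, None], 1e-300)

    from scipy.stats import binom

    # binomial pmf at each node: (sites, nodes)
    pmf = binom.pmf(kb[:, None], nb[:, None], np.clip(q_nodes, 1e-12, 1 - 1e-12)[None, :])
    lik = (dens * pmf) @ w
    return np.log(np.maximum(lik, 1e-300))


def xpclr_site_ll_matrix(
    ka, na, kb, nb, omega: float, s_grid=DEFAULT_S_GRID, n_nodes: int = 256
) -> np.ndarray:
    """Per-site log-likelihoods under every grid intensity: (sites, grid).

    Computed once genome-wide so overlapping windows can sum slices; the
    binomial sampling term is shared across the grid and evaluated once.
    Sites with fewer than 2 chromosomes in either population contribute 0
    at every s.
    """
    s_grid = tuple(s_grid)
    if 0.0 not in s_grid:
        raise ValueError("selection grid must include s=0 (null model)")
    ka, na, kb, nb = (np.asarray(v, dtype=float) for v in (ka, na, kb, nb))
    ok = (na >= 2) & (nb >= 2)
    out = np.zeros((len(ka), len(s_grid)))
    if not ok.any():
        return out
    pa = ka[ok] / na[ok]
    # clamp reference frequencies off the boundary so drift variance > 0
    pa = np.clip(pa, 0.5 / na[ok], 1.0 - 0.5 / na[ok])
    q_nodes, w = _quad_nodes(n_nodes)
    from scipy.stats import binom

    pmf = binom.pmf(
        kb[ok][:, None], nb[ok][:, None], np.clip(q_nodes, 1e-12, 1 - 1e-12)[None, :]
    )
    # latent-frequency spread: drift plus the sampling noise of the
    # estimated reference frequency (the reference is not known truth)
    var = pa * (1.0 - pa) * (omega + 1.0 / na[ok])
    sd = np.sqrt(np.maximum(var, 1e-12))

    def lik_given_mean(mean_alt):
        zz = (q_nodes[None, :] - mean_alt[:, None]) / sd[:, None]
        dens = np.exp(-0.5 * zz * zz)
        norm = np.maximum(dens @ w, 1e-300)
        return np.einsum("ij,ij,j->i", dens, pmf, w) / norm

    ll = np.empty((int(ok.sum()), len(s_grid)))
    for j, s in enumerate(s_grid):
        expo = 1.0 / (1.0 + s)
        if s == 0.0:
            lik = lik_given_mean(pa)
        else:
            # which allele is favored is unknown a priori: average the
            # likelihood over both orientations (nested at s = 0)
            lik = 0.5 * lik_given_mean(pa**expo) + 0.5 * lik_given_mean(
                1.0 - (1.0 - pa) ** expo
            )
        ll[:, j] = np.log(np.maximum(lik, 1e-300))
    out[ok] = ll
    return out


def xpclr_score(
    ka,
    na,
    kb,
    nb,
    omega: float,
    s_grid=DEFAULT_S_GRID,
    n_nodes: int = 256,
) -> float:
    """Window XP-CLR-style score: max over the selection grid of the
    summed per-site log-likelihood ratio against s = 0.

    The grid must include 0 (the null), which also makes the score
    non-negative.
    """
    ll = xpclr_site_ll_matrix(ka, na, kb, nb, omega, s_grid, n_nodes)
    s_grid = tuple(s_grid)
    tot = ll.sum(axis=0)
    return float(np.max(tot - tot[s_grid.index(0.0)]))


# ------------------------------------------------------------------- windows

@dataclass
class ScanConfig:
    """Window scheme and estimator switches for the sweep scan."""

    window: int = 50_000
    step: int = 25_000
    min_snps: int = 5
    fst_estimator: str = "hudson"
    s_grid: tuple = DEFAULT_S_GRID
    n_nodes: int = 256


def pop_allele_counts(geno: GenotypeMatrix, pops: pd.Series, pop_a, pop_b):
    """Per-site (ka, na, kb, nb) for the two requested population labels."""
    labels = pops.reindex(geno.samples)
    idx_a = np.flatnonzero((labels == pop_a).to_numpy())
    idx_b = np.flatnonzero((labels == pop_b).to_numpy())
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError(f"no samples for population {pop_a!r} or {pop_b!r}")
    ka, na = geno.allele_counts(idx_a)
    kb, nb = geno.allele_counts(idx_b)
    return ka, na, kb, nb


def window_stats(
    geno: GenotypeMatrix,
    pops: pd.Series,
    pop_a,
    pop_b,
    cfg: ScanConfig | None = None,
) -> pd.DataFrame:
    """Sliding-window Fst, pi (both pops), log2 pi ratio, and XP-CLR score.

    ``pop_a`` is the reference population (e.g. European breeds) and
    ``pop_b`` the test population screened for sweeps. Windows with fewer
    than ``min_snps`` SNPs are dropped.
    """
    cfg = cfg or ScanConfig()
    ka, na, kb, nb = pop_allele_counts(geno, pops, pop_a, pop_b)
    omega = estimate_omega(ka, na, kb, nb)
    logger.info("xpclr drift variance multiplier omega=%.4g", omega)

    ll_mat = xpclr_site_ll_matrix(ka, na, kb, nb, omega, cfg.s_grid, cfg.n_nodes)
    null_col = tuple(cfg.s_grid).index(0.0)

    chrom_arr = geno.loci["chrom"].to_numpy()
    pos0 = geno.loci["pos"].to_numpy() - 1  # 0-based
    lengths = geno.chrom_lengths or {}
    rows = []
    for chrom in dict.fromkeys(chrom_arr):
        sel = chrom_arr == chrom
        cpos = pos0[sel]
        cka, cna, ckb, cnb = ka[sel], na[sel], kb[sel], nb[sel]
        cll = ll_mat[sel]
        chrom_len = lengths.get(chrom, int(cpos.max()) + 1)
        for start in range(0, max(chrom_len - cfg.window, 0) + cfg.step, cfg.step):
            end = min(start + cfg.window, chrom_len)
            lo, hi = np.searchsorted(cpos, [start, end])
            n_snps = hi - lo
            if n_snps < cfg.min_snps:
                continue
            sl = slice(lo, hi)
            fst = windowed_fst(cka[sl], cna[sl], ckb[sl], cnb[sl], cfg.fst_estimator)
            pi_a = nucleotide_diversity(cka[sl], cna[sl], end - start)
            pi_b = nucleotide_diversity(ckb[sl], cnb[sl], end - start)
            with np.errstate(divide="ignore"):
                ratio = np.log2(pi_a / pi_b) if pi_b > 0 else np.inf
            tot = cll[sl].sum(axis=0)
            score = float(np.max(tot - tot[null_col]))
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "n_snps": int(n_snps),
                    "fst": fst,
                    "pi_a": pi_a,
                    "pi_b": pi_b,
                    "pi_ratio": ratio,
                    "xpclr": score,
                }
            )
    return pd.DataFrame(rows)


def select_sweep_regions(
    stats: pd.DataFrame,
    q_fst: float = 0.99,
    q_pi: float = 0.99,
    q_xpclr: float = 0.99,
    combine: str = "vote2",
) -> pd.DataFrame:
    """Top-quantile window selection and merging into candidate regions.

    ``combine`` is ``"intersection"`` (all three statistics extreme),
    ``"union"`` (any), or ``"vote2"`` (at least two of three, default).
    High Fst, high pi_ratio (diversity loss in the test population), and
    high XP-CLR score count as extreme. Overlapping or book-ended
    selected windows are merged.
    """
    if stats.empty:
        raise ValueError("no windows to select from")
    for q in (q_fst, q_pi, q_xpclr):
        if not (0 < q < 1):
            raise ValueError("quantile thresholds must lie in (0, 1)")
    if combine not in ("intersection", "union", "vote2"):
        raise ValueError(f"unknown combination rule {combine!r}")
    fin = stats.replace([np.inf, -np.inf], np.nan)
    votes = (
        (stats["fst"] >= fin["fst"].quantile(q_fst)).astype(int)
        + (stats["pi_ratio"] >= fin["pi_ratio"].quantile(q_pi)).astype(int)
        + (stats["xpclr"] >= fin["xpclr"].quantile(q_xpclr)).astype(int)
    )
    need = {"intersection": 3, "vote2": 2, "union": 1}[combine]
    hits = stats.loc[votes >= need, ["chrom", "start", "end"]]
    if hits.empty:
        return hits.reset_index(drop=True)
    hits = hits.sort_values(["chrom", "start"], kind="mergesort")
    merged = []
    for _, row in hits.iterrows():
        if merged and merged[-1]["chrom"] == row["chrom"] and row["start"] <= merged[-1]["end"]:
            merged[-1]["end"] = max(merged[-1]["end"], row["end"])
        else:
            merged.append(dict(row))
    return pd.DataFrame(merged)
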