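"""De-regressed EBVs, genomic relationships, and mixed-model association.

The association model is the standard single-marker linear mixed model

    y = X m + W a + e,   a ~ N(0, G sigma_a^2),   e ~ N(0, I sigma_e^2)

with ``y`` the response (de-regressed EBVs or a phenotype), ``m`` the
marker effect, ``G`` the VanRaden realized relationship matrix, and the
variance components estimated once on the null model (no marker) by
REML via a single eigendecomposition of G, then held fixed across
markers (EMMAX-style).

De-regression follows Garrick's two-equation recipe: the parent-average
and individual information contents are recovered from the published
reliabilities, the individual's right-hand side is reconstructed, and
the de-regressed proof is that right-hand side divided by its
information. The weight for downstream weighted analyses is
w = (1 - h2) / ((c + (1 - r*^2)/r*^2) * h2) with r*^2 the reliability of
the de-regressed proof and c the fraction of genetic variance not
captured by markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variants import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default genome-wide and suggestive association thresholds.
GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5


def significance_lines(genome_wide: float = GENOME_WIDE_P, suggestive: float = SUGGESTIVE_P):
    """Return ``(genome_wide, suggestive)`` p-value thresholds."""
    if genome_wide <= 0 or suggestive <= 0:
        raise ValueError("significance thresholds must be positive")
    return float(genome_wide), float(suggestive)


# -------------------------------------------------------------- de-regression

def garrick_information(rel: float, pa_rel: float, h2: float):
    """Information contents (Z'Z terms) of the parent-average and the
    individual implied by their reliabilities under Garrick's recipe.

    Requires ``pa_rel < rel`` (the animal has own information) and
    ``pa_rel >= 0.5 - (2 - rel)/4`` for a non-negative parent-average
    information content.
    """
    if not (0 < h2 < 1):
        raise ValueError("h2 must lie in (0, 1)")
    if not (0 < pa_rel < 0.5):
        raise ValueError("pa_rel must lie in (0, 0.5)")
    if rel <= pa_rel:
        raise ValueError("no own information: rel must exceed pa_rel")
    rel = min(rel, 1 - 1e-12)  # guard rel -> 1
    lam = (1 - h2) / h2
    alpha = 1.0 / (0.5 - pa_rel)
    delta = (0.5 - pa_rel) / (1.0 - rel)
    zz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
    zz_i = delta * zz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    return float(zz_pa), float(zz_i)


@dataclass
class DEBVRecord:
    """One animal's de-regressed proof."""

    id: str
    ebv: float
    rel: float
    pa_ebv: float
    pa_rel: float
    debv: float
    weight: float
    rel_star: float  # reliability of the de-regressed proof
    c: float


def deregress_ebv(
    ebv: float,
    rel: float,
    pa_ebv: float,
    pa_rel: float,
    h2: float = 0.3,
    c: float = 0.1,
    animal_id: str = "",
) -> DEBVRecord:
    """Garrick de-regression of one EBV given its parent average.

    The individual's right-hand side of the 2x2 mixed-model system is
    y_i = -2 lambda pa_ebv + (Z'Z_i + 2 lambda) ebv and the de-regressed
    proof is DEBV = y_i / Z'Z_i.
    """
    if not (0 <= c < 1):
        raise ValueError("c must lie in [0, 1)")
    lam = (1 - h2) / h2
    zz_pa, zz_i = garrick_information(rel, pa_rel, h2)
    if zz_i <= 0:
        raise ValueError("non-positive individual information; check reliabilities")
    y_i = -2.0 * lam * pa_ebv + (zz_i + 2.0 * lam) * ebv
    debv = y_i / zz_i
    rel_star = zz_i / (zz_i + lam)
    weight = (1.0 - h2) / ((c + (1.0 - rel_star) / rel_star) * h2)
    return DEBVRecord(
        id=animal_id,
        ebv=float(ebv),
        rel=float(rel),
        pa_ebv=float(pa_ebv),
        pa_rel=float(pa_rel),
        debv=float(debv),
        weight=float(weight),
        rel_star=float(rel_star),
        c=float(c),
    )


def blend_forward(record: DEBVRecord, h2: float = 0.3) -> tuple[float, float]:
    """Invert de-regression: rebuild (ebv, rel) from a DEBV record.

    The EBV comes from the individual's mixed-model row,
    ebv = (Z'Z_i * debv + 2 lambda pa_ebv) / (Z'Z_i + 2 lambda), and the
    reliability from the proof reliability via Z'Z_i = lambda r*^2/(1-r*^2)
    solved against Garrick's information equation.
    """
    lam = (1 - h2) / h2
    zz_i = lam * record.rel_star / (1.0 - record.rel_star)
    ebv = (zz_i * record.debv + 2.0 * lam * record.pa_ebv) / (zz_i + 2.0 * lam)

    def f(rel):
        return garrick_information(rel, record.pa_rel, h2)[1] - zz_i

    rel = optimize.brentq(f, record.pa_rel + 1e-12, 1 - 1e-12, xtol=1e-14)
    return float(ebv), float(rel)


def deregress_table(
    ebv_table: pd.DataFrame, h2: float = 0.3, c: float = 0.1
) -> pd.DataFrame:
    """Vectorised de-regression of an EBV table.

    Expects columns ``id, ebv, rel, pa_ebv, pa_rel``. Logs the h2/c in
    use since these are analysis choices, not data.
    """
    logger.info("de-regressing %d EBVs with h2=%.3g, c=%.3g", len(ebv_table), h2, c)
    recs = [
        deregress_ebv(
            r.ebv, r.rel, r.pa_ebv, r.pa_rel, h2=h2, c=c, animal_id=str(r.id)
        )
        for r in ebv_table.itertuples()
    ]
    return pd.DataFrame([vars(r) for r in recs])


# ------------------------------------------------------------------------ GRM

def imputed_dosage(geno: GenotypeMatrix) -> np.ndarray:
    """Float dosage matrix with missing calls mean-imputed per locus."""
    g = geno.calls.astype(float)
    g[g == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    return np.where(np.isnan(g), mean, g)


def build_grm(geno: GenotypeMatrix, ridge: float = 1e-6) -> np.ndarray:
    """VanRaden method-1 realized relationship matrix.

    G = ZZ' / (2 sum p_k (1 - p_k)) with Z the dosages centered by twice
    the allele frequency; missing genotypes are mean-imputed before
    centering. A small ridge keeps G numerically positive semidefinite.
    """
    if (geno.calls == MISSING).all(axis=1).any():
        raise ValueError("a sample has no called genotypes")
    g = imputed_dosage(geno)
    p = g.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all loci monomorphic: GRM denominator is zero")
    g = g[:, poly]
    p = p[poly]
    z = g - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    grm = (z @ z.T) / denom
    grm[np.diag_indices_from(grm)] += ridge
    return grm


# ----------------------------------------------------------------------- REML

@dataclass
class RemlFit:
    """Null-model REML fit used by the association scan."""

    sigma_a2: float
    sigma_e2: float
    gamma: float  # sigma_a2 / sigma_e2
    loglik: float
    eigvals: np.ndarray  # of (weighted) G
    eigvecs: np.ndarray
    sqrt_w: np.ndarray  # sqrt of observation weights (ones if unweighted)


def fit_null_reml(
    y: np.ndarray,
    grm: np.ndarray,
    weights: np.ndarray | None = None,
    x: np.ndarray | None = None,
) -> RemlFit:
    """REML variance components for y = Xb + a + e via one
    eigendecomposition of (the weighted) G.

    With observation weights w the residual covariance is
    sigma_e^2 diag(1/w); pre-scaling by sqrt(w) reduces the problem to
    the unweighted one with G* = W^(1/2) G W^(1/2). The one-dimensional
    profile REML criterion in gamma = sigma_a^2/sigma_e^2 is maximised
    by bounded scalar search on log gamma.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 observations for REML")
    if x is None:
        x = np.ones((n, 1))
    sw = np.ones(n) if weights is None else np.sqrt(np.asarray(weights, dtype=float))
    if (sw <= 0).any():
        raise ValueError("weights must be positive")
    gs = grm * np.outer(sw, sw)
    d, u = np.linalg.eigh(gs)
    d = np.maximum(d, 0.0)
    yt = u.T @ (sw * y)
    xt = u.T @ (sw[:, None] * x)
    p = x.shape[1]

    def neg_restricted_ll(log_gamma: float) -> float:
        gamma = np.exp(log_gamma)
        v = gamma * d + 1.0
        xv = xt / v[:, None]
        xvx = xt.T @ xv
        beta = np.linalg.solve(xvx, xv.T @ yt)
        r = yt - xt @ beta
        rss = float(np.sum(r * r / v))
        if not np.isfinite(rss) or rss <= 0:
            return np.inf
        sigma_e2 = rss / (n - p)
        ll = -0.5 * (
            (n - p) * np.log(2.0 * np.pi * sigma_e2)
            + np.sum(np.log(v))
            + np.linalg.slogdet(xvx)[1]
            + (n - p)
        )
        return -ll

    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(
            f"REML likelihood non-finite (n={n}, gamma search failed): {res}"
        )
    gamma = float(np.exp(res.x))
    v = gamma * d + 1.0
    xv = xt / v[:, None]
    xvx = xt.T @ xv
    beta = np.linalg.solve(xvx, xv.T @ yt)
    r = yt - xt @ beta
    sigma_e2 = float(np.sum(r * r / v) / (n - p))
    return RemlFit(
        sigma_a2=gamma * sigma_e2,
        sigma_e2=sigma_e2,
        gamma=gamma,
        loglik=-float(res.fun),
        eigvals=d,
        eigvecs=u,
        sqrt_w=sw,
    )


# ----------------------------------------------------------------------- scan

def single_marker_scan(
    y: np.ndarray,
    geno: GenotypeMatrix,
    fit: RemlFit,
    gamma: float | None = None,
) -> pd.DataFrame:
    """EMMAX-style association scan with fixed variance components.

    Observations are rotated into the eigenbasis of G and whitened by
    sqrt(gamma d_i + 1); each marker is then an ordinary two-column
    regression (intercept + dosage) with a Wald z test against the
    Normal. Monomorphic markers are emitted with p = 1 and
    ``flag = "monomorphic"`` rather than dropped.

    Returns a DataFrame with chrom, pos, beta, se, z, p, flag.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != geno.n_samples:
        raise ValueError("response length does not match sample count")
    g = fit.gamma if gamma is None else gamma
    v = g * fit.eigvals + 1.0
    isv = 1.0 / np.sqrt(v)
    u = fit.eigvecs
    sw = fit.sqrt_w
    ys = isv * (u.T @ (sw * y))
    ones_s = isv * (u.T @ sw)

    dos = imputed_dosage(geno)
    xs = (u.T @ (sw[:, None] * dos)) * isv[:, None]  # (n, m) whitened markers

    aa = float(ones_s @ ones_s)
    ay = float(ones_s @ ys)
    yy = float(ys @ ys)
    ax = ones_s @ xs  # (m,)
    xy = ys @ xs
    xx = np.einsum("ij,ij->j", xs, xs)

    det = aa * xx - ax * ax
    mono = dos.std(axis=0) == 0
    det_safe = np.where(det > 1e-12 * np.maximum(aa * xx, 1e-300), det, np.nan)
    beta = (aa * xy - ax * ay) / det_safe
    alpha = (xx * ay - ax * xy) / det_safe
    rss = yy - alpha * ay - beta * xy
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 * aa / det_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    bad = mono | ~np.isfinite(z)
    p = np.where(bad, 1.0, p)
    out = pd.DataFrame(
        {
            "chrom": geno.loci["chrom"],
            "pos": geno.loci["pos"],
            "beta": np.where(bad, 0.0, beta),
            "se": np.where(bad, np.nan, se),
            "z": np.where(bad, 0.0, z),
            "p": p,
            "flag": np.where(mono, "monomorphic", ""),
        }
    )
    return out


def genomic_inflation(p: np.ndarray) -> float:
    """Genomic-control lambda: median association chi-square over its
    null expectation (0.4549)."""
    chi2 = stats.chi2.isf(np.asarray(p, dtype=float), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))
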