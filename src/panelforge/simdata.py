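"""Synthetic inputs with known ground truth for the panel pipeline.

Four generators cover everything downstream modules consume:

* :func:`simulate_populations` — two (or more) diverged populations of
  unrelated diploids under the Balding–Nichols model, which gives direct
  analytic control of the differentiation parameter F (the expected
  Hudson Fst).
* :func:`simulate_sweep_region` — a positive control for the sweep scan:
  inside a chosen region the test population's favored-allele frequency
  is pushed toward fixation via p -> p**(1/(1+strength)).
* :func:`simulate_breeding_values` — polygenic true breeding values from
  the simulated genotypes plus EBV/reliability tables generated through
  the same 2x2 parent-average mixed-model equations that Garrick
  de-regression inverts, so EBVs have the requested reliability and the
  de-regressed values are unbiased for the TBVs.
* :func:`simulate_capture_experiment` — targeted-capture depth (Gamma
  noise around a piecewise-exponential flank decay) and GBTS genotype
  calls with allele drop-out (ADO) on heterozygotes and whole-locus
  dropout.

Loci are simulated independent (no linkage disequilibrium); this is a
stated limitation, noted in the methods documentation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .variants import MISSING, GenotypeMatrix, write_vcf

logger = logging.getLogger(__name__)

# Default chromosome sizes of the simulated genome (bp). Two 10 Mb
# autosomes keep windowed scans dense at the default locus count.
DEFAULT_CHROM_LENGTHS = {"chr1": 10_000_000, "chr2": 10_000_000}


def _draw_law(law, rng: np.random.Generator, size: int) -> np.ndarray:
    """Draw from a distribution spec: ("uniform", lo, hi), ("beta", a, b),
    a float (point mass), or a callable(rng, size)."""
    if callable(law):
        return np.asarray(law(rng, size), dtype=float)
    if np.isscalar(law):
        return np.full(size, float(law))
    name, *args = law
    if name == "uniform":
        return rng.uniform(args[0], args[1], size)
    if name == "beta":
        return rng.beta(args[0], args[1], size)
    if name == "normal":
        return rng.normal(args[0], args[1], size)
    raise ValueError(f"unknown distribution spec {law!r}")


@dataclass
class PopulationSimConfig:
    """Two-or-more population genotype simulation settings.

    Defaults emulate a resequencing cohort of 110 unrelated dairy goats
    split into a European group (68) and a Chinese indigenous group (42)
    with moderate differentiation.
    """

    n_populations: int = 2
    samples_per_pop: tuple = (68, 42)
    n_loci: int = 20_000
    chrom_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    target_fst: float = 0.1
    ancestral_maf_law: tuple = ("uniform", 0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.target_fst < 1):
            raise ValueError("target_fst must lie in [0, 1)")
        if self.n_populations < 1 or len(self.samples_per_pop) != self.n_populations:
            raise ValueError("samples_per_pop must list one count per population")
        if any(s < 1 for s in self.samples_per_pop):
            raise ValueError("each population needs at least one sample")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not self.chrom_lengths or any(v < 1 for v in self.chrom_lengths.values()):
            raise ValueError("chrom_lengths must be positive")


@dataclass
class CaptureSimConfig:
    """Targeted-capture (GBTS) genotyping simulation settings.

    Depth anchors default to 91X on target with 60X / 26X at 100 / 250 bp
    offsets; flank decay is piecewise-exponential through those anchors.
    ``ado_prob`` is the chance a heterozygote is emitted as one of its
    homozygotes (fair coin between them); ``dropout_prob`` the chance a
    target x sample yields no call (and zero depth).
    """

    target_mean_depth: float = 91.0
    flank_depth_100bp: float = 60.0
    flank_depth_250bp: float = 26.0
    flank_halfwidth: int = 500
    depth_dispersion: float = 0.3
    ado_prob: float = 0.02
    dropout_prob: float = 0.012
    seed: int = 0

    def validate(self) -> None:
        if min(self.target_mean_depth, self.flank_depth_100bp, self.flank_depth_250bp) <= 0:
            raise ValueError("depths must be positive")
        if not (self.flank_depth_250bp <= self.flank_depth_100bp <= self.target_mean_depth):
            raise ValueError("flank depths must decay with distance from the target")
        for p in (self.ado_prob, self.dropout_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")


@dataclass
class BreedingSimConfig:
    """Polygenic trait / EBV simulation settings."""

    h2: float = 0.3
    n_causal: int = 100
    effect_law: tuple = ("normal", 0.0, 1.0)
    reliability_law: tuple = ("uniform", 0.5, 0.9)
    pa_rel: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.h2 < 1):
            raise ValueError("h2 must lie in (0, 1)")
        if self.n_causal < 1:
            raise ValueError("n_causal must be >= 1")
        if not (0 < self.pa_rel < 0.5):
            raise ValueError("pa_rel must lie in (0, 0.5)")


@dataclass
class PopulationTruth:
    """Ground truth accompanying a simulated genotype matrix."""

    freqs: np.ndarray  # (n_pops, n_loci) true per-population alt frequencies
    pop_of_sample: pd.Series  # sample id -> population label
    pop_labels: list
    config: PopulationSimConfig

    def pop_index(self, label) -> np.ndarray:
        return np.flatnonzero((self.pop_of_sample == label).to_numpy())


# ----------------------------------------------------------------- genotypes

def simulate_populations(cfg: PopulationSimConfig):
    """Balding–Nichols genotypes for diverged populations.

    Per locus an ancestral frequency p is drawn from
    ``ancestral_maf_law``; each population's frequency is then
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``target_fst`` (a point mass
    at p when F = 0), and diploid genotypes are Binomial(2, freq).

    Returns ``(GenotypeMatrix, PopulationTruth)``; deterministic under a
    fixed seed.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.n_loci

    # positions: strictly increasing within chromosome, loci spread
    # proportionally to chromosome length
    lengths = np.array(list(cfg.chrom_lengths.values()), dtype=float)
    chroms = list(cfg.chrom_lengths.keys())
    per_chrom = np.maximum(1, np.round(L * lengths / lengths.sum()).astype(int))
    # adjust rounding drift
    while per_chrom.sum() > L:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < L:
        per_chrom[np.argmin(per_chrom / lengths)] += 1
    rows = []
    for c, n_c in zip(chroms, per_chrom):
        ln = cfg.chrom_lengths[c]
        pos = np.sort(rng.choice(np.arange(1, ln + 1), size=min(n_c, ln), replace=False))
        rows.append(pd.DataFrame({"chrom": c, "pos": pos}))
    loci = pd.concat(rows, ignore_index=True)
    L = len(loci)

    ref_alt = rng.integers(0, 4, size=(L, 2))
    ref_alt[:, 1] = (ref_alt[:, 0] + 1 + rng.integers(0, 3, size=L)) % 4
    bases = np.array(list("ACGT"))
    loci["ref"] = bases[ref_alt[:, 0]]
    loci["alt"] = bases[ref_alt[:, 1]]

    p_anc = _draw_law(cfg.ancestral_maf_law, rng, L)
    F = cfg.target_fst
    freqs = np.empty((cfg.n_populations, L))
    if F == 0:
        freqs[:] = p_anc
    else:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        for k in range(cfg.n_populations):
            freqs[k] = rng.beta(a, b)

    samples: list[str] = []
    pop_of_sample = []
    calls = np.empty((sum(cfg.samples_per_pop), L), dtype=np.int8)
    row = 0
    pop_labels = [f"pop{k + 1}" for k in range(cfg.n_populations)]
    for k, n_k in enumerate(cfg.samples_per_pop):
        calls[row : row + n_k] = rng.binomial(2, freqs[k], size=(n_k, L)).astype(np.int8)
        samples.extend(f"{pop_labels[k]}_s{i + 1:03d}" for i in range(n_k))
        pop_of_sample.extend([pop_labels[k]] * n_k)
        row += n_k
    geno = GenotypeMatrix(samples, loci, calls, dict(cfg.chrom_lengths))
    truth = PopulationTruth(
        freqs=freqs,
        pop_of_sample=pd.Series(pop_of_sample, index=samples),
        pop_labels=pop_labels,
        config=cfg,
    )
    return geno, truth


def simulate_sweep_region(
    geno: GenotypeMatrix,
    truth: PopulationTruth,
    region: tuple,
    strength: float,
    swept_pop=None,
    seed: int = 0,
):
    """Overlay a selective sweep on one population inside ``region``.

    ``region`` is ``(chrom, start, end)`` in 0-based half-open bp. Within
    it the swept population's favored allele (its current major allele)
    has frequency transformed p -> p**(1/(1+strength)) and genotypes are
    redrawn from the new frequency; everything outside is untouched.
    ``strength = 0`` returns an unmodified copy.

    Returns ``(GenotypeMatrix, PopulationTruth)`` copies with the truth
    frequencies updated.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    chrom, start, end = region
    if chrom not in set(geno.loci["chrom"]):
        raise ValueError(f"region chromosome {chrom!r} not in simulated coordinates")
    lengths = geno.chrom_lengths or {}
    if end <= start or start < 0 or (chrom in lengths and start >= lengths[chrom]):
        raise ValueError(f"region {region} outside simulated coordinates")
    in_region = (
        (geno.loci["chrom"] == chrom)
        & (geno.loci["pos"] - 1 >= start)
        & (geno.loci["pos"] - 1 < end)
    ).to_numpy()
    if in_region.all():
        warnings.warn("sweep region covers every simulated locus", stacklevel=2)
    out = geno.copy()
    new_truth = PopulationTruth(
        truth.freqs.copy(), truth.pop_of_sample.copy(), list(truth.pop_labels), truth.config
    )
    if strength == 0 or not in_region.any():
        return out, new_truth

    if swept_pop is None:
        swept_pop = truth.pop_labels[-1]
    k = truth.pop_labels.index(swept_pop)
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(in_region)
    p = new_truth.freqs[k, idx]
    expo = 1.0 / (1.0 + strength)
    # push the current major allele toward fixation
    p_new = np.where(p >= 0.5, p**expo, 1.0 - (1.0 - p) ** expo)
    new_truth.freqs[k, idx] = p_new
    rows = new_truth.pop_index(swept_pop)
    out.calls[np.ix_(rows, idx)] = rng.binomial(
        2, p_new, size=(len(rows), len(idx))
    ).astype(np.int8)
    return out, new_truth


# ------------------------------------------------------------ breeding values

def simulate_breeding_values(geno: GenotypeMatrix, cfg: BreedingSimConfig):
    """Polygenic phenotypes and EBV tables with controlled reliability.

    True breeding values are TBV = sum(effect * dosage) over ``n_causal``
    loci, centered; phenotype = TBV + environmental noise scaled so
    Var(TBV)/Var(phenotype) = h2. EBVs are produced by solving, per
    animal, the 2x2 parent-average mixed-model system with information
    contents chosen (Garrick's recipe) to give each animal its drawn
    reliability; this makes squared correlation(EBV, TBV) equal the
    reliability and keeps the table exactly de-regressable.

    Returns ``(ebv_table, truth_df)`` where ``ebv_table`` has columns
    ``id, ebv, rel, pa_ebv, pa_rel, sire, dam`` and ``truth_df`` carries
    ``tbv, phenotype`` plus the causal loci/effects in ``attrs``.
    """
    from .gwas import garrick_information

    cfg.validate()
    if cfg.n_causal > geno.n_loci:
        raise ValueError("n_causal exceeds the number of loci")
    rng = np.random.default_rng(cfg.seed)
    causal = np.sort(rng.choice(geno.n_loci, size=cfg.n_causal, replace=False))
    effects = _draw_law(cfg.effect_law, rng, cfg.n_causal)

    g = geno.calls[:, causal].astype(float)
    g[g == MISSING] = np.nan
    col_mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), col_mean, g)
    tbv = g @ effects
    tbv = tbv - tbv.mean()
    var_a = float(tbv.var(ddof=1))
    if var_a == 0:
        raise ValueError("degenerate simulation: TBV variance is zero")
    var_e = var_a * (1 - cfg.h2) / cfg.h2
    phen = tbv + rng.normal(0, np.sqrt(var_e), geno.n_samples)

    rel = np.clip(_draw_law(cfg.reliability_law, rng, geno.n_samples), 1e-6, 1 - 1e-9)
    lam = (1 - cfg.h2) / cfg.h2
    sigma_e2 = lam * var_a  # residual variance on the EBV scale

    # parent-average true values consistent with Var(PA)=sigma_a^2/2,
    # Cov(PA, TBV)=sigma_a^2/2 for unrelated parents drawn from the base
    pa_true = 0.5 * tbv + rng.normal(0, np.sqrt(var_a / 4.0), geno.n_samples)

    ebv = np.empty(geno.n_samples)
    pa_ebv = np.empty(geno.n_samples)
    for i in range(geno.n_samples):
        zz_pa, zz_i = garrick_information(rel[i], cfg.pa_rel, cfg.h2)
        y_pa = zz_pa * pa_true[i] + rng.normal(0, np.sqrt(max(zz_pa, 0) * sigma_e2))
        y_i = zz_i * tbv[i] + rng.normal(0, np.sqrt(zz_i * sigma_e2))
        lhs = np.array(
            [[zz_pa + 4 * lam, -2 * lam], [-2 * lam, zz_i + 2 * lam]]
        )
        sol = np.linalg.solve(lhs, [y_pa, y_i])
        pa_ebv[i], ebv[i] = sol

    ebv_table = pd.DataFrame(
        {
            "id": geno.samples,
            "ebv": ebv,
            "rel": rel,
            "pa_ebv": pa_ebv,
            "pa_rel": cfg.pa_rel,
            "sire": "0",
            "dam": "0",
        }
    )
    truth_df = pd.DataFrame({"id": geno.samples, "tbv": tbv, "phenotype": phen})
    truth_df.attrs["causal_idx"] = causal
    truth_df.attrs["effects"] = effects
    truth_df.attrs["var_tbv"] = var_a
    return ebv_table, truth_df


# ------------------------------------------------------------------- capture

def flank_decay_factor(offsets: np.ndarray, cfg: CaptureSimConfig) -> np.ndarray:
    """Relative depth vs |offset|, piecewise-exponential through the
    anchors (0, 1), (100, d100/d0), (250, d250/d0); the second rate
    extends beyond 250 bp."""
    off = np.abs(np.asarray(offsets, dtype=float))
    r1 = np.log(cfg.target_mean_depth / cfg.flank_depth_100bp) / 100.0
    r2 = np.log(cfg.flank_depth_100bp / cfg.flank_depth_250bp) / 150.0
    f_near = np.exp(-r1 * off)
    f100 = cfg.flank_depth_100bp / cfg.target_mean_depth
    f_far = f100 * np.exp(-r2 * (off - 100.0))
    return np.where(off <= 100.0, f_near, f_far)


@dataclass
class CaptureResult:
    """Outputs of a simulated GBTS run."""

    depths: pd.DataFrame  # targets x samples read depths (index chrom:pos)
    flank: pd.DataFrame  # long table: offset, depth draws pooled over targets
    gbts: GenotypeMatrix  # called genotypes (with ADO / dropout errors)
    truth_panel: GenotypeMatrix  # truth restricted to the panel loci


def simulate_capture_experiment(
    truth_geno: GenotypeMatrix,
    panel_loci: pd.DataFrame,
    cfg: CaptureSimConfig,
) -> CaptureResult:
    """Simulate targeted-capture sequencing of ``panel_loci``.

    Depth per target x sample is Gamma with mean ``target_mean_depth``
    and CV ``depth_dispersion``; dropout zeroes both depth and call. The
    flank table draws per-offset depths (25 bp grid to ±flank_halfwidth)
    whose means follow the piecewise-exponential decay. GBTS calls copy
    the truth except for dropout no-calls and ADO on heterozygotes.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    key = truth_geno.locus_key()
    want = pd.Index(panel_loci["chrom"].astype(str) + ":" + panel_loci["pos"].astype(str))
    pos_map = pd.Series(np.arange(len(key)), index=key)
    missing = want.difference(key)
    if len(missing):
        raise ValueError(f"panel locus absent from truth genotypes: {missing[0]}")
    idx = pos_map.loc[want].to_numpy()
    sub = truth_geno.subset_loci(idx)
    n_t, n_s = sub.n_loci, sub.n_samples

    shape = 1.0 / cfg.depth_dispersion**2
    depths = rng.gamma(shape, cfg.target_mean_depth / shape, size=(n_t, n_s))
    dropout = rng.random((n_t, n_s)) < cfg.dropout_prob
    depths[dropout] = 0.0

    offsets = np.arange(-cfg.flank_halfwidth, cfg.flank_halfwidth + 1, 25)
    factors = flank_decay_factor(offsets, cfg)
    n_draw = min(n_t * n_s, 2000)  # pooled library draws per offset
    fl_rows = []
    for off, f in zip(offsets, factors):
        mean = cfg.target_mean_depth * f
        d = rng.gamma(shape, mean / shape, size=n_draw)
        fl_rows.append(pd.DataFrame({"offset": off, "depth": d}))
    flank = pd.concat(fl_rows, ignore_index=True)

    calls = sub.calls.T.copy()  # (targets, samples)
    het = calls == 1
    ado = het & (rng.random((n_t, n_s)) < cfg.ado_prob)
    calls[ado] = np.where(rng.random((n_t, n_s)) < 0.5, 0, 2)[ado]
    calls[dropout] = MISSING
    gbts = GenotypeMatrix(
        list(sub.samples), sub.loci.copy(), calls.T, sub.chrom_lengths
    )

    depth_df = pd.DataFrame(depths, index=list(sub.locus_key()), columns=sub.samples)
    depth_df.index.name = "target"
    return CaptureResult(depths=depth_df, flank=flank, gbts=gbts, truth_panel=sub)


# ------------------------------------------------------------------ fixtures

def simulate_qtl_regions(
    chrom_lengths: dict, n_regions: int = 12, width: int = 200_000, seed: int = 0
) -> pd.DataFrame:
    """Random trait-tagged QTL intervals (BED-style 0-based half-open)."""
    tags = ["FU", "FL", "GA", "RU", "SL", "TE"]
    rng = np.random.default_rng(seed)
    rows = []
    chroms = list(chrom_lengths)
    for _ in range(n_regions):
        c = chroms[rng.integers(len(chroms))]
        ln = chrom_lengths[c]
        start = int(rng.integers(0, max(1, ln - width)))
        rows.append(
            {
                "chrom": c,
                "start": start,
                "end": start + width,
                "trait_tag": tags[rng.integers(len(tags))],
            }
        )
    out = pd.DataFrame(rows).sort_values(["chrom", "start"], kind="mergesort")
    return out.reset_index(drop=True)


def write_fixture_set(
    outdir,
    pop_cfg: PopulationSimConfig | None = None,
    breeding_cfg: BreedingSimConfig | None = None,
    capture_cfg: CaptureSimConfig | None = None,
    panel_every: int = 10,
    panel_loci: pd.DataFrame | None = None,
    n_qtl: int = 12,
):
    """Generate one coherent fixture set and write it in standard formats.

    Emits under ``outdir``: ``truth.vcf`` (resequencing genotypes),
    ``gbts.vcf`` (capture calls on a thinned panel), ``depth.tsv``,
    ``flank_depth.tsv``, ``qtl.bed``, ``ebv.tsv`` and ``config.json``.
    Returns a dict of the written paths plus the in-memory objects.
    """
    from pathlib import Path

    pop_cfg = pop_cfg or PopulationSimConfig()
    breeding_cfg = breeding_cfg or BreedingSimConfig(
        n_causal=min(100, pop_cfg.n_loci), seed=pop_cfg.seed + 1
    )
    capture_cfg = capture_cfg or CaptureSimConfig(seed=pop_cfg.seed + 2)

    if panel_loci is not None and panel_loci.empty:
        raise ValueError("empty panel: no loci to capture")
    geno, truth = simulate_populations(pop_cfg)
    if panel_loci is None:
        panel_loci = geno.loci.iloc[::panel_every][["chrom", "pos", "ref", "alt"]]
    if panel_loci.empty:
        raise ValueError("empty panel: no loci to capture")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    ebv_table, truth_df = simulate_breeding_values(geno, breeding_cfg)
    capture = simulate_capture_experiment(geno, panel_loci, capture_cfg)
    qtl = simulate_qtl_regions(pop_cfg.chrom_lengths, n_regions=n_qtl, seed=pop_cfg.seed + 3)

    paths = {
        "truth_vcf": outdir / "truth.vcf",
        "gbts_vcf": outdir / "gbts.vcf",
        "depth_tsv": outdir / "depth.tsv",
        "flank_tsv": outdir / "flank_depth.tsv",
        "qtl_bed": outdir / "qtl.bed",
        "ebv_tsv": outdir / "ebv.tsv",
        "pops_tsv": outdir / "populations.tsv",
        "config_json": outdir / "config.json",
    }
    write_vcf(geno, paths["truth_vcf"])
    write_vcf(capture.gbts, paths["gbts_vcf"])
    capture.depths.to_csv(paths["depth_tsv"], sep="\t")
    capture.flank.to_csv(paths["flank_tsv"], sep="\t", index=False)
    qtl.to_csv(paths["qtl_bed"], sep="\t", header=False, index=False)
    ebv_table.to_csv(paths["ebv_tsv"], sep="\t", index=False)
    truth.pop_of_sample.rename("population").to_csv(
        paths["pops_tsv"], sep="\t", index_label="id"
    )
    with open(paths["config_json"], "w") as fh:
        json.dump(
            {
                "population": asdict(pop_cfg),
                "breeding": asdict(breeding_cfg),
                "capture": asdict(capture_cfg),
                "panel_every": panel_every,
            },
            fh,
            indent=2,
            default=str,
        )
    return {
        "paths": paths,
        "geno": geno,
        "truth": truth,
        "ebv": ebv_table,
        "breeding_truth": truth_df,
        "capture": capture,
        "qtl": qtl,
    }
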