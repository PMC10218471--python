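# Methods

This note documents the models behind panelforge, the defaults and why
they were chosen, the numerical choices, and what the synthetic-data
tests do and do not establish about real data.

## Population simulation

Genotypes follow the Balding–Nichols model: per locus an ancestral
frequency *p* is drawn (default Uniform(0.05, 0.5), matching a
discovery set already screened for MAF ≥ 0.05); each population's
frequency is Beta(p(1−F)/F, (1−p)(1−F)/F) with *F* the target Fst
(degenerating to a point mass at F = 0), and diploid genotypes are
Binomial(2, freq). This construction was preferred over coalescent
simulation because it gives direct, analytic control of the
differentiation parameter: the Hudson ratio-of-averages estimator
converges to *F* as loci grow, which the tests verify at 20k loci to
±0.02. Defaults (two groups of 68 and 42 diploids, F = 0.1) mirror a
resequencing cohort of 110 animals from two diverged breed clusters.
Loci are simulated independently — there is no linkage disequilibrium —
so haplotype-based statistics are out of reach and window statistics
have somewhat less autocorrelation than real data would show.

A sweep overlay transforms the test population's major-allele frequency
*p → p^(1/(1+s))* inside a chosen region and redraws genotypes there;
*s* = 0 is an exact identity. Strength 5 (the positive-control setting)
drives, e.g., p = 0.5 to ≈ 0.89.

## Breeding values and de-regression

True breeding values are TBV = Σ effect·dosage over `n_causal` loci
(effects standard normal), and phenotype = TBV + noise scaled so
Var(TBV)/Var(phenotype) = h².

EBVs are *not* simulated as TBV plus noise. A published EBV is a shrunk,
parent-average-blended quantity, and de-regression presumes exactly that
structure. The simulator therefore generates each animal's EBV through
the same 2×2 mixed-model system Garrick's recipe inverts: reliabilities
(rel, pa_rel) determine the information contents Z'Z_PA and Z'Z_i;
pseudo-observations with those information contents are drawn around the
parent-average true value and the TBV; and the MME solve yields
(pa_ebv, ebv). This makes three properties hold simultaneously and
exactly in expectation: corr²(EBV, TBV) = rel, de-regression reproduces
the generating right-hand side, and the regression of DEBV on TBV has
slope 1. The reliability identity rel = 1 − λ·C₂₂ (λ = (1−h²)/h², C the
inverse coefficient matrix) holds algebraically in this recipe and is
asserted in the tests.

Garrick's Z'Z_PA is non-negative only when pa_rel ≥ 0.5 − (2 − rel)/4;
the simulator default pa_rel = 0.3 satisfies this for every rel < 1.
With unrelated parents the parent-average true value is drawn as
TBV/2 + N(0, σa²/4), the conditional distribution implied by
Var(PA) = σa²/2, Cov(PA, TBV) = σa²/2. The de-regression defaults
h² = 0.3 and c = 0.1 are analysis choices, logged at run time.

## Sweep statistics

Windows are fixed 50 kb with a 25 kb step and ≥ 5 SNPs — conventional
desk-scale settings; all three are configurable. Hudson's estimator is
the default because the ratio-of-averages form is robust to small and
unequal sample sizes; Weir–Cockerham per-site components are available
as a switch for parity with vcftools-style output. Per-site components
at sites with fewer than two called chromosomes in either group are
skipped and counted.

π uses the unbiased per-site heterozygosity n/(n−1)·2p̂(1−p̂), which
equals the mean pairwise difference k(n−k)/C(n,2); the tests verify this
identity against exhaustive pair enumeration to 1e-10. The window ratio
log2(π_a/π_b) is the diversity-loss signal for a sweep in the test
group.

The composite selection score is a deliberate simplification of the
cross-population composite likelihood ratio test. Per site, the latent
test-population frequency *q* has a truncated-Normal density centred on
the (possibly selection-shifted) reference frequency with variance
p̂a(1−p̂a)·(ω + 1/na); the 1/na term accounts for the reference
frequency being estimated, without which null data are over-dispersed
relative to the model and the score inflates. ω is estimated genome-wide
by method of moments (floored at 1e-4). Observed counts are Binomial
given *q*, integrated by 256-node Gauss–Legendre quadrature on [0, 1]
(verified against dense numeric integration to 1e-6 relative). Because
which allele is favored is unknown, the selection likelihood averages
both orientations with equal weight — a proper mixture that is nested in
the null at s = 0, keeping the per-site null expectation of the
log-ratio non-positive. The score is the window sum maximised over
s ∈ {0, 0.1, 0.25, 0.5, 1, 2, 5, 10}; requiring 0 in the grid makes it
non-negative. Known deviations from the original program: no LD-based
down-weighting of correlated sites (loci are simulated independent) and
a single genome-wide ω. Region calling uses a 2-of-3 vote at the 99th
percentile of Fst, π-ratio and the composite score, merging adjacent
windows; the vote and quantile are explicit choices, not inherited
conventions.

## Mixed-model GWAS

G is VanRaden method 1, G = ZZ'/(2Σp(1−p)) with mean imputation of
missing dosages before centering and a 1e-6 diagonal ridge. REML for
y = Xb + a + e uses a single eigendecomposition of G (with observation
weights w, of W^½GW^½ after scaling by √w): the profile restricted
likelihood is one-dimensional in γ = σa²/σe² and is maximised by bounded
search on log γ ∈ [−12, 12]. Variance components are then held fixed
across markers (EMMAX-style); each marker is an ordinary two-column
regression in the whitened basis with a per-marker residual scale and a
Wald test against the Normal. With G = I and γ → 0 this reduces exactly
to OLS, asserted to 1e-8 against statsmodels. The variance ratio is
identifiable only when G has eigenvalue spread; on cohorts of near-
unrelated animals the REML surface is nearly flat in γ — a property of
the model, not a defect of the optimiser. Monomorphic markers are
reported with p = 1 and a flag rather than dropped, keeping row order
aligned with the locus table. Significance defaults are 5e-8
(genome-wide) and 1e-5 (suggestive). A binary trait is handled as 0/1 on
the linear mixed model; no liability-scale transform is applied.

## Panel assembly

Candidates merge with source priority gwas > qtl > sweep > gapfill,
preferring trait-linked content; ties break by genomic order, so
assembly is deterministic. Gap filling is greedy and per chromosome:
every inter-locus (or locus-to-chromosome-end) gap wider than the
target spacing receives the pool locus with MAF ≥ 0.05 nearest each
ideal equally-spaced position. Because filling only ever splits
existing gaps, the maximum adjacent gap can never grow. When the union
exceeds K, loci are dropped from the densest neighbourhoods first
(smallest sum of flanking gaps), lowest-priority sources first; when it
falls short, the largest remaining gaps are split until exactly K. The
MAF bound for gap filling is 0.05, consistent with the site filter.

Probe designability is approximated by a transparent filter: no other
pool variant within the 120 bp probe window, plus probe-window GC in
[0.3, 0.7] when a reference FASTA is available (the GC check needs
sequence, which a VCF-only run does not carry). This replaces
proprietary probe scoring with a reproducible proxy; it is not a model
of capture chemistry.

## Capture simulation and QC

Per-target depth is Gamma with mean 91X and CV 0.3 (dispersion is
configurable; only mean anchors are externally constrained). Flank
depth decays piecewise-exponentially through the anchors 91X at 0 bp,
60X at 100 bp and 26X at 250 bp, extending the second rate to ±500 bp.
Genotype errors are: whole-target dropout (probability 0.012 per
target × sample; zero depth and no call) and allele drop-out
(probability 0.02 that a heterozygote is emitted as one of its
homozygotes, fair coin) — only one allele amplifying to a detectable
level is the mechanism being mimicked. Those two defaults were set so
that the default simulated study reproduces the validation regime the
panel targets: detection rate dp0 ≈ 98.8%, GBTS-vs-WGS concordance
≈ 98%, and missed targets (gbts_miss) as the dominant discordance class.

Detection-rate semantics: dp0 counts depth strictly > 0; dp5 and dp20
count depth ≥ threshold, so the three labels form a coherent family;
the convention is switchable. Concordance classification is the six-way
taxonomy over dosage pairs; pairs missing on both platforms are excluded
from the denominator. Both pooled and per-sample-mean concordance are
reported because either aggregation is defensible. The
gbts_hom / heterozygous-truth ratio is a consistent estimator of the
injected ADO probability (checked by binomial interval across seeds).
opposite_hom is kept as its own class so the taxonomy partitions; it is
not folded into either platform's attribution.

## Problem sizes

The default end-to-end run uses 110 discovery animals, 40k loci on two
10 Mb chromosomes, an 8,000-locus panel (target spacing 2.5 kb, the
same genome-length-to-K ratio as a 54K panel on a 2.6 Gb genome) and
200 validation animals. These sizes keep a full run to a few minutes on
one CPU while preserving the density relationships that matter for the
windowed scan and the spacing report; all of them are configuration,
not constants.

## What the synthetic tests do not show

The generators emulate drift-structured allele frequencies, calibrated
EBV reliabilities and capture-side genotyping error, but not linkage
disequilibrium, reference-bias or mapping artifacts, batch structure in
capture efficiency, pedigree relationships within groups, or
ascertainment of the discovery SNPs. Passing tests therefore establish
internal correctness (estimators recover known truth; contracts hold),
not field performance of a physical probe set. Family structure is
absent by design: all animals within a group are unrelated, so the GRM's
structure comes from group differentiation only.
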