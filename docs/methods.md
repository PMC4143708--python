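# Methods

## Model and test

`trioskat` tests whether a genomic region (gene) is associated with a
quantitative or dichotomous offspring trait using *trios* — father,
mother, offspring — as the unit of analysis.  For trio *i* with trait
`Y_i`, covariates `C_i` (always including an intercept) and offspring
dosages `X_i = (X_i1 … X_im)` over the region's m variants, the working
model is a generalized linear mixed model

    h(E[Y_i]) = C_i α + X_i β,

with the identity link for continuous traits and the logit link for
dichotomous traits.  The variant effects β_j are treated as independent
random effects with mean 0 and variance w_j² τ; "no genetic effect" is
the variance-component null H0: τ = 0.  The score statistic is the
quadratic form

    Q_ρ = (Y − μ̂0)ᵀ S W R_ρ W Sᵀ (Y − μ̂0),

where μ̂0 is the null fit (μ̂0 = Cα̂ or logit⁻¹(Cα̂)),
S = X − E(X | X_p) are the offspring dosages centered at their Mendelian
conditional expectation given the parental genotypes X_p
(E(X_ij | X_p) = (g_father + g_mother)/2 under additive coding),
W = diag(w_j) and R_ρ = (1−ρ)I + ρ11ᵀ.  ρ = 0 gives the
variance-component kernel test (family-based SKAT): Q_0 = Σ_j w_j² u_j²
with u_j = Σ_i (Y_i − μ̂_i,0)(X_ij − E(X_ij|X_p)).  ρ = 1 gives the
collapsing burden statistic Q_1 = (Σ_j w_j u_j)², the squared FBAT-style
weighted transmission score.  The burden form follows directly from the
kernel definition W R_1 W = (W1)(W1)ᵀ, so each weight enters once.

Conditioning the genotype scores on the parents makes the test a
transmission-disequilibrium-type test: under H0, given parents and
trait, each score entry has mean zero regardless of population structure,
which is why the test is robust to stratification and admixture.

### Weights

w_j = Beta-density(f̂_j; a, b) with the parental minor-allele frequency
f̂_j (coded alleles among non-missing parents over parental allele
count).  Defaults a = 1, b = 25, the established convention that
upweights rare variants (w ≈ 20+ below MAF 0.01, w < 0.01 above MAF
0.3).  Weights are computed from the variants actually included in a
given stratum, not genome-wide.  Monomorphic-in-parents variants are
excluded before weighting (the density diverges at 0 for a < 1).

### Null distribution and p-values

Under H0, conditionally on parents and trait, Q_ρ converges to a mixture
Σ_j λ_j χ²_1.  The λ_j are the eigenvalues of W R_ρ W V with
V = Cov(Sᵀ r | X_p, Y) = Σ_i r_i² v_i, where r = Y − μ̂0 and v_i is the
conditional covariance of trio i's score vector.  Two estimators of v_i
are provided:

* `mendelian` (default): v_i diagonal with entries Var(X_ij | X_p) from
  the transmission law (0.25 per heterozygous parent).  Transmissions at
  different variants are treated as independent given parents — exact for
  variants in linkage equilibrium, which is what the simulator generates.
* `empirical`: v_i = s_i s_iᵀ, the observed score outer products,
  appropriate for real, linked variants.

Eigenvalues are computed from the symmetrized form
V^{1/2} W R_ρ W V^{1/2}, clipped at zero and truncated below
1e-10 × λ_max.

P-values come from numerically inverting the characteristic function of
the mixture (Gil-Pelaez/Imhof integral).  The smooth head of the
integral is handled by adaptive quadrature and the oscillatory tail by
Fourier-weighted quadrature with cycle extrapolation, giving ~1e-9
absolute accuracy even for a single component (verified against χ²
closed forms).  If the quadrature error estimate is unusable the code
falls back to Liu-type moment matching: the first cumulants of the
mixture are matched to a scaled (non)central chi-square, exact when only
one component is present.

### Small-sample behaviour (important caveat)

The mixture law is a *limiting* distribution.  Its accuracy per variant
is governed by the number of informative transmissions (heterozygous
parents).  A variant with a single heterozygous parent contributes
u_j² = λ_j *deterministically* (the score is ±r_i/2 either way), so when
many near-singleton variants carry large Beta(1,25) weights the true
conditional null of Q_0 is lighter-tailed than the mixture and the
kernel test is conservative.  At the default study scale (93 trios,
30 variants, 80% rare with a 1/f spectrum down to 1/(4N)) the measured
type-I error of the kernel test at α = 0.05 is ≈ 0.01–0.02, while the
burden test — whose single aggregated score is approximately normal —
calibrates at ≈ 0.05.  The acceptance script and the test suite measure
and report exactly this.  With common variants (or larger per-variant
informativeness) both tests calibrate at both N = 93 and N = 1000.  The
test is conservative, never anti-conservative, in every regime we
measured; the suite asserts that validity property under the rare
default.  Users testing very rare variants in small trio samples should
prefer the burden statistic or interpret kernel p-values as conservative
bounds.

## Trio extraction

Offspring are grouped by their unordered (father, mother) pair within a
family; for each pair whose father, mother and at least one offspring
are genotyped, exactly one genotyped offspring is drawn uniformly at
random (seeded, reproducible).  Each parent pair contributes at most one
trio, so transmissions are independent across trios given parents.
Half-siblings form distinct parent pairs and may each contribute a trio.
The random draw is made among genotype-complete offspring only, so no
family is lost to an unlucky draw.  Residual per-variant missingness
inside a selected trio is handled by zeroing that trio-variant score and
its variance (no imputation, no trio dropping); Mendelian-inconsistent
cells are likewise zeroed and counted.

Minor-allele recoding uses the parental sample only; at a frequency tie
of exactly 0.5 the ALT allele (VCF) or allele "1" (dosage matrix) stays
coded.  BED intervals are 0-based half-open, VCF positions 1-based; the
conversion lives in one function (`bed_interval_to_vcf`).

## Synthetic cohorts

The simulator generates what the analysis needs and nothing more:

* **Parents**: independent Hardy–Weinberg draws from a MAF spectrum with
  a configurable rare fraction (default 0.8).  Rare frequencies follow a
  density ∝ 1/f on (1/(4N), 0.05], a neutral-spectrum caricature that
  produces realistic rare-variant sparsity at N = 93; common frequencies
  are uniform on (0.05, 0.5].
* **Offspring**: one allele from each parent (transmit probability =
  dosage/2), so cohorts are Mendelian-consistent by construction.
* **Traits**: trait1 = β0 + Xβ + ε1 and trait2 with effects scaled by a
  sharing factor (default 0.8) and residual correlation 0.6 — a stand-in
  for a highly correlated blood-pressure pair — plus a pure-noise null
  trait for type-I-error work.  Effect magnitudes default to
  |β_j| = c·|log10 f_j| (rarer ⇒ larger), with a constant-effect mode
  for burden-friendly architectures; signs are positive with probability
  `direction_mix`.
* **Stratification (optional)**: two subpopulations with Balding–Nichols
  allele-frequency divergence (default Fst = 0.1); both parents of a
  trio share a subpopulation, and a configurable mean offset (default
  1 residual SD) is added to every trait, creating genotype–trait
  confounding with no genetic effect.

What the simulator does **not** emulate: linkage disequilibrium (variants
are independent, matching the default `mendelian` covariance estimator),
genotyping error, pedigree structures beyond trios, sequencing-depth
artefacts.  Passing tests therefore demonstrate the statistics under
clean trio data in linkage equilibrium, not robustness to those
real-data features.

## Power study design

The scenario grid crosses trait (trait1/trait2) × method (skat/burden) ×
stratum (rare/common/all): 12 cells, optionally × causal proportion
(0.10, 0.25, 0.50): 36 cells.  Signal dilution fixes the causal set and
adds k = round(n_causal(1−π)/π) randomly chosen noncausal variants.
Replicates redraw phenotype noise on fixed genotypes by default
(mirroring a shared-genotype replicate design); a switch regenerates
genotypes too, which the type-I-error estimator uses so rates average
over genotype configurations.  Per-gene, per-cell rejection counts at
α = 0.05 form the power table.

The cross-scenario comparison fits the marginal binomial-logit model

    logit p_ij = β0 + β1 I(trait1) + β2 I(common) + β3 I(common and rare)
                 + β4 I(SKAT)  [+ β5·proportion]

by GEE with gene clusters (each gene's 12 or 36 cells as correlated
binomial measurements), exchangeable working correlation and sandwich
standard errors.  Counts enter as proportions with the trial count as
case weight, which reproduces binomial GLM estimating equations exactly.
If the free alternating updates diverge (they have no step control and
can blow up when within-gene correlation is high), the correlation
parameter is estimated once from an independence start, frozen, and the
mean model refitted — a one-step GEE with the same asymptotics.  The
"overall variant-stratum effect" is the joint Wald test of (β2, β3).

## Numerical and design choices

* CF-inversion target accuracy 1e-9; fallback to moment matching on
  quadrature failure; p-values clamped to (0, 1].
* Eigenvalue truncation 1e-10 × λ_max; negative numerical eigenvalues
  clipped to 0.
* Degenerate inputs: all-zero V ⇒ single zero eigenvalue and p = 1;
  empty stratum ⇒ structured "untestable" result, not an exception;
  all-parents-missing variants excluded and flagged.
* Q at ρ = 1 uses a single weight per variant, as the kernel matrix
  W R_1 W dictates and as required for equivalence with the FBAT
  statistic.
* Dichotomous-trait residuals are used exactly as Y − μ̂0, with no
  variance rescaling beyond the conditional covariance estimator.
* Seeds: every stochastic entry point takes a seed or Generator;
  per-gene/per-replicate streams are spawned from a master
  `SeedSequence`, so whole studies are bit-reproducible.

## Problem sizes used by the shipped studies

Type-I-error runs use 2000 null cohorts of 93 trios × 30 variants;
power-ordering runs use 500 replicates × 2 genes per architecture;
the null-law validation uses 10⁴ transmission resamplings of a fixed
93-trio, 2-variant instance.  These sizes give binomial/KS Monte-Carlo
noise well below the effects being asserted while keeping each study in
the tens of seconds to a few minutes on one core.

## Known limitations

* Conservative kernel p-values for near-singleton variants in small trio
  samples (see above); no small-sample moment correction is applied.
* Trios only — general pedigrees, X chromosome, parent-of-origin
  effects, imputation and phasing are out of scope.
* τ and β are never estimated; only the score test under H0 is provided
  (no SKAT-O style grid search over ρ beyond exposing ρ as a parameter).
* The `empirical` covariance estimator is provided for linked data, but
  the simulator cannot generate linkage disequilibrium to exercise it
  end-to-end.
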