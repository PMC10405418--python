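# Methods

This note documents the models, the simulator, the numerical choices and the
design decisions behind `leakscan`, in the order the pipeline runs them.

## 1. The residual-GWAS diagnostic

A genetic-evaluation model produces a per-animal prediction ĝᵢ (intercept
included). Its residual eᵢ = yᵢ* − ĝᵢ, computed against the pre-corrected
phenotype yᵢ*, contains whatever the model failed to capture. For each SNP
the package fits ordinary least squares of e on the dosage (0/1/2) with an
intercept, over the animals non-missing at that SNP, and tests the slope
with a two-sided t test on n_used − 2 df. SNPs with zero dosage variance or
fewer than three calls are skipped with a reason. Significance uses
Benjamini–Hochberg q-values with a strict `q < target` rule (default target
0.01); each scan (model × panel × set) is adjusted separately, since each is
a separate family of tests. Diagnostics: QQ data against uniform
order-statistic quantiles −log₁₀((i−0.5)/m), the median-χ² inflation factor
median(χ²)/0.4549, Manhattan tables with cumulative per-chromosome offsets
(no gap padding), and a greedy peak report (take the most significant
remaining SNP, absorb significant SNPs within a window, repeat; ties broken
by chromosome then position).

The scan treats residuals as i.i.d., which estimates of residuals are not,
strictly speaking: BLUP residuals are linear functions of all phenotypes and
inherit correlations from the model that produced them. Least squares is
robust to this mis-specification, and the null calibration experiment
(`null_scan_fdp`) confirms the realized false-discovery proportion sits at
the nominal 0.01 when residuals truly are exchangeable noise — but p-values
from scans of heavily structured residuals (e.g. PBLUP with strong families)
should be read as ranking evidence, not exact tail probabilities. Inflation
factors below 1 for genomic models are expected for the same reason: their
residuals are partially orthogonalized against the very genotypes being
tested.

## 2. Phenotype pre-correction

Raw phenotypes are adjusted with the mixed model
y = CG + (covariate) + litter + animal + e, where CG (contemporary group) and
the optional covariate are fixed, litter is i.i.d. random with variance
σ²_litter, and the animal effect carries the pedigree covariance A σ²_g.
The equations are solved sparsely (SuperLU). The pre-corrected value removes
only the estimated fixed effects and litter solutions:
y* = y − ĈG − covariate·β̂ − litter̂, keeping genetic signal and residual.
Pre-correction is translation-invariant (a constant added to y is absorbed
by the CG solutions). Variance components are *inputs* throughout the
package (defaults equal the simulation truth); variance-component estimation
is deliberately out of scope — the diagnostic under study is downstream of
them.

## 3. The model ladder

All genetic-evaluation stages fit the pre-corrected phenotype with an
intercept as the only fixed effect.

**PBLUP.** Animal-model MME with A⁻¹λ, λ = σ²_e/σ²_g. A is built by the
tabular method with inbreeding (a(x,x) = 1 + F(x), F from ½·a(sire, dam));
A⁻¹ by Henderson's rules with Mendelian-sampling variances
d = ½ − ¼(F_s + F_d), with the one-parent (¾ − ¼F) and no-parent (1) cases.

**ssGBLUP.** The same MME with A⁻¹ replaced by
H⁻¹ = A⁻¹ + [(G*)⁻¹ − (A22)⁻¹] on the genotyped block. G is VanRaden's first
method, ZZ′/(2Σp(1−p)) on dosages centered at 2p, allele frequencies from
the genotyped animals themselves, monomorphic SNPs excluded, missing
dosages mean-imputed. Before inversion G is tuned to A22 with a
two-coefficient rescaling (G ← a + bG so that mean diagonal and mean
off-diagonal match A22) and blended, G* = 0.95·G + 0.05·A22 — standard
defaults, exposed in the config. Genotyping scenarios take a nested random
subset of training animals (the 20% set is inside the 50% set, etc., so
scenarios differ only by added genotypes); testing animals are always
genotyped, since they are the ones predicted from genomic data.

**Bayesian whole-genome regressions.** y = 1μ + Xβ + e on column-centered
dosages of the (fully genotyped) training animals, single-site Gibbs:
Bayesian ridge (Gaussian prior on all effects), BayesC (point mass at zero +
common Gaussian slab, indicator per SNP), BayesB (point mass + per-SNP
variance with inverse-χ² updates, i.e. a scaled-t slab). Hyperpriors follow
common whole-genome-regression defaults: scaled inverse-χ² with 5 df for the
variances, scales set so the prior **expected** variances correspond to the
model explaining R² = 0.5 of var(y) (residual scale S_e = var(y)(1−R²)(df−2)/df;
slab scale divides the marker share by Σvar(xⱼ) and, for the selection
models, by the prior mean of π), and π ~ Beta(5, 5). π is sampled from
Beta(5 + k, 5 + p − k); fixing π = 1 reduces BayesC to ridge exactly (the
package exposes this as `pi_fixed`, used as a sampler cross-check). The
kernel is numba-compiled, maintains residuals incrementally (O(n) per SNP
update), and is a pure function of the seed. Posterior summaries are running
means past burn-in at the thinning interval; the σ²_e chain's effective
sample size is computed from the initial positive autocorrelation sequence.
Chain-length defaults in `GibbsConfig` are conservative (30,000 iterations,
10,000 burn-in, thin 5); the ladder runs 2,500/800/2 — at the package's
problem sizes (n ≈ 2,000, p ≈ 1,000) posterior-mean predictions stabilize
well before that, which the BayesC≡BRR equivalence check verifies at
20,000 iterations.

**Solvers.** MME systems up to 4,000 equations are solved by dense Cholesky
(with a symmetric-solve fallback); larger systems by conjugate gradients
with a Jacobi preconditioner, relative tolerance 1e-10, max 10,000
iterations, raising a diagnostic error on non-convergence. The two paths are
tested against each other. Out-of-sample predictions come from the joint
MME (BLUP models: testing animals included with unobserved phenotypes) or
from X_test times posterior-mean effects (Bayesian models); training
residual + prediction reconstructs y* to 1e−8 by construction.

## 4. The simulator

The simulator emulates the qualitative structure of a closed pig breeding
line; real production data of this kind are proprietary, so the package
generates its own study material.

* **Pedigree**: discrete generations; each generation the previous one is
  randomly split into sires and dams (configurable dams per sire), every
  mating produces one full-sib litter. Defaults: 500 founders, 5
  generations, single-pair matings, litters of 2 — a constant 500 animals
  per generation, 2,500 phenotyped, with the last generation (500) held out
  as the testing set (forward prediction, the analogue of a birth-date
  split). Litters of two are a desk-scale compromise: they carry a common
  environment without inflating the dataset.
* **Founder LD**: along each chromosome, haplotype alleles copy the previous
  SNP's allele with probability exp(−κ·d) (d = inter-SNP distance, κ =
  `ld_decay`, default 1e-6/bp) and otherwise draw fresh at the SNP's target
  frequency (uniform on [0.1, 0.5]). Pairwise r² then decays roughly
  exponentially with distance — r² ≈ 0.95 at 25 kb, ≈ 0.02 at 2 Mb at the
  default κ — which is the only LD feature the method needs: markers can
  tag, or fail to tag, causal loci as a function of distance. This is not a
  demographic model; it has no allele-frequency spectrum realism, no
  recombination hotspots, no population bottlenecks.
* **Genotypes**: Mendelian gene dropping of founder haplotypes with
  Poisson(recomb_rate × chromosome length) crossovers per meiosis, uniform
  crossover positions, no mutation, no genotyping error (an optional
  missingness knob exists to exercise the call-rate QC filter). Genome:
  5 chromosomes × 50 Mb, 2,000 UHD SNPs each (positions uniform), 1 cM/Mb.
* **Panels**: the MD panel is a flagged subset of the UHD map (1,000 of
  10,000 SNPs), approximately evenly spaced per chromosome, excluding all
  QTL positions and everything within 2 Mb of the designated untagged QTL.
  The nearest eligible neighbour of the designated large-effect QTL is
  forced into the panel, modelling the fact that commercial arrays tag known
  large QTL well.
* **QTL architecture**: 30 additive loci; baseline effects i.i.d. standard
  normal, rescaled at phenotype construction so the realized QTL-score
  variance equals h²_qtl. Two loci are *designed* rather than drawn: the
  large-effect QTL (effect set to ±4, at a common variant whose nearest UHD
  neighbour is 10–20 kb away, so its best tag has r² ≈ 0.97–0.99) and the
  untagged QTL (effect ±2.5, no MD marker within 2 Mb, while its UHD
  neighbours at ~12 kb tag it nearly perfectly). Setting the designated
  effects to fixed magnitudes, instead of multiplier × N(0,1), guarantees
  the two mechanisms the study design is about — a shrinkage-sensitive
  large effect and a density-limited region — are actually present in every
  replicate. The 10–20 kb tag window matters: with a near-perfect tag
  (r² ≈ 1) even Gaussian models capture the large QTL essentially fully and
  there is no shrinkage peak to detect; with a much weaker tag the
  selection priors could not capture it either.
* **Phenotypes**: y = CG + slope·covariate + QTL score + polygenic + litter
  + noise, variances of the random part scaled to 1. The polygenic term
  follows the pedigree by mean-parental recursion with Mendelian-sampling
  variance ½ − ¼(F_s + F_d) times σ²_pg, so PBLUP has genuine signal to
  capture that is *not* marker-borne. Contemporary groups are allocated
  within generation (≈20 groups total, effect SD 0.5); the covariate slope
  defaults to 0 and is exercised in the pre-correction tests. Defaults:
  h²_qtl = 0.45, h²_polygenic = 0.05, litter fraction 0.10 (total h² = 0.50,
  within the plausible range for pig growth/fatness traits). The polygenic
  share is deliberately small: total h² sets the BLUP shrinkage λ =
  σ²_e/σ²_g, and at λ ≈ 0.5 the Gaussian models' shrinkage leak of the
  large-effect QTL falls below what FDR < 0.01 can detect at n = 2,000 —
  the mechanism exists at any h², but a 2,000-animal study only has power
  to see it when shrinkage is appreciable (λ = 0.8 at the defaults). At the
  sample sizes of industry breeding datasets (tens of thousands of animals)
  this constraint would not bind.
* **QC**: MD panels are filtered at MAF < 0.01 and call rate < 0.8; UHD
  panels at MAF < 0.001 (call-rate filter off by default since the
  simulator produces no missingness).

Every generator is a pure function of its config and seed; the ladder
derives per-stage seeds from one master seed via `SeedSequence`. What
passing tests on this material show is that the diagnostic detects,
localizes and correctly attributes leakage when the generating mechanisms
are as stated; they cannot show robustness to demographic realism,
imputation noise, or genotyping error, none of which the simulator emulates.

## 5. Default analysis scales

The replicated ladder experiment (5 master seeds) runs the full model grid
on the default population and scans training residuals against both panels:
about 30 s per replicate for simulation + kinship, dense MME solves for the
five BLUP-family scenarios, three Gibbs chains of 2,500 sweeps, and 16
vectorized scans. The null-FDR calibration uses 200 replicate scans of
2,000 independent SNPs on 300 animals, redrawing genotypes each replicate.
Oracle comparisons run at n ≤ 200 where dense variance-form GBLUP is exact.
These sizes are the package's chosen desk-scale defaults; all of them are
config knobs.

## 6. Known limitations

* Variance components are assumed known; mis-specified components shift the
  shrinkage and hence the leakage landscape.
* The scan is single-marker OLS on residuals by design (that is the method
  under study); it is not a mixed-model association scan, and no LD
  clumping beyond the greedy peak report is provided.
* FDR is controlled per scan, not across the scenario grid.
* BLUP residuals violate the i.i.d. assumption of the scan (see §1); the
  package follows the standard practice of using them anyway.
* The LD model is first-order Markov: r² between non-adjacent markers is
  governed by the product of link correlations, so long-range LD is always
  weaker than short-range — adequate for tagging mechanics, wrong for fine
  demographic inference.
* No metafounders, unknown-parent groups, APY inversion, multi-trait
  models, dominance or epistasis.
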