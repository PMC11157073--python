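# Methods

## Statistical model

`mrkit` performs two-sample Mendelian randomization on GWAS summary
statistics. For SNP *j* the exposure sample supplies an estimated per-allele
effect γ̂_j with standard error σ_Xj, and an independent outcome sample
supplies Γ̂_j with σ_Yj. Writing θ for the causal effect of exposure on
outcome and α_j for any direct (horizontally pleiotropic) effect of the SNP
on the outcome, the working model is

    Γ_j = θ γ_j + α_j .

A SNP is a valid instrument when it is robustly associated with the exposure
(relevance), not associated with confounders (independence), and α_j = 0
(exclusion). All estimators treat γ̂_j as fixed at its observed value
("NO Measurement Error" approximation); the residual weak-instrument
dilution this induces is of order 1/F per instrument, which motivates the
F > 10 screen below.

## Instrument selection

1. **p-value threshold.** SNPs associated with the exposure at p below a
   class-specific threshold: 1e-5 for microbiome taxa and 5e-6 for
   cytokines (relaxed thresholds commonly used for these traits, where few
   loci reach genome-wide significance), 5e-8 otherwise (including disease
   traits in reverse MR and cis-eQTL exposures).
2. **Greedy LD clumping.** Candidates are sorted by p (ties broken by
   chromosome, position, then variant id, so the result is deterministic);
   the best remaining SNP becomes an index, and every unclaimed SNP on the
   same chromosome within the window (default 10,000 kb, inclusive) with
   r² > the cutoff (default 0.01; 0.1 in eQTL mode) is claimed. LD comes
   from an explicit pairwise-r² file (triplets or square matrix; absent
   pairs are r² = 0, cross-chromosome pairs always 0), so the package runs
   fully offline. Note the retained count is *not* monotone in the r²
   cutoff: loosening it can free a claimed SNP that then claims several
   others. The invariants that do hold — output is a subset of input and no
   retained same-chromosome pair within the window exceeds the cutoff — are
   property-tested.
3. **Weak-instrument screen.** F_j = β̂_j²/se_j²; instruments with F ≤ 10
   are dropped by default (`f_action="flag"` retains them flagged, for
   diagnostics).

## Harmonization

Outcome effects are re-expressed per copy of the exposure's effect allele:
matching orientations pass through; swapped alleles flip the outcome beta
sign and complement the effect-allele frequency; palindromic (A/T, C/G)
SNPs are dropped unconditionally, because strand cannot be resolved from
the alleles and we deliberately do not attempt frequency-based strand
inference; pairs that match neither orientation are dropped. Matching is by
variant id only (no positional fallback). Indels and multi-allelic records
are dropped at read time with a logged count. Effect-allele frequency is
never required downstream, so it may be missing throughout.

## Estimators

* **Wald ratio** (single SNP): θ̂ = Γ̂/γ̂, first-order se σ_Y/|γ̂| — the
  uncertainty model the IVW weights imply. The second-order term
  θ²σ_X²/γ̂² is ignored; with the F > 10 screen in place it contributes
  under 10% of the variance for |θ| of order one.
* **IVW**: θ̂ = Σ w_j γ̂_j Γ̂_j / Σ w_j γ̂_j², w_j = 1/σ_Yj², the weighted
  least-squares slope through the origin. Fixed-effect se
  (Σ w_j γ̂_j²)^{-1/2}; the default multiplicative random-effects model
  multiplies it by max(1, √(Q/(J−1))), changing no point estimate. A
  single-instrument fit short-circuits to the Wald ratio so the collapse is
  exact to the last bit. p-values are two-sided normal.
* **MR-Egger**: instruments are first oriented so γ̂_j ≥ 0 (joint sign flip
  of γ̂ and Γ̂ — without a fixed orientation the intercept has no meaning);
  then weighted least squares of Γ̂ on γ̂ with intercept, weights 1/σ_Yj²,
  solved from the 2×2 normal equations. Both coefficient variances are
  inflated multiplicatively by max(1, RSS_w/(J−2)) and p-values use
  t(J−2). The intercept, its se and p are exposed as the directional
  pleiotropy test. Requires J ≥ 3.
* **Weighted median**: per-SNP ratios θ̂_j with weights ∝ 1/se(θ̂_j)²
  normalized to one; sort (stable), form cumulative midpoints
  p_j = Σ_{k≤j} w_k − w_j/2, and linearly interpolate the ordered ratios at
  p = 0.5. Standard error by parametric bootstrap: resample
  γ̂*_j ~ N(γ̂_j, σ_Xj), Γ̂*_j ~ N(Γ̂_j, σ_Yj) and recompute (default 1,000
  replicates, explicit integer seed; identical seeds give bit-identical
  standard errors).
* **Simple / weighted mode**: normal-kernel density over the ratios with
  weights uniform (simple) or ∝ 1/se(θ̂_j)² (weighted), bandwidth
  h = φ · 0.9 · s · J^{−1/5} with s = min(sd, mad/0.6745) the robust spread
  and φ = 1 by default. The argmax is located on a fixed 512-point grid
  spanning the ratios ± 3h and refined by golden-section search inside the
  winning cell, so it is deterministic; all-identical ratios (h = 0) return
  the common ratio directly. Bootstrap se as for the weighted median.

`run_all_methods` executes whichever of (ivw, egger, weighted_median,
simple_mode, weighted_mode) meets its instrument minimum, in that fixed
order, recording the rest as skips rather than errors. Confidence intervals
are normal-theory θ̂ ± 1.96·se on the beta scale, exponentiated for the
odds-ratio presentation.

## Diagnostics

* **Cochran's Q** over the Wald ratios around the fixed-effect IVW estimate,
  referred to χ²(J−1); I² = max(0, (Q−(J−1))/Q)·100.
* **Egger intercept test**: re-exposes the intercept record of the Egger
  fit, p from t(J−2).
* **MR-PRESSO**: observed statistic RSSobs = Σ_j w_j (Γ̂_j − γ̂_j θ̂_{−j})²
  with θ̂_{−j} the leave-one-out IVW estimate. The null distribution comes
  from parametric simulations (γ*_j ~ N(γ̂_j, σ_Xj),
  Γ*_j ~ N(γ̂_j θ̂_{−j}, σ_Yj), statistic recomputed per simulation,
  default 1,000 draws); the global p uses the add-one estimator
  (1 + #{RSS* ≥ RSSobs})/(n_sim + 1), so p ≥ 1/(n_sim+1) always. Per-SNP
  outlier p-values compare each observed residual to its own simulated
  distribution, Bonferroni-adjusted across the J SNPs, with outliers called
  at 0.05. Sets with J < 4 return NA-valued fields rather than raising, so
  screen tables keep one row per pair. The distortion test is out of scope.
* **Leave-one-out**: J IVW refits, each excluding one SNP.

## Orchestration

The forward screen runs every exposure × outcome pair through selection,
harmonization, all estimators and all diagnostics. Benjamini–Hochberg FDR
(via `statsmodels`) is applied to the IVW p-values within each
(outcome, exposure-class) family; whether a screen should instead correct
within finer strata is a study-design question, so the family definition is
an explicit parameter rather than a hidden constant. Pairs that fail
selection or harmonization are logged skips — one degenerate exposure
cannot abort a screen of hundreds. Reverse MR re-runs the analysis with
disease as exposure for every nominally significant (IVW p < 0.05) forward
pair, selecting disease instruments at 5e-8, and flags reverse IVW
p < 0.05 as potential reverse causality. The eQTL mode is the forward
screen with cis-eQTL conventions (clump r² = 0.1, FDR across genes within
outcome) plus a per-pair flag recording whether all computed methods agree
in sign. Per-pair bootstrap/simulation seeds are derived from the master
seed by fixed spawn indices, making full pipeline runs byte-reproducible.

Two-step mediation multiplies the exposure→mediator IVW estimate (β₁, from
the exposure's instruments) by the mediator→outcome estimate (β₂, from the
mediator's own instruments) and divides by the total effect β₃ from the
direct exposure→outcome MR. The indirect-effect se is the Sobel
approximation √(β₁²se₂² + β₂²se₁²), with a product-of-normals Monte-Carlo
alternative available. The decomposition is only *claimed* when step 1 is
itself significant (gate at 0.05 on the step-1 IVW p); a failed gate still
reports the numbers, flagged unsupported. β₃ = 0 yields an NA proportion.

## Synthetic data generator

The generator emulates two-sample summary statistics under the structural
model above, standardized traits, with per-SNP standard errors
σ = 1/√(2 f (1−f) n) from the minor-allele frequency f ~ U(0.05, 0.5) and
the sample size. Reference conditions (the defaults): J = 50 instruments,
n = 20,000 per trait, θ = 0.2, no pleiotropy, no LD. True effects are drawn
N(0, 0.05²), oriented to the exposure-increasing allele (a pure reporting
convention every estimator is invariant to), and rescaled once so the mean
true F statistic is 100 — a strong-instrument regime representative of
instruments that survive selection and the F screen. Pleiotropy regimes:
`balanced` (α ~ N(0, τ²), InSiDE holds), `directional` (α ~ N(μ, τ²)), and
`inside_violating` (α correlated with γ at a configurable ρ); a
`pleiotropy_frac` applies the chosen regime to a random subset of
instruments. In calibration scenarios τ is set to 0.01, the same order as
the sampling standard errors at n = 20,000. `noise_scale = 0` silences both
sampling-noise draws, giving the deterministic regime Γ̂ = θ·γ̂ in which
IVW recovers θ exactly — the sharpest possible correctness check.

Optional components: decoy SNPs whose exposure p-value is drawn above 1e-4
by construction (they must never survive selection); outcome-specific SNPs
with their own effects on the outcome and a configurable `theta_reverse`
effect back on the exposure, which is what makes reverse-MR scenarios
possible; compound-symmetric LD blocks (constant within-block r², zero
between) emitted as the LD file; and fractions of palindromic SNPs and of
allele-swapped outcome rows to exercise harmonization end to end. Each
component draws from its own RNG stream spawned from the master seed, so
enabling one never perturbs another. The mediation-chain generator adds a
mediator trait: exposure instruments act on it through β₁ and on the
outcome through direct + β₁β₂; the mediator's own instruments act on the
outcome through β₂ and on the exposure not at all; the analytic proportion
mediated β₁β₂/(direct + β₁β₂) is recorded in the truth file.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: correlated sampling noise across linked
SNPs (LD labels exist only to exercise clumping), case-control
ascertainment and the binary-trait likelihood (binary outcomes are treated
as linear effects on the log-odds scale), winner's-curse bias from
selecting instruments in the same sample that estimated them, sample
overlap between exposure and outcome GWAS, population stratification, and
realistic microbiome taxon architectures.

## Validation scenarios and problem sizes

The acceptance suite and `scripts/acceptance.py` use desk-scale Monte
Carlo: 500 replicates for recovery and coverage (J = 50, n = 20,000,
θ = 0.2), 1,000 for the size of the Egger-intercept test (balanced
pleiotropy null) and Cochran's Q (homogeneity null) at J = 30, 200
replicates at 200 PRESSO simulations for null uniformity of the global p,
200 for the weighted-median robustness comparison (40% of instruments
directionally pleiotropic, μ = 0.05), 100 for outlier detection (one
10σ-offset SNP) and for directionality (30 exposure SNPs, 30
outcome-specific SNPs). Simulated instrument sets are passed through the
same F > 10 screen the pipeline applies before estimation.

## Known limitations

* The NOME approximation leaves a dilution of order θ/(mean F + 1) in the
  IVW estimate (≈ 0.002 at the reference conditions), visible as a small
  but systematic shortfall in recovery means.
* The MR-PRESSO null simulation centers on observed estimates, making the
  global p mildly conservative (null mean slightly above 0.5).
* The bootstrap standard error of median/mode estimators is seed-dependent
  by construction; only the point estimates are deterministic functions of
  the data.
* Steiger filtering, MR-RAPS, contamination-mixture and multivariable MR
  are intentionally out of scope, as are proxy-SNP lookup, genome-build
  liftover and computing LD from reference panels.
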