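# Methods

`qtlmed` infers cell-type-specific causal relationships among a genetic
variant (X), a chromatin-accessibility phenotype (M), and a gene-expression
phenotype (Y), using only observational QTL data. This note records the
models, the numerical choices, and what the synthetic test bed does and does
not establish.

## Causal model space

For each X-M-Y triplet, twelve directed acyclic graphs are scored — every
combination of the X→M edge (absent/present), the mediation edge (absent,
M→Y, or Y→M), and the direct X→Y edge (absent/present). The biologically
named members are:

- **complete mediation** (X→M→Y) and **partial mediation** (adds X→Y):
  the *forward* call;
- **complete reactive** (X→Y→M) and **partial reactive** (adds X→M):
  the *reactive* call;
- **co-local/independence** (X→M and X→Y, no M–Y edge): two separate
  consequences of the same variant.

Each graph factorizes the joint likelihood into two linear-model equations
(one for M, one for Y, each with its own covariates). Equations are scored
by the closed-form marginal likelihood of a conjugate Bayesian linear
model: coefficients Gaussian with variance σ²·V, residual variance σ²
scaled-inverse-chi-square(κ, λ); integrating both gives a multivariate-t
density. Posterior model probabilities combine the per-graph joint
evidence with a uniform prior over the allowed set; the "complete" prior
mode excludes the four reactive-edge graphs a priori, the "reactive" mode
allows all twelve. A triplet is *called* forward (or reactive) when the
corresponding posterior pair sums strictly above 0.5; otherwise it is
independence when the co-local graph is the argmax, else "other".

### Hyperparameters

| parameter | default | meaning |
| --- | --- | --- |
| φ² (3 values) | (1, 1, 1) | prior effect size per edge on the odds-of-PVE scale; odds = pve/(1−pve), so 1 ⇔ 50% variance explained a priori |
| κ, λ | 0.001, 0.001 | scaled-inverse-chi-square residual-variance prior (non-informative) |
| τ | 1000, 1000 | prior variance (× σ²) of the intercept and each covariate coefficient (effectively flat) |

The φ² odds scale is realized by giving each effect coefficient prior
variance φ²·σ²/Var(column). M and Y are centered and variance-standardized
before evaluation; X is encoded −1/0/1 and left unstandardized. The
standardization convention is ours: it is what makes the odds-of-PVE
interpretation of φ² exact regardless of phenotype units. `select_phi2`
exposes the empirical-Bayes grid search that justifies the default:
summed log evidence over a triplet collection, maximized at (1,1,1) when
the planted per-edge PVE is 0.5.

All likelihood work is in log space; posteriors use log-sum-exp and must
sum to one within 1e-10. The closed form is verified in the test suite
against brute-force two-dimensional quadrature on small single-effect
cases (1e-3 log-unit tolerance).

## QTL engine

Association tests are covariate-adjusted least squares with two-sided
t-tests on the dosage term. Samples are unrelated by construction in the
synthetic setting, so no kinship random effect is fitted; fixed-effect OLS
is the exact limit of the mixed model at zero relatedness. Monomorphic
variants and rank-deficient designs yield a flagged degenerate result with
the p = 1 convention rather than an error. An exact fit (residuals at
round-off) also falls back to the deterministic convention: p = 0 for a
genuinely nonzero coefficient, 1 otherwise.

Multiple testing follows a two-tier scheme: per-gene local adjustment by
an effective-test count (the smallest number of eigenvalues of the cis
variant correlation matrix explaining ≥ 99% of its variance — a fully
specified surrogate for permutation-free local correction), then
Benjamini–Hochberg across genes' top variants, with eGenes declared at
global q < 0.05. Chromatin peaks, having few cis variants each, use plain
BH at 5% FDR. Trans scans test only variant–gene pairs more than 1 Mb from
the TSS or on different chromosomes, exclude pseudogenes, drop pairs whose
symmetric log2 cross-mappability — (crossmap(A,B)+crossmap(B,A))/2 —
exceeds 5 (missing entries count as 0 and are retained), require MAF >
0.025, prune variants by greedy windowed LD (50-variant window, step 5,
r² > 0.5 removes the later variant), and control BH FDR at 10%.

## Triplet eligibility

*Forward*: variant inside the peak it regulates (half-open BED interval,
start ≤ pos < end) and within 1 Mb (inclusive) of the outcome gene's TSS,
significant for both phenotypes. *Reactive*: variant cis-regulates a
transcription-factor gene (TF-restricted rerun of the hierarchical eGene
procedure) and is a significant trans-caQTL for a peak carrying that TF's
motif at ≥ 80% min–max relative score — variants inside the target peak
are excluded, because local action implies a forward mechanism.
*Trans*: variant is the cis-eSNP of an upstream gene and a significant
trans-eQTL of a distal gene, with the cross-mappability filter applied.
PWM scanning scores both strands (reverse complement); the min–max
relative score convention ((score − min)/(max − min) on the log-odds
matrix) is our reading of the "80% match" rule and is recorded here as an
assumption. A validator re-checks every eligibility invariant on any
pipeline output.

## Measurement error: ICC and the flip threshold

Technical replicates give a one-way random-effects intraclass correlation
per feature, ICC(1) = (MSB − MSW)/(MSB + (k₀−1)·MSW) with k₀ the
harmonic-adjusted mean replicate count; negative estimates are possible
and are grounds for exclusion.

Measurement error imbalanced between M and Y can reverse the inferred
causal direction. The flip-threshold simulation quantifies this: simulate
the true structure at a triplet's effect sizes (n = 75 donors, variant MAF
0.5 — our defaults for the donor count and allele frequency, chosen to
match a realistic cell-culture QTL cohort); inject Gaussian error into the
chromatin phenotype so its ICC equals each of 20 grid points in
(0.05, 1]; run the twelve-model selection with reactive-mode priors; fit
tricube-weighted local linear regressions (span 0.75) of the forward-sum
and reactive-sum posteriors against ICC; locate the crossing of the two
fitted curves by sign-change bracketing and linear interpolation. A
crossing is accepted only when, just above it, the forward curve rises and
the reactive curve falls — with error always injected on the chromatin
phenotype this is the geometry of both scenarios, because noise on M
degrades a forward call (M is the causal middle node) but is absorbed into
the residual of a reactive call (M is terminal). The procedure runs 10
repetitions and averages accepted per-repetition thresholds.

Under forward truth the threshold bounds trust in reactive calls: a
reactive-classified triplet whose measured chromatin ICC falls below its
threshold is discarded, as are triplets with non-positive or missing ICC
on either phenotype. Under reactive truth the question is whether a
*forward* call can be manufactured by error at all, so detection is
stricter: the classification must genuinely flip (both posterior sums
exceed the 0.5 decision surface on their respective sides of the
crossing), and the flip must recur in a majority of repetitions to count
as possible rather than as sampling noise. With these rules, reproducible
reactive→forward flipping appears only at the extreme-effect corner of
the PVE grid (both fractions ≈ 0.95), where mediator and outcome are
nearly collinear and the directions are close to statistically
indistinguishable. Occasional seeds also flip at (PVE_A ≈ 0.3,
PVE_B ≈ 0.95) — the same near-collinearity regime entered through one
edge — which we report as a genuine identifiability limit rather than
suppress.

## Regression comparator

The frequentist check on a forward call is the conditional p-value of the
variant in Y ~ X + Z_Y + M_resid (M residualized on its own covariates):
complete mediation drives it toward 1. Its null reference is built from
decoy mediators — 10 off-chromosome peaks per permutation (count is our
choice; the procedure prescribes "regions") — each of 1000 permutations
shuffles the decoy rows, records the maximum conditional p across decoys,
and a generalized extreme value distribution is fitted to the maxima by
maximum likelihood. The family-wise-error-controlled mediation p-value is
the upper-tail GEV probability of the observed statistic, significant
below 0.05; if the GEV fit degenerates the empirical tail proportion is
used and flagged. The alternative reading (testing the M coefficient) is
available via `test_term="m"`.

## Replication and colocalization

Storey's π1 = 1 − π0 with π0(λ) = #{p>λ}/(n(1−λ)) on the grid
seq(0.2, 0.8, 0.1) (trans replication: seq(0.1, max p, 0.05)), smoothed by
a least-squares natural cubic spline with 3 degrees of freedom evaluated
at the largest λ and clamped to [0,1]; a grid-mean alternative sits behind
`smoother="mean"`. Confidence intervals are percentile bootstrap (1000
resamples). Sign concordance is the fraction of triplets whose two QTL
effects share a sign, excluding (and counting) zero or non-finite betas.

Colocalization is LD-thresholded: GWAS index variants are chosen greedily
by ascending p among genome-wide hits (p < 5×10⁻⁸) subject to pairwise
r² < 0.2; a QTL colocalizes with an index when their dosages have r² > 0.8
and the QTL association attenuates above its discovery significance
threshold upon conditioning on the index dosage. The attenuation cutoff is
the discovery threshold, not nominal 0.05 — a signal can attenuate by
twenty orders of magnitude and still be called colocalized; the fold
attenuation is reported alongside. Identical variants (r² = 1) colocalize
by definition.

## Synthetic data

Genotypes are binomial(2, MAF) under Hardy–Weinberg; LD blocks copy each
allele from the previous variant with probability √r², giving adjacent
dosage correlation near the target. Triplet phenotypes are built
structurally: each planted edge contributes a component scaled to exactly
its target variance fraction (signs fixed by default, randomizable), and
residual Gaussian noise tops the phenotype up to unit scale. Observed
phenotypes add error with variance Var(true)·(1−ICC)/ICC; replicate tables
draw the same donor truth with independent error per draw. Peak sequences
are i.i.d. uniform DNA with the PWM consensus planted in a recorded
fraction of peaks; GWAS cohorts resample panel rows (preserving LD) with a
single causal variant at a stated trait PVE.

What this establishes: the inference machinery recovers planted truths
under its own generative assumptions. What it does not establish:
robustness to count noise, batch structure, relatedness, non-Gaussian
phenotype distributions, or realistic LD — real chromatin and expression
data have all of these, and results here should be read as verification,
not biological validation.

## Problem sizes

Default test-bed sizes are chosen to exercise every code path at desk
scale: n = 75 donors for the measurement-error study (the cohort scale the
method targets), n = 150–300 for model-recovery and pipeline runs, 200
replicates for recovery rates, 300 null triplets × 1000 permutations for
comparator calibration, and n = 50,000 only where estimator consistency
(±0.02 on variance fractions) is the claim. The acceptance script pools
accepted per-repetition thresholds over 10 independent runs of the 10-rep
flip simulation, and sweeps a 5×5 PVE grid at 5 repetitions per point for
the reactive-flip boundary, reporting the smallest PVE among
reproducibly-flipping grid points (the grid maximum, 0.95, when only the
extreme corner flips).

## Known limitations

- The conjugate prior's fixed effect scale (odds 1) shrinks extreme
  effects; near-deterministic edges (PVE ≥ 0.9) push posterior mass toward
  the three-edge graphs even without measurement error.
- The effective-test count is an eigenvalue surrogate, not a permutation
  calibration; its 99% level is configurable but not data-adaptive.
- The GEV null assumes the decoy-maximum distribution is stable across
  permutations; heavy-tailed conditional p distributions at very small n
  may trip the empirical fallback.
- Real-data ingestion (VCF/BED/TSV) covers the formats' plain subsets;
  no liftover, no multi-allelic variants, no missing-genotype handling in
  synthetic mode (real-input mode mean-imputes with a logged count).
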