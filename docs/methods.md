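# Methods

`mrkit` implements two-sample summary-data Mendelian randomization (MR) for
drug-target (cis) and genome-wide analyses, with Bayesian colocalization,
mixture clustering of variant-level estimates, and cross-study meta-analysis.
This note records the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Model and assumptions

For variant *j*, let γ̂_j (se σ_γj) be its association with the exposure (SD
units of a quantitative trait) and Γ̂_j (se σ_Γj) its association with the
outcome (log-odds for a binary trait), both expressed per copy of a common
effect allele. Under the instrumental-variable assumptions (relevance,
no confounding of the variant–outcome relation, exclusion restriction), each
variant's Wald ratio θ_j = Γ̂_j/γ̂_j estimates the causal effect β of a 1-SD
exposure change, with first-order standard error σ_Γj/|γ̂_j|. Exposure-side
error is ignored in the weights (conventional first-order weighting): with
instrument F-statistics (γ̂/σ_γ)² well above 10 the attenuation this induces
is negligible, and we verify <0.02 absolute bias by simulation.

### IVW

The inverse-variance-weighted estimate is the weighted regression of Γ̂ on γ̂
through the origin with weights 1/σ_Γj²:

    β̂ = Σ γ̂_j Γ̂_j /σ_Γj² ÷ Σ γ̂_j²/σ_Γj² ,  se_fixed = (Σ γ̂_j²/σ_Γj²)^(-1/2).

Heterogeneity is Cochran's Q = Σ (Γ̂_j − β̂ γ̂_j)²/σ_Γj² on J−1 df. The
multiplicative random-effects se is se_fixed · max(1, √(Q/(J−1))) — the
inflation is floored at 1 so a random-effects se can never undercut the
fixed se. The `auto` rule uses fixed effects for J ≤ 3 and random effects
for J ≥ 4. With correlated instruments (cis analyses), the fit becomes
generalized weighted least squares with weighting matrix
Ω_ij = σ_Γi σ_Γj ρ_ij, where ρ is the signed LD correlation:
β̂ = (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ, se = (γᵀΩ⁻¹γ)^(-1/2), Q = rᵀΩ⁻¹r. Ω is used as-is
when positive definite; otherwise a 1e-8 diagonal ridge is tried once and a
numerical error naming the minimum eigenvalue is raised if that fails. The
conditional ridge keeps the identity-LD case *exactly* equal to the
independent IVW fit.

### MR-Egger

Weighted (or GLS) regression of Γ̂ on γ̂ with an intercept, after flipping
signs so every γ̂_j > 0 — Egger is not invariant to allele coding, so a
deterministic orientation is mandatory; flipping re-signs the corresponding
rows/columns of ρ as well. The intercept estimates directional pleiotropy;
the slope is causal under the InSIDE assumption. Random-effects scaling
uses max(1, √(Q_e/(J−2))) on both standard errors.

### Weighted median

Ratios θ_j sorted ascending with weights w_j ∝ γ̂_j²/σ_Γj²; the estimate
interpolates θ at cumulative midpoint weight 0.5 (S_j = Σ_{i≤j} w_i − w_j/2).
It is consistent when valid instruments carry ≥50% of weight. The se is the
standard deviation of the statistic over parametric bootstrap resamples
(default 1000) of (γ̂, Γ̂) from their stated normal errors; the bootstrap
seed is a required argument in the CLI.

All confidence intervals and p-values use the normal distribution, the
summary-data MR convention. Estimates are reported per 1-SD *reduction* in
the exposure (`lowering_orientation` negates the slope and mirrors the CI;
p, Q and the intercept test are unchanged), and binary-outcome slopes are
exponentiated to odds ratios only at the report layer.

## Instrument selection

Cis instruments: variants within ±100 kb (configurable) of the target gene,
p ≤ 5e-8, greedily pruned by p-value rank so that every retained pair has
r² < 0.1 — repeatedly keep the most significant remaining candidate and drop
candidates with r² ≥ the threshold against any kept variant (clumping).
Genome-wide instruments use the same rule at r² < 0.001; cross-chromosome
pairs count as r² = 0. Ties in p break by position then variant id, making
selection invariant to input row order. Confounder-associated variants are
excluded via a user-supplied list (main analysis keeps them, sensitivity
analysis drops them); no external annotation service is queried.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
alleles are kept; swapped alleles negate the outcome beta; alleles matching
only after base complementation are strand-flipped then aligned. Palindromic
variants (A/T, G/C) are retained only when the exposure frequency and the
aligned outcome frequency of the same allele fall on the same side of 0.5
and both lie outside the ambiguity window (0.42, 0.58) — the window is a
configuration knob; missing frequencies drop the variant. Variants absent
from the outcome are replaced by the best LD proxy with r² ≥ 0.8, the
proxy's outcome beta multiplied by sign(r) so it refers to the original
variant's effect allele; ties in r² break by base-pair distance then id.
Every input variant is returned with an explicit action, so retained +
dropped always equals the input count.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor
log ABF = ½(log(1−r) + r z²) with r = W/(V+W), V = se², W the effect-prior
variance. Prior standard deviations default to 0.15 (quantitative) and 0.20
(binary, log-odds) — the cited convention for this approximation; the
region-level priors are p1 = p2 = 1e-4 and p12 = 1e-5 per variant. Variants
with MAF ≤ 0.1% are excluded; variants lacking a frequency are kept (they
cannot be filtered). Hypothesis sums are done in log space with
log-sum-exp; the distinct-variants sum S3 = log(e^{S1+S2} − e^{S12}) uses
log1p and is set to −∞ (PP3 = 0) when a single shared variant makes it
undefined or when cancellation would go negative. The conditional
colocalization probability PP4/(PP3+PP4) is reported alongside PP0–PP4, and
per-variant shared-signal posteriors softmax(lbf1+lbf2) identify the lead
variant.

## Clustered MR

Wald ratios are modelled as a Gaussian mixture over K substantive clusters
N(μ_k, σ_j²), a null component N(0, σ_j²), and a junk component
N(θ̄, σ_j² + ψ²) with θ̄ and ψ² fixed at the unweighted mean and variance of
all ratios. ψ² is floored at 4× the median observation variance so the junk
component is always broader than sampling noise; without the floor a
degenerate input (all ratios equal) lets the junk component impersonate a
substantive cluster. The fixed null and junk components demand substantial
evidence of similarity before a cluster forms, suppressing spurious
clusters. EM updates μ_k as inclusion-weighted precision-weighted means and
the mixing proportions as mean inclusions; convergence at log-likelihood
gain < 1e-8 or 500 iterations. K is selected by
BIC = −2·loglik + (2K+1)·log J over K = 0..k_max (default 10), taking the
best of n_restarts (default 20) seeded restarts per K, initial means drawn
from random quantiles of θ. Components abandoned by the data (π < 1e-6) are
removed; components whose means coincide within 1e-3·ψ are merged (EM
symmetric splits are non-identifiable and the merge strictly improves BIC).
No within-cluster variance beyond σ_j² is modelled (a τ² extension is out
of scope). Clusters are *reported* only when ≥4 variants are assigned at
inclusion probability strictly >0.80, and per-cluster IVW, weighted-median
and Egger estimates are recomputed on the members.

## Meta-analysis

Per-study estimates (same scale and orientation enforced) are pooled by
inverse variance. The `auto` rule keeps fixed effects unless Cochran's Q has
p < het_alpha (default 0.05), in which case DerSimonian–Laird
τ² = max(0, (Q−(S−1))/(Σw − Σw²/Σw)) re-weights as 1/(se² + τ²). Subgroup
(sex, ancestry) contrasts use the two-sided z-test on the difference.

## Synthetic data generator

The generator emulates the statistical structure of a large lipid GWAS
paired with biobank-scale binary-outcome GWAS:

* **Genome-wide mode** — true exposure effects γ_j ~ N(0, 0.05²) SD,
  rejection-sampled to exceed the genome-wide detection threshold at the
  exposure sample size (default 1.2M, lipid-consortium scale). Each variant
  belongs to a substantive cluster (Γ_j = μ_k γ_j; defaults μ = −0.3, +0.4
  with weights 0.4/0.4 — opposing clusters), a null cluster (Γ_j = 0, weight
  0.15) or a junk cluster (independent pleiotropy N(0, 0.02²), weight 0.05).
  Observed effects add normal noise with se_γ = 1/√n_exp and
  se_Γ = 1/√(n_out·φ(1−φ)) (default n_out = 367,289, case fraction 0.083 —
  the largest biobank's scale). The standardized-genotype parameterization
  (se = 1/√n, no frequency dependence) is a deliberate simplification; the
  0.05 SD effect scale reflects that genome-wide significant lipid loci
  include many large-effect variants and keeps variant-level ratio
  uncertainty near what published cluster scatter plots show.
* **Region mode** — an AR(1) LD block (default ρ = 0.9, 200 variants);
  z-vectors drawn from MVN(√n·R·b, R) with causal configurations shared /
  distinct / trait1-only / none, then beta = z/√n, se = 1/√n.
* **Multi-study mode** — with shared truth, one set of true effects is drawn
  and every study observes it with its own noise (the fixed-effects regime);
  otherwise truths are independent.

Everything is deterministic given the config seed. The generator does *not*
simulate individual genotypes, allele-frequency-dependent standard errors,
ancestry-specific frequencies, sample overlap, or winner's-curse selection;
passing calibration tests therefore demonstrates correctness of the
estimators under their own sampling model, not robustness to those
real-data complications.

## Problem sizes used in the test and acceptance suites

Colocalization calibration: 200-variant regions, n = 50,000 per trait,
causal β = 0.05, 50 seeds per causal mode. Cluster recovery: J = 100 ratios,
σ = 0.05, 20 seeds (k_max = 4, 10 restarts); null calibration 200 seeds
(k_max = 3, 5 restarts). Estimator calibration: 500 replicates at J = 100.
Meta-analysis calibration: 200 seeds of two biobank-sized studies at J = 40.
These sizes make the whole suite run in a couple of minutes on one CPU while
leaving the Monte-Carlo error of each rate well inside its acceptance band.

## Known limitations

* No MR-PRESSO, mode-based, multivariable MR or Steiger filtering; no
  second-order ratio weights.
* Colocalization assumes at most one causal variant per trait (no
  SuSiE-style decomposition or conditioning).
* LD is always supplied, never computed from genotypes; no liftover, no
  indels.
* The junk-component anchoring (sample mean/variance of ratios) is a
  pragmatic stabilization; an upstream implementation may re-estimate the
  junk scale within EM.
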