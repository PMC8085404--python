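# Methods

## The subtyping model

NSCLC subtype is modeled as a Bernoulli outcome: for sample *i* with
normalized diagnostic-gene profile **g**ᵢ,

    log pᵢ/(1−pᵢ) = β₀ + gᵢ·βᵀ,

where pᵢ is the probability the sample is LUAD (yᵢ = 1) rather than LUSC
(yᵢ = 0). The package ships a published 15-gene instance of this model
(`published_model()`); coefficients are meaningful only on the individually
normalized scale described below, which is why every serialized model
carries a `normalization_contract` marker. Gene symbols are matched
case-sensitively and exactly (GPR116, an alias-prone symbol, is stored as
published and never remapped).

## Individual normalization

Each sample is normalized in isolation — no cross-sample statistics — so
that a clinical sample can be processed the day it arrives:

1. `v_g = log2(raw_g + pseudocount)` over all panel genes
   (pseudocount 1 by default, keeping zero counts finite);
2. `c_g = v_g − mean(v over housekeeping genes)` for diagnostic genes;
3. `z_g = (c_g − mean(c)) / sd(c)`, the sample (n−1) standard deviation
   taken across the diagnostic genes.

The z-transform is computed over the diagnostic genes only; housekeeping
genes serve purely as the centering reference. (Whether the original
procedure z-scaled over 63 or all 67 genes is not documented; the 63-gene
convention avoids counting the reference genes twice and is fixed here so
the published coefficients are always applied on one well-defined scale.)
Step 3 re-centers, so step 2 is mathematically absorbed; it is retained
verbatim as the procedure's clinical description.

Two numerical notes. A sample whose centered profile is constant has
sd(c) = 0 and is returned as an all-zero profile with a `degenerate` flag
rather than NaNs. And scale invariance — normalize(c·x) = normalize(x) for
any c > 0, the property that makes library size irrelevant — is exact for
the pure log2 transform (pseudocount 0) but deviates by O(1/count) under
the default pseudocount; the test suite checks the exact property at
pseudocount 0 and the approximate one at the default.

## Classification and confident calling

`predict_proba` evaluates the logistic model with a numerically stable
sigmoid (no overflow to exactly 0/1 for |logit| ≤ 700). The default
reporting rule calls LUAD iff p ≥ 0.5. Dual-threshold mode calls LUAD iff
p ≥ θ_LUAD, LUSC iff p ≤ θ_LUSC, and INDETERMINATE in between; a
probability exactly at a threshold yields the confident call, mirroring the
closed ≥ of the default rule.

`calibrate_thresholds` chooses the tightest pair reaching a target per-call
specificity: θ_LUAD is the smallest candidate at which the LUAD call's
specificity among true-LUSC samples reaches the target, θ_LUSC symmetric.
Candidates are the observed probabilities, midpoints of neighbors, and
{0, 1} — every achievable operating point occurs at one of these. Per-call
specificity denominators are the opposite class's truth (a documented
choice; "specificity" alone does not pin them down). If a side is
infeasible (e.g. target 1.0 with an opposite-class sample at the extreme),
its extreme threshold is returned with a feasibility flag cleared. At
modest targets the two feasible regions can overlap (θ_LUSC > θ_LUAD as
raw argmin/argmax); samples in the overlap are confidently callable either
way, so θ_LUSC is collapsed down to θ_LUAD, preserving both specificities
(the LUSC-side feasible set is downward-closed).

## Model development engine

Feature selection uses elastic-net penalized logistic regression,

    (1/n) Σᵢ [−yᵢηᵢ + log(1+e^ηᵢ)] + λ[(1−α)‖β‖₂²/2 + α‖β‖₁],

with the intercept unpenalized. The solver is the classic proximal-Newton /
coordinate-descent scheme of the glmnet family, JIT-compiled and
warm-started along a decreasing λ path (100 values, log-spaced over two
decades below the data-derived λ_max = maxⱼ|⟨xⱼ, y−ȳ⟩|/(n·max(α, 10⁻³))).
Safeguards: logits clipped at ±30 when forming IRLS weights, weights
floored at 10⁻⁵, convergence on the maximum weighted squared parameter
change (the glmnet `thresh` criterion; tolerance 10⁻⁵ for cross-validation
fits, 10⁻⁹ for final fits, where the objective is then accurate to about
the tolerance — verified against a general-purpose numeric minimizer to
10⁻⁶ in the tests). Features are not re-standardized: the normalized
profiles are already on a fixed per-sample z scale.

Model selection runs repeated stratified k-fold cross-validation (defaults:
3 folds, 1000 resampling iterations, α from 0 to 1 in steps of 0.1). Each
iteration draws a fresh stratified partition seeded by (seed, iteration).
Along each α's λ path, the λ maximizing mean held-out accuracy at the
p ≥ 0.5 rule is selected, ties going to the largest (most parsimonious) λ.
The λ path and the full-data reference fit used for complexity bookkeeping
are computed once per α from the full data and shared across folds —
selecting a common λ by averaging fold accuracies requires a common grid
(the convention of cv.glmnet). The winning α maximizes mean accuracy across
iterations (ties → smaller α, i.e. toward ridge); the final model is refit
on all samples at the median of that α's selected λs, a robust stand-in for
a final-λ rule the original description leaves unstated.

`convergence_summary` reports, at each checkpoint k, the running mean and
95% CI (mean ± 1.96·sd/√k) of the per-iteration optimum's complexity,
accuracy, and α — the diagnostics used to argue that on a small cohort
(~70 samples vs 63 candidate genes) on the order of 1000 iterations are
needed before complexity and α stabilize. At k = 1 the sd is reported NaN.

## Evaluation primitives

The c-statistic is the tie-corrected pairwise concordance probability
(#concordant + ½·#tied over all cross-class pairs), computed via the
rank-sum identity and verified against brute force. The two-sample KS
statistic D is the supremum of the ECDF difference over pooled points; its
two-sided p-value uses the asymptotic Kolmogorov distribution at
√(n₁n₂/(n₁+n₂))·D. With NOS groups of ~11 samples this asymptotic p is an
approximation, which is why small-sample KS p-values are reported but never
treated as exact. NOS profiling returns ECDFs, Gaussian kernel densities
(Silverman bandwidth), and the KS comparisons of NOS against each typical
subtype. Events-per-variable is n_samples/n_model_genes, the usual ≈5
lower guardrail against overfitting.

## Synthetic cohorts: the stated world

`generate_cohort` emulates a targeted NanoString panel, not any particular
dataset. Per gene g and sample i the latent log2 mean is
`baseline_g + s_i + sign·e_g·strength_i`: sign +1 for role/class
concordance, −1 for discordance, 0 for housekeeping; `e_g` drawn once per
gene from Normal(effect_log2fc, effect_sd) clipped at 0; `s_i` a
Normal(0, libsize_sigma) library factor. Counts are negative-binomial with
size `dispersion` around 2^latent (Poisson when dispersion is infinite);
the FPKM-UQ platform instead adds Normal(0, 0.25) log2 noise — transcript
lengths are not modeled, since portability is tested at the
normalized-profile level.

Defaults state the emulated world once: a 23/40/4 panel; a 47/25/11
LUAD/LUSC/NOS cohort; mean subtype shift 2 on the log2 scale with sd 0.5
(strong marker-gene differential expression, as targeted subtyping panels
are designed to have); baselines 7 ± 1.5 log2 units (hundreds of counts);
library sd 0.5; dispersion 10 (moderate overdispersion typical of targeted
count assays). NOS cases default to INTERMEDIATE mode — a hidden class at
half effect strength, yielding probabilities concentrated between the class
modes, matching the observation that NOS cases look molecularly distinct
from both typical subtypes; MIXTURE mode (full-strength hidden class) is
the alternative. `n_signal_genes` restricts true signal to a subset of
diagnostic genes (allocated to roles proportionally) for sparse-recovery
experiments.

What a green synthetic test establishes: that the machinery — normalization
algebra, solver optimality, selection bookkeeping, threshold logic — is
correct, and that the engine recovers planted structure in a world where
that structure is strong. It does not establish clinical performance: the
generator draws genes independently (no co-expression blocks), has no tumor
purity, batch, or background-count structure, and its default effects make
cohorts nearly separable, so c-statistics near 1.0 on synthetic cohorts say
nothing about accuracy on real FNA data.

## Known limitations

- The original clinical cohort numbers (c-statistics 0.986/0.911/0.982,
  94.7% coverage at 95% specificity, CV accuracy 0.902 ± 0.053) require
  undeposited clinical data and are not reproduced here; the test suite
  substitutes property-based and parameter-recovery checks.
- "Enrichment analysis" of NOS cases is not implemented: the original
  description never defines it.
- The RCC reader performs no probe-level QC (binding density,
  positive-control linearity) and no background subtraction.
- λ = 0 fits on separable data have no finite maximum-likelihood solution;
  the solver then stops at its iteration budget and
  `fit_elastic_net` raises a convergence error rather than returning a
  silently truncated estimate.
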