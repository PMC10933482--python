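# Methods

## Model and assumptions

The package treats a dataset as an intuitionistic-fuzzy information system
(IFIS): samples × conditional attributes, where each numeric cell carries a
membership/non-membership pair (μ, ν) with μ + ν ≤ 1, nominal attributes
stay crisp, and exactly one crisp decision attribute labels the samples.
The working assumptions are: no missing values after loading (optional
mean/mode imputation behind an explicit flag), a finite nominal alphabet
per column, and a decision with at least one class. Everything downstream
— relation, granules, entropies, selection — is deterministic given the
inputs.

### Fuzzification

μ is the min–max normalisation of the raw column; ν is the Sugeno-class
complement ν = (1 − μ)/(1 + λμ). λ > 0 (default 1) controls the hesitancy
budget: λ = 0 would give the standard complement ν = 1 − μ (no hesitancy),
larger λ depresses ν and widens π = 1 − μ − ν. The construction guarantees
μ + ν ≤ 1 for every λ ≥ 0, is order-preserving, and is invariant to affine
rescaling of the column. A constant column has no discriminating content;
it is mapped to μ = 0.5 everywhere, which makes its relation all-similar
and its selection gain exactly zero rather than undefined.

### Hybrid similarity relation

Nominal attributes compare crisply (μ_R = 1 on equal codes, else 0; ν_R is
the Sugeno complement of μ_R, which on {0, 1} reduces to 1 − μ_R). For a
numeric attribute the per-pair similarity is s(i,j) = 1 − |Δμ|·|Δν|, gated
by the adaptive radius ζ_a = (1/n²)ΣΣ |Δμ|·|Δν| (mean over all ordered
pairs, diagonal included): pairs with |Δμ| ≤ ζ_a get s(i,j), all others 0.
ζ_a is a per-attribute spread statistic — zero for constants, larger for
attributes whose IF values scatter — so the neighbourhood width adapts to
each attribute without a user-set kernel parameter. Two gate modes exist:
`mu_only` (default, total, reflexive) and `as_printed`, which also
conditions on |Δν| and deliberately raises on pairs its two cases do not
cover (including the diagonal); it exists to document that the
four-condition variant is not a total rule. The gate comparison uses an
absolute tolerance of 1e-12 so boundary pairs are admitted stably.

Subset relations are the elementwise min of the μ parts and max of the ν
parts (dual t-norm/t-conorm). This preserves reflexivity, symmetry and
μ + ν ≤ 1, and gives the monotonicity R_{C₁} ⊇ R_{C₂} for C₁ ⊆ C₂ on which
the entropy inequalities rest.

### Granules and cardinality

The granule of sample i at level ε zeroes every relation value below ε,
independently in μ and ν (the ν cut can be disabled via `threshold_nu`;
with the default sigma-count cardinality it has no numerical effect). With
a crisp relation and ε = 0 granules are exactly classical equivalence
classes. Cardinality modes:

* `sigma_mu` (default): Σ_j μ_i(x_j). Reproduces the crisp limits exactly
  — ET = log₂n for the all-similar relation, ET = 0 for the identity —
  which the entropy extremes require.
* `mean_pi_adjusted`: Σ_j (1 + μ − ν)/2 over the support μ > 0, for
  analyses that want non-membership to temper the count.

Both keep every cardinality in [1, n] (self-membership is always 1), so
logarithms never need flooring.

### Entropy algebra and conventions

ET(B) = (1/n) Σ log₂|[x_i]_B| (granularity form); joint entropy uses
per-sample granule intersections (min/max); conditional entropy is defined
by the chain rule ET(C₂|C₁) = ET(C₁,C₂) − ET(C₁), with the logarithm
applied to the cardinality ratio — the only form under which the chain
rule and the "refined given ⇒ zero conditional entropy" identity hold.
Mutual information is the symmetric three-term combination
I = ET(C₁) + ET(C₂) − ET(C₁,C₂).

The granularity form is *anti-monotone* in class consistency: a subset
whose granules cut across the decision classes scores a *larger*
I_gran(·;D) than one aligned with them (on the worked fixture, the
class-crossing nominal attribute scores 4/3 against 2/3 for the
class-consistent numeric one). For ranking, the package therefore defaults
to the information convention H = log₂n − ET, I_info = log₂n − I_gran — an
exact complement, so either convention is recoverable from the other and
both are asserted against each other to 1e-12 in the tests. The empty
subset is given the universal (all-similar) relation, making
I_info(∅;D) = 0; under the granularity convention the significance of the
first attribute is special-cased to I({Y};D), keeping the two conventions'
greedy scores consistent where they overlap.

### Approximations and dependency

Lower/upper approximations are the standard inf–max / sup–min IF rough
operators against a crisp class indicator, and the dependency degree γ
averages each sample's best score-level lower-approximation membership
(μ + 1 − ν)/2 over classes. γ is monotone under subset growth and equals 1
exactly when every sample's neighbourhood is class-pure. It is reported in
the selection trace as the classical rough-set view of subset quality but
never participates in the stopping rule, which is driven solely by the MI
quantities defined above.

### Greedy selection

Forward search from ∅; each step adds argmax_Y Ω(Y, red, D) with ties
broken by schema order (determinism). Stopping, checked in this order each
iteration: best gain ≤ δ (`gain_below_delta`, the usual exit; a first-step
exit logs a warning and returns an empty reduct), subset MI within δ of
the full set's (`reached_full_MI`), or no attributes left (`exhausted`).
Defaults: ε = 0.5, δ = 1e-3, information convention, sigma-count
cardinality. An exhaustive oracle (`greedy_step_oracle`) recomputes every
candidate through the full pipeline with no caching and must agree with
the incremental path step-for-step; this guards the subset-relation
aggregation against drift. The ε sweep mirrors the evaluation protocol:
reducts are computed per grid value and scored by a caller-supplied
evaluator (e.g. cross-validated accuracy), smaller ε winning ties.

## Evaluation harness

Sn, Sp, Ac are percentages; MCC is reported on its native [−1, 1] scale
(a zero marginal yields MCC = 0 with a logged warning). AUC is the rank
statistic with ties counting ½, identical to trapezoidal ROC integration
(asserted against scikit-learn to 1e-12 on randomized vectors). Protocols
(k-fold CV, percentage split) are stratified by the decision class and
seeded; stratification is a package default to protect small classes.
SMOTE balancing interpolates new minority samples between a minority
sample and one of its k = 5 nearest minority neighbours (Euclidean on
min–max-normalised numerics), copying nominal values from the seed sample;
it is seeded and applied, by default, only where the caller applies it —
the harness itself never balances inside evaluation, and the recommended
placement is inside training folds only, since balancing before splitting
leaks synthetic copies of test information into training.

## Synthetic data

The generator emulates screening-style tables: balanced classes,
informative numeric attributes from class-shifted unit-variance Gaussians
(separation = `effect`, default 2.0), redundant attributes as positive
affine transforms of informative parents plus N(0, 0.1·noise_scale) noise,
and independent N(0, noise_scale) noise attributes; a `nominal_frac`
(default 0.3) of attributes is rendered nominal by tercile binning of the
same draws, so ground-truth roles survive the conversion. Defaults:
n = 200, 3 informative, 2 redundant, 10 noise. What it deliberately does
not emulate: heavy-tailed or multimodal descriptor marginals, correlated
noise blocks, structural-alert-style sparse binary features, and label
noise. Passing recovery tests on this generator therefore shows the
selector can find well-separated planted signal among independent noise —
not that it handles the collinearity structure of real descriptor sets.

## Known limitations

* **MI rewards refinement.** Because granule cardinalities shrink as
  attributes are added, I_info(·;D) increases toward its cap for *any*
  refining attribute, informative or not. On planted-structure data the
  practical consequence is measurable: once two informative attributes
  make the granules nearly class-pure, a noise attribute's refinement gain
  can exceed the third informative attribute's residual alignment gain, so
  across 20 generator seeds (3 informative, 10 noise, effect 2.0) all
  three informative attributes enter the reduct in about 80–85% of runs
  rather than always, while reducts stay small (mean ≈ 4.5 attributes).
  This is a property of the granule-cardinality MI itself: it is
  insensitive to ε here (the gated numeric relation is effectively
  bimodal, so any cut in (0.1, 0.9) yields the same granules) and is
  unchanged when nominal binning is disabled.
* With redundant (monotone-copy) attributes present, the copy and its
  parent are interchangeable to the criterion; whichever enters first
  blocks the other (zero residual gain), so "recovery of the original" is
  not a meaningful target under planted redundancy.
* The n×n relation matrices make the implementation quadratic in sample
  count; it is intended for the hundreds-to-few-thousands regime, not
  out-of-core scale.
* The `as_printed` relation gate is intentionally partial and exists for
  documentation; all shipped defaults use the total `mu_only` gate.

## Problem sizes used in the shipped checks

The randomized identity sweep uses 220 systems with n ≤ 12, m ≤ 5 and
ε ∈ {0, 0.3, 0.5, 0.8}; greedy-vs-oracle agreement uses 100 systems with
n ≤ 10, m ≤ 6; recovery uses 20 generator seeds at n = 200; the AUC
cross-check uses 1,000 randomized score vectors. These sizes keep the
whole suite in the tens of seconds while exercising every code path at
the scales where brute-force verification is exact.
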