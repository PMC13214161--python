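# Methods

This note documents the models, defaults, and design choices behind
`tsponet`, and what the synthetic cohorts can and cannot tell you about
real data.

## Kinetic features

Each region is reduced to four parameters chosen to index both tracer
delivery and target expression:

| feature | meaning | units |
|---|---|---|
| SUV(1.25 min) | early uptake, delivery/perfusion dominated | dimensionless |
| SUV(13.5 min) | intermediate uptake, mixed delivery/binding | dimensionless |
| SUV(50 min) | late uptake, expression dominated | dimensionless |
| K₁ | blood-to-tissue influx rate | min⁻¹ (mL·cm⁻³·min⁻¹ equivalent) |

SUV uses the 1 g/mL tissue-density convention, so kBq/mL divided by MBq/kg
is treated as dimensionless. The TAC is sampled at the three target times
by linear interpolation with linear extrapolation from the two nearest
frames — relevant only for 60-minute acquisitions where 50 min lies beyond
the last frame mid-time on some schedules. The "common sparse time grid"
is realized as the three target times themselves: nothing else in the
method consumes the interpolated curve.

K₁ comes from the single irreversible compartment model
C_t(t) = K₁ ∫₀ᵗ C_p(u) du with the user-supplied input column as C_p
(C_p(0) = 0 assumed, trapezoid cumulation from t = 0), solved in closed
form as K₁ = Σ C_t X / Σ X² over frames with mid-time ≤ 3.0 min. The
3-minute window keeps the fit in the flow-dominated regime where efflux
and specific binding are negligible; it is exposed in the configuration
(`k1_window`). On forward-simulated irreversible data the estimator is
exact to machine precision; with efflux it is a deliberate
early-window approximation, biased low by design, which is acceptable
because the network uses K₁ as a relative regional contrast, not as an
absolute quantification.

## Standardization and similarity

The robust z-score (x − median)/MAD is computed per feature by pooling
**all scans and all regions of a tracer group** — patients included, since
standardization precedes any case/control split. Pooling over regions
preserves the between-region contrast the similarity depends on;
standardizing each region separately would destroy it. The MAD is left
unscaled (no 1.4826 normal-consistency factor): the definition is the
literal ratio. MAD = 0 for any feature raises an error rather than
silently producing infinities. A `standardized` flag on feature tables
guards against double standardization (z-scores of z-scores), and
similarity construction refuses raw tables.

S_ij = 1/(1 + d_ij) with Euclidean d over the four standardized features;
the diagonal is forced to 1 and excluded from all statistics. Edge vectors
are the strict upper triangle in row-major (i < j) order — 3741 entries
for 87 regions, 190 for the 20-region test atlas.

## Reliability statistics

- Blocking: per-subject median of the edge vector, one-tailed Wilcoxon
  signed-rank with alternative "block > baseline", the exact null for
  n ≤ 25, zero differences dropped. With n = 6 all-positive differences
  the exact p is 1/2⁶ = 0.015625, the smallest attainable at that n.
- Edgewise ICC(3,1): consistency form (MSR − MSE)/(MSR + (k−1)MSE) with
  k = 2 from the two-way ANOVA decomposition, the standard reading of
  "two-way mixed effects, single measurement". Computed vectorized over
  all edges; degenerate edges (no variance) return NaN and are excluded
  from the median ± MAD summary. Cross-checked in the test suite against
  pingouin's ICC(C,1).
- Fingerprinting is 1-nearest-neighbour on Spearman correlation (Pearson
  available as an option); argmax ties break to the lowest candidate index
  and are flagged. Rank correlation makes the identification invariant to
  any monotone transform of the edges.

## Confound model and harmonization

One OLS per edge (vectorized as a single multi-response least squares) on
a design of intercept + batch one-hot (reference = lexicographically first
level) + sex (F=0/M=1) + genotype (HAB=0/MAB=1) + age + dose-over-weight;
terms are droppable (genotype must be dropped for first-generation-tracer
cohorts where it is NA). A rank check names the collinear columns instead
of silently pseudo-inverting — batch perfectly confounded with genotype is
a real failure mode in retrospective multi-site data. Fitting is
restricted to healthy controls (`hc_only`) so disease variance is never
absorbed; residual z-scoring reuses training-sample mean/SD on held-out
scans, preserving the same leakage logic. For effect-size summaries the
outcome and all predictors are z-scored within the fit sample
(`standardized_beta`), and Cohen's d = mean(β)/SD(β) over edges gets a
percentile CI from 1000 seeded edge-bootstrap resamples.

## Classifiers

Disease-vs-control: L1 logistic regression (liblinear), 70/30 stratified
seeded split, C grid of 7 logarithmic points in 10⁻³…10³, stratified
k-fold CV repeated 10 times scored by average precision, with k reduced to
the positive-class training count so every fold holds a positive. Chance
AP is the positive prevalence. Test AP and ROC AUC carry 95% percentile
CIs from 1000 bootstrap resamples of the test set, stratified to preserve
class counts. No class weighting — imbalance is handled by the AP metric.
Regional importance is the sum of |β| over a region's incident edges
(every coefficient credits exactly two regions, so scores sum to 2Σ|β|).
Cross-disease overlap uses Kendall τ-b with Bonferroni correction over the
number of disease pairs. Task assembly is one-vs-all against same-tracer
controls, with psychosis-spectrum groups (SCZ, FEP) pooled against their
combined control pools. The multiclass variant uses saga with balanced
accuracy; nuisance probes (batch, sex, genotype) compare elastic-net
logistic regression, k-NN (k ∈ {3,5,7,9}) and SVMs (linear/poly/RBF) in
pipelines with within-training standardization. All grids, fold counts,
repeat counts and bootstrap sizes live in `ClassifierConfig` / the YAML
config; the test suite and acceptance script run reduced settings
(1–2 repeats, 3–5 C values, 50–500 bootstraps) — the package's choice of
desk-scale problem sizes, stated here so results are interpreted at that
scale.

## The synthetic cohort generator

Regional kinetics follow a one-tissue reversible model with
expression-modulated washout:

    C_t = K₁ · (e^(−k₂_eff t) ⊗ C_p),   k₂_eff = k₂₀ / (1 + f_s E_r)

This is the simplest mechanism with the right feature semantics: early SUV
tracks delivery (K₁ᵣ), late SUV tracks effective expression E_r (higher
expression ⇒ slower washout ⇒ higher late uptake), and K₁ is recoverable.
A two-tissue model would add parameters without changing what the network
sees. The input function is a gamma-variate A·t^α·e^(−t/τ) (α = 2,
τ = 0.75 min ⇒ peak at 1.5 min) scaled linearly with injected dose.

Curves are generated directly at the frame mid-times (with a virtual t = 0
zero sample) using an exact closed-form convolution for piecewise-linear
input. In the irreversible limit this reduces to the trapezoid-cumulated
input, which is precisely the quadrature the K₁ estimator assumes, so the
simulate-then-fit loop is exact — a deliberate consistency choice that
makes parameter-recovery tests sharp. Early frames are 15 s, so the
piecewise-linear input model is accurate.

Defaults (all in `SimConfig`):

- K₁ᵣ ~ U(0.08, 0.14) min⁻¹, E_r ~ U(0.5, 3.0), k₂₀ = 0.08 min⁻¹,
  drawn once per homolog pair so left/right homologues share kinetics —
  this produces the homotopic secondary diagonal in the similarity
  matrices.
- Between-subject variability: log-normal with σ = 0.10 on K₁ᵣ and E_r
  (shared within homolog pairs); retest sessions add σ = 0.02 jitter.
- Sex: male K₁ multiplier 0.9. A global multiplicative kinetic scale
  propagates to all four features, so a sub-unity male factor compresses
  inter-regional contrast and raises similarity, reproducing the
  positive-male direction of the sex effect; the magnitude is a modelling
  convenience, not a physiological estimate.
- Genotype: specific-binding fraction f_s scaled 1.0 (HAB) vs 0.6 (MAB) —
  mixed-affinity binders have flatter spatial signal, hence higher
  similarity. Blocking multiplies f_s by (1 − occupancy); at occupancy 1
  every region shares k₂_eff and TACs differ only by the K₁ scale, which
  is why median similarity rises monotonically with occupancy.
- Age widens the spread of E_r around its mean (gain 1 + 0.5·(age−40)/40),
  so similarity falls with age.
- Dose ~ U(150, 500) MBq, weight ~ U(55, 95) kg, with a mild saturation
  term reducing f_s at high dose/weight (similarity rises with dose).
- Batches carry a frame schedule, a global multiplicative activity scale
  and a noise level; frame noise is Gaussian with SD ∝ √(C/Δt) (count-
  statistics proxy for reconstructed PET), applied per batch.
- All randomness flows from the master seed through four named
  SeedSequence substreams (kinetic template, covariates, session jitter,
  frame noise); identical seeds give byte-identical output files.

A second, edge-level generator (`simulate_edge_cohort`) plants *additive*
covariate, batch and disease effects directly on edge values with exact
ground truth. It exists because additive planted effects are the natural
oracle for the linear confound model (recovered coefficients can be
compared to injected offsets) and for importance recovery, whereas the
TAC-level batch effect is multiplicative with no closed-form edge offset.

### What the simulator does not emulate

Scanner point-spread and reconstruction differences, partial-volume
effects, motion, metabolite correction errors, genuine two-tissue
kinetics, non-linear covariate effects, and spatially structured
(non-independent) noise. Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
clinical performance on real cohorts — real-data reliability and
classification levels cannot be inferred from these simulations.

## Study conditions used by the acceptance script

Problem sizes were chosen to exercise each analysis meaningfully at desk
scale: 20-region atlas for simulations (full 87-region atlas for formula
and edge-count checks); 6 blocking subjects at occupancy 0.9 and noise
0.01; 15 test–retest subjects at noise 0.05; 50 subjects × 400 edges for
the ICC variance-ratio recovery (σ_b = 1.0, σ_w = 0.8); 60 control scans
across 3 batches with additive offsets (0, +0.05, −0.03) for harmonization
recovery; 25 + 25 scans with a strong planted effect for the separable
classification check plus a label-shuffled null; and, for importance
recovery, 80 + 80 scans with a *distributed* weak disease effect (per-edge
shift 0.05 against noise SD 0.06) on 3 target regions. The distributed
regime matters: a near-separable effect lets L1 collapse onto one or two
edges, crediting each edge's non-target endpoint equally, so top-3
recovery of the planted regions requires coefficient mass spread over many
incident edges; the chosen shift gives a per-seed recovery rate around
0.97.

## Numerical choices and degenerate inputs

- Exact Wilcoxon null for n ≤ 25; all-zero difference sets are an error,
  not p = 1.
- ICC edges with zero denominator → NaN, excluded from summaries; an
  all-NaN result is an error.
- Constant edge vectors make rank correlations undefined and raise.
- Argmax ties in fingerprinting break deterministically to the lowest
  index and are flagged in the report.
- Negative SUV from extrapolating a noisy late TAC is clipped at zero.
- Matrices round-trip through CSV at 17 significant digits (< 1e-12
  error); simulated cohorts are written with fixed formats so reruns are
  byte-identical.

## Known limitations

The default 87-region label list is representative
(Desikan-Killiany + ASEG naming), not a certified clinical parcellation;
any atlas CSV can be substituted. The K₁ estimator ignores efflux within
the fit window. The confound model is linear; non-linear batch effects
survive residualization (though a linear classifier cannot exploit them).
The input function is taken as given — no vascular segmentation or
metabolite correction is modelled.
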