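# Methods

## Dynamics model

The package places noise-free linear discrete-time time-invariant dynamics
on each subject's structural connectome: x(t+1) = Ā x(t) + B_K u_K(t),
where x is the vector of regional activity states and Ā is the adjacency
matrix divided by one plus its largest singular value. For a symmetric
matrix this stabilization bounds the spectral radius by σ₀/(1+σ₀) < 1, so
uncontrolled trajectories contract and the infinite-horizon controllability
Gramian converges. The linear model is a deliberate simplification of
nonlinear neural dynamics: it is used only to derive per-region
controllability statistics, never to simulate biophysics. A trajectory
simulator (`dynamics.simulate`) exists as a test utility; all metrics are
computed in closed form.

Control is single-node: B_K = e_k, one canonical vector at a time. The
smallest eigenvalue of the full-control Gramian is available as a logged
diagnostic (`gramian_spectrum_diagnostic`) but does not gate computation —
single-input Gramians of sparse graphs are routinely near-singular, and the
metrics are traces, not inverses.

## Controllability metrics

**Average controllability** of node k is Trace(W_k) with
W_k = Σ_τ Ā^τ e_k e_kᵀ Ā^τ. For symmetric stable Ā,
Σ_k W_k = (I−Ā²)⁻¹ and Trace(W_k) is the k-th diagonal entry of that
inverse; the implementation uses this exact closed form (one O(N³) solve
per subject) rather than truncated series or the ill-conditioned
inverse-Gramian route. The τ=0 term contributes exactly 1, so values are
≥ 1. Tests verify three independent routes agree to 1e−8: the closed form,
a brute-force series truncated at relative increment < 1e−12, and the
discrete Lyapunov solution W = ĀWĀᵀ + I.

**Modal controllability** is φ_i = Σ_j (1−λ_j²) v_ij² over an orthonormal
eigendecomposition Ā = VΛVᵀ (symmetric eigensolver, modes unsorted). φ is
basis-stable under eigenvalue degeneracy because the loading sum over an
orthonormal basis of a degenerate eigenspace is rotation-invariant; a
repeated-eigenvalue case is tested. Orthonormality yields the conservation
law Σ_i φ_i = N − Trace(Ā²), asserted to 1e−9, and values in (0, 1] for
stabilized matrices.

## Synchronizability

Global synchronizability is the inverse normalized spread of the nonzero
Laplacian eigenvalues, 1/σ² = d̄²(N−1)/Σ(λ_i−λ̄)², with d̄ = (1/N)ΣΣ A_ij.
The orientation (large spread ⇒ low synchronizability) follows the
master-stability-function rationale: a tight eigenvalue cluster fits inside
a stability region more easily. The d̄² normalization makes the value
exactly invariant under uniform weight rescaling, so raw streamline counts
are used without stabilization.

The **regional split** is an interpretation this package defines explicitly
(the quantity is usually reported globally): the spread decomposes over
nodes through Laplacian eigenvector loadings,
s_i = Σ_{λ_j>0} (λ_j−λ̄)² u_ij², the unique linear decomposition that
(a) sums exactly to the global spread, (b) is permutation-equivariant and
(c) is constant on vertex-transitive graphs. Regional values are
d̄²(N−1)/(N·s_i), so equal loadings reproduce the global value. A caveat
worth knowing: on the 3-path every node receives the same regional value,
because its two nonzero eigenvalues deviate equally from their mean and the
constant eigenvector carries no spread — regional heterogeneity requires
unequal eigenvalue deviations (e.g. a star graph).

Numerical choices: eigenvalues below 1e−9 × max(λ, 1) count as zero; more
than one zero raises a disconnection error rather than silently analyzing
the giant component, which would corrupt group statistics. A degenerate
(zero-spread) spectrum — complete graphs — is flagged and represented as an
infinite sentinel; downstream statistics exclude non-finite values with a
logged count instead of propagating infinities.

## Supercontrollers

A region is a supercontroller for a group when its across-subject group-mean
metric value strictly exceeds the across-region mean plus one sample
(n−1) standard deviation. Mean-then-threshold (one map per group) was
chosen over per-subject thresholding with voting; both the strict
inequality and the sample-SD convention are stated here for
reproducibility. Selection is invariant to positive affine rescaling of the
metric. A top-k alternative is exposed without a default. System summaries
count selected regions per functional system and report each system's
covered fraction.

## Group statistics

- Omnibus differences: one-way ANOVA per metric (global level) or per
  region (regional level).
- Pairwise contrasts "adjusted for age and sex" are operationalized as the
  group-coefficient t (two-tailed) in an OLS fit
  y ~ 1 + group + age + sex — i.e. ANCOVA. The alternative
  (residualize-then-t-test) differs in degrees of freedom and is not used.
  Degenerate covariates (constant age, single-sex contrast) are dropped
  with a warning. With constant covariates the statistic reduces exactly to
  the pooled two-sample t.
- Multiplicity: Bonferroni at the nodal level, m = number of regions per
  metric per contrast (246 at full scale, 60 in the test-scale cohorts) —
  not metrics × contrasts × regions. Each metric × contrast family
  therefore has its own 5% familywise error rate; across the nine families
  of a three-group analysis, some family shows a false positive in roughly
  a third of null runs, which is nominal behaviour, and calibration checks
  are accordingly evaluated per family.
- Metric–symptom associations: partial Spearman. All variables (metric,
  scale, and each covariate) are rank-transformed with average ranks, the
  metric and scale ranks are residualized on an intercept plus covariate
  ranks, and the residual Pearson correlation is tested against a
  t-distribution with n−2−k degrees of freedom, two-tailed. Missing scale
  values are dropped pairwise with a logged n. Strong confounding leaves a
  small residual bias (rank-based partial correlation is approximate
  conditional independence), quantified in tests.

## Classification

Linear-kernel SVM on the stacked regional metric features, stratified
k-fold CV (default k = 10, seeded). Within each training fold: features
with an adjusted group-difference p < .05 (uncorrected) are selected,
standardized by training mean/SD, and the SVM is fit with box constraint
C ∈ (0, 1], default C = 1. Held-out decision values are pooled for
accuracy/sensitivity/specificity, the ROC curve and trapezoidal AUC (equal,
to numerical precision, to the Mann–Whitney normalization — tested). An
empty selection falls back to all features with a warning. Selection before
CV leaks labels; a `leaky_preselect` flag reproduces that protocol for
demonstration only and is excluded from reported results. Both pooled and
fold-averaged accuracies are reported because the two conventions differ.

## Scale prediction (improved CPM)

Leave-one-subject-out. Per fold, every node-metric feature is
Spearman-correlated with the scale on the n−1 training subjects; features
significantly positive and significantly negative (two-tailed p < .05) form
two sets; each set is z-scored by training statistics and summed per
subject; a multiple linear regression of the scale on {positive sum,
negative sum} predicts the held-out subject with training-derived
z-scoring. Predictive power is the Spearman correlation between held-out
predictions and true scores. When both sets are empty in a fold the
held-out prediction is the training mean, with a warning.

Known property: the null distribution of the LOOCV evaluation correlation
is wide at small n (SD ≈ 0.3 at n = 45, essentially independent of the
feature count), because in-fold-selected noise features persist across
folds, and because the training-mean fallback is perfectly
rank-anti-correlated with the held-out value under leave-one-out. This is
intrinsic to sum-based CPM and is the standard argument for permutation
testing of CPM results; the package's tests quantify it rather than hide
it.

## Synthetic cohorts

The generator emulates the products of a three-group structural study
without imaging data. Defaults are the study conditions themselves.

- **Cohort shape**: HC 105, SZ 45, BD 47; ages uniform on 21–50 years;
  group-specific male fractions 58/105, 34/45, 28/47. Region count defaults
  to 60 for test-scale work and 246 at full scale; all code is N-generic.
- **Connectomes**: a cohort-level *template* graph — block-modular edge
  presence (4 modules; within/between densities 0.6/0.15) with log-normal
  edge weights (log-mean 2.0, log-SD 0.8, mimicking heavy-tailed streamline
  counts) — shared by all subjects, with independent multiplicative
  log-normal per-subject jitter (log-SD 0.3) on every edge. The shared
  backbone with individual variation reproduces the cross-subject
  correlation structure of real cohorts; fully independent per-subject
  redraws were rejected because they make cross-subject metric
  distributions extremely heavy-tailed and "effect size in SD units"
  ill-defined. Weights are rounded to integers ≥ 1 on present edges;
  templates are redrawn until connected, and subjects inherit
  connectedness.
- **Group effects** act on the structure, not the metrics: the incident
  edge weights of designated regions are multiplied by a factor, so the
  whole metric pipeline sits inside every test loop. Effects stated in
  within-group SD units of a target metric are translated to a weight
  multiplier by a paired pilot simulation around the cohort template
  (20 pilot subjects, monotone interpolation over a 0.5–2.5 multiplier
  grid), deterministic given the seed. A 1.2-SD request realizes
  1.18 ± 0.19 SD across replicate cohorts.
- **Clinical scales** (SZ: BDRS, SANS, SAPS; BD: YMRS, HAMD) are linear
  combinations of designated node metrics plus Gaussian noise, or noise
  around plausible scale baselines when undriven. Driver coefficients can
  apply to within-group z-scored metric values (`standardized`), keeping
  effect statements in SD units. The canonical signal condition
  (`module_scale_model`) loads severity on one module's average
  controllability (positively) and modal controllability (negatively) —
  a subsystem-coherent severity model whose inter-correlated signal
  features dominate CPM's selected sets; single-isolated-node severity is
  a much harder target for sum-based CPM and is not the default.
- Optional age confounding: group age shifts plus a per-year multiplicative
  trend on all weights.

What the generator does *not* emulate: spatial embedding and
distance-dependent wiring, hemispheric asymmetries, subject-level topology
differences, scanner/site effects, and any biophysical tractography error
process. Passing tests therefore demonstrate the statistical machinery is
correct and calibrated under the assumed generative structure — not that
the pipeline's real-data conclusions are reproduced; those require the
original accession.

## Problem sizes and determinism

Test-scale simulations use 60-region cohorts at the study's group sizes;
calibration checks use 1000 univariate replicates, 10 full null-cohort
runs, 100 effect-recovery replicates and 20 CPM replicates; the full-scale
shape check generates the complete 197-subject, 246-region cohort. Every
stochastic component takes an explicit seed; pipeline outputs are pure
functions of (inputs, config, seed), and rerunning a configuration
reproduces tables byte for byte.

## Region metadata

The bundled `default_region_table(n)` produces a deterministic synthetic
atlas-like layout (hemisphere pairs, lobes, the seven cortical functional
systems plus a subcortical level, ~1/6 subcortical regions). It is a
stand-in for a real atlas-to-system mapping and is labelled as such; users
with a real parcellation supply their own table with the same columns.

## Known limitations

- The regional synchronizability split is an interpretation (see above);
  other decompositions are conceivable.
- The adjusted contrast assumes linear covariate effects; rank-based
  partial correlation removes monotone confounding only approximately.
- CPM's null evaluation correlation is wide at n ≤ 50; use permutation
  tests before interpreting a single cohort's prediction correlation.
- The SVM box-constraint search within (0, 1] is exposed but defaults to
  C = 1 without inner CV.
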