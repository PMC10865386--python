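# Methods

## Model and assumptions

The package models a baseline-subtracted postprandial response as a
discrete linear time-invariant system driven by an impulse,

    x_{t+1} = A x_t + B z_t,    z_1 = diet input vector, z_{t>1} = 0.

The assumptions this buys and their consequences:

* **Linearity.** Responses superpose: the reaction to any diet is a
  linear combination of reactions to a spanning set of diets. This is
  what makes unseen-diet prediction from baseline + input possible at
  all, and it is the dominant approximation — real postprandial
  physiology saturates and interacts.
* **Time invariance and a common sampling grid.** The time axis is an
  ordinal index; real sampling times are metadata. All fitted
  operators advance the state by one grid step.
* **Impulse input.** A meal acts once, at the first transition, after
  which the system relaxes autonomously. Slow nutrient release
  (delayed uptake) is not representable by a single impulse; this is a
  stated approximation, not a claim about digestion.
* **Baseline-subtracted coordinates.** The pre-meal sample is
  subtracted, so the initial state is exactly zero and every
  prediction is driven by B z₁. Reports in original units re-add the
  measured baseline.

Identification is least squares through the SVD of the stacked
snapshot-with-input matrix Ω = [X; Z], truncated at rank V. At
V = rank(Ω) this is the minimum-Frobenius-norm solution; smaller V
regularizes. The latent reduction projects the full-state operators
onto the leading-S left singular vectors of X′ (per-individual) or of
the fully concatenated data X_tot (the shared basis used for
metabotyping, which makes latent trajectories comparable across
individuals). Prediction deliberately stays at full state dimension;
latent projection is reserved for interpretation and clustering.

## Parameters that matter

| parameter | where | default | rationale |
|---|---|---|---|
| V (truncation rank) | `fit_dmdc` | chosen by validation | regularizes the pseudoinverse; V ≤ numerical rank enforced |
| S (latent dimension) | `compute_shared_basis` | scree knee | number of retained dynamic "themes"; always overridable |
| tol (early stop) | `select_rank` | 0.30 | relative excess of validation over training rollout RMSE that signals overfitting |
| tie_tol | `select_rank` | 0.05 | parsimony tie-break: smallest rank within 5% of the best validation RMSE (one-SE-rule style) |
| split fractions | `split_observations` | 0.6/0.2/0.2 | floor-allocated with remainder to train (51 observations → 31/10/10) |
| n_iter | `resampling_experiment` | 100 | resampling-without-replacement repetitions |
| F (CP components) | `cp_als` | workflow: 5 | see comparator note below |
| degeneracy threshold | `check_two_factor_degeneracy` | 0.85 | standard chemometrics cutoff on the (negative) triple cosine |

Rank-selection details that were genuinely open and are resolved here
as package choices:

* RMSE is computed on **full-trajectory rollouts** (from each
  observation's own initial state and impulse), matching the
  prediction use case, not on one-step-ahead transitions.
* The 30% rule is **one-sided**: only validation error *exceeding*
  training error triggers the stop. A validation error below training
  is not overfitting and must not halt the scan.
* Among visited ranks the **smallest** V within `tie_tol` of the best
  validation RMSE wins. With noise, the validation curve plateaus at
  the noise floor and an exact argmin would select an arbitrary
  plateau rank.

## The synthetic generator

`synthetic.PopulationSpec` draws per-individual stable latent systems
x̃_{t+1} = A_i x̃_t + B_i z_t observed through one shared orthonormal
mixing map (x = U_true x̃ + baseline + noise). Defaults emulate the
crossover-study geometry (M=79, T=8, I=17, D=3) and, for populations,
a two-group structure with a 2× multiplicative shift on a designated
parameter subset and 16% within-group coefficient of variation —
magnitudes taken from the healthy/diabetic parameter table of the
metabolic-simulation literature this design mirrors.

Concretely, the designated (shifted) latent states form a damped
oscillatory pair; the group shift multiplies its rotation rate, its
log-damping rate and the designated input gains, so groups differ in
response *shape* (timing, damping, sign pattern) — a pure amplitude
shift would be invisible to cosine-similarity clustering. Individual
variation acts multiplicatively on the designated input gains, the
closest linear-system analogue of the Vmax/Km-type rate constants that
vary between individuals in the mirrored design; one consequence is
that each group's tensor stays near-multilinear, so the CP comparator
has a fair chance at the same clusters. Diet impulse magnitudes are
normal draws truncated at zero (glucose 220 ± 88.9 mmol and
triglyceride 25 ± 10.1 mmol for two-input settings; meal macronutrient
statistics for three-input settings). The true B is scaled by the
reciprocal mean diet magnitude so observed responses are O(1)
regardless of input units; `noise_sd` (default 0.02) and the baseline
distribution (1.0 ± 0.2) are absolute on that scale.

What the generator does **not** emulate: nonlinear saturation,
metabolite-specific noise structure, delayed nutrient uptake (a single
impulse cannot express release delays; an optional input spreading is
deliberately not implemented), missing values, and any real metabolite
identities. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated statistical structure —
not performance on measured clinical data.

## The CP comparator

The four-way CANDECOMP/PARAFAC model X ≈ Σ_f r_f ⊗ q_f ⊗ p_f ⊗ h_f is
fitted by alternating least squares (unfoldings + Khatri–Rao products,
best of `n_starts` seeded random initializations; the objective is
non-increasing by construction and iteration stops on relative
improvement < 1e-8). The metabotyping workflow uses F=5 on the
default two-group population — two common decay states plus one
oscillatory cos/sin pair per group span about five to six rank-1
terms — and clusters **direction-normalized** individual scores,
treating overall response amplitude as an individual nuisance. The
two-factor-degeneracy diagnostic (triple cosine < −0.85 for any
component pair) is computed and reported for every fitted model;
near-degenerate solutions on this data still separate the groups, so
the diagnostic gates interpretation, not the workflow's component
count.

## Numerical choices

* Singular values below max(dims)·eps·σ₁ are treated as zero when
  validating ranks, preventing ill-conditioned Σ̂⁻¹.
* Every SVD fixes signs deterministically (largest-magnitude entry of
  each left singular vector made positive), so factorizations are
  bit-reproducible across runs and platforms.
* The scree knee is the argmax of the discrete second difference of
  the normalized spectrum; a maximal curvature below 0.1 raises a
  "weak inflection" warning because knee-less spectra (e.g. geometric
  decay) make the criterion meaningless.
* Agglomerative clustering uses complete linkage throughout — with
  1 − cosine similarity between individuals, and 1 − Pearson
  correlation between metabolite time profiles — with deterministic
  relabeling by first appearance.
* Degenerate inputs fail loudly and name the offender: incomplete
  tensor crossings, zero-variance slices under standardization,
  constant profiles under correlation, zero-norm trajectories under
  cosine similarity.
* Zero-magnitude diets (possible under truncation at zero) produce
  identically zero baseline-subtracted responses; per-diet
  standardization rejects them by the zero-variance rule rather than
  silently rescaling.

## Evaluation protocol and problem sizes

An observation is one (individual, diet) response. The resampling
protocol permutes observations, splits 60/20/20, selects V on the
validation set, fits the pooled full-state model, predicts the test
responses from baseline + impulse and scores the tensor-wide
R² = 1 − Σ‖vec(X̂ᵢ)−vec(Xᵢ)‖² / Σ‖X̄−vec(Xᵢ)‖² against the grand mean
of the test tensor; the mean over iterations is reported.

The increasing-diet-count benchmark holds 50 diets out, sweeps the
training diet count 3→40 with 5 scrambling repetitions, and fits the
pooled model at full usable rank: the sweep isolates how input-space
coverage grows with the diet count, and at thousands of snapshot
columns per fit there is no overfitting for truncation to guard
against (the early-stopping variant is available as
`rank_policy="select"`). The benchmark population uses a
32-dimensional diet encoding (mean 100, sd 40 per component) precisely
so each added diet keeps revealing new input directions across the
whole sweep — with a 2-input encoding, three diets already span the
input space of a linear model and there is no trend to measure. It
also uses mild individual variation (cv = 0.05): a pooled fit's R² is
floored by inter-individual spread independently of diet count, and
the benchmark targets the coverage effect, not that floor.

Problem sizes used by the test suite and `scripts/acceptance.py`,
chosen as the smallest instances in which each property is sharply
expressed: random fit instances with M ≤ 8, l ≤ 3, N ≤ 40 snapshot
columns; a rank-5 instance (latent dimension 4 + one input row) for
order selection; the diet sweep at M=30, I=17, D=90; metabotyping at
the full M=79, T=8, I=100 (50+50), D=3 design; planted rank-2 tensors
of shape 6×5×4×3 for CP. Population-level robustness of the stochastic
checks was verified over hundreds of generator seeds during
development.

## Known limitations

* Fitted Â can be unstable (spectral radius ≥ 1) on noisy data;
  eigenvalue rescaling ("stabilized DMD") is intentionally out of
  scope, so long-horizon rollouts of such fits can diverge.
* Per-diet standardization of measured data breaks exact linear
  consistency across diets (each diet is scaled separately); for
  synthetic linear data the pooled-scale variant with identically
  rescaled impulses preserves exactness and is what the rank-selection
  fixtures use.
* The equivalence of per-(metabolite, diet) vs pooled per-diet
  standardization is data-dependent; both are exposed
  (`standardize_per_diet(mode=...)`).
* Scaling with train-only statistics (`train_only_scaling`) is not
  implemented; scales are computed on the full tensor, which leaks a
  small amount of scale information into evaluation and is flagged
  here for transparency.
* Control synthesis (choosing a diet to reach target metabolite
  trajectories) is out of scope.
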