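# pdmdc — parametric dynamic mode decomposition with control for postprandial metabolomics

Crossover nutrition studies measure a four-way response tensor
**X** ∈ ℝ^(M×T×I×D): M metabolites at T time points for I individuals
across D meal challenges. Two questions dominate the analysis of such
data: can the full multivariate postprandial time course be
**predicted** for a diet an individual never ate, and do individuals
fall into subgroups with distinct dynamic responses — **metabotypes**?

`pdmdc` answers both with one model family: a discrete linear
dynamical system identified directly from snapshot data (dynamic mode
decomposition with control), extended parametrically across diets.

## The model

Each baseline-subtracted response is assumed to follow

    x_{t+1} = A x_t + B z_t,        x_t ∈ ℝ^M,  z_t ∈ ℝ^l,

with the meal entering as an impulse: z_1 is the diet's input vector
(e.g. macronutrient grams), z_t = 0 afterwards. Stacking past
snapshots X, future snapshots X′ and inputs Z gives X′ = [A B][X; Z] =
GΩ, solved in the least-squares (Frobenius) sense through a truncated
SVD of Ω:

    G = X′ Ŵ Σ̂⁻¹ Ûᵀ,   Â = X′ Ŵ Σ̂⁻¹ Û_Xᵀ,   B̂ = X′ Ŵ Σ̂⁻¹ Û_zᵀ,

where the truncation rank V regularizes the fit. The *parametric*
extension concatenates the snapshot blocks of all D diets (and, for
the pooled prediction model, of all training individuals), so one
operator pair explains every response. Because x₁ = 0 after baseline
subtraction, a prediction needs only the metabolite baseline and the
diet composition.

For metabotyping, all data are projected onto a single shared
orthonormal basis Ũ_tot (leading left singular vectors of the
concatenated data matrix X_tot), each individual's dynamics (Ã_i, B̃_i)
are fitted inside that common S-dimensional latent space, and
individuals are clustered per latent state and diet on the cosine
similarities of their trajectories x̃_{s,1:T,i,d}. An unconstrained
four-way CP (CANDECOMP/PARAFAC) decomposition — fitted by alternating
least squares, with a two-factor-degeneracy diagnostic — serves as the
tensor-decomposition comparator, clustering individuals by k-means on
their CP scores.

Because the measured data of such trials is typically access-restricted,
the package ships a first-class synthetic-population generator:
per-individual stable linear systems in a shared latent space, impulse
diets with configurable magnitude distributions, cluster-level ~2×
parameter shifts with ~16% within-cluster variation, baselines and
measurement noise — with the full ground truth returned for recovery
testing.

## Worked example

`examples/predict_unseen_diet.py` trains a pooled model on 5
individuals × 7 diets and predicts the entirely held-out eighth diet:

```
trained on 35 observations (5 individuals x 7 diets)
held-out diet diet_007 with input vector [35.8 41.  80.1]
test R^2 over all 5 individuals: 0.9966
```

The R² of 0.9966 means the unseen responses are almost fully explained
by the fitted linear dynamics driven by baseline + diet impulse alone.
`examples/metabotype_clustering.py` runs the companion use case on a
50+50 two-cluster population:

```
best pDMDc state ARI: 1.00  (1.0 = perfect recovery)
CP-score k-means ARI: 1.00  (CP explains 96.7% of the variance)
agreement between the two methods: 100.0%
```

An adjusted Rand index of 1.0 against the generator's labels means
both routes recover the planted metabotypes exactly. The other
examples cover tensor I/O and preprocessing, rank selection, and the
increasing-diet-count benchmark.

A thin CLI wraps the same workflows:

```bash
pdmdc simulate --preset metabotype-100 --seed 0 --out data/
pdmdc evaluate --tensor data/tensor.csv --diet-file data/diets.csv --out report/
pdmdc metabotype --tensor data/tensor.csv --diet-file data/diets.csv --out report/
```

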