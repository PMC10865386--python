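"""Metabotyping: clustering latent dynamics, with a CP comparator.

Individuals sharing the output map Ũ_tot live in the same latent
coordinate system, so their latent state trajectories x̃_{s,1:T,i,d}
can be compared directly.  For each latent state s and diet d we form
the I × I matrix of pairwise cosine similarities between individuals'
trajectories and cluster it agglomeratively (complete linkage on
1 − similarity); groups of individuals with similar postprandial
dynamics are candidate metabotypes.

Supporting pieces:

* model-order selection by the inflection (knee) of the singular-value
  scree of X_tot;
* "dynamical classes": clustering metabolite time-profiles of the
  individual/diet-averaged data by correlation distance, to read off
  which kind of dynamics each latent state represents;
* an unconstrained 4-way CANDECOMP/PARAFAC (CP) decomposition fitted
  by alternating least squares, the standard tensor-decomposition
  comparator, with a two-factor-degeneracy diagnostic and k-means on
  the individual scores;
* cluster-overlap (optimal label matching) and one-way ANOVA linking
  clusters to clinical baseline measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.stats import f as f_dist
from scipy.stats import pearsonr
from sklearn.cluster import AgglomerativeClustering, KMeans
from sklearn.metrics import adjusted_rand_score

from .data_model import ClinicalTable, DietInputMatrix, ResponseTensor
from .parametric import IndividualLatentModel, SharedBasis

__all__ = [
    "StateTrajectorySet",
    "SimilarityMatrix",
    "CPModel",
    "extract_state_trajectories",
    "cosine_similarity_matrix",
    "cluster_similarity",
    "scree_inflection",
    "dynamical_class_profiles",
    "profile_correlation",
    "cp_als",
    "check_two_factor_degeneracy",
    "cluster_cp_scores",
    "cluster_overlap",
    "anova_association",
]


@dataclass(frozen=True)
class StateTrajectorySet:
    """Latent state trajectories as a 4-way array (state, time,
    individual, diet) plus the ids they came from."""

    trajectories: np.ndarray  # S × T × I × D
    individual_ids: tuple[str, ...]
    diet_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        traj = np.asarray(self.trajectories, dtype=float)
        object.__setattr__(self, "trajectories", traj)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        object.__setattr__(self, "diet_ids", tuple(self.diet_ids))
        if traj.ndim != 4:
            raise ValueError("trajectories must be a 4-way (s, t, i, d) array")
        if not np.all(np.isfinite(traj)):
            raise ValueError("trajectories contain non-finite values")

    @property
    def S(self) -> int:
        return self.trajectories.shape[0]

    @property
    def T(self) -> int:
        return self.trajectories.shape[1]


@dataclass(frozen=True)
class SimilarityMatrix:
    """I × I cosine-similarity matrix for one (latent state, diet)."""

    values: np.ndarray
    state_index: int
    diet_id: str
    individual_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "individual_ids", tuple(self.individual_ids))
        if v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        if np.any(v < -1 - 1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("cosine similarities must lie in [-1, 1]")


@dataclass
class CPModel:
    """Unconstrained 4-way CP decomposition X ≈ Σ_f r_f ⊗ q_f ⊗ p_f ⊗ h_f."""

    metabolite_factors: np.ndarray  # M × F  (r)
    time_factors: np.ndarray        # T × F  (q)
    individual_scores: np.ndarray   # I × F  (p)
    diet_factors: np.ndarray        # D × F  (h)
    F: int
    explained_variance: float
    converged: bool
    objective_history: np.ndarray
    degenerate: bool = False

    @property
    def factors(self) -> list[np.ndarray]:
        return [self.metabolite_factors, self.time_factors,
                self.individual_scores, self.diet_factors]


def extract_state_trajectories(models: list[IndividualLatentModel],
                               diets: DietInputMatrix, T: int) -> StateTrajectorySet:
    """Roll each individual's latent model forward per diet.

    Every model must be expressed in the same :class:`SharedBasis`;
    trajectories are then directly comparable across individuals.
    """
    if not models:
        raise ValueError("no models given")
    bases = {id(m.basis) for m in models}
    if len(bases) > 1 or not isinstance(models[0].basis, SharedBasis):
        raise ValueError("all models must share one SharedBasis")
    S = models[0].S
    I, D = len(models), diets.n_diets
    traj = np.empty((S, T, I, D))
    for i, model in enumerate(models):
        for d, diet_id in enumerate(diets.diet_ids):
            traj[:, :, i, d] = model.trajectory(diet_id, diets.inputs[:, d], T)
    return StateTrajectorySet(traj, tuple(m.individual_id for m in models),
                              diets.diet_ids)


def cosine_similarity_matrix(ts: StateTrajectorySet, s: int, d: int) -> SimilarityMatrix:
    """Pairwise cosine similarities between individuals' trajectories of
    latent state ``s`` under diet ``d``; the diagonal is set to 1."""
    traj = ts.trajectories[s, :, :, d].T  # I × T
    norms = np.linalg.norm(traj, axis=1)
    small = np.where(norms <= 1e-12)[0]
    if small.size:
        names = [ts.individual_ids[i] for i in small]
        raise ValueError(
            f"zero-norm trajectory for individuals {names} (state {s}, diet {ts.diet_ids[d]})")
    sim = (traj @ traj.T) / np.outer(norms, norms)
    sim = np.clip((sim + sim.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(sim, s, ts.diet_ids[d], ts.individual_ids)


def cluster_similarity(sim: SimilarityMatrix, k: int) -> np.ndarray:
    """Agglomerative clustering of a similarity matrix into k groups
    (complete linkage on the distance 1 − similarity)."""
    I = sim.values.shape[0]
    if not 2 <= k <= I:
        raise ValueError(f"k must be in 2..{I}")
    dist = 1.0 - sim.values
    np.fill_diagonal(dist, 0.0)
    model = AgglomerativeClustering(n_clusters=k, metric="precomputed",
                                    linkage="complete")
    return model.fit_predict(dist)


def scree_inflection(singular_values: np.ndarray, *, weak_threshold: float = 0.1
                     ) -> tuple[int, dict]:
    """Model order from the knee of a singular-value scree.

    Returns the index maximizing the discrete second difference of the
    spectrum normalized by its first value — the count of components
    retained before the curve flattens.  A ``weak_inflection`` flag is
    raised when the maximal curvature is small (knee-less spectra such
    as geometric decay); callers should then inspect the spectrum and
    override.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 singular values")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("singular values must be non-increasing")
    sn = s / s[0]
    d2 = sn[:-2] - 2.0 * sn[1:-1] + sn[2:]  # curvature at positions 1..n-2
    k = int(np.argmax(d2)) + 1
    weak = bool(d2.max() < weak_threshold)
    if weak:
        warnings.warn("weak inflection: scree has no clear knee; inspect the spectrum",
                      stacklevel=2)
    return k, {"second_differences": d2, "weak_inflection": weak, "spectrum": s}


def dynamical_class_profiles(tensor: ResponseTensor, S: int
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Group metabolites into S dominant dynamical classes.

    Averages the tensor over individuals and diets to an M × T profile
    matrix, clusters the profiles by complete-linkage ("farthest
    distance") agglomeration with 1 − Pearson correlation as distance,
    and returns per-metabolite labels plus the S × T mean profile of
    each class.
    """
    Xbar = tensor.values.mean(axis=(2, 3))  # M × T
    const = np.where(np.std(Xbar, axis=1) == 0)[0]
    if const.size:
        names = [tensor.metabolite_ids[m] for m in const]
        raise ValueError(f"constant metabolite profiles (correlation undefined): {names}")
    if S < 1 or S > Xbar.shape[0]:
        raise ValueError(f"S must be in 1..{Xbar.shape[0]}")
    if S == 1:
        return np.zeros(Xbar.shape[0], dtype=int), Xbar.mean(axis=0, keepdims=True)
    Z = linkage(Xbar, method="complete", metric="correlation")
    raw = fcluster(Z, t=S, criterion="maxclust")
    # relabel by first appearance for determinism
    remap: dict[int, int] = {}
    labels = np.empty_like(raw)
    for idx, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[idx] = remap[r]
    profiles = np.vstack([Xbar[labels == c].mean(axis=0) for c in range(labels.max() + 1)])
    return labels, profiles


def profile_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two time profiles."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation undefined for a constant profile")
    return float(pearsonr(a, b)[0])


# ---------------------------------------------------------------------------
# CANDECOMP/PARAFAC by alternating least squares
# ---------------------------------------------------------------------------


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _khatri_rao(mats: list[np.ndarray]) -> np.ndarray:
    # column-wise Kronecker product, first matrix varies slowest
    out = mats[0]
    for m in mats[1:]:
        out = (out[:, None, :] * m[None, :, :]).reshape(-1, out.shape[1])
    return out


def cp_reconstruct(factors: list[np.ndarray]) -> np.ndarray:
    """Dense tensor from CP factors."""
    shape = tuple(f.shape[0] for f in factors)
    full = _khatri_rao(factors[1:]) @ factors[0].T  # (prod rest) × n0
    return np.moveaxis(full.T.reshape(shape), 0, 0)


def cp_als(tensor: ResponseTensor | np.ndarray, F: int, n_starts: int = 4,
           max_iter: int = 200, tol: float = 1e-8, seed: int = 0) -> CPModel:
    """Unconstrained 4-way CP decomposition by alternating least squares.

    Runs ``n_starts`` random initializations (seeded) and keeps the
    best fit.  The ALS objective (relative reconstruction error) is
    non-increasing across sweeps; iteration stops when its relative
    improvement drops below ``tol``.  A non-converged best run is
    returned with ``converged=False`` rather than raising.  The
    degeneracy flag is filled by the two-factor-degeneracy check at the
    default threshold.
    """
    x = tensor.values if isinstance(tensor, ResponseTensor) else np.asarray(tensor, float)
    if x.ndim != 4:
        raise ValueError("expected a 4-way tensor")
    if F < 1:
        raise ValueError("F must be >= 1")
    norm_x = np.linalg.norm(x)
    unfoldings = [_unfold(x, n) for n in range(4)]
    children = np.random.SeedSequence(seed).spawn(n_starts)

    best: tuple[float, list[np.ndarray], bool, list[float]] | None = None
    for child in children:
        rng = np.random.default_rng(child)
        factors = [rng.standard_normal((dim, F)) for dim in x.shape]
        history: list[float] = []
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            for mode in range(4):
                others = [factors[n] for n in range(4) if n != mode]
                kr = _khatri_rao(others)
                gram = np.ones((F, F))
                for f in others:
                    gram *= f.T @ f
                factors[mode] = unfoldings[mode] @ kr @ np.linalg.pinv(gram)
            err = np.linalg.norm(unfoldings[0] - factors[0] @ _khatri_rao(
                [factors[1], factors[2], factors[3]]).T) / norm_x
            history.append(float(err))
            if prev - err < tol * max(prev, 1e-30):
                converged = True
                break
            prev = err
        final = history[-1]
        if best is None or final < best[0]:
            best = (final, [f.copy() for f in factors], converged, history)

    assert best is not None
    err, factors, converged, history = best
    model = CPModel(factors[0], factors[1], factors[2], factors[3], F,
                    explained_variance=float(max(0.0, 1.0 - err ** 2)),
                    converged=converged, objective_history=np.asarray(history))
    if F >= 2:
        model.degenerate = check_two_factor_degeneracy(model)
    return model


def check_two_factor_degeneracy(model: CPModel, threshold: float = 0.85) -> bool:
    """Detect the two-factor degeneracy signature: a pair of CP
    components whose triple cosine (product of per-mode factor
    congruences) is strongly negative (< −threshold), i.e. two large
    components nearly cancelling each other."""
    if model.F < 2:
        return False
    normed = []
    for f in model.factors:
        norms = np.linalg.norm(f, axis=0)
        norms[norms == 0] = 1.0
        normed.append(f / norms)
    for a in range(model.F):
        for b in range(a + 1, model.F):
            triple = 1.0
            for f in normed:
                triple *= float(f[:, a] @ f[:, b])
            if triple < -threshold:
                return True
    return False


def cluster_cp_scores(model: CPModel, k: int, seed: int = 0, n_init: int = 50,
                      normalize: bool = False) -> np.ndarray:
    """k-means on the I × F individual-score matrix.

    ``normalize=True`` clusters score *directions* (rows scaled to unit
    norm): an individual's overall response amplitude is then treated
    as a nuisance and only the profile mix across components counts.
    """
    scores = model.individual_scores
    if k > scores.shape[0]:
        raise ValueError(f"k={k} exceeds the number of individuals {scores.shape[0]}")
    if k == 1:
        return np.zeros(scores.shape[0], dtype=int)
    if normalize:
        norms = np.linalg.norm(scores, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        scores = scores / norms
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(scores)


def cluster_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> dict:
    """Best-case agreement between two labelings under optimal label
    matching (assignment problem), as a percentage; ARI is reported
    alongside."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have the same length")
    cats_a = {v: i for i, v in enumerate(np.unique(a))}
    cats_b = {v: i for i, v in enumerate(np.unique(b))}
    conf = np.zeros((len(cats_a), len(cats_b)))
    for x, y in zip(a, b):
        conf[cats_a[x], cats_b[y]] += 1
    rows, cols = linear_sum_assignment(-conf)
    agree = conf[rows, cols].sum()
    return {"percent": float(100.0 * agree / a.size),
            "ari": float(adjusted_rand_score(a, b))}


def anova_association(labels: np.ndarray, clinical: ClinicalTable,
                      *, correct: bool = False) -> list[dict]:
    """One-way ANOVA of each clinical measure across clusters.

    Measures where any cluster has fewer than 2 non-missing values are
    skipped with a warning.  No multiplicity correction by default;
    ``correct=True`` adds Benjamini–Hochberg adjusted p-values.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != len(clinical.individual_ids):
        raise ValueError("labels length does not match the clinical table")
    results = []
    for ci, name in enumerate(clinical.measure_names):
        values = clinical.measures[:, ci]
        groups = []
        skip = False
        for lab in np.unique(labels):
            g = values[(labels == lab) & ~np.isnan(values)]
            if g.size < 2:
                skip = True
                break
            groups.append(g)
        if skip or len(groups) < 2:
            warnings.warn(f"measure {name!r} skipped: a cluster has <2 non-missing values",
                          stacklevel=2)
            continue
        F_stat, p = _one_way_anova(groups)
        results.append({"measure": name, "F": F_stat, "p": p})
    if correct and results:
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([r["p"] for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r["p_adj"] = float(q)
    return results


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ss_between == 0.0:
        return 0.0, 1.0
    if ss_within == 0.0:
        return float("inf"), 0.0
    F_stat = (ss_between / df_b) / (ss_within / df_w)
    return float(F_stat), float(f_dist.sf(F_stat, df_b, df_w))
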