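"""Prediction-performance protocol: splits, rank selection, R², resampling.

An *observation* is one (individual, diet) response.  The protocol
permutes observations, splits them 60/20/20 into train/validation/test,
fits a pooled full-state model on the training set while choosing the
SVD truncation rank V with an early-stopping rule (stop once validation
RMSE deviates more than 30% from training RMSE; keep the V with the
lowest validation RMSE seen), predicts the held-out test responses from
baseline + diet impulse alone, and scores them with a tensor-wide R²:

    R² = 1 − Σ‖vec(X̂_i) − vec(X_i)‖² / Σ‖X̄ − vec(X_i)‖²

with X̄ the grand mean of the test tensor.  The whole cycle is repeated
(default 100 resamplings without replacement) and the mean R² reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DietInputMatrix, ResponseTensor
from .dmdc import RankReducedModel, fit_dmdc, simulate_impulse, usable_rank
from .parametric import (
    MultiResponseSnapshots,
    concat_response_snapshots,
    predict_response,
    tensor_observations,
)

__all__ = [
    "ObservationSplit",
    "ExperimentReport",
    "split_observations",
    "r_squared",
    "rollout_rmse",
    "select_rank",
    "resampling_experiment",
    "diet_count_experiment",
]


@dataclass(frozen=True)
class ObservationSplit:
    """Disjoint train/validation/test lists of (individual, diet) keys."""

    train: tuple
    validation: tuple
    test: tuple
    seed: int
    fractions: tuple[float, float, float]

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(s) for s in sets)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValueError("split groups are not disjoint")


@dataclass
class ExperimentReport:
    """Per-iteration R² values, selected ranks and the headline mean."""

    r2_per_iteration: list[float] = field(default_factory=list)
    selected_ranks: list[int] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    diet_counts: list[int] | None = None
    r2_per_count: dict[int, list[float]] | None = None

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.r2_per_iteration))

    def mean_r2_by_count(self) -> dict[int, float]:
        if self.r2_per_count is None:
            raise ValueError("report has no diet-count grid")
        return {k: float(np.mean(v)) for k, v in self.r2_per_count.items()}


def split_observations(keys: list, fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                       seed: int = 0) -> ObservationSplit:
    """Randomly permute observation keys and split by the fractions.

    Sizes are floor-allocated with the remainder going to the training
    set, so 51 observations at 60/20/20 give 31/10/10.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    n = len(keys)
    rng = np.random.default_rng(seed)
    perm = [keys[j] for j in rng.permutation(n)]
    n_val = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train <= 0 or (fractions[1] > 0 and n_val == 0) or (fractions[2] > 0 and n_test == 0):
        raise ValueError(f"cannot form nonempty splits from {n} observations at {fractions}")
    return ObservationSplit(tuple(perm[:n_train]),
                            tuple(perm[n_train:n_train + n_val]),
                            tuple(perm[n_train + n_val:]),
                            seed, tuple(fractions))


def r_squared(pred: np.ndarray, data: np.ndarray) -> float:
    """Tensor-wide coefficient of determination against the grand mean.

    ``pred`` and ``data`` may be any matching shape; both are
    vectorized.  Returns ≤ 1 and can be negative; raises on a constant
    data tensor (zero total sum of squares).
    """
    pred = np.asarray(pred, dtype=float)
    data = np.asarray(data, dtype=float)
    if pred.shape != data.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {data.shape}")
    grand_mean = data.mean()
    ss_tot = float(np.sum((data - grand_mean) ** 2))
    if ss_tot == 0.0:
        raise ValueError("data tensor is constant; R² undefined")
    ss_res = float(np.sum((pred - data) ** 2))
    return 1.0 - ss_res / ss_tot


def _rollout(model: RankReducedModel, series: np.ndarray, z1: np.ndarray) -> np.ndarray:
    T = series.shape[1]
    return simulate_impulse(model.A_hat, model.B_hat, series[:, 0], z1, T)


def rollout_rmse(model: RankReducedModel,
                 observations: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """RMSE of full-trajectory rollouts (from each observation's own
    initial state and impulse) over all entries of all observations."""
    sq, n = 0.0, 0
    for series, z1 in observations:
        pred = _rollout(model, series, z1)
        sq += float(np.sum((pred - series) ** 2))
        n += series.size
    return float(np.sqrt(sq / n))


def observations_from_snapshots(ms: MultiResponseSnapshots) -> list[tuple[np.ndarray, np.ndarray]]:
    """Reassemble the (series, z1) pairs that built a concatenated
    snapshot set (each block's trajectory plus its impulse column)."""
    out = []
    for (lo, hi), imp in zip(ms.diet_boundaries, ms.impulse_columns):
        series = np.hstack([ms.X[:, lo:hi], ms.Xp[:, hi - 1:hi]])
        out.append((series, ms.Z[:, imp]))
    return out


def select_rank(
    train_snapshots: MultiResponseSnapshots,
    val_observations: list[tuple[np.ndarray, np.ndarray]],
    V_grid: list[int] | None = None,
    tol: float = 0.30,
    tie_tol: float = 0.05,
) -> tuple[RankReducedModel, int, dict]:
    """Choose the SVD truncation rank V by early stopping.

    Iterates V over an ascending grid (default 1..rank(Ω)), fitting on
    the training snapshots and scoring full rollouts on training and
    validation observations.  The scan stops at the first V whose
    validation RMSE exceeds the training RMSE by more than ``tol``
    (relative) — the overfitting signature.  Among the visited ranks
    the smallest V whose validation RMSE lies within ``tie_tol``
    (relative) of the minimum is returned: on noisy data the validation
    curve plateaus at the noise floor, and this parsimony tie-break
    avoids picking an arbitrary rank along the plateau.  ``tol=inf``
    scans the whole grid.  If the very first rank already triggers the
    rule, that model is returned with ``diagnostics['warning']`` set.
    """
    max_rank = usable_rank(train_snapshots.Omega)
    if V_grid is None:
        V_grid = list(range(1, max_rank + 1))
    if not V_grid:
        raise ValueError("empty rank grid")
    if sorted(V_grid) != list(V_grid):
        raise ValueError("rank grid must be ascending")

    train_obs = observations_from_snapshots(train_snapshots)
    visited: list[tuple[int, RankReducedModel, float, float]] = []
    stopped_early = False
    for V in V_grid:
        if V > max_rank:
            break
        model = fit_dmdc(train_snapshots, V)
        rmse_train = rollout_rmse(model, train_obs)
        rmse_val = rollout_rmse(model, val_observations)
        visited.append((V, model, rmse_train, rmse_val))
        # one-sided: the rule guards against overfitting, so only a
        # validation error *exceeding* the training error triggers it
        if rmse_train > 0 and (rmse_val - rmse_train) / rmse_train > tol:
            stopped_early = True
            break
    best_rmse = min(item[3] for item in visited)
    best = next(item for item in visited
                if item[3] <= best_rmse * (1.0 + tie_tol))
    diagnostics = {
        "visited": [(V, rt, rv) for V, _, rt, rv in visited],
        "stopped_early": stopped_early,
        "warning": stopped_early and len(visited) == 1,
        "max_rank": max_rank,
    }
    return best[1], best[0], diagnostics


def _predict_test(model: RankReducedModel, tensor: ResponseTensor,
                  diets: DietInputMatrix, keys: list[tuple[str, str]]
                  ) -> tuple[np.ndarray, np.ndarray]:
    preds, datas = [], []
    for ind, diet in keys:
        i = tensor.individual_ids.index(ind)
        d = tensor.diet_ids.index(diet)
        series = tensor.values[:, :, i, d]
        pred = predict_response(model, series[:, 0], diets.inputs[:, d], tensor.n_times)
        preds.append(pred)
        datas.append(series)
    return np.stack(preds), np.stack(datas)


def resampling_experiment(
    tensor: ResponseTensor,
    diets: DietInputMatrix,
    n_iter: int = 100,
    seed: int = 0,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    tol: float = 0.30,
    V_grid: list[int] | None = None,
) -> ExperimentReport:
    """Full resampling protocol: permute → split → rank-select → predict
    the test observations → R², repeated ``n_iter`` times.

    Predictions start from each test observation's own baseline-
    subtracted initial state (zero for fully preprocessed data) and its
    diet impulse.  Fully deterministic given (data, config, seed).
    """
    keys = [(i, d) for i in tensor.individual_ids for d in tensor.diet_ids]
    report = ExperimentReport()
    seeds = np.random.SeedSequence(seed).generate_state(n_iter) % (2 ** 31)
    for it in range(n_iter):
        it_seed = int(seeds[it])
        split = split_observations(keys, fractions, seed=it_seed)
        train_ms = concat_response_snapshots(
            tensor_observations(tensor, diets, list(split.train)))
        val_obs = tensor_observations(tensor, diets, list(split.validation))
        model, V, _ = select_rank(train_ms, val_obs, V_grid, tol)
        preds, datas = _predict_test(model, tensor, diets, list(split.test))
        report.r2_per_iteration.append(r_squared(preds, datas))
        report.selected_ranks.append(V)
        report.seeds.append(it_seed)
    return report


def diet_count_experiment(
    tensor: ResponseTensor,
    diets: DietInputMatrix,
    diet_counts: list[int],
    n_test_diets: int,
    reps: int = 5,
    seed: int = 0,
    tol: float = 0.30,
    val_fraction: float = 0.25,
    rank_policy: str = "full",
) -> ExperimentReport:
    """Sweep the number of training diets against a fixed held-out diet
    set (the scaled analogue of the increasing-diet benchmark).

    The test diets are drawn once from the available pool and held
    fixed; for each repetition the remaining diets are scrambled, the
    pooled model is fitted on the first k (all individuals × those
    diets are the observations), and R² is measured on all individuals
    × test diets.

    ``rank_policy='full'`` (default) fits at the full usable rank of
    Ω: the sweep isolates how input-space coverage grows with the diet
    count, and with thousands of snapshot columns per fit there is no
    overfitting for truncation to guard against.
    ``rank_policy='select'`` instead splits each count's diets into
    train/validation and applies the 30% early-stopping rule.
    """
    if rank_policy not in ("full", "select"):
        raise ValueError(f"unknown rank_policy {rank_policy!r}")
    D = tensor.n_diets
    if max(diet_counts) + n_test_diets > D:
        raise ValueError(
            f"need {max(diet_counts)} training + {n_test_diets} test diets, only {D} available")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(D)
    test_d = list(perm[:n_test_diets])
    pool = list(perm[n_test_diets:])
    test_keys = [(i, tensor.diet_ids[d]) for i in tensor.individual_ids for d in test_d]

    report = ExperimentReport(diet_counts=list(diet_counts),
                              r2_per_count={k: [] for k in diet_counts})
    for rep in range(reps):
        scramble = rng.permutation(len(pool))
        for k in diet_counts:
            chosen = [pool[j] for j in scramble[:k]]
            if rank_policy == "select":
                n_val = max(1, int(round(val_fraction * k))) if k >= 2 else 0
                val_d, train_d = chosen[:n_val], chosen[n_val:]
                if not train_d:
                    train_d, val_d = chosen, []
            else:
                train_d, val_d = chosen, []
            train_keys = [(i, tensor.diet_ids[d]) for i in tensor.individual_ids
                          for d in train_d]
            val_keys = [(i, tensor.diet_ids[d]) for i in tensor.individual_ids
                        for d in val_d]
            train_ms = concat_response_snapshots(
                tensor_observations(tensor, diets, train_keys))
            if rank_policy == "select":
                val_obs = tensor_observations(tensor, diets, val_keys) or \
                    observations_from_snapshots(train_ms)
                model, V, _ = select_rank(train_ms, val_obs, None, tol)
            else:
                V = usable_rank(train_ms.Omega)
                model = fit_dmdc(train_ms, V)
            preds, datas = _predict_test(model, tensor, diets, test_keys)
            report.r2_per_count[k].append(r_squared(preds, datas))
            report.selected_ranks.append(V)
    report.r2_per_iteration = [float(np.mean(v)) for v in report.r2_per_count.values()]
    report.seeds = [seed]
    return report
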