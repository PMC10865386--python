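"""Parametric DMDc: one linear model per individual from several diets.

A crossover study exposes the same individual to D diets.  Because
least squares over snapshots is blind to where columns came from, the D
impulse responses can be concatenated column-wise into joint snapshot
matrices X_{i,*}, X'_{i,*}, Ω_{i,*} and fitted as one DMDc problem,
yielding a single (Â_i, B̂_i) that explains all diets of individual i.

Two downstream variants:

* **Prediction** — pool every training observation (individual, diet)
  into one fit and keep the full state dimension (no latent
  projection); predictions for an unseen diet need only the metabolite
  baseline and the diet's input vector.
* **Metabotyping** — compute one shared orthonormal basis Ũ_tot from
  the SVD of all data X_tot and fit each individual's dynamics inside
  that common latent space, so latent state trajectories are directly
  comparable across individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import DietInputMatrix, ResponseTensor
from .dmdc import (
    LatentModel,
    RankReducedModel,
    SnapshotSet,
    build_snapshots,
    fit_dmdc,
    impulse_inputs,
    reduce_to_latent,
    simulate_impulse,
    truncated_svd,
    usable_rank,
)

__all__ = [
    "MultiResponseSnapshots",
    "SharedBasis",
    "IndividualLatentModel",
    "concat_response_snapshots",
    "fit_individual",
    "compute_shared_basis",
    "fit_shared_latent",
    "fit_pooled",
    "predict_response",
    "tensor_observations",
]


@dataclass(frozen=True)
class MultiResponseSnapshots(SnapshotSet):
    """Snapshots from D concatenated responses; block d spans columns
    [d·(T-1), (d+1)·(T-1)) and its first column carries the impulse."""

    diet_boundaries: tuple[tuple[int, int], ...] = ()
    impulse_columns: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        object.__setattr__(self, "diet_boundaries", tuple(tuple(b) for b in self.diet_boundaries))
        object.__setattr__(self, "impulse_columns", tuple(self.impulse_columns))
        widths = {b[1] - b[0] for b in self.diet_boundaries}
        if len(widths) > 1:
            raise ValueError("diet blocks must all have the same width T-1")
        for c in range(self.Z.shape[1]):
            if c not in self.impulse_columns and np.any(self.Z[:, c]):
                raise ValueError(f"non-impulse column {c} of Z is nonzero")

    @property
    def n_responses(self) -> int:
        return len(self.diet_boundaries)


@dataclass(frozen=True)
class SharedBasis:
    """Leading-S left singular vectors of X_tot (all data concatenated):
    the output map Ũ_tot shared by every individual."""

    U_tot: np.ndarray
    singular_values: np.ndarray
    S: int

    def __post_init__(self) -> None:
        if self.U_tot.shape[1] != self.S:
            raise ValueError("U_tot column count must equal S")
        if not np.allclose(self.U_tot.T @ self.U_tot, np.eye(self.S), atol=1e-10):
            raise ValueError("shared basis is not orthonormal")
        if np.any(np.diff(self.singular_values) > 1e-12):
            raise ValueError("singular values must be non-increasing")

    def project(self, series: np.ndarray) -> np.ndarray:
        return self.U_tot.T @ series


@dataclass(frozen=True)
class IndividualLatentModel:
    """Per-individual latent dynamics (Ã_i, B̃_i) with per-diet initial
    states, expressed in a shared or individual basis."""

    individual_id: str
    A_tilde: np.ndarray
    B_tilde: np.ndarray
    initial_states: dict = field(default_factory=dict)
    basis: SharedBasis | LatentModel | None = None

    @property
    def S(self) -> int:
        return self.A_tilde.shape[0]

    def trajectory(self, diet_id: str, z1: np.ndarray, T: int) -> np.ndarray:
        """Latent rollout S × T for one diet from its stored initial state."""
        x1 = self.initial_states[diet_id]
        return simulate_impulse(self.A_tilde, self.B_tilde, x1, z1, T)


def concat_response_snapshots(
    responses: list[tuple[np.ndarray, np.ndarray]],
) -> MultiResponseSnapshots:
    """Column-wise concatenation of per-response snapshot blocks.

    Each item is (M × T series, impulse vector z1); all must share M
    and T.  Block order follows input order.
    """
    if not responses:
        raise ValueError("need at least one response")
    shapes = {np.atleast_2d(np.asarray(s, dtype=float)).shape for s, _ in responses}
    if len(shapes) > 1:
        raise ValueError(f"responses disagree on (M, T): {sorted(shapes)}")
    X_blocks, Xp_blocks, Z_blocks = [], [], []
    boundaries, impulse_cols = [], []
    col = 0
    for series, z1 in responses:
        snap = build_snapshots(series, z1)
        X_blocks.append(snap.X)
        Xp_blocks.append(snap.Xp)
        Z_blocks.append(snap.Z)
        width = snap.n_snapshots
        boundaries.append((col, col + width))
        impulse_cols.append(col)
        col += width
    return MultiResponseSnapshots(
        np.hstack(X_blocks), np.hstack(Xp_blocks), np.hstack(Z_blocks),
        diet_boundaries=tuple(boundaries), impulse_columns=tuple(impulse_cols),
    )


def fit_individual(ms: MultiResponseSnapshots, V: int, S: int,
                   diet_ids: list[str] | None = None,
                   individual_id: str = "") -> IndividualLatentModel:
    """Fit one individual's latent model from concatenated diet blocks.

    Runs the full-state DMDc fit on Ω_{i,*}, then reduces to an
    S-dimensional latent system via the SVD of X'_{i,*}; per-diet
    initial states are the projections of each block's first snapshot.
    """
    model = fit_dmdc(ms, V)
    if diet_ids is None:
        diet_ids = [f"diet_{d}" for d in range(ms.n_responses)]
    firsts = {d: ms.X[:, b[0]] for d, b in zip(diet_ids, ms.diet_boundaries)}
    latent = reduce_to_latent(model, ms.Xp, S, initial_states=firsts)
    return IndividualLatentModel(individual_id, latent.A_tilde, latent.B_tilde,
                                 latent.initial_states, basis=latent)


def compute_shared_basis(tensor: ResponseTensor, S: int) -> SharedBasis:
    """SVD of X_tot ∈ R^{M × T·D·I} (all responses side by side) truncated
    to S components; the full spectrum is kept for scree analysis."""
    M = tensor.n_metabolites
    X_tot = tensor.values.reshape(M, -1)
    r = usable_rank(X_tot)
    if S > r:
        raise ValueError(f"S={S} exceeds rank(X_tot)={r}")
    U, _, _ = truncated_svd(X_tot, S)
    spectrum = np.linalg.svd(X_tot, compute_uv=False)
    return SharedBasis(U, spectrum, S)


def fit_shared_latent(
    tensor: ResponseTensor,
    diets: DietInputMatrix,
    basis: SharedBasis,
    V: int | None = None,
) -> list[IndividualLatentModel]:
    """Fit every individual's dynamics inside the shared latent space.

    Each individual's concatenated snapshots are projected through
    Ũ_tot first, and DMDc runs wholly on the S-dimensional states, so
    the resulting latent trajectories are comparable across
    individuals.  ``V`` defaults to the numerical rank of each
    individual's projected Ω̃_{i,*}.
    """
    diets.check_matches(tensor)
    models = []
    for i, ind in enumerate(tensor.individual_ids):
        responses = [(basis.project(tensor.values[:, :, i, d]), diets.inputs[:, d])
                     for d in range(tensor.n_diets)]
        ms = concat_response_snapshots(responses)
        rank = usable_rank(ms.Omega)
        Vi = rank if V is None else V
        if Vi > rank:
            raise ValueError(
                f"individual {ind!r}: requested V={Vi} exceeds usable rank {rank}")
        fitted = fit_dmdc(ms, Vi)
        init = {d_id: ms.X[:, b[0]]
                for d_id, b in zip(tensor.diet_ids, ms.diet_boundaries)}
        models.append(IndividualLatentModel(ind, fitted.A_hat, fitted.B_hat,
                                            init, basis=basis))
    return models


def fit_pooled(observations: list[tuple[np.ndarray, np.ndarray]], V: int) -> RankReducedModel:
    """One full-state model from all training observations pooled.

    Each observation is an (M × T series, z1) pair — one individual's
    response to one diet.  Mechanically identical to the per-individual
    concatenated fit, but across individuals, and the state is kept at
    full dimension for prediction accuracy.
    """
    ms = concat_response_snapshots(observations)
    return fit_dmdc(ms, V)


def predict_response(model: RankReducedModel, baseline_state: np.ndarray,
                     z1: np.ndarray, T: int) -> np.ndarray:
    """Predict an M × T response to diet impulse z1.

    In baseline-subtracted coordinates the initial state is
    ``baseline_state`` minus itself, i.e. the zero vector, so the whole
    prediction is driven by B̂z₁ — this is what lets the method predict
    from only the baseline and the diet composition.  Pass the
    baseline-subtracted initial state directly (zeros for fully
    preprocessed data).
    """
    x1 = np.zeros(model.n_states) if baseline_state is None else \
        np.asarray(baseline_state, dtype=float)
    return simulate_impulse(model.A_hat, model.B_hat, x1, z1, T)


def tensor_observations(
    tensor: ResponseTensor, diets: DietInputMatrix,
    keys: list[tuple[str, str]] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Extract (series, z1) observation pairs for the given
    (individual, diet) keys (default: all I × D observations)."""
    diets.check_matches(tensor)
    if keys is None:
        keys = [(i, d) for i in tensor.individual_ids for d in tensor.diet_ids]
    out = []
    for ind, diet in keys:
        i = tensor.individual_ids.index(ind)
        d = tensor.diet_ids.index(diet)
        out.append((tensor.values[:, :, i, d], diets.inputs[:, d]))
    return out
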