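"""Dynamic mode decomposition with control (DMDc) for a single response.

Given one trajectory x_1..x_T of M metabolites responding to a dietary
impulse z_1, DMDc identifies the discrete linear dynamical system

    x_{t+1} = A x_t + B z_t

by least squares: stack past snapshots X, future snapshots X' and the
input snapshots Z, write X' = [A B] [X; Z] = G Ω, and solve for G with
the Moore–Penrose pseudoinverse through a (possibly truncated) SVD of
Ω.  Truncating the SVD at rank V regularizes the fit; the operators Â,
B̂ keep the full state dimension.  A further reduction maps the state
onto the leading-S left singular vectors Ũ of X', giving the latent
system (Ã, B̃) with output map x̂ = Ũ x̃.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SnapshotSet",
    "RankReducedModel",
    "LatentModel",
    "build_snapshots",
    "truncated_svd",
    "usable_rank",
    "fit_dmdc",
    "reduce_to_latent",
    "simulate",
    "simulate_impulse",
    "impulse_inputs",
]


@dataclass(frozen=True)
class SnapshotSet:
    """Snapshot matrices for one or more concatenated responses.

    X holds states 1..T-1 column-wise, Xp states 2..T, Z the inputs
    aligned with X's columns (z_t drives the transition x_t → x_{t+1});
    Omega is the vertical stack [X; Z].
    """

    X: np.ndarray
    Xp: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        Xp = np.atleast_2d(np.asarray(self.Xp, dtype=float))
        Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Xp", Xp)
        object.__setattr__(self, "Z", Z)
        if not (X.shape[1] == Xp.shape[1] == Z.shape[1]):
            raise ValueError("X, Xp and Z must share the column (snapshot) count")
        if X.shape[0] != Xp.shape[0]:
            raise ValueError("X and Xp must share the state dimension")

    @property
    def n_states(self) -> int:
        return self.X.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.Z.shape[0]

    @property
    def n_snapshots(self) -> int:
        return self.X.shape[1]

    @property
    def Omega(self) -> np.ndarray:
        return np.vstack([self.X, self.Z])


@dataclass(frozen=True)
class RankReducedModel:
    """Full-state operator pair (Â, B̂) fitted at SVD truncation rank V."""

    A_hat: np.ndarray
    B_hat: np.ndarray
    rank_V: int
    sv_omega: np.ndarray
    fit_residual: float

    @property
    def n_states(self) -> int:
        return self.A_hat.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B_hat.shape[1]


@dataclass(frozen=True)
class LatentModel:
    """Reduced S-dimensional system with orthonormal output map U_map."""

    A_tilde: np.ndarray
    B_tilde: np.ndarray
    U_map: np.ndarray
    S: int
    initial_states: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        gram = self.U_map.T @ self.U_map
        if not np.allclose(gram, np.eye(self.S), atol=1e-10):
            raise ValueError("U_map columns are not orthonormal")

    def lift(self, latent_traj: np.ndarray) -> np.ndarray:
        """Map latent trajectories back to observed coordinates x̂ = Ũ x̃."""
        return self.U_map @ latent_traj


def impulse_inputs(z1: np.ndarray, n_cols: int) -> np.ndarray:
    """Input snapshot matrix for an impulse: z1 in column 0, zeros after.

    A meal is modeled as a one-time perturbation at the first
    transition; the system then relaxes autonomously.
    """
    z1 = np.atleast_1d(np.asarray(z1, dtype=float))
    Z = np.zeros((z1.shape[0], n_cols))
    Z[:, 0] = z1
    return Z


def build_snapshots(series: np.ndarray, z1: np.ndarray) -> SnapshotSet:
    """Snapshot matrices for a single M × T response to impulse z1."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] < 2:
        raise ValueError("need at least T=2 time points to form snapshots")
    X = series[:, :-1]
    Xp = series[:, 1:]
    Z = impulse_inputs(z1, X.shape[1])
    return SnapshotSet(X, Xp, Z)


def _deterministic_signs(U: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # make the largest-magnitude entry of each left singular vector
    # positive so factorizations reproduce across runs/platforms
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, W * signs


def truncated_svd(matrix: np.ndarray, V: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leading-V SVD factors (U_hat, s_hat, W_hat) with a deterministic
    sign convention; U_hat s_hat W_hatᵀ is the best rank-V approximation."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if not 1 <= V <= min(matrix.shape):
        raise ValueError(f"truncation rank V={V} outside 1..min{matrix.shape}")
    U, s, Wt = np.linalg.svd(matrix, full_matrices=False)
    U, W = _deterministic_signs(U[:, :V], Wt.T[:, :V])
    return U, s[:V], W


def usable_rank(matrix: np.ndarray, *, rtol: float | None = None) -> int:
    """Numerical rank: singular values below max(dims)·eps·σ₁ (or a
    caller-supplied relative tolerance) count as zero."""
    s = np.linalg.svd(np.atleast_2d(matrix), compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    if rtol is None:
        rtol = max(matrix.shape) * np.finfo(float).eps
    return int(np.sum(s > rtol * s[0]))


def fit_dmdc(snapshots: SnapshotSet, V: int) -> RankReducedModel:
    """Fit (Â, B̂) by truncated-SVD least squares on X' = G Ω.

    With V equal to the numerical rank of Ω this is the minimum-
    Frobenius-norm least-squares solution; smaller V regularizes.
    Raises if V exceeds the numerical rank (Σ̂⁻¹ would blow up).
    """
    Omega = snapshots.Omega
    U, s, Wt = np.linalg.svd(Omega, full_matrices=False)
    rtol = max(Omega.shape) * np.finfo(float).eps
    r = int(np.sum(s > rtol * s[0])) if s.size and s[0] > 0 else 0
    if V > r:
        raise ValueError(f"rank too high for data: requested V={V}, usable rank is {r}")
    U_hat, W_hat = _deterministic_signs(U[:, :V], Wt.T[:, :V])
    s_hat = s[:V]
    M = snapshots.n_states
    G = (snapshots.Xp @ W_hat) * (1.0 / s_hat) @ U_hat.T
    A_hat, B_hat = G[:, :M], G[:, M:]
    residual = float(np.linalg.norm(snapshots.Xp - A_hat @ snapshots.X - B_hat @ snapshots.Z))
    return RankReducedModel(A_hat, B_hat, V, s_hat.copy(), residual)


def reduce_to_latent(model: RankReducedModel, Xp: np.ndarray, S: int,
                     initial_states: dict | None = None) -> LatentModel:
    """Project a full-state model onto the leading-S left singular
    vectors Ũ of X', giving Ã = ŨᵀÂŨ, B̃ = ŨᵀB̂ and output map Ũ.

    Optional ``initial_states`` maps a condition key to a full-state
    initial vector x₁; each is projected to x̃₁ = Ũᵀx₁.
    """
    Xp = np.atleast_2d(np.asarray(Xp, dtype=float))
    r = usable_rank(Xp)
    if S > r:
        raise ValueError(f"latent dimension S={S} exceeds rank(X')={r}")
    U_map, _, _ = truncated_svd(Xp, S)
    A_tilde = U_map.T @ model.A_hat @ U_map
    B_tilde = U_map.T @ model.B_hat
    init = {}
    if initial_states:
        init = {k: U_map.T @ np.asarray(v, dtype=float) for k, v in initial_states.items()}
    return LatentModel(A_tilde, B_tilde, U_map, S, init)


def simulate(A: np.ndarray, B: np.ndarray, x1: np.ndarray, inputs: np.ndarray,
             T: int) -> np.ndarray:
    """Roll the LDS x_{t+1} = A x_t + B z_t forward for T time points.

    ``inputs`` has one column per transition (l × (T-1)); returns the
    state trajectory as an M × T matrix with x1 in the first column.
    Works identically for full and latent systems.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
    M = A.shape[0]
    if A.shape != (M, M):
        raise ValueError("A must be square")
    if B.shape[0] != M or x1.shape[0] != M:
        raise ValueError("B rows and x1 length must match A")
    if inputs.shape != (B.shape[1], T - 1):
        raise ValueError(
            f"inputs must be {B.shape[1]} x {T - 1}, got {inputs.shape}")
    traj = np.empty((M, T))
    traj[:, 0] = x1
    for t in range(T - 1):
        traj[:, t + 1] = A @ traj[:, t] + B @ inputs[:, t]
    return traj


def simulate_impulse(A: np.ndarray, B: np.ndarray, x1: np.ndarray, z1: np.ndarray,
                     T: int) -> np.ndarray:
    """Convenience: simulate under an impulse input (z1 at the first
    transition, zero afterwards)."""
    return simulate(A, B, x1, impulse_inputs(z1, T - 1), T)
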