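"""Weighted graph-regularized matrix factorization (WGRMF).

The drug response matrix R ∈ R^{n×m} (n drugs, m cell lines, many entries
unobserved) is approximated by a low-rank product A Bᵀ with A ∈ R^{n×k},
B ∈ R^{m×k}.  The objective combines a masked squared loss, Tikhonov
regularization and graph regularization through normalized Laplacians of
sparsified drug and cell-line similarity matrices:

    min_{A,B}  ‖W ⊙ (R − ABᵀ)‖²_F + λ_l (‖A‖²_F + ‖B‖²_F)
               + λ_d Tr(Aᵀ L̃_d A) + λ_c Tr(Bᵀ L̃_c B)

where W is the binary observation mask.  The minimization alternates
row-wise updates solving the stationarity condition ∂L/∂a_i = 0 exactly:

    a_i [Σ_j W(i,j) b_jᵀ b_j + (λ_l + λ_d L̃_d(i,i)) I_k]
        = Σ_j W(i,j) R(i,j) b_j − λ_d Σ_{r≠i} L̃_d(i,r) a_r

(and symmetrically for b_j), applied Gauss–Seidel style: within one sweep a
row update sees the already-updated rows before it.  Keeping the diagonal
Laplacian term on the left makes every row update the exact minimizer of
the objective in that row, so the sweep is a block coordinate descent with
a guaranteed non-increasing objective; the variant that leaves
λ_d L̃_d(i,i) a_i on the right with the row's previous value has the same
fixed points but can oscillate or diverge when a row has few observations.

Predictions for all pairs, observed or not, are R̂ = A Bᵀ.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .graph import build_pnn_graph, laplacians, sparsify
from .similarity import SimilarityMatrix, ValidationError

__all__ = [
    "ResponseMatrix",
    "HyperParams",
    "LatentFactors",
    "objective",
    "initialize",
    "update_sweep",
    "fit",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class ResponseMatrix:
    """Observed drug × cell-line responses with a binary observation mask.

    ``R[i, j]`` is meaningful only where ``W[i, j] == 1``; masked-out
    positions are ignored by every computation.
    """

    drug_ids: list[str]
    cell_ids: list[str]
    R: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.R = np.asarray(self.R, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        n, m = len(self.drug_ids), len(self.cell_ids)
        if len(set(self.drug_ids)) != n or len(set(self.cell_ids)) != m:
            raise ValidationError("drug_ids and cell_ids must be unique")
        if self.R.shape != (n, m) or self.W.shape != (n, m):
            raise ValidationError(
                f"R/W shape must be ({n}, {m}); got {self.R.shape} and {self.W.shape}"
            )
        if not np.isin(self.W, (0.0, 1.0)).all():
            raise ValidationError("mask W must contain only 0/1")
        if np.isnan(self.R[self.W == 1]).any():
            raise ValidationError("observed entries of R must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.R.shape

    def n_observed(self) -> int:
        return int(self.W.sum())

    def masked_copy(self, holdout: np.ndarray) -> "ResponseMatrix":
        """Copy with the given (row, col) index pairs removed from the mask."""
        W = self.W.copy()
        W[holdout[:, 0], holdout[:, 1]] = 0.0
        return ResponseMatrix(self.drug_ids, self.cell_ids, self.R, W)


@dataclass
class HyperParams:
    """Solver hyperparameters.

    k
        Latent dimension of both factor matrices.
    lambda_l
        Tikhonov weight on ‖A‖²_F + ‖B‖²_F; must be > 0 for rows or
        columns with no observations to stay well-posed.
    lambda_d, lambda_c
        Weights of the drug-graph and cell-line-graph penalties.
    p_drug, p_cell
        Neighbor counts for the p-NN sparsification of each similarity.
    max_sweeps, tol
        One sweep updates all rows of A then all rows of B; iteration stops
        when the relative objective change drops below ``tol``.
    clip_negative_similarity
        Clip negative similarity values at 0 before graph construction
        (default); disable to use signed degrees as literally defined.
    """

    k: int = 10
    lambda_l: float = 0.5
    lambda_d: float = 0.125
    lambda_c: float = 0.125
    p_drug: int = 20
    p_cell: int = 20
    max_sweeps: int = 200
    tol: float = 1e-5
    seed: int = 0
    init: Literal["svd", "random"] = "svd"
    clip_negative_similarity: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if min(self.lambda_l, self.lambda_d, self.lambda_c) < 0:
            raise ValidationError("regularization weights must be >= 0")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.max_sweeps < 1:
            raise ValidationError("max_sweeps must be >= 1")


@dataclass
class LatentFactors:
    """Factor pair (A: drugs × k, B: cell lines × k) plus fit diagnostics."""

    A: np.ndarray
    B: np.ndarray
    drug_ids: list[str]
    cell_ids: list[str]
    objective_trajectory: list[float] = field(default_factory=list)
    converged: bool = False
    sweeps_run: int = 0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.ndim != 2 or self.B.ndim != 2 or self.A.shape[1] != self.B.shape[1]:
            raise ValidationError("A and B must be 2-D with a common latent dimension")

    @property
    def k(self) -> int:
        return self.A.shape[1]


def objective(
    rm: ResponseMatrix,
    lf: LatentFactors,
    Ld_tilde: np.ndarray,
    Lc_tilde: np.ndarray,
    hp: HyperParams,
) -> float:
    """Value of the regularized masked factorization objective."""
    A, B = lf.A, lf.B
    n, m = rm.shape
    if A.shape[0] != n or B.shape[0] != m:
        raise ValidationError("factor shapes do not match the response matrix")
    if Ld_tilde.shape != (n, n) or Lc_tilde.shape != (m, m):
        raise ValidationError("Laplacian shapes do not match the response matrix")
    resid = rm.W * (rm.R - A @ B.T)
    # nan*0 at masked positions must not poison the residual
    resid = np.where(rm.W == 1, resid, 0.0)
    val = float(np.sum(resid**2))
    val += hp.lambda_l * (float(np.sum(A**2)) + float(np.sum(B**2)))
    val += hp.lambda_d * float(np.trace(A.T @ Ld_tilde @ A))
    val += hp.lambda_c * float(np.trace(B.T @ Lc_tilde @ B))
    return val


def initialize(rm: ResponseMatrix, k: int, seed: int = 0,
               strategy: Literal["svd", "random"] = "svd") -> LatentFactors:
    """Deterministic starting factors.

    The default strategy mean-imputes the unobserved entries, takes the
    rank-k truncated SVD UΣVᵀ and splits the singular values symmetrically:
    A = U_k Σ_k^{1/2}, B = V_k Σ_k^{1/2}.  A Gaussian fallback with scale
    1/√k is available for degenerate inputs.
    """
    n, m = rm.shape
    if k > min(n, m):
        raise ValidationError(f"k={k} exceeds min(n, m)={min(n, m)}")
    if strategy == "random":
        rng = np.random.default_rng(seed)
        A = rng.normal(scale=1.0 / np.sqrt(k), size=(n, k))
        B = rng.normal(scale=1.0 / np.sqrt(k), size=(m, k))
        return LatentFactors(A, B, rm.drug_ids, rm.cell_ids)
    if rm.n_observed() == 0:
        raise ValidationError("SVD initialization needs at least one observed entry")
    mean = float(rm.R[rm.W == 1].mean())
    filled = np.where(rm.W == 1, rm.R, mean)
    U, s, Vt = np.linalg.svd(filled, full_matrices=False)
    # fix each singular-vector sign so the factorization is reproducible
    for j in range(min(k, len(s))):
        pivot = np.argmax(np.abs(U[:, j]))
        if U[pivot, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j, :] = -Vt[j, :]
    root = np.sqrt(s[:k])
    A = U[:, :k] * root
    B = Vt[:k, :].T * root
    return LatentFactors(A, B, rm.drug_ids, rm.cell_ids)


def _solve_row(gram: np.ndarray, rhs: np.ndarray, ridge: float) -> np.ndarray:
    k = gram.shape[0]
    M = gram + ridge * np.eye(k)
    try:
        return np.linalg.solve(M, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValidationError(
            "singular row system: too few observations and lambda_l == 0; "
            "set lambda_l > 0"
        ) from exc


def update_sweep(
    rm: ResponseMatrix,
    lf: LatentFactors,
    Ld_tilde: np.ndarray,
    Lc_tilde: np.ndarray,
    hp: HyperParams,
    order: Literal["gauss-seidel", "jacobi"] = "gauss-seidel",
) -> LatentFactors:
    """One full alternating sweep: every row of A, then every row of B.

    Each row update solves its k×k stationarity system exactly (solved,
    never inverted), with the diagonal Laplacian term folded into the
    left-hand side so the update is an exact per-row minimization.  In
    Gauss–Seidel mode the off-diagonal graph term sees rows already updated
    in this sweep; Jacobi mode evaluates all graph terms at the sweep's
    starting factors.
    """
    n, m = rm.shape
    A = lf.A.copy()
    B = lf.B.copy()
    R = np.where(rm.W == 1, rm.R, 0.0)
    W = rm.W

    A_ref = A if order == "gauss-seidel" else A.copy()
    for i in range(n):
        w = W[i]
        Bw = B * w[:, None]
        gram = Bw.T @ B
        rhs = (w * R[i]) @ B - hp.lambda_d * (
            Ld_tilde[i] @ A_ref - Ld_tilde[i, i] * A_ref[i]
        )
        A[i] = _solve_row(gram, rhs, hp.lambda_l + hp.lambda_d * Ld_tilde[i, i])

    B_ref = B if order == "gauss-seidel" else B.copy()
    for j in range(m):
        w = W[:, j]
        Aw = A * w[:, None]
        gram = Aw.T @ A
        rhs = (w * R[:, j]) @ A - hp.lambda_c * (
            Lc_tilde[j] @ B_ref - Lc_tilde[j, j] * B_ref[j]
        )
        B[j] = _solve_row(gram, rhs, hp.lambda_l + hp.lambda_c * Lc_tilde[j, j])

    return LatentFactors(
        A, B, lf.drug_ids, lf.cell_ids,
        objective_trajectory=list(lf.objective_trajectory),
        converged=lf.converged, sweeps_run=lf.sweeps_run,
    )


def fit(
    rm: ResponseMatrix,
    Sd: SimilarityMatrix,
    Sc: SimilarityMatrix,
    hp: HyperParams,
) -> LatentFactors:
    """Full pipeline: p-NN graphs → sparsified similarities → normalized
    Laplacians → initialization → alternating sweeps until the relative
    objective change falls below ``hp.tol`` or ``hp.max_sweeps`` is reached.
    """
    n, m = rm.shape
    if Sd.n != n:
        raise ValidationError(f"drug similarity is {Sd.n}×{Sd.n}, expected {n}×{n}")
    if Sc.n != m:
        raise ValidationError(f"cell similarity is {Sc.n}×{Sc.n}, expected {m}×{m}")

    Sd_arr, Sc_arr = Sd.S, Sc.S
    if hp.clip_negative_similarity:
        Sd_arr = np.clip(Sd_arr, 0.0, None)
        Sc_arr = np.clip(Sc_arr, 0.0, None)

    Nd = build_pnn_graph(Sd_arr, hp.p_drug)
    Nc = build_pnn_graph(Sc_arr, hp.p_cell)
    Ld = laplacians(sparsify(Sd_arr, Nd))
    Lc = laplacians(sparsify(Sc_arr, Nc))

    lf = initialize(rm, hp.k, seed=hp.seed, strategy=hp.init)
    traj = [objective(rm, lf, Ld.L_tilde, Lc.L_tilde, hp)]
    converged = False
    sweeps = 0
    for sweeps in range(1, hp.max_sweeps + 1):
        lf = update_sweep(rm, lf, Ld.L_tilde, Lc.L_tilde, hp)
        val = objective(rm, lf, Ld.L_tilde, Lc.L_tilde, hp)
        prev = traj[-1]
        traj.append(val)
        if val > prev * (1 + 1e-12):
            warnings.warn(
                f"objective increased at sweep {sweeps}: {prev:.6g} -> {val:.6g}",
                RuntimeWarning,
                stacklevel=2,
            )
        denom = max(abs(prev), 1e-300)
        if abs(prev - val) / denom < hp.tol:
            converged = True
            break

    lf.objective_trajectory = traj
    lf.converged = converged
    lf.sweeps_run = sweeps
    return lf


def predict(lf: LatentFactors):
    """Predicted response matrix R̂ = A Bᵀ as a labeled DataFrame."""
    import pandas as pd

    return pd.DataFrame(lf.A @ lf.B.T, index=lf.drug_ids, columns=lf.cell_ids)


def save_model(lf: LatentFactors, hp: HyperParams, path: str | Path) -> None:
    """Serialize factors, identifiers and hyperparameters to one JSON file."""
    payload = {
        "format": "wgrmf-model-v1",
        "drug_ids": lf.drug_ids,
        "cell_ids": lf.cell_ids,
        "A": lf.A.tolist(),
        "B": lf.B.tolist(),
        "objective_trajectory": [float(v) for v in lf.objective_trajectory],
        "converged": bool(lf.converged),
        "sweeps_run": int(lf.sweeps_run),
        "hyperparams": asdict(hp),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[LatentFactors, HyperParams]:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "wgrmf-model-v1":
        raise ValidationError(f"{path} is not a recognized model file")
    lf = LatentFactors(
        A=np.array(payload["A"], dtype=float),
        B=np.array(payload["B"], dtype=float),
        drug_ids=list(payload["drug_ids"]),
        cell_ids=list(payload["cell_ids"]),
        objective_trajectory=list(payload["objective_trajectory"]),
        converged=bool(payload["converged"]),
        sweeps_run=int(payload["sweeps_run"]),
    )
    hp = HyperParams(**payload["hyperparams"])
    return lf, hp
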