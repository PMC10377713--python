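"""Projection dictionary pair learning (PDPL).

Per class k a synthesis block D_k (p x m, atom norms <= 1) and an analysis
block P_k (m x p) are learned jointly by alternating minimization of

    sum_k ||F_k - D_k A_k||_F^2 + tau ||P_k F_k - A_k||_F^2
                                + lam ||P_k Fbar_k||_F^2,

where Fbar_k collects the samples of every other class.  The code update
and the analysis update are closed-form least squares; the norm-constrained
synthesis update runs a small ADMM.  Classification assigns a query to the
class with minimum reconstruction residual ||f - D_k P_k f||^2.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

MODEL_FORMAT_VERSION = 1


@dataclass
class TrainingSet:
    """Class-grouped training samples: F_blocks[k] is p x n_k."""

    F_blocks: list[np.ndarray]

    def __post_init__(self) -> None:
        self.F_blocks = [np.asarray(F, dtype=float) for F in self.F_blocks]
        if not self.F_blocks:
            raise ValueError("TrainingSet needs at least one class block")
        p = self.F_blocks[0].shape[0]
        for k, F in enumerate(self.F_blocks):
            if F.ndim != 2 or F.shape[0] != p:
                raise ValueError(f"class block {k + 1} has wrong shape {F.shape}")
            if F.shape[1] < 1:
                raise ValueError(f"class block {k + 1} is empty")

    @property
    def K(self) -> int:
        return len(self.F_blocks)

    @property
    def p(self) -> int:
        return self.F_blocks[0].shape[0]

    def complement(self, k: int) -> np.ndarray:
        """All samples not belonging to class k (0-based), as one p x n matrix."""
        others = [F for i, F in enumerate(self.F_blocks) if i != k]
        return np.hstack(others) if others else np.empty((self.p, 0))


@dataclass
class AdmmConfig:
    rho: float = 1.0
    rho_adapt: bool = True
    factor: float = 2.0
    inner_tol: float = 1e-4
    max_inner: int = 100

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("ADMM penalty rho must be positive")


@dataclass
class PDPLParams:
    """The four tuned hyperparameters plus solver settings.

    Defaults follow the reference configuration: m=32, tau=0.03, lam=0.003,
    gam=0.0001; outer alternation stops when the energy change drops below
    0.01 or after max_outer rounds.
    """

    m: int = 32
    tau: float = 0.03
    lam: float = 0.003
    gam: float = 0.0001
    outer_tol: float = 0.01
    max_outer: int = 50
    admm: AdmmConfig = field(default_factory=AdmmConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.tau < 0 or self.lam < 0:
            raise ValueError("tau and lam must be nonnegative")
        if self.gam <= 0:
            raise ValueError("gam must be positive")
        if self.outer_tol <= 0:
            raise ValueError("outer_tol must be positive")


@dataclass
class DictionaryPair:
    D_blocks: list[np.ndarray]  # each p x m
    P_blocks: list[np.ndarray]  # each m x p


@dataclass
class TrainedModel:
    pair: DictionaryPair
    params: PDPLParams
    energy_trace: list[float]
    converged: bool

    @property
    def K(self) -> int:
        return len(self.pair.D_blocks)

    @property
    def p(self) -> int:
        return self.pair.D_blocks[0].shape[0]


def init_dictionaries(p: int, m: int, K: int, seed: int) -> DictionaryPair:
    """Random synthesis/analysis blocks, each rescaled to unit Frobenius norm."""
    if min(p, m, K) < 1:
        raise ValueError("p, m and K must all be >= 1")
    rng = np.random.default_rng(seed)
    D_blocks, P_blocks = [], []
    for _ in range(K):
        D = rng.standard_normal((p, m))
        P = rng.standard_normal((m, p))
        D_blocks.append(D / np.linalg.norm(D))
        P_blocks.append(P / np.linalg.norm(P))
    return DictionaryPair(D_blocks, P_blocks)


def update_codes(
    F: TrainingSet, D_blocks: list[np.ndarray], P_blocks: list[np.ndarray], tau: float
) -> list[np.ndarray]:
    """Closed-form code update: A_k = (D_k'D_k + tau I)^-1 (tau P_k F_k + D_k' F_k)."""
    A_blocks = []
    for k, Fk in enumerate(F.F_blocks):
        Dk, Pk = D_blocks[k], P_blocks[k]
        m = Dk.shape[1]
        G = Dk.T @ Dk + tau * np.eye(m)
        rhs = tau * (Pk @ Fk) + Dk.T @ Fk
        try:
            A_blocks.append(np.linalg.solve(G, rhs))
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular code system for class {k + 1}; use tau > 0 to "
                "regularize a rank-deficient dictionary"
            ) from exc
    return A_blocks


def update_analysis(
    F: TrainingSet, A_blocks: list[np.ndarray], tau: float, lam: float, gam: float
) -> list[np.ndarray]:
    """Closed-form analysis update:

    P_k = tau A_k F_k' (tau F_k F_k' + lam Fbar_k Fbar_k' + gam I)^-1.
    """
    P_blocks = []
    p = F.p
    for k, Fk in enumerate(F.F_blocks):
        Fbar = F.complement(k)
        M = tau * (Fk @ Fk.T) + lam * (Fbar @ Fbar.T) + gam * np.eye(p)
        rhs = tau * (A_blocks[k] @ Fk.T)
        # P_k M = rhs  =>  M' P_k' = rhs'; M is symmetric positive definite.
        P_blocks.append(np.linalg.solve(M, rhs.T).T)
    return P_blocks


def _project_columns(M: np.ndarray) -> np.ndarray:
    """Project each column onto the unit Euclidean ball."""
    norms = np.linalg.norm(M, axis=0)
    return M / np.maximum(norms, 1.0)


def update_synthesis(
    F: TrainingSet,
    A_blocks: list[np.ndarray],
    D_init: list[np.ndarray],
    cfg: AdmmConfig,
) -> list[np.ndarray]:
    """ADMM solve of min_D sum_k ||F_k - D_k A_k||_F^2 s.t. atom norms <= 1.

    Per class: ridge solve for D, column-wise unit-ball projection of D + T
    for the copy S, dual ascent on T, with optional residual-balancing of the
    penalty rho.  Returns the feasible iterates S_k.
    """
    out = []
    for k, Fk in enumerate(F.F_blocks):
        Ak = A_blocks[k]
        m = Ak.shape[0]
        D = D_init[k].copy()
        S = _project_columns(D)
        T = np.zeros_like(D)
        rho = cfg.rho
        FA = Fk @ Ak.T
        AA = Ak @ Ak.T
        for _ in range(cfg.max_inner):
            D = np.linalg.solve(AA + rho * np.eye(m), (FA + rho * (S - T)).T).T
            S_prev = S
            S = _project_columns(D + T)
            T = T + D - S
            if not (np.isfinite(D).all() and np.isfinite(S).all()):
                raise FloatingPointError(
                    f"non-finite values in ADMM update for class {k + 1}"
                )
            primal = np.linalg.norm(D - S)
            dual = rho * np.linalg.norm(S - S_prev)
            scale = max(np.linalg.norm(D), 1e-12)
            if primal / scale < cfg.inner_tol and dual / scale < cfg.inner_tol:
                break
            if cfg.rho_adapt:
                if primal > 10 * dual:
                    rho *= cfg.factor
                    T = T / cfg.factor
                elif dual > 10 * primal:
                    rho /= cfg.factor
                    T = T * cfg.factor
        out.append(S)
    return out


def objective(
    F: TrainingSet,
    D_blocks: list[np.ndarray],
    P_blocks: list[np.ndarray],
    A_blocks: list[np.ndarray],
    tau: float,
    lam: float,
) -> float:
    total = 0.0
    for k, Fk in enumerate(F.F_blocks):
        Dk, Pk, Ak = D_blocks[k], P_blocks[k], A_blocks[k]
        total += np.linalg.norm(Fk - Dk @ Ak) ** 2
        total += tau * np.linalg.norm(Pk @ Fk - Ak) ** 2
        total += lam * np.linalg.norm(Pk @ F.complement(k)) ** 2
    return float(total)


def train(F: TrainingSet, params: PDPLParams) -> TrainedModel:
    """Alternate code / analysis / synthesis updates until the energy change
    falls below ``outer_tol`` or ``max_outer`` rounds elapse."""
    pair = init_dictionaries(F.p, params.m, F.K, params.seed)
    D, P = pair.D_blocks, pair.P_blocks
    trace: list[float] = []
    converged = False
    for _ in range(params.max_outer):
        A = update_codes(F, D, P, params.tau)
        P = update_analysis(F, A, params.tau, params.lam, params.gam)
        D = update_synthesis(F, A, D, params.admm)
        energy = objective(F, D, P, A, params.tau, params.lam)
        trace.append(energy)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < params.outer_tol:
            converged = True
            break
    return TrainedModel(DictionaryPair(D, P), params, trace, converged)


def classify(model: TrainedModel, f_t: np.ndarray) -> tuple[int, np.ndarray]:
    """Minimum-residual classification of a single sample.

    Returns the 1-based class label and the per-class squared residuals
    ||f - D_k P_k f||^2.  Ties resolve to the smallest class index.
    """
    f_t = np.asarray(f_t, dtype=float).ravel()
    if f_t.size != model.p:
        raise ValueError(f"sample has dimension {f_t.size}, model expects {model.p}")
    residuals = np.array(
        [
            np.linalg.norm(f_t - D @ (P @ f_t)) ** 2
            for D, P in zip(model.pair.D_blocks, model.pair.P_blocks)
        ]
    )
    return int(np.argmin(residuals)) + 1, residuals


def predict_batch(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Column-wise classify; returns one 1-based label per column."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != model.p:
        raise ValueError(f"expected a {model.p} x n matrix, got shape {X.shape}")
    if X.shape[1] == 0:
        return np.empty(0, dtype=int)
    # Residuals for all columns at once, one class at a time.
    res = np.empty((model.K, X.shape[1]))
    for k, (D, P) in enumerate(zip(model.pair.D_blocks, model.pair.P_blocks)):
        R = X - D @ (P @ X)
        res[k] = np.einsum("ij,ij->j", R, R)
    return np.argmin(res, axis=0) + 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize a trained model to a JSON archive."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "D_blocks": [D.tolist() for D in model.pair.D_blocks],
        "P_blocks": [P.tolist() for P in model.pair.P_blocks],
        "params": {**asdict(model.params), "admm": asdict(model.params.admm)},
        "energy_trace": model.energy_trace,
        "converged": model.converged,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    D_blocks = [np.asarray(D, dtype=float) for D in payload["D_blocks"]]
    P_blocks = [np.asarray(P, dtype=float) for P in payload["P_blocks"]]
    for k, D in enumerate(D_blocks):
        norms2 = (np.linalg.norm(D, axis=0) ** 2).max()
        if norms2 > 1 + 1e-9:
            warnings.warn(
                f"class {k + 1}: synthesis atom norm^2 {norms2:.3g} exceeds 1",
                stacklevel=2,
            )
    pd = payload["params"]
    params = PDPLParams(
        m=pd["m"], tau=pd["tau"], lam=pd["lam"], gam=pd["gam"],
        outer_tol=pd["outer_tol"], max_outer=pd["max_outer"],
        admm=AdmmConfig(**pd["admm"]), seed=pd["seed"],
    )
    return TrainedModel(
        DictionaryPair(D_blocks, P_blocks),
        params,
        list(payload["energy_trace"]),
        bool(payload["converged"]),
    )
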