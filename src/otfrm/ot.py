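"""Entropic and exact optimal transport between embedding sets.

The ground cost between two samples is the cosine distance raised to the
Wasserstein order ``p``:

    C_ij = (1 − x_i·y_j / (‖x_i‖ ‖y_j‖))^p ∈ [0, 2^p]

Two solvers are provided for the Kantorovich problem
``min_{π ∈ Π(a,b)} ⟨C, π⟩``:

* ``sinkhorn`` — entropy-regularized (objective ``⟨C, π⟩ − εH(π)`` with
  ``H(π) = −Σ π_ij log π_ij``), solved by log-domain Sinkhorn iterations,
  numerically stable down to small ε.  The *reported* transport cost is
  the sharp ``⟨C, π*⟩`` under the entropic plan, so the self-distance
  tends to 0 as ε → 0 and ``cost^{1/p}`` keeps its p-Wasserstein meaning.
* ``exact`` — the unregularized linear program, solved with HiGHS via
  ``scipy.optimize.linprog``; guarded to small instances, it doubles as
  the brute-force oracle in the test-suite.

The p-Wasserstein distance is ``W_p = cost^{1/p}`` and the OT similarity
of two tasks is ``1 − W_p``, which lies in [−1, 1] because the cosine
cost is bounded by ``2^p``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.special import logsumexp

from .exceptions import ConvergenceError, DegenerateInputError, SizeError

__all__ = [
    "OTConfig",
    "CouplingPlan",
    "cosine_distance_matrix",
    "sinkhorn_plan",
    "exact_ot",
    "wasserstein_p",
    "ot_similarity",
]

logger = logging.getLogger(__name__)

_EXACT_GUARD = 10_000  # max m·n for the LP solver
_ZERO_NORM_TOL = 1e-12


@dataclass(frozen=True)
class OTConfig:
    """Solver configuration.

    Parameters
    ----------
    p:
        Wasserstein order (cost = cosine distance^p), p ≥ 1.
    epsilon:
        Entropic regularization strength for Sinkhorn (default 0.1).
    max_iter:
        Sinkhorn iteration cap.
    marginal_tol:
        Largest tolerated violation of the coupling's marginal
        constraints (sup-norm).
    solver:
        "sinkhorn" or "exact".
    subsample_cap:
        Tasks larger than this are subsampled (without replacement,
        seeded) before the O(mn) cost matrix is formed.
    subsample_seed:
        Seed for that subsampling.
    """

    p: float = 1.0
    epsilon: float = 0.1
    max_iter: int = 10_000
    marginal_tol: float = 1e-6
    solver: str = "sinkhorn"
    subsample_cap: int = 2_000
    subsample_seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"p must be ≥ 1, got {self.p}")
        if self.solver not in ("sinkhorn", "exact"):
            raise ValueError(f"unknown solver {self.solver!r}")
        if self.solver == "sinkhorn" and self.epsilon <= 0:
            raise ValueError("epsilon must be > 0 for the sinkhorn solver")
        if self.subsample_cap < 1:
            raise ValueError("subsample_cap must be ≥ 1")


@dataclass
class CouplingPlan:
    """A transport plan with its prescribed marginals."""

    pi: np.ndarray
    a: np.ndarray
    b: np.ndarray

    def marginal_residual(self) -> float:
        """Sup-norm violation of the row/column marginal constraints."""
        return max(
            float(np.max(np.abs(self.pi.sum(axis=1) - self.a))),
            float(np.max(np.abs(self.pi.sum(axis=0) - self.b))),
        )


def _check_simplex(w: np.ndarray, name: str) -> np.ndarray:
    w = np.asarray(w, dtype=np.float64)
    if w.ndim != 1 or np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError(f"{name} must be a probability vector, got sum {w.sum()}")
    return w


def _unit_rows(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[None, :]
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms < _ZERO_NORM_TOL):
        bad = int(np.argmin(norms))
        raise DegenerateInputError(
            f"{name} row {bad} has (near-)zero norm; cosine distance undefined"
        )
    return X / norms[:, None]


def cosine_distance_matrix(X: np.ndarray, Y: np.ndarray, p: float = 1.0) -> np.ndarray:
    """Pairwise cost matrix ``C_ij = (1 − cos(x_i, y_j))^p``."""
    if p < 1:
        raise ValueError(f"p must be ≥ 1, got {p}")
    Xu = _unit_rows(X, "X")
    Yu = _unit_rows(Y, "Y")
    if Xu.shape[1] != Yu.shape[1]:
        raise ValueError(f"dimension mismatch: {Xu.shape[1]} vs {Yu.shape[1]}")
    cos = np.clip(Xu @ Yu.T, -1.0, 1.0)
    return (1.0 - cos) ** p


def sinkhorn_plan(
    C: np.ndarray,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
    cfg: OTConfig | None = None,
) -> tuple[CouplingPlan, float]:
    """Entropic OT via log-domain Sinkhorn.

    Returns the converged coupling and the sharp transport cost
    ``⟨C, π⟩`` (entropy term excluded).  Marginals default to uniform.

    Raises
    ------
    ConvergenceError
        If after ``cfg.max_iter`` sweeps the marginal violation still
        exceeds ``10 × cfg.marginal_tol``.
    """
    cfg = cfg or OTConfig()
    C = np.asarray(C, dtype=np.float64)
    m, n = C.shape
    a = np.full(m, 1.0 / m) if a is None else _check_simplex(a, "a")
    b = np.full(n, 1.0 / n) if b is None else _check_simplex(b, "b")

    eps = cfg.epsilon
    log_a = np.log(a)
    log_b = np.log(b)
    f = np.zeros(m)
    g = np.zeros(n)
    residual = np.inf
    for it in range(1, cfg.max_iter + 1):
        f = eps * log_a - eps * logsumexp((g[None, :] - C) / eps, axis=1)
        g = eps * log_b - eps * logsumexp((f[:, None] - C) / eps, axis=0)
        if it % 10 == 0 or it == cfg.max_iter:
            log_pi = (f[:, None] + g[None, :] - C) / eps
            pi = np.exp(log_pi)
            residual = max(
                float(np.max(np.abs(pi.sum(axis=1) - a))),
                float(np.max(np.abs(pi.sum(axis=0) - b))),
            )
            if residual <= cfg.marginal_tol:
                break
    else:  # pragma: no cover - loop always breaks or falls through above
        pass
    pi = np.exp((f[:, None] + g[None, :] - C) / eps)
    residual = CouplingPlan(pi, a, b).marginal_residual()
    if residual > cfg.marginal_tol:
        if residual > 10 * cfg.marginal_tol:
            raise ConvergenceError(
                f"Sinkhorn failed to converge in {cfg.max_iter} iterations "
                f"(marginal residual {residual:.3e})",
                residual=residual,
            )
        logger.warning(
            "Sinkhorn stopped at max_iter=%d with marginal residual %.3e",
            cfg.max_iter,
            residual,
        )
    cost = float(np.sum(C * pi))
    return CouplingPlan(pi, a, b), cost


def exact_ot(
    C: np.ndarray, a: np.ndarray | None = None, b: np.ndarray | None = None
) -> float:
    """Unregularized Kantorovich OT cost by linear programming.

    Intended for small instances (guard: m·n ≤ 10 000); serves as the
    exact oracle against which the Sinkhorn path is validated.
    """
    C = np.asarray(C, dtype=np.float64)
    m, n = C.shape
    if m * n > _EXACT_GUARD:
        raise SizeError(f"exact solver guard: m·n = {m * n} > {_EXACT_GUARD}")
    a = np.full(m, 1.0 / m) if a is None else _check_simplex(a, "a")
    b = np.full(n, 1.0 / n) if b is None else _check_simplex(b, "b")

    # Row-sum and column-sum equality constraints; the final column
    # constraint is redundant (total mass) and dropped for rank.
    rows = np.zeros((m, m * n))
    for i in range(m):
        rows[i, i * n : (i + 1) * n] = 1.0
    cols = np.zeros((n - 1, m * n))
    for j in range(n - 1):
        cols[j, j::n] = 1.0
    A_eq = np.vstack([rows, cols])
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - feasible by construction
        raise RuntimeError(f"LP solver failed: {res.message}")
    return float(res.fun)


def _maybe_subsample(X: np.ndarray, cfg: OTConfig, which: int) -> np.ndarray:
    if X.shape[0] <= cfg.subsample_cap:
        return X
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.subsample_seed, which, X.shape[0]])
    )
    idx = rng.choice(X.shape[0], size=cfg.subsample_cap, replace=False)
    return X[np.sort(idx)]


def transport_cost(
    A: np.ndarray,
    B: np.ndarray,
    cfg: OTConfig | None = None,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> float:
    """OT cost between two embedding sets under the cosine^p ground cost."""
    cfg = cfg or OTConfig()
    A = np.atleast_2d(np.asarray(A, dtype=np.float64))
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    if a is None:
        A = _maybe_subsample(A, cfg, 0)
    if b is None:
        B = _maybe_subsample(B, cfg, 1)
    C = cosine_distance_matrix(A, B, cfg.p)
    if cfg.solver == "exact":
        return exact_ot(C, a, b)
    _, cost = sinkhorn_plan(C, a, b, cfg)
    return cost


def wasserstein_p(
    A: np.ndarray,
    B: np.ndarray,
    cfg: OTConfig | None = None,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> float:
    """p-Wasserstein distance ``(OT cost)^{1/p}`` between two tasks."""
    cfg = cfg or OTConfig()
    cost = max(transport_cost(A, B, cfg, a, b), 0.0)  # clip LP round-off
    return float(cost ** (1.0 / cfg.p))


def ot_similarity(
    A: np.ndarray,
    B: np.ndarray,
    cfg: OTConfig | None = None,
    a: np.ndarray | None = None,
    b: np.ndarray | None = None,
) -> float:
    """OT similarity ``1 − W_p(A, B)``; lies in [−1, 1]."""
    return 1.0 - wasserstein_p(A, B, cfg, a, b)
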