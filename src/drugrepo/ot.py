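"""Entropically regularised optimal transport (log-domain Sinkhorn).

Solves  min_gamma <gamma, C> + eps * KL(gamma | P x Q)  subject to the
marginal constraints gamma 1 = P and gamma^T 1 = Q. The alternating dual
updates are performed on the potentials in the log domain (logsumexp), so
small epsilon values do not underflow. A batched variant shares one cost
matrix across many marginal pairs, which is what the predictor's training
loop needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["TransportPlan", "sinkhorn_plan", "SinkhornKernel", "sinkhorn_batch"]

_MARGINAL_TOL = 1e-6


@dataclass
class TransportPlan:
    """Coupling gamma with its prescribed marginals P (rows) and Q (columns)."""

    gamma: np.ndarray
    source: np.ndarray
    target: np.ndarray
    cost: float
    n_iter: int
    converged: bool

    def marginal_error(self) -> float:
        row = np.abs(self.gamma.sum(axis=1) - self.source).max()
        col = np.abs(self.gamma.sum(axis=0) - self.target).max()
        return float(max(row, col))


def _check_distribution(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.min(p) < 0:
        raise ValueError(f"{name} must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1 (got {p.sum():.12f})")
    return p


def sinkhorn_plan(P, Q, cost, epsilon: float = 0.01,
                  max_iter: int = 1000, tol: float = 1e-9) -> TransportPlan:
    """Entropic optimal transport between distributions P and Q.

    Iterates the dual updates until the worst marginal violation falls
    below ``tol`` or ``max_iter`` is reached (then the best iterate is
    returned with a warning). Zero-mass bins are handled in the log domain
    (log 0 = -inf potentials give exact zero rows/columns of gamma).
    """
    P = _check_distribution(P, "P")
    Q = _check_distribution(Q, "Q")
    C = np.asarray(cost, dtype=float)
    if C.shape != (P.size, Q.size):
        raise ValueError("cost shape does not match marginals")
    if not np.all(np.isfinite(C)) or np.min(C) < 0:
        raise ValueError("cost must be finite and non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")

    with np.errstate(divide="ignore"):
        log_p = np.log(P)
        log_q = np.log(Q)
    mlog = -C / epsilon
    f = np.zeros(P.size)  # scaled potentials (phi = f/eps)
    g = np.zeros(Q.size)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        f = log_p - logsumexp(mlog + g[None, :], axis=1)
        g = log_q - logsumexp(mlog + f[:, None], axis=0)
        # row marginals after a g-update are off by at most the update size;
        # check true violation every iteration
        log_gamma = mlog + f[:, None] + g[None, :]
        gamma = np.exp(log_gamma)
        err = max(np.abs(gamma.sum(axis=1) - P).max(),
                  np.abs(gamma.sum(axis=0) - Q).max())
        if err < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"Sinkhorn did not reach tol={tol:g} in {max_iter} iterations "
            f"(marginal error {err:.3g}); returning best iterate",
            RuntimeWarning,
        )
    transport_cost = float(np.sum(gamma * C))
    return TransportPlan(gamma, P, Q, transport_cost, it, converged)


class SinkhornKernel:
    """Precomputed Gibbs kernel for repeated batched Sinkhorn solves.

    Shares one cost matrix across many marginal pairs (the training loop
    solves one small OT problem per disease row per epoch). Iterations run
    in the kernel domain — two (batch x n) @ (n x n) products per sweep —
    which is orders of magnitude faster than log-domain broadcasting and is
    numerically safe as long as cost / epsilon stays within float range
    (the caller normalises the cost scale).
    """

    def __init__(self, cost: np.ndarray, epsilon: float):
        C = np.asarray(cost, float)
        if epsilon <= 0:
            raise ValueError("epsilon must be positive")
        self.C = C
        self.epsilon = epsilon
        self.K = np.exp(-C / epsilon)
        self.KC = self.K * C

    def solve(self, A: np.ndarray, B: np.ndarray, max_iter: int = 50,
              tol: float = 1e-6, return_plans: bool = False):
        """Returns ``(costs, grad_b[, plans])`` for paired marginal rows.

        ``costs[r]`` is the transport cost <gamma_r, C>; ``grad_b[r]`` is
        the gradient of the entropic OT value w.r.t. the target marginal
        B[r] (the dual potential, by the envelope theorem), centred to the
        simplex tangent space. Rows of B must be strictly positive.
        """
        A = np.asarray(A, float)
        B = np.asarray(B, float)
        tiny = 1e-300
        U = np.ones_like(A)
        V = np.ones_like(B)
        for it in range(max_iter):
            U = A / np.maximum(V @ self.K.T, tiny)
            V_new = B / np.maximum(U @ self.K, tiny)
            if it % 10 == 9 and np.max(np.abs(V_new - V)) < tol:
                V = V_new
                break
            V = V_new
        costs = np.einsum("bi,ij,bj->b", U, self.KC, V)
        with np.errstate(divide="ignore"):
            grad_b = self.epsilon * np.log(np.maximum(V, tiny))
        grad_b = grad_b - np.sum(np.where(B > 0, grad_b * B, 0.0), axis=1, keepdims=True)
        if return_plans:
            plans = U[:, :, None] * self.K[None, :, :] * V[:, None, :]
            return costs, grad_b, plans
        return costs, grad_b

    def marginals(self, A: np.ndarray, B: np.ndarray, **kw):
        """Row/column marginals of the solved plans (diagnostic helper)."""
        _, _, plans = self.solve(A, B, return_plans=True, **kw)
        return plans.sum(axis=2), plans.sum(axis=1)


def sinkhorn_batch(A: np.ndarray, B: np.ndarray, cost: np.ndarray,
                   epsilon: float, max_iter: int = 50, tol: float = 1e-6,
                   return_plans: bool = False):
    """One-shot convenience wrapper around :class:`SinkhornKernel`."""
    return SinkhornKernel(cost, epsilon).solve(A, B, max_iter=max_iter, tol=tol,
                                               return_plans=return_plans)
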