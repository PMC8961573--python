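"""Independent brute-force oracles used to cross-check the implementation.

Each oracle re-derives a quantity from first principles (full dynamic
programming, exhaustive enumeration, or an exact LP) without touching the
package's own computation paths.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import linprog

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_dp(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0) -> float:
    """Quadratic-space Gotoh local alignment (gap of length L costs
    open + (L-1) * extend)."""
    n, m = len(a), len(b)
    neg = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), neg)
    F = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] - gap_open, E[i, j - 1] - gap_extend)
            F[i, j] = max(H[i - 1, j] - gap_open, F[i - 1, j] - gap_extend)
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            H[i, j] = max(0.0, H[i - 1, j - 1] + s, E[i, j], F[i, j])
            best = max(best, H[i, j])
    return best


def sw_similarity_dp(a: str, b: str) -> float:
    s_ab = sw_score_dp(a, b)
    if s_ab == 0:
        return 0.0
    return min(s_ab / np.sqrt(sw_score_dp(a, a) * sw_score_dp(b, b)), 1.0)


def ppmi_elementwise(C: np.ndarray) -> np.ndarray:
    """Scalar-loop PPMI: max(log(C_ij * T / (rowsum_i * colsum_j)), 0)."""
    C = np.asarray(C, float)
    T = C.sum()
    out = np.zeros_like(C)
    for i in range(C.shape[0]):
        for j in range(C.shape[1]):
            if C[i, j] > 0:
                out[i, j] = max(np.log(C[i, j] * T / (C[i].sum() * C[:, j].sum())), 0.0)
    return out


def wang_svalues_paths(term: str, edges: dict) -> dict[str, float]:
    """S-values by exhaustive path enumeration: S(t) = max over directed
    paths term -> t of the product of edge weights (S(term) = 1)."""
    best = {term: 1.0}

    def walk(node: str, weight: float) -> None:
        for parent, w in edges.get(node, ()):
            new = weight * w
            if new > best.get(parent, 0.0):
                best[parent] = new
            walk(parent, new)

    walk(term, 1.0)
    return best


def wang_similarity_paths(t1: str, t2: str, edges: dict) -> float:
    s1 = wang_svalues_paths(t1, edges)
    s2 = wang_svalues_paths(t2, edges)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    return sum(s1[t] + s2[t] for t in common) / (sum(s1.values()) + sum(s2.values()))


def auroc_paircount(scores, labels) -> float:
    """AUROC by exhaustive positive/negative pair counting (ties = 1/2)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def lp_transport_cost(P, Q, cost) -> float:
    """Exact optimal-transport cost by linear programming."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    C = np.asarray(cost, float)
    n, m = C.shape
    A_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros(n * m)
        row[i * m:(i + 1) * m] = 1.0
        A_eq.append(row)
        b_eq.append(P[i])
    for j in range(m - 1):  # drop one redundant constraint
        col = np.zeros(n * m)
        col[j::m] = 1.0
        A_eq.append(col)
        b_eq.append(Q[j])
    res = linprog(C.ravel(), A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    assert res.success
    return float(res.fun)
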