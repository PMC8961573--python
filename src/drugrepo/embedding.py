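"""Random-walk network representation and PPMI factorisation.

Each network is turned into a positive pointwise-mutual-information (PPMI)
matrix in three steps: row-normalise the adjacency into a transition matrix
M, propagate a restart random walk p_k = w * p_{k-1} M + (1 - w) * p_0 for k
steps from every start node (accumulating the visit distributions into a
co-occurrence matrix C), and apply the PPMI transform

    PPMI(i, j) = max( log( C(i,j) * T / (rowsum_i * colsum_j) ), 0 )

with T the total mass of C. The walk is propagated in closed form on
distributions rather than by sampling vertex sequences: it computes exactly
the co-occurrence expectations the sampled walks converge to, and is
deterministic.

Bipartite networks are first collapsed to drug-drug Jaccard similarity
(:func:`drugrepo.similarity.jaccard_network`) and then treated identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import BipartiteNetwork, DrugVocabulary, HomogeneousNetwork, PPMIMatrix
from .similarity import jaccard_network

__all__ = [
    "RandomWalkConfig",
    "TransitionMatrix",
    "transition_matrix",
    "rwr_cooccurrence",
    "ppmi",
    "embed_network",
    "embed_all",
]


@dataclass(frozen=True)
class RandomWalkConfig:
    """Restart-walk parameters: continue probability ``omega`` and length ``walk_length``.

    Defaults (omega=0.5, walk_length=3) follow the deepNF construction of
    the same representation. ``seed`` is accepted for API symmetry with
    sampled variants; the closed-form propagation itself is deterministic.
    """

    omega: float = 0.5
    walk_length: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must lie in [0, 1]")
        if int(self.walk_length) != self.walk_length or self.walk_length < 1:
            raise ValueError("walk_length must be an integer >= 1")


@dataclass
class TransitionMatrix:
    """Row-stochastic non-negative matrix of walk transition probabilities."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.min(m) < 0:
            raise ValueError("transition matrix must be non-negative")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")
        self.matrix = m


def transition_matrix(net: HomogeneousNetwork | np.ndarray) -> TransitionMatrix:
    """Row-normalise a non-negative adjacency; all-zero rows become uniform.

    Uniform replacement keeps the matrix stochastic for isolated drugs.
    """
    a = net.matrix if isinstance(net, HomogeneousNetwork) else np.asarray(net, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.min(a) < 0:
        raise ValueError("adjacency must be non-negative")
    n = a.shape[0]
    rowsum = a.sum(axis=1)
    zero = rowsum == 0
    m = np.empty_like(a, dtype=float)
    nz = ~zero
    m[nz] = a[nz] / rowsum[nz, None]
    m[zero] = 1.0 / n
    return TransitionMatrix(m)


def rwr_cooccurrence(M: TransitionMatrix, cfg: RandomWalkConfig | None = None) -> np.ndarray:
    """Accumulated restart-walk visit distributions from every start node.

    Row i of the result is sum_{step=1..k} p_step with p_0 = one-hot(i) and
    p_step = omega * p_{step-1} M + (1 - omega) * p_0. Every p_step is a
    probability distribution, so each row of C sums to the walk length k.
    All starts are propagated simultaneously (P_0 = identity).
    """
    cfg = cfg or RandomWalkConfig()
    m = M.matrix
    n = m.shape[0]
    p = np.eye(n)
    c = np.zeros((n, n))
    for _ in range(cfg.walk_length):
        p = cfg.omega * (p @ m) + (1.0 - cfg.omega) * np.eye(n)
        c += p
    return c


def ppmi(C: np.ndarray, source_kind: str = "") -> PPMIMatrix:
    """Positive pointwise mutual information of a non-negative count matrix.

    Entries with C(i, j) = 0 map to 0 (the log's limit is clipped anyway);
    the transform is invariant to global scaling of C.
    """
    c = np.asarray(C, dtype=float)
    if np.min(c) < 0:
        raise ValueError("co-occurrence matrix must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValueError("co-occurrence matrix has no mass")
    rows = c.sum(axis=1)
    cols = c.sum(axis=0)
    expected = rows[:, None] * cols[None, :]
    out = np.zeros_like(c)
    mask = c > 0
    # rows/cols of a positive entry are necessarily positive
    out[mask] = np.log(c[mask] * total / expected[mask])
    np.maximum(out, 0.0, out=out)
    return PPMIMatrix(out, source_kind=source_kind)


def embed_network(
    net: HomogeneousNetwork | BipartiteNetwork,
    cfg: RandomWalkConfig | None = None,
    rwr_on_bipartite: bool = True,
) -> PPMIMatrix:
    """Full embedding of one network: (Jaccard ->) transitions -> walk -> PPMI."""
    cfg = cfg or RandomWalkConfig()
    if isinstance(net, BipartiteNetwork):
        collapsed = jaccard_network(net)
        if not rwr_on_bipartite:
            total = collapsed.matrix.sum()
            if total <= 0:
                raise ValueError(f"network {collapsed.kind!r} is empty")
            return ppmi(collapsed.matrix, source_kind=collapsed.kind)
        net = collapsed
    C = rwr_cooccurrence(transition_matrix(net), cfg)
    return ppmi(C, source_kind=net.kind)


def embed_all(
    networks,
    cfg: RandomWalkConfig | None = None,
    rwr_on_bipartite: bool = True,
) -> list[PPMIMatrix]:
    """Embed a list of homogeneous/bipartite networks sharing one vocabulary.

    Output order follows input order (conventionally: interaction, chemical,
    side-effect, target-sequence, GO, ATC similarities, then the drug-gene,
    drug-side-effect and drug-disease bipartite networks).
    """
    networks = list(networks)
    if not networks:
        raise ValueError("no networks to embed")
    vocab = networks[0].vocabulary
    for net in networks:
        if net.vocabulary.ids != vocab.ids:
            raise ValueError("all networks must share one drug vocabulary")
    return [embed_network(net, cfg, rwr_on_bipartite) for net in networks]
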