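"""Wang graph-based GO semantic similarity.

Implements the graph-based measure popularised by the GOSemSim package:
each term's ancestor closure receives S-values (S(term)=1, S(parent) =
max over child edges of w * S(child), with w the semantic contribution of
the relation, by default 0.8 for is_a and 0.6 for part_of). The similarity
of two terms is

    sim(t1, t2) = sum_{t in common ancestors} (S1(t) + S2(t)) / (SV1 + SV2)

where SV is the sum of a term's S-values. Gene-level similarity combines
term similarities by best-match average; drug-level similarity is the mean
over all target-gene pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MissingDataError

__all__ = [
    "DEFAULT_RELATION_WEIGHTS",
    "GoDag",
    "go_term_similarity",
    "gene_go_similarity",
    "drug_go_similarity",
    "make_drug_go_measure",
]

DEFAULT_RELATION_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class GoDag:
    """GO DAG as weighted child -> parent edges.

    ``edges`` maps each child term to a list of ``(parent, weight)`` with
    weight in (0, 1). Terms appearing only as parents are roots.
    """

    edges: dict[str, list[tuple[str, float]]]
    _svalues: dict[str, dict[str, float]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_edge_list(cls, triples, relation_weights=None) -> "GoDag":
        """Build from (child, parent, relation) triples."""
        weights = dict(DEFAULT_RELATION_WEIGHTS, **(relation_weights or {}))
        edges: dict[str, list[tuple[str, float]]] = {}
        for child, parent, relation in triples:
            if relation not in weights:
                raise ValueError(f"unknown GO relation: {relation!r}")
            edges.setdefault(child, []).append((parent, weights[relation]))
            edges.setdefault(parent, edges.get(parent, []))
        return cls(edges)

    def __post_init__(self) -> None:
        for child, parents in self.edges.items():
            for parent, w in parents:
                if not 0 < w < 1:
                    raise ValueError(f"relation weight must be in (0,1): {child}->{parent}")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {t: WHITE for t in self.terms()}
        for start in colour:
            if colour[start] != WHITE:
                continue
            stack = [(start, iter(self.edges.get(start, ())))]
            colour[start] = GREY
            while stack:
                node, it = stack[-1]
                advanced = False
                for parent, _ in it:
                    if colour.get(parent, WHITE) == GREY:
                        raise ValueError("GO DAG contains a cycle")
                    if colour.get(parent, WHITE) == WHITE:
                        colour[parent] = GREY
                        stack.append((parent, iter(self.edges.get(parent, ()))))
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    stack.pop()

    def terms(self) -> set[str]:
        out = set(self.edges)
        for parents in self.edges.values():
            out.update(p for p, _ in parents)
        return out

    def __contains__(self, term: str) -> bool:
        return term in self.terms()

    def s_values(self, term: str) -> dict[str, float]:
        """S-values over the ancestor closure of ``term`` (term itself = 1)."""
        if term not in self:
            raise KeyError(f"unknown GO term: {term!r}")
        cached = self._svalues.get(term)
        if cached is not None:
            return cached
        sval = {term: 1.0}
        # best-first propagation: a term's S-value is the max over paths of
        # the product of edge weights back to the query term
        frontier = [term]
        while frontier:
            nxt: list[str] = []
            for child in frontier:
                for parent, w in self.edges.get(child, ()):
                    cand = w * sval[child]
                    if cand > sval.get(parent, 0.0):
                        sval[parent] = cand
                        nxt.append(parent)
            frontier = nxt
        self._svalues[term] = sval
        return sval


def go_term_similarity(t1: str, t2: str, dag: GoDag) -> float:
    """Wang similarity of two GO terms in [0, 1]."""
    s1 = dag.s_values(t1)
    s2 = dag.s_values(t2)
    common = set(s1) & set(s2)
    if not common:
        return 0.0
    num = sum(s1[t] + s2[t] for t in common)
    return float(num / (sum(s1.values()) + sum(s2.values())))


def gene_go_similarity(terms_a, terms_b, dag: GoDag) -> float:
    """Best-match-average combination of term similarities for two genes."""
    ta, tb = list(terms_a), list(terms_b)
    if not ta or not tb:
        raise MissingDataError("gene term sets must be non-empty")
    sim = np.array([[go_term_similarity(a, b, dag) for b in tb] for a in ta])
    return float((sim.max(axis=1).sum() + sim.max(axis=0).sum()) / (len(ta) + len(tb)))


def drug_go_similarity(genes_a, genes_b, annotations: dict, dag: GoDag) -> float:
    """Functional similarity of two drugs via their target-coding genes.

    ``annotations`` maps gene -> set of GO terms. Unannotated genes are
    excluded; if no annotated gene pair remains a ``ValueError`` signals
    missing data (callers map it to a zero network entry).
    """
    ga = [g for g in genes_a if annotations.get(g)]
    gb = [g for g in genes_b if annotations.get(g)]
    if not ga or not gb:
        raise MissingDataError("no annotated gene pairs for drug GO similarity")
    vals = [gene_go_similarity(annotations[a], annotations[b], dag) for a in ga for b in gb]
    return float(np.mean(vals))


def make_drug_go_measure(annotations: dict, dag: GoDag):
    """Return a drug-pair measure with gene-pair memoisation.

    Across a whole similarity network the same gene pairs recur in many
    drug pairs; caching the gene-level values makes the n^2 drug loop cheap.
    The returned callable raises ``ValueError`` on missing annotation data,
    matching :func:`drug_go_similarity`.
    """
    gene_cache: dict[tuple[str, str], float] = {}

    def gene_sim(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        val = gene_cache.get(key)
        if val is None:
            val = gene_go_similarity(annotations[a], annotations[b], dag)
            gene_cache[key] = val
        return val

    def measure(genes_a, genes_b) -> float:
        ga = [g for g in genes_a if annotations.get(g)]
        gb = [g for g in genes_b if annotations.get(g)]
        if not ga or not gb:
            raise MissingDataError("no annotated gene pairs for drug GO similarity")
        return float(np.mean([gene_sim(a, b) for a in ga for b in gb]))

    return measure
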