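"""Shared in-memory containers for the pipeline.

A single :class:`DrugVocabulary` fixes the row/column order of every matrix
produced downstream, so the nine input networks, the PPMI representations,
the fused feature matrix and the disease x drug association matrix all index
drugs identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DrugVocabulary",
    "HomogeneousNetwork",
    "BipartiteNetwork",
    "PPMIMatrix",
    "FusedFeatures",
    "AssociationMatrix",
]

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class DrugVocabulary:
    """Ordered, unique drug identifiers; defines matrix row/column order."""

    ids: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("drug identifiers must be unique")
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "index", {d: i for i, d in enumerate(self.ids)})

    @classmethod
    def from_ids(cls, ids) -> "DrugVocabulary":
        return cls(tuple(ids))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, drug: str) -> bool:
        return drug in self.index

    def position(self, drug: str) -> int:
        try:
            return self.index[drug]
        except KeyError:
            raise KeyError(f"unknown drug identifier: {drug!r}") from None


@dataclass
class HomogeneousNetwork:
    """A drug x drug network (adjacency or similarity), symmetric by construction.

    ``kind`` labels the measure (e.g. ``"chemical"``, ``"interaction"``).
    Similarity networks (``is_similarity=True``) additionally satisfy
    entries in [0, 1] with unit diagonal for drugs that carry data.
    """

    matrix: np.ndarray
    vocabulary: DrugVocabulary
    kind: str = "network"
    is_similarity: bool = True

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.vocabulary)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != vocabulary size {n}")
        if not np.all(np.isfinite(m)):
            raise ValueError("network matrix contains non-finite entries")
        if np.min(m) < 0:
            raise ValueError("network matrix must be non-negative")
        if np.max(np.abs(m - m.T)) > _SYM_TOL:
            raise ValueError("network matrix must be symmetric")
        if self.is_similarity and np.max(m) > 1 + _SYM_TOL:
            raise ValueError("similarity entries must lie in [0, 1]")
        self.matrix = m

    @property
    def n_drugs(self) -> int:
        return len(self.vocabulary)


@dataclass
class BipartiteNetwork:
    """Binary drug x entity incidence matrix (genes, side effects, diseases)."""

    matrix: np.ndarray
    vocabulary: DrugVocabulary
    entity_ids: tuple[str, ...]
    kind: str = "bipartite"

    def __post_init__(self) -> None:
        self.entity_ids = tuple(self.entity_ids)
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("entity identifiers must be unique")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.vocabulary), len(self.entity_ids)):
            raise ValueError("incidence shape does not match vocabulary/entities")
        if not np.array_equal(m, m.astype(bool).astype(float)):
            raise ValueError("incidence entries must be binary")
        self.matrix = m

    def item_sets(self) -> list[set[str]]:
        """Per-drug set of associated entity identifiers, vocabulary order."""
        ents = np.asarray(self.entity_ids, dtype=object)
        return [set(ents[row.astype(bool)]) for row in self.matrix]


@dataclass
class PPMIMatrix:
    """Positive pointwise-mutual-information representation of one network."""

    matrix: np.ndarray
    source_kind: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("PPMI matrix must be square")
        if not np.all(np.isfinite(m)) or np.min(m) < 0:
            raise ValueError("PPMI entries must be finite and non-negative")
        self.matrix = m


@dataclass
class FusedFeatures:
    """Low-dimensional drug features from the fusion autoencoder bottleneck."""

    matrix: np.ndarray
    vocabulary: DrugVocabulary

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != len(self.vocabulary):
            raise ValueError("feature rows must align with the vocabulary")
        if not np.all(np.isfinite(m)):
            raise ValueError("features must be finite")
        self.matrix = m

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


@dataclass
class AssociationMatrix:
    """Disease x drug association scores in [0, 1] (binary for known data)."""

    matrix: np.ndarray
    disease_ids: tuple[str, ...]
    vocabulary: DrugVocabulary

    def __post_init__(self) -> None:
        self.disease_ids = tuple(self.disease_ids)
        if len(set(self.disease_ids)) != len(self.disease_ids):
            raise ValueError("disease identifiers must be unique")
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.disease_ids), len(self.vocabulary)):
            raise ValueError("association shape does not match diseases/vocabulary")
        if np.min(m) < 0 or np.max(m) > 1:
            raise ValueError("association entries must lie in [0, 1]")
        self.matrix = m

    @classmethod
    def from_pairs(cls, pairs, disease_ids, vocabulary: DrugVocabulary) -> "AssociationMatrix":
        """Build a binary matrix from (disease_id, drug_id) positives."""
        disease_ids = tuple(disease_ids)
        didx = {d: i for i, d in enumerate(disease_ids)}
        m = np.zeros((len(disease_ids), len(vocabulary)))
        for dis, drug in pairs:
            m[didx[dis], vocabulary.position(drug)] = 1.0
        return cls(m, disease_ids, vocabulary)
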