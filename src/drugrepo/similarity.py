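"""Pairwise drug-drug similarity measures and similarity-network assembly.

Five drug-drug similarity networks feed the pipeline: chemical structure
(Tanimoto on 166-bit fingerprints), side-effect profiles (Tanimoto on
annotation sets), target protein sequences (normalised Smith-Waterman,
averaged over target pairs), biological function (Wang GO semantic
similarity, see :mod:`drugrepo.gosim`) and therapeutic class (ATC code
prefix overlap). The Jaccard transform converts bipartite incidence
networks into drug-drug similarity before embedding.

Missing-data convention: a drug without data for a modality keeps its row
in the network but contributes zeros (self-similarity included), so one
shared vocabulary indexes all networks.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .containers import BipartiteNetwork, DrugVocabulary, HomogeneousNetwork
from .errors import MissingDataError

__all__ = [
    "tanimoto",
    "set_tanimoto",
    "jaccard",
    "jaccard_network",
    "AlignmentScoring",
    "sw_score",
    "sw_similarity",
    "target_similarity",
    "atc_similarity",
    "build_similarity_network",
]

logger = logging.getLogger(__name__)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient T = c / (a + b - c) on binary fingerprints.

    a, b are set-bit counts of the two fingerprints, c the shared set bits.
    Two all-zero fingerprints score 0 (no shared evidence).
    """
    fa = np.asarray(fp_a)
    fb = np.asarray(fp_b)
    if fa.shape != fb.shape:
        raise ValueError(f"fingerprint length mismatch: {fa.shape} vs {fb.shape}")
    fa = fa.astype(bool)
    fb = fb.astype(bool)
    a = int(fa.sum())
    b = int(fb.sum())
    c = int((fa & fb).sum())
    denom = a + b - c
    return c / denom if denom > 0 else 0.0


def set_tanimoto(set_a, set_b) -> float:
    """Tanimoto coefficient on annotation sets: |A∩B| / (|A|+|B|-|A∩B|)."""
    sa, sb = set(set_a), set(set_b)
    c = len(sa & sb)
    denom = len(sa) + len(sb) - c
    return c / denom if denom > 0 else 0.0


def jaccard(set_a, set_b) -> float:
    """Jaccard coefficient |A∩B| / |A∪B|; 0 when both sets are empty.

    Identical to :func:`set_tanimoto` on sets; kept as the named transform
    applied to bipartite networks before embedding.
    """
    sa, sb = set(set_a), set(set_b)
    union = len(sa | sb)
    return len(sa & sb) / union if union > 0 else 0.0


def jaccard_network(bn: BipartiteNetwork) -> HomogeneousNetwork:
    """Drug x drug Jaccard similarity of the rows of a bipartite network.

    Computed vectorised from the binary incidence matrix: the intersection
    is B @ B.T and the union follows from row sums. Drugs with empty rows
    get all-zero similarity rows (including the diagonal).
    """
    if len(bn.vocabulary) < 1:
        raise ValueError("bipartite network must contain at least one drug")
    b = bn.matrix.astype(bool).astype(float)
    inter = b @ b.T
    sizes = b.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return HomogeneousNetwork(sim, bn.vocabulary, kind=f"jaccard({bn.kind})")


# ---------------------------------------------------------------------------
# Smith-Waterman target-sequence similarity


@dataclass(frozen=True)
class AlignmentScoring:
    """Local-alignment scoring scheme: substitution matrix + affine gaps.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def _validate_sequence(seq: str, alphabet: str) -> None:
    if len(seq) == 0:
        raise ValueError("empty protein sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"invalid residues {sorted(bad)} for scoring alphabet")


def sw_score(seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None) -> float:
    """Raw Smith-Waterman optimal local-alignment score (>= 0)."""
    scoring = scoring or AlignmentScoring()
    aligner = _aligner(scoring.matrix_name, scoring.gap_open, scoring.gap_extend)
    alphabet = str(aligner.substitution_matrix.alphabet).replace("*", "")
    _validate_sequence(seq_a, alphabet)
    _validate_sequence(seq_b, alphabet)
    return max(float(aligner.score(seq_a, seq_b)), 0.0)


def sw_similarity(seq_a: str, seq_b: str, scoring: AlignmentScoring | None = None) -> float:
    """Normalised local-alignment similarity SW(a,b) / sqrt(SW(a,a) SW(b,b)).

    The geometric-mean normalisation makes self-similarity 1 and values
    comparable across sequence lengths.
    """
    scoring = scoring or AlignmentScoring()
    s_ab = sw_score(seq_a, seq_b, scoring)
    if s_ab == 0.0:
        return 0.0
    s_aa = sw_score(seq_a, seq_a, scoring)
    s_bb = sw_score(seq_b, seq_b, scoring)
    if s_aa <= 0 or s_bb <= 0:
        return 0.0
    return min(s_ab / np.sqrt(s_aa * s_bb), 1.0)


def target_similarity(targets_a, targets_b, scoring: AlignmentScoring | None = None) -> float:
    """Mean normalised SW similarity over the Cartesian product of targets."""
    ta, tb = list(targets_a), list(targets_b)
    if not ta or not tb:
        raise MissingDataError("target sets must be non-empty")
    vals = [sw_similarity(a, b, scoring) for a in ta for b in tb]
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# ATC therapeutic-class similarity

_ATC_RE = re.compile(r"^[A-Z]\d{2}[A-Z][A-Z]\d{2}$")
# character spans of the five ATC levels within a 7-character code
_ATC_LEVELS = [(0, 1), (1, 3), (3, 4), (4, 5), (5, 7)]


def _atc_pair_similarity(code_a: str, code_b: str) -> float:
    matched = 0
    for lo, hi in _ATC_LEVELS:
        if code_a[lo:hi] == code_b[lo:hi]:
            matched += 1
        else:
            break
    return matched / 5.0


def atc_similarity(codes_a, codes_b, combine: str = "mean") -> float:
    """Therapeutic similarity from 5-level ATC codes.

    Each code pair scores (number of leading matched levels) / 5; multiple
    codes per drug are combined by the mean over all code pairs (``combine=
    "max"`` takes the best pair instead).
    """
    ca, cb = list(codes_a), list(codes_b)
    if not ca or not cb:
        raise MissingDataError("ATC code sets must be non-empty")
    for code in ca + cb:
        if not _ATC_RE.match(code):
            raise ValueError(f"malformed ATC code: {code!r}")
    vals = [_atc_pair_similarity(a, b) for a in ca for b in cb]
    if combine == "mean":
        return float(np.mean(vals))
    if combine == "max":
        return float(np.max(vals))
    raise ValueError(f"unknown combine mode: {combine!r}")


# ---------------------------------------------------------------------------
# Network assembly


def build_similarity_network(
    vocabulary: DrugVocabulary,
    per_drug_data: dict,
    measure,
    kind: str = "similarity",
    self_similarity: float = 1.0,
) -> HomogeneousNetwork:
    """Apply a symmetric pairwise measure to every drug pair.

    ``per_drug_data`` maps drug id -> modality payload (fingerprint, item
    set, sequence list, ...); ``measure(payload_i, payload_j)`` returns a
    similarity in [0, 1]. Drugs missing from ``per_drug_data`` (or whose
    payload is empty) get all-zero rows, logged once per network.
    """
    n = len(vocabulary)
    m = np.zeros((n, n))

    def _has_data(drug: str) -> bool:
        if drug not in per_drug_data:
            return False
        payload = per_drug_data[drug]
        try:
            return len(payload) > 0
        except TypeError:
            return True

    present = [d for d in vocabulary.ids if _has_data(d)]
    missing = [d for d in vocabulary.ids if not _has_data(d)]
    if missing:
        logger.warning(
            "%s network: %d/%d drugs lack data; their rows are zero",
            kind, len(missing), n,
        )
    n_missing_pairs = 0
    for ii, di in enumerate(present):
        i = vocabulary.position(di)
        m[i, i] = self_similarity
        for dj in present[ii + 1:]:
            j = vocabulary.position(dj)
            try:
                val = float(measure(per_drug_data[di], per_drug_data[dj]))
            except MissingDataError:
                val = 0.0
                n_missing_pairs += 1
            m[i, j] = m[j, i] = val
    if n_missing_pairs:
        logger.warning("%s network: %d pairs unscorable, set to 0", kind, n_missing_pairs)
    return HomogeneousNetwork(m, vocabulary, kind=kind)
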