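"""Readers and writers for the raw-input interchange formats.

All tables are TSV with a header row; sequences are FASTA. Reading
cross-checks every file against the shared drug vocabulary: rows that
reference unknown drugs are excluded with a warning (orphans), while
structurally malformed lines raise with the file name and line number.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .containers import DrugVocabulary
from .synthetic import SyntheticBundle

__all__ = [
    "read_vocabulary",
    "read_edge_list",
    "read_fingerprints",
    "read_fasta",
    "read_inputs",
    "file_sha256",
]

logger = logging.getLogger(__name__)

INPUT_FILES = {
    "drugs": "drugs.tsv",
    "ddi": "ddi.tsv",
    "fingerprints": "fingerprints.tsv",
    "drug_targets": "drug_targets.tsv",
    "targets_fasta": "targets.fasta",
    "gene_go": "gene_go.tsv",
    "go_dag": "go_dag.tsv",
    "atc": "atc.tsv",
    "drug_gene": "drug_gene.tsv",
    "drug_sideeffect": "drug_sideeffect.tsv",
    "drug_disease": "drug_disease.tsv",
}


def _read_tsv(path, n_cols: int) -> list[tuple[str, ...]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != n_cols:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_cols} tab-separated fields, "
                    f"got {len(parts)}")
            if lineno == 1:
                continue  # header
            rows.append(tuple(parts))
    return rows


def read_vocabulary(path) -> DrugVocabulary:
    return DrugVocabulary.from_ids(r[0] for r in _read_tsv(path, 1))


def read_edge_list(path, vocabulary: DrugVocabulary | None = None,
                   check_cols=(0,)) -> list[tuple[str, str]]:
    """Two-column edge list; rows with out-of-vocabulary drugs are dropped."""
    rows = _read_tsv(path, 2)
    if vocabulary is None:
        return rows
    kept, orphans = [], set()
    for row in rows:
        ok = all(row[c] in vocabulary for c in check_cols)
        if ok:
            kept.append(row)
        else:
            orphans.update(row[c] for c in check_cols if row[c] not in vocabulary)
    if orphans:
        logger.warning("%s: excluded %d rows with unknown drugs: %s",
                       path, len(rows) - len(kept), sorted(orphans)[:5])
    return kept


def read_fingerprints(path, vocabulary: DrugVocabulary) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    orphans = []
    for drug, bits in _read_tsv(path, 2):
        if set(bits) - {"0", "1"}:
            raise ValueError(f"{path}: fingerprint for {drug} is not a 0/1 bitstring")
        if drug not in vocabulary:
            orphans.append(drug)
            continue
        out[drug] = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    if orphans:
        logger.warning("%s: excluded %d unknown drugs", path, len(orphans))
    lengths = {len(v) for v in out.values()}
    if len(lengths) > 1:
        raise ValueError(f"{path}: inconsistent fingerprint lengths {sorted(lengths)}")
    return out


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_inputs(input_dir) -> SyntheticBundle:
    """Read all nine raw inputs from a directory into one validated bundle."""
    d = Path(input_dir)
    for f in INPUT_FILES.values():
        if not (d / f).exists():
            raise FileNotFoundError(f"missing input file: {d / f}")
    vocab = read_vocabulary(d / INPUT_FILES["drugs"])
    ddi = read_edge_list(d / INPUT_FILES["ddi"], vocab, check_cols=(0, 1))
    fingerprints = read_fingerprints(d / INPUT_FILES["fingerprints"], vocab)
    target_rows = read_edge_list(d / INPUT_FILES["drug_targets"], vocab)
    sequences = read_fasta(d / INPUT_FILES["targets_fasta"])
    drug_targets: dict[str, list[str]] = {}
    for drug, acc in target_rows:
        if acc not in sequences:
            raise ValueError(f"accession {acc!r} has no sequence in targets.fasta")
        drug_targets.setdefault(drug, []).append(acc)
    gene_go: dict[str, set[str]] = {}
    for gene, term in _read_tsv(d / INPUT_FILES["gene_go"], 2):
        gene_go.setdefault(gene, set()).add(term)
    dag_edges = [tuple(r) for r in _read_tsv(d / INPUT_FILES["go_dag"], 3)]
    atc_rows = read_edge_list(d / INPUT_FILES["atc"], vocab)
    drug_atc: dict[str, list[str]] = {}
    for drug, code in atc_rows:
        drug_atc.setdefault(drug, []).append(code)
    drug_gene = read_edge_list(d / INPUT_FILES["drug_gene"], vocab)
    drug_se = read_edge_list(d / INPUT_FILES["drug_sideeffect"], vocab)
    assoc = read_edge_list(d / INPUT_FILES["drug_disease"], vocab, check_cols=(1,))
    diseases = tuple(sorted({a for a, _ in assoc}))
    return SyntheticBundle(
        cfg=None, vocabulary=vocab, disease_ids=diseases, ddi_edges=ddi,
        fingerprints=fingerprints, drug_targets=drug_targets, sequences=sequences,
        drug_genes=drug_gene, gene_go=gene_go, go_dag_edges=dag_edges,
        drug_side_effects=drug_se, drug_atc=drug_atc, associations=assoc,
    )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
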