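"""Synthetic raw-input generator with planted drug-disease structure.

Drugs and diseases are partitioned into clusters. Each cluster owns
prototype data for every modality — a fingerprint, a target-gene set, a
side-effect set, an ATC stem and target protein sequences — and each member
drug receives a noisy copy (bit flips, item drops/additions, residue point
mutations). True drug-disease associations are exactly the within-cluster
pairs; the visible association table additionally has each (disease, drug)
cell flipped with a small noise probability. The planted block structure is
therefore recoverable from every similarity network, and a fraction of true
pairs can be held out to test end-to-end recovery.

The generator targets testability, not realism: marginal statistics of real
drug databases (degree distributions, annotation sparsity patterns) are not
emulated.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .containers import DrugVocabulary

__all__ = ["SyntheticConfig", "SyntheticGroundTruth", "SyntheticBundle",
           "generate", "holdout", "write_bundle"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_ATC_LETTERS = "ABCDGHJLMNPRSV"


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults size the benchmark to desk scale."""

    n_drugs: int = 300
    n_genes: int = 400
    n_side_effects: int = 500
    n_diseases: int = 30
    n_clusters: int = 6
    within_cluster_edge_prob: float = 0.3
    between_cluster_edge_prob: float = 0.02
    association_noise: float = 0.05
    fingerprint_length: int = 166
    seq_length: tuple[int, int] = (80, 150)
    seed: int = 0
    # member-level noise rates
    bit_flip_prob: float = 0.05
    item_drop_prob: float = 0.2
    item_add_mean: float = 1.0
    seq_mut_within: float = 0.05
    seq_mut_between: float = 0.30
    targets_per_drug: int = 2
    genes_per_prototype: int = 8
    side_effects_per_prototype: int = 12

    def __post_init__(self) -> None:
        for name in ("within_cluster_edge_prob", "between_cluster_edge_prob",
                     "association_noise", "bit_flip_prob", "item_drop_prob",
                     "seq_mut_within", "seq_mut_between"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_clusters < 1:
            raise ValueError("need at least one cluster")
        for name in ("n_drugs", "n_genes", "n_side_effects", "n_diseases"):
            if getattr(self, name) < self.n_clusters:
                raise ValueError(f"{name} must be >= n_clusters")


@dataclass
class SyntheticGroundTruth:
    drug_cluster: dict[str, int]
    disease_cluster: dict[str, int]
    true_pairs: list[tuple[str, str]]  # (disease_id, drug_id), pre-noise


@dataclass
class SyntheticBundle:
    """All nine raw inputs, in memory, plus the generating configuration.

    ``cfg`` is None for bundles read back from disk by :mod:`drugrepo.io`.
    """

    cfg: SyntheticConfig | None
    vocabulary: DrugVocabulary
    disease_ids: tuple[str, ...]
    ddi_edges: list[tuple[str, str]]
    fingerprints: dict[str, np.ndarray]
    drug_targets: dict[str, list[str]]
    sequences: dict[str, str]
    drug_genes: list[tuple[str, str]]
    gene_go: dict[str, set[str]]
    go_dag_edges: list[tuple[str, str, str]]
    drug_side_effects: list[tuple[str, str]]
    drug_atc: dict[str, list[str]]
    associations: list[tuple[str, str]]  # (disease_id, drug_id), noisy/visible

    def gene_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for drug, gene in self.drug_genes:
            out.setdefault(drug, set()).add(gene)
        return out

    def side_effect_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for drug, se in self.drug_side_effects:
            out.setdefault(drug, set()).add(se)
        return out

    def target_sequences(self) -> dict[str, list[str]]:
        return {d: [self.sequences[a] for a in accs]
                for d, accs in self.drug_targets.items()}


def _mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        chars[i] = _AA[rng.integers(len(_AA))]
    return "".join(chars)


def _noisy_item_set(prototype: list[str], pool: list[str], cfg: SyntheticConfig,
                    rng: np.random.Generator) -> set[str]:
    kept = {it for it in prototype if rng.random() >= cfg.item_drop_prob}
    n_add = rng.poisson(cfg.item_add_mean)
    for _ in range(n_add):
        kept.add(pool[rng.integers(len(pool))])
    if not kept:  # guarantee at least one annotation per drug
        kept.add(prototype[rng.integers(len(prototype))])
    return kept


def generate(cfg: SyntheticConfig | None = None) -> tuple[SyntheticBundle, SyntheticGroundTruth]:
    """Generate the full raw input bundle; fully determined by ``cfg.seed``."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    K = cfg.n_clusters
    drugs = [f"D{i:04d}" for i in range(cfg.n_drugs)]
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    side_effects = [f"SE{i:04d}" for i in range(cfg.n_side_effects)]
    diseases = [f"DIS{i:03d}" for i in range(cfg.n_diseases)]
    vocab = DrugVocabulary.from_ids(drugs)
    drug_cluster = {d: i % K for i, d in enumerate(drugs)}
    disease_cluster = {d: i % K for i, d in enumerate(diseases)}

    # cluster resource pools (disjoint so the block structure is clean)
    gene_pools = [genes[c::K] for c in range(K)]
    se_pools = [side_effects[c::K] for c in range(K)]

    # --- prototypes per cluster
    fp_protos = rng.random((K, cfg.fingerprint_length)) < 0.3
    gene_protos = [list(rng.choice(pool, size=min(cfg.genes_per_prototype, len(pool)),
                                   replace=False)) for pool in gene_pools]
    se_protos = [list(rng.choice(pool, size=min(cfg.side_effects_per_prototype, len(pool)),
                                 replace=False)) for pool in se_pools]
    lo, hi = cfg.seq_length
    ancestors = ["".join(_AA[i] for i in rng.integers(len(_AA), size=rng.integers(lo, hi + 1)))
                 for _ in range(cfg.targets_per_drug)]
    seq_protos = [[_mutate_sequence(anc, cfg.seq_mut_between, rng) for anc in ancestors]
                  for _ in range(K)]
    atc_stems = []
    for c in range(K):
        letters = "".join(_AA[i] for i in rng.integers(len(_AA), size=2))
        atc_stems.append(f"{_ATC_LETTERS[c % len(_ATC_LETTERS)]}{c + 1:02d}"
                         f"{letters[0]}{letters[1]}")

    # --- member data
    fingerprints: dict[str, np.ndarray] = {}
    drug_targets: dict[str, list[str]] = {}
    sequences: dict[str, str] = {}
    drug_genes: list[tuple[str, str]] = []
    drug_side_effects: list[tuple[str, str]] = []
    drug_atc: dict[str, list[str]] = {}
    for d in drugs:
        c = drug_cluster[d]
        flips = rng.random(cfg.fingerprint_length) < cfg.bit_flip_prob
        fingerprints[d] = (fp_protos[c] ^ flips).astype(np.int8)
        accs = []
        for j, proto_seq in enumerate(seq_protos[c]):
            acc = f"{d}_T{j + 1}"
            accs.append(acc)
            sequences[acc] = _mutate_sequence(proto_seq, cfg.seq_mut_within, rng)
        drug_targets[d] = accs
        for g in sorted(_noisy_item_set(gene_protos[c], gene_pools[c], cfg, rng)):
            drug_genes.append((d, g))
        for se in sorted(_noisy_item_set(se_protos[c], se_pools[c], cfg, rng)):
            drug_side_effects.append((d, se))
        n_codes = 1 + int(rng.random() < 0.5)
        drug_atc[d] = [f"{atc_stems[c]}{rng.integers(100):02d}" for _ in range(n_codes)]

    # --- drug-drug interaction network
    ddi_edges: list[tuple[str, str]] = []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            p = (cfg.within_cluster_edge_prob if drug_cluster[a] == drug_cluster[b]
                 else cfg.between_cluster_edge_prob)
            if rng.random() < p:
                ddi_edges.append((a, b))

    # --- GO DAG: a root with one branch per cluster, two levels deep
    dag_edges: list[tuple[str, str, str]] = []
    branch_terms: list[list[str]] = []
    relations = ("is_a", "part_of")
    for c in range(K):
        head = f"GO:B{c}"
        dag_edges.append((head, "GO:ROOT", "is_a"))
        terms = []
        for m in range(4):
            mid = f"GO:B{c}M{m}"
            dag_edges.append((mid, head, relations[int(rng.random() < 0.3)]))
            terms.append(mid)
            for l in range(2):
                leaf = f"GO:B{c}M{m}L{l}"
                dag_edges.append((leaf, mid, relations[int(rng.random() < 0.3)]))
                terms.append(leaf)
        branch_terms.append(terms)
    gene_go: dict[str, set[str]] = {}
    for c, pool in enumerate(gene_pools):
        for g in pool:
            k = rng.integers(2, 5)
            gene_go[g] = set(rng.choice(branch_terms[c], size=k, replace=False))

    # --- associations: within-cluster pairs, then cell-level noise
    true_pairs = sorted(
        (dis, drug) for dis in diseases for drug in drugs
        if disease_cluster[dis] == drug_cluster[drug]
    )
    true_set = set(true_pairs)
    associations = []
    for dis in diseases:
        for drug in drugs:
            is_pos = (dis, drug) in true_set
            if rng.random() < cfg.association_noise:
                is_pos = not is_pos
            if is_pos:
                associations.append((dis, drug))

    bundle = SyntheticBundle(
        cfg=cfg, vocabulary=vocab, disease_ids=tuple(diseases),
        ddi_edges=ddi_edges, fingerprints=fingerprints,
        drug_targets=drug_targets, sequences=sequences,
        drug_genes=drug_genes, gene_go=gene_go, go_dag_edges=dag_edges,
        drug_side_effects=drug_side_effects, drug_atc=drug_atc,
        associations=associations,
    )
    truth = SyntheticGroundTruth(drug_cluster, disease_cluster, true_pairs)
    return bundle, truth


def holdout(pairs, fraction: float, seed: int) -> tuple[list, list]:
    """Split association pairs into (visible, hidden) for recovery testing."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    pairs = sorted(set(pairs))
    rng = np.random.default_rng(seed)
    n_hidden = int(round(fraction * len(pairs)))
    idx = rng.permutation(len(pairs))
    hidden = sorted(pairs[i] for i in idx[:n_hidden])
    visible = sorted(pairs[i] for i in idx[n_hidden:])
    return visible, hidden


def write_bundle(bundle: SyntheticBundle, outdir) -> dict[str, Path]:
    """Write every raw input in its interchange format, plus a manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def tsv(name: str, header: list[str], rows) -> None:
        p = out / name
        with open(p, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
        paths[name.split(".")[0]] = p

    tsv("drugs.tsv", ["drug_id"], [(d,) for d in bundle.vocabulary.ids])
    tsv("ddi.tsv", ["drug_id", "drug_id2"], bundle.ddi_edges)
    tsv("fingerprints.tsv", ["drug_id", "bits"],
        [(d, "".join(map(str, bundle.fingerprints[d]))) for d in bundle.vocabulary.ids])
    tsv("drug_targets.tsv", ["drug_id", "accession"],
        [(d, a) for d in bundle.vocabulary.ids for a in bundle.drug_targets[d]])
    tsv("gene_go.tsv", ["gene", "go_term"],
        [(g, t) for g in sorted(bundle.gene_go) for t in sorted(bundle.gene_go[g])])
    tsv("go_dag.tsv", ["child", "parent", "relation"], bundle.go_dag_edges)
    tsv("atc.tsv", ["drug_id", "atc_code"],
        [(d, c) for d in bundle.vocabulary.ids for c in bundle.drug_atc[d]])
    tsv("drug_gene.tsv", ["drug_id", "gene"], bundle.drug_genes)
    tsv("drug_sideeffect.tsv", ["drug_id", "side_effect"], bundle.drug_side_effects)
    tsv("drug_disease.tsv", ["disease_id", "drug_id"], bundle.associations)
    fasta = out / "targets.fasta"
    with open(fasta, "w") as fh:
        for acc in sorted(bundle.sequences):
            fh.write(f">{acc}\n{bundle.sequences[acc]}\n")
    paths["targets"] = fasta
    manifest = out / "manifest.json"
    cfg = asdict(bundle.cfg)
    cfg["seq_length"] = list(cfg["seq_length"])
    manifest.write_text(json.dumps({"config": cfg, "seed": bundle.cfg.seed}, indent=2))
    paths["manifest"] = manifest
    return paths
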