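"""End-to-end pipeline orchestration with per-stage caching.

Stages run in order: similarity -> embed -> fuse -> predict -> evaluate.
Each stage writes its outputs plus a marker file holding a hash of the
stage's configuration and its upstream state; a rerun with identical
config and inputs skips completed stages, while deleting a stage's cache
(or changing its config) recomputes that stage and everything downstream.
A run manifest (config snapshot, input hashes, stage timings, version)
is written at the end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .containers import AssociationMatrix, BipartiteNetwork, DrugVocabulary, \
    FusedFeatures, HomogeneousNetwork, PPMIMatrix
from .embedding import RandomWalkConfig, embed_all
from .evaluation import cross_validate
from .fusion import MAEConfig, build_mae, extract_features, scale_inputs, train_mae
from .gosim import GoDag, make_drug_go_measure
from .io import INPUT_FILES, file_sha256, read_inputs
from .predictor import LossWeights, WVAEConfig, build_wvae, predict, save_wvae, \
    train_wvae
from .similarity import AlignmentScoring, atc_similarity, build_similarity_network, \
    set_tanimoto, tanimoto, target_similarity
from .synthetic import SyntheticBundle

__all__ = ["EvalSettings", "PipelineConfig", "build_networks", "run_pipeline"]

logger = logging.getLogger(__name__)

STAGES = ("similarity", "embed", "fuse", "predict", "evaluate")


@dataclass(frozen=True)
class EvalSettings:
    folds: int = 5
    split_ratio: float = 0.8
    negative_ratio: float = 1.0


@dataclass
class PipelineConfig:
    """Paths plus the configuration of every stage; one global seed.

    Stage seeds are derived from the global seed unless a stage config sets
    its own explicitly (sub-config dataclasses carry their seed fields).
    """

    input_dir: Path | None = None
    output_dir: Path | None = None
    seed: int = 0
    random_walk: RandomWalkConfig = field(default_factory=RandomWalkConfig)
    rwr_on_bipartite: bool = True
    mae: MAEConfig | None = None
    weights: LossWeights = field(default_factory=LossWeights)
    wvae: WVAEConfig | None = None
    evaluation: EvalSettings = field(default_factory=EvalSettings)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)

    def __post_init__(self) -> None:
        if self.input_dir is not None:
            self.input_dir = Path(self.input_dir)
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)
        if self.mae is None:
            self.mae = MAEConfig(seed=self.seed)
        if self.wvae is None:
            self.wvae = WVAEConfig(seed=self.seed + 1)

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, value in (overrides or {}).items():
            section = raw
            *parents, leaf = key.split(".")
            for p in parents:
                section = section.setdefault(p, {})
            section[leaf] = value
        sub = {
            "random_walk": RandomWalkConfig,
            "mae": MAEConfig,
            "weights": LossWeights,
            "wvae": WVAEConfig,
            "evaluation": EvalSettings,
            "scoring": AlignmentScoring,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in sub and isinstance(value, dict):
                kwargs[key] = sub[key](**value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, tuple):
                return list(obj)
            return obj
        return {f.name: conv(getattr(self, f.name)) for f in dataclasses.fields(self)}


# ---------------------------------------------------------------------------
# stage computations


def build_networks(bundle: SyntheticBundle, scoring: AlignmentScoring | None = None):
    """Assemble the six homogeneous and three bipartite input networks."""
    vocab = bundle.vocabulary
    n = len(vocab)
    adj = np.zeros((n, n))
    for a, b in bundle.ddi_edges:
        i, j = vocab.position(a), vocab.position(b)
        adj[i, j] = adj[j, i] = 1.0
    interaction = HomogeneousNetwork(adj, vocab, kind="interaction", is_similarity=False)
    chemical = build_similarity_network(vocab, bundle.fingerprints, tanimoto, kind="chemical")
    se_sim = build_similarity_network(vocab, bundle.side_effect_sets(), set_tanimoto,
                                      kind="side_effect")
    scoring = scoring or AlignmentScoring()
    target = build_similarity_network(
        vocab, bundle.target_sequences(),
        lambda a, b: target_similarity(a, b, scoring), kind="target_sequence")
    dag = GoDag.from_edge_list(bundle.go_dag_edges)
    go_net = build_similarity_network(vocab, bundle.gene_sets(),
                                      make_drug_go_measure(bundle.gene_go, dag), kind="go")
    atc_net = build_similarity_network(vocab, bundle.drug_atc, atc_similarity, kind="atc")

    def bipartite(pairs, kind, col=1, row=0):
        entities = tuple(sorted({p[col] for p in pairs}))
        eidx = {e: i for i, e in enumerate(entities)}
        m = np.zeros((n, len(entities)))
        for p in pairs:
            m[vocab.position(p[row]), eidx[p[col]]] = 1.0
        return BipartiteNetwork(m, vocab, entities, kind=kind)

    gene_bn = bipartite(bundle.drug_genes, "drug_gene")
    se_bn = bipartite(bundle.drug_side_effects, "drug_side_effect")
    dis_bn = bipartite([(d, dis) for dis, d in bundle.associations], "drug_disease")
    homogeneous = [interaction, chemical, se_sim, target, go_net, atc_net]
    return homogeneous, [gene_bn, se_bn, dis_bn]


# ---------------------------------------------------------------------------
# caching helpers


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class _StageCache:
    def __init__(self, outdir: Path):
        self.outdir = outdir

    def marker(self, stage: str) -> Path:
        return self.outdir / f".stage_{stage}.json"

    def is_fresh(self, stage: str, state_hash: str, outputs: list[Path]) -> bool:
        m = self.marker(stage)
        if not m.exists() or not all(p.exists() for p in outputs):
            return False
        try:
            return json.loads(m.read_text()).get("hash") == state_hash
        except json.JSONDecodeError:
            return False

    def commit(self, stage: str, state_hash: str) -> None:
        self.marker(stage).write_text(json.dumps({"hash": state_hash}))


def _write_matrix_tsv(path: Path, matrix: np.ndarray, columns) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in matrix:
            fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def _read_matrix_tsv(path: Path) -> tuple[np.ndarray, list[str]]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        m = np.loadtxt(fh, delimiter="\t", ndmin=2)
    return m, header


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages with caching; returns a summary dict.

    The summary contains the evaluation report, the path of every artifact
    and the run manifest. Identical config + inputs reproduce identical
    outputs bit for bit on the same platform.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(out / "run.log")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logging.getLogger("drugrepo").addHandler(log_handler)
    cache = _StageCache(out)
    timings: dict[str, float] = {}
    input_hashes = {k: file_sha256(cfg.input_dir / f)
                    for k, f in INPUT_FILES.items()}
    bundle = read_inputs(cfg.input_dir)
    vocab = bundle.vocabulary
    upstream = _hash(input_hashes)
    recomputed = False

    # -- similarity ---------------------------------------------------------
    state = _hash([upstream, dataclasses.asdict(cfg.scoring)])
    net_path = out / "networks.npz"
    t0 = time.perf_counter()
    if not recomputed and cache.is_fresh("similarity", state, [net_path]):
        data = np.load(net_path)
        kinds = list(data["kinds"])
        homogeneous = [HomogeneousNetwork(data[f"h{i}"], vocab, kind=k,
                                          is_similarity=(k != "interaction"))
                       for i, k in enumerate(kinds[:6])]
        bip_entities = json.loads(str(data["entities"]))
        bipartite = [BipartiteNetwork(data[f"b{i}"], vocab, tuple(bip_entities[i]),
                                      kind=k) for i, k in enumerate(kinds[6:])]
    else:
        homogeneous, bipartite = build_networks(bundle, cfg.scoring)
        arrays = {f"h{i}": net.matrix for i, net in enumerate(homogeneous)}
        arrays.update({f"b{i}": bn.matrix for i, bn in enumerate(bipartite)})
        arrays["kinds"] = np.array([n.kind for n in homogeneous + bipartite])
        arrays["entities"] = np.array(json.dumps([list(b.entity_ids) for b in bipartite]))
        np.savez_compressed(net_path, **arrays)
        cache.commit("similarity", state)
        recomputed = True
    timings["similarity"] = time.perf_counter() - t0
    upstream = state

    # -- embed --------------------------------------------------------------
    state = _hash([upstream, dataclasses.asdict(cfg.random_walk), cfg.rwr_on_bipartite])
    ppmi_path = out / "ppmi.npz"
    t0 = time.perf_counter()
    if not recomputed and cache.is_fresh("embed", state, [ppmi_path]):
        data = np.load(ppmi_path)
        ppmis = [PPMIMatrix(data[f"p{i}"], source_kind=str(k))
                 for i, k in enumerate(data["kinds"])]
    else:
        ppmis = embed_all(homogeneous + bipartite, cfg.random_walk, cfg.rwr_on_bipartite)
        arrays = {f"p{i}": p.matrix for i, p in enumerate(ppmis)}
        arrays["kinds"] = np.array([p.source_kind for p in ppmis])
        np.savez_compressed(ppmi_path, **arrays)
        cache.commit("embed", state)
        recomputed = True
    timings["embed"] = time.perf_counter() - t0
    upstream = state

    # -- fuse ---------------------------------------------------------------
    state = _hash([upstream, dataclasses.asdict(cfg.mae)])
    feat_path = out / "features.tsv"
    t0 = time.perf_counter()
    if not recomputed and cache.is_fresh("fuse", state, [feat_path]):
        fmat, _ = _read_matrix_tsv(feat_path)
        features = FusedFeatures(fmat, vocab)
    else:
        scaled, _ = scale_inputs(ppmis)
        mae = build_mae(cfg.mae, len(scaled), len(vocab))
        train_mae(mae, scaled)
        features = extract_features(mae, scaled, vocab)
        _write_matrix_tsv(feat_path, features.matrix,
                          [f"f{i}" for i in range(features.dim)])
        cache.commit("fuse", state)
        recomputed = True
    timings["fuse"] = time.perf_counter() - t0
    upstream = state

    # -- predict ------------------------------------------------------------
    X = AssociationMatrix.from_pairs(bundle.associations, bundle.disease_ids, vocab)
    state = _hash([upstream, dataclasses.asdict(cfg.wvae), dataclasses.asdict(cfg.weights)])
    pred_path = out / "predictions.tsv"
    t0 = time.perf_counter()
    if recomputed or not cache.is_fresh("predict", state, [pred_path]):
        model = build_wvae(len(vocab), features, cfg.wvae)
        train_wvae(model, X, cfg.weights)
        save_wvae(model, out / "model", cfg.weights)
        with open(pred_path, "w") as fh:
            fh.write("disease_id\tdrug_id\tscore\trank\tknown\n")
            for i, dis in enumerate(X.disease_ids):
                table = predict(model, X.matrix[i], vocab, disease_id=dis)
                for d, g, s, r, known in table.rows:
                    fh.write(f"{d}\t{g}\t{s:.8f}\t{r}\t{int(known)}\n")
        cache.commit("predict", state)
        recomputed = True
    timings["predict"] = time.perf_counter() - t0
    upstream = state

    # -- evaluate -----------------------------------------------------------
    state = _hash([upstream, dataclasses.asdict(cfg.evaluation), cfg.seed])
    eval_path = out / "evaluation.json"
    t0 = time.perf_counter()
    if recomputed or not cache.is_fresh("evaluate", state, [eval_path]):
        report = cross_validate(features, bundle.associations, bundle.disease_ids,
                                folds=cfg.evaluation.folds, seed=cfg.seed,
                                weights=cfg.weights, wvae_cfg=cfg.wvae)
        eval_path.write_text(json.dumps(report.to_dict(), indent=2))
        report.to_tsv(out / "evaluation.tsv")
        cache.commit("evaluate", state)
    report_dict = json.loads(eval_path.read_text())
    timings["evaluate"] = time.perf_counter() - t0

    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "input_hashes": input_hashes,
        "stage_timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    tmp = out / "manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    tmp.replace(out / "manifest.json")  # atomic final write
    logger.info("stage timings (s): %s", manifest["stage_timings_s"])
    logging.getLogger("drugrepo").removeHandler(log_handler)
    log_handler.close()
    return {
        "evaluation": report_dict,
        "predictions": pred_path,
        "features": feat_path,
        "manifest": out / "manifest.json",
    }
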