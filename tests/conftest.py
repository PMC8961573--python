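"""Shared fixtures.

Two tiers: a small synthetic bundle for cheap structural tests, and the
full default benchmark (300 drugs, 30 diseases, 6 clusters, seed 7) whose
expensive stages — similarity networks, PPMI embedding, fusion training —
are computed once per session and shared by the training-behaviour and
end-to-end tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from drugrepo.containers import DrugVocabulary, FusedFeatures
from drugrepo.embedding import embed_all
from drugrepo.fusion import MAEConfig, build_mae, extract_features, scale_inputs, train_mae
from drugrepo.pipeline import build_networks
from drugrepo.synthetic import SyntheticConfig, generate

SMALL_CFG = SyntheticConfig(
    n_drugs=48, n_genes=60, n_side_effects=80, n_diseases=12, n_clusters=4,
    seq_length=(40, 60), seed=11,
)

BENCH_CFG = SyntheticConfig(seed=7)  # the default study conditions
BENCH_MAE_CFG = MAEConfig(seed=7)


@pytest.fixture(scope="session")
def small_bundle():
    return generate(SMALL_CFG)


@pytest.fixture(scope="session")
def small_networks(small_bundle):
    bundle, _ = small_bundle
    return build_networks(bundle)


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(1234)


@pytest.fixture()
def tiny_vocab():
    return DrugVocabulary.from_ids([f"D{i}" for i in range(6)])


@pytest.fixture()
def tiny_features(tiny_vocab):
    gen = np.random.default_rng(5)
    return FusedFeatures(gen.normal(size=(6, 3)), tiny_vocab)


# --- benchmark tier (shared across the heavy tests) ------------------------


@pytest.fixture(scope="session")
def bench_bundle():
    return generate(BENCH_CFG)


@pytest.fixture(scope="session")
def bench_scaled(bench_bundle):
    bundle, _ = bench_bundle
    homogeneous, bipartite = build_networks(bundle)
    ppmis = embed_all(homogeneous + bipartite)
    scaled, _ = scale_inputs(ppmis)
    return scaled


@pytest.fixture(scope="session")
def bench_fusion(bench_bundle, bench_scaled):
    """Trained fusion autoencoder on the benchmark: (model, history, features)."""
    bundle, _ = bench_bundle
    model = build_mae(BENCH_MAE_CFG, len(bench_scaled), len(bundle.vocabulary))
    history = train_mae(model, bench_scaled)
    features = extract_features(model, bench_scaled, bundle.vocabulary)
    return model, history, features
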