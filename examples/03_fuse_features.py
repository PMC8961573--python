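"""Fuse nine PPMI matrices into drug features with the multimodal autoencoder.

Trains a small fusion autoencoder on a 40-drug synthetic bundle and checks
that the learned bottleneck features cluster drugs the way the planted
structure does (centred cosine similarity within vs between clusters).
"""

import numpy as np

from drugrepo import (
    MAEConfig, SyntheticConfig, build_mae, embed_all, extract_features,
    generate, scale_inputs, train_mae,
)
from drugrepo.pipeline import build_networks

cfg = SyntheticConfig(n_drugs=40, n_genes=60, n_side_effects=60, n_diseases=8,
                      n_clusters=4, seq_length=(40, 60), seed=1)
bundle, truth = generate(cfg)
homogeneous, bipartite = build_networks(bundle)
ppmis = embed_all(homogeneous + bipartite)
scaled, _ = scale_inputs(ppmis)

mae_cfg = MAEConfig(per_network_hidden=32, joint_hidden=64, embedding_dim=16,
                    epochs=100, seed=1)
model = build_mae(mae_cfg, len(scaled), len(bundle.vocabulary))
history = train_mae(model, scaled)
features = extract_features(model, scaled, bundle.vocabulary)

print(f"reconstruction loss: {history.total[0]:.3f} (epoch 1) "
      f"-> {history.total[-1]:.3f} (epoch {mae_cfg.epochs})")
print(f"feature matrix: {features.matrix.shape}")

F = features.matrix - features.matrix.mean(axis=0)
F = F / (np.linalg.norm(F, axis=1, keepdims=True) + 1e-12)
cos = F @ F.T
cluster = np.array([truth.drug_cluster[d] for d in bundle.vocabulary.ids])
same = cluster[:, None] == cluster[None, :]
off = ~np.eye(len(cluster), dtype=bool)
print(f"mean feature cosine within clusters:  {cos[same & off].mean():.3f}")
print(f"mean feature cosine between clusters: {cos[~same].mean():.3f}")
# A positive within / negative between contrast means the bottleneck fused
# the nine evidence channels into a geometry that mirrors the planted drug
# classes — exactly what the association predictor needs as ground metric.
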