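"""Evaluation protocol: 80:20 split, five-fold cross-validation, AUROC.

Known drug-disease pairs are the positives; negatives are sampled 1:1 from
unobserved (disease, drug) pairs — a standard link-prediction convention
with the usual caveat that unobserved pairs may hide true associations, so
measured AUROC is conservative. The AUROC statistic is the Mann-Whitney
probability that a random positive outscores a random negative, with ties
counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .containers import AssociationMatrix, DrugVocabulary, FusedFeatures
from .predictor import LossWeights, WVAEConfig, build_wvae, predict, train_wvae

__all__ = [
    "SplitPlan",
    "EvaluationReport",
    "split_pairs",
    "auroc",
    "kfold_partition",
    "sample_negatives",
    "permute_pairs",
    "cross_validate",
    "rank_report",
]

Pair = tuple[str, str]  # (disease_id, drug_id)


@dataclass
class SplitPlan:
    """Disjoint train/test positives with matched sampled negatives."""

    train_pos: list[Pair]
    test_pos: list[Pair]
    train_neg: list[Pair]
    test_neg: list[Pair]
    seed: int


@dataclass
class EvaluationReport:
    """Per-fold train/test AUROC with summary statistics."""

    train_aurocs: list[float]
    test_aurocs: list[float]
    n_positives: int
    n_negatives: int
    seed: int

    @property
    def train_mean(self) -> float:
        return float(np.mean(self.train_aurocs))

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_aurocs))

    @property
    def train_sd(self) -> float:
        return float(np.std(self.train_aurocs, ddof=1))

    @property
    def test_sd(self) -> float:
        return float(np.std(self.test_aurocs, ddof=1))

    def to_tsv(self, path) -> None:
        """Per-fold TSV report (one row per fold, then the summary row)."""
        with open(path, "w") as fh:
            fh.write("fold\ttrain_auroc\ttest_auroc\n")
            for i, (tr, te) in enumerate(zip(self.train_aurocs, self.test_aurocs), 1):
                fh.write(f"{i}\t{tr:.6f}\t{te:.6f}\n")
            fh.write(f"mean\t{self.train_mean:.6f}\t{self.test_mean:.6f}\n")
            fh.write(f"sd\t{self.train_sd:.6f}\t{self.test_sd:.6f}\n")

    def to_dict(self) -> dict:
        return {
            "train_aurocs": self.train_aurocs,
            "test_aurocs": self.test_aurocs,
            "train_mean": self.train_mean,
            "train_sd": self.train_sd,
            "test_mean": self.test_mean,
            "test_sd": self.test_sd,
            "n_positives": self.n_positives,
            "n_negatives": self.n_negatives,
            "seed": self.seed,
        }


def sample_negatives(n: int, positives, disease_ids, vocabulary: DrugVocabulary,
                     rng: np.random.Generator) -> list[Pair]:
    """Sample ``n`` unobserved (disease, drug) pairs uniformly without replacement."""
    disease_ids = list(disease_ids)
    pos = set(positives)
    universe = len(disease_ids) * len(vocabulary)
    if universe - len(pos) < n:
        raise ValueError("not enough unobserved pairs to sample negatives")
    out: set[Pair] = set()
    while len(out) < n:
        di = rng.integers(len(disease_ids), size=n - len(out))
        dj = rng.integers(len(vocabulary), size=n - len(out))
        for a, b in zip(di, dj):
            pair = (disease_ids[a], vocabulary.ids[b])
            if pair not in pos and pair not in out:
                out.add(pair)
                if len(out) == n:
                    break
    return sorted(out)


def split_pairs(positives, disease_ids, vocabulary: DrugVocabulary,
                ratio: float = 0.8, seed: int = 0,
                negative_ratio: float = 1.0) -> SplitPlan:
    """Stratified-by-disease 80:20 split of positive pairs.

    The overall test count is round((1 - ratio) * N); per-disease quotas use
    largest-remainder allocation so stratification and the exact overall
    ratio hold simultaneously. Negatives are sampled ``negative_ratio``:1
    from unobserved pairs, separately for each partition.
    """
    positives = list(positives)
    if len(positives) < 5:
        raise ValueError("need at least 5 positive pairs to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    by_disease: dict[str, list[Pair]] = {}
    for pair in positives:
        by_disease.setdefault(pair[0], []).append(pair)
    n_test_total = int(round((1.0 - ratio) * len(positives)))
    quotas = {}
    fracs = []
    for dis in sorted(by_disease):
        exact = (1.0 - ratio) * len(by_disease[dis])
        quotas[dis] = int(np.floor(exact))
        fracs.append((exact - np.floor(exact), dis))
    remainder = n_test_total - sum(quotas.values())
    for _, dis in sorted(fracs, key=lambda t: (-t[0], t[1]))[:max(remainder, 0)]:
        quotas[dis] += 1
    train_pos: list[Pair] = []
    test_pos: list[Pair] = []
    for dis in sorted(by_disease):
        pairs = sorted(by_disease[dis])
        rng.shuffle(pairs)
        test_pos.extend(pairs[:quotas[dis]])
        train_pos.extend(pairs[quotas[dis]:])
    n_train_neg = int(round(negative_ratio * len(train_pos)))
    n_test_neg = int(round(negative_ratio * len(test_pos)))
    train_neg = sample_negatives(n_train_neg, positives, disease_ids, vocabulary, rng)
    taken = set(positives) | set(train_neg)
    test_neg = sample_negatives(n_test_neg, taken, disease_ids, vocabulary, rng)
    return SplitPlan(sorted(train_pos), sorted(test_pos), train_neg, test_neg, seed)


def auroc(scores, labels) -> float:
    """Mann-Whitney AUROC: P(random positive outscores random negative)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    pos = y.astype(bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def kfold_partition(items, folds: int, seed: int) -> list[list]:
    """Seeded disjoint partition into ``folds`` near-equal parts."""
    items = list(items)
    if folds < 2 or folds > len(items):
        raise ValueError("folds must lie in [2, n_items]")
    rng = np.random.default_rng(seed)
    order = list(items)
    rng.shuffle(order)
    return [order[i::folds] for i in range(folds)]


def permute_pairs(positives, disease_ids, vocabulary: DrugVocabulary,
                  seed: int) -> list[Pair]:
    """Label-permutation null: re-draw each positive's drug uniformly.

    Keeps the per-disease positive counts but destroys any drug-disease
    structure, so a sound evaluation should score near AUROC 0.5.
    """
    rng = np.random.default_rng(seed)
    out: set[Pair] = set()
    for dis, _ in positives:
        while True:
            pair = (dis, vocabulary.ids[rng.integers(len(vocabulary))])
            if pair not in out:
                out.add(pair)
                break
    return sorted(out)


def _score_pairs(model, X_train: AssociationMatrix, pairs) -> np.ndarray:
    """Score (disease, drug) pairs by reconstructing each disease's row."""
    didx = {d: i for i, d in enumerate(X_train.disease_ids)}
    rows_needed = sorted({didx[d] for d, _ in pairs})
    recon = model.reconstruct(X_train.matrix[rows_needed])
    row_of = {r: k for k, r in enumerate(rows_needed)}
    return np.array([
        recon[row_of[didx[d]], X_train.vocabulary.position(g)] for d, g in pairs
    ])


def cross_validate(features: FusedFeatures, positives, disease_ids,
                   folds: int = 5, seed: int = 0,
                   weights: LossWeights | None = None,
                   wvae_cfg: WVAEConfig | None = None) -> EvaluationReport:
    """Five-fold cross-validation of the association predictor.

    Positives are partitioned into disjoint folds; for each fold the model
    is trained on the remaining folds' association matrix and held-out
    positives are scored against freshly sampled unobserved negatives
    (1:1). Train AUROC uses the training positives against their own
    negative sample.
    """
    weights = weights or LossWeights()
    wvae_cfg = wvae_cfg or WVAEConfig()
    positives = sorted(set(positives))
    disease_ids = list(disease_ids)
    vocab = features.vocabulary
    if len(positives) < folds:
        raise ValueError("need at least one positive per fold")
    fold_lists = kfold_partition(positives, folds, seed)
    rng = np.random.default_rng(seed + 1)
    train_aurocs: list[float] = []
    test_aurocs: list[float] = []
    n_neg_total = 0
    for f, test_pos in enumerate(fold_lists):
        train_pos = sorted(set(positives) - set(test_pos))
        X_train = AssociationMatrix.from_pairs(train_pos, disease_ids, vocab)
        cfg = WVAEConfig(**{**wvae_cfg.__dict__, "seed": wvae_cfg.seed + f})
        model = build_wvae(len(vocab), features, cfg)
        train_wvae(model, X_train, weights)
        test_neg = sample_negatives(len(test_pos), positives, disease_ids, vocab, rng)
        train_neg = sample_negatives(len(train_pos), set(positives) | set(test_neg),
                                     disease_ids, vocab, rng)
        n_neg_total += len(test_neg) + len(train_neg)
        for pos, neg, store in ((train_pos, train_neg, train_aurocs),
                                (test_pos, test_neg, test_aurocs)):
            scores = np.concatenate([
                _score_pairs(model, X_train, pos),
                _score_pairs(model, X_train, neg),
            ])
            labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
            store.append(auroc(scores, labels))
    return EvaluationReport(train_aurocs, test_aurocs, len(positives), n_neg_total, seed)


def rank_report(model, X: AssociationMatrix, disease_id: str, top_k: int,
                novel_only: bool = False):
    """Top-k ranked candidates for one disease; known positives are flagged.

    With ``novel_only`` the known positives are dropped before slicing, so
    the table lists repositioning candidates only.
    """
    if disease_id not in X.disease_ids:
        raise KeyError(f"unknown disease: {disease_id!r}")
    i = X.disease_ids.index(disease_id)
    table = predict(model, X.matrix[i], X.vocabulary, disease_id=disease_id)
    return table.top(top_k, novel_only=novel_only)
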