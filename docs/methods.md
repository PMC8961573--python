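# Methods

## Overview

The package scores drug–disease associations by fusing heterogeneous drug
evidence into one low-dimensional feature space and reconstructing
disease-wise association vectors with a variational autoencoder trained
under a composite loss whose data term is an entropic optimal-transport
(Wasserstein) discrepancy. It proceeds in four stages:

1. **Network construction.** Nine drug-centric networks over one shared
   vocabulary of n drugs: a binary drug–drug interaction network; five
   drug–drug similarity networks (chemical structure, side-effect profile,
   target sequence, biological function, therapeutic class); and three
   drug–entity bipartite networks (genes, side effects, diseases).
2. **Network representation.** Each network becomes a positive
   pointwise-mutual-information (PPMI) matrix via a restart random walk.
3. **Fusion.** A multimodal autoencoder with one encoder branch per network
   and a shared bottleneck yields an n × d drug-feature matrix F.
4. **Prediction.** A variational autoencoder consumes one disease at a time
   as a 0/1 row vector over drugs and reconstructs per-drug association
   scores in [0, 1], conditioned on F in both its encoder and decoder.

## Similarity measures

- **Chemical / side-effect**: Tanimoto coefficient T = c/(a + b − c), with
  a, b the set-bit (or annotation) counts of the two drugs and c the shared
  count. Two empty profiles score 0: a 0/0 ratio carries no evidence of
  similarity, and a zero keeps the matrix well defined.
- **Target sequence**: Smith–Waterman local alignment (BLOSUM62, affine
  gaps costing 10 + (L−1)·1), normalised as SW(a,b)/√(SW(a,a)·SW(b,b)) so
  self-similarity is 1 and scores are length-comparable; drug-level
  similarity is the mean over the Cartesian product of the two drugs'
  target sequences. Alignment is delegated to Biopython's `PairwiseAligner`
  and checked in the test suite against an independent Gotoh dynamic
  program.
- **Biological function**: Wang's graph-based GO semantic similarity.
  S-values decay along the DAG with per-relation weights (is_a 0.8,
  part_of 0.6); term pairs combine S-values over common ancestors,
  gene pairs combine terms by best-match average, and the drug-level score
  is the mean over all target-gene pairs. The measure and its combination
  strategy follow the defaults of the GOSemSim family of tools.
- **Therapeutic class**: per ATC code pair, (number of leading matched
  levels)/5; multiple codes per drug are combined by the mean over code
  pairs (configurable to max).
- **Bipartite → drug–drug**: Jaccard coefficient |A∩B|/|A∪B| of incidence
  rows.

Drugs lacking data for a modality keep their row (all zeros, logged) so a
single vocabulary indexes every matrix; dropping them instead would
misalign the downstream feature rows.

## Random-walk PPMI representation

The adjacency is row-normalised into a transition matrix M (all-zero rows
become uniform so isolated drugs stay stochastic). From each start node i
the restart walk p_k = ω·p_{k−1}M + (1−ω)·p_0 is propagated for k steps and
the visit distributions are accumulated into a co-occurrence matrix C whose
row i sums to k. The walk is propagated *in closed form on distributions*
rather than by sampling vertex sequences: this computes exactly the
co-occurrence expectations that sampled walks estimate, and is
deterministic. The PPMI transform is

    PPMI(i,j) = max( log( C(i,j) · T / (rowsum_i · colsum_j) ), 0 ),  T = ΣC.

Defaults ω = 0.5, k = 3 follow the deepNF construction of the same
representation; both are configurable. Bipartite networks are first
collapsed by the Jaccard transform and then treated identically (a config
flag can skip the walk for them).

## Fusion autoencoder

Per-network encoders (n → 256, sigmoid) feed a concatenation, a joint
layer (→ 512, sigmoid, dropout 0.1), and a sigmoid embedding layer
(→ d = 128) that is mirrored by the decoder into one sigmoid
reconstruction head per network. Inputs are min–max scaled to [0, 1] per
network — matched to the sigmoid heads — and training minimises the summed
per-network binary cross-entropy with minibatch Adam (lr 1e−3, batch 32,
200 epochs, seeded Glorot initialisation). The published description of
this fusion step fixes none of these sizes; the defaults follow deepNF's
shapes at desk scale and are exposed in `MAEConfig`.

The autoencoders are implemented directly in NumPy (hand-derived backward
passes, verified against central finite differences in the test suite) with
a shared Adam optimiser; training is bit-reproducible for a fixed seed on
one platform.

## Transport-loss variational autoencoder

Input: one disease row x ∈ {0,1}^n. Encoder: the concatenation of a
feature pooling x·F and a learned linear map of x passes through a tanh
hidden layer (256, dropout 0.1) to a diagonal Gaussian (μ, σ) in a
32-dimensional latent space; z is reparameterised as μ + σ·ε. Decoder:
z → tanh layer → length-d vector h → scores x̂ = sigmoid(h·Fᵀ + bias). How
drug features should enter this model is genuinely open; conditioning both
the encoder (pooling) and the decoder (feature-inner-product readout) is
the reading implemented here, and it is what lets scores generalise across
drugs with similar fused features. F is z-scored per dimension inside the
model: the fusion bottleneck's sigmoid units carry their information on
small variations around large per-dimension offsets, and standardisation
restores a discriminative geometry for both the readout and the transport
ground cost.

Per row, the training objective is

    total = W(x, x̂) + α · KL( N(μ,σ) ‖ N(0,I) ) + 0.1 · BCE(x, x̂)

with α = 0.1 by default and both regularisers in their standard
non-negative orientation (the minimiser of the composite loss needs the
KL and cross-entropy proper, not their negations). The Wasserstein term
treats x and x̂ (each normalised to a distribution over drugs; an all-zero
row falls back to uniform with a warning) as marginals of an entropic
optimal-transport problem whose ground cost is the squared Euclidean
distance between fused feature rows. An alternative `diagonal` mode fixes
the coupling to the identity, collapsing the term to the mean squared
per-drug difference (algebraically equal to twice the halved-MSE loss);
it is the literal same-index reading of the geometry distance and is kept
as a cheap ablation.

### Sinkhorn solver

Entropic OT is solved two ways. `sinkhorn_plan` is a log-domain
(logsumexp) solver for a single marginal pair: stable at small ε
(tolerance 1e−9, 1000 iterations, warning + best iterate on
non-convergence), used for the public loss API and validated against an
exact linear program on small problems. Training uses `SinkhornKernel`, a
kernel-domain batched solver that shares one Gibbs kernel K = exp(−C/ε)
across all disease rows; each sweep is two dense (batch × n)(n × n)
products, which makes the per-epoch transport cost negligible. For
training, C is normalised by its mean so that ε (default 0.1) is a
dimensionless regularisation strength independent of the feature dimension;
the kernel stays inside float64 range by construction. Gradients with
respect to x̂ use the envelope theorem: the derivative of the entropic OT
value in the target marginal is the converged dual potential (centred to
the simplex tangent), chained through the normalisation and the sigmoid.
The finite-difference agreement of this gradient is tested.

Training is full-batch Adam (lr 1e−3, 300 epochs) — the benchmark has 30
disease rows, far below the full-batch threshold of 512. Inference is
deterministic: dropout off and z = μ. An optional warm-up
(`pretrain_epochs`) first fits the plain mean-squared reconstruction
before switching on the transport term.

## Evaluation protocol

Known (disease, drug) pairs are positives. Negatives are sampled 1:1 from
unobserved pairs — the standard link-prediction convention; unobserved
pairs may hide true associations, so measured AUROC is conservative, and
this caveat is inherited by every number the package reports. Two
protocols are provided: a stratified-by-disease 80:20 split
(largest-remainder quotas make stratification and the exact overall ratio
hold simultaneously) and five-fold cross-validation (seeded disjoint
partition of positives; per fold, the model trains on the remaining folds'
association matrix and scores held-out positives against freshly sampled
negatives). AUROC is the Mann–Whitney statistic with ties counted ½,
tested against exhaustive pair counting. A label-permutation control
(re-drawing each positive's drug uniformly, preserving per-disease counts)
must score at chance.

## Synthetic benchmark

The generator plants six clusters over 300 drugs and 30 diseases. Each
cluster owns prototype data per modality — fingerprint (Bernoulli 0.3
bits), target-gene and side-effect sets drawn from cluster-disjoint pools,
an ATC stem with a distinct anatomical letter, and target protein
sequences derived from shared ancestors mutated at 30% — and members are
noisy copies: 5% bit flips, 20% item drops plus Poisson(1) additions from
the cluster pool, 5% residue mutations. The interaction network has
within/between edge probabilities 0.3/0.02. True associations are exactly
the within-cluster (disease, drug) pairs; the visible table flips each
cell with probability 0.05. Sequences are 80–150 residues. These defaults
keep every stage's signal recoverable while the full pipeline runs in
minutes on one CPU; all randomness flows from a single seed and identical
seeds reproduce byte-identical files.

What the generator does *not* emulate: real-database marginal statistics —
degree distributions, annotation sparsity, correlated modality
missingness, or shared targets between drugs of different classes. Passing
the recovery tests therefore demonstrates that the pipeline's machinery
can extract planted multi-modal structure, not that it reproduces any
specific literature result on proprietary database snapshots.

## Numerical choices and degenerate inputs

- Empty sets / all-zero fingerprints → similarity 0; all-zero adjacency
  rows → uniform transition rows; all-zero disease rows → uniform source
  marginal (warned).
- PPMI of a zero co-occurrence entry is 0 (the limit); an all-zero matrix
  is an error.
- Prediction ties break by vocabulary order, making rankings total and
  reproducible.
- Log-σ outputs are clipped to ±8 before exponentiation; BCE predictions
  are clipped to [1e−7, 1 − 1e−7].
- Non-finite training losses abort with a diagnostic rather than continue.

## Known limitations

- Negative sampling treats unobserved pairs as negatives; reported AUROC
  is a lower-bound-flavoured estimate.
- The fusion and predictor architectures are deliberately small; no
  layer-wise pretraining, denoising schedule, or adversarial term is
  implemented.
- GO similarity assumes the provided DAG is the relevant sub-ontology;
  no evidence-code filtering is performed.
- Runtime is dominated by the all-pairs Smith–Waterman stage (O(n²)
  alignments); for vocabularies far beyond ~10³ drugs a vectorised
  alignment backend would be needed.
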