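# Methods

## Overview

`protgram` models a corpus of protein primary-structure sequences as a hierarchy of
global, directed, weighted n-gram transition graphs; learns n-gram embeddings on those
graphs with a directed graph convolutional network; pools them into protein-level
vectors with parameter-free attention; and evaluates the vectors on protein–protein
interaction (PPI) link prediction with a cross-validated classifier. This note records
the model, its assumptions, the tunable parameters and the design choices that were
genuinely open.

## The n-gram transition graph

Sequences are cleaned to the 20 standard amino acids, capped at 10,000 residues, and
joined into a token stream with a single reserved separator character (`|`) between
proteins. The level-n graph G_n has one node per unique n-gram of the stream; a
directed edge (u, v) exists when v follows u under a one-character window shift, and
its weight w_uv is the total count of that transition over the corpus.

At n = 1 the separator is an ordinary token — the level-1 graph therefore has 21 nodes
on a full-alphabet corpus and marks protein boundaries explicitly, and its
row-normalized weights are the empirical first-order Markov chain over tokens: the
probability of a sequence given its first residue is the product of the step
probabilities along its path. For n ≥ 2, n-grams containing the separator are excluded
and windows spanning a boundary contribute no edges; higher-order n-grams crossing a
protein boundary have no biological meaning. A consequence worth stating precisely is
the hierarchy identity: every observed edge (u, v) of G_n lifts to the (n+1)-gram
u + v[-1], and the set of separator-free lifted edges equals the node set of G_{n+1}
built directly from the corpus. The test suite enforces this as an exact set equality.

When the empirical level-1 chain is compared against a generating residue chain (as the
synthetic-data tests do), the comparison conditions on non-separator successors
(`TransitionMatrix.restricted`): each sequence end sends ≈ 1/L of a row's mass to the
separator, which is corpus bookkeeping, not estimation error.

Edge weights are stored as raw integer counts (lossless; probabilities are derived on
demand). Vocabulary order is first occurrence in the token stream, making node indexing
deterministic for identity features. Self-loops from repeats (e.g. poly-A) are ordinary
edges.

## Propagation matrices

The raw count adjacency A_raw is preprocessed once per graph into three propagation
matrices. For the directed branches, M = D⁻¹A (row normalization by weighted
out-strength; zero rows stay zero) is split into its symmetric part S = (M + Mᵀ)/2 and
skew-symmetric part K = (M − Mᵀ)/2, and the propagation matrix is the element-wise
magnitude

    A = sqrt(S∘S + K∘K + ε) + I,        ε = 1e-9

applied to M (outgoing branch) and to the pipeline on A_rawᵀ (incoming branch). The
magnitude map produces a symmetric, spectrally well-behaved operator while retaining
both the reciprocal and the directional component of each transition; +I adds
self-loops. The third matrix is the standard symmetrically normalized undirected
adjacency D̃^{-1/2}(A_raw + A_rawᵀ + I)D̃^{-1/2}, using weighted (not binarized)
symmetrization so that frequency information is treated consistently across branches
(configurable in principle; weighted is the default and only mode shipped).

Note that for a 2×2 single-edge adjacency the incoming and outgoing matrices coincide
(the sign of K is squared away and the row normalizations agree); they differ whenever
in- and out-strength distributions differ, which is the typical case on transition
graphs. All three matrices are materialized dense: ε enters every entry of the
magnitude, so the result is structurally dense, and the package targets desk-scale
graphs (up to a few thousand nodes).

## The directed GCN layer

Given node features H (N×F), each of the three paths computes

    H_path = A_path (H W_main,path) + b_main,path + H W_shared + b_shared,path

with a path-specific main transform and a single shared transform (per-path shared
biases). The paths are blended by a learnable gating mechanism, a learnable per-node
positional bias B_const (N×F_out, per layer) is added, and a residual connection
precedes a LeakyReLU:

    H' = LeakyReLU(C_undir∘H_undir + C_in∘H_in + C_out∘H_out + B_const + H W_res)

Gating modes: `vector` (one score per node per path, broadcast across features — the
default), `scalar` (one score per path), `none` (gates fixed at 1 and non-learnable).
Scalar mode with value g is exactly vector mode with all entries g, and `none` is
exactly vector mode with gates frozen at 1; both identities are tested. Gates
initialize to 1 and B_const to 0, so a fresh layer is an ungated multi-path graph
convolution. W_res is the identity (no parameters) when dimensions agree, a learned
Glorot-initialized projection otherwise. Dropout (default 0.2, inverted scaling) is
applied after the activation during training only; LeakyReLU slope is 0.01.

The final hidden output Z is the embedding matrix; a linear decoder with LogSoftmax
produces class log-probabilities for the auxiliary tasks, trained with masked mean
negative log-likelihood. Embeddings are L2-normalized per node on extraction (an
exactly zero row — never observed in practice — would map to the first basis vector to
keep the unit-norm contract).

### Numerics

The network is implemented in numpy with hand-derived analytic gradients and an Adam
optimizer (lr 0.01, β = (0.9, 0.999)); the reverse pass is validated against central
finite differences at 1e-4 relative tolerance in the test suite, and the forward pass
against an independent loop-based reimplementation at 1e-6. The graphs involved are
small and dense, so dense matrix algebra is the appropriate regime; no GPU or autodiff
framework is needed or used.

## Self-supervised training

Below the top level each node's label is its most frequent successor (argmax of
outgoing weight, ties to the smallest vocabulary index; nodes without out-edges are
masked out of the loss). The top level is labeled by Louvain communities of the
symmetrized weighted graph (resolution 1.0, seeded; community ids sorted by size then
smallest member for determinism) — community structure acts like a wider context
window, and Louvain requires an undirected graph. Both tasks are selectable per level.

Training is hierarchical: level-1 features are the identity matrix; level-n features
(n > 1) are the attention-pooled embeddings of each node's two constituent (n−1)-grams
(prefix and suffix), using the same mean-context attention as protein pooling. Levels
at or above `partition_threshold_level` (default 3) with more nodes than
`partition_batch_nodes` (default 512) train on community-derived subgraph mini-batches:
Louvain communities are greedily packed (largest first) into batches of at most the
target node count, each batch gets its own induced propagation set, and per-node
parameters (gates, B_const) are sliced by batch. Partitioning is an efficiency device;
a test checks that partitioned and full-graph training land within 5 percentage points
of training accuracy on a small level-3 graph.

Defaults: 300 epochs per level, learning rate 0.01, hidden dims (64, 64). The paper-
scale hierarchy (full Swiss-Prot, n = 4) is out of scope; the package targets corpora
where each level has at most a few thousand nodes.

## Attention pooling and standardization

For a protein sequence, every length-n sliding window (windows, not unique types — a
repeated motif contributes once per occurrence) is looked up in the n-gram table;
missing windows are skipped and counted against a reported coverage fraction. The found
vectors v_i are pooled with parameter-free mean-context attention: c = mean(v), scores
s_i = v_i·c, weights α = softmax(s), pooled vector Σ α_i v_i. The weights are exported
per protein (position, n-gram, weight), supporting attention heat-map analyses. The
looser "self-attention" reading with learned query/key projections is deliberately not
used — the formulas are exactly the mean-context ones.

Protein vectors are centered and PCA-reduced to 64 dimensions to standardize the
feature space. PCA is fitted on all protein vectors of the dataset before
cross-validation, mirroring a standardization step rather than a supervised transform;
this leaks only unlabeled feature structure across folds, and the fitted transform is
reusable on held-out vectors for per-fold fitting if desired. Inputs already at ≤ 64
dimensions are centered and passed through; rank-deficient inputs are zero-padded to
the target width with a logged warning.

## PPI link prediction

A pair (P_a, P_b) is represented by the concatenation [v_a ; v_b] (128 features after
PCA; orientation as given, no symmetrization by default). The classifier is a
multilayer perceptron — scikit-learn's `MLPClassifier` with hidden layers (128, 64),
ReLU, Adam, and early stopping on a 10% inner validation split — evaluated under
stratified 5-fold cross-validation (fold class ratios within one sample of the global
ratio). Metrics: ROC AUC (midrank tie handling), and F1/precision/recall at a 0.5
decision threshold, reported per fold and as mean ± std. Pairs whose proteins lack an
embedding are dropped with a logged count. Negatives come from the provided table; no
random negative sampling is injected.

## Synthetic data: what it emulates and what it does not

`sample_corpus` draws sequences from a known first-order Markov chain over a residue
alphabet — exactly the generative view the graph formalism assumes — so the empirical
level-1 chain converges to the generator (the tests require L∞ ≤ 0.02 at 2,000
sequences of length 50).

`sample_ppi` plants a sequence-detectable interaction signal: proteins belong to
families; family k's chain is (1 − m)·uniform + m·P_k with P_k a family-specific random
permutation matrix, so the mixing parameter m is a single separation dial (rows of two
family chains that disagree on the preferred successor are at total-variation distance
exactly m); a sampled unordered pair (without replacement) is labeled positive with a
probability depending only on the family pair. The canonical configuration is two
families over the full 20-letter alphabet, m = 0.6, 100 proteins per family, sequence
lengths uniform in 100–300 (far below the 10,000 cap, keeping desk-scale runtimes),
2,000 pairs, within-family interaction probability 0.9 and cross-family 0.1. Under
those label probabilities the Bayes-optimal AUC is ≈ 0.90, so the pipeline's measured
≈ 0.88 is close to the ceiling; a constant interaction matrix is the built-in null and
triggers a no-learnable-signal warning.

What the generator does not emulate: real proteins are not first-order Markov —
long-range dependencies, domain architecture, secondary-structure periodicity and
compositional biases are absent; family structure in real interactomes is continuous
rather than discrete; and real PPI labels carry assay noise and severe class imbalance
rather than symmetric Bernoulli noise. Passing tests therefore demonstrate that the
machinery is implemented correctly and can recover a planted sequence-level signal —
not that the method attains any particular accuracy on biological data.

## Known limitations

- Dense matrix algebra bounds practical graph size to a few thousand nodes per level
  (full-corpus n = 4 hierarchies are out of scope).
- Identity features at level 1 carry no physicochemical information.
- The level-1 Markov chain conflates within-protein transitions with boundary
  transitions unless the separator is conditioned out.
- Ambiguity codes (B, Z, X), selenocysteine (U) and pyrrolysine (O) are dropped, not
  remapped, per the 20-residue whitelist.
- The pair classifier uses ReLU (scikit-learn's MLP), not LeakyReLU; the classifier is
  deliberately standard plumbing and its exact activation is not load-bearing.
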