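# protgram

Protein–protein interaction (PPI) prediction from primary structure alone, via
globally inferred n-gram transition graphs and a directed graph convolutional
network — a lightweight alternative to protein language models for sequence-level
representation learning.

## The idea

A corpus of protein sequences is modeled as a hierarchy of global directed weighted
graphs G_n = (V_n, E_n): nodes are the unique n-grams of residues observed in the
corpus, a directed edge (u, v) exists when v arises from u by shifting a one-residue
window (e.g. `ACG → CGT` at n = 3), and the edge weight w_uv is the total corpus
frequency of that transition. At n = 1 the row-normalized graph is the empirical
first-order Markov chain over residues, P(r_{j+1}|r_j) = w_{r_j r_{j+1}} / Σ_k w_{r_j k},
and a sequence is a random walk whose probability is the product of its step
probabilities.

A custom directed GCN learns embeddings of these graphs. Its layer passes messages
through three parallel paths — incoming (built from Aᵀ), outgoing (from A) and
undirected — where each directed branch row-normalizes the adjacency, splits it into
symmetric and skew-symmetric parts S, K = (M ± Mᵀ)/2, and propagates with the
element-wise magnitude sqrt(S∘S + K∘K + ε) + I. The paths are combined with learnable
per-node gates, a learnable per-node positional bias, and a residual connection:

    H' = LeakyReLU(C_u∘H_undir + C_i∘H_in + C_o∘H_out + B_const + H W_res)

Training is self-supervised (predict each n-gram's most frequent successor; Louvain
community labels at the top level) and hierarchical (level-n features are pooled from
the two constituent (n−1)-gram embeddings). Protein vectors are built by parameter-free
mean-context attention pooling over all sliding-window n-gram embeddings, PCA-reduced
to 64 dimensions, and pairs are classified by an MLP under stratified 5-fold
cross-validation (AUC, F1, precision, recall).

See `docs/methods.md` for the full model description, parameter defaults and
limitations.

## Worked example

Generate a synthetic two-family PPI dataset with a planted, sequence-detectable
interaction signal, and run the whole pipeline (graphs → hierarchical training →
attention pooling → PCA-64 → 5-fold CV):

```python
import protgram as pg

spec = pg.PlantedPPISpec.two_family(seed=0)   # 2 families, 100 proteins each,
corpus, pairs, families = pg.sample_ppi(spec) # within-family P(interact)=0.9, cross 0.1
print(f"proteins: {len(corpus)}  pairs: {len(pairs)}  positives/negatives: {pairs.class_counts()}")

g1 = pg.build_ngram_graph(corpus, 1)
g2 = pg.build_ngram_graph(corpus, 2)
print(f"G1: {g1.n_nodes} nodes, {g1.n_edges} edges   G2: {g2.n_nodes} nodes, {g2.n_edges} edges")

summary = pg.planted_signal_run(corpus, pairs, n_max=2, seed=0)
for m in ("auc", "f1", "precision", "recall"):
    print(f"{m:>9}: {summary.mean[m]:.4f} +/- {summary.std[m]:.4f}")
```

Output:

```
proteins: 200  pairs: 2000  positives/negatives: (986, 1014)
G1: 21 nodes, 440 edges   G2: 400 nodes, 5139 edges
      auc: 0.8773 +/- 0.0226
       f1: 0.8381 +/- 0.0229
precision: 0.8304 +/- 0.0359
   recall: 0.8468 +/- 0.0218
```

The level-1 graph has 21 nodes (20 residues plus the protein-boundary separator).
The mean cross-validated AUC of 0.88 is close to the Bayes ceiling of ≈ 0.90 implied
by the planted label probabilities: the sequence-derived embeddings recover the family
structure almost completely. Shuffling the pair labels drops the AUC to ≈ 0.5.

## Command line

The same pipeline is available as a CLI for FASTA + pair-table inputs:

```sh
protgram simulate   --spec spec.yaml --out data/            # synthetic corpus + pairs
protgram clean      --input raw.fasta --output clean.fasta
protgram build-graph --fasta clean.fasta --n 2 --out graph2/
protgram train      --fasta clean.fasta --n-max 2 --out ngrams.tsv
protgram embed      --fasta clean.fasta --table ngrams.tsv --n 2 --out proteins.tsv
protgram ppi-eval   --pairs pairs.tsv --embeddings proteins.tsv --folds 5 --seed 0
```

Pair tables are TSV (`id_a`, `id_b`, `label`) or Parquet with the same schema.

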