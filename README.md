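# snolink

Decoupled variational graph autoencoding for **snoRNA–disease association
prediction**.

Small nucleolar RNAs (snoRNAs) guide chemical modification of rRNA and
tRNA, and their dysregulation is implicated in lung cancer and many other
diseases. Curated association databases give a sparse bipartite graph of
known snoRNA–disease links; the practical question is which of the
*unobserved* pairs are real. `snolink` is for computational biologists who
want to rank candidate associations from such an edge list — and to know
*why* a pair scored highly: because the two nodes are genuinely similar in
latent space, or merely because one of them is a well-studied hub.

## The model

The observed graph `G = (V_s ∪ V_d, E)` is reconstructed by a variational
graph autoencoder with **two decoupled generative mechanisms**:

- **Similarity branch.** A two-layer graph convolution with symmetric
  normalization `D̂^{-1/2} Â D̂^{-1/2}` (self-loops added) encodes one-hot
  node features into Gaussian posteriors `q(z_a) = N(μ_a, diag σ_a²)`.
  Before every propagation the linear output is rescaled row-wise to
  Euclidean norm `t = 1.8`, so low-degree nodes are not drowned out and
  hubs cannot dominate message passing. The branch scores a pair as
  `σ(cos(z_a, z_b))` — invariant to embedding norm.
- **Degree (popularity) branch.** The same propagation applied to the
  node identity (no feature vector, no row rescaling), with a
  Kolmogorov–Arnold layer — learnable B-spline functions on every
  input–output edge — as the second mean layer. It scores a pair as
  `σ(1ᵀz_a + 1ᵀz_b)`, monotone in every embedding component, so it
  tracks popularity.

A Bernoulli mixture with weight `p_s` combines the branches,

    P(edge a,b) = p_s · σ(cos(z_a^s, z_b^s)) + (1 − p_s) · σ(1ᵀz_a^d + 1ᵀz_b^d),

and training maximizes the evidence lower bound (full-adjacency
reconstruction likelihood estimated from balanced positive/negative
batches, minus per-node-averaged KL divergences to the `N(0, I)` priors),
alternating gradient steps with EM updates of `p_s`. The per-edge EM
responsibility — the posterior probability that an observed edge is
similarity-generated — is the interpretable output of the decoupling.

## Worked example

```python
from snolink import (AssociationModel, SyntheticSpec, TrainConfig,
                     binary_metrics, generate, make_split)

sample = generate(SyntheticSpec(n_s=100, n_d=30, n_edges=500,
                                mix_weight=0.95, seed=1))
graph = sample.graph
split = make_split(graph, 0.8, seed=1)        # 4:1 train/test
config = TrainConfig(epochs=100, hidden_dim=128, latent_dim=32, seed=1)
results = AssociationModel(graph, config).fit(
    train_edges=split.train_edges, exclude_negatives=split.negatives)
print(results.summary())
```

prints

```
            Decoupled Variational Graph Autoencoder
================================================================
snoRNA nodes:           100    disease nodes:         30
training edges:         400    epochs:               100
hidden dim:             128    latent dim (sim):      32
latent dim (deg):        16    norm scale t:        1.80
----------------------------------------------------------------
mixture weight p_s (similarity mechanism): 0.9935
degree-mechanism weight 1 - p_s:           0.0065
final ELBO:               -1604.615
  reconstruction:         -1498.208
  KL (similarity):           79.029
  KL (degree):               27.378
edge responsibilities: mean 0.994, 100.0% similarity-attributed
================================================================
```

The fitted mixture weight (0.99) correctly attributes this graph — 95% of
whose edges were generated by the similarity mechanism — to similarity.
Scoring the held-out edges against the frozen negatives:

```python
pairs = sorted(split.test_edges) + sorted(split.negatives)
labels = [1] * len(split.test_edges) + [0] * len(split.negatives)
report = binary_metrics(results.scores_for_pairs_array(pairs), labels)
print(f"held-out AUC {report.auc:.3f}  AUPR {report.aupr:.3f}")
# held-out AUC 0.897  AUPR 0.874
```

and a single pair carries its mechanism attribution with it:

```python
results.predict("s0000", "d000")
# score 0.367, p_similarity_branch 0.369, p_degree_branch 0.032,
# responsibility 0.999
```

## Command line

Each subcommand writes a replayable `manifest.json` (seeds, input hashes,
package version) next to its outputs:

```bash
snolink simulate --preset similarity_dominant --out demo/
snolink cv --edges demo/edges.tsv --k 5 --seed 1 --out demo/cv/
snolink train --edges demo/edges.tsv --seed 1 --out demo/run/
snolink rank --edges demo/edges.tsv --disease d003 --top 20 --out demo/rank.tsv
```

`rank` implements the leave-target-out case-study protocol: the target's
edges are removed, the model retrained, and all candidate partners ranked.
Edge lists are TSV (`snorna_id<TAB>disease_id[<TAB>label]`, UTF-8,
optional header); identifier matching is case-insensitive and
whitespace-trimmed.

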