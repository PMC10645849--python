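# Methods

## Problem setting

A parity-stratified cohort of pregnancies is screened for rare adverse
outcomes (LBW, PTB, vPTB) without using the labels: the detector scores
each patient by how poorly a graph autoencoder reconstructs her
risk-factor profile through her neighbourhood. Strata are always analyzed
separately (parous vs nulliparous); they are never pooled, because risk
profiles and prevalence differ strongly by parity.

## Knowledge graph

Nodes are typed: one `PATIENT` node per record and one `FEATURE_VALUE`
node per observed (feature, level) pair. Binary factors contribute value
nodes for level 0 as well as level 1 — sharing the *absence* of a risk
factor is also similarity, and most factors here are binary. Categorical
levels map one-to-one; continuous factors are discretized into quartile
bins before node creation. Edges are typed `HAS_<FACTOR>` relations from
patient to value node; a missing value contributes no edge, which encodes
missingness without imputation at the graph level. The graph is therefore
bipartite by construction, and all patient–patient similarity is induced
through shared value-node neighbours.

Outcome labels are **excluded** from the graph by default. Embedding the
target class would leak labels into an evaluation framed as prediction;
`include_outcome=True` exists for the label-bearing variant, with the
default documenting our position on the ambiguity rather than hiding it.

## Node2Vec

Second-order walks: from (prev, cur), each neighbour y of cur gets
unnormalized weight 1/p if y = prev, 1 if y is adjacent to prev, 1/q
otherwise; the step samples from the normalized weights. Defaults p = q = 1,
walk length 80, 10 walks per node, window 10, 5 negatives, 5 epochs — the
original Node2Vec settings; with p = q = 1 the walk is first-order and a
vectorized sampler is used. Walks terminate early only at isolated start
nodes (in an undirected graph no other dead end is reachable).

The skip-gram trainer is a self-contained numpy implementation of SGNS:
two embedding tables (input table initialized uniform in ±0.5/d, output
table zero), sigmoid scoring clipped at ±30, negatives drawn from the
unigram distribution raised to 3/4, linear step-size decay from 0.025.
Two deliberate departures from word2vec folklore:

- **Fixed-width context window** (no random shrinking): keeps the pair
  set a deterministic function of the corpus and seed.
- **Frequent-token subsampling is on by default (t = 1e-3)** and matters
  more here than in text: on a bipartite patient/value graph every second
  walk token is one of a few dozen hub value nodes. Besides the usual
  statistical argument, subsampling bounds how often one node recurs
  within a mini-batch; without it the batched gradient accumulation for
  hub nodes multiplies the effective step size and diverges. For the same
  reason the mini-batch size scales with the vocabulary
  (clip(4·|V|, 32, 4096)).

## FastRP

As implemented: R ~ i.i.d. N(0, 1) of shape (|nodes| × d); W = the
orthonormal factor of the reduced QR of A·R; row embeddings X = A·W, with
A the undirected, unweighted, loop-free adjacency. Consequences used by
the tests: WᵀW = I to machine precision, nodes with identical adjacency
rows embed identically, and inner products of embedding rows approximate
inner products of adjacency rows (the approximation tightens as d
approaches the node count). The canonical multi-iteration
degree-normalized FastRP is available behind `canonical=True` but is not
the default, because the single-projection description is the procedure
this pipeline is defined around.

"combine d" concatenates FastRP-d and Node2Vec-d (2d columns), reusing the
two already-computed matrices.

## Augmentation, propagation graph, autoencoder

Raw risk factors are mean-imputed and z-scored; the per-patient embedding
block is z-scored per column as well (one Euclidean geometry for the k-NN
graph and one reconstruction scale for the loss; constant columns stay
zero). The k-NN graph is built on the augmented matrix — the autoencoder
consumes that matrix, so neighbourhood structure and reconstruction
target share a space. Directed k-NN (Euclidean, ties broken by row index),
union-symmetrized, self-loops added, normalized D^(−1/2)(A+I)D^(−1/2);
its spectrum lies in [−1, 1].

The network is the two-weight form

    Z = LeakyReLU( G · LeakyReLU( G · X · W⁽⁰⁾ − b⁽⁰⁾ ) · W⁽¹⁾ − b⁽¹⁾ )

("three layers" counting the input layer), with hidden width
⌈(f + d)/2⌉ by default, LeakyReLU slope 0.01, biases entering by
subtraction, weights initialized N(0, 1)/√fan-in from a seeded generator,
biases zero. Training is full-batch gradient descent (or Adam) on the
summed (or mean) squared reconstruction error, with manual backpropagation;
divergence raises an error naming the epoch. The outlier score is
e_i = ‖x_i − z_i‖².

Default training settings are learning rate 1e-9 with **sum** reduction,
500 epochs, plain gradient descent, k = 90. A step of 1e-9 is only
meaningful against an unnormalized summed loss on a cohort-sized matrix;
under these defaults the parameters barely move, and the score is
dominated by each patient's deviation from what the randomly initialized
propagation network predicts from its neighbourhood. We keep these
defaults deliberately and note the behaviour rather than silently
"fixing" it; convergence-sensitive tests and examples use mean reduction
with Adam and a correspondingly larger step, all exposed in `TrainConfig`.
Empirically on the planted-outlier benchmark the near-untrained network
separates outliers slightly *better* than a converged one: once training
fits the data, the outlier direction (a high-variance, label-correlated
feature block) is itself learned and reconstructed, eroding the error gap.

## Evaluation

AUC-ROC is computed from midranks (exactly the pairwise probability with
ties half-credited); AUC-PR is average precision with grouped thresholds,
chosen over trapezoidal PR interpolation because linear interpolation in
PR space is optimistic. The experiment grid reproduces the published
method × dimension layout (Original + {FastRP, Node2Vec, combine} ×
{16, 32, 64}); repeats re-seed the embedding and autoencoder stages while
the cohort stays fixed, and per-row bold-facing is replaced by a
`best_auc_roc` flag (max of the mean, no statistical test implied).

## Synthetic cohorts

The generator emulates the published strata: exact sample sizes and
abnormal counts (2668/261, 785/130, 2708/297, 801/97, 2708/35, 801/22),
binary features only by default. Normal patients draw every feature
Bernoulli(base_rate = 0.2); abnormal patients draw 5 informative features
of 20 at base_rate + effect_delta (default 0.3) and the rest at base_rate.
The abnormal count is exact — round(prevalence·n) rows placed by sampling
without replacement — so the 1.3 % stratum is reproducible rather than
occasionally empty. One master seed fans out to independent substreams
for labels, features and missingness, so noise can vary with labels held
fixed. Effect sizes are calibration choices: the study reports none for
real risk factors.

What the generator does **not** model: covariance among risk factors
beyond the label-induced block, categorical hierarchies, informative
missingness, or any real obstetric effect sizes. Passing the recovery
tests therefore demonstrates that the pipeline detects distributional
outliers of moderate effect in an imbalanced binary cohort — not that it
attains any particular performance on clinical data.

## Problem sizes and numerical choices

The planted-outlier benchmark runs at n = 500, prevalence 0.1,
effect_delta 0.6, scoring with 100 epochs at the default (sum, 1e-9)
setting; recovery is judged by mean AUC-ROC over 10 detector seeds, and
the no-signal control re-draws the cohort per seed so the Monte-Carlo
interval reflects cohort randomness. Walk corpora in the examples and the
reproduction script use walk length 40, 5 walks per node, window 5 — a
corpus size chosen so a full Node2Vec run completes in seconds while
leaving clique-separation and frequency properties intact. k-NN distances
are computed from the full squared-distance matrix with a stable argsort,
so neighbour sets are deterministic including ties; duplicate rows are
each other's nearest neighbours by construction. Exact permutation
equivariance of scores holds for distinct rows; with duplicated rows the
index tie-break makes the propagation graph weakly order-dependent.

## Known limitations

- Neo4j is supported only via bulk-import CSV export; there is no live
  graph database connectivity.
- Embeddings are transductive: unseen patients require rebuilding the
  graph and re-embedding.
- The AUC values of the original clinical study are not reproducible here
  (private data); only the arithmetic of its cohort table and the
  qualitative planted-outlier behaviour are.
- No hard outlier threshold is chosen; explanatory flags use a
  configurable top-quantile of the score distribution.
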