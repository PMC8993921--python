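# Methods

## Model

`famgeo` trains a variational autoencoder on a fixed-length multiple
sequence alignment of one protein family. Each sequence is one-hot encoded
over C = 21 classes (20 amino acids plus a single gap class; ambiguity
codes map to the gap class so C stays fixed). The encoder is a dense
network producing a Gaussian posterior N(mu(x), diag(sigma^2(x))) over a
d-dimensional latent z (default d = 2); the decoder is a dense network
producing independent per-column categorical distributions
p(x_l | z) = Cat(softmax(logits_l(z))). Training maximizes the ELBO —
reconstruction cross-entropy (optionally reweighted per sequence) plus the
KL term against the standard-normal prior — with full-batch Adam.

### Entropy calibration

A plain decoder extrapolates arbitrarily far from the data, often with
high confidence, which ruins any geometry built on it. The decoder is
therefore blended toward the uniform distribution by a proximity function

    alpha(z) = sigmoid(6.9077 (beta - V(z)) / beta),
    V(z) = min_j ||z - kappa_j||^2,
    p(x|z) = alpha(z) softmax(logits(z)) + (1 - alpha(z)) / C,

with K trainable-scale cluster centers kappa_j initialized by k-means on
the training embeddings and a positive scale beta (softplus parametrized).
Since 6.9077 ~ ln(999), alpha saturates at ~0.999 on the centers, is 0.5
at V = beta and ~0.001 at V = 2 beta, so the decoded distribution is
exactly uniform (summed entropy L ln C) far from the data support.

The sign convention deserves a note: the naive form sigmoid(-k V/beta)
gives alpha(0) = 0.5, i.e. a half-uniform blend *on top of the data*,
which contradicts the intent of returning ~1 close to data. We therefore
use the shifted form above, which is 0.5 exactly at V = beta. The
proximity map is a small pluggable component should a different calibration
be preferred.

Training runs in two phases: (1) encoder and raw decoder by the ELBO;
(2) encoder frozen, centers set by k-means and kept fixed (this keeps
representative selection well-defined), beta and the raw decoder trained
jointly on the blended likelihood at the posterior means. All randomness
flows from one integer seed; identical seed, config and data give
bit-identical parameters. The networks are plain numpy with hand-written
backpropagation and Adam; gradient correctness is checked against finite
differences in the test suite.

## Geometry

Latent curve lengths are measured through the decoder. For two decoded
position-categoricals a, b (rows on the C-simplex), the squared distance
between one-hot samples is 0 or 2 per position, with expectation

    E[d^2](a, b) = sum_l 2 (1 - sum_d a_{l,d} b_{l,d}),

zero only for identical deterministic distributions and bounded by 2L.
The expected energy of a discretized curve c_1..c_N is

    E(c) = sum_i E[d^2](p(c_i), p(c_{i+1})) ||c_{i+1} - c_i||,

and the geodesic distance between two latent points is sqrt(E) of the
minimizing curve. Because the blend forces maximal entropy off-support,
nearly-uniform regions contribute close to the maximal 2L(1 - 1/C) per
unit length, so minimizing curves hug the data manifold.

Direct minimization from the straight line tends to stall (the landscape
is flat near initialization), so geodesics are computed in two stages:

1. **Grid initialization.** The entropy landscape is discretized into an
   R x R grid (default 100, bounding box of the training embeddings
   expanded 10% per side) with 8-neighbor edges weighted
   ||u - v|| (eps + (H(u) + H(v)) / 2 / (L ln C)), eps = 0.01 keeping
   weights positive; Dijkstra gives a robust initial polyline.
2. **Spline refinement.** A natural cubic spline with 16 uniformly spaced
   control points is fitted through the polyline (endpoints clamped) and
   10 gradient steps are taken on the interior control points with respect
   to the curve energy sampled at 128 points. Sampled points depend
   linearly on control points, so gradients are the spline basis transpose
   applied to the analytic energy gradient (backpropagated through the
   decoder and the proximity map). Steps use a fixed starting step size
   (1e-2) with backtracking halving; only non-increasing steps are
   accepted and counted, making descent a contract rather than a hope.
   The straight segment is refined as a fallback candidate, so the
   returned geodesic is never longer than the straight-line curve at equal
   sampling.

The expected-Hamming baseline decodes both endpoints and draws sequence
pairs (default 10; sample count configurable) whose mean Hamming distance
estimates E[d^2]/2 — the identity E[Hamming] = sum_l (1 - <a_l, b_l>) is
asserted against the closed form in the tests.

Bulk analyses (robustness, correlation) use a 50 x 50 grid and 64 energy
samples per curve; single-geodesic calls default to the full 100 x 100 /
128-sample settings. These sizes were chosen so the complete study battery
runs in minutes on one CPU while leaving the contract checks unchanged.

## Phylogeny comparison

Patristic distances are path-length sums over a Newick tree (trees and
ancestral sequences come from external tools and are only ingested).
Two diagnostics relate a latent metric to the phylogeny:

- **Robustness.** Train the model several times with different seeds,
  compute the same sampled set of pairwise distances under each model,
  normalize each model's set by its mean (so global rescalings cancel) and
  report the per-pair standard deviation across models. Pairs are sampled
  uniformly without replacement.
- **Correlation.** Pearson correlation between matched latent and
  patristic distances over seeded subsets; points can be sampled with
  probability proportional to their embedding norm so that the subset
  covers the full range of distances.

Representatives are selected per entropy-network center: greedily by
center index, each center takes the nearest not-yet-taken training
embedding.

## Synthetic families

The generator evolves aligned sequences along a pure-birth (Yule) tree
with Exp(0.1) branch lengths under a Jukes–Cantor model over the 20
amino-acid states (per branch of length b each site is redrawn uniformly
over all states with probability 1 - exp(-S/(S-1) rate b), S = 20, which
reproduces the JC closed forms used as test oracles). Defaults — 150
leaves, L = 100, rate 1.0 — give a family whose pairwise Hamming distances
correlate strongly (r > 0.5, measured ~0.87) with the true patristic
distances, the structural premise of the phylogeny analyses. Gaps never
arise from the substitution process; they are introduced only by the
two-subclass generator, so column-removal effects are fully controlled.

The two-subclass generator attaches two Yule clades to a common root
(stem branches 0.5), optionally overwrites class-specific consensus
letters in difference regions, and can add a block of columns that is gap
in every class-1 sequence (including the designated query, c1-0) and
carries a conserved class-2 motif — exactly the columns query-centric
reduction deletes. A class-divergence factor scales class-2 branch
lengths. With zero regions, no gap block and unit divergence the classes
are exchangeable by construction.

What the simulations do *not* emulate: realistic substitution matrices
(WAG/LG), indel processes, rate heterogeneity across sites, and
alignment error. Passing tests therefore demonstrate the machinery and
the qualitative orderings under a known-truth model, not performance on
curated Pfam alignments.

## Study conditions and design choices

- **Preprocessing study (reconstruction-accuracy gap).** Classes of 150
  and 50 sequences, class divergence 3, a 30-column query-gap block, and a
  reduced training budget (80 + 40 epochs). The shortened budget keeps the
  model in the population-fit regime: with long training a 2-d VAE
  memorizes individual sequences, a regime in which a tight minority
  cluster is reconstructed *better* — the opposite of the population-level
  phenomenon of interest, which is about how well each subclass's shared
  structure is captured.
- **Network sizes.** Hidden width 64, two hidden layers, K = min(50, N)
  centers by default. These are deliberately desk-scale; they reproduce
  the qualitative results the package tests for.
- **Identity threshold** for density reweighting defaults to 0.8, with
  identity computed over columns where the pair is not gap–gap; both
  choices are exposed because the field's practice varies.
- **Numerical guards.** Probabilities are floored at 1e-10 before logs in
  KL profiles; encoder log-variances are clipped to [-8, 8]; grid edge
  weights carry the eps floor; Dijkstra ties resolve deterministically via
  the sparse-graph implementation's fixed ordering.
- **Aggregation.** Attention pooling is single-head dot-product with a
  supplied query vector; light attention uses a depthwise convolution
  kernel with softmax over positions per dimension; kmax averages the K
  highest-attention positions (K = 5 default, falling back to all
  positions when K >= L). The bottleneck aggregator is a dense
  autoencoder over the padded one-hot sequence: with a fixed maximum
  length its contracts (fixed code size, reconstruction improvement,
  seeded determinism) are architecture-independent, and it embodies the
  learned-aggregation idea at desk scale rather than any benchmark
  backbone.

## Known limitations

- The grid initializer is 2-D (as is the latent space by default);
  refinement alone works in higher dimensions but without the robust
  initialization.
- Geodesic lengths are sqrt(energy) of the refined spline; the triangle
  inequality holds only approximately (audited at 5% tolerance).
- The entropy-weighted edge rule is one reasonable reading of
  "distance weighted with the entropy"; it is isolated in one function.
- Reported numbers from the synthetic battery (e.g. robustness stds
  ~0.13 geodesic vs ~0.23 Euclidean) are properties of the desk-scale
  study, not measurements on any curated family.
- The linear-vs-geodesic ordering of *maximum* path entropy is typical but
  not guaranteed pointwise: geodesics minimize the entropy-weighted energy
  integral, so on some family realizations the two maxima nearly tie and
  can invert by a fraction of a nat.
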