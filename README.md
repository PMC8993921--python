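# famgeo

Geometry-aware latent representations of aligned protein families.

Latent spaces of generative sequence models are routinely read with a
Euclidean ruler, but nothing about a nonlinear decoder makes straight-line
distances meaningful. `famgeo` trains a categorical variational autoencoder
on a multiple sequence alignment, calibrates the decoder so that its output
entropy rises to the maximum away from the data support, and measures latent
distances through the decoder: the length of a curve c is the square root of
its expected energy

    E(c) = Σᵢ E[‖X(cᵢ₊₁) − X(cᵢ)‖²] · ‖cᵢ₊₁ − cᵢ‖,
    E[‖X − Y‖²] = Σₗ 2 (1 − Σ_d a_{l,d} b_{l,d}),

where a, b are the decoded per-column categorical distributions and X, Y
one-hot samples from them. Geodesics under this pullback metric are found by
Dijkstra on an entropy-weighted grid followed by gradient refinement of a
cubic spline. The resulting distances are substantially more stable across
retrained models than Euclidean ones and correlate better with phylogenetic
(patristic) distances — the package ships the full analysis battery to
demonstrate both on synthetic families with known evolutionary ground truth.

Intended users: computational biologists working with per-family generative
models who want distances, interpolations and representative selections that
respect the learned manifold rather than the coordinate chart.

What's inside:

- `famgeo.families` — aligned FASTA/Stockholm I/O, one-hot encoding,
  query-centric column removal, density-based sequence reweighting.
- `famgeo.vae` — the entropy-calibrated categorical VAE (numpy, seeded,
  bit-reproducible), reconstruction accuracy, checkpointing.
- `famgeo.geometry` — expected one-hot distances, curve energies, entropy
  grids, Dijkstra initialization, spline geodesics, expected-Hamming
  baseline.
- `famgeo.phylo` — patristic distances from Newick, ancestor embedding,
  representative selection, robustness and tree-correlation reports.
- `famgeo.interpolation` — entropy profiles, per-position KL divergence and
  position-probability matrices along linear or geodesic interpolants.
- `famgeo.aggregation` — length-invariant pooling of per-residue
  representations (mean / attention / light attention / max / meanmax /
  kmax / lossless concat / learned bottleneck).
- `famgeo.synthetic` — tree-evolved synthetic families with known patristic
  distances, true ancestors, and controllable two-subclass structure.
- `famgeo.experiments` — the desk-scale study protocols tying it together.

## Worked example

```python
import numpy as np
import famgeo

# simulate a family of 60 sequences of length 50 along a known tree
tree = famgeo.simulate_tree(60, seed=7)
sim = famgeo.evolve_family(tree, 50, rate=1.0, seed=7)

model = famgeo.fit_vae(sim.family, config=famgeo.TrainingConfig(K=20), seed=0)
acc = famgeo.reconstruction_accuracy(model, sim.family)
print(f"mean reconstruction accuracy: {acc.mean():.3f}")

z1, _ = model.encode(sim.family.sequence("T0"))
z2, _ = model.encode(sim.family.sequence("T31"))
gd = famgeo.geodesic(model, z1, z2)
print(f"euclidean distance : {np.linalg.norm(z1 - z2):.3f}")
print(f"geodesic length    : {gd.length:.3f}")
print(f"expected Hamming   : {famgeo.expected_hamming(model, z1, z2, seed=0):.1f}")

td = famgeo.patristic_distances(sim.tree)
print(f"patristic distance : {td.distance('T0', 'T31'):.3f}")
```

Output:

```
mean reconstruction accuracy: 0.948
euclidean distance : 2.147
geodesic length    : 6.378
expected Hamming   : 24.6
patristic distance : 0.830
```

The model reconstructs 94.8% of residues. The two sequences sit 2.15 units
apart on the latent chart, but the decoder-aware geodesic length is 6.38 —
its square, ~40.7, is the accumulated expected squared one-hot distance
along the path, consistent with the directly sampled expected Hamming
distance of ~25 changed positions (out of 50) between the decoded
endpoints. The patristic distance is the ground-truth tree distance the
latent metrics are compared against.

A thin CLI mirrors the library (`famgeo simfam make`, `famgeo vae train`,
`famgeo geo distance`, `famgeo interp run`, `famgeo famio reduce`, ...);
run `famgeo --help`.

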