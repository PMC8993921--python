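"""Latent distances versus phylogeny.

Patristic distance matrices are read off Newick trees (trees and ancestral
sequences are produced by external tools and consumed here as inputs).
The module quantifies two properties of a latent metric: robustness of
mean-normalized pairwise distances across retrained models, and Pearson
correlation between latent and patristic distances on seeded subsamples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from famgeo.families import AlignedFamily
from famgeo.geometry import GeodesicConfig, GridConfig, entropy_grid, geodesic
from famgeo.vae import VaeModel


@dataclass
class TreeDistances:
    """Symmetric patristic (path-length) distance matrix over leaf labels."""

    ids: list
    D: np.ndarray

    def __post_init__(self):
        self.D = np.asarray(self.D, dtype=np.float64)
        if self.D.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")

    def distance(self, a: str, b: str) -> float:
        return float(self.D[self.ids.index(a), self.ids.index(b)])


@dataclass
class RobustnessReport:
    per_pair_std: np.ndarray
    mean_std: float
    n_pairs: int
    metric: str


@dataclass
class CorrelationReport:
    r_mean: float
    per_seed: list
    subset: int
    seeds: list


def patristic_distances(tree: str) -> TreeDistances:
    """Leaf-to-leaf path-length distances from Newick text."""
    try:
        dtree = dendropy.Tree.get(data=tree, schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
        raise ValueError(f"duplicate leaf labels in tree: {err}") from err
    labels = []
    for leaf in dtree.leaf_node_iter():
        labels.append(leaf.taxon.label.replace(" ", "-"))
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    for edge in dtree.preorder_edge_iter():
        if edge.head_node is not dtree.seed_node and edge.length is None:
            raise ValueError("tree has a branch without a length")
    pdm = dtree.phylogenetic_distance_matrix()
    taxa = {t.label.replace(" ", "-"): t for t in dtree.taxon_namespace}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return TreeDistances(labels, D)


def encode_ancestors(model: VaeModel, ancestral: AlignedFamily) -> dict:
    """Posterior-mean embeddings for ancestral (internal-node) sequences."""
    if ancestral.L != model.L:
        raise ValueError(f"ancestral length {ancestral.L} != model L={model.L}")
    mu, _ = model.encode_batch(ancestral.rows)
    return dict(zip(ancestral.ids, mu))


def select_representatives(model: VaeModel, family: AlignedFamily, n: int = 200) -> list:
    """For each of the first n entropy-network centers, the id of the
    training sequence whose embedding is nearest (greedy by center index;
    a sequence already taken falls through to the next nearest)."""
    if model.entropy is None:
        raise ValueError("model has no fitted entropy network")
    if n > model.entropy.K:
        raise ValueError(f"n={n} exceeds the model's K={model.entropy.K} centers")
    if n > family.N:
        raise ValueError(f"n={n} exceeds family size N={family.N}")
    mu, _ = model.encode_batch(family.rows)
    chosen: list = []
    taken = np.zeros(family.N, dtype=bool)
    for j in range(n):
        d = np.linalg.norm(mu - model.entropy.centers[j], axis=1)
        order = np.argsort(d, kind="stable")
        for k in order:
            if not taken[k]:
                taken[k] = True
                chosen.append(family.ids[int(k)])
                break
    return chosen


def sample_pairs(n_items: int, n_pairs: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of unordered index pairs without replacement."""
    total = n_items * (n_items - 1) // 2
    n_pairs = min(n_pairs, total)
    flat = rng.choice(total, size=n_pairs, replace=False)
    # invert the row-major upper-triangle linearization
    i = (n_items - 2 - np.floor(
        np.sqrt(-8.0 * flat + 4 * n_items * (n_items - 1) - 7) / 2.0 - 0.5
    )).astype(int)
    j = flat - (i * (2 * n_items - i - 1) // 2) + i + 1
    return np.column_stack([i, j.astype(int)])


def pairwise_distances(
    model: VaeModel,
    Z: np.ndarray,
    pairs: np.ndarray,
    metric: str = "euclidean",
    grid=None,
    grid_config: GridConfig | None = None,
    geo_config: GeodesicConfig | None = None,
    cache: dict | None = None,
) -> np.ndarray:
    """Distances for the given index pairs under 'euclidean' or 'geodesic'."""
    if metric == "euclidean":
        return np.linalg.norm(Z[pairs[:, 0]] - Z[pairs[:, 1]], axis=1)
    if metric != "geodesic":
        raise ValueError(f"unknown metric {metric!r}")
    if grid is None:
        gcfg = grid_config or GridConfig()
        lo = Z.min(axis=0)
        hi = Z.max(axis=0)
        if model.train_embeddings is not None:
            lo = np.minimum(lo, model.train_embeddings.min(axis=0))
            hi = np.maximum(hi, model.train_embeddings.max(axis=0))
        span = np.maximum(hi - lo, 1e-6)
        lo, hi = lo - gcfg.expand * span, hi + gcfg.expand * span
        grid = entropy_grid(model, (lo[0], hi[0], lo[1], hi[1]), gcfg.resolution, gcfg.eps)
    out = np.empty(pairs.shape[0])
    for k, (i, j) in enumerate(pairs):
        key = (int(min(i, j)), int(max(i, j)))
        if cache is not None and key in cache:
            out[k] = cache[key]
            continue
        out[k] = geodesic(model, Z[i], Z[j], grid=grid, config=geo_config).length
        if cache is not None:
            cache[key] = out[k]
    return out


def robustness_report(
    models,
    family: AlignedFamily,
    n_pairs: int = 500,
    metric: str = "euclidean",
    seed: int = 0,
    grid_config: GridConfig | None = None,
    geo_config: GeodesicConfig | None = None,
) -> RobustnessReport:
    """Stability of a latent metric across retrained models.

    Samples `n_pairs` sequence pairs once; for each model computes the pair
    distances, normalizes them by that model's mean distance (so global
    rescalings cancel), and reports the per-pair standard deviation across
    models together with its mean.
    """
    models = list(models)
    if len(models) < 2:
        raise ValueError("need at least 2 models")
    if metric not in ("euclidean", "geodesic"):
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)
    pairs = sample_pairs(family.N, n_pairs, rng)
    normed = []
    for model in models:
        Z, _ = model.encode_batch(family.rows)
        d = pairwise_distances(model, Z, pairs, metric, None, grid_config, geo_config)
        normed.append(d / d.mean())
    normed = np.stack(normed)  # (n_models, n_pairs)
    per_pair = normed.std(axis=0, ddof=0)
    return RobustnessReport(per_pair, float(per_pair.mean()), pairs.shape[0], metric)


def distance_tree_correlation(
    ids,
    latent_D: np.ndarray,
    tree_D: TreeDistances,
    subset: int = 500,
    norm_proportional: bool = False,
    norms: np.ndarray | None = None,
    seeds=(0, 1, 2, 3, 4),
) -> CorrelationReport:
    """Pearson correlation between latent and patristic distances.

    `latent_D` is a symmetric matrix over `ids` (any latent metric).  Per
    seed, points are sampled (with probability proportional to their
    embedding norm if requested), all pairs within the sample are formed and
    subsampled to `subset`, and Pearson r between matched latent and tree
    distances is computed.  The per-seed spread is reported.
    """
    ids = list(ids)
    shared = [i for i in ids if i in tree_D.ids]
    if len(shared) < 3:
        raise ValueError("need at least 3 ids shared between latent and tree distances")
    li = np.array([ids.index(s) for s in shared])
    ti = np.array([tree_D.ids.index(s) for s in shared])
    LD = np.asarray(latent_D)[np.ix_(li, li)]
    TD = tree_D.D[np.ix_(ti, ti)]
    n = len(shared)
    if norm_proportional:
        if norms is None:
            raise ValueError("norm_proportional sampling requires embedding norms")
        p = np.asarray(norms, dtype=float)[li]
        p = p / p.sum()
    else:
        p = None
    # smallest m with m*(m-1)/2 >= subset, plus head-room
    m = min(n, int(np.ceil(0.5 * (1 + np.sqrt(1 + 8 * subset)))) + 5)
    rs = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        pts = rng.choice(n, size=m, replace=False, p=p)
        iu, ju = np.triu_indices(m, k=1)
        take = rng.choice(iu.size, size=min(subset, iu.size), replace=False)
        a = LD[pts[iu[take]], pts[ju[take]]]
        b = TD[pts[iu[take]], pts[ju[take]]]
        rs.append(float(np.corrcoef(a, b)[0, 1]))
    return CorrelationReport(float(np.mean(rs)), rs, subset, list(seeds))
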