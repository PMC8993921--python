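"""Desk-scale study protocols on synthetic families.

Each function runs one of the package's headline analyses end to end on a
simulated family sized so the whole battery completes in minutes on one
CPU: metric robustness across retrained models, latent-vs-phylogenetic
distance correlation, entropy calibration, interpolation entropy profiles,
and the effect of query-centric preprocessing on reconstruction accuracy.
The same protocols back the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from famgeo.families import query_centric_reduce
from famgeo.geometry import GeodesicConfig, GridConfig, entropy_grid, geodesic
from famgeo.interpolation import entropy_profile, linear_path
from famgeo.phylo import (
    distance_tree_correlation,
    patristic_distances,
    robustness_report,
    sample_pairs,
)
from famgeo.synthetic import SimulatedFamily, evolve_family, simulate_tree, two_subclass_family
from famgeo.vae import TrainingConfig, VaeModel, fit_vae, reconstruction_accuracy
from famgeo.geometry import Curve, _resample_polyline

#: study conditions for the tree-evolved family (ground-truth phylogeny)
DEFAULT_LEAVES = 150
DEFAULT_L = 100
DEFAULT_RATE = 1.0

#: geodesic settings for bulk distance computations
BULK_GEO = GeodesicConfig(n_control=16, n_samples=64, steps=10)
BULK_GRID = GridConfig(resolution=50)


def default_family(seed: int = 0) -> SimulatedFamily:
    """The canonical synthetic family: 150 leaves, L = 100, JC rate 1."""
    tree = simulate_tree(DEFAULT_LEAVES, seed=seed)
    return evolve_family(tree, DEFAULT_L, DEFAULT_RATE, seed=seed)


def train_default(sim: SimulatedFamily, seed: int = 0) -> VaeModel:
    return fit_vae(sim.family, None, TrainingConfig(), seed=seed)


def train_ensemble(sim: SimulatedFamily, seeds=(0, 1, 2, 3, 4)) -> list:
    return [train_default(sim, seed=s) for s in seeds]


# ------------------------------------------------------------- calibration


def calibration_probe(model: VaeModel, n_probes: int = 100, seed: int = 0) -> dict:
    """Entropy at far-away probe points (V >= 10*beta) versus at the
    training embeddings."""
    rng = np.random.default_rng(seed)
    beta = model.entropy.beta
    centers = model.entropy.centers
    scale = np.abs(centers).max() + np.sqrt(10 * beta)
    probes = []
    while len(probes) < n_probes:
        z = rng.uniform(-4 * scale, 4 * scale, size=2)
        V = np.min(np.sum((centers - z) ** 2, axis=1))
        if V >= 10 * beta:
            probes.append(z)
    probes = np.array(probes)
    far_entropy = model.sequence_entropy_batch(probes)
    train_entropy = model.sequence_entropy_batch(model.train_embeddings)
    return {
        "max_entropy": model.max_entropy,
        "far_entropy_max_dev": float(np.abs(far_entropy - model.max_entropy).max()),
        "train_entropy_mean": float(train_entropy.mean()),
    }


# -------------------------------------------------------------- robustness


def robustness_experiment(
    models, sim: SimulatedFamily, n_pairs: int = 500, seed: int = 0
) -> dict:
    """Mean std of mean-normalized pairwise distances across retrained
    models, for the Euclidean and the geodesic metric on the same pairs."""
    euc = robustness_report(models, sim.family, n_pairs, "euclidean", seed)
    geo = robustness_report(
        models, sim.family, n_pairs, "geodesic", seed,
        grid_config=BULK_GRID, geo_config=BULK_GEO,
    )
    return {
        "euclidean_mean_std": euc.mean_std,
        "geodesic_mean_std": geo.mean_std,
        "n_pairs": euc.n_pairs,
    }


# -------------------------------------------------------------- correlation


def geodesic_matrix(model: VaeModel, Z: np.ndarray, indices: np.ndarray, cache: dict) -> dict:
    """Geodesic lengths for all pairs among `indices`, cached across calls."""
    grid = cache.setdefault(
        "__grid__",
        entropy_grid(model, resolution=BULK_GRID.resolution, eps=BULK_GRID.eps),
    )
    for a in range(len(indices)):
        for b in range(a + 1, len(indices)):
            i, j = int(indices[a]), int(indices[b])
            key = (min(i, j), max(i, j))
            if key not in cache:
                cache[key] = geodesic(model, Z[i], Z[j], grid=grid, config=BULK_GEO).length
    return cache


def correlation_experiment(
    model: VaeModel,
    sim: SimulatedFamily,
    subset: int = 300,
    seeds=(0, 1, 2, 3, 4),
    points_per_seed: int = 30,
) -> dict:
    """Pearson correlation of Euclidean and geodesic latent distances with
    patristic tree distances, over seeded norm-proportional point subsets."""
    tree_d = patristic_distances(sim.tree)
    Z, _ = model.encode_batch(sim.family.rows)
    ids = list(sim.family.ids)
    norms = np.linalg.norm(Z, axis=1)
    p = norms / norms.sum()
    tidx = {t: k for k, t in enumerate(tree_d.ids)}
    cache: dict = {}
    r_euc, r_geo = [], []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        pts = rng.choice(len(ids), size=points_per_seed, replace=False, p=p)
        geodesic_matrix(model, Z, pts, cache)
        iu, ju = np.triu_indices(points_per_seed, k=1)
        take = rng.choice(iu.size, size=min(subset, iu.size), replace=False)
        de, dg, dt = [], [], []
        for k in take:
            i, j = int(pts[iu[k]]), int(pts[ju[k]])
            de.append(np.linalg.norm(Z[i] - Z[j]))
            dg.append(cache[(min(i, j), max(i, j))])
            dt.append(tree_d.D[tidx[ids[i]], tidx[ids[j]]])
        r_euc.append(float(np.corrcoef(de, dt)[0, 1]))
        r_geo.append(float(np.corrcoef(dg, dt)[0, 1]))
    return {
        "r_euclidean": r_euc,
        "r_geodesic": r_geo,
        "r_euclidean_mean": float(np.mean(r_euc)),
        "r_geodesic_mean": float(np.mean(r_geo)),
        "geodesic_wins": int(sum(g > e for g, e in zip(r_geo, r_euc))),
        "n_seeds": len(list(seeds)),
    }


# ------------------------------------------------------------ interpolation


def two_cluster_family(seed: int = 0) -> SimulatedFamily:
    """Two well-separated subclasses, no gap block: a bimodal latent space."""
    return two_subclass_family(
        n_per_class=40, L=60, n_diff_regions=4, gap_block_in_query=None, seed=seed
    )


def interpolation_experiment(model: VaeModel, sim: SimulatedFamily, n_points: int = 10) -> dict:
    """Maximum summed entropy along the linear versus the geodesic
    interpolant between the two subclass centroids."""
    Z, _ = model.encode_batch(sim.family.rows)
    class1 = np.array([i.startswith("c1-") for i in sim.family.ids])
    z1 = Z[class1].mean(axis=0)
    z2 = Z[~class1].mean(axis=0)
    lin = linear_path(z1, z2, n_points)
    gd = geodesic(model, z1, z2)
    geo_path = Curve(_resample_polyline(gd.curve.points, n_points))
    ent_lin = entropy_profile(model, lin)
    ent_geo = entropy_profile(model, geo_path)
    return {
        "linear_max_entropy": float(ent_lin.max()),
        "geodesic_max_entropy": float(ent_geo.max()),
        "max_entropy": model.max_entropy,
    }


# ------------------------------------------------------------ preprocessing


def preprocessing_experiment(seed: int = 0) -> dict:
    """Reconstruction-accuracy gap between the query's subclass and the
    other subclass, trained on the query-reduced versus the full alignment.

    The family has a 30-column block that is gapped in the query's subclass
    and conserved in the other, and the non-query subclass is a more diverse
    minority (50 vs 150 sequences, class_divergence = 3), emulating a
    query-centric alignment of a family whose distant subclass is
    underrepresented.  Training uses a reduced epoch budget so the model
    stays in the population-fit (consensus) regime rather than memorizing
    individual sequences; the preprocessing effect is a statement about how
    well each subclass's shared structure is captured, not about
    per-sequence capacity.
    """
    sim = two_subclass_family(
        n_per_class=(150, 50),
        L=100,
        n_diff_regions=4,
        gap_block_in_query=(70, 30),
        class_divergence=3.0,
        seed=seed,
    )
    fam = sim.family
    class1 = np.array([i.startswith("c1-") for i in fam.ids])
    out = {}
    cfg = TrainingConfig(phase1_epochs=80, phase2_epochs=40)
    for name, family in (
        ("reduced", query_centric_reduce(fam, fam.query_id)),
        ("full", fam),
    ):
        model = fit_vae(family, None, cfg, seed=seed)
        acc = reconstruction_accuracy(model, family)
        out[f"{name}_acc_query_class"] = float(acc[class1].mean())
        out[f"{name}_acc_other_class"] = float(acc[~class1].mean())
        out[f"{name}_gap"] = out[f"{name}_acc_query_class"] - out[f"{name}_acc_other_class"]
    return out
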