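"""Interpolation diagnostics between two latent points.

Compares linear and geodesic interpolants through three lenses: the summed
decoder entropy along the path (high entropy marks crossings of no-data
regions), the per-position Kullback-Leibler divergence between the endpoint
output distributions (which alignment columns change), and
position-probability matrices along the interpolant (how they change).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from famgeo.geometry import Curve
from famgeo.vae import VaeModel


@dataclass
class InterpolationProfile:
    path: Curve
    entropies: np.ndarray          # summed decoder entropy per path point
    kl: np.ndarray                 # per-position KL, target relative to source
    regions: list                  # maximal 1-based runs with KL above threshold
    kl_threshold: float


def linear_path(z1: np.ndarray, z2: np.ndarray, n_points: int = 10) -> Curve:
    """Uniformly spaced points on the segment z1 -> z2, inclusive."""
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    return Curve((1.0 - t) * z1[None, :] + t * z2[None, :])


def entropy_profile(model: VaeModel, path: Curve) -> np.ndarray:
    """Summed decoder entropy at each path point, order preserved."""
    return model.sequence_entropy_batch(path.points)


def kl_profile(
    model: VaeModel,
    z_source: np.ndarray,
    z_target: np.ndarray,
    floor: float = 1e-10,
) -> np.ndarray:
    """Per-position KL(target || source) between the decoded endpoint
    distributions; probabilities are floored before the log so the value
    stays finite even for saturated raw-decoder outputs."""
    p = np.maximum(model.decode(np.asarray(z_target, float)), floor)
    q = np.maximum(model.decode(np.asarray(z_source, float)), floor)
    p = p / p.sum(axis=1, keepdims=True)
    q = q / q.sum(axis=1, keepdims=True)
    return np.sum(p * (np.log(p) - np.log(q)), axis=1)


def highlight_regions(kl: np.ndarray, threshold: float = 1.0) -> list:
    """Maximal runs of positions with KL above threshold, 1-based inclusive."""
    above = np.asarray(kl) > threshold
    regions = []
    start = None
    for pos, flag in enumerate(above, start=1):
        if flag and start is None:
            start = pos
        elif not flag and start is not None:
            regions.append((start, pos - 1))
            start = None
    if start is not None:
        regions.append((start, len(above)))
    return regions


def ppm_along_path(model: VaeModel, path: Curve, positions) -> list:
    """Decoded position-probability matrices restricted to the requested
    1-based alignment columns, one (len(positions), C) matrix per path point."""
    positions = list(positions)
    for p in positions:
        if not (1 <= p <= model.L):
            raise ValueError(f"position {p} outside [1, {model.L}]")
    cols = np.array(positions) - 1
    probs = model.decode_batch(path.points)
    return [probs[k][cols] for k in range(path.n_points)]


def interpolation_profile(
    model: VaeModel,
    path: Curve,
    kl_threshold: float = 1.0,
) -> InterpolationProfile:
    """Entropy and KL diagnostics for a path; endpoints define source/target."""
    ent = entropy_profile(model, path)
    kl = kl_profile(model, path.points[0], path.points[-1])
    return InterpolationProfile(path, ent, kl, highlight_regions(kl, kl_threshold), kl_threshold)
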