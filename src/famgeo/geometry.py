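"""Riemannian machinery on the latent space of a family VAE.

Curve lengths in latent space are measured through the decoder: the squared
norm between two one-hot sequences drawn from decoded categorical
distributions a, b has expectation

    E[d^2] = sum_l 2 * (1 - sum_d a_{l,d} * b_{l,d}),

which is 0 only for identical deterministic distributions and at most 2L.
The expected energy of a discretized latent curve c_1..c_N is

    E(c) ~ sum_i E[d^2](p(c_i), p(c_{i+1})) * ||c_{i+1} - c_i||,

and a geodesic minimizes it; its length is sqrt(E).  Direct minimization is
fragile (the landscape is flat near the straight line), so geodesics are
initialized by Dijkstra on an entropy-weighted 8-neighbor grid graph and
refined by gradient steps on the coefficients of a cubic spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from famgeo.vae import VaeModel


# ---------------------------------------------------------------- distances


def expected_sq_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Expected squared one-hot distance between two position-categoricals.

    `a`, `b` are (L, C) rows on the simplex.  Symmetric, in [0, 2L]; equals
    0 iff a == b and both are deterministic, and {0, 2} per position for
    one-hot inputs.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(2.0 * np.sum(1.0 - np.sum(a * b, axis=-1)))


@dataclass
class Curve:
    """Ordered latent points c_1..c_N (N >= 2); endpoints treated as fixed."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.points.shape[0] < 2:
            raise ValueError("a curve needs at least 2 points")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def length_euclidean(self) -> float:
        return float(self.segment_lengths().sum())


def _energy_terms(model: VaeModel, pts: np.ndarray):
    probs = model.decode_batch(pts)  # (M, L, C)
    ip = np.sum(probs[:-1] * probs[1:], axis=(1, 2))
    s = model.L - ip  # sum_l (1 - <a_l, b_l>)
    dt = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return probs, s, dt


def curve_energy(model: VaeModel, curve: Curve) -> float:
    """Discretized expected curve energy (Eq. above); 0 for constant curves."""
    _, s, dt = _energy_terms(model, curve.points)
    return float(np.sum(2.0 * s * dt))


def _energy_and_grad(model: VaeModel, pts: np.ndarray):
    """Energy and its gradient with respect to every curve point."""
    probs, s, dt = _energy_terms(model, pts)
    E = float(np.sum(2.0 * s * dt))
    gp = np.zeros_like(probs)
    gp[:-1] += -2.0 * dt[:, None, None] * probs[1:]
    gp[1:] += -2.0 * dt[:, None, None] * probs[:-1]
    g = model.decode_vjp(pts, gp)
    safe = np.where(dt > 0, dt, 1.0)
    unit = np.diff(pts, axis=0) / safe[:, None]
    unit[dt == 0] = 0.0
    g[:-1] += -2.0 * s[:, None] * unit
    g[1:] += 2.0 * s[:, None] * unit
    return E, g


# ---------------------------------------------------------------- grid graph


@dataclass
class GridConfig:
    resolution: int = 100   # nodes per axis
    expand: float = 0.10    # bounding-box expansion per side
    eps: float = 0.01       # entropy weight floor, keeps edges positive


@dataclass
class GridGraph:
    """Entropy-weighted 8-neighbor grid over a latent rectangle."""

    nodes: np.ndarray        # (R*R, 2) node coordinates
    entropies: np.ndarray    # (R*R,) summed decoder entropy per node
    graph: csr_matrix        # symmetric positive edge weights
    resolution: int
    bounds: tuple            # (xmin, xmax, ymin, ymax)

    def nearest_node(self, z: np.ndarray) -> int:
        xmin, xmax, ymin, ymax = self.bounds
        R = self.resolution
        ix = int(round((z[0] - xmin) / (xmax - xmin) * (R - 1)))
        iy = int(round((z[1] - ymin) / (ymax - ymin) * (R - 1)))
        ix = min(max(ix, 0), R - 1)
        iy = min(max(iy, 0), R - 1)
        return ix * R + iy

    def contains(self, z: np.ndarray) -> bool:
        xmin, xmax, ymin, ymax = self.bounds
        return xmin <= z[0] <= xmax and ymin <= z[1] <= ymax


def entropy_grid(
    model: VaeModel,
    bounds: tuple | None = None,
    resolution: int = 100,
    eps: float = 0.01,
    expand: float = 0.10,
) -> GridGraph:
    """Discretize the entropy landscape into an 8-connected grid graph.

    Edge weight between neighbors u, v is ||u - v|| * (eps + (H(u)+H(v))/2)
    with H the summed decoder entropy normalized by its maximum L*ln(C), so
    crossings of high-entropy (no-data) regions are penalized while weights
    stay strictly positive.
    """
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if bounds is None:
        if model.train_embeddings is None:
            raise ValueError("no bounds given and model has no training embeddings")
        emb = model.train_embeddings
        lo, hi = emb.min(axis=0), emb.max(axis=0)
        span = np.maximum(hi - lo, 1e-6)
        lo, hi = lo - expand * span, hi + expand * span
        bounds = (lo[0], hi[0], lo[1], hi[1])
    xmin, xmax, ymin, ymax = map(float, bounds)
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounds")
    R = resolution
    xs = np.linspace(xmin, xmax, R)
    ys = np.linspace(ymin, ymax, R)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([gx.ravel(), gy.ravel()])
    H = model.sequence_entropy_batch(nodes)
    Hn = H / model.max_entropy

    idx = np.arange(R * R).reshape(R, R)
    rows, cols, data = [], [], []
    for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):
        si = slice(None) if di == 0 else slice(0, R - di)
        ti = slice(None) if di == 0 else slice(di, R)
        if dj == 1:
            sj, tj = slice(0, R - 1), slice(1, R)
        elif dj == -1:
            sj, tj = slice(1, R), slice(0, R - 1)
        else:
            sj = tj = slice(None)
        u = idx[si, sj].ravel()
        v = idx[ti, tj].ravel()
        dist = np.linalg.norm(nodes[u] - nodes[v], axis=1)
        w = dist * (eps + 0.5 * (Hn[u] + Hn[v]))
        rows.append(u)
        cols.append(v)
        data.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    graph = csr_matrix(
        (np.concatenate([data, data]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(R * R, R * R),
    )
    return GridGraph(nodes, H, graph, R, (xmin, xmax, ymin, ymax))


def shortest_grid_path(grid: GridGraph, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal-cost grid polyline between the nodes nearest to a and b."""
    src = grid.nearest_node(np.asarray(a, dtype=float))
    dst = grid.nearest_node(np.asarray(b, dtype=float))
    if src == dst:
        return grid.nodes[[src]]
    dist, pred = _csgraph_dijkstra(
        grid.graph, directed=False, indices=src, return_predecessors=True
    )
    if not np.isfinite(dist[dst]):
        raise ValueError("grid graph is disconnected between the endpoints")
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return grid.nodes[path[::-1]]


def grid_path_cost(grid: GridGraph, a: np.ndarray, b: np.ndarray) -> float:
    src = grid.nearest_node(np.asarray(a, dtype=float))
    dst = grid.nearest_node(np.asarray(b, dtype=float))
    dist = _csgraph_dijkstra(grid.graph, directed=False, indices=src)
    return float(dist[dst])


# ---------------------------------------------------------------- refinement


@dataclass
class GeodesicConfig:
    n_control: int = 16
    n_samples: int = 128
    steps: int = 10          # accepted gradient steps on the spline coefficients
    step_size: float = 1e-2
    max_halvings: int = 30


@dataclass
class Geodesic:
    """A refined latent curve with its expected energy and length sqrt(E)."""

    curve: Curve
    energy: float
    length: float

    def __post_init__(self):
        assert abs(self.length**2 - self.energy) <= 1e-9 * max(1.0, self.energy)


_BASIS_CACHE: dict = {}


def _spline_basis(n_control: int, n_samples: int) -> np.ndarray:
    """Matrix B with samples = B @ control; natural cubic, uniform knots."""
    key = (n_control, n_samples)
    if key not in _BASIS_CACHE:
        tk = np.linspace(0.0, 1.0, n_control)
        ts = np.linspace(0.0, 1.0, n_samples)
        B = np.empty((n_samples, n_control))
        for j in range(n_control):
            e = np.zeros(n_control)
            e[j] = 1.0
            B[:, j] = CubicSpline(tk, e, bc_type="natural")(ts)
        _BASIS_CACHE[key] = B
    return _BASIS_CACHE[key]


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """n points uniformly spaced in arclength along a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] <= 0:
        return np.repeat(points[:1], n, axis=0)
    t /= t[-1]
    ts = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(ts, t, points[:, k]) for k in range(points.shape[1])])


def refine_geodesic(
    model: VaeModel, init: np.ndarray, config: GeodesicConfig | None = None
) -> Geodesic:
    """Fit a cubic spline to an initial polyline and take gradient steps on
    its coefficients with respect to the curve energy.

    Endpoints are clamped; only steps that do not increase the energy are
    accepted (fixed starting step, backtracking halving), so the returned
    energy never exceeds that of the initial spline.
    """
    cfg = config or GeodesicConfig()
    init = np.atleast_2d(np.asarray(init, dtype=np.float64))
    if init.shape[0] < 2:
        init = np.repeat(init, 2, axis=0)
    Q = _resample_polyline(init, cfg.n_control)
    Q[0], Q[-1] = init[0], init[-1]
    B = _spline_basis(cfg.n_control, cfg.n_samples)

    def eval_energy_grad(Qc):
        E, g_pts = _energy_and_grad(model, B @ Qc)
        gQ = B.T @ g_pts
        gQ[0] = 0.0
        gQ[-1] = 0.0
        return E, gQ

    E, gQ = eval_energy_grad(Q)
    step = cfg.step_size
    accepted = 0
    while accepted < cfg.steps:
        halvings = 0
        while True:
            Q_new = Q - step * gQ
            pts_new = B @ Q_new
            _, s, dt = _energy_terms(model, pts_new)
            E_new = float(np.sum(2.0 * s * dt))
            if not np.isfinite(E_new):
                raise FloatingPointError("non-finite energy during refinement")
            if E_new <= E:
                break
            step *= 0.5
            halvings += 1
            if halvings > cfg.max_halvings:
                break
        if halvings > cfg.max_halvings:
            break
        Q = Q_new
        accepted += 1
        E, gQ = eval_energy_grad(Q)
    pts = B @ Q
    pts[0], pts[-1] = init[0], init[-1]
    _, s, dt = _energy_terms(model, pts)
    E = float(np.sum(2.0 * s * dt))
    return Geodesic(Curve(pts), E, float(np.sqrt(E)))


def geodesic(
    model: VaeModel,
    z1: np.ndarray,
    z2: np.ndarray,
    grid: GridGraph | None = None,
    grid_config: GridConfig | None = None,
    config: GeodesicConfig | None = None,
) -> Geodesic:
    """Geodesic between two latent points: entropy grid -> Dijkstra ->
    spline refinement.  The straight segment is refined as a fallback
    candidate, so the result is never longer than the straight-line curve
    at equal sampling.
    """
    z1 = np.asarray(z1, dtype=np.float64)
    z2 = np.asarray(z2, dtype=np.float64)
    cfg = config or GeodesicConfig()
    if np.allclose(z1, z2):
        pts = np.vstack([z1, z2])
        return Geodesic(Curve(pts), 0.0, 0.0)
    if grid is None or not (grid.contains(z1) and grid.contains(z2)):
        gcfg = grid_config or GridConfig()
        lo = np.minimum(z1, z2)
        hi = np.maximum(z1, z2)
        if model.train_embeddings is not None:
            lo = np.minimum(lo, model.train_embeddings.min(axis=0))
            hi = np.maximum(hi, model.train_embeddings.max(axis=0))
        span = np.maximum(hi - lo, 1e-6)
        lo, hi = lo - gcfg.expand * span, hi + gcfg.expand * span
        grid = entropy_grid(
            model, (lo[0], hi[0], lo[1], hi[1]), gcfg.resolution, gcfg.eps, gcfg.expand
        )
    poly = shortest_grid_path(grid, z1, z2)
    poly = np.vstack([z1, poly, z2])
    best = refine_geodesic(model, poly, cfg)
    straight = np.vstack([z1, z2])
    straight_curve = Curve(_resample_polyline(straight, cfg.n_samples))
    E_straight = curve_energy(model, straight_curve)
    if best.energy > E_straight:
        alt = refine_geodesic(model, straight, cfg)
        if alt.energy < best.energy:
            best = alt
    return best


# ---------------------------------------------------------------- sampling


def sample_sequences(probs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n sequences (position-independent) from an (L, C) categorical."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random((n, probs.shape[0]))
    return (u[:, :, None] > cum[None, :, :]).sum(axis=2)


def expected_hamming(
    model: VaeModel,
    z1: np.ndarray,
    z2: np.ndarray,
    n_samples: int = 10,
    seed: int = 0,
) -> float:
    """Monte-Carlo expected Hamming distance between decoded endpoints.

    Draws `n_samples` sequence pairs (one from each decoded categorical,
    independent across positions) and averages the Hamming distance.  Its
    expectation equals expected_sq_distance / 2.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    pa = model.decode(np.asarray(z1, dtype=float))
    pb = model.decode(np.asarray(z2, dtype=float))
    sa = sample_sequences(pa, n_samples, rng)
    sb = sample_sequences(pb, n_samples, rng)
    return float(np.mean((sa != sb).sum(axis=1)))
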