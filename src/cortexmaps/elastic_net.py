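"""Elastic-net simulation of joint orientation-preference / ocular-dominance map development.

The model embeds a 5-D feature space — retinotopic position (sx, sy), ocularity
(od = ±d) and an orientation double-angle vector (opx, opy) of radius r — into a
2-D cortical sheet of reference vectors y_j, trading coverage of the feature
points against cortical continuity.  Annealing the scale K drives a cascade of
symmetry-breaking bifurcations that lays down OD bands and an OP map with
pinwheels.  Biased ("cross-reared") visual input is modelled by over-weighting
the coverage contribution of one orientation in each eye (α_i > 1).

Each annealing step minimizes, over the sheet Y with responsibilities frozen,

    E(Y, K) = -K Σ_i α_i log Σ_j exp(-‖x_i - y_j‖² / 2K²)
              + (β/2) Σ_{edges (j,k)} ‖y_j - y_k‖²

whose stationarity condition  Σ_i α_i p_ij (x_i - y_j) + βK L(y)_j = 0  is a
sparse SPD linear system (the implicit / EM-style step).  An explicit
gradient-style step with configurable step size is also provided.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._kernels import accumulate_responsibilities

logger = logging.getLogger(__name__)

#: cross-rearing default: horizontal contours to the left eye, vertical to the right
DEFAULT_OVER_ASSIGNMENTS = frozenset({("left", 0.0), ("right", 90.0)})


@dataclass(frozen=True)
class FeatureSet:
    """Training stimuli as 5-D points with per-point coverage weights α_i ≥ 1."""

    points: np.ndarray   # (N, 5): sx, sy, od, opx, opy
    weights: np.ndarray  # (N,)
    od_magnitude: float
    op_radius: float

    def __post_init__(self):
        if self.points.ndim != 2 or self.points.shape[1] != 5:
            raise ValueError("points must be (N, 5)")
        if self.weights.shape != (len(self.points),):
            raise ValueError("weights must match point count")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CorticalSheet:
    """W×H grid of 5-D reference vectors on a non-periodic 4-neighbor lattice."""

    grid: np.ndarray  # (H, W, 5)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]

    @property
    def flat(self) -> np.ndarray:
        return self.grid.reshape(-1, 5)

    def copy(self) -> "CorticalSheet":
        return CorticalSheet(self.grid.copy())


@dataclass(frozen=True)
class AnnealSchedule:
    """Geometric annealing of the scale parameter K."""

    K0: float = 0.2
    decay: float = 0.9925
    K_end: float = 0.0358

    def __post_init__(self):
        if not (0 < self.decay < 1):
            raise ValueError("decay must be in (0, 1)")
        if not (0 < self.K_end < self.K0):
            raise ValueError("require 0 < K_end < K0")

    @property
    def n_iterations(self) -> int:
        """Smallest n with K0·decayⁿ ≤ K_end (one step is taken at each larger K)."""
        n = math.ceil(math.log(self.K_end / self.K0) / math.log(self.decay))
        # guard against floating-point boundary cases
        while self.K0 * self.decay ** n > self.K_end:
            n += 1
        while n > 0 and self.K0 * self.decay ** (n - 1) <= self.K_end:
            n -= 1
        return n

    def k_values(self) -> np.ndarray:
        """The K at which each step is taken: K0, K0·decay, … (> K_end)."""
        return self.K0 * self.decay ** np.arange(self.n_iterations)


@dataclass(frozen=True)
class SimulationConfig:
    nx: int = 20
    ny: int = 20
    n_od: int = 2
    n_op: int = 6
    od_magnitude: float = 0.05
    op_radius: float = 0.08
    alpha_over: float = 1.0
    over_assignments: frozenset = DEFAULT_OVER_ASSIGNMENTS
    beta: float = 10.0
    cortex_shape: tuple[int, int] = (128, 128)
    schedule: AnnealSchedule = field(default_factory=AnnealSchedule)
    seed: int = 0
    # initialization noise amplitudes (uniform, zero-mean)
    init_noise_od: float = 0.005
    init_noise_op: float = 0.008
    # symmetry-breaking noise floor maintained during annealing; defaults to the
    # init amplitudes.  Without it the implicit step contracts the od/op
    # components to round-off during the high-K phase and no map can form by
    # K_end (the ± feature symmetry makes the unorganized sheet an invariant
    # manifold of the iteration).
    jitter_od: float = 0.005
    jitter_op: float = 0.008
    solver: str = "implicit"   # "implicit" (sparse solve) or "explicit"
    step_size: float = 1.0     # explicit solver only

    def __post_init__(self):
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.alpha_over < 1:
            raise ValueError("alpha_over must be >= 1")


def build_feature_set(nx: int, ny: int, d: float, r: float, n_op: int,
                      alpha_over: float = 1.0,
                      over_assignments=DEFAULT_OVER_ASSIGNMENTS) -> FeatureSet:
    """Build the nx·ny·2·n_op feature points on the unit square.

    Orientations are the n_op angles equally spaced on [0°, 180°), encoded as
    double-angle vectors (r·cos2θ, r·sin2θ).  Points whose (eye, θ) pair is in
    ``over_assignments`` get coverage weight ``alpha_over``; all others get 1.
    Eye labels: "left" ↔ od = −d, "right" ↔ od = +d.
    """
    if nx < 1 or ny < 1 or n_op < 1:
        raise ValueError("grid sizes must be >= 1")
    if alpha_over < 1:
        raise ValueError("alpha_over must be >= 1")
    over = {(e, float(t) % 180.0) for e, t in over_assignments}

    px = (np.arange(nx) + 0.5) / nx
    py = (np.arange(ny) + 0.5) / ny
    thetas = np.arange(n_op) * (180.0 / n_op)
    points, weights = [], []
    for sx in px:
        for sy in py:
            for eye, od in (("left", -d), ("right", +d)):
                for th in thetas:
                    a = np.deg2rad(2 * th)
                    points.append((sx, sy, od, r * np.cos(a), r * np.sin(a)))
                    weights.append(alpha_over if (eye, th % 180.0) in over else 1.0)
    return FeatureSet(np.asarray(points, float), np.asarray(weights, float),
                      od_magnitude=d, op_radius=r)


def init_cortex(config: SimulationConfig) -> CorticalSheet:
    """Smooth affine retinotopy plus small zero-mean uniform od/op perturbations."""
    H, W = config.cortex_shape
    rng = np.random.default_rng(config.seed)
    gy, gx = np.meshgrid(np.linspace(0, 1, H), np.linspace(0, 1, W), indexing="ij")
    grid = np.zeros((H, W, 5))
    grid[..., 0] = gx
    grid[..., 1] = gy
    grid[..., 2] = rng.uniform(-config.init_noise_od, config.init_noise_od, (H, W))
    grid[..., 3] = rng.uniform(-config.init_noise_op, config.init_noise_op, (H, W))
    grid[..., 4] = rng.uniform(-config.init_noise_op, config.init_noise_op, (H, W))
    return CorticalSheet(grid)


def lattice_laplacian(shape: tuple[int, int]) -> sp.csc_matrix:
    """D − A for the non-periodic 4-neighbor lattice (positive semi-definite).

    The continuity operator of the update is L(y) = −(D − A) y; boundary nodes
    simply have fewer neighbors (free boundary).
    """
    H, W = shape
    idx = np.arange(H * W).reshape(H, W)
    rows, cols = [], []
    for dr, dc in ((0, 1), (1, 0)):
        a = idx[: H - dr, : W - dc].ravel()
        b = idx[dr:, dc:].ravel()
        rows += [a, b]
        cols += [b, a]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    A = sp.coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(H * W, H * W))
    D = sp.diags(np.asarray(A.sum(axis=1)).ravel())
    return (D - A).tocsc()


def responsibilities(features: FeatureSet, sheet: CorticalSheet, K: float) -> np.ndarray:
    """Full responsibility matrix p_ij (normalized over cortical nodes per feature).

    Dense reference implementation via log-sum-exp; intended for small
    instances and tests.  The simulation path uses a fused kernel that never
    materializes p.
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    X = features.points
    Y = sheet.flat
    d2 = ((X[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
    logits = -d2 / (2 * K * K)
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def elastic_net_energy(sheet: CorticalSheet, features: FeatureSet, K: float,
                       beta: float) -> float:
    """E = −K Σ_i α_i log Σ_j exp(−‖x_i−y_j‖²/2K²) + (β/2) Σ_edges ‖y_j−y_k‖²."""
    if K <= 0:
        raise ValueError("K must be > 0")
    X, alpha = features.points, features.weights
    Y = sheet.flat
    coverage = 0.0
    chunk = max(1, int(2e7) // max(len(Y), 1))
    for s in range(0, len(X), chunk):
        xs = X[s:s + chunk]
        d2 = ((xs[:, None, :] - Y[None, :, :]) ** 2).sum(-1)
        logits = -d2 / (2 * K * K)
        m = logits.max(axis=1)
        lse = m + np.log(np.exp(logits - m[:, None]).sum(axis=1))
        coverage += -K * float(alpha[s:s + chunk] @ lse)
    g = sheet.grid
    tension = ((g[:, 1:] - g[:, :-1]) ** 2).sum() + ((g[1:] - g[:-1]) ** 2).sum()
    return coverage + beta / 2 * float(tension)


def elastic_net_step(cortex: CorticalSheet, features: FeatureSet, K: float,
                     beta: float, solver: str = "implicit",
                     step_size: float = 1.0,
                     laplacian: sp.spmatrix | None = None) -> CorticalSheet:
    """One annealing step at scale K.

    implicit (default): solve (diag(g) + βK(D−A)) Y' = M with
    g_j = Σ_i α_i p_ij and M_j = Σ_i α_i p_ij x_i — the exact minimizer of the
    coverage/continuity objective with responsibilities frozen, so the energy
    is non-increasing.  explicit: Y' = Y + s·[Σ_i α_i p_ij (x_i − y_j) + βK L(y)_j].
    """
    if K <= 0:
        raise ValueError("K must be > 0")
    H, W = cortex.shape
    Y = cortex.flat
    g, M = accumulate_responsibilities(features.points, Y, features.weights, K)
    Lap = laplacian if laplacian is not None else lattice_laplacian((H, W))
    if solver == "implicit":
        A = (sp.diags(g) + beta * K * Lap).tocsc()
        Ynew = spla.splu(A).solve(M)
    elif solver == "explicit":
        delta = (M - g[:, None] * Y) - beta * K * (Lap @ Y)
        Ynew = Y + step_size * delta
    else:
        raise ValueError(f"unknown solver {solver!r}")
    return CorticalSheet(Ynew.reshape(H, W, 5))


def run_simulation(config: SimulationConfig) -> CorticalSheet:
    """Anneal from K0 down, one step per K value, stopping at the first K ≤ K_end.

    Deterministic given the seed (and thread count).  Raises RuntimeError on
    divergence (any non-finite coordinate).
    """
    features = build_feature_set(config.nx, config.ny, config.od_magnitude,
                                 config.op_radius, config.n_op,
                                 config.alpha_over, config.over_assignments)
    cortex = init_cortex(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE1A5]))
    H, W = cortex.shape
    Lap = lattice_laplacian((H, W))
    ks = config.schedule.k_values()
    for it, K in enumerate(ks):
        if config.jitter_od or config.jitter_op:
            cortex.grid[..., 2] += rng.uniform(-config.jitter_od, config.jitter_od, (H, W))
            cortex.grid[..., 3] += rng.uniform(-config.jitter_op, config.jitter_op, (H, W))
            cortex.grid[..., 4] += rng.uniform(-config.jitter_op, config.jitter_op, (H, W))
        cortex = elastic_net_step(cortex, features, float(K), config.beta,
                                  solver=config.solver, step_size=config.step_size,
                                  laplacian=Lap)
        if not np.all(np.isfinite(cortex.grid)):
            raise RuntimeError(
                f"simulation diverged at iteration {it} (K={K:.4g}): "
                "non-finite cortical coordinates")
    logger.info("simulation finished: %d iterations, final K=%.6g",
                len(ks), ks[-1] * config.schedule.decay if len(ks) else config.schedule.K0)
    return cortex


def extract_maps(cortex: CorticalSheet):
    """Read out the OP map (complex field, angle = 2×preference) and OD map."""
    from .map_stats import OPMap, ODMap

    grid = cortex.grid
    field = grid[..., 3] + 1j * grid[..., 4]
    mask = np.ones(cortex.shape, bool)
    return OPMap(field=field, mask=mask), ODMap(field=grid[..., 2].copy(), mask=mask)
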