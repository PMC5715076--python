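"""Wind loads, load propagation, bending stress and fracture.

The wind blows horizontally with uniform speed ``U``.  Each foliage feels a
drag force ``(1/2) * C_Y * (U/U0)**2 * S_fol`` applied at its center (drag
coefficient 1), and each segment a force proportional to its frontal area and
the squared crossflow component, applied at its midpoint.  Forces and moments
are transmitted from the extremities to the base of every segment; the
maximal bending stress at the base surface of a cylinder of diameter ``d``
under bending moment ``M`` is ``(32/pi) * M / d**3``.

Everything is dimensionless: speeds in units of ``U0``, stresses in units of
the wood strength ``sigma0``; the single material/loading constant is the
Cauchy number ``C_Y``.  Fracture is Weibull-distributed with volume effects:
``P = 1 - exp(-(V/V0) * (sigma/sigma0)**m)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .architecture import Tree
from .params import SimulationParams


@dataclass
class WindEvent:
    """A yearly extreme-wind draw."""

    U: float          # speed [U0]
    azimuth: float    # [rad]
    year: int = 0


def level_index(depth: np.ndarray) -> list[np.ndarray]:
    """Segment indices grouped by topological depth, ascending."""
    if depth.size == 0:
        return []
    order = np.argsort(depth, kind="stable")
    sorted_depth = depth[order]
    boundaries = np.searchsorted(sorted_depth, np.arange(sorted_depth[-1] + 2))
    return [order[boundaries[k]:boundaries[k + 1]]
            for k in range(len(boundaries) - 1)]


def wind_forces(
    t: np.ndarray,
    d: np.ndarray,
    twig_mask: np.ndarray,
    U: float,
    u: np.ndarray,
    params: SimulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment and per-foliage wind forces.

    Parameters
    ----------
    u:
        Horizontal unit wind direction(s); shape ``(3,)`` or ``(A, 3)`` for a
        batch of azimuths.

    Returns
    -------
    F_mid, F_top:
        Forces applied at segment midpoints (stem drag) and at segment distal
        ends (foliage drag; zero for non-twigs).  Shapes ``(n, 3)`` or
        ``(n, A, 3)``.
    """
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    if single:
        u = u[None, :]
    q = 0.5 * params.C_Y * (U / params.U0) ** 2
    # t: (n, 3), u: (A, 3) -> work in (n, A, 3).  The drag is quadratic in
    # the crossflow speed: F = q d L ||t x u||^2 (n x t) with unit n, i.e.
    # ||t x u|| times the unnormalised cross product.
    txu = np.cross(t[:, None, :], u[None, :, :])
    crossflow = np.linalg.norm(txu, axis=-1, keepdims=True)
    F_mid = q * params.L * d[:, None, None] * crossflow \
        * np.cross(txu, t[:, None, :])
    F_top = np.zeros_like(F_mid)
    F_top[twig_mask] = q * params.S_fol * u[None, :, :]
    if single:
        return F_mid[:, 0, :], F_top[:, 0, :]
    return F_mid, F_top


def propagate_loads(
    parent: np.ndarray,
    depth: np.ndarray,
    t: np.ndarray,
    L: float,
    F_mid: np.ndarray,
    F_top: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Leaf-to-root accumulation of forces and moments at segment bases.

    ``F_mid`` acts at the segment midpoint, ``F_top`` at its distal end.  For
    every segment the base loads satisfy the cantilever transmission rule:
    base force = own forces + sum of children base forces, base moment = own
    moments + children base moments + lever arm ``L * t x F_children``.

    Accepts per-azimuth batches: force arrays of shape ``(n, A, 3)``.
    """
    single = F_mid.ndim == 2
    if single:
        F_mid = F_mid[:, None, :]
        F_top = F_top[:, None, :]
    tb = t[:, None, :]
    F_base = F_mid + F_top
    M_base = np.cross(tb, 0.5 * L * F_mid + L * F_top)
    for idx in reversed(level_index(depth)):
        p = parent[idx]
        has_parent = p >= 0
        idx, p = idx[has_parent], p[has_parent]
        if idx.size == 0:
            continue
        np.add.at(F_base, p, F_base[idx])
        np.add.at(M_base, p,
                  M_base[idx] + np.cross(L * t[p][:, None, :], F_base[idx]))
    if single:
        return F_base[:, 0, :], M_base[:, 0, :]
    return F_base, M_base


def bending_stress(M_base: np.ndarray, t: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Maximal surface bending stress ``(32/pi) * ||M x t|| / d**3``.

    A moment parallel to the axis (pure torsion) contributes nothing.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be positive")
    if M_base.ndim == 3:
        bend = np.linalg.norm(np.cross(M_base, t[:, None, :]), axis=-1)
        return (32.0 / math.pi) * bend / d[:, None] ** 3
    bend = np.linalg.norm(np.cross(M_base, t), axis=-1)
    return (32.0 / math.pi) * bend / d ** 3


def azimuth_directions(n: int) -> np.ndarray:
    """``n`` horizontal unit vectors separated by ``2*pi/n``."""
    phi = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n)])


def stress_at(
    parent: np.ndarray,
    depth: np.ndarray,
    t: np.ndarray,
    d: np.ndarray,
    twig_mask: np.ndarray,
    U: float,
    u: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Bending stress per segment for wind ``U`` along ``u`` (batched ok)."""
    F_mid, F_top = wind_forces(t, d, twig_mask, U, u, params)
    _, M_base = propagate_loads(parent, depth, t, params.L, F_mid, F_top)
    return bending_stress(M_base, t, d)


def max_stress(tree: Tree, params: SimulationParams | None = None) -> np.ndarray:
    """Felt stress ``sigma_max/sigma0``: max over fixed azimuths at ``U = U0``.

    The result is cached on ``tree.sigma_rel`` for the secondary-growth
    policy.
    """
    params = params or tree.params
    if tree.n == 0:
        return np.zeros(0)
    u = azimuth_directions(params.n_wind_orientations)
    sig = stress_at(
        tree.col("parent"), tree.col("depth"), tree.col("t"), tree.col("d"),
        tree.twig_mask(), params.U0, u, params,
    )
    smax = sig.max(axis=1)
    tree.col("sigma_rel")[:] = smax
    return smax


def sample_wind(rng: np.random.Generator, params: SimulationParams,
                year: int = 0) -> WindEvent:
    """Draw the yearly storm: exponential speed, uniform azimuth.

    The exponential rate is set so that speeds exceeding
    ``gust_factor * U0`` have a return period of ``return_period`` years.
    """
    U = rng.exponential(1.0 / params.wind_rate)
    azimuth = rng.uniform(0.0, 2.0 * math.pi)
    return WindEvent(U=float(U), azimuth=float(azimuth), year=year)


def fracture_probability(
    sigma: np.ndarray, V: np.ndarray, strength_factor: np.ndarray,
    params: SimulationParams,
) -> np.ndarray:
    """Weibull fracture probability with volume effect.

    Maintenance weakening divides the effective strength: a segment with
    ``strength_factor < 1`` fractures as if the stress were
    ``sigma / strength_factor``.
    """
    sigma = np.asarray(sigma, dtype=float)
    V = np.asarray(V, dtype=float)
    x = (V / params.V0) * (sigma / strength_factor) ** params.m
    return -np.expm1(-x)


def storm_removal_mask(
    parent: np.ndarray,
    depth: np.ndarray,
    sigma: np.ndarray,
    volumes: np.ndarray,
    strength: np.ndarray,
    rng: np.random.Generator,
    params: SimulationParams,
) -> np.ndarray:
    """Segments removed by one storm (root-most break wins).

    Each segment fractures independently with its Weibull probability;
    segments weakened below ``shed_threshold`` fall regardless of load.  A
    segment is removed if it or any of its ancestors breaks; stresses are not
    recomputed after partial breakage within the storm.
    """
    P = fracture_probability(sigma, volumes, strength, params)
    fractured = rng.uniform(size=P.shape) < P
    fractured |= strength <= params.shed_threshold
    removed = fractured.copy()
    for idx in level_index(depth):
        p = parent[idx]
        has_parent = p >= 0
        idx, p = idx[has_parent], p[has_parent]
        if idx.size:
            removed[idx] |= removed[p]
    return removed


def apply_storm(tree: Tree, event: WindEvent, rng: np.random.Generator,
                params: SimulationParams | None = None) -> float:
    """Apply one storm to a single tree; return pruned volume."""
    params = params or tree.params
    if tree.n == 0:
        return 0.0
    u = np.array([math.cos(event.azimuth), math.sin(event.azimuth), 0.0])
    sigma = stress_at(
        tree.col("parent"), tree.col("depth"), tree.col("t"), tree.col("d"),
        tree.twig_mask(), event.U, u, params,
    )
    removed = storm_removal_mask(
        tree.col("parent"), tree.col("depth"), sigma, tree.segment_volumes(),
        tree.col("strength"), rng, params,
    )
    if not removed.any():
        return 0.0
    return tree.remove_segments(removed)
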