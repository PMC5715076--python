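"""Carbon economy: production, sink strengths, secondary growth, maintenance,
primary growth and seed dispersal.

Each foliage produces a photosynthate volume ``V_prod = 4 * V0 * l`` set by
its intercepted light.  Each segment's sink strength is the volume needed to
reach its wind-safety target plus a yearly maintenance volume
``V_maint = pi * L * d * e``; it requests an equal share from every foliage
above it in the hierarchy.  A foliage that produces more than the total
requests fulfils them and banks the leftover in the tree's reserve; otherwise
it pays the requesting segments proportionally.  Received carbon pays
maintenance first; the remainder thickens the segment.  Unpaid maintenance
weakens a segment multiplicatively until it is shed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .architecture import Tree
from .mechanics import level_index
from .params import SimulationParams


def production(l: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Photosynthate volume ``4 * V0 * l`` produced by a foliage [L^3]."""
    l = np.asarray(l, dtype=float)
    if np.any(l < 0.0) or np.any(l > 1.0):
        raise ValueError("light must lie in [0, 1]")
    return params.prod_coeff * params.V0 * l


def segment_sink(
    d: np.ndarray, sigma_rel: np.ndarray, S: np.ndarray,
    params: SimulationParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Growth need and maintenance volume per segment.

    The safety target is a volume ``S * V_fract`` where ``V_fract`` is the
    volume at which the felt stress would equal the wood strength:
    ``d_fract**3 = sigma_rel * d**3``, hence ``V_fract = V * sigma_rel**(2/3)``
    with ``V`` the current volume.  A segment that reaches its target carries
    a relative stress ``sigma/sigma0 = S**(-3/2)``.
    """
    d = np.asarray(d, dtype=float)
    sigma_rel = np.asarray(sigma_rel, dtype=float)
    V_cur = math.pi * params.L * d ** 2 / 4.0
    growth_need = V_cur * np.maximum(0.0, S * sigma_rel ** (2.0 / 3.0) - 1.0)
    V_maint = math.pi * params.L * d * params.e
    return growth_need, V_maint


@dataclass
class AllocationResult:
    """Per-segment outcome of one year of secondary growth (array fields)."""

    production: np.ndarray      # per segment; nonzero on twigs only
    sink: np.ndarray
    received: np.ndarray
    maint_paid: np.ndarray
    maint_frac: np.ndarray      # in [0, 1]
    growth_volume: np.ndarray
    leftover: np.ndarray        # banked in the reserve; twigs only
    new_d: np.ndarray


def allocate_secondary_arrays(
    parent: np.ndarray,
    depth: np.ndarray,
    nchild: np.ndarray,
    d: np.ndarray,
    sigma_rel: np.ndarray,
    S: np.ndarray,
    light: np.ndarray,
    params: SimulationParams,
    levels: list[np.ndarray] | None = None,
) -> AllocationResult:
    """Source-sink allocation over one (or many concatenated) tree(s).

    Works on struct-of-arrays segment storage where children follow parents;
    forests are handled by concatenating trees and offsetting parent indices
    (roots keep parent ``-1``).
    """
    n = d.shape[0]
    twig = nchild == 0
    if levels is None:
        levels = level_index(depth)
    prod = np.zeros(n)
    prod[twig] = production(light[twig], params)

    growth_need, V_maint = segment_sink(d, sigma_rel, S, params)
    sink = growth_need + V_maint

    # Number of foliages above each segment (a twig counts itself).
    nfol = np.where(twig, 1.0, 0.0)
    for idx in reversed(levels):
        p = parent[idx]
        ok = p >= 0
        if ok.any():
            np.add.at(nfol, p[ok], nfol[idx[ok]])

    # Equal per-foliage request; cumulative request along root-to-twig paths.
    q = sink / nfol
    pathq = q.copy()
    for idx in levels:
        p = parent[idx]
        ok = p >= 0
        if ok.any():
            pathq[idx[ok]] += pathq[p[ok]]

    # Fulfilment ratio per foliage and leftover banked in the reserve.
    ratio = np.zeros(n)
    leftover = np.zeros(n)
    req = pathq[twig]
    pr = prod[twig]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(req > 0.0, np.minimum(1.0, pr / req), 1.0)
    ratio[twig] = r
    leftover[twig] = pr - r * req

    # Sum of fulfilment ratios over the foliages above each segment.
    rsum = ratio.copy()
    for idx in reversed(levels):
        p = parent[idx]
        ok = p >= 0
        if ok.any():
            np.add.at(rsum, p[ok], rsum[idx[ok]])

    received = q * rsum
    maint_paid = np.minimum(received, V_maint)
    maint_frac = maint_paid / V_maint
    growth_volume = received - maint_paid
    new_d = np.sqrt(d ** 2 + 4.0 * growth_volume / (math.pi * params.L))
    return AllocationResult(
        production=prod, sink=sink, received=received, maint_paid=maint_paid,
        maint_frac=maint_frac, growth_volume=growth_volume,
        leftover=leftover, new_d=new_d,
    )


def allocate_secondary(tree: Tree, S: np.ndarray,
                       params: SimulationParams | None = None) -> AllocationResult:
    """Run one year of secondary growth on a single tree, in place.

    Uses the cached ``tree.sigma_rel`` (felt stress) and ``tree.light``
    (per-twig intercepted light); updates diameters, strength factors and the
    reserve.
    """
    params = params or tree.params
    res = allocate_secondary_arrays(
        tree.col("parent"), tree.col("depth"), tree.col("nchild"),
        tree.col("d"), tree.col("sigma_rel"), np.asarray(S, dtype=float),
        tree.col("light"), params,
    )
    tree.col("d")[:] = res.new_d
    tree.col("strength")[:] = update_strength(
        tree.col("strength"), res.maint_frac, params)
    tree.reserve += float(np.sum(res.leftover))
    return res


def update_strength(strength: np.ndarray, maint_frac: np.ndarray,
                    params: SimulationParams) -> np.ndarray:
    """Maintenance-weakening state update.

    Underpaid maintenance multiplies the strength factor by
    ``decay + (1 - decay) * fraction`` (halving it at zero maintenance); full
    maintenance lets it recover by ``strength_recovery`` up to 1.
    """
    full = maint_frac >= 1.0
    decayed = strength * (params.strength_decay
                          + (1.0 - params.strength_decay) * maint_frac)
    recovered = np.minimum(1.0, strength * params.strength_recovery)
    return np.where(full, recovered, decayed)


def _pick_twigs(
    n_slots: int, light: np.ndarray, p: float, rng: np.random.Generator,
    replace: bool,
) -> np.ndarray:
    """Photosensitive twig selection.

    Each slot independently takes the best-lit still-available twig with
    probability ``p``, otherwise a uniformly random available one.  Without
    replacement the number of slots is capped by the number of twigs.
    """
    n_twigs = light.shape[0]
    if not replace:
        n_slots = min(n_slots, n_twigs)
    order = np.argsort(-light, kind="stable")  # best-lit first, ties by index
    available = np.ones(n_twigs, dtype=bool)
    chosen = np.empty(n_slots, dtype=np.int64)
    greedy = rng.uniform(size=n_slots) < p
    cursor = 0
    for s in range(n_slots):
        if greedy[s]:
            while not available[order[cursor]]:
                cursor += 1
            pick = order[cursor]
        else:
            avail_idx = np.flatnonzero(available) if not replace else None
            if replace:
                pick = int(rng.integers(0, n_twigs))
            else:
                pick = int(avail_idx[rng.integers(0, avail_idx.shape[0])])
        chosen[s] = pick
        if not replace:
            available[pick] = False
            if greedy[s]:
                cursor += 1
    return chosen


@dataclass
class SeedSpec:
    """A seed ready for dispersal: origin and release height."""

    x: float
    y: float
    height: float


def primary_growth(
    tree: Tree,
    P_seg: float,
    P_seed: float,
    p: float,
    rng: np.random.Generator,
    year: int = 0,
    params: SimulationParams | None = None,
) -> tuple[int, list[SeedSpec]]:
    """Spend the reserve on new segments and seeds.

    ``floor(P_seg * V_res / V0)`` segments and ``floor(P_seed * V_res / 5V0)``
    seeds are budgeted.  Twigs to branch are picked by photosensitivity ``p``
    (most-lit at 1, uniform at 0) without replacement, two children per twig
    (an odd remainder gives a single child); if the budget exceeds twice the
    twig count, only the affordable branchings happen.  Seeds are released
    from twigs picked with the same rule, with replacement, from the
    pre-branching twig set.  Only what is actually built is debited.
    """
    params = params or tree.params
    V0 = params.V0
    n_seg = int(P_seg * tree.reserve / V0)
    n_seed = int(P_seed * tree.reserve / params.seed_cost)
    twigs = np.flatnonzero(tree.twig_mask())
    light = tree.col("light")[twigs]
    ends = tree.distal_ends()[twigs]

    seeds: list[SeedSpec] = []
    if n_seed > 0 and twigs.size > 0:
        picks = _pick_twigs(n_seed, light, p, rng, replace=True)
        for k in picks:
            seeds.append(SeedSpec(x=float(ends[k, 0]), y=float(ends[k, 1]),
                                  height=float(ends[k, 2])))
        tree.reserve -= len(seeds) * params.seed_cost

    n_seg = min(n_seg, 2 * twigs.size)
    if n_seg > 0:
        theta1, theta2, gamma = tree.genome_angles()
        n_slots = (n_seg + 1) // 2
        slots = _pick_twigs(n_slots, light, p, rng, replace=False)
        remaining = n_seg
        for k in slots:
            nc = min(2, remaining)
            tree.attach_children(int(twigs[k]), nc, (theta1, theta2, gamma),
                                 rng, year=year)
            remaining -= nc
        tree.reserve -= n_seg * V0
    return n_seg, seeds


def disperse_seed(
    seed: SeedSpec, rng: np.random.Generator, params: SimulationParams,
) -> tuple[float, float] | None:
    """Ground landing position of a seed, or None if it leaves the island.

    Seeds fall at 45 degrees from the vertical: the horizontal range equals
    the release height, with uniformly random azimuth.  The island admits no
    gene influx or efflux: seeds landing beyond the radius ``R`` are lost.
    """
    phi = rng.uniform(0.0, 2.0 * math.pi)
    x = seed.x + seed.height * math.cos(phi)
    y = seed.y + seed.height * math.sin(phi)
    if math.hypot(x, y) > params.R:
        return None
    return x, y
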