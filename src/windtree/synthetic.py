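"""Synthetic structures for testing and calibration.

Two generators live here: random branched trees (topology/geometry fixtures
with no carbon economy), and synthetic tree cohorts drawn from the
closed-form allometry model with multiplicative log-normal scatter, used for
parameter-recovery studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import analytic
from .architecture import Tree
from .genome import random_genome
from .params import SimulationParams


def random_tree(
    rng: np.random.Generator,
    n_segments: int,
    params: SimulationParams | None = None,
    p_single: float = 0.2,
    diameter_scale: float = 0.0,
) -> Tree:
    """Grow a random tree by repeatedly branching random twigs.

    Branching angles are drawn uniformly per event; with probability
    ``p_single`` a twig gets one child instead of two.  If
    ``diameter_scale > 0``, diameters are jittered multiplicatively
    (log-normal with that sigma) to decorrelate geometry from topology.
    """
    params = params or SimulationParams()
    tree = Tree(params, random_genome(rng), (0.0, 0.0), rng)
    while tree.n < n_segments:
        twigs = np.flatnonzero(tree.twig_mask())
        twig = int(twigs[rng.integers(0, twigs.size)])
        n_children = 1 if rng.uniform() < p_single else 2
        n_children = min(n_children, n_segments - tree.n)
        angles = (float(rng.uniform(0.0, 90.0)),
                  float(rng.uniform(-90.0, 0.0)),
                  float(rng.uniform(0.0, 180.0)))
        tree.attach_children(twig, n_children, angles, rng)
    if diameter_scale > 0.0:
        d = tree.col("d")
        d *= np.exp(rng.normal(0.0, diameter_scale, size=tree.n))
    return tree


def comb_tree(params: SimulationParams, n_segments: int,
              rng: np.random.Generator | None = None) -> Tree:
    """Unbranched vertical chain of ``n_segments`` segments (rank-1 ladder)."""
    from dataclasses import replace

    rng = rng or np.random.default_rng(0)
    params = replace(params, delta_theta=0.0)  # keep the chain straight
    tree = Tree(params, random_genome(rng), (0.0, 0.0), rng)
    while tree.n < n_segments:
        twig = int(np.flatnonzero(tree.twig_mask())[0])
        tree.attach_children(twig, 1, (0.0, 0.0, 0.0), rng)
    return tree


def self_similar_tree(
    K: int,
    R_n: int = 4,
    R_l: int = 2,
    params: SimulationParams | None = None,
) -> Tree:
    """Exactly self-similar skeleton with integer Strahler ratios.

    A rank-``k`` branch is a run of ``R_l**(k-1)`` segments ending, for
    ``k > 1``, in two terminal rank-``(k-1)`` branches, with ``R_n - 2``
    further rank-``(k-1)`` side branches attached along the run; so every
    rank table follows an exact geometric progression with branching ratio
    ``R_n`` and length ratio ``R_l`` (hence fractal dimension
    ``ln R_n / ln R_l``).  Diameters are uniform ``d0``.
    """
    from dataclasses import replace

    if K < 1 or R_n < 2 or R_l < 1:
        raise ValueError("need K >= 1, R_n >= 2, R_l >= 1")
    params = replace(params or SimulationParams(), delta_theta=0.0)
    rng = np.random.default_rng(0)
    tree = Tree(params, random_genome(rng), (0.0, 0.0), rng)
    angles = (30.0, -30.0, 90.0)
    n_side = R_n - 2
    # Every fork along a rank-k run contributes one rank-k segment, so the
    # base run length must cover the n_side side forks: l_k = l1 * R_l**(k-1)
    # with l1 = max(1, n_side + 1) keeps every branch length exact.
    l1 = max(1, n_side + 1)

    def build(tip: int, k: int) -> None:
        # ``tip`` is the first segment of this rank-k branch, already placed.
        length = l1 * R_l ** (k - 1)
        if k == 1:
            for _ in range(length - 1):
                tip = tree.attach_children(tip, 1, angles, rng)[0]
            return
        n_plain = length - 1 - n_side  # unbranched run extensions
        for _ in range(n_plain):
            tip = tree.attach_children(tip, 1, angles, rng)[0]
        for _ in range(n_side):
            cont, side = tree.attach_children(tip, 2, angles, rng)
            build(side, k - 1)
            tip = cont
        left, right = tree.attach_children(tip, 2, angles, rng)
        build(left, k - 1)
        build(right, k - 1)

    build(0, K)
    return tree


def analytic_cohort(
    n: int,
    rng: np.random.Generator,
    p: analytic.AnalyticParams | None = None,
    sigma_log: float = 0.1,
    log10_d_range: tuple[float, float] = (-1.0, 2.0),
    crown_fraction: float = 0.3,
) -> pd.DataFrame:
    """Cohort of tree summaries drawn from the closed-form allometries.

    Latent trunk diameters are log-uniform over ``log10_d_range`` (units of
    L); height, crown radius, foliage count and stem volume follow the
    closed-form power laws, and every observed quantity (including the
    diameter) carries independent multiplicative log-normal scatter of
    sigma ``sigma_log`` in natural log — the errors-in-all-variables
    situation RMA regression is designed for.  Crown radius is modelled as
    isometric with height (``crown_fraction`` of it).  Output matches the
    per-tree summary schema (columns H, C, N, B, d_trunk, x, y).
    """
    p = p or analytic.AnalyticParams()
    beta_H, beta_N, beta_B, _ = analytic.exponents(p.D)
    c_H, c_N, c_B = analytic.prefactors(p)
    d = 10.0 ** rng.uniform(*log10_d_range, size=n)
    H = c_H * d ** beta_H
    C = crown_fraction * H
    N = c_N * d ** beta_N
    B = c_B * d ** beta_B
    noisy = lambda v: v * np.exp(rng.normal(0.0, sigma_log, size=n))
    return pd.DataFrame({
        "H": noisy(H), "C": noisy(C), "N": noisy(N), "B": noisy(B),
        "d_trunk": noisy(d),
        "age": 0, "x": np.zeros(n), "y": np.zeros(n),
    })
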