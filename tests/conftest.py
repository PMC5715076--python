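"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import windtree as wt
from windtree import synthetic
from windtree.params import SimulationParams


@pytest.fixture()
def params() -> SimulationParams:
    return SimulationParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_trees() -> list[wt.Tree]:
    """A reusable bank of 1,000 random trees of up to 100 segments."""
    gen = np.random.default_rng(2024)
    params = SimulationParams()
    trees = []
    for _ in range(1000):
        n = int(gen.integers(1, 101))
        trees.append(synthetic.random_tree(gen, n, params,
                                           diameter_scale=0.3))
    return trees


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------

def children_lists(tree: wt.Tree) -> list[list[int]]:
    kids: list[list[int]] = [[] for _ in range(tree.n)]
    parent = tree.col("parent")
    for i in range(1, tree.n):
        kids[parent[i]].append(i)
    return kids


def strahler_oracle(tree: wt.Tree) -> np.ndarray:
    """Textbook recursive Strahler ranking."""
    import sys
    sys.setrecursionlimit(10000)
    kids = children_lists(tree)
    rank = np.zeros(tree.n, dtype=int)

    def visit(i: int) -> int:
        if not kids[i]:
            rank[i] = 1
        elif len(kids[i]) == 1:
            rank[i] = visit(kids[i][0])
        else:
            r1, r2 = visit(kids[i][0]), visit(kids[i][1])
            rank[i] = r1 + 1 if r1 == r2 else max(r1, r2)
        return rank[i]

    visit(0)
    return rank


def mean_path_oracle(tree: wt.Tree) -> np.ndarray:
    """Exhaustive path enumeration: mean segment-count distance to foliages."""
    kids = children_lists(tree)
    out = np.zeros(tree.n)
    for i in range(tree.n):
        lengths = []
        stack = [(i, 1)]
        while stack:
            j, depth = stack.pop()
            if not kids[j]:
                lengths.append(depth)
            for c in kids[j]:
                stack.append((c, depth + 1))
        out[i] = tree.params.L * float(np.mean(lengths))
    return out


def subtree_matrix(tree: wt.Tree) -> np.ndarray:
    """Boolean matrix: entry (i, j) true iff j lies in the subtree of i."""
    n = tree.n
    parent = tree.col("parent")
    sub = np.zeros((n, n), dtype=bool)
    for j in range(n):
        if parent[j] >= 0:
            sub[:, j] = sub[:, parent[j]]
        sub[j, j] = True
    return sub


def moment_oracle(tree: wt.Tree, U: float, u: np.ndarray) -> np.ndarray:
    """Direct moment summation via the subtree membership matrix:
    M_i = sum over subtree loads of (r - r_base_i) x F."""
    from windtree import mechanics as mech

    params = tree.params
    F_mid, F_top = mech.wind_forces(tree.col("t"), tree.col("d"),
                                    tree.twig_mask(), U, u, params)
    mid_pts = tree.col("base") + 0.5 * params.L * tree.col("t")
    top_pts = tree.col("base") + params.L * tree.col("t")
    sub = subtree_matrix(tree).astype(float)
    torque = np.cross(mid_pts, F_mid) + np.cross(top_pts, F_top)
    F_sub = sub @ (F_mid + F_top)
    return sub @ torque - np.cross(tree.col("base"), F_sub)


def mean_path_oracle_chains(tree: wt.Tree) -> np.ndarray:
    """Mean path length by walking every twig's ancestor chain."""
    parent = tree.col("parent")
    depth = tree.col("depth")
    totals = np.zeros(tree.n)
    counts = np.zeros(tree.n)
    for f in np.flatnonzero(tree.twig_mask()):
        a = int(f)
        while a >= 0:
            counts[a] += 1
            totals[a] += depth[f] - depth[a] + 1
            a = int(parent[a])
    return tree.params.L * totals / counts


def brute_force_moments(tree: wt.Tree, U: float,
                        u: np.ndarray) -> np.ndarray:
    """Direct moment summation: for every segment, sum (r_i - r_base) x F_i
    over all wind loads applied anywhere in its subtree."""
    from windtree import mechanics as mech

    params = tree.params
    F_mid, F_top = mech.wind_forces(tree.col("t"), tree.col("d"),
                                    tree.twig_mask(), U, u, params)
    mid_pts = tree.col("base") + 0.5 * params.L * tree.col("t")
    top_pts = tree.col("base") + params.L * tree.col("t")
    kids = children_lists(tree)
    M = np.zeros((tree.n, 3))
    for i in range(tree.n):
        subtree = []
        stack = [i]
        while stack:
            j = stack.pop()
            subtree.append(j)
            stack.extend(kids[j])
        base = tree.col("base")[i]
        total = np.zeros(3)
        for j in subtree:
            total += np.cross(mid_pts[j] - base, F_mid[j])
            total += np.cross(top_pts[j] - base, F_top[j])
        M[i] = total
    return M
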