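"""Tree topology and 3-D geometry.

A tree is a rooted at-most-binary assembly of cylindrical segments of common
length ``L`` and varying diameter.  Segments are stored in struct-of-arrays
form, in creation order, which guarantees that every child has a larger index
than its parent; all topological passes exploit that ordering.  Twigs
(childless segments) each carry one spherical foliage centred on their distal
end.
"""

from __future__ import annotations

import math
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .params import SimulationParams

if TYPE_CHECKING:
    from .genome import Genome


def _rotate(v: np.ndarray, axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Right-handed Rodrigues rotation of ``v`` about unit ``axis``.

    The right-handed convention (positive angle = counterclockwise when the
    axis points at the viewer) is used for every rotation in the package.
    """
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return c * v + s * np.cross(axis, v) + (1.0 - c) * np.dot(axis, v) * axis


def make_child_frames(
    t: np.ndarray,
    b: np.ndarray,
    theta1: float,
    theta2: float,
    gamma: float,
    delta_theta: float,
    eps: Sequence[float],
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Construct the two child frames of a branching event.

    The child axes ``t1, t2`` are obtained by rotating the parent axis ``t``
    about the branching-plane normal ``b`` by ``theta1 + eps[0]*delta_theta``
    and ``theta2 + eps[1]*delta_theta`` (degrees); the child normals are ``b``
    rotated about each child axis by ``gamma + eps[2]*delta_theta``.

    Parameters
    ----------
    t, b:
        Orthonormal parent frame (axis direction, branching-plane normal).
    eps:
        Three standard-normal draws, one per rotated angle.
    """
    t = np.asarray(t, dtype=float)
    b = np.asarray(b, dtype=float)
    if abs(np.linalg.norm(t) - 1.0) > 1e-9 or abs(np.linalg.norm(b) - 1.0) > 1e-9:
        raise ValueError("t and b must be unit vectors")
    if abs(float(np.dot(t, b))) > 1e-9:
        raise ValueError("t and b must be orthogonal")
    a1 = theta1 + eps[0] * delta_theta
    a2 = theta2 + eps[1] * delta_theta
    g = gamma + eps[2] * delta_theta
    frames = []
    for a in (a1, a2):
        ti = _rotate(t, b, a)
        ti /= np.linalg.norm(ti)
        bi = _rotate(b, ti, g)
        bi /= np.linalg.norm(bi)
        frames.append((ti, bi))
    return frames


class Tree:
    """A single individual: genome, position, reserve and segment arrays.

    Segment fields (index ``i`` in ``[0, n)``; the trunk is index 0):

    - ``parent[i]``: parent index, ``-1`` for the trunk,
    - ``nchild[i]``: number of children (0, 1 or 2),
    - ``t[i], b[i]``: unit axis direction and branching-plane normal,
    - ``base[i]``: base position; the distal end is ``base + L*t``,
    - ``d[i]``: diameter (never decreases),
    - ``year[i]``: creation year,
    - ``strength[i]``: maintenance-weakening state in ``(0, 1]``,
    - ``depth[i]``: topological depth (trunk 0).
    """

    __slots__ = (
        "params", "id", "lineage_id", "genome", "position", "birth_year",
        "alive", "reserve", "n", "_cap", "parent", "nchild", "t", "b",
        "base", "d", "year", "strength", "depth", "sigma_rel", "light",
        "_decoded",
    )

    def __init__(
        self,
        params: SimulationParams,
        genome: "Genome",
        position: tuple[float, float],
        rng: np.random.Generator,
        tree_id: int = 0,
        lineage_id: int = 0,
        birth_year: int = 0,
    ) -> None:
        self.params = params
        self.id = tree_id
        self.lineage_id = lineage_id
        self.genome = genome
        self.position = (float(position[0]), float(position[1]))
        self.birth_year = birth_year
        self.alive = True
        self.reserve = params.initial_reserve
        self._decoded = None

        cap = 8
        self._cap = cap
        self.n = 0
        self.parent = np.full(cap, -1, dtype=np.int32)
        self.nchild = np.zeros(cap, dtype=np.int8)
        self.t = np.zeros((cap, 3))
        self.b = np.zeros((cap, 3))
        self.base = np.zeros((cap, 3))
        self.d = np.zeros(cap)
        self.year = np.zeros(cap, dtype=np.int32)
        self.strength = np.ones(cap)
        self.depth = np.zeros(cap, dtype=np.int32)
        # Per-segment felt stress (units sigma0), refreshed every year.
        self.sigma_rel = np.zeros(cap)
        # Per-twig intercepted light, refreshed every year (0 elsewhere).
        self.light = np.zeros(cap)

        # Trunk: vertical axis, random horizontal branching-plane normal.
        phi = rng.uniform(0.0, 2.0 * math.pi)
        self._append(
            parent=-1,
            t=np.array([0.0, 0.0, 1.0]),
            b=np.array([math.cos(phi), math.sin(phi), 0.0]),
            base=np.array([position[0], position[1], 0.0]),
            year=birth_year,
        )

    # -- storage ----------------------------------------------------------

    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        if need <= self._cap:
            return
        cap = max(need, 2 * self._cap)
        for name in ("parent", "nchild", "t", "b", "base", "d", "year",
                     "strength", "depth", "sigma_rel", "light"):
            old = getattr(self, name)
            shape = (cap,) + old.shape[1:]
            new = np.zeros(shape, dtype=old.dtype)
            new[: self.n] = old[: self.n]
            setattr(self, name, new)
        self.parent[self.n:] = -1
        self.strength[self.n:] = 1.0
        self._cap = cap

    def _append(self, parent: int, t: np.ndarray, b: np.ndarray,
                base: np.ndarray, year: int) -> int:
        self._ensure(1)
        i = self.n
        self.parent[i] = parent
        self.nchild[i] = 0
        self.t[i] = t
        self.b[i] = b
        self.base[i] = base
        self.d[i] = self.params.d0
        self.year[i] = year
        self.strength[i] = 1.0
        self.sigma_rel[i] = 0.0
        self.light[i] = 0.0
        if parent >= 0:
            self.depth[i] = self.depth[parent] + 1
            self.nchild[parent] += 1
        else:
            self.depth[i] = 0
        self.n += 1
        return i

    # -- views ------------------------------------------------------------

    def col(self, name: str) -> np.ndarray:
        """Live view of a segment field, length ``n``."""
        return getattr(self, name)[: self.n]

    @property
    def n_segments(self) -> int:
        return self.n

    def twig_mask(self) -> np.ndarray:
        return self.col("nchild") == 0

    @property
    def n_foliages(self) -> int:
        return int(np.count_nonzero(self.twig_mask()))

    def foliage_centers(self) -> np.ndarray:
        """Centers of all foliages (twig distal ends), shape (n_fol, 3)."""
        tw = self.twig_mask()
        return self.col("base")[tw] + self.params.L * self.col("t")[tw]

    def distal_ends(self) -> np.ndarray:
        return self.col("base") + self.params.L * self.col("t")

    def segment_volumes(self) -> np.ndarray:
        return math.pi * self.params.L * self.col("d") ** 2 / 4.0

    def age(self, current_year: int) -> int:
        return current_year - self.birth_year

    def decoded(self):
        """Cached genome decode: (theta1, theta2, gamma, primary, secondary)."""
        if self._decoded is None:
            from .genome import decode_genome
            self._decoded = decode_genome(self.genome)
        return self._decoded

    def genome_angles(self) -> tuple[float, float, float]:
        theta1, theta2, gamma, _, _ = self.decoded()
        return theta1, theta2, gamma

    # -- growth -----------------------------------------------------------

    def attach_children(
        self,
        twig_id: int,
        n_children: int,
        angles: tuple[float, float, float],
        rng: np.random.Generator,
        year: int = 0,
    ) -> list[int]:
        """Add ``n_children`` segments of diameter ``d0`` at a twig's distal end.

        The parent's foliage is implicitly replaced by the children's (a
        foliage exists exactly on childless segments).  With one child, the
        first frame of the branching rule is used.
        """
        if n_children not in (1, 2):
            raise ValueError("n_children must be 1 or 2")
        if twig_id < 0 or twig_id >= self.n:
            raise KeyError(f"no segment {twig_id}")
        if self.nchild[twig_id] != 0:
            raise ValueError(f"segment {twig_id} is not a twig")
        theta1, theta2, gamma = angles
        eps = rng.standard_normal(3)
        frames = make_child_frames(
            self.t[twig_id], self.b[twig_id], theta1, theta2, gamma,
            self.params.delta_theta, eps,
        )
        end = self.base[twig_id] + self.params.L * self.t[twig_id]
        ids = []
        for ti, bi in frames[:n_children]:
            ids.append(self._append(twig_id, ti, bi, end, year))
        return ids

    # -- topology ---------------------------------------------------------

    def descendant_mask(self, segment_id: int) -> np.ndarray:
        """Mask of ``segment_id`` and all its descendants."""
        if segment_id < 0 or segment_id >= self.n:
            raise KeyError(f"no segment {segment_id}")
        mask = np.zeros(self.n, dtype=bool)
        mask[segment_id] = True
        parent = self.col("parent")
        for i in range(segment_id + 1, self.n):
            if parent[i] >= 0 and mask[parent[i]]:
                mask[i] = True
        return mask

    def remove_segments(self, mask: np.ndarray) -> float:
        """Remove the masked segments (must be subtree-closed); return volume.

        The whole tree dies if the trunk is removed.  Surviving segments keep
        their geometry; parents that lose all children become twigs again.
        """
        mask = np.asarray(mask, dtype=bool)
        vol = float(np.sum(self.segment_volumes()[mask]))
        if mask[0]:
            self.n = 0
            self.alive = False
            return vol
        keep = ~mask
        new_index = np.cumsum(keep) - 1
        for name in ("nchild", "t", "b", "base", "d", "year", "strength",
                     "depth", "sigma_rel", "light"):
            arr = self.col(name)
            getattr(self, name)[: int(keep.sum())] = arr[keep]
        old_parent = self.col("parent").copy()
        kept_parent = old_parent[keep]
        remapped = np.where(kept_parent >= 0, new_index[kept_parent], -1)
        self.n = int(keep.sum())
        self.parent[: self.n] = remapped.astype(np.int32)
        counts = np.bincount(remapped[remapped >= 0], minlength=self.n)
        self.nchild[: self.n] = counts.astype(np.int8)
        return vol

    def remove_subtree(self, segment_id: int) -> float:
        """Remove a segment and all its descendants; return the removed volume."""
        return self.remove_segments(self.descendant_mask(segment_id))


def strahler_orders(tree: Tree) -> tuple[np.ndarray, np.ndarray]:
    """Strahler rank of every segment and its branch id.

    Twig segments have rank 1; a parent of two equal-rank-``r`` children has
    rank ``r + 1``, otherwise the maximum child rank; an unbranched run keeps
    its child's rank.  A *branch* is a maximal connected run of equal-rank
    segments; branch ids are contiguous integers in discovery (index) order.
    """
    n = tree.n
    if n == 0:
        return np.zeros(0, dtype=np.int32), np.zeros(0, dtype=np.int32)
    parent = tree.col("parent")
    nchild = tree.col("nchild")
    if np.any(parent[1:] >= np.arange(1, n)):
        raise ValueError("segment order is not topological (cycle?)")
    rank = np.ones(n, dtype=np.int32)
    cmax = np.zeros(n, dtype=np.int32)
    cmin = np.full(n, np.iinfo(np.int32).max, dtype=np.int32)
    for i in range(n - 1, -1, -1):
        if nchild[i] == 2:
            rank[i] = cmax[i] + 1 if cmax[i] == cmin[i] else cmax[i]
        elif nchild[i] == 1:
            rank[i] = cmax[i]
        p = parent[i]
        if p >= 0:
            if rank[i] > cmax[p]:
                cmax[p] = rank[i]
            if rank[i] < cmin[p]:
                cmin[p] = rank[i]
    branch = np.zeros(n, dtype=np.int32)
    nb = 0
    for i in range(n):
        p = parent[i]
        if p >= 0 and rank[i] == rank[p]:
            branch[i] = branch[p]
        else:
            branch[i] = nb
            nb += 1
    return rank, branch


def subtree_foliage_counts(tree: Tree) -> np.ndarray:
    """Number of descendant foliages per segment (a twig counts its own)."""
    n = tree.n
    parent = tree.col("parent")
    counts = np.where(tree.twig_mask(), 1, 0).astype(np.int64)
    for i in range(n - 1, 0, -1):
        counts[parent[i]] += counts[i]
    return counts
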