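"""Canopy light interception by hemisphere ray casting.

Sunlight is taken as uniformly distributed over the upper hemisphere, which is
partitioned into 32 equal solid angles (4 zenith bands of equal solid angle,
8 azimuth sectors each).  For each solid angle the whole scene is rotated so
that the mean direction of the cell points along +z, foliage centers are
binned onto an ``L x L`` ground grid, and within each column light attenuates
geometrically with occlusion depth: the highest foliage receives ``1/32`` of
full light, the next ``alpha_fol/32``, then ``alpha_fol**2/32`` and so on.
Segments cast no shadow.  The per-direction work is a sort, so the whole
computation scales as ``N log N`` in the number of foliages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass
class SkyPartition:
    """Mean directions (unit vectors) of the sky cells, equal weights."""

    directions: np.ndarray   # (n, 3), all with positive z
    weight: float            # light fraction carried by one cell (1/n)


def sky_directions(n: int = 32, n_bands: int = 4) -> SkyPartition:
    """Partition the upper hemisphere into ``n`` equal solid angles.

    ``n`` must factor as ``n_bands`` zenith bands times an integer number of
    azimuth sectors.  Bands are bounded by equally spaced cos-zenith values
    (for 4 bands: 1, 3/4, 1/2, 1/4, 0) so every cell subtends ``2*pi/n``
    steradians.  Each cell is represented by the normalised centroid of the
    direction vector over the cell.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if n % n_bands != 0:
        raise ValueError("n must be divisible by n_bands")
    n_az = n // n_bands
    mus = np.linspace(1.0, 0.0, n_bands + 1)  # cos-zenith boundaries
    dirs = []

    def _int_sin(mu: float) -> float:
        # integral of sqrt(1 - mu'^2) d mu'
        return 0.5 * (mu * math.sqrt(max(0.0, 1.0 - mu * mu)) + math.asin(mu))

    for ib in range(n_bands):
        mu_hi, mu_lo = mus[ib], mus[ib + 1]
        dmu = mu_hi - mu_lo
        z_mean = 0.5 * (mu_hi + mu_lo)
        rho_mean = (_int_sin(mu_hi) - _int_sin(mu_lo)) / dmu
        for ia in range(n_az):
            p0 = 2.0 * math.pi * ia / n_az
            p1 = 2.0 * math.pi * (ia + 1) / n_az
            dphi = p1 - p0
            cx = rho_mean * (math.sin(p1) - math.sin(p0)) / dphi
            cy = rho_mean * (math.cos(p0) - math.cos(p1)) / dphi
            v = np.array([cx, cy, z_mean])
            dirs.append(v / np.linalg.norm(v))
    return SkyPartition(directions=np.array(dirs), weight=1.0 / n)


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Orthonormal matrix whose third row is ``direction`` (maps it to +z)."""
    w = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(w[0]) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(ref, w)
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.vstack([u, v, w])


def intercept_light(
    centers: np.ndarray,
    alpha_fol: float,
    L: float = 1.0,
    sky: SkyPartition | None = None,
) -> np.ndarray:
    """Light ``l`` in [0, 1] intercepted by each foliage.

    Parameters
    ----------
    centers:
        Foliage center positions, shape ``(N, 3)``.  Ties in height within a
        grid column are broken by array index, for determinism.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        return np.zeros(0)
    if sky is None:
        sky = sky_directions()
    nf = centers.shape[0]
    light = np.zeros(nf)
    idx = np.arange(nf)
    for w in sky.directions:
        rot = _rotation_to_z(w)
        xyz = centers @ rot.T
        ix = np.floor(xyz[:, 0] / L).astype(np.int64)
        iy = np.floor(xyz[:, 1] / L).astype(np.int64)
        order = np.lexsort((idx, -xyz[:, 2], iy, ix))
        sx, sy = ix[order], iy[order]
        new_col = np.empty(nf, dtype=bool)
        new_col[0] = True
        new_col[1:] = (sx[1:] != sx[:-1]) | (sy[1:] != sy[:-1])
        col_start = np.maximum.accumulate(np.where(new_col, np.arange(nf), 0))
        depth = np.arange(nf) - col_start
        light[order] += sky.weight * alpha_fol ** depth
    return light
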