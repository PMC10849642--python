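"""Shared geometric fixtures: tubes, arcs, and brute-force helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import cKDTree


def make_cylinder_mask(radius_vox: float, length_vox: int, pad: int = 4,
                       axis_margin: int = 2) -> np.ndarray:
    """Flat-ended cylinder along x, center in (z, y)."""
    side = int(2 * (radius_vox + pad))
    c = side / 2
    z, y, x = np.mgrid[0:side, 0:side, 0 : length_vox + 2 * axis_margin]
    return (
        ((z + 0.5 - c) ** 2 + (y + 0.5 - c) ** 2 <= radius_vox**2)
        & (x >= axis_margin)
        & (x < axis_margin + length_vox)
    )


def make_arc_tube_mask(bend_radius_um: float, tube_radius_um: float,
                       voxel: float = 1.0):
    """Quarter-circle tube with flat-cut ends (a segment of a longer tube).

    Returns (mask, analytic_centerline_points, analytic_length).
    """
    r, R = tube_radius_um, bend_radius_um
    cz = r + 5.0
    c0 = r + 5.0  # arc center offset in y and x
    t = np.linspace(0, np.pi / 2, 800)
    ctr = np.stack(
        [np.full_like(t, cz), c0 + R * np.sin(t), c0 + R * np.cos(t)], axis=1
    )
    extent = int(np.ceil((c0 + R + r + 5) / voxel))
    nz = int(np.ceil(2 * cz / voxel))
    zz, yy, xx = np.mgrid[0:nz, 0:extent, 0:extent]
    pts = np.stack(
        [(zz.ravel() + 0.5) * voxel, (yy.ravel() + 0.5) * voxel, (xx.ravel() + 0.5) * voxel],
        axis=1,
    )
    d, _ = cKDTree(ctr).query(pts)
    theta = np.arctan2(pts[:, 1] - c0, pts[:, 2] - c0)
    mask = ((d <= r) & (theta >= 0) & (theta <= np.pi / 2)).reshape(zz.shape)
    return mask, ctr, np.pi * R / 2


def brute_force_distance(mask: np.ndarray, voxel_size) -> np.ndarray:
    """Min Euclidean center-to-center distance to any mask voxel (the oracle)."""
    vs = np.asarray(voxel_size, dtype=float)
    src = np.argwhere(mask) * vs
    out = np.empty(mask.size)
    all_pts = np.argwhere(np.ones_like(mask)) * vs
    for i, p in enumerate(all_pts):
        out[i] = np.sqrt(((src - p) ** 2).sum(axis=1).min())
    return out.reshape(mask.shape)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
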