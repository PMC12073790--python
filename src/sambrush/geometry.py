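"""Shared slab-geometry helpers.

The systems analysed here are slabs: a gold plane at Z = 0 with grafted
chains growing toward +Z.  All distance computations therefore apply the
minimum-image convention in X and Y only; Z is non-periodic.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "min_image_displacements",
    "pair_distance_matrix",
    "wrap_xy",
    "xy_periodic_tree",
]


def min_image_displacements(dv: np.ndarray, box: tuple[float, float, float]) -> np.ndarray:
    """Apply minimum-image wrapping in X and Y (in place on a copy)."""
    dv = np.asarray(dv, dtype=float).copy()
    for ax in (0, 1):
        L = box[ax]
        dv[..., ax] -= L * np.round(dv[..., ax] / L)
    return dv


def pair_distance_matrix(
    pos_a: np.ndarray, pos_b: np.ndarray, box: tuple[float, float, float]
) -> np.ndarray:
    """Dense |A| x |B| distance matrix under XY minimum image."""
    dv = pos_a[:, None, :] - pos_b[None, :, :]
    dv = min_image_displacements(dv, box)
    return np.sqrt(np.einsum("ijk,ijk->ij", dv, dv))


def wrap_xy(positions: np.ndarray, box: tuple[float, float, float]) -> np.ndarray:
    """Wrap X and Y into [0, L); Z is left untouched."""
    out = np.array(positions, dtype=float, copy=True)
    for ax in (0, 1):
        out[:, ax] %= box[ax]
    return out


def xy_periodic_tree(positions: np.ndarray, box: tuple[float, float, float]) -> tuple[cKDTree, np.ndarray, float]:
    """KD-tree periodic in XY only.

    Z is made effectively non-periodic by giving it a period far beyond any
    coordinate.  Returns (tree, shifted_positions, z_shift): Z is shifted by
    ``z_shift`` so all coordinates are non-negative, as cKDTree requires for
    periodic boxes.
    """
    pos = wrap_xy(positions, box)
    zmin = float(pos[:, 2].min())
    z_shift = -zmin if zmin < 0 else 0.0
    pos[:, 2] += z_shift
    z_period = 1000.0 * (pos[:, 2].max() + box[2] + 1.0)
    tree = cKDTree(pos, boxsize=[box[0], box[1], z_period])
    return tree, pos, z_shift
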