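"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use the most literal definition of each quantity —
pairwise distances, explicit cell counting, explicit ball painting — and
share no code with the package's algorithms.
"""

from __future__ import annotations

import numpy as np


def brute_force_edt(mask: np.ndarray) -> np.ndarray:
    """Distance from every voxel to the nearest True voxel, by explicit
    minimization over all foreground voxels (O(n^2))."""
    fg = np.argwhere(mask)
    if len(fg) == 0:
        raise ValueError("empty mask")
    coords = np.argwhere(np.ones(mask.shape, dtype=bool))
    d2 = np.full(len(coords), np.inf)
    for chunk in np.array_split(fg, max(len(fg) // 256, 1)):
        diff = coords[:, None, :] - chunk[None, :, :]
        d2 = np.minimum(d2, (diff.astype(float) ** 2).sum(axis=2).min(axis=1))
    return np.sqrt(d2).reshape(mask.shape)


def cubical_complex_chi(mask: np.ndarray) -> int:
    """Euler characteristic as vertices - edges + faces - cubes of the
    closed-cube complex (one closed unit cube per foreground voxel)."""
    verts, edges, faces, cubes = set(), set(), set(), set()
    for z, y, x in zip(*np.nonzero(mask)):
        cubes.add((z, y, x))
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    verts.add((z + a, y + b, x + c))
                edges.add(frozenset({(z + a, y + b, x), (z + a, y + b, x + 1)}))
                edges.add(frozenset({(z + a, y, x + b), (z + a, y + 1, x + b)}))
                edges.add(frozenset({(z, y + a, x + b), (z + 1, y + a, x + b)}))
            faces.add(
                frozenset(
                    {(z + a, y, x), (z + a, y, x + 1), (z + a, y + 1, x), (z + a, y + 1, x + 1)}
                )
            )
            faces.add(
                frozenset(
                    {(z, y + a, x), (z, y + a, x + 1), (z + 1, y + a, x), (z + 1, y + a, x + 1)}
                )
            )
            faces.add(
                frozenset(
                    {(z, y, x + a), (z, y + 1, x + a), (z + 1, y, x + a), (z + 1, y + 1, x + a)}
                )
            )
    return len(verts) - len(edges) + len(faces) - len(cubes)


def brute_force_local_thickness(mask: np.ndarray) -> np.ndarray:
    """Maximum-inscribed-ball thickness by painting every ball explicitly.

    Every foreground voxel j carries a ball of radius r_j = (distance to the
    nearest background voxel, by brute force); every voxel strictly inside
    any ball gets the diameter of the largest such ball.  Voxel units.
    """
    fg = np.argwhere(mask)
    if len(fg) == 0:
        return np.zeros(mask.shape)
    bg = np.argwhere(~mask)
    if len(bg) == 0:
        raise ValueError("mask has no background: radii are unbounded")
    # r_j^2: squared nearest-background distance per foreground voxel
    # (kept as exact integers so the strict open-ball test is unambiguous)
    r2 = np.full(len(fg), np.iinfo(np.int64).max)
    for chunk in np.array_split(bg, max(len(bg) // 256, 1)):
        diff = fg[:, None, :] - chunk[None, :, :]
        r2 = np.minimum(r2, (diff**2).sum(axis=2).min(axis=1))
    out = np.zeros(mask.shape)
    coords = np.indices(mask.shape)
    for (z, y, x), rj2 in zip(fg, r2):
        d2 = (coords[0] - z) ** 2 + (coords[1] - y) ** 2 + (coords[2] - x) ** 2
        covered = d2 < rj2
        out[covered] = np.maximum(out[covered], 2.0 * np.sqrt(rj2))
    return out
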