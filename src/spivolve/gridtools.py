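"""Trilinear gather/scatter between point sets and cubic grids.

The gather and scatter use the same eight-neighbour weights, so scatter is
the exact adjoint of gather — the property the orientation-recovery
compress step relies on.
"""

from __future__ import annotations

import numpy as np


def _corner_weights(coords: np.ndarray, n: int):
    """Eight corner flat indices and weights for points in voxel units.

    ``coords`` is (..., 3) in index space.  Points must lie inside the grid
    ``[0, n-1]`` (clipped by a half-voxel guard).
    """
    c = np.clip(coords, 0.0, n - 1.0 - 1e-9)
    f = np.floor(c).astype(np.int64)
    d = c - f
    idx = []
    wts = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = ((d[..., 0] if dz else 1 - d[..., 0])
                     * (d[..., 1] if dy else 1 - d[..., 1])
                     * (d[..., 2] if dx else 1 - d[..., 2]))
                i = ((f[..., 0] + dz) * n + (f[..., 1] + dy)) * n + (f[..., 2] + dx)
                idx.append(i)
                wts.append(w)
    return np.stack(idx, axis=-1), np.stack(wts, axis=-1)


def trilinear_gather(volume: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Sample a cubic ``volume`` at fractional index ``coords`` (..., 3)."""
    n = volume.shape[0]
    idx, wts = _corner_weights(np.asarray(coords, dtype=np.float64), n)
    return np.sum(volume.reshape(-1)[idx] * wts, axis=-1)


def trilinear_scatter(values: np.ndarray, coords: np.ndarray, n: int,
                      out: np.ndarray = None) -> np.ndarray:
    """Adjoint of :func:`trilinear_gather`: spread ``values`` onto an n^3 grid."""
    idx, wts = _corner_weights(np.asarray(coords, dtype=np.float64), n)
    flat = np.bincount(idx.reshape(-1),
                       weights=(values[..., None] * wts).reshape(-1),
                       minlength=n ** 3)
    if out is None:
        return flat.reshape(n, n, n)
    out += flat.reshape(n, n, n)
    return out


def precompute_weights(coords: np.ndarray, n: int):
    """Cache corner indices/weights (float32) for repeated gather/scatter."""
    idx, wts = _corner_weights(np.asarray(coords, dtype=np.float64), n)
    return idx.astype(np.int32), wts.astype(np.float32)


def gather_cached(volume: np.ndarray, idx: np.ndarray, wts: np.ndarray) -> np.ndarray:
    return np.sum(volume.reshape(-1)[idx] * wts, axis=-1)


def scatter_cached(values: np.ndarray, idx: np.ndarray, wts: np.ndarray,
                   n: int) -> np.ndarray:
    flat = np.bincount(idx.reshape(-1),
                       weights=(values[..., None] * wts).reshape(-1),
                       minlength=n ** 3)
    return flat.reshape(n, n, n)
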