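"""Closest-point queries against a triangle soup, KD-tree accelerated.

Used for projecting refined vertices back onto an original surface and for
sampled Hausdorff estimates. Candidate triangles come from a KD-tree over
face centroids; the exact closest point on each candidate follows the
classic region-based point/triangle test.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def _closest_point_triangles(tri: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    tri: (..., 3, 3) triangle vertices; p: (..., 3) points (broadcastable).
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp = p - c
    d5 = np.einsum("...i,...i->...", ab, cp)
    d6 = np.einsum("...i,...i->...", ac, cp)

    out = np.empty(np.broadcast_shapes(a.shape, p.shape))
    done = np.zeros(out.shape[:-1], dtype=bool)

    def assign(mask, value):
        m = mask & ~done
        out[m] = value[m] if value.shape == out.shape else np.broadcast_to(value, out.shape)[m]
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), np.broadcast_to(a, out.shape))            # vertex a
    assign((d3 >= 0) & (d4 <= d3), np.broadcast_to(b, out.shape))           # vertex b
    assign((d6 >= 0) & (d5 <= d6), np.broadcast_to(c, out.shape))           # vertex c

    vc = d1 * d4 - d3 * d2
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(np.abs(d1 - d3) > 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0.0)
    assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v_ab[..., None] * ab)     # edge ab

    vb = d5 * d2 - d1 * d6
    w_ac = d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0)
    assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w_ac[..., None] * ac)     # edge ac

    va = d3 * d6 - d5 * d4
    denom_bc = (d4 - d3) + (d5 - d6)
    w_bc = (d4 - d3) / np.where(denom_bc != 0, denom_bc, 1.0)
    assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
           b + w_bc[..., None] * (c - b))                                    # edge bc

    denom = va + vb + vc
    denom = np.where(denom != 0, denom, 1.0)
    v = vb / denom
    w = vc / denom
    assign(np.ones_like(done), a + v[..., None] * ab + w[..., None] * ac)    # interior
    return out


class MeshProximity:
    """Closest-point structure over a fixed triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self._tri = self.vertices[self.faces]
        self._tree = cKDTree(self._tri.mean(axis=1))

    def closest(self, points: np.ndarray, k: int = 8):
        """Return (closest_points, distances) for each query point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        k = min(k, len(self.faces))
        _, cand = self._tree.query(points, k=k)
        cand = cand.reshape(len(points), k)
        tri = self._tri[cand]                          # (N, k, 3, 3)
        cp = _closest_point_triangles(tri, points[:, None, :])
        d2 = ((cp - points[:, None, :]) ** 2).sum(-1)
        best = d2.argmin(axis=1)
        idx = np.arange(len(points))
        return cp[idx, best], np.sqrt(d2[idx, best])
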