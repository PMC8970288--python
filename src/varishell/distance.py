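"""Exact point-to-surface distance queries against a triangle mesh.

Distances are Euclidean distances to the closest point on the triangulated
surface.  Queries are exact (not sampled): a k-d tree over triangle centroids
prunes the candidate set, and the surviving candidates are resolved with the
exact point-triangle kernel from :mod:`trimesh.triangles`.  Pruning is
conservative — a triangle can only beat a candidate distance ``d`` if its
centroid lies within ``d + R``, where ``R`` is the largest centroid-to-vertex
radius over the mesh — so results equal a brute-force search over every
triangle.

The inside/outside sign is resolved by a ray-parity test (Möller–Trumbore),
valid for watertight meshes.  Convention: negative inside the cell, positive
outside, zero on the surface.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = ["MeshDistance"]

# Fixed, irrational-ish ray direction: avoids axis-aligned edge/vertex grazing
# for meshes generated on regular lattices.
_RAY_DIR = np.array([0.2357022603955158, 0.4082482904638631, 0.8819171036881969])
_RAY_DIR = _RAY_DIR / np.linalg.norm(_RAY_DIR)


def _pairs_min_distance(points, triangles, point_index, tri_index, n_points):
    """Exact min distance per point over (point, triangle) candidate pairs."""
    if len(point_index) == 0:
        return np.full(n_points, np.inf)
    closest = trimesh.triangles.closest_point(triangles[tri_index], points[point_index])
    d = np.linalg.norm(closest - points[point_index], axis=1)
    out = np.full(n_points, np.inf)
    np.minimum.at(out, point_index, d)
    return out


class MeshDistance:
    """Distance/containment query object for one watertight mesh."""

    def __init__(self, mesh: trimesh.Trimesh):
        self.mesh = mesh
        self.triangles = np.asarray(mesh.triangles)
        if len(self.triangles) == 0:
            raise ValueError("mesh has no faces")
        self._centroids = self.triangles.mean(axis=1)
        # largest centroid->vertex radius: conservative pruning slack
        self.prune_radius = float(
            np.linalg.norm(self.triangles - self._centroids[:, None, :], axis=2).max()
        )
        self._tree = cKDTree(self._centroids)

    # ------------------------------------------------------------------ #
    def centroid_distance(self, points: np.ndarray) -> np.ndarray:
        """Distance to the nearest triangle *centroid* (an upper bound on the
        surface distance; minus ``prune_radius`` it is a lower bound)."""
        d, _ = self._tree.query(points)
        return d

    def unsigned(self, points: np.ndarray) -> np.ndarray:
        """Exact unsigned distance to the surface for every point."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d_c, _ = self._tree.query(points)
        # any triangle that can beat the bound has centroid within d_c + R
        return self._resolve(points, d_c + self.prune_radius + 1e-12)

    def unsigned_within(self, points: np.ndarray, cutoff: float) -> np.ndarray:
        """Exact unsigned distance where it is <= ``cutoff``; ``inf`` elsewhere.

        Cheaper than :meth:`unsigned` when only near-surface points matter
        (shell membership, nearest-cell attribution).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d_c, _ = self._tree.query(points)
        out = np.full(len(points), np.inf)
        maybe = d_c - self.prune_radius <= cutoff
        if maybe.any():
            d = self._resolve(points[maybe], np.full(maybe.sum(), cutoff + self.prune_radius))
            d[d > cutoff] = np.inf
            out[maybe] = d
        return out

    def _resolve(self, points: np.ndarray, radii: np.ndarray) -> np.ndarray:
        """Exact distances via candidate triangles within per-point radii."""
        if len(points) == 0:
            return np.empty(0)
        lists = self._tree.query_ball_point(points, radii)
        lens = np.fromiter((len(l) for l in lists), dtype=np.intp, count=len(lists))
        tri_index = (
            np.concatenate([np.asarray(l, dtype=np.intp) for l in lists if l])
            if lens.sum()
            else np.empty(0, dtype=np.intp)
        )
        point_index = np.repeat(np.arange(len(points)), lens)
        return _pairs_min_distance(points, self.triangles, point_index, tri_index, len(points))

    # ------------------------------------------------------------------ #
    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inside test by ray-crossing parity (watertight meshes only)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inside = np.zeros(len(points), dtype=bool)
        tris = self.triangles
        v0 = tris[:, 0]
        e1 = tris[:, 1] - v0
        e2 = tris[:, 2] - v0
        h = np.cross(_RAY_DIR, e2)
        a = np.einsum("ij,ij->i", e1, h)
        ok = np.abs(a) > 1e-12  # non-degenerate, non-parallel triangles
        inv_a = np.zeros_like(a)
        inv_a[ok] = 1.0 / a[ok]
        # chunk over points to bound the (points x triangles) temporary
        chunk = max(1, int(4e6 // max(len(tris), 1)))
        for start in range(0, len(points), chunk):
            p = points[start : start + chunk]
            s = p[:, None, :] - v0[None, :, :]  # (np, nt, 3)
            u = np.einsum("ptj,tj->pt", s, h) * inv_a[None, :]
            q = np.cross(s, e1[None, :, :])
            v = np.einsum("ptj,j->pt", q, _RAY_DIR) * inv_a[None, :]
            t = np.einsum("ptj,tj->pt", q, e2) * inv_a[None, :]
            hit = (
                ok[None, :]
                & (u >= 0.0)
                & (v >= 0.0)
                & (u + v <= 1.0)
                & (t > 1e-12)
            )
            inside[start : start + chunk] = (hit.sum(axis=1) % 2).astype(bool)
        return inside

    def signed(self, points: np.ndarray) -> np.ndarray:
        """Signed distance: negative inside, positive outside."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.unsigned(points)
        sign = np.where(self.contains(points), -1.0, 1.0)
        return sign * d


def brute_force_unsigned(triangles: np.ndarray, points: np.ndarray, chunk: int = 2_000_000) -> np.ndarray:
    """Exhaustive exact unsigned distance: every point against every triangle.

    Independent of the pruned query path; used as an oracle in tests.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_tri = len(triangles)
    out = np.full(len(points), np.inf)
    pts_per_block = max(1, chunk // max(n_tri, 1))
    tri_index = np.tile(np.arange(n_tri), pts_per_block)
    for start in range(0, len(points), pts_per_block):
        block = points[start : start + pts_per_block]
        pi = np.repeat(np.arange(len(block)), n_tri)
        ti = tri_index[: len(block) * n_tri]
        out[start : start + len(block)] = _pairs_min_distance(block, triangles, pi, ti, len(block))
    return out
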