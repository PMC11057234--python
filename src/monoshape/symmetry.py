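"""Mirror-symmetry plane detection on 3D meshes.

RANSAC over vertex pairs: each sampled pair proposes the plane bisecting
the segment between the two vertices; the plane is scored by the number
of vertices whose mirror image lies within tolerance of another vertex.
The primary plane is the candidate with the most correspondences; the
secondary plane is the candidate at least 45 degrees from the primary
whose correspondences overlap the primary's the most (chained triplets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .mesh import Mesh

__all__ = [
    "SymmetryPlane",
    "CorrespondenceSet",
    "bisector_plane",
    "correspondences_under_plane",
    "ransac_symmetry_planes",
    "select_primary_secondary",
    "overlap_count",
    "shared_vertices",
]


@dataclass
class SymmetryPlane:
    """Plane n . p = c with unit normal, sign-canonicalized to n_z >= 0
    (falling back to n_x, then n_y, when earlier components vanish)."""

    normal: np.ndarray
    offset: float

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float).reshape(3)
        norm = np.linalg.norm(n)
        if norm < 1e-300:
            raise ValueError("zero normal")
        n = n / norm
        for comp in (2, 0, 1):
            if abs(n[comp]) > 1e-9:
                if n[comp] < 0:
                    n = -n
                    self.offset = -self.offset
                break
        self.normal = n
        self.offset = float(self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset

    def reflect(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        d = pts @ self.normal - self.offset
        return pts - 2.0 * np.outer(d, self.normal)

    @property
    def slant_deg(self) -> float:
        """Angle between the normal and the camera z-axis, in [0, 90]."""
        return math.degrees(math.acos(np.clip(abs(self.normal[2]), 0.0, 1.0)))

    @property
    def tilt_deg(self) -> float:
        """Orientation of the normal's image-plane projection."""
        return math.degrees(math.atan2(self.normal[1], self.normal[0]))

    def angle_to(self, other: "SymmetryPlane") -> float:
        """Acute angle between plane normals, degrees."""
        return math.degrees(
            math.acos(np.clip(abs(np.dot(self.normal, other.normal)), 0.0, 1.0))
        )


@dataclass
class CorrespondenceSet:
    """Vertex-index pairs symmetric about ``plane`` within ``tolerance``;
    pairs are disjoint and canonically ordered i < j."""

    plane: SymmetryPlane
    pairs: list[tuple[int, int]]
    tolerance: float
    mean_residual: float = field(default=float("nan"))

    def __post_init__(self):
        self.pairs = [(min(i, j), max(i, j)) for i, j in self.pairs]
        seen: set[int] = set()
        for i, j in self.pairs:
            if i == j or i in seen or j in seen:
                raise ValueError("pairs must be disjoint with i != j")
            seen.update((i, j))

    def __len__(self) -> int:
        return len(self.pairs)

    def partner_map(self) -> dict[int, int]:
        m: dict[int, int] = {}
        for i, j in self.pairs:
            m[i] = j
            m[j] = i
        return m


def bisector_plane(p, q) -> SymmetryPlane:
    """The unique mirror plane mapping p onto q (perpendicular bisector)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    d = p - q
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("coincident points define no unique bisector plane")
    n = d / norm
    c = float(n @ ((p + q) / 2.0))
    return SymmetryPlane(n, c)


def correspondences_under_plane(
    mesh: Mesh, plane: SymmetryPlane, tol: float
) -> CorrespondenceSet:
    """Greedy disjoint matching of each vertex's reflection to its nearest
    unmatched vertex within ``tol``. Closest matches are claimed first."""
    if not tol > 0:
        raise ValueError("tol must be positive")
    verts = mesh.vertices
    n = len(verts)
    refl = plane.reflect(verts)
    candidates: list[tuple[float, int, int]] = []
    if np.isfinite(tol):
        tree = cKDTree(verts)
        hits = tree.query_ball_point(refl, r=tol)
        for i, js in enumerate(hits):
            for j in js:
                if i < j:
                    candidates.append((float(np.linalg.norm(refl[i] - verts[j])), i, j))
    else:
        for i in range(n):
            d = np.linalg.norm(refl[i] - verts[i + 1 :], axis=1)
            for k, dist in enumerate(d):
                candidates.append((float(dist), i, i + 1 + k))
    candidates.sort()
    used = np.zeros(n, dtype=bool)
    pairs: list[tuple[int, int]] = []
    residuals: list[float] = []
    for dist, i, j in candidates:
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        pairs.append((i, j))
        residuals.append(dist)
    mean_res = float(np.mean(residuals)) if residuals else float("nan")
    return CorrespondenceSet(plane, pairs, tol, mean_res)


def _plane_from_pairs(verts: np.ndarray, pairs: list[tuple[int, int]]) -> SymmetryPlane:
    """Least-squares plane refit: the normal is the dominant direction of
    the pair difference vectors, the offset the mean midpoint projection."""
    a = verts[[i for i, _ in pairs]]
    b = verts[[j for _, j in pairs]]
    d = a - b
    # sign-align difference vectors before extracting the direction
    ref = d[np.argmax(np.linalg.norm(d, axis=1))]
    d = np.where((d @ ref)[:, None] < 0, -d, d)
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    n = vt[0]
    c = float(np.mean(((a + b) / 2.0) @ n))
    return SymmetryPlane(n, c)


def ransac_symmetry_planes(
    mesh: Mesh,
    n_iters: int = 2000,
    tol: float | None = None,
    seed: int | None = None,
) -> list[CorrespondenceSet]:
    """Candidate mirror planes ranked by correspondence count (ties broken
    by smaller mean residual), deduplicated (normals within 2 degrees and
    offsets within tolerance).

    When the mesh has fewer distinct vertex pairs than ``n_iters`` every
    pair is tried exhaustively, which makes the result seed-independent.
    Default tolerance: 0.01 x bounding-box diameter.
    """
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    verts = mesh.vertices
    n = len(verts)
    if n < 4:
        raise ValueError("mesh must have at least 4 vertices")
    if tol is None:
        tol = 0.01 * mesh.diameter()
    rng = np.random.default_rng(seed)
    n_pairs = n * (n - 1) // 2
    if n_pairs <= n_iters:
        samples = [(i, j) for i in range(n) for j in range(i + 1, n)]
    else:
        samples = []
        for _ in range(n_iters):
            i, j = rng.choice(n, size=2, replace=False)
            samples.append((int(i), int(j)))
    candidates: list[CorrespondenceSet] = []
    for i, j in samples:
        if np.linalg.norm(verts[i] - verts[j]) < 1e-12:
            continue
        plane = bisector_plane(verts[i], verts[j])
        corr = correspondences_under_plane(mesh, plane, tol)
        if len(corr) >= 2:
            # one least-squares refit to the inliers, then re-match
            plane = _plane_from_pairs(verts, corr.pairs)
            corr = correspondences_under_plane(mesh, plane, tol)
        if len(corr) >= 1:
            candidates.append(corr)

    def quality(c: CorrespondenceSet):
        res = c.mean_residual if np.isfinite(c.mean_residual) else np.inf
        return (-len(c), res)

    candidates.sort(key=quality)
    unique: list[CorrespondenceSet] = []
    for cand in candidates:
        dup = any(
            cand.plane.angle_to(kept.plane) < 2.0
            and abs(cand.plane.offset - kept.plane.offset) < tol
            for kept in unique
        )
        if not dup:
            unique.append(cand)
    return unique


def overlap_count(a: CorrespondenceSet, b: CorrespondenceSet) -> int:
    """Number of chained triplets (u, v, w) with (u, v) a pair of ``a``
    and (v, w) a pair of ``b``; u, v, w distinct."""
    pa, pb = a.partner_map(), b.partner_map()
    count = 0
    for v, u in pa.items():
        w = pb.get(v)
        if w is not None and w != u and w != v and u != v:
            count += 1
    return count


def shared_vertices(a: CorrespondenceSet, b: CorrespondenceSet) -> list[int]:
    """Vertices with a partner under both planes (the middles of the
    overlapping-correspondence triplets): the index set on which the
    two-plane depth-consistency loss is evaluated."""
    pa, pb = a.partner_map(), b.partner_map()
    return sorted(v for v in pa if v in pb and pb[v] != pa[v])


def select_primary_secondary(
    mesh: Mesh,
    candidates: list[CorrespondenceSet] | None = None,
    min_angle_deg: float = 45.0,
    n_iters: int = 2000,
    tol: float | None = None,
    large_tol: float | None = None,
    seed: int | None = None,
) -> tuple[CorrespondenceSet, CorrespondenceSet]:
    """Primary plane (most correspondences) and secondary plane (normal at
    least ``min_angle_deg`` from the primary's, maximal overlap).

    Objects with a single true mirror plane have no well-supported
    secondary candidate; following the protocol for random polyhedra the
    search is then repeated with a large tolerance (default 0.15 x
    diameter) and the best estimate under that tolerance is used.
    """
    if candidates is None:
        candidates = ransac_symmetry_planes(mesh, n_iters=n_iters, tol=tol, seed=seed)
    if not candidates:
        raise ValueError("no symmetry plane candidates found")
    primary = candidates[0]

    def best_secondary(cands: list[CorrespondenceSet]):
        # a usable secondary needs >= 2 pairs (one segment cannot anchor a
        # one-parameter family) and a nonzero overlap with the primary
        eligible = [
            c for c in cands
            if c is not primary
            and len(c) >= 2
            and c.plane.angle_to(primary.plane) >= min_angle_deg
        ]
        scored = [(overlap_count(primary, c), len(c), c) for c in eligible]
        scored = [s for s in scored if s[0] > 0]
        if not scored:
            return None
        return max(scored, key=lambda s: (s[0], s[1]))[2]

    secondary = best_secondary(candidates)
    if secondary is None:
        if large_tol is None:
            large_tol = 0.15 * mesh.diameter()
        loose = ransac_symmetry_planes(mesh, n_iters=n_iters, tol=large_tol, seed=seed)
        secondary = best_secondary(loose)
    if secondary is None:
        raise ValueError(
            f"no secondary plane >= {min_angle_deg} deg from the primary, "
            "even at large tolerance"
        )
    return primary, secondary
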