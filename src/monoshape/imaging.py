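"""Projection of posed symmetric objects into 2D pair images.

A *pair image* is the package's image representation: the 2D projected
endpoints of known 3D mirror pairs plus camera metadata (the transparent
object convention — every vertex is projected, nothing is occluded).
Includes the 1-degree segment-orientation noise model, angular-size
measurement, and the least-squares correction that turns any pair image
into a valid orthographic image (all symmetry segments parallel).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, RigidPose
from .symmetry import CorrespondenceSet

__all__ = [
    "Camera",
    "PairImage",
    "CorrectedPairImage",
    "project",
    "perturb_orientations",
    "angular_size",
    "correct_to_orthographic",
]

PROJECTIONS = ("orthographic", "perspective")


@dataclass
class Camera:
    """Camera at the origin looking along +z; the picture plane for
    perspective rendering sits at z = viewing_distance (cm). The default
    distance is the experiment's 20 inches."""

    projection: str = "orthographic"
    viewing_distance: float = 50.8

    def __post_init__(self):
        if self.projection not in PROJECTIONS:
            raise ValueError(f"projection must be one of {PROJECTIONS}")
        if not self.viewing_distance > 0:
            raise ValueError("viewing distance must be positive")


@dataclass
class PairImage:
    """2D endpoint pairs ((ax, ay), (bx, by)) of projected mirror pairs.

    Pair order is consistent: the first endpoint lies on the same side of
    the symmetry plane for all pairs (the 'b' endpoint is the deeper one
    at projection time). ``vertex_pairs`` optionally records the source
    mesh vertex indices of each (a, b) endpoint pair.
    """

    pairs: np.ndarray
    camera: Camera = field(default_factory=Camera)
    vertex_pairs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=float)
        if self.pairs.ndim != 3 or self.pairs.shape[1:] != (2, 2):
            raise ValueError("pairs must have shape (n, 2, 2)")
        if not np.all(np.isfinite(self.pairs)):
            raise ValueError("pair coordinates must be finite")
        if self.vertex_pairs is not None:
            self.vertex_pairs = np.asarray(self.vertex_pairs, dtype=int)
            if self.vertex_pairs.shape != (len(self.pairs), 2):
                raise ValueError("vertex_pairs must have shape (n, 2)")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a(self) -> np.ndarray:
        return self.pairs[:, 0, :]

    @property
    def b(self) -> np.ndarray:
        return self.pairs[:, 1, :]

    @property
    def segments(self) -> np.ndarray:
        """Directed segment vectors b - a."""
        return self.pairs[:, 1, :] - self.pairs[:, 0, :]

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.segments, axis=1)

    def endpoints(self) -> np.ndarray:
        return self.pairs.reshape(-1, 2)

    def diameter(self) -> float:
        pts = self.endpoints()
        ext = pts.max(axis=0) - pts.min(axis=0)
        return float(np.linalg.norm(ext))

    def to_json(self) -> str:
        obj = {
            "projection": self.camera.projection,
            "viewing_distance_cm": self.camera.viewing_distance,
            "pairs": self.pairs.tolist(),
            "meta": self.meta,
        }
        if self.vertex_pairs is not None:
            obj["vertex_pairs"] = self.vertex_pairs.tolist()
        return json.dumps(obj, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PairImage":
        obj = json.loads(text)
        cam = Camera(obj["projection"], obj.get("viewing_distance_cm", 50.8))
        return cls(
            np.array(obj["pairs"], dtype=float),
            cam,
            np.array(obj["vertex_pairs"], dtype=int) if "vertex_pairs" in obj else None,
            obj.get("meta", {}),
        )


@dataclass
class CorrectedPairImage(PairImage):
    """A valid orthographic pair image: every segment direction equals the
    common unit direction ``direction`` (whose orientation is the tilt)."""

    direction: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))

    def __post_init__(self):
        super().__post_init__()
        self.direction = np.asarray(self.direction, dtype=float).reshape(2)
        self.direction = self.direction / np.linalg.norm(self.direction)
        seg = self.segments
        lens = np.linalg.norm(seg, axis=1)
        live = lens > 0
        if np.any(live):
            cross = (
                np.abs(seg[live, 0] * self.direction[1] - seg[live, 1] * self.direction[0])
                / lens[live]
            )
            if np.max(cross) > 1e-9:
                raise ValueError(
                    "segments deviate from the common direction by more than 1e-9 rad"
                )

    @property
    def tilt_deg(self) -> float:
        return math.degrees(math.atan2(self.direction[1], self.direction[0]))


def project(
    mesh: Mesh,
    correspondences: CorrespondenceSet,
    pose: RigidPose,
    camera: Camera,
    meta: dict | None = None,
) -> PairImage:
    """Project the posed mirror pairs of ``mesh`` through ``camera``.

    Orthographic: (x, y) of each posed vertex. Perspective: picture-plane
    coordinates (d x/z, d y/z); every vertex must be strictly in front of
    the center of projection. Each pair is oriented so the deeper
    endpoint (along the posed symmetry normal, canonical z >= 0) is 'b'.
    """
    posed = pose.apply(mesh.vertices)
    m = pose.rotation @ correspondences.plane.normal
    for comp in (2, 0, 1):
        if abs(m[comp]) > 1e-9:
            if m[comp] < 0:
                m = -m
            break
    idx = np.array(correspondences.pairs, dtype=int)
    depth = posed @ m
    flip = depth[idx[:, 0]] > depth[idx[:, 1]]
    ordered = idx.copy()
    ordered[flip] = ordered[flip][:, ::-1]
    pts = posed[ordered.reshape(-1)]
    if camera.projection == "perspective":
        if np.any(pts[:, 2] <= 0):
            raise ValueError("vertex at or behind the center of projection (z <= 0)")
        xy = camera.viewing_distance * pts[:, :2] / pts[:, 2:3]
    else:
        xy = pts[:, :2]
    return PairImage(xy.reshape(-1, 2, 2), camera, ordered, dict(meta or {}))


def perturb_orientations(
    image: PairImage, sd_deg: float = 1.0, seed: int | None = None
) -> PairImage:
    """Rotate each segment about its own midpoint by an independent draw
    from N(0, sd_deg); lengths and midpoints are unchanged."""
    if sd_deg < 0:
        raise ValueError("sd_deg must be >= 0")
    if sd_deg == 0:
        return PairImage(image.pairs.copy(), image.camera, image.vertex_pairs, dict(image.meta))
    rng = np.random.default_rng(seed)
    ang = np.radians(rng.normal(0.0, sd_deg, size=len(image)))
    mid = image.pairs.mean(axis=1)
    half = image.segments / 2.0
    cos, sin = np.cos(ang), np.sin(ang)
    hx = cos * half[:, 0] - sin * half[:, 1]
    hy = sin * half[:, 0] + cos * half[:, 1]
    rot = np.stack([hx, hy], axis=1)
    pairs = np.stack([mid - rot, mid + rot], axis=1)
    return PairImage(pairs, image.camera, image.vertex_pairs, dict(image.meta))


def _circle_two(p, q):
    c = (p + q) / 2.0
    return c, float(np.linalg.norm(p - c))


def _circumcircle(p, q, r):
    ax, ay = p
    bx, by = q
    cx, cy = r
    d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(d) < 1e-300:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / d
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / d
    c = np.array([ux, uy])
    return c, float(np.linalg.norm(p - c))


def _min_enclosing_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest enclosing circle (Welzl's algorithm, move-to-front)."""
    pts = [np.array(p, dtype=float) for p in points]
    if not pts:
        return np.zeros(2), 0.0
    rng = np.random.default_rng(0)
    rng.shuffle(pts)
    eps = 1e-10

    def inside(circ, p):
        c, r = circ
        return np.linalg.norm(p - c) <= r * (1 + eps) + eps

    c = (pts[0].copy(), 0.0)
    for i, p in enumerate(pts):
        if inside(c, p):
            continue
        c = (p.copy(), 0.0)
        for j in range(i):
            q = pts[j]
            if inside(c, q):
                continue
            c = _circle_two(p, q)
            for k in range(j):
                s = pts[k]
                if inside(c, s):
                    continue
                cc = _circumcircle(p, q, s)
                c = cc if cc is not None else c
    return c


def angular_size(image: PairImage) -> float:
    """Angular size gamma (degrees) of the image seen from the center of
    projection: 2 atan(r / d) with r the radius of the smallest circle
    enclosing all endpoints on the picture plane."""
    pts = image.endpoints()
    if len(pts) == 0:
        return 0.0
    _, r = _min_enclosing_circle(pts)
    return math.degrees(2.0 * math.atan(r / image.camera.viewing_distance))


def correct_to_orthographic(image: PairImage) -> CorrectedPairImage:
    """Rotate every segment about its midpoint onto the common direction u
    minimizing sum ||(b_i - a_i) - L_i u||^2 (u proportional to the
    length-weighted sum of segment vectors). Midpoints and lengths are
    preserved; the output is a valid orthographic pair image."""
    if len(image) < 2:
        raise ValueError("need at least 2 pairs to correct an image")
    seg = image.segments
    lens = np.linalg.norm(seg, axis=1)
    if np.all(lens == 0):
        raise ValueError("all segments have zero length")
    u = (lens[:, None] * seg).sum(axis=0)
    nu = np.linalg.norm(u)
    if nu < 1e-300:
        raise ValueError("segment directions cancel; no common direction")
    u = u / nu
    mid = image.pairs.mean(axis=1)
    half = (lens / 2.0)[:, None] * u
    pairs = np.stack([mid - half, mid + half], axis=1)
    return CorrectedPairImage(
        pairs, image.camera, image.vertex_pairs, dict(image.meta), direction=u
    )
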