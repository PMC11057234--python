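"""Seeded generation of mirror-symmetric polyhedral stimuli and views.

Two object classes are produced, both exactly mirror-symmetric about the
YZ plane and both built from two boxes whose bottom faces lie in the
y = 0 plane, abutting at a shared vertical contact plane:

* *random* polyhedra — each box is a hexahedron whose cross section in
  the symmetry plane is a convex quadrilateral; three x half-widths per
  box are sampled and the fourth is solved from the planarity of the end
  face. No face angle is 90 degrees and at least 95% of face angles
  differ from 90 degrees by more than five degrees.
* *rectangular* polyhedra — each box is an axis-aligned rectangular
  prism; every face angle is exactly 90 degrees.

Edge lengths and widths of both classes are drawn from the same
configured distributions, and aspect ratios never exceed the configured
maximum (9 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mesh import Mesh, RigidPose

__all__ = [
    "ALLOWED_SLANTS_DEG",
    "StimulusParams",
    "ViewSpec",
    "Trial",
    "GenerationError",
    "generate_random_polyhedron",
    "generate_rectangular_polyhedron",
    "sample_view",
    "view_pose",
    "rotation_from_slant_tilt",
    "generate_condition_set",
    "face_angles_deg",
    "mirror_pairs",
]

ALLOWED_SLANTS_DEG = (15.0, 30.0, 45.0, 60.0, 75.0)


class GenerationError(RuntimeError):
    """Rejection-sampling budget exceeded; names the violated constraint."""


@dataclass
class StimulusParams:
    """Sampling configuration for both stimulus classes.

    Edge lengths (cross-section dimensions) and box widths are uniform on
    the configured intervals; the second box is shrunk by a relative-size
    factor uniform on [rel_min, rel_max].
    """

    edge_low: float = 1.0
    edge_high: float = 4.0
    width_low: float = 1.0
    width_high: float = 4.0
    rel_min: float = 0.3
    rel_max: float = 1.0
    max_aspect: float = 9.0
    # planarity-forced fourth width rejected beyond this multiple of the
    # largest sampled width
    max_fourth_width_factor: float = 3.0
    # face-angle rules for the random class
    hard_margin_deg: float = 1.0
    soft_margin_deg: float = 5.0
    max_soft_violations: int = 2
    max_attempts: int = 10_000

    def __post_init__(self):
        if self.edge_low <= 0 or self.width_low <= 0:
            raise ValueError("lower bounds must be positive")
        if self.edge_high < self.edge_low or self.width_high < self.width_low:
            raise ValueError("upper bounds must not be below lower bounds")
        if not (0 < self.rel_min <= self.rel_max <= 1.0):
            raise ValueError("need 0 < rel_min <= rel_max <= 1")

    def sample_edge(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.edge_low, self.edge_high))

    def sample_width(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.width_low, self.width_high))


@dataclass
class ViewSpec:
    """Viewing orientation of the symmetry plane: slant restricted to the
    experiment's set, tilt (mod 90) in [15, 75] degrees."""

    slant_deg: float
    tilt_deg: float
    roll_deg: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not any(abs(self.slant_deg - s) < 1e-9 for s in ALLOWED_SLANTS_DEG):
            raise ValueError(
                f"slant {self.slant_deg} deg not in {ALLOWED_SLANTS_DEG}"
            )
        m = self.tilt_deg % 90.0
        if not (15.0 - 1e-9 <= m <= 75.0 + 1e-9):
            raise ValueError(f"tilt {self.tilt_deg} deg: tilt mod 90 must be in [15, 75]")


@dataclass
class Trial:
    trial_id: int
    object_type: str
    seed: int
    view: ViewSpec
    mesh: Mesh
    params: StimulusParams = field(repr=False, default_factory=StimulusParams)


# ---------------------------------------------------------------------------
# box construction helpers


def _hexahedron(cross_yz: np.ndarray, half_widths: np.ndarray) -> tuple[np.ndarray, list[list[int]]]:
    """Vertices/faces of one box.

    ``cross_yz`` is the (4, 2) convex cross-section quadrilateral in
    (y, z); corner j is extruded to x = +/- half_widths[j]. Vertex 2j is
    the +x copy of corner j, vertex 2j+1 the -x copy, so mirror pairs
    about the YZ plane are (2j, 2j+1) and the symmetry is exact by
    construction.
    """
    verts = np.empty((8, 3))
    for j in range(4):
        y, z = cross_yz[j]
        w = half_widths[j]
        verts[2 * j] = (w, y, z)
        verts[2 * j + 1] = (-w, y, z)
    P = [0, 2, 4, 6]
    M = [1, 3, 5, 7]
    faces = [P, [M[3], M[2], M[1], M[0]]]
    for j in range(4):
        k = (j + 1) % 4
        faces.append([P[k], P[j], M[j], M[k]])
    return verts, faces


def _fix_orientation(verts: np.ndarray, faces: list[list[int]]) -> list[list[int]]:
    tri = np.array(
        [[f[0], f[a], f[a + 1]] for f in faces for a in range(1, len(f) - 1)]
    )
    p, q, r = verts[tri[:, 0]], verts[tri[:, 1]], verts[tri[:, 2]]
    qxr = np.stack(
        [
            q[:, 1] * r[:, 2] - q[:, 2] * r[:, 1],
            q[:, 2] * r[:, 0] - q[:, 0] * r[:, 2],
            q[:, 0] * r[:, 1] - q[:, 1] * r[:, 0],
        ],
        axis=1,
    )
    if float(np.sum(p * qxr)) < 0:
        faces = [f[::-1] for f in faces]
    return faces


def _convex_ccw(poly: np.ndarray, tol: float = 1e-9) -> bool:
    """Strict convexity of a 2D polygon with counterclockwise winding."""
    n = len(poly)
    for i in range(n):
        a, b, c = poly[i], poly[(i + 1) % n], poly[(i + 2) % n]
        e1, e2 = b - a, c - b
        if e1[0] * e2[1] - e1[1] * e2[0] <= tol:
            return False
    return True


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array(
        [
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        ]
    )


def _planar_quad_convex(q: np.ndarray, tol: float = 1e-9) -> bool:
    """Convexity of a planar 3D quadrilateral."""
    n = _cross3(q[1] - q[0], q[2] - q[0])
    nn = np.linalg.norm(n)
    if nn < tol:
        return False
    n = n / nn
    for i in range(4):
        a, b, c = q[i], q[(i + 1) % 4], q[(i + 2) % 4]
        if np.dot(_cross3(b - a, c - b), n) <= tol * np.linalg.norm(b - a):
            return False
    return True


def face_angles_deg(mesh: Mesh) -> np.ndarray:
    """All interior corner angles of all faces, in degrees."""
    prev, cur, nxt = [], [], []
    for f in mesh.faces:
        k = len(f)
        for i in range(k):
            prev.append(f[(i - 1) % k])
            cur.append(f[i])
            nxt.append(f[(i + 1) % k])
    v = mesh.vertices
    e1 = v[prev] - v[cur]
    e2 = v[nxt] - v[cur]
    cosang = np.sum(e1 * e2, axis=1) / (
        np.linalg.norm(e1, axis=1) * np.linalg.norm(e2, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def mirror_pairs(mesh: Mesh) -> list[tuple[int, int]]:
    """Constructed mirror pairs (+x, -x) of a generated stimulus."""
    return [(2 * j, 2 * j + 1) for j in range(mesh.n_vertices // 2)]


def _aspect_ratio_ok(verts: np.ndarray, max_aspect: float) -> bool:
    ext = verts.max(axis=0) - verts.min(axis=0)
    return float(ext.max() / ext.min()) <= max_aspect


def _solve_fourth_halfwidth(cross_yz: np.ndarray, hw012: np.ndarray) -> float | None:
    """x half-width of corner 3 making the +x end face planar.

    The end face has corners q_j = (hw_j, y_j, z_j); planarity of q3 with
    the plane of q0, q1, q2 is linear in hw_3.
    """
    q0 = np.array([hw012[0], *cross_yz[0]])
    q1 = np.array([hw012[1], *cross_yz[1]])
    q2 = np.array([hw012[2], *cross_yz[2]])
    n = _cross3(q1 - q0, q2 - q0)
    if abs(n[0]) < 1e-12:
        return None
    y3, z3 = cross_yz[3]
    return float((np.dot(n, q0) - n[1] * y3 - n[2] * z3) / n[0])


def _sample_random_box(
    params: StimulusParams,
    rng: np.random.Generator,
    z_start: float,
    depth: float,
    scale: float,
    contact: str,
) -> tuple[np.ndarray, np.ndarray] | None:
    """Cross-section quad and half-widths for one random-class box.

    ``contact`` says which vertical side of the quad must lie exactly in
    a z = const plane ('front' for the first box, 'back' for the second),
    so the two boxes meet flush at the shared contact plane.
    Returns None when a constraint fails and the caller must resample.
    """
    y_a = scale * params.sample_edge(rng)
    y_b = scale * params.sample_edge(rng)
    if contact == "front":
        # c0 bottom-back, c1 bottom-front, c2 top-front (on contact plane),
        # c3 top-back (z jittered inside the box depth)
        z3 = z_start + rng.uniform(0.05, 0.8) * depth
        cross = np.array(
            [
                [0.0, z_start],
                [0.0, z_start + depth],
                [y_a, z_start + depth],
                [y_b, z3],
            ]
        )
    else:
        # c0 bottom-back (on contact plane), c1 bottom-front, c2 top-front
        # (z jittered), c3 top-back (on contact plane)
        z2 = z_start + rng.uniform(0.2, 0.95) * depth
        cross = np.array(
            [
                [0.0, z_start],
                [0.0, z_start + depth],
                [y_a, z2],
                [y_b, z_start],
            ]
        )
    # polygon in (z, y) must be convex and counterclockwise
    if not _convex_ccw(cross[:, ::-1]):
        return None
    hw012 = np.array([scale * params.sample_width(rng) / 2 for _ in range(3)])
    hw3 = _solve_fourth_halfwidth(cross, hw012)
    if hw3 is None or hw3 <= 0.02 * hw012.max():
        return None
    if hw3 > params.max_fourth_width_factor * hw012.max():
        return None
    hw = np.append(hw012, hw3)
    # the end face must be a simple convex quad ("caused intersections")
    quad = np.column_stack([hw, cross[:, 0], cross[:, 1]])
    if not _planar_quad_convex(quad):
        return None
    return cross, hw


def _angles_ok(mesh: Mesh, params: StimulusParams) -> bool:
    ang = np.abs(face_angles_deg(mesh) - 90.0)
    if np.any(ang < params.hard_margin_deg):
        return False
    return int(np.sum(ang < params.soft_margin_deg)) <= params.max_soft_violations


def generate_random_polyhedron(
    params: StimulusParams | None = None, seed: int | None = None
) -> Mesh:
    """A random symmetric polyhedron: two appended hexahedral boxes,
    coplanar bottoms at y = 0, exact mirror symmetry about the YZ plane,
    planar faces and no right angles on any face."""
    params = params or StimulusParams()
    rng = np.random.default_rng(seed)
    last_fail = "no attempt made"
    for _ in range(params.max_attempts):
        d1 = params.sample_edge(rng)
        r = float(rng.uniform(params.rel_min, params.rel_max))
        d2 = r * params.sample_edge(rng)
        box1 = _sample_random_box(params, rng, 0.0, d1, 1.0, contact="front")
        if box1 is None:
            last_fail = "box-1 cross-section/width constraints"
            continue
        box2 = _sample_random_box(params, rng, d1, d2, r, contact="back")
        if box2 is None:
            last_fail = "box-2 cross-section/width constraints"
            continue
        v1, f1 = _hexahedron(*box1)
        v2, f2 = _hexahedron(*box2)
        f1 = _fix_orientation(v1, f1)
        f2 = _fix_orientation(v2, f2)
        verts = np.vstack([v1, v2])
        faces = f1 + [[i + 8 for i in f] for f in f2]
        mesh = Mesh(verts, faces)
        if not _aspect_ratio_ok(verts, params.max_aspect):
            last_fail = f"aspect ratio > {params.max_aspect}"
            continue
        if not _angles_ok(mesh, params):
            last_fail = "face angles too close to 90 degrees"
            continue
        return mesh
    raise GenerationError(
        f"rejection budget ({params.max_attempts}) exceeded; last violated "
        f"constraint: {last_fail}"
    )


def generate_rectangular_polyhedron(
    params: StimulusParams | None = None, seed: int | None = None
) -> Mesh:
    """Two appended axis-aligned rectangular prisms with coplanar bottoms
    at y = 0, mirror-symmetric about YZ; every face angle is 90 degrees.
    Dimensions are drawn from the same distributions as the random class."""
    params = params or StimulusParams()
    rng = np.random.default_rng(seed)
    for _ in range(params.max_attempts):
        d1 = params.sample_edge(rng)
        h1 = params.sample_edge(rng)
        w1 = params.sample_width(rng)
        r = float(rng.uniform(params.rel_min, params.rel_max))
        d2 = r * params.sample_edge(rng)
        h2 = r * params.sample_edge(rng)
        w2 = r * params.sample_width(rng)
        cross1 = np.array([[0.0, 0.0], [0.0, d1], [h1, d1], [h1, 0.0]])
        cross2 = np.array([[0.0, d1], [0.0, d1 + d2], [h2, d1 + d2], [h2, d1]])
        v1, f1 = _hexahedron(cross1, np.full(4, w1 / 2))
        v2, f2 = _hexahedron(cross2, np.full(4, w2 / 2))
        f1 = _fix_orientation(v1, f1)
        f2 = _fix_orientation(v2, f2)
        verts = np.vstack([v1, v2])
        if not _aspect_ratio_ok(verts, params.max_aspect):
            continue
        faces = f1 + [[i + 8 for i in f] for f in f2]
        return Mesh(verts, faces)
    raise GenerationError(
        f"rejection budget ({params.max_attempts}) exceeded; last violated "
        f"constraint: aspect ratio > {params.max_aspect}"
    )


_GENERATORS = {
    "random": generate_random_polyhedron,
    "rectangular": generate_rectangular_polyhedron,
}


# ---------------------------------------------------------------------------
# viewing orientations


def sample_view(seed: int | None = None) -> ViewSpec:
    """Random trial orientation: slant from the experiment set, tilt with
    tilt mod 90 uniform in [15, 75], free roll about the symmetry normal."""
    rng = np.random.default_rng(seed)
    slant = float(rng.choice(ALLOWED_SLANTS_DEG))
    tilt = 90.0 * rng.integers(0, 4) + rng.uniform(15.0, 75.0)
    roll = float(rng.uniform(0.0, 360.0))
    return ViewSpec(slant_deg=slant, tilt_deg=float(tilt), roll_deg=roll, seed=seed)


def rotation_from_slant_tilt(
    slant_deg: float, tilt_deg: float, roll_deg: float = 0.0
) -> np.ndarray:
    """Rotation taking the object symmetry normal (the x-axis) to the
    direction with the given slant (angle from the camera z-axis) and
    tilt (orientation of its image projection)."""
    s, t = math.radians(slant_deg), math.radians(tilt_deg)
    n = np.array([math.cos(t) * math.sin(s), math.sin(t) * math.sin(s), math.cos(s)])
    up = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(n, up)) > 1 - 1e-9:
        up = np.array([0.0, 1.0, 0.0])
    b = np.cross(up, n)
    b /= np.linalg.norm(b)
    c = np.cross(n, b)
    R = np.column_stack([n, b, c])
    rho = math.radians(roll_deg)
    Rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(rho), -math.sin(rho)],
            [0.0, math.sin(rho), math.cos(rho)],
        ]
    )
    return R @ Rx


def view_pose(view: ViewSpec, translation=(0.0, 0.0, 0.0)) -> RigidPose:
    """Rotation-only pose realizing the view's slant/tilt (plus optional
    translation, applied after the rotation)."""
    R = rotation_from_slant_tilt(view.slant_deg, view.tilt_deg, view.roll_deg)
    return RigidPose(R, np.asarray(translation, dtype=float))


def generate_condition_set(
    n_per_slant: int,
    object_type: str,
    params: StimulusParams | None = None,
    seed: int = 0,
) -> list[Trial]:
    """One experimental condition: ``n_per_slant`` trials at each slant in
    the experiment set (20 per slant = 100 trials in the experiment).
    Trial ``i`` uses seed ``seed + i`` so any trial regenerates alone."""
    if n_per_slant < 1:
        raise ValueError("n_per_slant must be >= 1")
    if object_type not in _GENERATORS:
        raise ValueError(f"unknown object_type {object_type!r}")
    params = params or StimulusParams()
    gen = _GENERATORS[object_type]
    trials = []
    idx = 0
    for slant in ALLOWED_SLANTS_DEG:
        for _ in range(n_per_slant):
            trial_seed = seed + idx
            mesh = gen(params, seed=trial_seed)
            rng = np.random.default_rng(trial_seed + 1_000_003)
            tilt = 90.0 * rng.integers(0, 4) + rng.uniform(15.0, 75.0)
            roll = float(rng.uniform(0.0, 360.0))
            view = ViewSpec(slant, float(tilt), roll, seed=trial_seed)
            trials.append(Trial(idx, object_type, trial_seed, view, mesh, params))
            idx += 1
    return trials


def manifest_rows(trials: list[Trial]) -> list[dict]:
    """Plain-dict manifest (one row per trial) for CSV export."""
    return [
        {
            "trial_id": t.trial_id,
            "object_type": t.object_type,
            "seed": t.seed,
            "slant_deg": t.view.slant_deg,
            "tilt_deg": t.view.tilt_deg,
            "roll_deg": t.view.roll_deg,
        }
        for t in trials
    ]
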