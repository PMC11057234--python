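"""Core 3D mesh types, metrics and ASCII mesh file I/O.

Coordinate convention throughout the package: the Z-axis is the depth
dimension (camera line of sight), X is horizontal and Y is vertical.
Lengths are in arbitrary but scene-consistent units; physical image
coordinates are in centimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "Mesh",
    "MeshError",
    "MeshParseError",
    "RigidPose",
    "mesh_volume",
    "mesh_surface_area",
    "convex_hull",
    "aspect_ratio",
    "apply_pose",
    "read_mesh",
    "write_mesh",
]


class MeshError(ValueError):
    """Raised for geometrically invalid meshes (open, degenerate...)."""


class MeshParseError(MeshError):
    """Raised when a mesh file cannot be parsed; carries a line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = f"{path or '<mesh>'}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line = line


@dataclass
class Mesh:
    """Polygonal mesh: ``vertices`` is an (n, 3) float array, ``faces`` a
    list of vertex-index lists (each with >= 3 entries)."""

    vertices: np.ndarray
    faces: list[list[int]]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be an (n, 3) array")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshError("vertex coordinates must be finite")
        n = len(self.vertices)
        self.faces = [list(map(int, f)) for f in self.faces]
        for f in self.faces:
            if len(f) < 3:
                raise MeshError(f"face {f} has fewer than 3 vertices")
            if any(i < 0 or i >= n for i in f):
                raise MeshError(f"face {f} references a vertex out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def diameter(self) -> float:
        """Length of the bounding-box diagonal (cheap size scale)."""
        if self.n_vertices == 0:
            return 0.0
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def copy(self) -> "Mesh":
        return Mesh(self.vertices.copy(), [list(f) for f in self.faces])


@dataclass
class RigidPose:
    """Rigid transform v -> R @ v + t with R a proper rotation."""

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-12):
            raise ValueError("rotation is not orthonormal (R^T R != I)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose equivalent to applying ``other`` first, then ``self``."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


# ---------------------------------------------------------------------------
# metrics


def _face_triangles(mesh: Mesh):
    """Fan triangulation of every face; yields (i, j, k) index triples."""
    for f in mesh.faces:
        for a in range(1, len(f) - 1):
            yield f[0], f[a], f[a + 1]


def _connected_components(mesh: Mesh) -> list[list[int]]:
    """Face indices grouped by vertex-connected component."""
    parent = list(range(mesh.n_vertices))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for f in mesh.faces:
        r = find(f[0])
        for v in f[1:]:
            parent[find(v)] = r
    comp: dict[int, list[int]] = {}
    for fi, f in enumerate(mesh.faces):
        comp.setdefault(find(f[0]), []).append(fi)
    return list(comp.values())


def _check_closed(mesh: Mesh):
    """Every undirected edge must be used by exactly two faces."""
    count: dict[tuple[int, int], int] = {}
    for f in mesh.faces:
        for a, b in zip(f, f[1:] + f[:1]):
            e = (a, b) if a < b else (b, a)
            count[e] = count.get(e, 0) + 1
    bad = [e for e, c in count.items() if c != 2]
    if bad:
        raise MeshError(
            f"mesh is not watertight: {len(bad)} edge(s) not shared by "
            f"exactly two faces (e.g. {bad[0]})"
        )


def mesh_volume(mesh: Mesh) -> float:
    """Volume of a closed mesh by the signed-tetrahedron sum.

    Orientation is fixed up internally: the signed volume of each
    connected component is accumulated with its absolute value, so
    inward-wound components still count positively.
    """
    _check_closed(mesh)
    v = mesh.vertices
    total = 0.0
    for faces_idx in _connected_components(mesh):
        signed = 0.0
        for fi in faces_idx:
            f = mesh.faces[fi]
            for a in range(1, len(f) - 1):
                p, q, r = v[f[0]], v[f[a]], v[f[a + 1]]
                signed += np.dot(p, np.cross(q, r)) / 6.0
        total += abs(signed)
    return float(total)


def mesh_surface_area(mesh: Mesh) -> float:
    """Total face area (planar polygon faces, fan-triangulated)."""
    v = mesh.vertices
    total = 0.0
    for f in mesh.faces:
        area = 0.0
        for a in range(1, len(f) - 1):
            area += 0.5 * np.linalg.norm(
                np.cross(v[f[a]] - v[f[0]], v[f[a + 1]] - v[f[0]])
            )
        if area == 0.0:
            warnings.warn(f"degenerate zero-area face {f}", stacklevel=2)
        total += area
    return float(total)


def convex_hull(points: np.ndarray) -> Mesh:
    """Convex hull of a 3D point set as a watertight triangle mesh.

    Only hull vertices are retained, so ``convex_hull`` is idempotent on
    vertex sets. Raises :class:`MeshError` for degenerate (coplanar or
    collinear) input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise MeshError("points must be an (n, 3) array")
    if len(pts) < 4:
        raise MeshError("need at least 4 points for a 3D hull")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise MeshError(f"degenerate hull (coplanar/collinear input): {exc}") from exc
    keep = np.array(sorted(set(hull.vertices)))
    remap = {old: new for new, old in enumerate(keep)}
    verts = pts[keep]
    faces = []
    for simplex, eq in zip(hull.simplices, hull.equations):
        tri = [remap[i] for i in simplex]
        # orient outward: winding normal must agree with the facet equation
        a, b, c = verts[tri[0]], verts[tri[1]], verts[tri[2]]
        if np.dot(np.cross(b - a, c - a), eq[:3]) < 0:
            tri = [tri[0], tri[2], tri[1]]
        faces.append(tri)
    return Mesh(verts, faces)


def aspect_ratio(mesh: Mesh, axes: np.ndarray | None = None) -> float:
    """Longest over shortest bounding-box extent, measured in the object
    frame (x = symmetry-plane normal, y = vertical, z = their cross
    product). ``axes`` rows override the frame for posed meshes."""
    pts = mesh.vertices
    if axes is not None:
        pts = pts @ np.asarray(axes, dtype=float).T
    ext = pts.max(axis=0) - pts.min(axis=0)
    if np.min(ext) <= 1e-12 * max(np.max(ext), 1.0):
        raise MeshError("flat object: zero extent along one axis")
    return float(np.max(ext) / np.min(ext))


def apply_pose(mesh: Mesh, pose: RigidPose) -> Mesh:
    return Mesh(pose.apply(mesh.vertices), [list(f) for f in mesh.faces])


# ---------------------------------------------------------------------------
# file I/O (ASCII OBJ / OFF / PLY)


def read_mesh(path) -> Mesh:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".obj":
        return _read_obj(path)
    if ext == ".off":
        return _read_off(path)
    if ext == ".ply":
        return _read_ply(path)
    raise MeshParseError(f"unknown mesh extension {ext!r}", path)


def write_mesh(mesh: Mesh, path) -> None:
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".obj":
        _write_obj(mesh, path)
    elif ext == ".off":
        _write_off(mesh, path)
    elif ext == ".ply":
        _write_ply(mesh, path)
    else:
        raise MeshParseError(f"unknown mesh extension {ext!r}", path)


def _read_obj(path: Path) -> Mesh:
    verts, faces = [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tok = line.split()
            if tok[0] == "v":
                if len(tok) < 4:
                    raise MeshParseError("vertex line needs 3 coordinates", path, ln)
                try:
                    verts.append([float(t) for t in tok[1:4]])
                except ValueError:
                    raise MeshParseError("bad vertex coordinate", path, ln)
            elif tok[0] == "f":
                try:
                    # OBJ is 1-based; v/vt/vn references keep the v part
                    idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
                except ValueError:
                    raise MeshParseError("bad face index", path, ln)
                if len(idx) < 3:
                    raise MeshParseError("face needs >= 3 indices", path, ln)
                faces.append(idx)
    if not verts:
        raise MeshParseError("no vertices found", path, 1)
    return Mesh(np.array(verts), faces)


def _write_obj(mesh: Mesh, path: Path) -> None:
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write("f " + " ".join(str(i + 1) for i in f) + "\n")


def _data_lines(path: Path):
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#")[0].strip()
            if line:
                yield ln, line


def _read_off(path: Path) -> Mesh:
    lines = _data_lines(path)
    try:
        ln, header = next(lines)
    except StopIteration:
        raise MeshParseError("empty file", path, 1)
    if header != "OFF":
        raise MeshParseError("missing OFF header", path, ln)
    try:
        ln, counts = next(lines)
        nv, nf, _ = (int(t) for t in counts.split()[:3])
    except (StopIteration, ValueError):
        raise MeshParseError("bad count line", path, ln)
    verts, faces = [], []
    for _ in range(nv):
        try:
            ln, line = next(lines)
            verts.append([float(t) for t in line.split()[:3]])
        except (StopIteration, ValueError):
            raise MeshParseError("bad or missing vertex line", path, ln)
    for _ in range(nf):
        try:
            ln, line = next(lines)
            tok = line.split()
            k = int(tok[0])
            faces.append([int(t) for t in tok[1 : 1 + k]])
            if len(faces[-1]) != k:
                raise ValueError
        except (StopIteration, ValueError):
            raise MeshParseError("bad or missing face line", path, ln)
    return Mesh(np.array(verts), faces)


def _write_off(mesh: Mesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {len(mesh.faces)} 0\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"{len(f)} " + " ".join(str(i) for i in f) + "\n")


def _read_ply(path: Path) -> Mesh:
    lines = _data_lines(path)
    try:
        ln, magic = next(lines)
    except StopIteration:
        raise MeshParseError("empty file", path, 1)
    if magic != "ply":
        raise MeshParseError("missing ply magic", path, ln)
    nv = nf = None
    element = None
    for ln, line in lines:
        tok = line.split()
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise MeshParseError("only ASCII PLY is supported", path, ln)
        elif tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                nv = int(tok[2])
            elif element == "face":
                nf = int(tok[2])
        elif tok[0] == "end_header":
            break
    else:
        raise MeshParseError("missing end_header", path, ln)
    if nv is None or nf is None:
        raise MeshParseError("header lacks vertex/face elements", path, ln)
    verts, faces = [], []
    for _ in range(nv):
        try:
            ln, line = next(lines)
            verts.append([float(t) for t in line.split()[:3]])
        except (StopIteration, ValueError):
            raise MeshParseError("bad or missing vertex line", path, ln)
    for _ in range(nf):
        try:
            ln, line = next(lines)
            tok = line.split()
            k = int(tok[0])
            faces.append([int(t) for t in tok[1 : 1 + k]])
        except (StopIteration, ValueError):
            raise MeshParseError("bad or missing face line", path, ln)
    return Mesh(np.array(verts), faces)


def _write_ply(mesh: Mesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float64 x\nproperty float64 y\nproperty float64 z\n")
        fh.write(f"element face {len(mesh.faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"{len(f)} " + " ".join(str(i) for i in f) + "\n")
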