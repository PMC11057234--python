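import numpy as np
import pytest

from monoshape.mesh import Mesh
from monoshape.stimuli import StimulusParams
from monoshape.symmetry import CorrespondenceSet, SymmetryPlane

CUBE_FACES = [
    [0, 1, 3, 2],
    [4, 6, 7, 5],
    [0, 4, 5, 1],
    [2, 3, 7, 6],
    [0, 2, 6, 4],
    [1, 5, 7, 3],
]


def make_box(dx=1.0, dy=1.0, dz=1.0, center=False) -> Mesh:
    """Axis-aligned box [0,dx]x[0,dy]x[0,dz] with outward-wound quads."""
    verts = np.array(
        [[x, y, z] for x in (0.0, dx) for y in (0.0, dy) for z in (0.0, dz)]
    )
    if center:
        verts -= np.array([dx, dy, dz]) / 2.0
    return Mesh(verts, [list(f) for f in CUBE_FACES])


def icosphere(subdivisions: int = 3, radius: float = 1.0) -> Mesh:
    """Unit icosahedron subdivided and projected to a sphere."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    for _ in range(subdivisions):
        vlist = [tuple(v) for v in verts]
        index = {v: i for i, v in enumerate(vlist)}
        cache = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = (np.array(vlist[i]) + np.array(vlist[j])) / 2.0
                m /= np.linalg.norm(m)
                t = tuple(m)
                if t not in index:
                    index[t] = len(vlist)
                    vlist.append(t)
                cache[key] = index[t]
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
        verts = np.array(vlist)
    return Mesh(verts * radius, [list(f) for f in faces])


def cube_mirror_correspondences() -> tuple[Mesh, CorrespondenceSet]:
    """Centered unit cube with its x = 0 mirror plane and the 4 pairs."""
    cube = make_box(center=True)
    plane = SymmetryPlane(np.array([1.0, 0.0, 0.0]), 0.0)
    pairs = [(0, 4), (1, 5), (2, 6), (3, 7)]
    return cube, CorrespondenceSet(plane, pairs, 1e-9)


@pytest.fixture
def unit_cube() -> Mesh:
    return make_box()


@pytest.fixture
def box123() -> Mesh:
    return make_box(1.0, 2.0, 3.0)


@pytest.fixture
def params() -> StimulusParams:
    return StimulusParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
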