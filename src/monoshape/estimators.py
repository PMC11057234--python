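"""The four per-trial slant estimators.

* theta_v2s3 — slant maximizing compactness V^2/S^3 of the convex hull
  of the family member, over the adjustment grid.
* theta_s3v — slant maximizing the modified compactness V/S^3 (whose
  maximization correlates with minimizing the depth range).
* theta_sym2 — slant of the primary-plane family at the global minimum
  of the two-plane depth-consistency loss L over a (theta1, theta2) grid.
* theta_persp — median over segment pairs of the slant implied by their
  vanishing point (exactly 90 degrees for a parallel, i.e. orthographic,
  image).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .family import FamilyGrid, Reconstruction3D, reconstruct_at_slant
from .imaging import PairImage
from .mesh import Mesh, MeshError, convex_hull, mesh_surface_area, mesh_volume

__all__ = [
    "SlantEstimate",
    "compactness_c1",
    "compactness_c2",
    "select_slant_compactness",
    "two_plane_loss",
    "select_slant_two_planes",
    "vanishing_point_slant",
    "depth_range",
]

#: absolute tolerance for flagging tied grid optima
TIE_TOL = 1e-12


@dataclass
class SlantEstimate:
    value_deg: float
    estimator: str
    diagnostics: dict = field(default_factory=dict)


def compactness_c1(mesh: Mesh) -> float:
    """V^2 / S^3: dimensionless compactness, maximal for a sphere."""
    s = mesh_surface_area(mesh)
    if s <= 0:
        raise MeshError("zero surface area")
    return mesh_volume(mesh) ** 2 / s**3


def compactness_c2(mesh: Mesh) -> float:
    """V / S^3: modified compactness (units length^-3)."""
    s = mesh_surface_area(mesh)
    if s <= 0:
        raise MeshError("zero surface area")
    return mesh_volume(mesh) / s**3


_COMPACTNESS = {"c1": compactness_c1, "c2": compactness_c2}
_COMPACTNESS_ID = {"c1": "v2s3", "c2": "s3v"}


def _flag_ties(values: np.ndarray, best: int) -> bool:
    """True when a non-adjacent grid cell matches the optimum within
    TIE_TOL (such ties are flagged, never silently broken)."""
    close = np.flatnonzero(np.abs(values - values[best]) <= TIE_TOL)
    return bool(np.any(np.abs(close - best) > 1))


def select_slant_compactness(family: FamilyGrid, which: str = "c1") -> SlantEstimate:
    """Exhaustive grid argmax of the chosen compactness of the convex hull
    of each family member."""
    if which not in _COMPACTNESS:
        raise ValueError("which must be 'c1' or 'c2'")
    comp = _COMPACTNESS[which]
    values = np.empty(len(family.grid_rad))
    for k, recon in enumerate(family.members()):
        values[k] = comp(convex_hull(recon.flat_points))
    best = int(np.argmax(values))
    tie = _flag_ties(values, best)
    if tie:
        warnings.warn(f"non-unique {which} maximum on the slant grid", stacklevel=2)
    return SlantEstimate(
        float(family.grid_deg[best]),
        _COMPACTNESS_ID[which],
        {"values": values, "argmax": best, "tie": tie},
    )


def _centered_depths(
    family: FamilyGrid, shared: list[int], theta_deg: float
) -> np.ndarray:
    recon = reconstruct_at_slant(family.image, theta_deg)
    depth = recon.depth_by_vertex()
    z = np.array([depth[v] for v in shared])
    return z - z.mean()


def two_plane_loss(
    fam1: FamilyGrid,
    fam2: FamilyGrid,
    shared: list[int],
    theta1_deg: float,
    theta2_deg: float,
) -> float:
    """Sum of squared differences between the mean-centered depths that
    the two families assign to the shared vertices; invariant to adding a
    constant to either depth set, zero iff the centered profiles agree."""
    if not shared:
        raise ValueError("shared vertex set is empty")
    z1 = _centered_depths(fam1, shared, theta1_deg)
    z2 = _centered_depths(fam2, shared, theta2_deg)
    return float(np.sum((z1 - z2) ** 2))


def select_slant_two_planes(
    fam1: FamilyGrid, fam2: FamilyGrid, shared: list[int]
) -> SlantEstimate:
    """Exhaustive search of the loss over the (theta1, theta2) grid;
    returns the primary-plane slant at the global minimum."""
    if not shared:
        raise ValueError("shared vertex set is empty")
    Z1 = np.stack(
        [_centered_depths(fam1, shared, t) for t in fam1.grid_deg]
    )
    Z2 = np.stack(
        [_centered_depths(fam2, shared, t) for t in fam2.grid_deg]
    )
    # L[i, j] = ||Z1_i - Z2_j||^2 via the gram expansion
    sq1 = np.sum(Z1**2, axis=1)[:, None]
    sq2 = np.sum(Z2**2, axis=1)[None, :]
    L = sq1 + sq2 - 2.0 * Z1 @ Z2.T
    np.maximum(L, 0.0, out=L)
    i, j = np.unravel_index(np.argmin(L), L.shape)
    flat = L.ravel()
    best = int(np.argmin(flat))
    close = np.flatnonzero(np.abs(flat - flat[best]) <= TIE_TOL)
    cells = np.column_stack(np.unravel_index(close, L.shape))
    tie = bool(np.any(np.abs(cells - np.array([i, j])).max(axis=1) > 1))
    if tie:
        warnings.warn("non-unique two-plane loss minimum on the grid", stacklevel=2)
    return SlantEstimate(
        float(fam1.grid_deg[i]),
        "sym2",
        {
            "theta2_deg": float(fam2.grid_deg[j]),
            "loss": float(L[i, j]),
            "argmin": (int(i), int(j)),
            "loss_surface": L,
            "tie": tie,
        },
    )


def vanishing_point_slant(
    image: PairImage, viewing_distance: float | None = None
) -> SlantEstimate:
    """Median, over all pairs of symmetry segments, of the slant implied
    by the pair's vanishing point.

    The ray from the center of projection through the intersection of two
    extended symmetry lines is normal to the symmetry plane, so each
    intersection v on the picture plane gives slant atan(||v|| / d).
    Segment pairs that are parallel (or intersect beyond 1e6 image
    diameters) contribute exactly 90 degrees, the orthographic limit.
    """
    d = viewing_distance if viewing_distance is not None else image.camera.viewing_distance
    seg = image.segments
    lens = np.linalg.norm(seg, axis=1)
    live = np.flatnonzero(lens > 0)
    if len(live) < 2:
        raise ValueError("need at least 2 non-degenerate symmetry segments")
    anchors = image.pairs[:, 0, :]
    center = image.endpoints().mean(axis=0)
    diam = max(image.diameter(), 1e-300)
    slants: list[float] = []
    for ii in range(len(live)):
        for jj in range(ii + 1, len(live)):
            i, j = live[ii], live[jj]
            e1, e2 = seg[i], seg[j]
            cross = e1[0] * e2[1] - e1[1] * e2[0]
            if abs(cross) <= 1e-14 * lens[i] * lens[j]:
                slants.append(90.0)
                continue
            rhs = anchors[j] - anchors[i]
            s = (rhs[0] * e2[1] - rhs[1] * e2[0]) / cross
            v = anchors[i] + s * e1
            if np.linalg.norm(v - center) > 1e6 * diam:
                slants.append(90.0)
            else:
                slants.append(math.degrees(math.atan(np.linalg.norm(v) / d)))
    slants_arr = np.array(slants)
    return SlantEstimate(
        float(np.median(slants_arr)),
        "persp",
        {"per_pair_deg": slants_arr, "spread_deg": float(np.ptp(slants_arr))},
    )


def depth_range(recon: Reconstruction3D) -> float:
    """max z - min z of the reconstructed points (shift-invariant)."""
    z = recon.flat_points[:, 2]
    if len(z) == 0:
        raise ValueError("empty reconstruction")
    return float(z.max() - z.min())
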