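"""The one-parameter family of mirror-symmetric 3D interpretations of a
corrected orthographic pair image, indexed by symmetry-plane slant.

With tilt tau (the common segment direction) and slant sigma, the family
member at sigma places the symmetry plane through the origin with normal
n = (cos tau sin sigma, sin tau sin sigma, cos sigma). Each image pair
(a_i, b_i) of length L_i keeps its image (x, y); the midpoint depth is
chosen so the 3D midpoint lies on the plane and the two endpoints are
offset by -/+ (L_i / 2) cot(sigma) (the 'b' endpoint deeper). Depth is
defined up to a global shift (gauge: plane offset 0).

Shape dissimilarity between two members is the binary logarithm of the
ratio of the tangents of their slants; a dissimilarity x corresponds to
an aspect-ratio factor of 2**x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .imaging import CorrectedPairImage

__all__ = [
    "Reconstruction3D",
    "FamilyGrid",
    "default_slant_grid",
    "reconstruct_at_slant",
    "dissimilarity",
    "aspect_ratio_factor",
]

#: experiment adjustment range, radians
SLANT_MIN_RAD = 0.2
SLANT_MAX_RAD = math.pi / 2 - 0.2
SLANT_STEP_RAD = 0.01


@dataclass
class Reconstruction3D:
    """One family member: ``points`` has shape (n_pairs, 2, 3) holding the
    (a, b) 3D endpoints of every mirror pair."""

    points: np.ndarray
    slant_deg: float
    tilt_deg: float
    vertex_pairs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def flat_points(self) -> np.ndarray:
        return self.points.reshape(-1, 3)

    @property
    def normal(self) -> np.ndarray:
        s, t = math.radians(self.slant_deg), math.radians(self.tilt_deg)
        return np.array(
            [math.cos(t) * math.sin(s), math.sin(t) * math.sin(s), math.cos(s)]
        )

    def depth_by_vertex(self) -> dict[int, float]:
        """Depth of each source mesh vertex (requires vertex_pairs)."""
        if self.vertex_pairs is None:
            raise ValueError("reconstruction carries no vertex indices")
        out: dict[int, float] = {}
        for k, (ia, ib) in enumerate(self.vertex_pairs):
            out[int(ia)] = float(self.points[k, 0, 2])
            out[int(ib)] = float(self.points[k, 1, 2])
        return out


def reconstruct_at_slant(image: CorrectedPairImage, slant_deg: float) -> Reconstruction3D:
    """Family member at the given slant (degrees, strictly inside (0, 90))."""
    if not (0.0 < slant_deg < 90.0):
        raise ValueError("slant must be strictly inside (0, 90) degrees")
    s = math.radians(slant_deg)
    u = image.direction
    mid = image.pairs.mean(axis=1)
    lens = image.lengths
    z_mid = -math.tan(s) * (mid @ u)
    dz = 0.5 * lens / math.tan(s)
    a3 = np.column_stack([image.pairs[:, 0, 0], image.pairs[:, 0, 1], z_mid - dz])
    b3 = np.column_stack([image.pairs[:, 1, 0], image.pairs[:, 1, 1], z_mid + dz])
    return Reconstruction3D(
        np.stack([a3, b3], axis=1),
        slant_deg,
        image.tilt_deg,
        image.vertex_pairs,
        dict(image.meta),
    )


def dissimilarity(slant_ref_deg: float, slant_rec_deg: float) -> float:
    """log2(tan sigma_ref / tan sigma_rec); zero means a veridical
    reconstruction, negative means the reconstructed slant is larger."""
    for s in (slant_ref_deg, slant_rec_deg):
        if not (0.0 < s < 90.0):
            raise ValueError("slants must be strictly inside (0, 90) degrees")
    return math.log2(
        math.tan(math.radians(slant_ref_deg)) / math.tan(math.radians(slant_rec_deg))
    )


def aspect_ratio_factor(x: float) -> float:
    """Aspect-ratio ratio implied by a dissimilarity of x: 2**x."""
    return 2.0 ** x


def default_slant_grid(
    start_rad: float = SLANT_MIN_RAD,
    stop_rad: float = SLANT_MAX_RAD,
    step_rad: float = SLANT_STEP_RAD,
) -> np.ndarray:
    """The experiment's adjustable slant grid, radians."""
    return np.arange(start_rad, stop_rad + 1e-12, step_rad)


@dataclass
class FamilyGrid:
    """A corrected image together with the slant grid over which family
    members are enumerated."""

    image: CorrectedPairImage
    grid_rad: np.ndarray = field(default_factory=default_slant_grid)

    def __post_init__(self):
        self.grid_rad = np.asarray(self.grid_rad, dtype=float)
        if np.any(self.grid_rad <= 0) or np.any(self.grid_rad >= math.pi / 2):
            raise ValueError("slant grid must lie strictly inside (0, pi/2)")

    @property
    def grid_deg(self) -> np.ndarray:
        return np.degrees(self.grid_rad)

    def member(self, index: int) -> Reconstruction3D:
        return reconstruct_at_slant(self.image, math.degrees(self.grid_rad[index]))

    def members(self):
        for k in range(len(self.grid_rad)):
            yield self.member(k)
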