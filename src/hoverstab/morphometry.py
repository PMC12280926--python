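"""Morphometric geometry: centers of mass and buoyancy, fin positions,
fineness ratios.

The center of mass (COM) is located photographically: the specimen is
suspended from several anatomical landmarks, a vertical line through each
suspension point is overlaid on the coregistered lateral images, and the
COM is the point where the lines cross.  With more than two (noisy) lines
the crossing is taken in the least-squares sense.  The center of buoyancy
(COB) is the centroid of the segmented swim-bladder voxel mask from a
micro-CT scan.

Both centers are expressed in a proportional body frame: the
anterior-posterior (AP) coordinate is the distance from the snout along
the snout-to-caudal-peduncle axis divided by that axis length; the
dorsal-ventral (DV) coordinate uses the dorsal-most point as origin and is
divided by the local dorsal-ventral span.  The signed COM-COB offsets are
``com - cob`` per axis, so with the dorsal origin a COB lying ventral of
the COM gives a negative ``comcob_dv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Line2D",
    "SuspensionAxes",
    "VoxelMask",
    "BodyFrame",
    "MorphometricsRecord",
    "intersect_axes",
    "cob_from_mask",
    "proportional_position",
    "com_cob_offsets",
    "fineness",
    "read_voxel_mask",
]


@dataclass(frozen=True)
class Line2D:
    """A 2-D line given by a point on it and a (normalised) direction."""

    point: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("line direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / n))


@dataclass
class SuspensionAxes:
    """Vertical reference axes from the suspension photographs."""

    lines: list[Line2D]

    def __post_init__(self) -> None:
        if len(self.lines) < 2:
            raise ValueError("need at least 2 suspension axes")


@dataclass
class VoxelMask:
    """Binary 3-D occupancy grid of a segmented volume."""

    occupancy: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy).astype(bool)
        if self.occupancy.ndim != 3:
            raise ValueError("occupancy must be a 3-D array")
        if not self.occupancy.any():
            raise ValueError("voxel mask is empty")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")


@dataclass
class BodyFrame:
    """Lateral-view anatomical reference frame of one specimen.

    Points are 2-D (anterior-posterior, dorsal-ventral) image coordinates;
    linear measures are in the same length unit.
    """

    snout: tuple[float, float]
    caudal_peduncle: tuple[float, float]
    dorsal_extreme: tuple[float, float]
    ventral_extreme: tuple[float, float]
    total_length: float
    max_body_depth: float
    max_body_width: float

    def __post_init__(self) -> None:
        if self.total_length <= 0 or self.max_body_depth <= 0 or self.max_body_width <= 0:
            raise ValueError("TL, MBD and MBW must be positive")
        if np.allclose(self.snout, self.caudal_peduncle):
            raise ValueError("snout and caudal peduncle coincide")


@dataclass
class MorphometricsRecord:
    """Per-species morphology row used by the regression stage."""

    species: str
    mass: float
    fineness_depth: float
    fineness_width: float
    com_ap: float
    com_dv: float
    cob_ap: float
    cob_dv: float
    comcob_ap: float
    comcob_dv: float
    pect_fin_ap: float
    caud_fin_ap: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extra"}
        d.update(self.extra)
        return d


def intersect_axes(axes: SuspensionAxes) -> tuple[np.ndarray, float]:
    """Least-squares intersection point of the suspension axes.

    Minimises the sum of squared perpendicular distances to all lines;
    returns the point and the RMS of the residual perpendicular distances.
    Raises if all lines are (near-)parallel.
    """
    dim = 2
    M = np.zeros((dim, dim))
    b = np.zeros(dim)
    for line in axes.lines:
        a = np.asarray(line.point, dtype=float)
        u = np.asarray(line.direction, dtype=float)
        P = np.eye(dim) - np.outer(u, u)  # projector onto the normal space
        M += P
        b += P @ a
    # all-parallel: the normal-space projectors share a null direction
    w = np.linalg.eigvalsh(M)
    if w[0] < 1e-10 * max(w[-1], 1.0):
        raise ValueError("suspension axes are all parallel; no intersection")
    p = np.linalg.solve(M, b)
    sq = [
        float(np.sum(((np.eye(dim) - np.outer(u, u)) @ (p - a)) ** 2))
        for a, u in (
            (np.asarray(l.point, float), np.asarray(l.direction, float))
            for l in axes.lines
        )
    ]
    return p, float(np.sqrt(np.mean(sq)))


def cob_from_mask(mask: VoxelMask) -> np.ndarray:
    """Centroid of the occupied voxels: mean voxel coordinate * voxel size."""
    idx = np.argwhere(mask.occupancy)
    return idx.mean(axis=0) * np.asarray(mask.voxel_size, dtype=float)


def proportional_position(
    point, frame: BodyFrame
) -> tuple[float, float]:
    """Proportional (AP, DV) coordinates of a 2-D point in the body frame.

    AP is the projection onto the snout->peduncle axis divided by the axis
    length; DV is measured from the dorsal-most point toward the ventral
    extreme, divided by the dorsal-ventral span, so DV=0 at the dorsal
    surface and DV=1 at the ventral one.
    """
    p = np.asarray(point, dtype=float)
    s = np.asarray(frame.snout, dtype=float)
    c = np.asarray(frame.caudal_peduncle, dtype=float)
    axis = c - s
    length = np.linalg.norm(axis)
    u = axis / length
    ap = float(np.dot(p - s, u) / length)
    if not -0.1 <= ap <= 1.1:
        warnings.warn(
            f"point projects at AP={ap:.3f}, outside [-0.1, 1.1]; "
            "landmark may be mislabeled",
            stacklevel=2,
        )
    d = np.asarray(frame.dorsal_extreme, dtype=float)
    v = np.asarray(frame.ventral_extreme, dtype=float)
    dv_axis = v - d
    dv_axis = dv_axis - np.dot(dv_axis, u) * u  # perpendicular to the AP axis
    span = np.linalg.norm(dv_axis)
    if span == 0:
        raise ValueError("dorsal and ventral extremes define no DV span")
    w = dv_axis / span
    dv = float(np.dot(p - d, w) / span)
    return ap, dv


def com_cob_offsets(
    com: tuple[float, float],
    cob: tuple[float, float],
    absolute_ap: bool = False,
) -> tuple[float, float]:
    """Signed COM-COB offsets (AP, DV), each ``com - cob`` on its axis.

    With the dorsal-origin DV convention a COB ventral of the COM yields a
    negative DV offset.  ``absolute_ap=True`` returns |AP offset| instead
    (used to ask whether anterior-vs-posterior COB placement matters, as
    opposed to sheer separation).
    """
    ap = com[0] - cob[0]
    dv = com[1] - cob[1]
    if absolute_ap:
        ap = abs(ap)
    return ap, dv


def fineness(frame: BodyFrame) -> tuple[float, float]:
    """Fineness ratios (TL/MBD, TL/MBW)."""
    return (
        frame.total_length / frame.max_body_depth,
        frame.total_length / frame.max_body_width,
    )


def read_voxel_mask(path, voxel_size=(1.0, 1.0, 1.0)) -> VoxelMask:
    """Read a binary mask from a multi-page TIFF or an ``x y z`` text list.

    The text format holds one occupied voxel index triple per line; the
    grid is sized to the maximal index.
    """
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        vol = tifffile.imread(path)
        return VoxelMask(occupancy=vol > 0, voxel_size=voxel_size)
    coords = np.loadtxt(path, dtype=int, ndmin=2)
    if coords.shape[1] != 3:
        raise ValueError("voxel list must have three columns: x y z")
    shape = tuple(coords.max(axis=0) + 1)
    occ = np.zeros(shape, dtype=bool)
    occ[tuple(coords.T)] = True
    return VoxelMask(occupancy=occ, voxel_size=voxel_size)
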