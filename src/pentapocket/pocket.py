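"""Convex-hull pocket cage, water occupancy and Loop C orientation.

The pocket "atomic cage" is the convex hull of the Calpha atoms of the 11
binding residues, rebuilt at every frame.  Water occupancy is the number of
water oxygens inside (or on) the hull; the hull volume serves as a pocket
expansion estimate.  The Loop C orientation angle is measured at the hinge
centroid (O) between the rays to the apex centroid (C) and to a
complementary-subunit reference centroid (G); small angles correspond to a
capped (ligand-bound) pocket, large angles to an open lid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .core import Frame, ValidationError, angle_deg
from .topology import PocketSpec

__all__ = [
    "PocketCage",
    "PocketTimeSeries",
    "pocket_cage",
    "count_waters_in_cage",
    "points_in_hull",
    "loopc_angle",
    "pocket_timeseries",
]

#: boundary tolerance for the point-in-hull half-space test (A); points on a
#: facet count as inside, keeping the count deterministic under ties
HULL_BOUNDARY_TOL = 1e-9


@dataclass
class PocketCage:
    """Convex hull of the 11 binding-residue Calpha positions of one frame."""

    vertices: np.ndarray  # (11, 3) input points
    hull: ConvexHull
    volume: float

    @property
    def equations(self) -> np.ndarray:
        """Facet half-space equations [normal | offset]; inside <= 0."""
        return self.hull.equations


def pocket_cage(frame: Frame, pocket: PocketSpec) -> PocketCage:
    """Build the pocket cage from the 11 binding-residue Calpha atoms."""
    points = frame.coords[pocket.cage_ca]
    return cage_from_points(points)


def cage_from_points(points: np.ndarray) -> PocketCage:
    points = np.asarray(points, dtype=float)
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValidationError(
            f"degenerate pocket cage (coplanar/collinear points): {exc}"
        ) from exc
    return PocketCage(vertices=points, hull=hull, volume=float(hull.volume))


def points_in_hull(points: np.ndarray, cage: PocketCage,
                   tol: float = HULL_BOUNDARY_TOL) -> np.ndarray:
    """Boolean mask: which points lie inside or on the cage hull."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    eq = cage.equations
    # a point is inside iff every facet half-space test A.x + b <= tol
    return np.all(points @ eq[:, :3].T + eq[:, 3] <= tol, axis=1)


def count_waters_in_cage(frame: Frame, cage: PocketCage) -> int:
    """Number of water oxygens enclosed by the cage (boundary = inside)."""
    ow = frame.system.water_oxygens
    if ow.size == 0:
        return 0
    return int(np.count_nonzero(points_in_hull(frame.coords[ow], cage)))


def loopc_angle(frame: Frame, pocket: PocketSpec,
                vertex: str = "hinge") -> float:
    """Loop C orientation angle (degrees) for one pocket in one frame.

    C, O and G are the Calpha centroids of the apex, hinge and
    complementary-reference residue pairs.  By default the angle is taken at
    the hinge (the loop pivots there); *vertex* may name any of the three
    anchors for sensitivity analysis.
    """
    c = frame.coords[pocket.apex_ca].mean(axis=0)
    o = frame.coords[pocket.hinge_ca].mean(axis=0)
    g = frame.coords[pocket.reference_ca].mean(axis=0)
    corners = {"apex": (o, c, g), "hinge": (c, o, g), "reference": (c, g, o)}
    if vertex not in corners:
        raise ValidationError(f"unknown angle vertex {vertex!r}")
    a, v, b = corners[vertex]
    return angle_deg(a, v, b)


@dataclass
class PocketTimeSeries:
    """Per-frame water count, hull volume and Loop C angle for one pocket."""

    pocket: str
    occupied: bool
    frames: np.ndarray       # frame indices
    water_count: np.ndarray  # int per frame
    hull_volume: np.ndarray  # A^3 per frame
    loopc_angle: np.ndarray  # degrees per frame

    def __post_init__(self) -> None:
        n = len(self.frames)
        if not (len(self.water_count) == len(self.hull_volume)
                == len(self.loopc_angle) == n):
            raise ValidationError("pocket time series must have equal lengths")
        if n and (self.water_count < 0).any():
            raise ValidationError("negative water count")

    def __len__(self) -> int:
        return len(self.frames)

    def summary(self, display_offset: bool = False) -> dict:
        """Mean/std of the three series.

        ``display_offset=True`` adds 5 to the reported water mean of occupied
        pockets (a display-only convention that makes bound-pocket water
        contents visually comparable to empty ones by crediting the ligand's
        excluded volume); stored data are never offset.
        """
        offset = 5.0 if (display_offset and self.occupied) else 0.0
        return {
            "pocket": self.pocket,
            "occupied": self.occupied,
            "n_frames": int(len(self)),
            "water_mean": float(np.mean(self.water_count)) + offset,
            "water_std": float(np.std(self.water_count)),
            "volume_mean": float(np.mean(self.hull_volume)),
            "volume_std": float(np.std(self.hull_volume)),
            "angle_mean": float(np.mean(self.loopc_angle)),
            "angle_std": float(np.std(self.loopc_angle)),
        }

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "frame": self.frames,
            "water_count": self.water_count,
            "hull_volume_A3": self.hull_volume,
            "loopc_angle_deg": self.loopc_angle,
        })


def pocket_timeseries(frames: Iterable[Frame], pocket: PocketSpec,
                      vertex: str = "hinge") -> PocketTimeSeries:
    """Compute the per-frame descriptor triplet for one pocket.

    The cage hull is rebuilt at every frame.
    """
    idx, waters, volumes, angles = [], [], [], []
    for frame in frames:
        cage = pocket_cage(frame, pocket)
        idx.append(frame.frame_index)
        waters.append(count_waters_in_cage(frame, cage))
        volumes.append(cage.volume)
        angles.append(loopc_angle(frame, pocket, vertex=vertex))
    if not idx:
        raise ValidationError("empty trajectory")
    return PocketTimeSeries(
        pocket=pocket.label,
        occupied=pocket.occupied,
        frames=np.asarray(idx, dtype=int),
        water_count=np.asarray(waters, dtype=int),
        hull_volume=np.asarray(volumes, dtype=float),
        loopc_angle=np.asarray(angles, dtype=float),
    )
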