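"""Shared geometry and container types used across the analysis modules.

Units are carried explicitly: electron-microscopy point patterns are in
nanometres, single-particle tracks in micrometres (or pixels before
calibration), and assay curves tag their abscissa unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("memnano")


@dataclass(frozen=True)
class Region:
    """A rectangular observation window with its lower-left corner at (0, 0).

    Parameters
    ----------
    width, height : float
        Side lengths, in whatever length unit the enclosing analysis uses
        (nm for EM sheets, um for TIRF fields of view). Must be positive.
    """

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"Region sides must be positive, got {self.width} x {self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the closed rectangle."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return (
            (xy[:, 0] >= 0)
            & (xy[:, 0] <= self.width)
            & (xy[:, 1] >= 0)
            & (xy[:, 1] <= self.height)
        )


@dataclass
class PointPattern:
    """A set of point coordinates observed within a rectangular region.

    The unit of spatial analysis: one plasma-membrane sheet's gold-particle
    coordinates. Coordinates are continuous, in nm, origin at the region's
    lower-left corner.
    """

    points: np.ndarray
    region: Region
    sheet_id: str = "sheet"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", pts)
        if pts.size and not self.region.contains(pts).all():
            bad = int((~self.region.contains(pts)).sum())
            raise ValueError(
                f"{bad} point(s) of pattern {self.sheet_id!r} fall outside the region"
            )
        if pts.shape[0] > 1:
            # exact duplicates are legal but worth noting (overlapping labels)
            n_unique = np.unique(pts, axis=0).shape[0]
            if n_unique < pts.shape[0]:
                logger.info(
                    "pattern %s contains %d exact duplicate point(s)",
                    self.sheet_id,
                    pts.shape[0] - n_unique,
                )

    @property
    def n(self) -> int:
        return int(self.points.shape[0])

    @property
    def density(self) -> float:
        """Points per unit area (same length unit as the region)."""
        return self.n / self.region.area


@dataclass
class Track:
    """One linked particle trajectory: strictly increasing frame indices and
    matching (x, y) positions."""

    id: int
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=int)
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        if frames.shape[0] != xy.shape[0]:
            raise ValueError("frames and xy lengths differ")
        if frames.size > 1 and not (np.diff(frames) > 0).all():
            raise ValueError("track frames must be strictly increasing")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class TrackSet:
    """A collection of trajectories sharing a frame interval and unit.

    ``unit`` is ``"um"`` for calibrated positions or ``"px"`` straight out of
    detection; ``truth`` optionally carries the ground-truth trajectories a
    simulator produced alongside the observations.
    """

    tracks: list[Track]
    frame_interval: float = 0.010
    unit: str = "um"
    region: Region | None = None
    truth: list[Track] | None = None
    n_frames: int | None = None

    def __len__(self) -> int:
        return len(self.tracks)


@dataclass
class CurveTrace:
    """A generic (abscissa, signal) series: TRACT/FLIM decays, melt curves,
    or scattering-vs-log-concentration series."""

    x: np.ndarray
    y: np.ndarray
    kind: str = ""
    x_unit: str = ""
    y_unit: str = "au"

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if x.size > 1 and not (np.diff(x) > 0).all():
            raise ValueError("abscissa must be strictly increasing")
        if not np.isfinite(y).all():
            raise ValueError("signal contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.x.size)
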