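"""Shared domain types for the retinal registration pipeline.

Conventions used throughout the package:

* raster indices are 0-based ``(row, col)`` with the origin at the top-left
  pixel center;
* geometric points are ``(x, y) = (col, row)`` so that a homography acts on
  the usual Cartesian pixel coordinates;
* images are numpy arrays, 2-D grayscale or 3-D ``(rows, cols, 3)``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FundusImage",
    "VesselMask",
    "SkeletonMask",
    "JunctionKind",
    "Provenance",
    "JunctionPoint",
    "CorrespondenceSet",
    "ConfusionCounts",
    "Homography",
    "rc_to_xy",
    "xy_to_rc",
]


class JunctionKind(str, enum.Enum):
    """Type of vascular junction: a vessel split or a vessel crossing."""

    BIFURCATION = "bifurcation"
    CROSSOVER = "crossover"
    UNKNOWN = "unknown"


class Provenance(str, enum.Enum):
    """How a junction point was obtained."""

    GROUND_TRUTH = "ground_truth"
    DETECTED = "detected"
    CALIBRATED = "calibrated"


@dataclass
class FundusImage:
    """A fundus photograph (or any raster the pipeline moves through).

    Pixels are either 8-bit integers in ``[0, 255]`` or floats in ``[0, 1]``;
    shape is ``(rows, cols)`` or ``(rows, cols, 3)``.
    """

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError("image must be 2-D or 3-D")
        if self.pixels.ndim == 3 and self.pixels.shape[2] not in (1, 3):
            raise ValueError("channel count must be 1 or 3")
        if self.pixels.shape[0] < 32 or self.pixels.shape[1] < 32:
            raise ValueError("image must be at least 32x32 pixels")
        if not np.all(np.isfinite(np.asarray(self.pixels, dtype=np.float64))):
            raise ValueError("image contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]

    def as_gray(self) -> np.ndarray:
        """Grayscale float view in [0, 1].

        Color images use the green channel, which shows retinal tissue with
        the best contrast of the three.
        """
        px = self.pixels
        if px.ndim == 3:
            px = px[:, :, 1] if px.shape[2] == 3 else px[:, :, 0]
        px = np.asarray(px, dtype=np.float64)
        if px.max() > 1.0:
            px = px / 255.0
        return px


@dataclass
class VesselMask:
    """Binary vessel map: 1 on vessel pixels, 0 on background."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        vals = np.unique(m)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask values must be 0/1")
        self.mask = m.astype(np.uint8)

    @property
    def shape(self) -> tuple:
        return self.mask.shape


@dataclass
class SkeletonMask:
    """Binary one-pixel-wide vessel centerline map."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("skeleton must be 2-D")
        self.mask = (m > 0).astype(np.uint8)


@dataclass(frozen=True)
class JunctionPoint:
    """A located vascular landmark (bifurcation or crossover)."""

    row: int
    col: int
    kind: JunctionKind = JunctionKind.UNKNOWN
    score: float = 1.0
    provenance: Provenance = Provenance.DETECTED

    def __post_init__(self) -> None:
        if self.row < 0 or self.col < 0:
            raise ValueError("junction coordinates must be non-negative")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")

    @property
    def xy(self) -> tuple:
        return (float(self.col), float(self.row))


@dataclass
class CorrespondenceSet:
    """Paired control points: (x, y) in the reference and sensed frames."""

    ref_points: np.ndarray  # (n, 2) float, (x, y)
    sensed_points: np.ndarray  # (n, 2) float, (x, y)

    def __post_init__(self) -> None:
        self.ref_points = np.atleast_2d(np.asarray(self.ref_points, dtype=np.float64))
        self.sensed_points = np.atleast_2d(
            np.asarray(self.sensed_points, dtype=np.float64)
        )
        if self.ref_points.shape != self.sensed_points.shape:
            raise ValueError("reference and sensed point arrays differ in shape")
        if self.ref_points.ndim != 2 or self.ref_points.shape[1] != 2:
            raise ValueError("points must be (n, 2) arrays")
        if len(self.ref_points) < 1:
            raise ValueError("at least one correspondence is required")
        if not (
            np.all(np.isfinite(self.ref_points))
            and np.all(np.isfinite(self.sensed_points))
        ):
            raise ValueError("correspondence points must be finite")

    def __len__(self) -> int:
        return len(self.ref_points)


@dataclass
class ConfusionCounts:
    """TP/FP/FN/TN counts; TN is None for detection tasks where true
    negatives cannot be enumerated."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be non-negative")


@dataclass
class Homography:
    """A 3x3 projective map normalized so its last element is 1.

    By package convention the matrix maps sensed-image pixel coordinates
    ``(a, b)`` into the reference frame:

        a' = (h11 a + h12 b + h13) / (h31 a + h32 b + 1)
        b' = (h21 a + h22 b + h23) / (h31 a + h32 b + 1)
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (3, 3):
            raise ValueError("homography must be 3x3")
        if m[2, 2] == 0 or not np.all(np.isfinite(m)):
            raise ValueError("invalid homography matrix")
        m = m / m[2, 2]
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("homography is singular")
        self.matrix = m

    @classmethod
    def identity(cls) -> "Homography":
        return cls(np.eye(3))

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))

    def compose(self, other: "Homography") -> "Homography":
        """self ∘ other: apply `other` first, then `self`."""
        return Homography(self.matrix @ other.matrix)


def rc_to_xy(points_rc: np.ndarray) -> np.ndarray:
    """(row, col) index pairs -> (x, y) geometric points. Inverse of
    :func:`xy_to_rc`."""
    pts = np.atleast_2d(np.asarray(points_rc, dtype=np.float64))
    return pts[:, ::-1].copy()


def xy_to_rc(points_xy: np.ndarray) -> np.ndarray:
    """(x, y) geometric points -> (row, col) index pairs."""
    pts = np.atleast_2d(np.asarray(points_xy, dtype=np.float64))
    return pts[:, ::-1].copy()
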