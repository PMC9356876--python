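"""Junction calibration by skeleton crossing-number analysis.

A detected landmark is kept only if the vessel centerline around it truly
has three or more branches meeting: the vessel mask is skeletonized and
every skeleton pixel's crossing number (0->1 transitions around its
8-neighborhood ring) is computed inside a window around each candidate.
Interior line pixels score 2, endpoints 1, and junctions 3 or more;
candidates are snapped to the nearest qualifying skeleton pixel or
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize

from .types import (
    JunctionKind,
    JunctionPoint,
    Provenance,
    SkeletonMask,
    VesselMask,
)

__all__ = [
    "CalibrationParams",
    "prune_spurs",
    "skeletonize_region",
    "count_branch_neighbors",
    "calibrate_junctions",
    "detect_junctions_from_mask",
]


@dataclass
class CalibrationParams:
    """window_half_size crops a (2w+1)^2 sub-image around each candidate;
    snap_radius bounds how far a candidate may move to a skeleton junction
    pixel (0 = filter only, never move)."""

    window_half_size: int = 12
    snap_radius: int = 8
    spur_length: int = 4

    def __post_init__(self) -> None:
        if self.snap_radius < 0:
            raise ValueError("snap_radius must be >= 0")
        if self.window_half_size < max(1, self.snap_radius):
            raise ValueError("window_half_size must be >= snap_radius >= 1")


def skeletonize_region(mask: VesselMask) -> SkeletonMask:
    """Thin a binary vessel region to its one-pixel-wide centerline."""
    return SkeletonMask(skeletonize(mask.mask.astype(bool)).astype(np.uint8))


# 8-neighborhood ring in clockwise order starting at north
_RING = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def count_branch_neighbors(skeleton: SkeletonMask, pixel: tuple) -> int:
    """Crossing number of a skeleton pixel: the count of 0->1 transitions
    met while walking the 8-neighborhood ring, i.e. the number of distinct
    branches leaving the pixel."""
    r, c = int(pixel[0]), int(pixel[1])
    sk = skeleton.mask
    if not (0 <= r < sk.shape[0] and 0 <= c < sk.shape[1]) or sk[r, c] == 0:
        raise ValueError(f"pixel {pixel} is not on the skeleton")
    ring = []
    for dr, dc in _RING:
        rr, cc = r + dr, c + dc
        inside = 0 <= rr < sk.shape[0] and 0 <= cc < sk.shape[1]
        ring.append(int(sk[rr, cc]) if inside else 0)
    return sum(
        1 for i in range(8) if ring[i] == 0 and ring[(i + 1) % 8] == 1
    )


def prune_spurs(skeleton: SkeletonMask, length: int = 4) -> SkeletonMask:
    """Remove short terminal twigs by iteratively deleting endpoint pixels.

    Thinning a rasterized vessel leaves pixel-scale spurs whose bases look
    like 3-branch junctions; ``length`` rounds of endpoint deletion erase
    them while only trimming the tips of real branches.
    """
    sk = skeleton.mask.copy()
    kernel = np.ones((3, 3), dtype=np.int64)
    for _ in range(max(0, length)):
        neigh = ndimage.convolve(sk.astype(np.int64), kernel, mode="constant") - sk
        endpoints = (sk == 1) & (neigh <= 1)
        if not endpoints.any():
            break
        sk[endpoints] = 0
    return SkeletonMask(sk)


def _junction_pixels(skeleton: np.ndarray) -> np.ndarray:
    """(n, 2) array of skeleton pixels with crossing number >= 3."""
    sk = SkeletonMask(skeleton)
    rows, cols = np.nonzero(skeleton)
    out = [
        (r, c)
        for r, c in zip(rows, cols)
        if count_branch_neighbors(sk, (r, c)) >= 3
    ]
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _canonical_junction_pixels(skeleton: np.ndarray, merge_radius: float = 4.0) -> np.ndarray:
    """One representative junction pixel per cluster.

    Thinning an X-shaped crossing often yields two 3-branch pixels a few
    px apart; treating each cluster's most central member as *the*
    junction pixel makes snapping deterministic and stable.
    """
    cand = _junction_pixels(skeleton)
    reps = []
    used = np.zeros(len(cand), dtype=bool)
    order = np.argsort(cand[:, 0] * (skeleton.shape[1] + 1) + cand[:, 1]) if len(cand) else []
    for i in order:
        if used[i]:
            continue
        d = np.hypot(cand[:, 0] - cand[i, 0], cand[:, 1] - cand[i, 1])
        group = (d <= merge_radius) & ~used
        used |= group
        members = cand[group]
        centroid = members.mean(axis=0)
        k = int(np.argmin(np.hypot(*(members - centroid).T)))
        reps.append(tuple(members[k]))
    return np.array(reps, dtype=np.int64).reshape(-1, 2)


def calibrate_junctions(
    points: list,
    mask: VesselMask,
    params: CalibrationParams | None = None,
) -> list:
    """Snap each candidate to the nearest skeleton junction pixel within
    the snap radius; drop candidates with no such pixel; deduplicate
    survivors landing on the same pixel (highest score wins).

    Calibration is idempotent: feeding its output back returns it
    unchanged.
    """
    params = params or CalibrationParams()
    h_img, w_img = mask.shape
    # one global skeleton: stable under repeated calibration, unlike
    # per-crop thinning whose result depends on where the window falls
    sk = prune_spurs(
        SkeletonMask(skeletonize(mask.mask.astype(bool)).astype(np.uint8)),
        params.spur_length,
    ).mask
    cand = _canonical_junction_pixels(sk)
    best: dict[tuple, JunctionPoint] = {}
    for p in points:
        if not (0 <= p.row < h_img and 0 <= p.col < w_img):
            continue
        if len(cand) == 0:
            break
        keep = (np.abs(cand[:, 0] - p.row) <= params.window_half_size) & (
            np.abs(cand[:, 1] - p.col) <= params.window_half_size
        )
        local = cand[keep]
        if len(local) == 0:
            continue
        d = np.hypot(local[:, 0] - p.row, local[:, 1] - p.col)
        i = int(np.argmin(d))
        if params.snap_radius == 0:
            if d[i] > 0.5:  # filter-only mode: keep iff already on a junction
                continue
            target = (p.row, p.col)
        elif d[i] <= params.snap_radius:
            target = (int(local[i, 0]), int(local[i, 1]))
        else:
            continue
        new = JunctionPoint(
            target[0], target[1], p.kind, p.score, Provenance.CALIBRATED
        )
        old = best.get(target)
        if old is None or new.score > old.score:
            best[target] = new
    return sorted(best.values(), key=lambda q: (q.row, q.col))


def detect_junctions_from_mask(
    mask: VesselMask, merge_radius: float = 4.0, spur_length: int = 4
) -> list:
    """Skeleton-based junction detection: skeletonize the whole mask, keep
    pixels with crossing number >= 3, and merge clusters of nearby
    junction pixels into single points.

    This is the classical detector the learned one is benchmarked against,
    and the route used when a trusted vessel mask is already available.
    """
    sk = prune_spurs(skeletonize_region(mask), spur_length)
    reps = _canonical_junction_pixels(sk.mask, merge_radius)
    return [
        JunctionPoint(int(r), int(c), JunctionKind.UNKNOWN, 1.0, Provenance.DETECTED)
        for r, c in reps
    ]
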