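"""Synthetic vascular phantoms and registered fundus image pairs.

The generator emulates the data the pipeline is built for: branching
vascular trees rendered as dark vessels on a bright textured background
inside a circular field of view, with every bifurcation/crossover
coordinate recorded as ground truth, and image pairs related by a known
projective homography with an illumination change. Optional defocus blur
emulates poor-quality acquisitions and intensity inversion emulates
fluorescein-angiography pairs.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import draw as skdraw
from skimage import transform as sktransform

from .types import (
    FundusImage,
    Homography,
    JunctionKind,
    JunctionPoint,
    Provenance,
    VesselMask,
)

__all__ = [
    "VascularTreeParams",
    "TransformSpec",
    "PairQuality",
    "SyntheticPair",
    "generate_vascular_tree",
    "render_fundus",
    "compose_homography",
    "generate_pair",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Raised when parameters cannot produce a usable phantom."""


class PairQuality(str, enum.Enum):
    GOOD = "good"
    BLURRED = "blurred"
    INVERTED = "inverted"


@dataclass
class VascularTreeParams:
    """Parameters of the recursive branching vascular phantom.

    Defaults describe a desk-scale retina: a 256-px field of view with
    four major vessels entering at the rim, branching with probability
    0.85 per generation at bifurcation half-angles of 25-50 degrees, 5-px
    trunks tapering by 0.85 per generation over at most 7 generations.
    """

    image_size: int = 256
    n_roots: int = 4
    branch_prob: float = 0.85
    min_branch_angle: float = 25.0  # degrees, each child off the parent heading
    max_branch_angle: float = 50.0
    initial_width: float = 5.0
    width_decay: float = 0.85
    max_depth: int = 7
    min_junction_sep: float = 9.0  # px between recorded junctions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.initial_width < 1:
            raise ValueError("vessel width must be >= 1 px")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValueError("branch_prob must lie in [0, 1]")


@dataclass
class TransformSpec:
    """Reference->sensed viewpoint change, kept in realistic fundus ranges."""

    rotation_deg: float = 0.0
    translation: tuple = (0.0, 0.0)  # (tx, ty) px
    scale: float = 1.0
    perspective: tuple = (0.0, 0.0)  # (p1, p2), bottom row of the matrix

    def __post_init__(self) -> None:
        if abs(self.rotation_deg) > 45.0:
            raise ValueError("|rotation| must be <= 45 degrees")
        if not (0.8 <= self.scale <= 1.25):
            raise ValueError("scale must lie in [0.8, 1.25]")
        if max(abs(self.perspective[0]), abs(self.perspective[1])) > 2e-4:
            raise ValueError("|perspective terms| must be <= 2e-4")


@dataclass
class SyntheticPair:
    """A reference/sensed fundus pair with exhaustive ground truth."""

    ref_image: FundusImage
    sensed_image: FundusImage
    true_mask_ref: VesselMask
    true_mask_sensed: VesselMask
    true_junctions_ref: list
    true_junctions_sensed: list
    true_H: Homography  # maps sensed -> reference
    quality: PairQuality = PairQuality.GOOD


def _fov(size: int) -> tuple:
    c = (size - 1) / 2.0
    return c, 0.47 * size


def _inside_fov(x: float, y: float, size: int, margin: float = 0.0) -> bool:
    c, r = _fov(size)
    return (x - c) ** 2 + (y - c) ** 2 <= (r - margin) ** 2


def _stamp_segment(canvas: np.ndarray, p0, p1, width: float) -> None:
    """Draw a thick segment by stamping discs along it (binary raster)."""
    size = canvas.shape[0]
    length = math.hypot(p1[0] - p0[0], p1[1] - p0[1])
    n = max(2, int(math.ceil(length * 2)))
    radius = max(0.6, width / 2.0)
    for t in np.linspace(0.0, 1.0, n):
        x = p0[0] + t * (p1[0] - p0[0])
        y = p0[1] + t * (p1[1] - p0[1])
        rr, cc = skdraw.disk((y, x), radius, shape=(size, size))
        canvas[rr, cc] = 1


def _seg_intersection(a0, a1, b0, b1):
    """Interior intersection point of two segments, or None."""
    d1 = (a1[0] - a0[0], a1[1] - a0[1])
    d2 = (b1[0] - b0[0], b1[1] - b0[1])
    den = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(den) < 1e-9:
        return None
    dx, dy = b0[0] - a0[0], b0[1] - a0[1]
    t = (dx * d2[1] - dy * d2[0]) / den
    u = (dx * d1[1] - dy * d1[0]) / den
    # keep away from endpoints so crossings are not confused with branches
    if 0.12 < t < 0.88 and 0.12 < u < 0.88:
        return (a0[0] + t * d1[0], a0[1] + t * d1[1])
    return None


def _seg_angle(a0, a1, b0, b1) -> float:
    """Acute angle between two segments, degrees."""
    v1 = np.array([a1[0] - a0[0], a1[1] - a0[1]])
    v2 = np.array([b1[0] - b0[0], b1[1] - b0[1]])
    c = abs(float(np.dot(v1, v2))) / max(
        np.linalg.norm(v1) * np.linalg.norm(v2), 1e-12
    )
    return math.degrees(math.acos(min(1.0, c)))


def _point_seg_dist(p, b0, b1) -> float:
    v = np.array([b1[0] - b0[0], b1[1] - b0[1]])
    w = np.array([p[0] - b0[0], p[1] - b0[1]])
    t = float(np.clip(np.dot(w, v) / max(np.dot(v, v), 1e-12), 0.0, 1.0))
    return float(np.hypot(w[0] - t * v[0], w[1] - t * v[1]))


def _seg_seg_dist(a0, a1, b0, b1) -> float:
    if _seg_intersection(a0, a1, b0, b1) is not None:
        return 0.0
    return min(
        _point_seg_dist(a0, b0, b1),
        _point_seg_dist(a1, b0, b1),
        _point_seg_dist(b0, a0, a1),
        _point_seg_dist(b1, a0, a1),
    )


def generate_vascular_tree(params: VascularTreeParams):
    """Grow a branching vascular phantom.

    Returns the binary vessel mask and the ground-truth junction list:
    every branching event is a bifurcation, every interior intersection of
    segments from different roots is a crossover. Deterministic given the
    params seed.
    """
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    c, fov_r = _fov(size)
    canvas = np.zeros((size, size), dtype=np.uint8)
    junctions: list[JunctionPoint] = []
    segments: list[tuple] = []  # (p0, p1, width)

    base_len = 0.17 * size

    def grow(p, heading, width, depth, root_id) -> bool:
        """Grow one segment (and its subtree); True if the segment drew."""
        if depth >= params.max_depth:
            return False
        length = base_len * (0.92**depth) * rng.uniform(0.8, 1.2)
        q = (p[0] + length * math.cos(heading), p[1] + length * math.sin(heading))
        if not _inside_fov(q[0], q[1], size, margin=2.0):
            return False
        # geometry hygiene: a new vessel may cross an existing one only at
        # a steep angle (a clean, recordable crossover); shallow crossings
        # and near-tangent passes produce skeleton junctions that match no
        # ground-truth landmark, so such segments are rejected outright
        crossings = []
        for b0, b1, bw in segments:
            adjacent = (
                math.hypot(p[0] - b0[0], p[1] - b0[1]) < 1.0
                or math.hypot(p[0] - b1[0], p[1] - b1[1]) < 1.0
            )
            hit = _seg_intersection(p, q, b0, b1)
            if hit is not None:
                if adjacent or _seg_angle(p, q, b0, b1) < 35.0:
                    return False
                if any(
                    math.hypot(hit[0] - j.col, hit[1] - j.row)
                    < params.min_junction_sep
                    for j in junctions
                ):
                    return False
                crossings.append(hit)
            elif not adjacent and _seg_seg_dist(p, q, b0, b1) < (width + bw) / 2 + 3.0:
                return False
        for hit in crossings:
            junctions.append(
                JunctionPoint(
                    int(round(hit[1])),
                    int(round(hit[0])),
                    JunctionKind.CROSSOVER,
                    1.0,
                    Provenance.GROUND_TRUTH,
                )
            )
        _stamp_segment(canvas, p, q, width)
        segments.append((p, q, width))
        child_width = max(1.2, width * params.width_decay)
        sep_ok = not any(
            math.hypot(q[0] - j.col, q[1] - j.row) < params.min_junction_sep
            for j in junctions
        )
        if rng.uniform() < params.branch_prob and depth + 1 < params.max_depth and sep_ok:
            half = math.radians(
                rng.uniform(params.min_branch_angle, params.max_branch_angle)
            )
            drew = [
                grow(q, heading + sign * half * rng.uniform(0.7, 1.0),
                     child_width, depth + 1, root_id)
                for sign in (+1, -1)
            ]
            # a branch point is a junction only if both children materialized
            if all(drew):
                junctions.append(
                    JunctionPoint(
                        int(round(q[1])),
                        int(round(q[0])),
                        JunctionKind.BIFURCATION,
                        1.0,
                        Provenance.GROUND_TRUTH,
                    )
                )
        else:
            grow(q, heading + rng.uniform(-0.25, 0.25), child_width,
                 depth + 1, root_id)
        return True

    for root in range(params.n_roots):
        phi = 2 * math.pi * root / params.n_roots + rng.uniform(-0.3, 0.3)
        p = (c + fov_r * 0.98 * math.cos(phi), c + fov_r * 0.98 * math.sin(phi))
        heading = phi + math.pi + rng.uniform(-0.3, 0.3)  # point inward
        grow(p, heading, params.initial_width, 0, root)

    if canvas.sum() == 0:
        raise GenerationError("parameters produced no vessel pixels")

    # drop junctions that fell outside the field of view
    junctions = [
        j for j in junctions if _inside_fov(j.col, j.row, size, margin=4.0)
    ]
    return VesselMask(canvas), _refine_to_skeleton(canvas, junctions)


def _refine_to_skeleton(canvas: np.ndarray, junctions: list, radius: float = 5.0) -> list:
    """Snap recorded junction coordinates to the rendered geometry.

    Rasterizing thick vessels displaces the point where centerlines
    actually meet by a few pixels from the ideal polyline vertex; the
    ground truth must describe the image that was drawn, so each recorded
    coordinate is moved to the nearest skeleton pixel with three or more
    branches (within ``radius``; duplicates collapse to one point).
    """
    from .calibration import _canonical_junction_pixels, prune_spurs, skeletonize_region
    from .types import SkeletonMask

    if not junctions:
        return junctions
    sk = prune_spurs(skeletonize_region(VesselMask(canvas)))
    cand = _canonical_junction_pixels(sk.mask)
    out, seen = [], set()
    for j in junctions:
        r, c = j.row, j.col
        if len(cand):
            d = np.hypot(cand[:, 0] - j.row, cand[:, 1] - j.col)
            i = int(np.argmin(d))
            if d[i] <= radius:
                r, c = int(cand[i, 0]), int(cand[i, 1])
        if (r, c) in seen:
            continue
        seen.add((r, c))
        out.append(JunctionPoint(r, c, j.kind, 1.0, Provenance.GROUND_TRUTH))
    return out


def render_fundus(
    mask: VesselMask, style: str = "fundus", seed: int = 0, noise_sigma: float = 3.0
) -> FundusImage:
    """Render a vessel mask as an 8-bit fundus-style (dark vessels on a
    bright textured disc) or angiography-style (inverted) image."""
    rng = np.random.default_rng(seed)
    size = mask.shape[0]
    c, fov_r = _fov(size)
    yy, xx = np.mgrid[0:size, 0 : mask.shape[1]]
    r2 = ((yy - c) ** 2 + (xx - c) ** 2) / fov_r**2
    fov = r2 <= 1.0

    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, mask.shape), 6.0)
    texture = 14.0 * texture / max(texture.std(), 1e-9)
    soft_vessels = ndimage.gaussian_filter(mask.mask.astype(np.float64), 0.7)
    soft_vessels /= max(soft_vessels.max(), 1e-9)

    if style == "fundus":
        background = 150.0 + 55.0 * (1.0 - r2) + texture
        img = background - 70.0 * soft_vessels
    elif style == "angiography":
        background = 45.0 + 15.0 * (1.0 - r2) + texture
        img = background + 80.0 * soft_vessels
    else:
        raise ValueError(f"unknown render style {style!r}")

    img = img + rng.normal(0.0, noise_sigma, mask.shape)
    img = np.where(fov, img, 0.0)
    return FundusImage(np.clip(img, 0, 255).round().astype(np.uint8))


def compose_homography(spec: TransformSpec, image_size: int) -> Homography:
    """Compose the sensed->reference projective map from a rotation and
    scale about the image center, a translation, and perspective terms."""
    c = (image_size - 1) / 2.0
    th = math.radians(spec.rotation_deg)
    t_c = np.array([[1, 0, c], [0, 1, c], [0, 0, 1]], dtype=np.float64)
    t_nc = np.array([[1, 0, -c], [0, 1, -c], [0, 0, 1]], dtype=np.float64)
    rot = np.array(
        [
            [math.cos(th), -math.sin(th), 0],
            [math.sin(th), math.cos(th), 0],
            [0, 0, 1],
        ],
        dtype=np.float64,
    )
    sc = np.diag([spec.scale, spec.scale, 1.0])
    persp = np.array(
        [[1, 0, 0], [0, 1, 0], [spec.perspective[0], spec.perspective[1], 1]],
        dtype=np.float64,
    )
    trans = np.array(
        [[1, 0, spec.translation[0]], [0, 1, spec.translation[1]], [0, 0, 1]],
        dtype=np.float64,
    )
    return Homography(trans @ t_c @ persp @ sc @ rot @ t_nc)


def _apply_h(matrix: np.ndarray, pts_xy: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(pts_xy)
    hom = np.c_[pts, np.ones(len(pts))] @ matrix.T
    return hom[:, :2] / hom[:, 2:3]


def generate_pair(
    params: VascularTreeParams,
    transform: TransformSpec | None = None,
    quality: PairQuality | str = PairQuality.GOOD,
    seed: int = 0,
) -> SyntheticPair:
    """Generate a registered reference/sensed phantom pair.

    The sensed mask and junctions are the reference ones pushed through the
    inverse of the true homography (nearest-neighbor mask resampling); the
    sensed rendering uses an independent noise seed so the pair differs in
    illumination and noise, not only in geometry.
    """
    quality = PairQuality(quality)
    transform = transform or TransformSpec()
    size = params.image_size
    true_h = compose_homography(transform, size)

    mask_ref, junc_ref = generate_vascular_tree(params)
    # sensed pixel p takes the reference value at true_H(p)
    tform = sktransform.ProjectiveTransform(matrix=true_h.matrix)
    sensed = sktransform.warp(
        mask_ref.mask.astype(np.float64), tform, order=0, preserve_range=True
    )
    mask_sensed = VesselMask((sensed > 0.5).astype(np.uint8))
    if mask_sensed.mask.sum() < 0.2 * mask_ref.mask.sum():
        raise GenerationError("transform pushes most of the field of view out of frame")

    h_inv = np.linalg.inv(true_h.matrix)
    junc_sensed = []
    for j in junc_ref:
        x, y = _apply_h(h_inv, np.array([[j.col, j.row]]))[0]
        r, cpx = int(round(y)), int(round(x))
        if 0 <= r < size and 0 <= cpx < size and _inside_fov(x, y, size, margin=4.0):
            junc_sensed.append(
                JunctionPoint(r, cpx, j.kind, 1.0, Provenance.GROUND_TRUTH)
            )

    ref_img = render_fundus(mask_ref, "fundus", seed=seed * 2 + 1)
    sensed_style = "angiography" if quality is PairQuality.INVERTED else "fundus"
    sensed_img = render_fundus(mask_sensed, sensed_style, seed=seed * 2 + 2)
    if quality is PairQuality.BLURRED:
        blurred = ndimage.gaussian_filter(
            sensed_img.pixels.astype(np.float64), 2.0
        )
        sensed_img = FundusImage(np.clip(blurred, 0, 255).round().astype(np.uint8))

    return SyntheticPair(
        ref_image=ref_img,
        sensed_image=sensed_img,
        true_mask_ref=mask_ref,
        true_mask_sensed=mask_sensed,
        true_junctions_ref=junc_ref,
        true_junctions_sensed=junc_sensed,
        true_H=true_h,
        quality=quality,
    )


def synthetic_patches(n: int, size: int = 64, seed: int = 0) -> list:
    """(image, mask) training patches cropped from rendered phantoms.

    Each patch is a contrast-equalized grayscale crop containing at least
    2% vessel pixels, paired with its binary ground-truth mask — the
    desk-scale stand-in for a patch-sampled segmentation training set.
    """
    from .preprocessing import apply_clahe

    rng = np.random.default_rng(seed)
    out = []
    tree_seed = seed
    while len(out) < n:
        big = max(128, 2 * size)
        mask, _ = generate_vascular_tree(
            VascularTreeParams(image_size=big, seed=tree_seed)
        )
        img = apply_clahe(render_fundus(mask, seed=tree_seed))
        gray = img.as_gray()
        for _ in range(max(4, n // 4)):
            if len(out) >= n:
                break
            r = int(rng.integers(0, big - size + 1))
            c = int(rng.integers(0, big - size + 1))
            m = mask.mask[r : r + size, c : c + size]
            if m.mean() < 0.02:
                continue
            out.append(
                (
                    gray[r : r + size, c : c + size].astype(np.float32),
                    m.copy(),
                )
            )
        tree_seed += 1000003  # new phantom, decorrelated from the crop rng
    return out
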