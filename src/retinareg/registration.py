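"""Feature-based registration from vascular landmarks.

Calibrated junction points become keypoints; each keypoint gets a dominant
gradient orientation and a 128-dimensional SIFT-style descriptor (4x4
spatial grid x 8 orientation bins, measured relative to the dominant
orientation, clipped at 0.2 and renormalized). Descriptors are matched by
Euclidean distance under Lowe's ratio test at 0.84, the surviving matches
feed a RANSAC projective fit, and the resulting 3x3 homography

    a' = (h11 a + h12 b + h13) / (h31 a + h32 b + 1)
    b' = (h21 a + h22 b + h23) / (h31 a + h32 b + 1)

maps sensed pixels (a, b) into the reference frame.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from skimage.measure import ransac as sk_ransac
from skimage.transform import ProjectiveTransform, warp as sk_warp

from .calibration import CalibrationParams, calibrate_junctions, detect_junctions_from_mask
from .preprocessing import apply_clahe
from .types import FundusImage, Homography, JunctionPoint, VesselMask

logger = logging.getLogger(__name__)

__all__ = [
    "Keypoint",
    "MatchPair",
    "RegistrationStatus",
    "RegistrationConfig",
    "RegistrationResult",
    "extract_keypoints",
    "compute_descriptors",
    "match_descriptors",
    "estimate_homography",
    "transform_point",
    "transform_points",
    "warp_image",
    "register_pair",
]


@dataclass(frozen=True)
class Keypoint:
    """A registration keypoint anchored at (or near) a junction."""

    x: float
    y: float
    scale: float = 3.0
    orientation: float = 0.0  # radians in [0, 2*pi)
    source_junction: int = -1


@dataclass(frozen=True)
class MatchPair:
    ref_index: int
    sensed_index: int
    d1: float  # nearest descriptor distance
    d2: float  # second-nearest descriptor distance

    @property
    def ratio(self) -> float:
        return self.d1 / self.d2 if self.d2 > 0 else 1.0


class RegistrationStatus(str, enum.Enum):
    OK = "ok"
    DEGENERATE = "degenerate"
    INSUFFICIENT_MATCHES = "insufficient_matches"


@dataclass
class RegistrationConfig:
    """End-to-end registration parameters (all unstated values exposed)."""

    keypoint_radius: int = 5
    max_aux_keypoints: int = 2
    ratio_threshold: float = 0.84
    ransac_threshold: float = 3.0
    ransac_max_trials: int = 2000
    ransac_confidence: float = 0.995
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    seed: int = 0


@dataclass
class RegistrationResult:
    homography: Homography | None
    matches: list
    inliers: np.ndarray | None
    warped: FundusImage | None
    status: RegistrationStatus
    stage_counts: dict = field(default_factory=dict)


# ----------------------------------------------------------------- keypoints


def _gradients(img: np.ndarray, sigma: float = 1.0):
    sm = ndimage.gaussian_filter(np.asarray(img, dtype=np.float64), sigma)
    gy, gx = np.gradient(sm)
    return gx, gy


def _dominant_orientations(gx, gy, x, y, scale):
    """Peak(s) of the Gaussian-weighted 36-bin orientation histogram."""
    h, w = gx.shape
    r = int(round(4 * scale))
    r0, r1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    c0, c1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    wgt = np.exp(-(((xx - x) ** 2 + (yy - y) ** 2) / (2 * (1.5 * scale) ** 2)))
    mag = np.hypot(gx[r0:r1, c0:c1], gy[r0:r1, c0:c1]) * wgt
    ang = np.arctan2(gy[r0:r1, c0:c1], gx[r0:r1, c0:c1]) % (2 * math.pi)
    hist = np.histogram(ang, bins=36, range=(0, 2 * math.pi), weights=mag)[0]
    hist = np.convolve(np.r_[hist[-2:], hist, hist[:2]], [1, 4, 6, 4, 1], "same")[2:-2]
    if hist.max() <= 0:
        return [0.0]
    # all local peaks within 80% of the strongest, as in standard SIFT:
    # junction patches often have near-tied arm orientations and keeping
    # both hypotheses makes matching robust to blur and modality changes
    out = []
    for i in np.argsort(hist)[::-1]:
        if hist[i] < 0.8 * hist.max() or len(out) >= 3:
            break
        if hist[i] >= hist[(i - 1) % 36] and hist[i] >= hist[(i + 1) % 36]:
            out.append((i + 0.5) * 2 * math.pi / 36)
    return out or [(int(np.argmax(hist)) + 0.5) * 2 * math.pi / 36]


def extract_keypoints(
    junctions: list,
    image: FundusImage | np.ndarray,
    radius: int = 5,
    max_aux: int = 2,
    scale: float = 3.0,
) -> list:
    """One keypoint per junction plus up to ``max_aux`` auxiliary keypoints
    at local gradient-magnitude maxima within ``radius`` pixels.

    Junctions too close to the border for a descriptor window are skipped.
    """
    gray = image.as_gray() if isinstance(image, FundusImage) else np.asarray(image)
    gx, gy = _gradients(gray)
    h, w = gray.shape
    border = int(math.ceil(10 * scale)) + radius
    mag = np.hypot(gx, gy)
    kps: list[Keypoint] = []
    for idx, j in enumerate(junctions):
        x0, y0 = float(j.col), float(j.row)
        if not (border <= y0 < h - border and border <= x0 < w - border):
            logger.warning("junction %d too close to border; skipped", idx)
            continue
        spots = [(x0, y0)]
        if radius > 0 and max_aux > 0:
            r0, c0 = int(y0) - radius, int(x0) - radius
            win = mag[r0 : r0 + 2 * radius + 1, c0 : c0 + 2 * radius + 1]
            loc_max = (win == ndimage.maximum_filter(win, 3)) & (win > 0)
            ys, xs = np.nonzero(loc_max)
            order = np.argsort(win[ys, xs])[::-1]
            for k in order[:max_aux]:
                ax, ay = c0 + xs[k], r0 + ys[k]
                if math.hypot(ax - x0, ay - y0) <= radius and (ax, ay) != (x0, y0):
                    spots.append((float(ax), float(ay)))
        for sx, sy in spots:
            for theta in _dominant_orientations(gx, gy, sx, sy, scale):
                kps.append(Keypoint(sx, sy, scale, theta, idx))
    return kps


# --------------------------------------------------------------- descriptors

_N_SPATIAL = 4  # 4x4 grid
_N_ORI = 8  # orientation bins
_WIDTH = 16  # descriptor window in samples


def compute_descriptors(
    image: FundusImage | np.ndarray, keypoints: list
) -> tuple:
    """128-D SIFT-style descriptors for the given keypoints.

    Gradients are sampled on a 16x16 grid rotated to the keypoint
    orientation, soft-binned into a 4x4 spatial grid of 8-bin orientation
    histograms, normalized, clipped at 0.2 and renormalized. Flat patches
    (zero gradient energy) are invalid; those keypoints are dropped.

    Returns ``(descriptors, kept_keypoints)``.
    """
    gray = image.as_gray() if isinstance(image, FundusImage) else np.asarray(image)
    gx, gy = _gradients(gray)

    # sample offsets in keypoint-aligned units, one sample per scale unit
    lin = (np.arange(_WIDTH) - (_WIDTH - 1) / 2.0) * 1.0
    uu, vv = np.meshgrid(lin, lin)  # u along x', v along y'
    gauss = np.exp(-((uu**2 + vv**2) / (2 * (_WIDTH / 2) ** 2)))

    descs, kept = [], []
    for kp in keypoints:
        ct, st = math.cos(kp.orientation), math.sin(kp.orientation)
        # rotate sampling grid into image coordinates
        xs = kp.x + kp.scale * (ct * uu - st * vv)
        ys = kp.y + kp.scale * (st * uu + ct * vv)
        sgx = ndimage.map_coordinates(gx, [ys, xs], order=1, mode="nearest")
        sgy = ndimage.map_coordinates(gy, [ys, xs], order=1, mode="nearest")
        mag = np.hypot(sgx, sgy) * gauss
        if mag.sum() <= 1e-12:
            continue
        ang = (np.arctan2(sgy, sgx) - kp.orientation) % (2 * math.pi)

        # soft trilinear binning
        cell_u = (uu + _WIDTH / 2) / (_WIDTH / _N_SPATIAL) - 0.5
        cell_v = (vv + _WIDTH / 2) / (_WIDTH / _N_SPATIAL) - 0.5
        obin = ang / (2 * math.pi / _N_ORI)
        hist = np.zeros((_N_SPATIAL, _N_SPATIAL, _N_ORI))
        u0 = np.floor(cell_u).astype(int)
        v0 = np.floor(cell_v).astype(int)
        o0 = np.floor(obin).astype(int)
        fu, fv, fo = cell_u - u0, cell_v - v0, obin - o0
        for du, wu in ((0, 1 - fu), (1, fu)):
            for dv, wv in ((0, 1 - fv), (1, fv)):
                for do, wo in ((0, 1 - fo), (1, fo)):
                    ui, vi, oi = u0 + du, v0 + dv, (o0 + do) % _N_ORI
                    ok = (ui >= 0) & (ui < _N_SPATIAL) & (vi >= 0) & (vi < _N_SPATIAL)
                    np.add.at(
                        hist,
                        (vi[ok], ui[ok], oi[ok]),
                        (mag * wu * wv * wo)[ok],
                    )
        vec = hist.ravel()
        norm = np.linalg.norm(vec)
        if norm <= 1e-12:
            continue
        vec = np.minimum(vec / norm, 0.2)
        vec = vec / np.linalg.norm(vec)
        descs.append(vec)
        kept.append(kp)
    if not descs:
        return np.zeros((0, _N_SPATIAL * _N_SPATIAL * _N_ORI)), []
    return np.asarray(descs), kept


# ------------------------------------------------------------------ matching


def match_descriptors(
    ref_desc: np.ndarray,
    sensed_desc: np.ndarray,
    ratio_threshold: float = 0.84,
) -> list:
    """Lowe ratio-test matching by Euclidean distance.

    Each reference descriptor is paired with its nearest sensed descriptor
    and kept iff nearest/second-nearest <= ``ratio_threshold``; a sensed
    keypoint claimed twice keeps only its lowest-distance match.
    """
    ref_desc = np.atleast_2d(ref_desc)
    sensed_desc = np.atleast_2d(sensed_desc)
    if len(sensed_desc) < 2:
        raise ValueError("ratio-test matching needs at least 2 sensed descriptors")
    if len(ref_desc) == 0:
        return []
    d = cdist(ref_desc, sensed_desc)
    nn = np.argsort(d, axis=1)[:, :2]
    raw = []
    for i in range(len(ref_desc)):
        j1, j2 = int(nn[i, 0]), int(nn[i, 1])
        d1, d2 = float(d[i, j1]), float(d[i, j2])
        if d2 > 0 and d1 / d2 <= ratio_threshold:
            raw.append(MatchPair(i, j1, d1, d2))
    # one-to-one: lowest distance claim wins per sensed index
    raw.sort(key=lambda m: m.d1)
    taken: set[int] = set()
    out = []
    for m in raw:
        if m.sensed_index not in taken:
            taken.add(m.sensed_index)
            out.append(m)
    out.sort(key=lambda m: (m.ref_index, m.sensed_index))
    return out


# ---------------------------------------------------------------- homography


def transform_point(h: Homography, point) -> tuple:
    """Map one sensed-frame point (a, b) into the reference frame."""
    a, b = float(point[0]), float(point[1])
    m = h.matrix
    den = m[2, 0] * a + m[2, 1] * b + m[2, 2]
    if abs(den) < 1e-12:
        raise ZeroDivisionError("point maps to projective infinity")
    return (
        (m[0, 0] * a + m[0, 1] * b + m[0, 2]) / den,
        (m[1, 0] * a + m[1, 1] * b + m[1, 2]) / den,
    )


def transform_points(h: Homography, points_xy: np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points_xy, dtype=np.float64))
    hom = np.c_[pts, np.ones(len(pts))] @ h.matrix.T
    den = hom[:, 2:3]
    if np.any(np.abs(den) < 1e-12):
        raise ZeroDivisionError("a point maps to projective infinity")
    return hom[:, :2] / den


def estimate_homography(
    ref_xy: np.ndarray,
    sensed_xy: np.ndarray,
    threshold: float = 3.0,
    max_trials: int = 2000,
    confidence: float = 0.995,
    seed: int = 0,
):
    """RANSAC projective fit mapping sensed points onto reference points.

    Minimal 4-point hypotheses inside a RANSAC loop, final model
    re-estimated on the inlier set by the normalized direct linear
    transform; returns ``(Homography | None, inlier_mask, status)``.
    """
    ref_xy = np.atleast_2d(np.asarray(ref_xy, dtype=np.float64))
    sensed_xy = np.atleast_2d(np.asarray(sensed_xy, dtype=np.float64))
    n = len(ref_xy)
    if n < 4:
        return None, np.zeros(n, dtype=bool), RegistrationStatus.INSUFFICIENT_MATCHES
    try:
        if n == 4:
            if hasattr(ProjectiveTransform, "from_estimate"):
                tf = ProjectiveTransform.from_estimate(sensed_xy, ref_xy)
                model = tf if tf else None
            else:
                tf = ProjectiveTransform()
                model = tf if tf.estimate(sensed_xy, ref_xy) else None
            inliers = np.ones(n, dtype=bool)
        else:
            model, inliers = sk_ransac(
                (sensed_xy, ref_xy),
                ProjectiveTransform,
                min_samples=4,
                residual_threshold=threshold,
                max_trials=max_trials,
                stop_probability=confidence,
                rng=seed,
            )
    except Exception:
        model, inliers = None, None
    if (
        model is None
        or inliers is None
        or int(np.sum(inliers)) < 4
        or not np.all(np.isfinite(model.params))
        or abs(np.linalg.det(model.params)) < 1e-12
        or abs(model.params[2, 2]) < 1e-12
    ):
        return None, np.zeros(n, dtype=bool), RegistrationStatus.DEGENERATE
    return (
        Homography(model.params),
        np.asarray(inliers, dtype=bool),
        RegistrationStatus.OK,
    )


def warp_image(
    h: Homography, sensed: FundusImage, canvas_shape: tuple | None = None
) -> FundusImage:
    """Resample the sensed image onto the reference canvas through the
    inverse map with bilinear interpolation; out-of-frame pixels are 0."""
    shape = canvas_shape or sensed.pixels.shape[:2]
    inv = ProjectiveTransform(matrix=np.linalg.inv(h.matrix))
    src = np.asarray(sensed.pixels, dtype=np.float64)
    out = sk_warp(src, inv, output_shape=shape, order=1, cval=0.0, preserve_range=True)
    if sensed.pixels.dtype == np.uint8:
        out = np.clip(out, 0, 255).round().astype(np.uint8)
    return FundusImage(out, image_id=sensed.image_id)


# ------------------------------------------------------------------ pipeline


def _vesselness_image(mask: VesselMask) -> np.ndarray:
    """Smooth rendering of the vessel *centerlines* used as the
    descriptor substrate.

    Working on the skeleton of the segmented vessel map rather than raw
    intensities makes descriptors insensitive to illumination changes, to
    the intensity inversion of angiography frames, and to the vessel-width
    changes a defocused acquisition produces.
    """
    from .calibration import skeletonize_region

    sk = skeletonize_region(mask).mask.astype(np.float64)
    return ndimage.gaussian_filter(sk, 1.5)


def register_pair(
    ref: FundusImage,
    sensed: FundusImage,
    config: RegistrationConfig | None = None,
    ref_mask: VesselMask | None = None,
    sensed_mask: VesselMask | None = None,
    segmenter=None,
) -> RegistrationResult:
    """Full registration: segment -> detect -> calibrate -> describe ->
    match -> RANSAC homography -> warp.

    Vessel masks may be supplied (ground truth or precomputed); otherwise
    ``segmenter`` (a callable image -> VesselMask, e.g. a trained network
    or the classical fallback) is used.
    """
    config = config or RegistrationConfig()
    counts: dict = {}

    if segmenter is None and (ref_mask is None or sensed_mask is None):
        from .vessel_segmentation import segment_vessels  # local: avoids cycle

        segmenter = lambda img: segment_vessels(None, img)[1]
    # the segmenter owns its preprocessing (the ridge fallback infers
    # vessel polarity from the raw background, which CLAHE would destroy)
    if ref_mask is None:
        ref_mask = segmenter(ref)
    if sensed_mask is None:
        sensed_mask = segmenter(sensed)

    stages = {}
    for name, mask in (("ref", ref_mask), ("sensed", sensed_mask)):
        detected = detect_junctions_from_mask(mask)
        calibrated = calibrate_junctions(detected, mask, config.calibration)
        img = _vesselness_image(mask)
        kps = extract_keypoints(
            calibrated, img, radius=config.keypoint_radius,
            max_aux=config.max_aux_keypoints,
        )
        desc, kps = compute_descriptors(img, kps)
        stages[name] = (desc, kps)
        counts[f"{name}_detected"] = len(detected)
        counts[f"{name}_calibrated"] = len(calibrated)
        counts[f"{name}_keypoints"] = len(kps)

    ref_desc, ref_kps = stages["ref"]
    sen_desc, sen_kps = stages["sensed"]
    if len(ref_desc) == 0 or len(sen_desc) < 2:
        return RegistrationResult(
            None, [], None, None, RegistrationStatus.INSUFFICIENT_MATCHES, counts
        )
    matches = match_descriptors(ref_desc, sen_desc, config.ratio_threshold)
    counts["matches"] = len(matches)
    if len(matches) < 4:
        return RegistrationResult(
            None, matches, None, None, RegistrationStatus.INSUFFICIENT_MATCHES, counts
        )

    ref_xy = np.array([(ref_kps[m.ref_index].x, ref_kps[m.ref_index].y) for m in matches])
    sen_xy = np.array(
        [(sen_kps[m.sensed_index].x, sen_kps[m.sensed_index].y) for m in matches]
    )
    h, inliers, status = estimate_homography(
        ref_xy,
        sen_xy,
        threshold=config.ransac_threshold,
        max_trials=config.ransac_max_trials,
        confidence=config.ransac_confidence,
        seed=config.seed,
    )
    counts["inliers"] = int(inliers.sum()) if inliers is not None else 0
    if status is not RegistrationStatus.OK:
        return RegistrationResult(None, matches, inliers, None, status, counts)
    warped = warp_image(h, sensed, canvas_shape=ref.pixels.shape[:2])
    return RegistrationResult(h, matches, inliers, warped, status, counts)
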