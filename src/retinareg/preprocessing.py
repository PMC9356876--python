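"""Intensity normalization and training-time augmentation.

Images are contrast-equalized with CLAHE on an 8x8 tile grid before any
network sees them; training augmentation is horizontal/vertical flips and
rotation by an arbitrary angle in [0, 360).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure
from skimage import transform as sktransform

from .types import FundusImage, VesselMask

__all__ = ["ClaheParams", "apply_clahe", "augment"]


@dataclass
class ClaheParams:
    """CLAHE configuration: the image is divided into ``tile_rows`` x
    ``tile_cols`` contextual regions and each tile's histogram is clipped
    at ``clip_limit`` (in units of the uniform bin height) before
    equalization."""

    tile_rows: int = 8
    tile_cols: int = 8
    clip_limit: float = 2.0

    def __post_init__(self) -> None:
        if self.tile_rows < 1 or self.tile_cols < 1:
            raise ValueError("tile grid must be at least 1x1")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")


def apply_clahe(image: FundusImage, params: ClaheParams | None = None) -> FundusImage:
    """Contrast-limited adaptive histogram equalization.

    Color inputs are equalized on the green channel and returned as
    grayscale, which is what the downstream networks consume. Output is
    8-bit in [0, 255]; constant images pass through unchanged.
    """
    params = params or ClaheParams()
    gray = image.as_gray()
    rows, cols = gray.shape
    if rows < params.tile_rows or cols < params.tile_cols:
        raise ValueError("image smaller than one CLAHE tile")
    if np.ptp(gray) == 0:  # no contrast to redistribute
        out = (gray * 255.0).round().astype(np.uint8)
        return FundusImage(out, image_id=image.image_id)
    kernel = (
        max(1, rows // params.tile_rows),
        max(1, cols // params.tile_cols),
    )
    # equalize_adapthist expresses the clip limit as a fraction of tile
    # pixel count; convert from the bin-height multiple convention
    clip = min(1.0, params.clip_limit / 256.0)
    eq = exposure.equalize_adapthist(gray, kernel_size=kernel, clip_limit=clip)
    out = np.clip(eq * 255.0, 0, 255).round().astype(np.uint8)
    return FundusImage(out, image_id=image.image_id)


def augment(
    image: FundusImage,
    mask: VesselMask | None = None,
    flip: str = "none",
    rotation_deg: float = 0.0,
):
    """Apply the same flip/rotation to an image and (optionally) its mask.

    ``flip`` is one of none/h/v/hv; rotation is counter-clockwise about the
    image center on a same-size canvas, bilinear for the image and
    nearest-neighbor for the mask so the mask stays binary.
    """
    if not (0.0 <= rotation_deg < 360.0):
        raise ValueError("rotation must lie in [0, 360)")
    if flip not in ("none", "h", "v", "hv"):
        raise ValueError("flip must be one of none/h/v/hv")

    img = np.asarray(image.pixels)
    msk = None if mask is None else mask.mask

    if flip in ("h", "hv"):
        img = img[:, ::-1].copy()
        msk = None if msk is None else msk[:, ::-1].copy()
    if flip in ("v", "hv"):
        img = img[::-1, :].copy()
        msk = None if msk is None else msk[::-1, :].copy()

    if rotation_deg != 0.0:
        if rotation_deg % 90.0 == 0.0:
            k = int(rotation_deg // 90) % 4
            img = np.rot90(img, k).copy()
            msk = None if msk is None else np.rot90(msk, k).copy()
        else:
            img = sktransform.rotate(
                img, rotation_deg, order=1, preserve_range=True
            ).astype(img.dtype)
            if msk is not None:
                msk = (
                    sktransform.rotate(
                        msk.astype(np.float64), rotation_deg, order=0,
                        preserve_range=True,
                    )
                    > 0.5
                ).astype(np.uint8)

    out_img = FundusImage(img, image_id=image.image_id)
    out_mask = None if msk is None else VesselMask(msk)
    return out_img, out_mask
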