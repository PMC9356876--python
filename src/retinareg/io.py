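"""Readers and writers for images, landmark point lists, and
correspondence files.

Point files are CSV with header ``row,col,kind[,score]`` (canonical) or a
JSON array of objects with the same keys. Correspondence files are plain
text with four numbers per row, ``x_ref y_ref x_sensed y_sensed``,
comma- or whitespace-delimited.
"""

from __future__ import annotations

import csv
import json
import logging
import os
from typing import Iterable

import numpy as np
from PIL import Image

from .types import (
    CorrespondenceSet,
    FundusImage,
    JunctionKind,
    JunctionPoint,
    Provenance,
    VesselMask,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_points",
    "write_points",
    "read_correspondences",
    "write_correspondences",
    "FormatError",
]


class FormatError(ValueError):
    """Raised for unreadable or malformed input files."""


def read_image(path: str | os.PathLike) -> FundusImage:
    """Read a PNG/JPEG/TIFF raster; 16-bit inputs are rescaled to 8-bit."""
    if not os.path.exists(path):
        raise FormatError(f"no such image file: {path}")
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # PIL raises a zoo of types for bad files
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        logger.warning("16-bit image %s rescaled to 8-bit", path)
        arr = (arr.astype(np.float64) / 65535.0 * 255.0).round().astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    return FundusImage(arr, image_id=os.path.splitext(os.path.basename(path))[0])


def write_image(image: FundusImage | np.ndarray, path: str | os.PathLike) -> None:
    arr = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.asarray(arr, dtype=np.float64), 0, 255)
        if arr.max() <= 1.0:
            arr = arr * 255.0
        arr = arr.round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def read_mask(path: str | os.PathLike) -> VesselMask:
    """Read a binary mask stored as an 8-bit image with {0, 255}."""
    img = read_image(path)
    gray = img.pixels if img.pixels.ndim == 2 else img.pixels[:, :, 0]
    return VesselMask((np.asarray(gray) > 127).astype(np.uint8))


def write_mask(mask: VesselMask, path: str | os.PathLike) -> None:
    Image.fromarray((mask.mask * 255).astype(np.uint8)).save(path)


_KIND_NAMES = {k.value: k for k in JunctionKind}
_PROV_NAMES = {p.value: p for p in Provenance}


def _parse_point(rec: dict, lineno: int) -> JunctionPoint:
    try:
        row = float(rec["row"])
        col = float(rec["col"])
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"line {lineno}: non-numeric or missing coordinates") from exc
    if row < 0 or col < 0 or row != int(row) or col != int(col):
        raise FormatError(f"line {lineno}: coordinates must be non-negative integers")
    kind_s = str(rec.get("kind", "unknown")).strip().lower()
    if kind_s not in _KIND_NAMES:
        logger.warning("line %d: unknown junction kind %r mapped to 'unknown'", lineno, kind_s)
        kind_s = "unknown"
    score = float(rec.get("score", 1.0) or 1.0)
    prov_s = str(rec.get("provenance", "detected")).strip().lower()
    prov = _PROV_NAMES.get(prov_s, Provenance.DETECTED)
    return JunctionPoint(int(row), int(col), _KIND_NAMES[kind_s], score, prov)


def read_points(path: str | os.PathLike) -> list[JunctionPoint]:
    """Read a landmark point list from CSV or JSON (0-based coordinates)."""
    if not os.path.exists(path):
        raise FormatError(f"no such point file: {path}")
    with open(path, "r") as fh:
        text = fh.read()
    if text.lstrip().startswith("["):
        try:
            records = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"bad JSON point file {path}: {exc}") from exc
        return [_parse_point(rec, i + 1) for i, rec in enumerate(records)]
    reader = csv.DictReader(text.splitlines())
    if reader.fieldnames is None or "row" not in reader.fieldnames:
        raise FormatError(f"point CSV {path} must have a 'row,col,kind[,score]' header")
    return [_parse_point(rec, i + 2) for i, rec in enumerate(reader)]


def write_points(points: Iterable[JunctionPoint], path: str | os.PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "col", "kind", "score", "provenance"])
        for p in points:
            writer.writerow([p.row, p.col, p.kind.value, repr(float(p.score)), p.provenance.value])


def read_correspondences(path: str | os.PathLike) -> CorrespondenceSet:
    """Read 4-column ground-truth control points (x_ref y_ref x_sen y_sen)."""
    if not os.path.exists(path):
        raise FormatError(f"no such correspondence file: {path}")
    ref, sen = [], []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", " ").split()
            if len(fields) != 4:
                raise FormatError(
                    f"{path}, line {lineno}: expected 4 fields, got {len(fields)}"
                )
            try:
                xr, yr, xs, ys = (float(f) for f in fields)
            except ValueError as exc:
                raise FormatError(f"{path}, line {lineno}: non-numeric field") from exc
            ref.append((xr, yr))
            sen.append((xs, ys))
    if not ref:
        raise FormatError(f"{path}: no correspondence rows")
    return CorrespondenceSet(np.array(ref), np.array(sen))


def write_correspondences(cs: CorrespondenceSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for (xr, yr), (xs, ys) in zip(cs.ref_points, cs.sensed_points):
            fh.write(f"{xr:.6f} {yr:.6f} {xs:.6f} {ys:.6f}\n")
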