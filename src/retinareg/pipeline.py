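"""Pipeline orchestration: YAML configuration and the end-to-end run.

Exit codes of :func:`run_pipeline` (also used by the CLI):

====  =============================================
0     registration ok
2     insufficient matches
3     degenerate geometry (RANSAC found no model)
4     input/output error
====  =============================================
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time

import numpy as np
import yaml

from . import io as rio
from .calibration import CalibrationParams
from .evaluation import registration_error
from .preprocessing import ClaheParams
from .registration import (
    RegistrationConfig,
    RegistrationStatus,
    register_pair,
)
from .types import Homography

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "EXIT_CODES"]

EXIT_CODES = {
    RegistrationStatus.OK: 0,
    RegistrationStatus.INSUFFICIENT_MATCHES: 2,
    RegistrationStatus.DEGENERATE: 3,
}


@dataclasses.dataclass
class PipelineConfig:
    """Nested stage parameters plus a global seed."""

    clahe: ClaheParams = dataclasses.field(default_factory=ClaheParams)
    calibration: CalibrationParams = dataclasses.field(default_factory=CalibrationParams)
    registration: RegistrationConfig = dataclasses.field(default_factory=RegistrationConfig)
    segmentation_threshold: float = 0.5
    seed: int = 0
    verbosity: int = 1


_SECTIONS = {
    "clahe": ClaheParams,
    "calibration": CalibrationParams,
    "registration": RegistrationConfig,
}


def load_config(path_or_dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or mapping;
    unknown keys are rejected so typos cannot silently change a run."""
    if isinstance(path_or_dict, (str, os.PathLike)):
        with open(path_or_dict) as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict or {})
    cfg = PipelineConfig()
    for key, val in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            fields = {f.name for f in dataclasses.fields(cls)}
            unknown = set(val) - fields
            if unknown:
                raise ValueError(f"unknown keys in section {key!r}: {sorted(unknown)}")
            base = getattr(cfg, key)
            setattr(cfg, key, dataclasses.replace(base, **val))
        elif key in ("segmentation_threshold", "seed", "verbosity"):
            setattr(cfg, key, val)
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg.registration = dataclasses.replace(
        cfg.registration, calibration=cfg.calibration, seed=cfg.seed
    )
    return cfg


def run_pipeline(
    config: PipelineConfig,
    ref_path,
    sensed_path,
    out_dir,
    ref_mask_path=None,
    sensed_mask_path=None,
    correspondences_path=None,
    segmenter=None,
) -> int:
    """Register two images from disk and write all artifacts.

    Produces ``H.txt`` (3x3 row-major), ``warped.png``, ``log.json`` with
    per-stage counts, and ``metrics.json`` when ground-truth
    correspondences are supplied. Returns a coded exit status.
    """
    t0 = time.time()
    try:
        ref = rio.read_image(ref_path)
        sensed = rio.read_image(sensed_path)
        ref_mask = rio.read_mask(ref_mask_path) if ref_mask_path else None
        sensed_mask = rio.read_mask(sensed_mask_path) if sensed_mask_path else None
        gt = (
            rio.read_correspondences(correspondences_path)
            if correspondences_path
            else None
        )
    except rio.FormatError as exc:
        logger.error("input error: %s", exc)
        return 4

    result = register_pair(
        ref,
        sensed,
        config.registration,
        ref_mask=ref_mask,
        sensed_mask=sensed_mask,
        segmenter=segmenter,
    )

    os.makedirs(out_dir, exist_ok=True)
    log = {
        "status": result.status.value,
        "stage_counts": result.stage_counts,
        "elapsed_s": round(time.time() - t0, 3),
        "seed": config.seed,
    }
    if result.status is RegistrationStatus.OK:
        np.savetxt(os.path.join(out_dir, "H.txt"), result.homography.matrix, fmt="%.10g")
        rio.write_image(result.warped, os.path.join(out_dir, "warped.png"))
        _write_matches(result, os.path.join(out_dir, "matches.csv"))
        if gt is not None:
            err = registration_error(result.homography, gt)
            metrics = {"control_point_error_px": err, "n_control_points": len(gt)}
            with open(os.path.join(out_dir, "metrics.json"), "w") as fh:
                json.dump(metrics, fh, indent=2)
            log["control_point_error_px"] = err
    with open(os.path.join(out_dir, "log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    return EXIT_CODES[result.status]


def _write_matches(result, path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_index,sensed_index,d1,d2,inlier\n")
        inl = result.inliers if result.inliers is not None else [False] * len(result.matches)
        for m, flag in zip(result.matches, inl):
            fh.write(f"{m.ref_index},{m.sensed_index},{m.d1:.6f},{m.d2:.6f},{int(bool(flag))}\n")
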