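"""Reproducible desk-scale experiments on synthetic phantoms.

Each function regenerates its inputs from a seed, runs the pipeline, and
returns summary statistics; the test suite and the results-reproduction
script both call these, so the numbers they report are always recomputed
from scratch.
"""

from __future__ import annotations

import numpy as np

from .evaluation import (
    confusion_metrics,
    match_detections,
    registration_error,
    success_rate_curve,
)
from .registration import (
    RegistrationConfig,
    RegistrationStatus,
    estimate_homography,
    register_pair,
    transform_points,
)
from .synthetic import (
    PairQuality,
    TransformSpec,
    VascularTreeParams,
    generate_pair,
    generate_vascular_tree,
)
from .types import CorrespondenceSet, Homography

__all__ = [
    "sample_transform",
    "pair_control_point_error",
    "homography_recovery_suite",
    "junction_detection_suite",
    "ransac_robustness_suite",
    "vsn_desk_experiment",
    "jdn_desk_experiment",
    "robustness_suite",
]


def sample_transform(
    rng, max_rotation=20.0, max_translation=30.0, max_perspective=1e-4
) -> TransformSpec:
    """A random viewpoint change within realistic fundus-pair ranges."""
    return TransformSpec(
        rotation_deg=float(rng.uniform(-max_rotation, max_rotation)),
        translation=(
            float(rng.uniform(-max_translation, max_translation)),
            float(rng.uniform(-max_translation, max_translation)),
        ),
        scale=float(rng.uniform(0.9, 1.1)),
        perspective=(
            float(rng.uniform(-max_perspective, max_perspective)),
            float(rng.uniform(-max_perspective, max_perspective)),
        ),
    )


def pair_control_point_error(pair, homography: Homography) -> float:
    """Mean control-point error of a recovered homography, using the
    pair's true junctions as control points and the true homography as
    ground truth."""
    pts = np.array([[j.col, j.row] for j in pair.true_junctions_sensed], float)
    cs = CorrespondenceSet(transform_points(pair.true_H, pts), pts)
    return registration_error(homography, cs)


def _register_one(pair, seed: int, use_true_masks: bool) -> float:
    config = RegistrationConfig(seed=seed)
    if use_true_masks:
        result = register_pair(
            pair.ref_image,
            pair.sensed_image,
            config,
            ref_mask=pair.true_mask_ref,
            sensed_mask=pair.true_mask_sensed,
        )
    else:
        result = register_pair(pair.ref_image, pair.sensed_image, config)
    if result.status is not RegistrationStatus.OK:
        return float("inf")
    return pair_control_point_error(pair, result.homography)


def homography_recovery_suite(
    n_pairs: int = 50, seed: int = 0, use_true_masks: bool = True
) -> dict:
    """Register ``n_pairs`` seeded phantom pairs (rotation <= 20 deg,
    translation <= 30 px, |perspective| <= 1e-4) with detection from the
    ground-truth vessel masks, and score homography recovery."""
    errors = []
    for i in range(n_pairs):
        pair_seed = seed * 1000 + i
        rng = np.random.default_rng(pair_seed)
        pair = generate_pair(
            VascularTreeParams(seed=pair_seed),
            sample_transform(rng),
            seed=pair_seed,
        )
        errors.append(_register_one(pair, pair_seed, use_true_masks))
    errors = np.array(errors)
    curve = success_rate_curve(errors)
    return {
        "errors": errors,
        "success_rate_2px": float(np.mean(errors <= 2.0)),
        "mean_error_px": float(np.mean(errors[np.isfinite(errors)])),
        "success_rate_auc": curve.auc,
    }


def junction_detection_suite(n_trees: int = 20, seed: int = 0) -> dict:
    """Skeleton-based detection + calibration on phantom trees, scored
    against the generator's ground truth at 5-px tolerance."""
    from .calibration import calibrate_junctions, detect_junctions_from_mask

    tp = fp = fn = 0
    for i in range(n_trees):
        mask, truth = generate_vascular_tree(
            VascularTreeParams(seed=seed * 1000 + i)
        )
        detected = detect_junctions_from_mask(mask)
        calibrated = calibrate_junctions(detected, mask)
        counts = match_detections(calibrated, truth, tolerance=5.0)
        tp += counts.tp
        fp += counts.fp
        fn += counts.fn
    from .types import ConfusionCounts

    metrics = confusion_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=None))
    return {"f1": metrics["f1"], "precision": metrics["precision"],
            "recall": metrics["sensitivity"]}


def ransac_robustness_suite(n_seeds: int = 20, seed: int = 0) -> dict:
    """60 synthetic correspondences with 40% gross outliers per trial;
    reports the mean reprojection error on the true inliers."""
    errs = []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + i)
        h_true = Homography(
            np.array(
                [
                    [1.0 + rng.uniform(-0.05, 0.05), rng.uniform(-0.05, 0.05), rng.uniform(-15, 15)],
                    [rng.uniform(-0.05, 0.05), 1.0 + rng.uniform(-0.05, 0.05), rng.uniform(-15, 15)],
                    [rng.uniform(-1e-5, 1e-5), rng.uniform(-1e-5, 1e-5), 1.0],
                ]
            )
        )
        sensed = rng.uniform(20, 230, (60, 2))
        ref = transform_points(h_true, sensed)
        n_out = 24  # 40%
        ref[:n_out] += rng.uniform(30, 80, (n_out, 2)) * rng.choice([-1, 1], (n_out, 2))
        h, _, status = estimate_homography(ref, sensed, seed=seed * 1000 + i)
        if status is not RegistrationStatus.OK:
            errs.append(float("inf"))
            continue
        inl = np.arange(60) >= n_out
        d = np.hypot(*(transform_points(h, sensed[inl]) - ref[inl]).T)
        errs.append(float(d.mean()))
    return {"errors": errs, "max_mean_error_px": float(np.max(errs)),
            "mean_error_px": float(np.mean(errs))}


def vsn_desk_experiment(seed: int = 0, n_patches: int = 200, epochs: int = 20) -> dict:
    """Train the reduced segmentation network (3 levels, 8 base channels)
    on synthetic 64-px patches and report held-out Dice (80/20 split)."""
    from .synthetic import synthetic_patches
    from .vessel_segmentation import VSNConfig, build_vsn, train_vsn

    data = synthetic_patches(n_patches, 64, seed=seed)
    n_train = int(0.8 * len(data))
    train, held = data[:n_train], data[n_train:]
    cfg = VSNConfig(
        levels=3, base_channels=8, epochs=epochs, learning_rate=1e-3,
        batch_size=8, seed=seed,
    )
    model, history = train_vsn(build_vsn(cfg), train, cfg)
    model.eval()
    dices = []
    for img, mask in held:
        pred = (model.predict_proba(img) >= 0.5).astype(int)
        inter = int((pred * mask).sum())
        dices.append(2 * inter / max(int(pred.sum()) + int(mask.sum()), 1))
    return {"dice": float(np.mean(dices)), "loss_history": history}


def jdn_desk_experiment(seed: int = 0, n_images: int = 10, steps: int = 300) -> dict:
    """Overfit a toy detection network on phantom vessel masks and report
    training-set recall at 5-px tolerance after calibration-free
    decoding."""
    from .junction_detection import JDN, JDNConfig, detect_junctions, train_jdn

    data = [
        generate_vascular_tree(VascularTreeParams(seed=seed * 1000 + i))
        for i in range(n_images)
    ]
    cfg = JDNConfig(steps=steps, seed=seed)
    model, history = train_jdn(JDN(cfg), data, cfg)
    tp = fn = 0
    for mask, truth in data:
        points = detect_junctions(model, mask)
        counts = match_detections(points, truth, tolerance=5.0)
        tp += counts.tp
        fn += counts.fn
    return {"recall": tp / max(tp + fn, 1), "loss_history": history}


def robustness_suite(
    quality: PairQuality | str, n_pairs: int = 20, seed: int = 0
) -> dict:
    """Register degraded pairs (defocus blur or angiography inversion)
    using the classical fallback segmenter on the rendered images, and
    report the fraction with mean control-point error <= 5 px."""
    from .preprocessing import apply_clahe
    from .vessel_segmentation import fallback_segment

    quality = PairQuality(quality)
    errors = []
    for i in range(n_pairs):
        pair_seed = seed * 1000 + i
        rng = np.random.default_rng(pair_seed)
        pair = generate_pair(
            VascularTreeParams(seed=pair_seed),
            sample_transform(rng),
            quality,
            seed=pair_seed,
        )
        segmenter = lambda img: fallback_segment(img)[1]
        config = RegistrationConfig(seed=pair_seed)
        result = register_pair(
            pair.ref_image, pair.sensed_image, config, segmenter=segmenter
        )
        if result.status is not RegistrationStatus.OK:
            errors.append(float("inf"))
        else:
            errors.append(pair_control_point_error(pair, result.homography))
    errors = np.array(errors)
    return {
        "errors": errors,
        "fraction_within_5px": float(np.mean(errors <= 5.0)),
    }
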