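"""Junction detection network (JDN): anchor-based detection of vascular
bifurcations and crossovers.

A residual backbone produces feature maps C1-C5, halving the spatial size
per level; C3-C5 feed a feature pyramid whose top-down path upsamples by
2 with a 3x3 transposed convolution and merges laterally by element-wise
addition, followed by a 3x3 anti-aliasing convolution to give P3-P5, with
P6 and P7 from stride-2 3x3 convolutions. Each pyramid cell carries 6
anchors (2 scales x 3 aspect ratios, area-preserving parameterization

    H = BA * S / sqrt(AR),   W = BA * S * sqrt(AR)

for base-anchor length BA). A classification subnet is trained with the
focal loss and a box-regression subnet with the smooth-L1 loss; decoding
keeps at most 200 boxes after score thresholding and non-maximum
suppression, and each surviving box contributes its center as a candidate
junction point.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .nn.optim import cosine_lr
from .types import FundusImage, JunctionPoint, Provenance, VesselMask

__all__ = [
    "AnchorSpec",
    "DetectionBox",
    "JDNConfig",
    "ResidualBlock",
    "FeaturePyramid",
    "JDN",
    "make_anchors",
    "focal_loss",
    "smooth_l1",
    "decode_detections",
    "boxes_to_points",
    "train_jdn",
    "detect_junctions",
    "save_jdn",
    "load_jdn",
]

PYRAMID_LEVELS = (3, 4, 5, 6, 7)
ANCHOR_SCALES = (2**0, 2**0.5)
ANCHOR_RATIOS = (1.0, 2.0, 0.5)
ANCHORS_PER_CELL = len(ANCHOR_SCALES) * len(ANCHOR_RATIOS)
MAX_BOXES = 200


@dataclass
class AnchorSpec:
    """Base anchor lengths per pyramid level, in pixels at the image's own
    scale (defaults are the reference 512-px values scaled down)."""

    base_sizes: dict = field(
        default_factory=lambda: {3: 16.0, 4: 32.0, 5: 64.0, 6: 128.0, 7: 256.0}
    )
    scales: tuple = ANCHOR_SCALES
    ratios: tuple = ANCHOR_RATIOS
    max_boxes: int = MAX_BOXES

    def scaled(self, image_size: int, reference: int = 512) -> "AnchorSpec":
        f = image_size / reference
        return AnchorSpec(
            {k: v * f for k, v in self.base_sizes.items()},
            self.scales,
            self.ratios,
            self.max_boxes,
        )


@dataclass(frozen=True)
class DetectionBox:
    """An axis-aligned detection: center (x, y), size, score, level."""

    cx: float
    cy: float
    height: float
    width: float
    score: float = 0.0
    level: int = 0


def make_anchors(spec: AnchorSpec, level: int, feature_size: tuple) -> np.ndarray:
    """Anchor templates for one pyramid level.

    Returns an (H*W*6, 4) array of (cx, cy, h, w): 6 anchors per cell (2
    scales x 3 ratios), centered on feature cells mapped to image
    coordinates by the level stride.
    """
    if level not in PYRAMID_LEVELS:
        raise ValueError(f"level must be one of {PYRAMID_LEVELS}")
    ba = spec.base_sizes[level]
    if ba <= 0:
        raise ValueError("base anchor length must be positive")
    stride = 2**level
    fh, fw = feature_size
    shapes = np.array(
        [
            (ba * s / math.sqrt(r), ba * s * math.sqrt(r))
            for s in spec.scales
            for r in spec.ratios
        ]
    )  # (6, 2) -> (h, w)
    cy = (np.arange(fh) + 0.5) * stride
    cx = (np.arange(fw) + 0.5) * stride
    cyy, cxx = np.meshgrid(cy, cx, indexing="ij")
    centers = np.stack([cxx.ravel(), cyy.ravel()], axis=1)  # (H*W, 2)
    out = np.zeros((fh * fw, ANCHORS_PER_CELL, 4))
    out[:, :, 0] = centers[:, None, 0]
    out[:, :, 1] = centers[:, None, 1]
    out[:, :, 2] = shapes[None, :, 0]
    out[:, :, 3] = shapes[None, :, 1]
    return out.reshape(-1, 4)


# ------------------------------------------------------------------ network


class ResidualBlock(nn.Module):
    """Bottleneck residual layer: R(x) = conv1x1 -> ReLU -> conv3x3 ->
    ReLU -> conv1x1 (batch-normalized), added to the identity-mapped input
    and passed through a final ReLU."""

    def __init__(self, c_in, c_out, stride=1, rng=None):
        mid = max(4, c_out // 2)
        self.conv1 = nn.Conv2d(c_in, mid, kernel=1, pad=0, bias=False, rng=rng)
        self.bn1 = nn.BatchNorm2d(mid)
        self.conv2 = nn.Conv2d(mid, mid, kernel=3, stride=stride, bias=False, rng=rng)
        self.bn2 = nn.BatchNorm2d(mid)
        self.conv3 = nn.Conv2d(mid, c_out, kernel=1, pad=0, bias=False, rng=rng)
        self.bn3 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.short = nn.Conv2d(c_in, c_out, kernel=1, pad=0, stride=stride, bias=False, rng=rng)
            self.short_bn = nn.BatchNorm2d(c_out)
        else:
            self.short = None

    def residual(self, x: Tensor) -> Tensor:
        h = nn.relu(self.bn1(self.conv1(x)))
        h = nn.relu(self.bn2(self.conv2(h)))
        return self.bn3(self.conv3(h))

    def identity(self, x: Tensor) -> Tensor:
        if self.short is None:
            return x
        return self.short_bn(self.short(x))

    def __call__(self, x: Tensor) -> Tensor:
        return nn.relu(nn.add(self.residual(x), self.identity(x)))


class FeaturePyramid(nn.Module):
    """Top-down merge of C3-C5 into P3-P7."""

    def __init__(self, c3, c4, c5, width, rng=None):
        self.lat3 = nn.Conv2d(c3, width, kernel=1, pad=0, rng=rng)
        self.lat4 = nn.Conv2d(c4, width, kernel=1, pad=0, rng=rng)
        self.lat5 = nn.Conv2d(c5, width, kernel=1, pad=0, rng=rng)
        self.up54 = nn.ConvTranspose2d(width, width, rng=rng)
        self.up43 = nn.ConvTranspose2d(width, width, rng=rng)
        self.smooth3 = nn.Conv2d(width, width, rng=rng)
        self.smooth4 = nn.Conv2d(width, width, rng=rng)
        self.smooth5 = nn.Conv2d(width, width, rng=rng)
        self.down6 = nn.Conv2d(width, width, stride=2, rng=rng)
        self.down7 = nn.Conv2d(width, width, stride=2, rng=rng)

    def __call__(self, c3: Tensor, c4: Tensor, c5: Tensor) -> dict:
        s3, s4, s5 = (t.data.shape[-1] for t in (c3, c4, c5))
        if not (s3 == 2 * s4 == 4 * s5):
            raise ValueError("C3:C4:C5 spatial sizes must be in ratio 4:2:1")
        m5 = self.lat5(c5)
        m4 = nn.add(self.lat4(c4), self.up54(m5))
        m3 = nn.add(self.lat3(c3), self.up43(m4))
        p3, p4, p5 = self.smooth3(m3), self.smooth4(m4), self.smooth5(m5)
        p6 = self.down6(p5)
        p7 = self.down7(p6)
        return {3: p3, 4: p4, 5: p5, 6: p6, 7: p7}


@dataclass
class JDNConfig:
    """Toy-scale by default; the published model uses a 50-layer backbone.

    ``gt_box_size`` is the side of the square box drawn around each
    ground-truth junction point for training (the detector is trained on
    areas that contain junctions, not bare points)."""

    base_channels: int = 8
    blocks_per_level: int = 1
    fpn_width: int = 16
    head_depth: int = 2
    gt_box_size: float = 24.0
    anchors: AnchorSpec = field(default_factory=AnchorSpec)
    reference_size: int = 512
    # training
    steps: int = 300
    batch_size: int = 2
    lr_max: float = 0.01
    lr_min: float = 1e-4
    momentum: float = 0.9
    focal_gamma: float = 2.0
    focal_alpha: float = 0.25
    pos_iou: float = 0.5
    neg_iou: float = 0.4
    score_threshold: float = 0.05
    nms_iou: float = 0.3
    seed: int = 0


class JDN(nn.Module):
    """Backbone + pyramid + classification/box subnets."""

    def __init__(self, config: JDNConfig | None = None):
        self.config = config or JDNConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        b = cfg.base_channels
        widths = [b, b * 2, b * 4, b * 8, b * 8]  # C1..C5
        self.stem = nn.ConvBnRelu(1, b, stride=2, rng=rng)  # C1
        self.stages = []
        c_in = b
        for lvl in range(4):  # C2..C5
            blocks = [ResidualBlock(c_in, widths[lvl + 1], stride=2, rng=rng)]
            for _ in range(cfg.blocks_per_level - 1):
                blocks.append(ResidualBlock(widths[lvl + 1], widths[lvl + 1], rng=rng))
            self.stages.append(blocks)
            c_in = widths[lvl + 1]
        self.fpn = FeaturePyramid(widths[2], widths[3], widths[4], cfg.fpn_width, rng=rng)

        def head(out_ch, bias_init=0.0):
            layers = [
                nn.ConvBnRelu(cfg.fpn_width, cfg.fpn_width, rng=rng)
                for _ in range(cfg.head_depth)
            ]
            final = nn.Conv2d(cfg.fpn_width, out_ch, rng=rng)
            final.bias.data[:] = bias_init
            return layers, final

        # rare-positive prior keeps early focal loss small and stable
        prior = -math.log((1 - 0.01) / 0.01)
        self.cls_layers, self.cls_final = head(ANCHORS_PER_CELL, prior)
        self.box_layers, self.box_final = head(4 * ANCHORS_PER_CELL)

    def backbone(self, x: Tensor) -> dict:
        c = {1: self.stem(x)}
        t = c[1]
        for lvl, blocks in enumerate(self.stages, start=2):
            for blk in blocks:
                t = blk(t)
            c[lvl] = t
        return c

    def forward(self, x: np.ndarray):
        """Returns (per-level class logits, per-level box deltas)."""
        c = self.backbone(Tensor(x))
        pyr = self.fpn(c[3], c[4], c[5])
        cls_out, box_out = {}, {}
        for lvl, p in pyr.items():
            t = p
            for layer in self.cls_layers:
                t = layer(t)
            cls_out[lvl] = self.cls_final(t)
            t = p
            for layer in self.box_layers:
                t = layer(t)
            box_out[lvl] = self.box_final(t)
        return cls_out, box_out

    __call__ = forward


# ----------------------------------------------------------------- losses


def focal_loss(p: float, y: int, gamma: float = 2.0, alpha: float = 0.25) -> float:
    """Closed-form focal loss for one probability: -alpha (1-p_t)^gamma
    log p_t; reduces to alpha-weighted cross-entropy at gamma = 0."""
    p = float(p)
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly inside (0, 1)")
    pt = p if y == 1 else 1.0 - p
    return -alpha * (1.0 - pt) ** gamma * math.log(pt)


def smooth_l1(d: float) -> float:
    """0.5 d^2 for |d| < 1, |d| - 0.5 otherwise."""
    d = abs(float(d))
    return 0.5 * d * d if d < 1.0 else d - 0.5


# ------------------------------------------------------- anchors & decoding


def _iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """IoU between (n,4) and (m,4) arrays of (cx, cy, h, w)."""

    def corners(b):
        x0 = b[:, 0] - b[:, 3] / 2
        x1 = b[:, 0] + b[:, 3] / 2
        y0 = b[:, 1] - b[:, 2] / 2
        y1 = b[:, 1] + b[:, 2] / 2
        return x0, y0, x1, y1

    ax0, ay0, ax1, ay1 = corners(np.atleast_2d(boxes_a))
    bx0, by0, bx1, by1 = corners(np.atleast_2d(boxes_b))
    ix = np.maximum(
        0.0,
        np.minimum(ax1[:, None], bx1[None, :]) - np.maximum(ax0[:, None], bx0[None, :]),
    )
    iy = np.maximum(
        0.0,
        np.minimum(ay1[:, None], by1[None, :]) - np.maximum(ay0[:, None], by0[None, :]),
    )
    inter = ix * iy
    area_a = ((ax1 - ax0) * (ay1 - ay0))[:, None]
    area_b = ((bx1 - bx0) * (by1 - by0))[None, :]
    return inter / np.maximum(area_a + area_b - inter, 1e-12)


def _flatten_level(arr: np.ndarray, per_cell: int) -> np.ndarray:
    """(C, H, W) head output -> (H*W*anchors, per_cell) in anchor order."""
    c, h, w = arr.shape
    a = c // per_cell
    return arr.reshape(a, per_cell, h, w).transpose(2, 3, 0, 1).reshape(-1, per_cell)


def _apply_deltas(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    out = np.empty_like(anchors)
    out[:, 0] = anchors[:, 0] + deltas[:, 0] * anchors[:, 3]
    out[:, 1] = anchors[:, 1] + deltas[:, 1] * anchors[:, 2]
    out[:, 2] = anchors[:, 2] * np.exp(np.clip(deltas[:, 2], -4, 4))
    out[:, 3] = anchors[:, 3] * np.exp(np.clip(deltas[:, 3], -4, 4))
    return out


def _box_targets(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    t = np.empty_like(anchors)
    t[:, 0] = (gt[:, 0] - anchors[:, 0]) / anchors[:, 3]
    t[:, 1] = (gt[:, 1] - anchors[:, 1]) / anchors[:, 2]
    t[:, 2] = np.log(gt[:, 2] / anchors[:, 2])
    t[:, 3] = np.log(gt[:, 3] / anchors[:, 3])
    return t


def _nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> list:
    order = np.argsort(scores)[::-1]
    keep = []
    while len(order):
        i = order[0]
        keep.append(int(i))
        if len(order) == 1:
            break
        ious = _iou_matrix(boxes[i : i + 1], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thr]
    return keep


def decode_detections(
    class_scores: dict,
    box_deltas: dict,
    anchors: dict,
    score_threshold: float = 0.05,
    nms_iou: float = 0.3,
    cap: int = MAX_BOXES,
    image_shape: tuple | None = None,
) -> list:
    """Turn per-level head outputs into at most ``cap`` scored boxes.

    ``class_scores``/``box_deltas`` map level -> (anchors, 1) / (anchors,
    4) arrays in anchor order; scores are sigmoid probabilities. Boxes
    failing the score threshold are dropped, overlaps are suppressed at
    ``nms_iou``, and the ``cap`` highest-scoring survivors are returned in
    descending score order.
    """
    all_boxes, all_scores, all_levels = [], [], []
    for lvl in sorted(class_scores):
        sc = np.asarray(class_scores[lvl]).reshape(-1)
        dl = np.asarray(box_deltas[lvl]).reshape(-1, 4)
        keep = sc >= score_threshold
        if not keep.any():
            continue
        boxes = _apply_deltas(anchors[lvl][keep], dl[keep])
        all_boxes.append(boxes)
        all_scores.append(sc[keep])
        all_levels.append(np.full(keep.sum(), lvl))
    if not all_boxes:
        return []
    boxes = np.concatenate(all_boxes)
    scores = np.concatenate(all_scores)
    levels = np.concatenate(all_levels)
    if image_shape is not None:
        h, w = image_shape
        inside = (
            (boxes[:, 0] + boxes[:, 3] / 2 > 0)
            & (boxes[:, 0] - boxes[:, 3] / 2 < w)
            & (boxes[:, 1] + boxes[:, 2] / 2 > 0)
            & (boxes[:, 1] - boxes[:, 2] / 2 < h)
        )
        boxes, scores, levels = boxes[inside], scores[inside], levels[inside]
        if len(boxes) == 0:
            return []
    keep = _nms(boxes, scores, nms_iou)[:cap]
    return [
        DetectionBox(
            float(boxes[i, 0]),
            float(boxes[i, 1]),
            float(boxes[i, 2]),
            float(boxes[i, 3]),
            float(scores[i]),
            int(levels[i]),
        )
        for i in keep
    ]


def boxes_to_points(boxes: list) -> list:
    """Box centers as junction points: (x, y) -> (row, col), rounded."""
    return [
        JunctionPoint(
            int(round(b.cy)),
            int(round(b.cx)),
            score=min(1.0, max(0.0, b.score)),
            provenance=Provenance.DETECTED,
        )
        for b in boxes
    ]


# ----------------------------------------------------------------- training


def _prepare_image(img) -> np.ndarray:
    if isinstance(img, VesselMask):
        arr = img.mask.astype(np.float64)
    elif isinstance(img, FundusImage):
        arr = img.as_gray()
    else:
        arr = np.asarray(img, dtype=np.float64)
    if arr.max() > 1.0:
        arr = arr / 255.0
    return arr.astype(np.float32)


def _anchor_pack(config: JDNConfig, image_size: int) -> dict:
    spec = config.anchors.scaled(image_size, config.reference_size)
    sizes = {lvl: (image_size // 2**lvl, image_size // 2**lvl) for lvl in PYRAMID_LEVELS}
    return {lvl: make_anchors(spec, lvl, sizes[lvl]) for lvl in PYRAMID_LEVELS}


def _assign_anchors(anchors_flat, gt_boxes, pos_iou, neg_iou):
    """RetinaNet-style assignment: IoU >= pos positive, < neg negative,
    in between ignored; the best anchor of each ground-truth box is forced
    positive."""
    n = len(anchors_flat)
    labels = np.zeros(n, dtype=np.int64)
    ignore = np.zeros(n, dtype=bool)
    matched = np.zeros(n, dtype=np.int64)
    if len(gt_boxes) == 0:
        return labels, ignore, matched
    iou = _iou_matrix(anchors_flat, gt_boxes)
    best_gt = iou.argmax(axis=1)
    best_iou = iou[np.arange(n), best_gt]
    labels[best_iou >= pos_iou] = 1
    ignore[(best_iou >= neg_iou) & (best_iou < pos_iou)] = True
    force = iou.argmax(axis=0)  # best anchor per gt
    labels[force] = 1
    ignore[force] = False
    matched = best_gt
    matched[force] = np.arange(len(gt_boxes))
    return labels, ignore, matched


def train_jdn(model: JDN, dataset, config: JDNConfig | None = None):
    """Train on (image-or-mask, junction list) pairs.

    Ground-truth points become ``gt_box_size`` square boxes (scaled by the
    image size relative to the 512-px reference). Loss = focal + smooth-L1
    over positive anchors; optimization is momentum SGD under a cosine
    learning-rate schedule from ``lr_max`` to ``lr_min``.

    Returns ``(model, loss_history)``.
    """
    config = config or model.config
    if len(dataset) == 0:
        raise ValueError("training needs at least one annotated image")
    rng = np.random.default_rng(config.seed)

    prepared = []
    anchor_cache: dict = {}
    for img, junctions in dataset:
        arr = _prepare_image(img)
        size = arr.shape[0]
        if size not in anchor_cache:
            anchor_cache[size] = _anchor_pack(config, size)
        box_side = config.gt_box_size * size / config.reference_size
        gt = np.array(
            [[j.col, j.row, box_side, box_side] for j in junctions], dtype=np.float64
        ).reshape(-1, 4)
        packs = anchor_cache[size]
        flat_anchors = np.concatenate([packs[lvl] for lvl in PYRAMID_LEVELS])
        labels, ignore, matched = _assign_anchors(
            flat_anchors, gt, config.pos_iou, config.neg_iou
        )
        box_t = np.zeros((len(flat_anchors), 4), dtype=np.float32)
        if len(gt):
            box_t = _box_targets(flat_anchors, gt[matched]).astype(np.float32)
        prepared.append((arr, labels, ignore, box_t))

    opt = nn.MomentumSGD(model.parameters(), lr=config.lr_max, momentum=config.momentum)
    history = []
    model.train()
    for step in range(config.steps):
        opt.lr = cosine_lr(step, config.steps, config.lr_max, config.lr_min)
        idx = rng.choice(len(prepared), size=min(config.batch_size, len(prepared)), replace=False)
        x = np.stack([prepared[i][0] for i in idx])[:, None]
        cls_out, box_out = model.forward(x)
        logits = nn_concat_levels(cls_out, 1)
        deltas = nn_concat_levels(box_out, 4)
        labels = np.stack([prepared[i][1] for i in idx])
        ignore = np.stack([prepared[i][2] for i in idx])
        box_t = np.stack([prepared[i][3] for i in idx])
        n_pos = max(1.0, float((labels == 1).sum()))
        cls_w = (~ignore).astype(np.float32)[..., None]
        box_w = (labels == 1).astype(np.float32)[..., None]
        model.zero_grad()
        loss_c = nn.sigmoid_focal_loss(
            logits, labels[..., None], config.focal_gamma, config.focal_alpha,
            weights=cls_w, normalizer=n_pos,
        )
        loss_b = nn.smooth_l1_loss(deltas, box_t, weights=box_w, normalizer=n_pos)
        total = nn.add(loss_c, loss_b)
        total.backward()
        opt.step()
        history.append(total.item())
    return model, history


def nn_concat_levels(level_outputs: dict, per_cell: int) -> Tensor:
    """Concatenate per-level head tensors into (N, total_anchors,
    per_cell) matching the flat anchor enumeration order."""
    pieces = []
    for lvl in sorted(level_outputs):
        t = level_outputs[lvl]
        n, c, h, w = t.data.shape
        a = c // per_cell

        def make_backward(tt, nn_, a_, per_, h_, w_):
            def backward(g):
                gg = (
                    g.reshape(nn_, h_, w_, a_, per_)
                    .transpose(0, 3, 4, 1, 2)
                    .reshape(nn_, a_ * per_, h_, w_)
                )
                tt._accumulate(gg)

            return backward

        data = (
            t.data.reshape(n, a, per_cell, h, w)
            .transpose(0, 3, 4, 1, 2)
            .reshape(n, h * w * a, per_cell)
        )
        from .nn.tensor import _node

        pieces.append(_node(data, (t,), make_backward(t, n, a, per_cell, h, w)))
    return nn.concat(pieces, axis=1)


def detect_junctions(
    model: JDN,
    image,
    score_threshold: float | None = None,
    nms_iou: float | None = None,
) -> list:
    """Run the JDN on one image (or vessel mask) and return candidate
    junction points (box centers, provenance=detected)."""
    cfg = model.config
    arr = _prepare_image(image)
    size = arr.shape[0]
    packs = _anchor_pack(cfg, size)
    model.eval()
    cls_out, box_out = model.forward(arr[None, None])
    scores, deltas = {}, {}
    for lvl in PYRAMID_LEVELS:
        sc = _flatten_level(cls_out[lvl].data[0], 1)
        scores[lvl] = 1.0 / (1.0 + np.exp(-sc))
        deltas[lvl] = _flatten_level(box_out[lvl].data[0], 4)
    boxes = decode_detections(
        scores,
        deltas,
        packs,
        cfg.score_threshold if score_threshold is None else score_threshold,
        cfg.nms_iou if nms_iou is None else nms_iou,
        cfg.anchors.max_boxes,
        image_shape=arr.shape,
    )
    return boxes_to_points(boxes)


def save_jdn(model: JDN, path) -> None:
    state = model.state_arrays()
    cfg = asdict(model.config)
    np.savez_compressed(
        path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8), **state
    )


def load_jdn(path) -> JDN:
    with np.load(path) as data:
        raw = json.loads(bytes(data["__config__"]).decode())
        raw["anchors"] = AnchorSpec(
            {int(k): v for k, v in raw["anchors"]["base_sizes"].items()},
            tuple(raw["anchors"]["scales"]),
            tuple(raw["anchors"]["ratios"]),
            raw["anchors"]["max_boxes"],
        )
        model = JDN(JDNConfig(**raw))
        model.load_state_arrays({k: data[k] for k in data.files if k != "__config__"})
    return model
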