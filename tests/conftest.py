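import numpy as np
import pytest

from retinareg.synthetic import (
    TransformSpec,
    VascularTreeParams,
    generate_pair,
    generate_vascular_tree,
    render_fundus,
)


@pytest.fixture(scope="session")
def tree():
    """A deterministic vascular phantom: (mask, ground-truth junctions)."""
    return generate_vascular_tree(VascularTreeParams(seed=3))


@pytest.fixture(scope="session")
def fundus(tree):
    mask, _ = tree
    return render_fundus(mask, seed=3)


@pytest.fixture(scope="session")
def pair():
    """One registered phantom pair with moderate viewpoint change."""
    spec = TransformSpec(
        rotation_deg=12.0, translation=(18.0, -9.0), scale=1.05,
        perspective=(5e-5, -5e-5),
    )
    return generate_pair(VascularTreeParams(seed=11), spec, seed=11)


def random_transform(rng, max_rot=20.0, max_trans=30.0, max_persp=1e-4):
    """Sample a viewpoint change within the study's realistic ranges."""
    return TransformSpec(
        rotation_deg=float(rng.uniform(-max_rot, max_rot)),
        translation=(
            float(rng.uniform(-max_trans, max_trans)),
            float(rng.uniform(-max_trans, max_trans)),
        ),
        scale=float(rng.uniform(0.9, 1.1)),
        perspective=(
            float(rng.uniform(-max_persp, max_persp)),
            float(rng.uniform(-max_persp, max_persp)),
        ),
    )


def control_point_error(pair, homography):
    """Mean error of a recovered homography at the pair's true junctions."""
    from retinareg.evaluation import registration_error
    from retinareg.registration import transform_points
    from retinareg.types import CorrespondenceSet

    pts = np.array([[j.col, j.row] for j in pair.true_junctions_sensed], float)
    cs = CorrespondenceSet(transform_points(pair.true_H, pts), pts)
    return registration_error(homography, cs)
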