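import numpy as np
import pytest

import rootcarto as rc


def qc_position(params: rc.SyntheticParams) -> np.ndarray:
    """Ground-truth QC location on the generator's axis."""
    yq, zq = params.axis_center(params.qc_x_um)
    return np.array([params.qc_x_um, float(yq), float(zq)])


@pytest.fixture(scope="session")
def clean_params():
    """Noise-free study conditions (σ=0, zero background)."""
    return rc.SyntheticParams(sigma=0.0, background=0.0)


@pytest.fixture(scope="session")
def clean_root(clean_params):
    """Rasterized noise-free root: (stack, labels, truth)."""
    return rc.generate_root(clean_params, 1)


@pytest.fixture(scope="session")
def noisy_params():
    return rc.SyntheticParams()


@pytest.fixture(scope="session")
def noisy_root(noisy_params):
    """Rasterized root under the default noise model."""
    return rc.generate_root(noisy_params, 2)


@pytest.fixture(scope="session")
def noisy_frame(noisy_params, noisy_root):
    stack, labels, truth = noisy_root
    records = rc.extract_features(labels, stack)
    frame = rc.fit_axis(records, qc_position(noisy_params))
    return frame, records


def straight_frame(length: float = 120.0, y0: float = 36.0, z0: float = 36.0):
    """Hand-built straight root frame along x (n1 = +y, n2 = +z)."""
    s = np.linspace(-20.0, length, 561)
    points = np.stack([s, np.full_like(s, y0), np.full_like(s, z0)], axis=1)
    normals = np.tile([0.0, 1.0, 0.0], (len(s), 1))
    return rc.RootFrame(s_grid=s, points=points, normals1=normals)


def run_fate_pipeline(records, params):
    """records → fully annotated table + zone boundaries."""
    frame = rc.fit_axis(records, qc_position(params))
    ann = rc.annotate_cylindrical(records, frame)
    ann = rc.assign_layer(ann, rc.DEFAULT_LAYER_RADII)
    ann = rc.assign_files(ann)
    ann, bounds = rc.assign_zone(ann)
    ann = rc.classify_epidermis(ann)
    return ann, bounds, frame


def file_assignment_accuracy(merged) -> float:
    """Best-bijection accuracy of predicted vs true file partitions,
    pooled over layers (file indices are arbitrary up to rotation)."""
    from scipy.optimize import linear_sum_assignment
    total = correct = 0
    for layer, sub in merged.groupby("layer_true"):
        if layer == "columella":
            continue
        cm = sub.groupby(["file_true", "file"]).size().unstack(fill_value=0)
        ri, ci = linear_sum_assignment(-cm.to_numpy())
        correct += int(cm.to_numpy()[ri, ci].sum())
        total += len(sub)
    return correct / total
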