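"""Independent brute-force oracles used by the tests.

These re-derive quantities by direct per-voxel summation in plain
Python/NumPy, deliberately sharing no code with the package's feature
extraction.
"""

import itertools

import numpy as np


def brute_force_features(labels: np.ndarray, channels: dict, voxel_size):
    """Per-label features by direct summation.

    Returns {label: {volume, surface, width, height, depth,
    centroid (x,y,z), intensity_<ch>, com_<ch> (x,y,z)}}.
    """
    dz, dy, dx = voxel_size
    nz, ny, nx = labels.shape
    out = {}
    for lab in sorted(set(labels.ravel().tolist()) - {0}):
        vox = [(z, y, x) for z in range(nz) for y in range(ny) for x in range(nx)
               if labels[z, y, x] == lab]
        n = len(vox)
        zs = [v[0] for v in vox]
        ys = [v[1] for v in vox]
        xs = [v[2] for v in vox]
        surface = 0.0
        face = {0: dy * dx, 1: dz * dx, 2: dz * dy}
        for (z, y, x) in vox:
            for axis, (ddz, ddy, ddx) in enumerate(
                    [(1, 0, 0), (-1, 0, 0)] + [(0, 1, 0), (0, -1, 0)]
                    + [(0, 0, 1), (0, 0, -1)]):
                z2, y2, x2 = z + ddz, y + ddy, x + ddx
                outside = not (0 <= z2 < nz and 0 <= y2 < ny and 0 <= x2 < nx)
                if outside or labels[z2, y2, x2] != lab:
                    surface += face[axis // 2]
        feats = {
            "volume": n * dz * dy * dx,
            "surface": surface,
            "width": (max(xs) - min(xs) + 1) * dx,
            "height": (max(ys) - min(ys) + 1) * dy,
            "depth": (max(zs) - min(zs) + 1) * dz,
            "centroid": (sum(xs) / n * dx, sum(ys) / n * dy, sum(zs) / n * dz),
        }
        for name, chan in channels.items():
            tot = sum(float(chan[v]) for v in vox)
            feats[f"intensity_{name}"] = tot
            if tot > 0:
                feats[f"com_{name}"] = (
                    sum(float(chan[v]) * v[2] for v in vox) / tot * dx,
                    sum(float(chan[v]) * v[1] for v in vox) / tot * dy,
                    sum(float(chan[v]) * v[0] for v in vox) / tot * dz,
                )
        out[lab] = feats
    return out


def run_lengths_oracle(seq):
    """Maximal-run extraction via itertools.groupby."""
    return [(k, len(list(g))) for k, g in itertools.groupby(seq)]
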