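"""Per-nucleus feature tables and their CSV interchange format.

The pipeline's tabular currency is a pandas DataFrame with one row per
nucleus.  Column conventions (all lengths in µm, volumes in µm³,
intensities in arbitrary units):

* ``id`` — integer label, matching the label volume.
* ``centroid_x/y/z`` — unweighted mask centroid in the stack's Cartesian
  frame (x = column index * dx, y = row * dy, z = slice * dz).
* ``com_<channel>_x/y/z`` — intensity-weighted centre of mass per channel.
* ``volume_um3``, ``surface_um2`` — voxel-count volume and boundary-face
  surface area.
* ``width_um``, ``height_um``, ``depth_um`` — bounding-box extents along
  the stack x, y, z axes (W, H, D).
* ``intensity_<channel>`` — integrated (summed) intensity per channel.
* ``asym_x/y/z``, ``asym_norm`` — asymmetry vector, centroid minus DNA
  centre of mass, and its Euclidean norm.

Annotation, ploidy and call tables reuse ``id`` as the join key.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: columns that every feature table must carry, in stable order
CORE_COLUMNS = [
    "id",
    "centroid_x", "centroid_y", "centroid_z",
    "volume_um3", "surface_um2",
    "width_um", "height_um", "depth_um",
    "asym_x", "asym_y", "asym_z", "asym_norm",
]


def column_order(df: pd.DataFrame) -> list[str]:
    """Stable column order: core columns first, then the rest sorted."""
    extra = sorted(c for c in df.columns if c not in CORE_COLUMNS)
    return [c for c in CORE_COLUMNS if c in df.columns] + extra


def write_table(records: pd.DataFrame, path: str | Path, precision: int = 6) -> Path:
    """Write a per-nucleus table to CSV with stable column order.

    Numeric values are written with ``precision`` decimal digits; a
    write→read round trip is lossless at that precision.

    Raises
    ------
    ValueError
        Empty record table.
    """
    if len(records) == 0:
        raise ValueError("refusing to write an empty record table")
    path = Path(path)
    out = records[column_order(records)]
    out.to_csv(path, index=False, float_format=f"%.{precision}g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    if "id" in df.columns:
        df["id"] = df["id"].astype(int)
    return df


def validate_records(records: pd.DataFrame) -> None:
    """Check the invariants a feature table must satisfy."""
    missing = [c for c in CORE_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"feature table missing columns {missing}")
    if (records["volume_um3"] <= 0).any():
        raise ValueError("non-positive nucleus volume")
    if (records[["width_um", "height_um", "depth_um"]] <= 0).any().any():
        raise ValueError("non-positive bounding extent")
    max_ext = records[["width_um", "height_um", "depth_um"]].max(axis=1)
    if (records["asym_norm"] > max_ext + 1e-9).any():
        raise ValueError("asymmetry norm exceeds bounding extent")
    for col in records.columns:
        if col.startswith("intensity_") and (records[col] < 0).any():
            raise ValueError(f"negative integrated intensity in {col}")


def centroids(records: pd.DataFrame) -> np.ndarray:
    """(n, 3) array of centroid (x, y, z) positions in µm."""
    return records[["centroid_x", "centroid_y", "centroid_z"]].to_numpy(float)
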