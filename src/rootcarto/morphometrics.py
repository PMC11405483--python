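"""Nuclear shape factors, relative ploidy, and axial trend analysis.

Relative ploidy follows the in-situ calibration logic: nuclei in a
window around the quiescent centre are taken as the 2C reference cohort
(their median integrated DNA intensity defines 2C), and every nucleus'
C-value is twice its intensity over that reference.  C is reported
continuously; nearest-power-of-two binning is a separate optional step.

The shape factor is the nucleus' extent along the root's longitudinal
axis over its extent along the radial axis.  Extents are derived from
the stack-axis bounding box by treating the nucleus as the inscribed
ellipsoid (semi-axes W/2, H/2, D/2 along stack x/y/z): the width of that
ellipsoid along a unit direction u is 2·√(Σ (extᵢ/2 · uᵢ)²).  This makes
a sphere's factor exactly 1 for any axis orientation and is the fixed
convention used everywhere in the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import PreconditionError
from .frame import RootFrame

CALIBRATION_EXCLUDED_LAYERS = ("columella", "LRC", "unassigned")


def _ellipsoid_width(extents: np.ndarray, u: np.ndarray) -> float:
    """Width along unit direction u of the bbox-inscribed ellipsoid."""
    semi = np.asarray(extents, float) / 2.0
    return 2.0 * float(np.sqrt(np.sum((semi * u) ** 2)))


def shape_factor(record, frame: RootFrame) -> float:
    """Axial / radial extent ratio of one nucleus in the root frame.

    ``record`` needs centroid and W/H/D columns.  Raises on zero radial
    extent.
    """
    p = np.array([record["centroid_x"], record["centroid_y"], record["centroid_z"]])
    z, r, phi, _ = frame.to_cylindrical(p[None, :])
    t, n1, n2 = frame.frame(z[0])
    u_ax = t
    u_rad = np.cos(phi[0]) * n1 + np.sin(phi[0]) * n2
    # extents along stack (x, y, z); W is along x
    ext = np.array([record["width_um"], record["height_um"], record["depth_um"]])
    axial = _ellipsoid_width(ext, u_ax)
    radial = _ellipsoid_width(ext, u_rad)
    if radial <= 0:
        raise PreconditionError("zero radial extent")
    return axial / radial


def shape_factors(records: pd.DataFrame, frame: RootFrame) -> pd.Series:
    vals = [shape_factor(row, frame) for _, row in records.iterrows()]
    return pd.Series(vals, index=records.index, name="shape_factor")


def estimate_ploidy(records: pd.DataFrame, annotations: pd.DataFrame,
                    calibration_window: float = 15.0,
                    intensity_col: str = "intensity_dna",
                    min_calibration: int = 5):
    """Relative DNA content in C units against the 2C cohort near the QC.

    The calibration cohort is every nucleus with |z| ≤ window outside the
    columella/LRC; its median integrated DNA intensity is assigned 2C.
    Returns ``(estimates, reference)`` where estimates has columns
    ``id, c_value, c_class`` (c_class = nearest power-of-two C).
    """
    merged = records.merge(annotations, on="id", how="inner")
    cohort = merged[(merged["z_cyl"].abs() <= calibration_window)]
    if "layer" in merged.columns:
        cohort = cohort[~cohort["layer"].isin(CALIBRATION_EXCLUDED_LAYERS)]
    if len(cohort) < min_calibration:
        raise PreconditionError(
            f"calibration window holds {len(cohort)} nuclei; need ≥ {min_calibration}")
    reference = float(cohort[intensity_col].median())
    if reference <= 0:
        raise PreconditionError("non-positive reference intensity")
    c = 2.0 * merged[intensity_col].to_numpy(float) / reference
    estimates = pd.DataFrame({
        "id": merged["id"],
        "c_value": c,
        "c_class": nearest_ploidy_class(c),
        "reference_intensity": reference,
        "calibration_n": len(cohort),
    })
    return estimates, reference


def nearest_ploidy_class(c) -> np.ndarray:
    """Bin continuous C-values to the nearest power-of-two class (≥ 1C)."""
    c = np.clip(np.asarray(c, float), 1e-12, None)
    return 2.0 ** np.round(np.log2(c))


def ploidy_map(estimates: pd.DataFrame, annotations: pd.DataFrame):
    """Long-format in situ ploidy map plus per-layer axial summaries.

    Returns ``(map_table, summaries)``.  The map table has one row per
    joined nucleus (z, r, φ, layer, C); unjoined ids are dropped with a
    log entry.  Per layer the summary reports the OLS slope of C vs z
    (with 95% CI) and the step-change position of median C.
    """
    merged = estimates.merge(annotations, on="id", how="inner")
    dropped = len(estimates) - len(merged)
    if dropped:
        import logging
        logging.getLogger(__name__).warning("%d estimates had no annotation; dropped", dropped)
    cols = ["id", "z_cyl", "r_cyl", "phi_cyl", "c_value"]
    if "layer" in merged.columns:
        cols.append("layer")
    table = merged[cols].copy()
    summaries = {}
    if "layer" in merged.columns:
        for layer, grp in merged.groupby("layer"):
            if len(grp) < 5:
                continue
            fit = _ols_slope(grp["z_cyl"], grp["c_value"])
            summaries[layer] = dict(fit, change_point=change_point(
                grp["z_cyl"].to_numpy(), grp["c_value"].to_numpy()))
    return table, summaries


def change_point(z: np.ndarray, values: np.ndarray) -> float | None:
    """Best single step position of a two-level piecewise-constant fit.

    Minimizes the total squared error of a left-mean/right-mean model over
    all split points; returns the z midpoint of the best split, or None
    when no split beats the constant model.
    """
    order = np.argsort(z)
    z, values = np.asarray(z, float)[order], np.asarray(values, float)[order]
    n = len(values)
    if n < 4:
        return None
    csum = np.cumsum(values)
    csq = np.cumsum(values**2)
    total_sse = csq[-1] - csum[-1] ** 2 / n
    best_sse, best_i = np.inf, None
    for i in range(2, n - 1):
        left = csq[i - 1] - csum[i - 1] ** 2 / i
        right = (csq[-1] - csq[i - 1]) - (csum[-1] - csum[i - 1]) ** 2 / (n - i)
        if left + right < best_sse:
            best_sse, best_i = left + right, i
    if best_i is None or best_sse >= total_sse:
        return None
    return float(0.5 * (z[best_i - 1] + z[best_i]))


def _ols_slope(x, y) -> dict:
    X = sm.add_constant(np.asarray(x, float))
    fit = sm.OLS(np.asarray(y, float), X).fit()
    lo, hi = fit.conf_int()[1]
    return {"slope": float(fit.params[1]), "slope_ci": (float(lo), float(hi)),
            "slope_p": float(fit.pvalues[1]), "n": int(fit.nobs)}


def dna_volume_trend(records: pd.DataFrame, annotations: pd.DataFrame,
                     layer: str, min_n: int = 10) -> dict:
    """OLS slope of DNA volume vs axial position for one layer."""
    merged = records.merge(annotations, on="id", how="inner")
    grp = merged[merged["layer"] == layer]
    if len(grp) < min_n:
        raise PreconditionError(f"layer {layer!r} has {len(grp)} nuclei; need ≥ {min_n}")
    return _ols_slope(grp["z_cyl"], grp["volume_um3"])


def compare_volume_trends(records: pd.DataFrame, annotations: pd.DataFrame,
                          layer_a: str, layer_b: str) -> dict:
    """Test equality of DNA-volume slopes between two layers.

    Fits volume ~ z * layer on the pooled data; the interaction term's
    p-value tests the slope difference.
    """
    merged = records.merge(annotations, on="id", how="inner")
    sub = merged[merged["layer"].isin([layer_a, layer_b])]
    if sub["layer"].nunique() < 2:
        raise PreconditionError("need nuclei from both layers")
    z = sub["z_cyl"].to_numpy(float)
    is_b = (sub["layer"] == layer_b).astype(float).to_numpy()
    X = sm.add_constant(np.column_stack([z, is_b, z * is_b]))
    fit = sm.OLS(sub["volume_um3"].to_numpy(float), X).fit()
    return {"slope_diff": float(fit.params[3]), "p": float(fit.pvalues[3]),
            "n": int(fit.nobs)}
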