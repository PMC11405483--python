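"""Root axis fitting, cylindrical coordinates, and positional cell fate.

The root frame is a smooth axis curve parametrized by arclength ``z``
(µm, 0 at the quiescent centre, increasing shootward) together with a
parallel-transported orthonormal moving frame ``(t, n1, n2)``.  A point
maps to cylindrical coordinates ``(z, r, φ)`` by projecting onto the
curve; φ is measured in the (n1, n2) normal plane, so file indices are
stable along z but arbitrary up to a global rotation (the azimuthal
origin is a convention, not biology — comparisons are partition-based).

Cell-fate assignment is purely positional: radial bins give the tissue
layer, circular clustering of φ within a layer gives the cell file,
per-file axial spacing in the proliferation domain separates trichoblast
from atrichoblast files (T files are markedly denser), and the
PD→TD→EZ zone boundaries are detected as step increases of the
inter-nucleus spacing along each file.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks
from scipy.spatial import cKDTree

from .errors import AxisFitError, ChannelError, PreconditionError
from .stack import VoxelStack
from .tables import centroids

log = logging.getLogger(__name__)

RING_LAYERS = ("vascular", "pericycle", "endodermis", "cortex", "epidermis")


# --------------------------------------------------------------- RootFrame

@dataclass
class RootFrame:
    """Fitted root axis with arclength parametrization and moving frame."""

    s_grid: np.ndarray            # dense arclength samples (µm), z=0 at QC
    points: np.ndarray            # (n, 3) axis positions (x, y, z µm)
    normals1: np.ndarray          # (n, 3) parallel-transported normal
    residual_rms: float = 0.0     # radial spread of the fit control points

    _pos: CubicSpline = field(init=False, repr=False)
    _n1: CubicSpline = field(init=False, repr=False)
    _tree: cKDTree = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos = CubicSpline(self.s_grid, self.points)
        self._n1 = CubicSpline(self.s_grid, self.normals1)
        self._tree = cKDTree(self.points)

    @property
    def s_min(self) -> float:
        return float(self.s_grid[0])

    @property
    def s_max(self) -> float:
        return float(self.s_grid[-1])

    @property
    def total_length(self) -> float:
        return self.s_max - self.s_min

    def point(self, s):
        return self._pos(s)

    def tangent(self, s):
        d = self._pos(s, 1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def frame(self, s):
        """Orthonormal (t, n1, n2) at arclength s (vectorized)."""
        t = self.tangent(s)
        n1 = self._n1(s)
        n1 = n1 - np.sum(n1 * t, axis=-1, keepdims=True) * t
        n1 = n1 / np.linalg.norm(n1, axis=-1, keepdims=True)
        n2 = np.cross(t, n1)
        return t, n1, n2

    # ------------------------------------------------------------- mapping
    def to_cylindrical(self, pts: np.ndarray):
        """Map Cartesian points (…, 3) µm to (z, r, φ).

        Returns ``(z, r, phi, extrapolated)``; ``extrapolated`` flags
        points whose projection clamps to a curve end.
        """
        pts = np.atleast_2d(np.asarray(pts, float))
        _, idx = self._tree.query(pts)
        s = self.s_grid[idx].astype(float)
        lo, hi = self.s_min, self.s_max
        # Newton iterations on g(s) = (p - c(s)) · c'(s) = 0
        for _ in range(60):
            c = self._pos(s)
            d1 = self._pos(s, 1)
            d2 = self._pos(s, 2)
            q = pts - c
            g = np.sum(q * d1, axis=-1)
            gp = -np.sum(d1 * d1, axis=-1) + np.sum(q * d2, axis=-1)
            step = np.where(np.abs(gp) > 1e-12, g / gp, 0.0)
            step = np.clip(step, -2.0, 2.0)
            s_new = np.clip(s - step, lo, hi)
            if np.max(np.abs(s_new - s)) < 1e-12:
                s = s_new
                break
            s = s_new
        c = self._pos(s)
        t, n1, n2 = self.frame(s)
        q = pts - c
        a = np.sum(q * n1, axis=-1)
        b = np.sum(q * n2, axis=-1)
        r = np.hypot(a, b)
        phi = np.mod(np.arctan2(b, a), 2 * math.pi)
        g = np.sum(q * t, axis=-1)
        extrapolated = ((np.isclose(s, lo) | np.isclose(s, hi)) & (np.abs(g) > 1e-6))
        return s, r, phi, extrapolated

    def from_cylindrical(self, z, r, phi):
        """Inverse mapping: (z, r, φ) → Cartesian points (…, 3) µm."""
        z = np.atleast_1d(np.asarray(z, float))
        r = np.atleast_1d(np.asarray(r, float))
        phi = np.atleast_1d(np.asarray(phi, float))
        c = self._pos(z)
        _, n1, n2 = self.frame(z)
        return c + r[..., None] * (np.cos(phi)[..., None] * n1
                                   + np.sin(phi)[..., None] * n2)


def fit_axis(records: pd.DataFrame, qc_position, bin_um: float = 12.0,
             min_nuclei: int = 20, min_per_bin: int = 5, degree: int = 3,
             pad_um: float = 8.0) -> RootFrame:
    """Fit the root axis to nucleus centroids.

    Centroids are ordered along their first principal component and
    binned; the transverse mean of a radially symmetric cloud is the
    axis centre, so a low-order polynomial is fitted through the per-bin
    means, weighted by bin occupancy (sparse end bins carry azimuthal
    sampling noise of several µm).  The curve is reparametrized by
    arclength with z=0 at the projection of ``qc_position``.

    Raises
    ------
    PreconditionError
        Fewer than ``min_nuclei`` nuclei.
    AxisFitError
        Degenerate point cloud (rank < 2).
    """
    pts = centroids(records)
    if len(pts) < min_nuclei:
        raise PreconditionError(f"need ≥ {min_nuclei} nuclei, got {len(pts)}")
    mean = pts.mean(axis=0)
    centered = pts - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] < 1e-9 * max(svals[0], 1.0):
        raise AxisFitError("degenerate point cloud (rank < 2)")
    axis_dir = vt[0]
    # orient the axis shootward: the QC sits at the rootward end, so the
    # bulk of the cloud must project to larger t than the QC
    if np.median(centered @ axis_dir) < (np.asarray(qc_position, float) - mean) @ axis_dir:
        axis_dir = -axis_dir
    t_proj = centered @ axis_dir

    order = np.argsort(t_proj)
    t_sorted = t_proj[order]
    p_sorted = pts[order]
    edges = np.arange(t_sorted[0], t_sorted[-1] + bin_um, bin_um)
    which = np.clip(np.digitize(t_sorted, edges) - 1, 0, len(edges) - 2)
    ctrl_t, ctrl_p, ctrl_n = [], [], []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.sum() >= min_per_bin:
            ctrl_t.append(t_sorted[sel].mean())
            ctrl_p.append(p_sorted[sel].mean(axis=0))
            ctrl_n.append(int(sel.sum()))
    if len(ctrl_t) < 2:
        raise AxisFitError("too few populated bins along the axis")
    ctrl_t = np.array(ctrl_t)
    ctrl_p = np.array(ctrl_p)
    weights = np.sqrt(np.array(ctrl_n, float))

    deg = min(degree, len(ctrl_t) - 1)
    coeffs = np.polynomial.polynomial.polyfit(ctrl_t, ctrl_p, deg, w=weights)

    t0, t1 = t_sorted[0] - pad_um, t_sorted[-1] + pad_um
    t_dense = np.linspace(t0, t1, max(int((t1 - t0) / 0.25), 64))
    p_dense = np.polynomial.polynomial.polyval(t_dense, coeffs).T

    seglen = np.linalg.norm(np.diff(p_dense, axis=0), axis=1)
    s_dense = np.concatenate([[0.0], np.cumsum(seglen)])

    # parallel transport of the first normal along the curve
    tangents = np.gradient(p_dense, s_dense, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    n1 = np.zeros_like(tangents)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, tangents[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - np.dot(ref, tangents[0]) * tangents[0]
    n1[0] = v / np.linalg.norm(v)
    for i in range(1, len(tangents)):
        v = n1[i - 1] - np.dot(n1[i - 1], tangents[i]) * tangents[i]
        n1[i] = v / np.linalg.norm(v)

    frame = RootFrame(s_grid=s_dense, points=p_dense, normals1=n1)
    qc = np.asarray(qc_position, float)
    s_qc, _, _, _ = frame.to_cylindrical(qc[None, :])
    frame = RootFrame(s_grid=s_dense - float(s_qc[0]), points=p_dense, normals1=n1)

    z, r, _, _ = frame.to_cylindrical(pts)
    frame.residual_rms = float(np.sqrt(np.mean((r - r.mean()) ** 2)))
    return frame


def annotate_cylindrical(records: pd.DataFrame, frame: RootFrame) -> pd.DataFrame:
    """Start an annotation table: id plus cylindrical coordinates."""
    z, r, phi, extrap = frame.to_cylindrical(centroids(records))
    return pd.DataFrame({"id": records["id"], "z_cyl": z, "r_cyl": r,
                         "phi_cyl": phi, "extrapolated": extrap})


# ---------------------------------------------------------- cell fate

def assign_layer(annotations: pd.DataFrame, layer_radii: dict[str, float],
                 lrc_extent_um: float = 35.0,
                 columella_radius_um: float = 6.0) -> pd.DataFrame:
    """Radial-bin layer assignment.

    Bin edges are the outer radii of the ring layers; a radius exactly on
    an edge resolves inward.  Nuclei below the QC (z < 0) are columella
    (small r) or lateral root cap; nuclei outside the outermost ring are
    LRC while z is within the cap extent, otherwise unassigned.
    """
    names = list(layer_radii)
    outer = np.array([layer_radii[n] for n in names])
    if np.any(np.diff(outer) <= 0):
        raise PreconditionError("layer radii must be strictly increasing")
    ann = annotations.copy()
    r = ann["r_cyl"].to_numpy(float)
    z = ann["z_cyl"].to_numpy(float)
    idx = np.searchsorted(outer, r, side="left")
    layer = np.array([names[i] if i < len(names) else "LRC" for i in idx], dtype=object)
    beyond = idx >= len(names)
    layer[beyond & (z > lrc_extent_um)] = "unassigned"
    below = z < 0
    layer[below & (r <= columella_radius_um)] = "columella"
    layer[below & (r > columella_radius_um)] = "LRC"
    ann["layer"] = layer
    return ann


def _circular_cluster(phi: np.ndarray, max_files: int = 16,
                      min_gap_rad: float = 0.12,
                      harmonic_threshold: float = 0.7) -> np.ndarray:
    """Cluster azimuths into files; clusters are indexed by ascending mean φ.

    Cell files of one layer sit at near-regular azimuthal positions, so
    the file count k is first read off the circular harmonics: the
    smallest k with |⟨e^{ikφ}⟩| above ``harmonic_threshold`` (a k-fold
    regular arrangement concentrates the k-th harmonic even when φ is
    noisy at small radii).  Members then go to the nearest of the k phase
    centres.  If no harmonic dominates, the fallback cuts the largest
    circular gaps, with the file count set by the largest drop in the
    sorted-gap sequence.
    """
    n = len(phi)
    if n == 1:
        return np.zeros(1, dtype=int)
    amps = [np.abs(np.mean(np.exp(1j * k * phi))) for k in range(1, max_files + 1)]
    candidates = [k for k, a in enumerate(amps, start=1) if a >= harmonic_threshold]
    if candidates:
        k = candidates[0]
        if k == 1:
            return np.zeros(n, dtype=int)
        theta = np.angle(np.mean(np.exp(1j * k * phi))) / k
        centers = np.mod(theta + 2 * math.pi * np.arange(k) / k, 2 * math.pi)
        order_c = np.argsort(centers)
        centers = centers[order_c]
        d = np.angle(np.exp(1j * (phi[:, None] - centers[None, :])))
        return np.argmin(np.abs(d), axis=1)
    order = np.argsort(phi)
    sp = phi[order]
    gaps = np.diff(np.concatenate([sp, [sp[0] + 2 * math.pi]]))
    gap_order = np.argsort(gaps)[::-1]
    sorted_gaps = gaps[gap_order]
    kmax = min(n, max_files)
    # number of files = position of the largest drop in the sorted-gap
    # sequence: between-file gaps are large and comparable, within-file
    # gaps small — the boundary is the steepest step
    best_k, best_drop = 1, -1.0
    for k in range(1, kmax):
        g_k = sorted_gaps[k - 1]
        if g_k < min_gap_rad:
            break
        g_next = sorted_gaps[k] if k < n else 0.0
        drop = g_k - g_next
        if drop > best_drop:
            best_drop, best_k = drop, k
    if sorted_gaps[0] < min_gap_rad:
        best_k = 1
    if best_k == 1:
        return np.zeros(n, dtype=int)
    cut_positions = np.sort(gap_order[:best_k])  # gap i separates sp[i] from sp[i+1]
    membership = np.zeros(n, dtype=int)
    cluster = 0
    for i in range(n):
        membership[i] = cluster
        if i in cut_positions and i < n - 1:
            cluster += 1
    # the run crossing the 2π wrap joins the first cluster unless the wrap
    # gap itself was cut
    if (n - 1) not in cut_positions and best_k > 1:
        membership[membership == cluster] = 0
        # re-densify indices
        uniq = {c: i for i, c in enumerate(sorted(set(membership)))}
        membership = np.array([uniq[c] for c in membership])
    out = np.zeros(n, dtype=int)
    # order clusters by circular mean phi for a stable (convention) index
    means = []
    for c in sorted(set(membership)):
        vals = sp[membership == c]
        means.append((np.angle(np.mean(np.exp(1j * vals))) % (2 * math.pi), c))
    rank = {c: i for i, (_, c) in enumerate(sorted(means))}
    out[order] = [rank[c] for c in membership]
    return out


def assign_files(annotations: pd.DataFrame, max_files: int = 16) -> pd.DataFrame:
    """Cluster nuclei of each layer into longitudinal files by azimuth."""
    if "layer" not in annotations.columns:
        raise PreconditionError("assign_layer must run first")
    ann = annotations.copy()
    ann["file"] = -1
    for layer, group in ann.groupby("layer"):
        if layer in ("columella", "unassigned"):
            continue
        phi = group["phi_cyl"].to_numpy(float)
        files = _circular_cluster(phi, max_files=max_files)
        ann.loc[group.index, "file"] = files
    return ann


def classify_epidermis(annotations: pd.DataFrame, min_contrast: float = 1.3,
                       min_per_file: int = 3) -> pd.DataFrame:
    """Split epidermal files into trichoblast (T) / atrichoblast (AT).

    Uses the per-file mean inter-nucleus z-spacing in the proliferation
    domain; the denser class is T.  Files are split at the largest gap in
    the sorted spacing means; if the between-class contrast is below
    ``min_contrast`` the subtype stays "n/a".
    """
    ann = annotations.copy()
    ann["subtype"] = "n/a"
    epi = ann[(ann["layer"] == "epidermis")]
    if "zone" in ann.columns:
        epi = epi[epi["zone"] == "PD"]
    spacings: dict[int, float] = {}
    for f, group in epi.groupby("file"):
        z = np.sort(group["z_cyl"].to_numpy(float))
        if len(z) >= min_per_file:
            spacings[int(f)] = float(np.diff(z).mean())
    if len(spacings) < 2:
        log.warning("epidermis T/AT: not enough files with ≥%d PD nuclei", min_per_file)
        return ann
    files = np.array(sorted(spacings))
    vals = np.array([spacings[f] for f in files])
    order = np.argsort(vals)
    sv = vals[order]
    jumps = np.diff(sv)
    cut = int(np.argmax(jumps))
    t_files = set(files[order[: cut + 1]].tolist())
    mean_t = sv[: cut + 1].mean()
    mean_at = sv[cut + 1:].mean()
    if mean_at / mean_t < min_contrast:
        log.warning("epidermis T/AT: spacing contrast %.2f below %.2f; all n/a",
                    mean_at / mean_t, min_contrast)
        return ann
    is_epi = ann["layer"] == "epidermis"
    ann.loc[is_epi, "subtype"] = [
        "T" if f in t_files else "AT" for f in ann.loc[is_epi, "file"]]
    return ann


def assign_zone(annotations: pd.DataFrame, k: float = 1.5, k2: float = 3.0,
                baseline_frac: float = 1 / 3):
    """Detect PD/TD and TD/EZ boundaries from spacing steps along files.

    Per file, the spacing baseline is the median of the first
    ``baseline_frac`` of inter-nucleus gaps; the PD/TD boundary is the
    midpoint of the first gap exceeding ``k``× baseline, TD/EZ the first
    exceeding ``k2``× baseline.  Per-file boundaries are pooled by median.
    Returns ``(annotations, boundaries)`` with zone ∈ {PD, TD, EZ}.
    """
    if k <= 1.0 or k2 <= 1.0:
        raise PreconditionError("zone factors k and k2 must exceed 1")
    if "file" not in annotations.columns:
        raise PreconditionError("assign_files must run first")
    pd_td, td_ez = [], []
    for (layer, f), group in annotations.groupby(["layer", "file"]):
        if layer in ("columella", "LRC", "unassigned") or f < 0:
            continue
        g = group.sort_values(["z_cyl", "id"])
        z = g["z_cyl"].to_numpy(float)
        z = z[z >= 0]
        if len(z) < 4:
            continue
        gaps = np.diff(z)
        nb = max(3, int(len(gaps) * baseline_frac))
        base = np.median(gaps[:nb])
        over1 = np.flatnonzero(gaps > k * base)
        over2 = np.flatnonzero(gaps > k2 * base)
        # boundary at the last nucleus before the first super-threshold
        # gap (the spacing step begins there)
        if len(over1):
            pd_td.append(z[over1[0]])
        if len(over2):
            td_ez.append(z[over2[0]])
    b1 = float(np.median(pd_td)) if pd_td else math.inf
    b2 = float(np.median(td_ez)) if td_ez else math.inf
    if not pd_td:
        log.warning("no PD/TD spacing step found; whole root treated as PD")
    if b2 < b1:
        b2 = math.inf
    ann = annotations.copy()
    z = ann["z_cyl"].to_numpy(float)
    ann["zone"] = np.where(z < b1, "PD", np.where(z < b2, "TD", "EZ"))
    return ann, {"pd_td": b1, "td_ez": b2}


# ----------------------------------------- intracellular nucleus position

def nucleus_position_in_cell(record, stack: VoxelStack, labels: np.ndarray,
                             frame: RootFrame, search_um: float = 10.0,
                             step_um: float = 0.2, prominence_frac: float = 0.25):
    """Radial distances from the nucleus edge to the outer (L1) and inner
    (L2) cell walls, along the radial ray through the nucleus centroid.

    Returns ``(L1, L2, measured)``; ``measured`` is False when no wall
    peak is found on one side (distances are then NaN).
    """
    if "wall" not in stack.channels:
        raise ChannelError("wall channel required for L1/L2 measurement")
    wall = np.asarray(stack.channel("wall"), float)
    nid = int(record["id"])
    p = np.array([record["centroid_x"], record["centroid_y"], record["centroid_z"]])
    z, r, phi, _ = frame.to_cylindrical(p[None, :])
    c = frame.point(z[0])
    u = (p - c)
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise PreconditionError("nucleus centroid lies on the axis; radial ray undefined")
    u = u / norm

    t_samples = np.arange(max(0.0, norm - search_um), norm + search_um, step_um)
    pts = c[None, :] + t_samples[:, None] * u[None, :]
    dz, dy, dx = stack.voxel_size
    idx = np.stack([pts[:, 2] / dz, pts[:, 1] / dy, pts[:, 0] / dx])
    wall_line = ndimage.map_coordinates(wall, idx, order=1, mode="nearest")
    lab_line = ndimage.map_coordinates((np.asarray(labels) == nid).astype(float),
                                       idx, order=1, mode="nearest") > 0.5
    if not lab_line.any():
        raise PreconditionError(f"radial ray misses nucleus {nid}")
    t_in = t_samples[lab_line][0]
    t_out = t_samples[lab_line][-1]

    peaks, _ = find_peaks(wall_line, prominence=prominence_frac * wall_line.max())
    peak_t = t_samples[peaks]
    outward = peak_t[peak_t > t_out]
    inward = peak_t[peak_t < t_in]
    if len(outward) == 0 or len(inward) == 0:
        return math.nan, math.nan, False
    l1 = float(outward[0] - t_out)
    l2 = float(t_in - inward[-1])
    return l1, l2, True
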