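"""Euchromatin/heterochromatin colocalization and axial configuration codes.

Three complementary quantifications of the two histone-mark channels:

* **Hue-range colocalization** — the two marks are composed into an RGB
  image (heterochromatin red, euchromatin green) and each signal pixel is
  classified by its hue on the 0–255 scale: 0–15 exclusive red, 16–58
  overlay (red+green → yellow ≈ 42), 59–255 exclusive green.
* **Peripheral profiles** — intensity sampled along the nuclear periphery
  of the equatorial z-projection, on one shared arc parametrization per
  nucleus, so channels can be correlated point-by-point.
* **Configuration codes** — each mark gets an orientation code from the
  nuclear hemisphere holding at least a threshold fraction of its
  integrated signal: 1 rootward / 2 shootward along the root axis,
  3 / 4 along the lateral axis (orthogonal to both the root axis and the
  radial direction), else "uniform".  The joint code is written
  euchromatin-first ("e_h", e.g. "1_2" = euchromatin rootward,
  heterochromatin shootward).  The rootward polarity of code 1 is an
  arbitrary but fixed convention; all statistics are invariant to it.

Configuration frequencies are tested against the uniform null (equal
probability of every code after a random post-mitotic rearrangement)
with a chi-squared goodness-of-fit test plus per-code binomial
enrichment tests, Benjamini–Hochberg adjusted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib.colors import rgb_to_hsv
from scipy import ndimage, stats
from skimage.measure import find_contours
from statsmodels.stats.multitest import multipletests

from .errors import PreconditionError
from .frame import RootFrame
from .stack import VoxelStack

DEFAULT_HUE_RANGES = ((0, 15), (16, 58), (59, 255))
AXIAL_CODES = ("1", "2", "3", "4")
ALL_JOINT_CODES = tuple(f"{a}_{b}" for a in AXIAL_CODES for b in AXIAL_CODES)


# ------------------------------------------------------------ colocalization

@dataclass
class ColocalizationSummary:
    red_exclusive: float
    overlap: float
    green_exclusive: float
    profile_correlation: float = math.nan

    def fractions(self) -> tuple[float, float, float]:
        return (self.red_exclusive, self.overlap, self.green_exclusive)


def hue_overlap_fractions(red: np.ndarray, green: np.ndarray,
                          mask: np.ndarray | None = None,
                          ranges=DEFAULT_HUE_RANGES) -> ColocalizationSummary:
    """Fractions of signal pixels in the exclusive-red / overlay /
    exclusive-green hue ranges of the two-channel RGB composite.

    The hue of (R=red, G=green, B=0) runs 0 (pure red) → ~42 (equal,
    yellow) → 85 (pure green) on the 0–255 scale, so the classical
    0–15 / 16–58 / 59–255 ranges split red-only, overlapping and
    green-only signal.  Scale-invariant by construction.
    """
    red = np.asarray(red, float)
    green = np.asarray(green, float)
    if mask is None:
        mask = np.ones(red.shape, bool)
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise PreconditionError("empty mask")
    r = red[mask].ravel()
    g = green[mask].ravel()
    signal = (r + g) > 0
    if not signal.any():
        raise PreconditionError("no signal pixels in mask")
    r, g = r[signal], g[signal]
    peak = max(r.max(), g.max())
    rgb = np.stack([r, g, np.zeros_like(r)], axis=-1) / peak
    hue255 = np.round(rgb_to_hsv(rgb)[..., 0] * 255.0)
    n = len(hue255)
    fracs = []
    for lo, hi in ranges:
        fracs.append(float(np.sum((hue255 >= lo) & (hue255 <= hi)) / n))
    return ColocalizationSummary(*fracs)


def peripheral_profile(mask: np.ndarray, channel: np.ndarray,
                       n_samples: int = 72, inset_px: int = 1,
                       projection: str = "max"):
    """Intensity along the periphery of the nucleus' z-projection.

    The 3D mask is projected along z (maximum projection by default —
    insensitive to the chord-length variation of an ellipsoid, so
    peripheral foci dominate the profile; ``projection='sum'`` gives the
    integrated alternative).  The reference line is the boundary contour
    of the (slightly inset) projected mask, resampled at ``n_samples``
    uniform arc steps starting from the contour point of smallest polar
    angle.  The same arc parametrization applies to every channel of one
    nucleus, so profiles are directly comparable.

    Returns ``(arc, intensities)`` where arc is the cumulative arclength
    (pixel units) of each sample.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim != 3:
        raise PreconditionError("mask must be 3D")
    if int(mask.any(axis=(1, 2)).sum()) < 3:
        raise PreconditionError("nucleus mask must span ≥ 3 slices")
    proj_mask = mask.any(axis=0)
    masked = np.where(mask, np.asarray(channel, float), 0.0)
    if projection == "max":
        proj_int = masked.max(axis=0)
    elif projection == "sum":
        proj_int = masked.sum(axis=0)
    else:
        raise ValueError(f"unknown projection {projection!r}")
    inner = proj_mask
    for _ in range(inset_px):
        eroded = ndimage.binary_erosion(inner)
        if not eroded.any():
            break
        inner = eroded
    contours = find_contours(inner.astype(float), 0.5)
    if not contours:
        raise PreconditionError("degenerate boundary")
    contour = max(contours, key=len)
    if len(contour) < 8:
        raise PreconditionError("degenerate boundary (<8 contour points)")
    # canonical start: point with the smallest polar angle around the center
    center = contour.mean(axis=0)
    angles = np.mod(np.arctan2(contour[:, 0] - center[0], contour[:, 1] - center[1]),
                    2 * math.pi)
    start = int(np.argmin(angles))
    contour = np.roll(contour[:-1] if np.allclose(contour[0], contour[-1]) else contour,
                      -start, axis=0)
    closed = np.vstack([contour, contour[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    arc = np.linspace(0.0, total, n_samples, endpoint=False)
    rows = np.interp(arc, cum, closed[:, 0])
    cols = np.interp(arc, cum, closed[:, 1])
    vals = ndimage.map_coordinates(proj_int, np.stack([rows, cols]), order=1,
                                   mode="nearest")
    return arc, vals


def profile_correlation(p1: np.ndarray, p2: np.ndarray) -> float:
    """Pearson correlation of two peripheral profiles; NaN when either
    profile has zero variance (correlation undefined)."""
    p1, p2 = np.asarray(p1, float), np.asarray(p2, float)
    if p1.std() == 0 or p2.std() == 0:
        return math.nan
    return float(np.corrcoef(p1, p2)[0, 1])


# ------------------------------------------------------ configuration codes

@dataclass
class ConfigurationCall:
    id: int
    euchromatin_code: str
    heterochromatin_code: str
    fractions: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def joint_code(self) -> str:
        return f"{self.euchromatin_code}_{self.heterochromatin_code}"


def mark_orientation(coords: np.ndarray, values: np.ndarray, centroid: np.ndarray,
                     axial: np.ndarray, lateral: np.ndarray,
                     threshold: float) -> tuple[str, dict[str, float]]:
    """Orientation code of one mark from its voxel coordinates/intensities.

    Hemisphere fractions of the integrated signal are computed for the
    rootward (−axial), shootward (+axial), −lateral and +lateral halves;
    the code of the dominant hemisphere is returned if its fraction is at
    least ``threshold``, else "uniform".
    """
    total = float(values.sum())
    if total <= 0:
        raise PreconditionError("zero mark signal")
    d = coords - centroid
    ax = d @ axial
    lat = d @ lateral
    # voxels exactly on a splitting plane count half to each hemisphere,
    # making the code mapping exactly antisymmetric under mirroring
    fracs = {
        "1": float((values[ax < 0].sum() + 0.5 * values[ax == 0].sum()) / total),
        "2": float((values[ax > 0].sum() + 0.5 * values[ax == 0].sum()) / total),
        "3": float((values[lat < 0].sum() + 0.5 * values[lat == 0].sum()) / total),
        "4": float((values[lat > 0].sum() + 0.5 * values[lat == 0].sum()) / total),
    }
    best = max(AXIAL_CODES, key=lambda c: fracs[c])
    code = best if fracs[best] >= threshold else "uniform"
    return code, fracs


def _classify_in_box(nucleus_id: int, stack: VoxelStack, labels: np.ndarray,
                     box, frame: RootFrame, marks, threshold) -> ConfigurationCall:
    sub = labels[box]
    where = np.nonzero(sub == nucleus_id)
    if len(where[0]) == 0:
        raise PreconditionError(f"label {nucleus_id} not present")
    dz, dy, dx = stack.voxel_size
    off = np.array([b.start for b in box])
    coords = np.stack([(where[2] + off[2]) * dx,
                       (where[1] + off[1]) * dy,
                       (where[0] + off[0]) * dz], axis=1)
    centroid = coords.mean(axis=0)
    z, r, phi, _ = frame.to_cylindrical(centroid[None, :])
    t, n1, n2 = frame.frame(z[0])
    u_rad = np.cos(phi[0]) * n1 + np.sin(phi[0]) * n2
    lateral = np.cross(t, u_rad)
    codes, fracs = {}, {}
    for mark in marks:
        vals = np.asarray(stack.channel(mark), float)[box][where]
        codes[mark], fracs[mark] = mark_orientation(coords, vals, centroid, t,
                                                    lateral, threshold)
    return ConfigurationCall(id=int(nucleus_id),
                             euchromatin_code=codes[marks[0]],
                             heterochromatin_code=codes[marks[1]],
                             fractions=fracs)


def classify_configuration(nucleus_id: int, stack: VoxelStack, labels: np.ndarray,
                           frame: RootFrame,
                           marks: tuple[str, str] = ("euchromatin", "heterochromatin"),
                           threshold: float = 0.55) -> ConfigurationCall:
    """Joint axial configuration code of one nucleus (euchromatin first)."""
    stack.require(*marks)
    labels = np.asarray(labels)
    box = tuple(slice(0, s) for s in labels.shape)
    return _classify_in_box(int(nucleus_id), stack, labels, box, frame, marks,
                            threshold)


def classify_configurations(stack, labels, frame, ids=None,
                            marks=("euchromatin", "heterochromatin"),
                            threshold: float = 0.55) -> pd.DataFrame:
    """Batch version; returns a calls table (id, codes, joint code)."""
    stack.require(*marks)
    labels = np.asarray(labels)
    objects = ndimage.find_objects(labels)
    if ids is None:
        ids = np.unique(labels)
        ids = ids[ids > 0]
    rows = []
    for nid in ids:
        box = objects[int(nid) - 1]
        if box is None:
            raise PreconditionError(f"label {nid} not present")
        call = _classify_in_box(int(nid), stack, labels, box, frame, marks, threshold)
        rows.append({"id": call.id,
                     "euchromatin_code": call.euchromatin_code,
                     "heterochromatin_code": call.heterochromatin_code,
                     "config_code": call.joint_code})
    return pd.DataFrame(rows)


# ------------------------------------------------------ frequency analysis

@dataclass
class FrequencyTest:
    table: pd.DataFrame          # code, count, expected, p_binom, q_binom
    statistic: float
    df: int
    pvalue: float
    n: int
    method: str = "chi-squared"  # or "monte-carlo multinomial"


def configuration_frequencies(calls: pd.DataFrame, codes=None, min_n: int = 30,
                              mc_draws: int = 10000, seed: int = 0) -> FrequencyTest:
    """Joint-code frequency table tested against the uniform null.

    Only non-uniform joint codes enter the test.  ``codes`` fixes the
    code space (default: all 16 axial/lateral combinations plus any other
    observed code).  When any expected count falls below 1 the chi-squared
    approximation is replaced by a Monte-Carlo multinomial test (flagged
    in ``method``).  Per-code binomial enrichment p-values are BH-adjusted.
    """
    col = "config_code" if "config_code" in calls.columns else "joint_code"
    observed = calls[col].astype(str)
    observed = observed[~observed.str.contains("uniform")]
    n = len(observed)
    if n < min_n:
        raise PreconditionError(f"need ≥ {min_n} classified nuclei, got {n}")
    if codes is None:
        codes = sorted(set(ALL_JOINT_CODES) | set(observed))
    counts = observed.value_counts().reindex(codes, fill_value=0)
    m = len(codes)
    expected = n / m
    if expected < 1:
        rng = np.random.default_rng(seed)
        stat = float(np.sum((counts - expected) ** 2 / expected))
        sims = rng.multinomial(n, np.full(m, 1 / m), size=mc_draws)
        sim_stats = np.sum((sims - expected) ** 2 / expected, axis=1)
        pvalue = float((np.sum(sim_stats >= stat) + 1) / (mc_draws + 1))
        method = "monte-carlo multinomial"
        df = m - 1
    else:
        stat, pvalue = stats.chisquare(counts.to_numpy())
        stat, pvalue = float(stat), float(pvalue)
        method = "chi-squared"
        df = m - 1
    p_binom = np.array([
        stats.binomtest(int(k), n, 1 / m, alternative="greater").pvalue
        for k in counts])
    q_binom = multipletests(p_binom, method="fdr_bh")[1]
    table = pd.DataFrame({"code": codes, "count": counts.to_numpy(),
                          "expected": expected, "p_binom": p_binom,
                          "q_binom": q_binom})
    return FrequencyTest(table=table, statistic=stat, df=df, pvalue=pvalue,
                         n=n, method=method)


# ------------------------------------------------- anaphase region profiles

def anaphase_region_intensity(mask: np.ndarray, channel: np.ndarray,
                              plane_point, plane_normal, nbins: int = 4,
                              voxel_size=(1.0, 1.0, 1.0)) -> pd.DataFrame:
    """Mean channel intensity by distance from the division plane.

    Mask voxels are split by the sign of their distance to the plane
    (the two daughter sides) and binned by |distance| into ``nbins``
    equal-width bins per side.  Returns a table (side, bin, distance
    bin centre, mean intensity, n); a single populated side is flagged
    with ``one_sided=True`` in ``DataFrame.attrs``.
    """
    if nbins < 1:
        raise PreconditionError("nbins must be ≥ 1")
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise PreconditionError("empty chromatin mask")
    dz, dy, dx = voxel_size
    where = np.nonzero(mask)
    coords = np.stack([where[2] * dx, where[1] * dy, where[0] * dz], axis=1)
    normal = np.asarray(plane_normal, float)
    normal = normal / np.linalg.norm(normal)
    d = (coords - np.asarray(plane_point, float)) @ normal
    vals = np.asarray(channel, float)[where]
    rows = []
    sides = {"minus": d < 0, "plus": d >= 0}
    populated = [s for s, sel in sides.items() if sel.any()]
    for side in populated:
        sel = sides[side]
        dd = np.abs(d[sel])
        vv = vals[sel]
        top = dd.max() if dd.max() > 0 else 1.0
        edges = np.linspace(0.0, top, nbins + 1)
        which = np.clip(np.digitize(dd, edges) - 1, 0, nbins - 1)
        for b in range(nbins):
            in_bin = which == b
            if not in_bin.any():
                continue
            rows.append({"side": side, "bin": b,
                         "distance_um": 0.5 * (edges[b] + edges[b + 1]),
                         "mean_intensity": float(vv[in_bin].mean()),
                         "n": int(in_bin.sum())})
    out = pd.DataFrame(rows)
    out.attrs["one_sided"] = len(populated) < 2
    return out
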