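"""Synthetic root-tip generator with complete ground truth.

Emulates the structure of a dicot root apical meristem as seen in a
multi-channel confocal stack, at a deliberately desk-scale geometry:

* concentric tissue layers around a (optionally bent) central axis —
  vascular cylinder, pericycle, endodermis, cortex, epidermis with
  alternating trichoblast (T) / atrichoblast (AT) files, and a lateral
  root cap ring near the tip; a small columella cluster below the QC;
* nuclei as oriented ellipsoids arranged in longitudinal cell files, with
  inter-nucleus spacing that steps up at the PD→TD and TD→EZ zone
  boundaries, and T files ~1.8× denser than AT files in the PD;
* per-nucleus DNA content (C-value) that doubles in the outer layers past
  the endoreduplication onset, with the integrated DNA-channel intensity
  an exact linear function of C before noise;
* nuclear substructure: peripheral chromocenter speckles (bright in DNA,
  carrying the heterochromatin mark) and a central DNA-void nucleolus;
* an EdU channel following an assigned S0 (absent) / S1 (homogeneous) /
  S2 (spotted, chromocenter-colocalized) replication pattern;
* euchromatin / heterochromatin mark channels polarized into nuclear
  hemispheres according to an assigned axial configuration code
  ("1" rootward, "2" shootward, "3"/"4" lateral);
* a cell-wall channel of Gaussian shells at the layer boundaries.

Two entry points share one placement plan: :func:`generate_root`
rasterizes a :class:`~rootcarto.stack.VoxelStack` plus label volume, and
:func:`generate_feature_table` emits the equivalent per-nucleus tables
without rasterization for fast statistical tests.
"""

from __future__ import annotations


import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import DEFAULT_LAYER_RADII
from .errors import PlacementError
from .stack import VoxelStack

#: layer bin outer radii (µm): the generator shares the pipeline default
GEN_LAYER_RADII = dict(DEFAULT_LAYER_RADII)
#: file placement radii (µm, mid-layer) and file counts
GEN_FILE_RADII = {
    "vascular": 3.0,
    "pericycle": 8.5,
    "endodermis": 13.5,
    "cortex": 17.5,
    "epidermis": 23.0,
    "LRC": 27.5,
}
GEN_FILES_PER_LAYER = {
    "vascular": 3,
    "pericycle": 5,
    "endodermis": 6,
    "cortex": 6,
    "epidermis": 8,
    "LRC": 8,
}
#: per-layer azimuthal offsets (rad) staggering files between adjacent layers
GEN_PHI_OFFSETS = {
    "vascular": 0.0,
    "pericycle": 2 * math.pi * 0.1,
    "endodermis": math.pi / 6,
    "cortex": 0.0,
    "epidermis": math.pi / 8,
    "LRC": 0.0,
}

ZONES = ("PD", "TD", "EZ")
AXIAL_CODES = ("1", "2", "3", "4")


def default_config_distribution() -> dict[str, float]:
    """Joint configuration-code distribution the generator samples from.

    Mirrors the observed structure: the opposed euchromatin/heterochromatin
    "1_2" configuration enriched to 40%, the fully colocalized orthogonal
    "3_3"/"4_4" codes absent, and the remaining codes equiprobable.
    """
    codes = [f"{a}_{b}" for a in AXIAL_CODES for b in AXIAL_CODES]
    codes = [c for c in codes if c not in ("3_3", "4_4")]
    rest = [c for c in codes if c != "1_2"]
    dist = {c: 0.6 / len(rest) for c in rest}
    dist["1_2"] = 0.4
    return dist


def uniform_config_distribution() -> dict[str, float]:
    """Uniform distribution over all 16 joint axial codes (the null)."""
    codes = [f"{a}_{b}" for a in AXIAL_CODES for b in AXIAL_CODES]
    return {c: 1.0 / len(codes) for c in codes}


@dataclass
class SyntheticParams:
    """Geometry, biology and noise parameters of the synthetic root.

    Lengths in µm; array shape is (z, y, x) voxels with the root axis
    along x.  Defaults are the package's reference study conditions.
    """

    shape: tuple[int, int, int] = (144, 144, 256)
    voxel_size: tuple[float, float, float] = (0.5, 0.5, 0.5)
    bit_depth: int = 65535

    # axis: x_qc is the QC position along x; a quadratic bend displaces the
    # axis in y by bend * (x - x_qc)^2
    qc_x_um: float = 16.0
    bend: float = 0.0

    layer_radii: dict[str, float] = field(default_factory=lambda: dict(GEN_LAYER_RADII))
    file_radii: dict[str, float] = field(default_factory=lambda: dict(GEN_FILE_RADII))
    files_per_layer: dict[str, int] = field(default_factory=lambda: dict(GEN_FILES_PER_LAYER))
    phi_offsets: dict[str, float] = field(default_factory=lambda: dict(GEN_PHI_OFFSETS))
    lrc_extent_um: float = 30.0
    lrc_s_min_um: float = -10.0
    columella_nuclei: int = 6
    columella_radius_um: float = 5.5

    # nucleus ellipsoid semi-axes (radial, lateral, axial)
    nucleus_semiaxes_um: tuple[float, float, float] = (1.8, 2.0, 2.2)
    t_axial_factor: float = 0.5        # trichoblast axial flattening
    lrc_axial_factor: float = 1.6      # LRC axial elongation
    volume_growth_per_um: dict[str, float] = field(
        default_factory=lambda: {"epidermis": 0.008}
    )

    # axial spacing
    spacing_um: float = 7.0
    t_spacing_ratio: float = 1.0 / 1.8
    lrc_spacing_um: float = 10.0
    zone_spacing_factors: tuple[float, float, float] = (1.0, 2.0, 4.0)
    pd_td_um: float = 50.0
    td_ez_um: float = 85.0
    s_margin_um: float = 3.0           # keep nuclei off the stack faces

    # placement jitter
    s_jitter_frac: float = 0.05
    r_jitter_um: float = 0.15
    phi_jitter_rad: float = 0.015

    # nuclear substructure
    n_chromocenters: int = 6           # placed as antipodal pairs
    chromocenter_radius_um: float = 0.6
    chromocenter_peripherality: float = 0.75
    chromocenter_boost: float = 2.5
    nucleolus_fraction: float = 0.3

    # ploidy / DNA intensity
    dna_per_c: float = 50000.0
    euch_per_c: float = 20000.0
    het_total: float = 8000.0
    endoreduplicating_layers: tuple[str, ...] = ("epidermis", "cortex")
    ploidy_profile: tuple[tuple[float, float], ...] | None = None
    intensity_cv: float = 0.10         # table-mode multiplicative noise
    volume_cv: float = 0.03            # table-mode volume measurement noise

    # EdU
    edu_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "PD": (0.60, 0.25, 0.15),
            "TD": (0.40, 0.40, 0.20),
            "EZ": (0.30, 0.60, 0.10),
        }
    )
    edu_s1_level: float = 300.0
    edu_spot_level: float = 800.0
    edu_spot_radius_um: float = 0.6

    # chromatin configuration
    config_distribution: dict[str, float] | None = None
    enrichment: float = 0.8            # mark fraction in the coded hemisphere

    # wall + noise
    wall_level: float = 500.0
    wall_sigma_um: float = 0.5
    background: float = 3.0
    sigma: float = 1.5

    max_placement_retries: int = 10

    def __post_init__(self) -> None:
        radii = list(self.layer_radii.values())
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("layer radii must be strictly increasing outward")
        for zone, p in self.edu_probs.items():
            if abs(sum(p) - 1.0) > 1e-9 or any(q < 0 for q in p):
                raise ValueError(f"EdU probabilities for {zone} must be a distribution")
        dist = self.config_distribution
        if dist is not None:
            if abs(sum(dist.values()) - 1.0) > 1e-9 or any(v < 0 for v in dist.values()):
                raise ValueError("configuration distribution must sum to 1")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")
        if not 0.5 < self.enrichment <= 1.0:
            raise ValueError("enrichment must be in (0.5, 1]")

    # ------------------------------------------------------------------ axis
    def axis_center(self, x_um: np.ndarray | float):
        """(y, z) µm of the axis centerline at position(s) x (µm)."""
        nz, ny, _ = self.shape
        dz, dy, _ = self.voxel_size
        y0 = (ny - 1) * dy / 2.0
        z0 = (nz - 1) * dz / 2.0
        y = y0 + self.bend * (np.asarray(x_um, float) - self.qc_x_um) ** 2
        return y, z0 * np.ones_like(np.asarray(x_um, float))

    def _arclength_interp(self):
        nx = self.shape[2]
        dx = self.voxel_size[2]
        xg = np.linspace(0.0, (nx - 1) * dx, 4 * nx)
        slope = 2.0 * self.bend * (xg - self.qc_x_um)
        ds = np.sqrt(1.0 + slope**2)
        s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(xg))])
        s -= np.interp(self.qc_x_um, xg, s)  # s = 0 at the QC
        return xg, s

    def s_of_x(self, x_um):
        xg, s = self._arclength_interp()
        return np.interp(x_um, xg, s)

    def x_of_s(self, s_um):
        xg, s = self._arclength_interp()
        return np.interp(s_um, s, xg)

    def frame_at(self, x_um: float):
        """Orthonormal (tangent, n1, n2) frame vectors at x, in (x, y, z)."""
        slope = 2.0 * self.bend * (x_um - self.qc_x_um)
        t = np.array([1.0, slope, 0.0])
        t /= np.linalg.norm(t)
        n1 = np.array([-t[1], t[0], 0.0])   # z_hat x t : in-plane normal
        n2 = np.array([0.0, 0.0, 1.0])
        return t, n1, n2

    def zone_of(self, s_um: float) -> str:
        if s_um < self.pd_td_um:
            return "PD"
        if s_um < self.td_ez_um:
            return "TD"
        return "EZ"

    def c_value(self, layer: str, s_um: float) -> float:
        if layer not in self.endoreduplicating_layers:
            return 2.0
        profile = self.ploidy_profile or ((self.pd_td_um, 2.0), (math.inf, 4.0))
        for s_max, c in profile:
            if s_um < s_max:
                return float(c)
        return float(profile[-1][1])


# ---------------------------------------------------------------- planning

GROUND_TRUTH_COLUMNS = [
    "id", "x", "y", "z", "s", "r", "phi", "layer", "file", "subtype", "zone",
    "c_value", "edu_pattern", "config_code", "spot_count",
    "semi_radial", "semi_lateral", "semi_axial", "volume_um3",
]


def _sample_codes(rng: np.random.Generator, dist: dict[str, float], n: int) -> np.ndarray:
    codes = sorted(dist)
    probs = np.array([dist[c] for c in codes])
    probs = probs / probs.sum()
    return rng.choice(codes, size=n, p=probs)


def plan_nuclei(params: SyntheticParams, seed: int) -> pd.DataFrame:
    """Place every nucleus and assign its ground-truth labels.

    Returns the ground-truth table (one row per nucleus).  Raises
    :class:`PlacementError` if jittered positions cannot be made
    non-overlapping within the retry budget.
    """
    rng = np.random.default_rng(seed)
    nx_um = (params.shape[2] - 1) * params.voxel_size[2]
    lat_half = min(
        (params.shape[0] - 1) * params.voxel_size[0],
        (params.shape[1] - 1) * params.voxel_size[1],
    ) / 2.0
    s_max = params.s_of_x(nx_um - params.s_margin_um)
    a0, b0, c0 = params.nucleus_semiaxes_um

    rows: list[dict] = []

    def add(s, r, phi, layer, file_idx, subtype, axial_factor, growth_rate):
        x = float(params.x_of_s(s))
        t, n1, n2 = params.frame_at(x)
        yc, zc = params.axis_center(x)
        pos = np.array([x, float(yc), float(zc)]) + r * (math.cos(phi) * n1 + math.sin(phi) * n2)
        scale = (1.0 + growth_rate * max(s, 0.0)) ** (1.0 / 3.0)
        zone = params.zone_of(s)
        rows.append(dict(
            x=pos[0], y=pos[1], z=pos[2], s=s, r=r, phi=phi % (2 * math.pi),
            layer=layer, file=file_idx, subtype=subtype, zone=zone,
            c_value=params.c_value(layer, s),
            semi_radial=a0 * scale, semi_lateral=b0 * scale,
            semi_axial=c0 * axial_factor * scale,
        ))

    # ring layers and the lateral root cap
    for layer, n_files in params.files_per_layer.items():
        r_mid = params.file_radii[layer]
        if r_mid + max(a0, b0) + 1.0 > lat_half:
            raise PlacementError(f"layer {layer!r} radius exceeds the stack cross-section")
        phi0 = params.phi_offsets.get(layer, 0.0)
        for f in range(n_files):
            phi_f = phi0 + 2 * math.pi * f / n_files
            if layer == "LRC":
                subtype, axial, spacing0, growth = "n/a", params.lrc_axial_factor, params.lrc_spacing_um, 0.0
                s, s_stop = params.lrc_s_min_um, min(params.lrc_extent_um, s_max)
            else:
                is_t = layer == "epidermis" and f % 2 == 0
                subtype = ("T" if is_t else "AT") if layer == "epidermis" else "n/a"
                axial = params.t_axial_factor if (layer == "epidermis" and is_t) else 1.0
                spacing0 = params.spacing_um * (params.t_spacing_ratio if (layer == "epidermis" and is_t) else 1.0)
                growth = params.volume_growth_per_um.get(layer, 0.0)
                s, s_stop = params.s_of_x(params.qc_x_um + 4.0), s_max
            while s < s_stop:
                zone_i = ZONES.index(params.zone_of(s))
                step = spacing0 * params.zone_spacing_factors[zone_i]
                sig = params.s_jitter_frac * step
                s_j = s + float(np.clip(rng.normal(0.0, sig), -1.5 * sig, 1.5 * sig))
                r_j = r_mid + float(np.clip(rng.normal(0.0, params.r_jitter_um),
                                            -2 * params.r_jitter_um, 2 * params.r_jitter_um))
                phi_j = phi_f + rng.normal(0.0, params.phi_jitter_rad)
                if params.s_of_x(0.0) + params.s_margin_um < s_j < s_max:
                    add(s_j, r_j, phi_j, layer, f, subtype, axial, growth)
                s += step

    # columella: one axial nucleus plus a small ring below the QC
    if params.columella_nuclei > 0:
        add(-8.0, 0.3, 0.0, "columella", -1, "n/a", 1.0, 0.0)
        n_ring = params.columella_nuclei - 1
        for k in range(n_ring):
            add(-8.0 + rng.normal(0.0, 0.3), params.columella_radius_um,
                2 * math.pi * k / max(n_ring, 1), "columella", -1, "n/a", 1.0, 0.0)

    truth = pd.DataFrame(rows)
    truth.insert(0, "id", np.arange(1, len(truth) + 1))

    _resolve_overlaps(truth, params, rng)

    truth["volume_um3"] = (
        4.0 / 3.0 * math.pi
        * truth["semi_radial"] * truth["semi_lateral"] * truth["semi_axial"]
    )

    # per-nucleus assigned calls
    zone_probs = np.array([params.edu_probs[z] for z in truth["zone"]])
    u = rng.random(len(truth))
    cum = np.cumsum(zone_probs, axis=1)
    pattern_idx = (u[:, None] > cum).sum(axis=1)
    truth["edu_pattern"] = np.array(["S0", "S1", "S2"])[pattern_idx]
    truth["spot_count"] = np.where(truth["edu_pattern"] == "S2", params.n_chromocenters, 0)
    dist = params.config_distribution or default_config_distribution()
    truth["config_code"] = _sample_codes(rng, dist, len(truth))
    return truth[GROUND_TRUTH_COLUMNS]


def _nucleus_axes(params: SyntheticParams, row) -> np.ndarray:
    """3x3 matrix of the nucleus' (radial, lateral, axial) unit axes (rows)."""
    t, n1, n2 = params.frame_at(row.x)
    u_r = math.cos(row.phi) * n1 + math.sin(row.phi) * n2
    u_l = np.cross(t, u_r)
    return np.vstack([u_r, u_l, t])


def _support(semi: np.ndarray, axes: np.ndarray, d: np.ndarray) -> float:
    """Ellipsoid support radius along unit direction d."""
    return float(np.sqrt(np.sum((semi * (axes @ d)) ** 2)))


def _resolve_overlaps(truth: pd.DataFrame, params: SyntheticParams, rng,
                      margin_um: float = 0.9) -> None:
    """Re-jitter positions until every ellipsoid pair keeps a clearance of
    ``margin_um`` (≥ one voxel diagonal, so rasterized masks stay
    disconnected even under 26-connectivity)."""
    bad: set[int] = set()
    for attempt in range(params.max_placement_retries):
        pos = truth[["x", "y", "z"]].to_numpy(float)
        semis = truth[["semi_radial", "semi_lateral", "semi_axial"]].to_numpy(float)
        reach = 2.0 * semis.max() + margin_um
        pairs = cKDTree(pos).query_pairs(reach, output_type="ndarray")
        bad = set()
        moves: dict[int, np.ndarray] = {}
        for i, j in pairs:
            d = pos[j] - pos[i]
            dist = np.linalg.norm(d)
            if dist == 0:
                bad.add(int(j))
                moves[int(j)] = rng.normal(0.0, 0.5, 3)
                continue
            d = d / dist
            ri = _support(semis[i], _nucleus_axes(params, truth.iloc[i]), d)
            rj = _support(semis[j], _nucleus_axes(params, truth.iloc[j]), d)
            deficit = ri + rj + margin_um - dist
            if deficit > 0:
                bad.add(int(j))
                # push the later nucleus apart along the separation line
                moves[int(j)] = moves.get(int(j), np.zeros(3)) + d * (deficit + 0.05)
        if not bad:
            return
        for j, mv in moves.items():
            truth.loc[truth.index[j], ["x", "y", "z"]] += mv
    raise PlacementError(f"{len(bad)} overlapping nuclei after "
                         f"{params.max_placement_retries} retries")


# ------------------------------------------------------------ rasterization

def _hemisphere_values(local: np.ndarray, code: str,
                       total: float, enrichment: float) -> np.ndarray:
    """Distribute `total` over voxels with local (radial, lateral, axial)
    displacement rows `local` (µm), putting `enrichment` of it into the
    hemisphere named by `code`.

    Codes: 1 rootward (-axial), 2 shootward (+axial), 3 -lateral,
    4 +lateral, anything else uniform.
    """
    n = len(local)
    vals = np.full(n, total / n)
    comp_sign = {"1": (2, -1.0), "2": (2, 1.0), "3": (1, -1.0), "4": (1, 1.0)}.get(code)
    if comp_sign is None or n == 0:
        return vals
    comp, sign = comp_sign
    side = sign * local[:, comp] > 0.0
    n_in, n_out = int(side.sum()), int((~side).sum())
    if n_in == 0 or n_out == 0:   # degenerate split: fall back to uniform
        return vals
    vals[side] = total * enrichment / n_in
    vals[~side] = total * (1.0 - enrichment) / n_out
    return vals


def generate_root(params: SyntheticParams, seed: int):
    """Rasterize the synthetic root.

    Returns ``(stack, labels, truth)``: a 5-channel
    :class:`~rootcarto.stack.VoxelStack` ("dna", "euchromatin",
    "heterochromatin", "edu", "wall"), an integer label volume aligned
    with it, and the ground-truth table (with ``volume_um3`` replaced by
    the exact voxel-count volume of each label).
    """
    truth = plan_nuclei(params, seed)
    rng = np.random.default_rng(seed + 1)
    nz, ny, nx = params.shape
    dz, dy, dx = params.voxel_size
    vol_vox = dz * dy * dx

    labels = np.zeros(params.shape, dtype=np.int32)
    chans = {n: np.zeros(params.shape, dtype=np.float64)
             for n in ("dna", "euchromatin", "heterochromatin", "edu")}

    for row in truth.itertuples():
        axes = _nucleus_axes(params, row)            # rows: u_r, u_l, u_ax
        semi = np.array([row.semi_radial, row.semi_lateral, row.semi_axial])
        center = np.array([row.x, row.y, row.z])
        margin = semi.max() + params.edu_spot_radius_um + 0.5
        iz = np.arange(max(0, int((row.z - margin) / dz)), min(nz, int((row.z + margin) / dz) + 2))
        iy = np.arange(max(0, int((row.y - margin) / dy)), min(ny, int((row.y + margin) / dy) + 2))
        ix = np.arange(max(0, int((row.x - margin) / dx)), min(nx, int((row.x + margin) / dx) + 2))
        Z, Y, X = np.meshgrid(iz * dz, iy * dy, ix * dx, indexing="ij")
        disp = np.stack([X - center[0], Y - center[1], Z - center[2]], axis=-1)
        local = disp @ axes.T                         # (…, 3) radial/lateral/axial µm
        q = np.sum((local / semi) ** 2, axis=-1)
        mask = q <= 1.0
        sub = np.ix_(iz, iy, ix)
        if np.any(labels[sub][mask] != 0):
            raise PlacementError(f"nucleus {row.id} rasterizes onto an existing label")
        lab_block = labels[sub]
        lab_block[mask] = row.id
        labels[sub] = lab_block

        nucleolus = q <= params.nucleolus_fraction ** 2
        body = mask & ~nucleolus

        # chromocenters: antipodal pairs of peripheral speckles.  Directions
        # are the best of several random draws, maximizing the minimum
        # pairwise distance of the anisotropically scaled centres, so
        # speckles stay discrete even in flattened (trichoblast) nuclei.
        n_pairs = max(1, params.n_chromocenters // 2)
        best_centers, best_sep = None, -1.0
        for _ in range(40):
            # randomly rotated orthogonal triad (octahedral template):
            # pairs are antipodal and maximally spread before scaling
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            cand = q.T[:n_pairs] if n_pairs <= 3 else np.vstack(
                [q.T, rng.normal(size=(n_pairs - 3, 3))])
            cand = cand / np.linalg.norm(cand, axis=1, keepdims=True)
            dirs = np.concatenate([cand, -cand])[: params.n_chromocenters]
            centers = params.chromocenter_peripherality * dirs * semi
            if len(centers) > 1:
                dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
                sep = dists[np.triu_indices(len(centers), 1)].min()
            else:
                sep = np.inf
            if sep > best_sep:
                best_sep, best_centers = sep, centers
        cc_centers_local = best_centers
        cc = np.zeros_like(mask)
        for c_loc in cc_centers_local:
            d2 = np.sum((local - c_loc) ** 2, axis=-1)
            cc |= d2 <= params.chromocenter_radius_um ** 2
        cc &= body

        # DNA: weights normalized so the integral is exactly C * dna_per_c
        w = body.astype(np.float64) + (params.chromocenter_boost - 1.0) * cc
        wsum = w.sum()
        if wsum > 0:
            blk = chans["dna"][sub]
            blk += w * (row.c_value * params.dna_per_c / wsum)
            chans["dna"][sub] = blk

        e_code, h_code = str(row.config_code).split("_")
        flat_local = local[body]
        if len(flat_local):
            ev = _hemisphere_values(flat_local, e_code,
                                    row.c_value * params.euch_per_c, params.enrichment)
            blk = chans["euchromatin"][sub]
            bvals = blk[body]
            bvals += ev
            blk[body] = bvals
            chans["euchromatin"][sub] = blk
        cc_local = local[cc]
        if len(cc_local):
            hv = _hemisphere_values(cc_local, h_code,
                                    params.het_total, params.enrichment)
            blk = chans["heterochromatin"][sub]
            bvals = blk[cc]
            bvals += hv
            blk[cc] = bvals
            chans["heterochromatin"][sub] = blk

        if row.edu_pattern == "S1":
            blk = chans["edu"][sub]
            blk[body] += params.edu_s1_level
            chans["edu"][sub] = blk
        elif row.edu_pattern == "S2":
            spots = np.zeros_like(mask)
            for c_loc in cc_centers_local:
                d2 = np.sum((local - c_loc) ** 2, axis=-1)
                spots |= d2 <= params.edu_spot_radius_um ** 2
            spots &= mask
            blk = chans["edu"][sub]
            blk[spots] += params.edu_spot_level
            chans["edu"][sub] = blk

    # wall channel: Gaussian shells at the layer boundary radii
    wall = np.zeros(params.shape, dtype=np.float64)
    zz = (np.arange(nz) * dz)[:, None]
    yy = (np.arange(ny) * dy)[None, :]
    x_vals = np.arange(nx) * dx
    yc_arr, zc_arr = params.axis_center(x_vals)
    radii = list(params.layer_radii.values())
    for i, x in enumerate(x_vals):
        if x < params.qc_x_um - 6.0:
            continue
        r_grid = np.sqrt((yy - yc_arr[i]) ** 2 + (zz - zc_arr[i]) ** 2)
        plane = np.zeros_like(r_grid)
        for rad in radii:
            plane += params.wall_level * np.exp(
                -((r_grid - rad) ** 2) / (2.0 * params.wall_sigma_um**2))
        wall[:, :, i] = plane
    chans["wall"] = wall

    for name, arr in chans.items():
        arr = arr + params.background
        if params.sigma > 0:
            arr = arr + rng.normal(0.0, params.sigma, arr.shape)
        chans[name] = np.clip(arr, 0.0, params.bit_depth).astype(np.float32)

    # exact voxel-count volumes into the ground truth
    counts = np.bincount(labels.ravel(), minlength=len(truth) + 1)
    truth = truth.copy()
    truth["volume_um3"] = counts[truth["id"].to_numpy()] * vol_vox

    stack = VoxelStack(channels=chans, voxel_size=params.voxel_size,
                       bit_depth=params.bit_depth)
    return stack, labels, truth


# ------------------------------------------------------------- table mode

def generate_feature_table(params: SyntheticParams, seed: int):
    """Draw per-nucleus tables from the generative model without imaging.

    Returns ``(records, annotations, calls, truth)`` where ``records`` is a
    feature table statistically matching ideal extraction from
    :func:`generate_root`, ``annotations`` the true positional fate table,
    and ``calls`` the true replication/configuration calls.
    """
    truth = plan_nuclei(params, seed)
    rng = np.random.default_rng(seed + 2)
    n = len(truth)
    cv = params.intensity_cv

    def noisy(base):
        if cv <= 0:
            return np.asarray(base, float)
        return np.asarray(base, float) * np.clip(rng.normal(1.0, cv, n), 0.05, None)

    semi = truth[["semi_radial", "semi_lateral", "semi_axial"]].to_numpy(float)
    # bounding extents along the stack axes from the oriented ellipsoid
    ext = np.zeros((n, 3))
    for i, row in enumerate(truth.itertuples()):
        axes = _nucleus_axes(params, row)
        for k, e in enumerate(np.eye(3)):
            ext[i, k] = 2.0 * _support(semi[i], axes, e)

    a, b, c = semi.T
    p = 1.6075  # Thomsen's ellipsoid-surface approximation
    surface = 4 * math.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p)

    asym = rng.normal(0.0, 0.1, (n, 3))
    records = pd.DataFrame({
        "id": truth["id"],
        "centroid_x": truth["x"], "centroid_y": truth["y"], "centroid_z": truth["z"],
        # voxelization-like measurement noise on top of the analytic volume
        "volume_um3": truth["volume_um3"].to_numpy()
        * np.clip(rng.normal(1.0, params.volume_cv, n), 0.5, None),
        "surface_um2": surface,
        "width_um": ext[:, 0], "height_um": ext[:, 1], "depth_um": ext[:, 2],
        "asym_x": asym[:, 0], "asym_y": asym[:, 1], "asym_z": asym[:, 2],
        "asym_norm": np.linalg.norm(asym, axis=1),
        "intensity_dna": noisy(truth["c_value"] * params.dna_per_c),
        "intensity_euchromatin": noisy(truth["c_value"] * params.euch_per_c),
        "intensity_heterochromatin": noisy(np.full(n, params.het_total)),
    })
    for k, name in enumerate(("x", "y", "z")):
        records[f"com_dna_{name}"] = records[f"centroid_{name}"] - asym[:, k]

    s1 = truth["edu_pattern"] == "S1"
    s2 = truth["edu_pattern"] == "S2"
    spot_vol = 4 / 3 * math.pi * params.edu_spot_radius_um**3
    edu_int = np.zeros(n)
    edu_int[s1] = params.edu_s1_level * truth.loc[s1, "volume_um3"] * 0.95
    edu_int[s2] = params.edu_spot_level * spot_vol * truth.loc[s2, "spot_count"]
    coverage = np.zeros(n)
    coverage[s1] = 1.0 - params.nucleolus_fraction**3
    coverage[s2] = np.clip(spot_vol * truth.loc[s2, "spot_count"]
                           / truth.loc[s2, "volume_um3"], 0, 1)
    records["intensity_edu"] = noisy(edu_int)

    annotations = truth[["id", "layer", "file", "subtype", "zone", "s", "r", "phi"]].copy()
    annotations = annotations.rename(columns={"s": "z_cyl", "r": "r_cyl", "phi": "phi_cyl"})
    calls = pd.DataFrame({
        "id": truth["id"],
        "pattern": truth["edu_pattern"],
        "coverage": coverage,
        "n_spots": truth["spot_count"],
        "integrated_edu": records["intensity_edu"],
        "config_code": truth["config_code"],
    })
    return records, annotations, calls, truth


# ------------------------------------------------------- mitotic figures

def generate_anaphase_pair(params: SyntheticParams | None = None, *,
                           separation_um: float = 6.0,
                           mass_semi_um: tuple[float, float, float] = (2.5, 2.5, 2.0),
                           shape: tuple[int, int, int] = (48, 48, 64),
                           voxel_um: float = 0.25,
                           het_distal_slope: float = 1.0,
                           euch_proximal_slope: float = 0.3,
                           base: float = 100.0):
    """Small synthetic late-anaphase figure for division-plane profiling.

    Two chromatin masses straddle a transverse division plane.  The
    heterochromatin channel increases with distance from the plane
    (pole-proximal heterochromatin), the euchromatin channel decreases.
    Returns ``(mask, channels, plane_point, plane_normal, voxel_size)``.
    """
    nz, ny, nx = shape
    zc, yc, xc = ((nz - 1) / 2, (ny - 1) / 2, (nx - 1) / 2)
    Z, Y, X = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij")
    x_um = (X - xc) * voxel_um
    y_um = (Y - yc) * voxel_um
    z_um = (Z - zc) * voxel_um
    a, b, c = mass_semi_um
    half = separation_um / 2.0
    mask = ((x_um - half) ** 2 / c**2 + y_um**2 / a**2 + z_um**2 / b**2 <= 1.0) | (
        (x_um + half) ** 2 / c**2 + y_um**2 / a**2 + z_um**2 / b**2 <= 1.0)
    dist = np.abs(x_um)
    het = np.where(mask, base * (1.0 + het_distal_slope * dist), 0.0)
    euch = np.where(mask, base * np.clip(1.0 - euch_proximal_slope * dist / (half + c), 0.05, None) * 2.0, 0.0)
    plane_point = np.array([xc * voxel_um, yc * voxel_um, zc * voxel_um])
    plane_normal = np.array([1.0, 0.0, 0.0])
    channels = {"heterochromatin": het, "euchromatin": euch}
    return mask, channels, plane_point, plane_normal, (voxel_um,) * 3
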