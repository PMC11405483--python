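"""EdU S-phase pattern classification and spatial clustering statistics.

Replication patterns per nucleus:

* **S0** — no EdU incorporation: mean in-mask EdU at or below the noise
  floor (background mean + k·SD measured outside all nuclei);
* **S1** — homogeneous staining: EdU-positive coverage of the nucleus
  mask at or above the coverage threshold (early S phase, euchromatin
  replicating everywhere);
* **S2** — spotted staining: low coverage but at least ``min_spots``
  local maxima above the floor (late S phase, heterochromatin foci).

A nucleus matching neither the S1 coverage rule nor the S2 spot rule is
called S0 and flagged; mixed appearances resolve to S1 whenever coverage
reaches the threshold (dominance rule keeping the classes exclusive).

Cluster statistics: within each longitudinal cell file, nuclei ordered by
axial position form a sequence of states; maximal same-state runs are the
clusters.  Under i.i.d. labeling with probability p the run-length law of
the labeled state is geometric with success probability 1−p, which the
property tests exploit.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import PreconditionError
from .stack import VoxelStack

log = logging.getLogger(__name__)

PATTERNS = ("S0", "S1", "S2")


def noise_floor(stack: VoxelStack, labels: np.ndarray, k: float = 3.0,
                channel: str = "edu") -> float:
    """Background mean + k·SD of the channel outside every nucleus."""
    vals = np.asarray(stack.channel(channel), float)[np.asarray(labels) == 0]
    if len(vals) == 0:
        raise PreconditionError("no background voxels to calibrate the noise floor")
    return float(vals.mean() + k * vals.std())


def classify_edu_pattern(nucleus_id: int, stack: VoxelStack, labels: np.ndarray,
                         floor: float, coverage_threshold: float = 0.6,
                         min_spots: int = 3, min_spot_voxels: int = 2,
                         bbox=None):
    """Classify one nucleus; returns ``(call_dict, spots)``.

    ``call_dict`` has pattern, integrated EdU, coverage and spot count;
    ``spots`` is a list of (centroid_xyz_um, integrated_intensity) for
    detected EdU foci.  Foci are connected components (26-connectivity)
    of EdU-positive voxels inside the mask with at least
    ``min_spot_voxels`` voxels — robust to the flat-topped intensity
    profiles of replication foci, where local-maximum detection merges or
    fragments spots.
    """
    labels = np.asarray(labels)
    if bbox is None:
        objs = ndimage.find_objects((labels == nucleus_id).astype(np.int8))
        if not objs or objs[0] is None:
            raise PreconditionError(f"label {nucleus_id} not present")
        bbox = objs[0]
    sl = bbox
    mask = labels[sl] == nucleus_id
    if not mask.any():
        raise PreconditionError(f"label {nucleus_id} not present")
    edu = np.asarray(stack.channel("edu"), float)[sl]
    vals = edu[mask]
    integrated = float(vals.sum())
    coverage = float((vals > floor).mean())
    dz, dy, dx = stack.voxel_size
    call = {"id": int(nucleus_id), "integrated_edu": integrated,
            "coverage": coverage, "n_spots": 0, "flag": ""}
    spots: list[tuple[np.ndarray, float]] = []
    if vals.mean() <= floor:
        call["pattern"] = "S0"
        return call, spots
    if coverage >= coverage_threshold:
        call["pattern"] = "S1"
        return call, spots
    positive = mask & (edu > floor)
    comp, n_comp = ndimage.label(positive,
                                 structure=ndimage.generate_binary_structure(3, 3))
    for cid in range(1, n_comp + 1):
        where = comp == cid
        if int(where.sum()) < min_spot_voxels:
            continue
        intensity = float(edu[where].sum())
        zz, yy, xx = np.nonzero(where)
        centroid = np.array([(sl[2].start + xx.mean()) * dx,
                             (sl[1].start + yy.mean()) * dy,
                             (sl[0].start + zz.mean()) * dz])
        spots.append((centroid, intensity))
    call["n_spots"] = len(spots)
    if len(spots) >= min_spots:
        call["pattern"] = "S2"
    else:
        call["pattern"] = "S0"
        call["flag"] = "positive_but_unclassified"
        spots = []
    return call, spots


def classify_all(stack: VoxelStack, labels: np.ndarray, noise_k: float = 3.0,
                 coverage_threshold: float = 0.6, min_spots: int = 3,
                 min_spot_voxels: int = 2):
    """Classify every labeled nucleus; returns ``(calls, spots)`` tables."""
    stack.require("edu")
    labels = np.asarray(labels)
    floor = noise_floor(stack, labels, k=noise_k)
    objects = ndimage.find_objects(labels)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    calls, spot_rows = [], []
    for nid in ids:
        call, spots = classify_edu_pattern(int(nid), stack, labels, floor,
                                           coverage_threshold, min_spots,
                                           min_spot_voxels,
                                           bbox=objects[int(nid) - 1])
        calls.append(call)
        for centroid, intensity in spots:
            spot_rows.append({"id": int(nid), "x": centroid[0], "y": centroid[1],
                              "z": centroid[2], "integrated_intensity": intensity})
    calls_df = pd.DataFrame(calls)
    calls_df.attrs["noise_floor"] = floor
    return calls_df, pd.DataFrame(spot_rows)


# ---------------------------------------------------------- time courses

def pattern_timecourse(tables: dict[float, pd.DataFrame]) -> dict:
    """Pattern composition across EdU incubation times.

    ``tables`` maps incubation time (min) to a calls table.  Returns the
    proportion table, a chi-squared test of homogeneity of the S0/S1/S2
    composition across times, and the labeled-fraction trend.
    """
    if len(tables) < 2:
        raise PreconditionError("need ≥ 2 time points")
    times = sorted(tables)
    counts = np.zeros((len(times), len(PATTERNS)), dtype=int)
    for i, t in enumerate(times):
        vc = tables[t]["pattern"].value_counts()
        counts[i] = [int(vc.get(p, 0)) for p in PATTERNS]
    keep = counts.sum(axis=1) > 0
    if not keep.all():
        log.warning("dropping empty strata at times %s",
                    [t for t, k in zip(times, keep) if not k])
        times = [t for t, k in zip(times, keep) if k]
        counts = counts[keep]
    col_keep = counts.sum(axis=0) > 0
    stat, p, dof, _ = stats.chi2_contingency(counts[:, col_keep], correction=False)
    props = counts / counts.sum(axis=1, keepdims=True)
    labeled = props[:, 1] + props[:, 2]
    monotone = bool(np.all(np.diff(labeled) >= 0))
    return {
        "times": times,
        "proportions": pd.DataFrame(props, index=times, columns=PATTERNS),
        "counts": pd.DataFrame(counts, index=times, columns=PATTERNS),
        "statistic": float(stat), "pvalue": float(p), "df": int(dof),
        "labeled_fraction": labeled, "labeled_fraction_monotone": monotone,
    }


def chi2_homogeneity(counts_a, counts_b) -> tuple[float, int, float]:
    """Chi-squared test of homogeneity on a 2×k count table (no continuity
    correction)."""
    table = np.array([counts_a, counts_b], dtype=float)
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


# ------------------------------------------------------- mark overlap

def mark_overlap_by_pattern(calls: pd.DataFrame, stack: VoxelStack,
                            labels: np.ndarray,
                            marks=("euchromatin", "heterochromatin"),
                            noise_k: float = 3.0) -> pd.DataFrame:
    """Fraction of EdU-positive voxels that are mark-positive, per nucleus.

    Mark thresholds are background mean + k·SD outside nuclei (same rule
    as the EdU noise floor).  Only S1/S2 nuclei are measured; an S1/S2
    nucleus without a single EdU-positive voxel is an inconsistent call.
    """
    stack.require("edu", *marks)
    labels = np.asarray(labels)
    edu_floor = noise_floor(stack, labels, k=noise_k, channel="edu")
    mark_floors = {m: noise_floor(stack, labels, k=noise_k, channel=m) for m in marks}
    edu = np.asarray(stack.channel("edu"), float)
    mark_arrays = {m: np.asarray(stack.channel(m), float) for m in marks}
    objects = ndimage.find_objects(labels)
    rows = []
    for rec in calls.itertuples():
        if rec.pattern == "S0":
            continue
        sl = objects[int(rec.id) - 1]
        mask = labels[sl] == rec.id
        epos = mask & (edu[sl] > edu_floor)
        n_epos = int(epos.sum())
        if n_epos == 0:
            raise PreconditionError(
                f"nucleus {rec.id} called {rec.pattern} but has no EdU-positive voxels")
        row = {"id": rec.id, "pattern": rec.pattern, "n_edu_pos": n_epos}
        for m in marks:
            mpos = mark_arrays[m][sl] > mark_floors[m]
            row[f"overlap_{m}"] = float((epos & mpos).sum() / n_epos)
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_overlap(overlap: pd.DataFrame, marks=("euchromatin", "heterochromatin")):
    """Group means with 95% t-CIs of mark overlap by pattern."""
    rows = []
    for pattern, grp in overlap.groupby("pattern"):
        for m in marks:
            vals = grp[f"overlap_{m}"].to_numpy(float)
            mean = vals.mean()
            if len(vals) > 1:
                half = stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / math.sqrt(len(vals))
            else:
                half = math.nan
            rows.append({"pattern": pattern, "mark": m, "mean_overlap": mean,
                         "ci_low": mean - half, "ci_high": mean + half,
                         "n": len(vals)})
    return pd.DataFrame(rows)


# --------------------------------------------------- run-length clustering

def run_lengths(sequence) -> list[tuple[object, int]]:
    """Maximal same-state runs of a sequence: [(state, length), ...]."""
    out: list[tuple[object, int]] = []
    for item in sequence:
        if out and out[-1][0] == item:
            out[-1] = (item, out[-1][1] + 1)
        else:
            out.append((item, 1))
    return out


@dataclass
class ClusterDistribution:
    """Run-length histograms of same-state clusters along cell files."""

    counts: dict[str, Counter] = field(default_factory=dict)

    def add_run(self, state: str, length: int) -> None:
        self.counts.setdefault(state, Counter())[length] += 1

    def histogram(self, state: str) -> dict[int, int]:
        return dict(sorted(self.counts.get(state, Counter()).items()))

    def mean_run_length(self, state: str) -> float:
        c = self.counts.get(state, Counter())
        total = sum(c.values())
        return sum(k * v for k, v in c.items()) / total if total else math.nan

    def total_runs(self, state: str) -> int:
        return sum(self.counts.get(state, Counter()).values())

    def nuclei(self, state: str) -> int:
        """Σ(length × count): number of nuclei in that state (conservation)."""
        return sum(k * v for k, v in self.counts.get(state, Counter()).items())


def file_run_lengths(annotations: pd.DataFrame, calls: pd.DataFrame,
                     state_groups=(("S0",), ("S1", "S2")),
                     zone: str | None = None) -> ClusterDistribution:
    """Run-length distribution of replication states along cell files.

    Nuclei are ordered by axial position within each (layer, file)
    sequence (ties broken by id, deterministically); patterns are mapped
    to the requested state groups and maximal runs pooled across files.
    ``zone`` restricts to one zone before run extraction.
    """
    merged = annotations.merge(calls[["id", "pattern"]], on="id", how="inner")
    if zone is not None:
        if "zone" not in merged.columns:
            raise PreconditionError("zone restriction requires zone annotations")
        merged = merged[merged["zone"] == zone]
    group_of = {}
    names = {}
    for grp in state_groups:
        name = "+".join(grp)
        names[name] = grp
        for state in grp:
            group_of[state] = name
    dist = ClusterDistribution()
    for (_, _), g in merged.groupby(["layer", "file"]):
        if g["z_cyl"].duplicated().any():
            log.warning("tied axial positions in a file; ordering by id")
        ordered = g.sort_values(["z_cyl", "id"])
        seq = [group_of.get(p) for p in ordered["pattern"] if p in group_of]
        for state, length in run_lengths(seq):
            if state is not None:
                dist.add_run(state, length)
    return dist


def compare_cluster_distributions(d1: ClusterDistribution, d2: ClusterDistribution,
                                  state: str, min_expected: float = 5.0):
    """Chi-squared homogeneity test of two run-length histograms.

    Histograms are binned on the union of observed run lengths and
    tail-pooled (from the longest run down) until every expected count
    reaches ``min_expected``.  Returns ``(statistic, df, pvalue)``;
    a single shared bin is degenerate and returns p = 1.
    """
    h1, h2 = d1.histogram(state), d2.histogram(state)
    if not h1 or not h2:
        raise PreconditionError("both histograms must be non-empty")
    lengths = sorted(set(h1) | set(h2))
    a = np.array([h1.get(k, 0) for k in lengths], float)
    b = np.array([h2.get(k, 0) for k in lengths], float)
    # tail-pool from the right until all expected counts are adequate
    while len(a) > 1:
        table = np.array([a, b])
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
        if expected.min() >= min_expected:
            break
        a = np.concatenate([a[:-2], [a[-2] + a[-1]]])
        b = np.concatenate([b[:-2], [b[-2] + b[-1]]])
    if len(a) == 1:
        return 0.0, 0, 1.0
    stat, p, dof, _ = stats.chi2_contingency(np.array([a, b]), correction=False)
    return float(stat), int(dof), float(p)
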