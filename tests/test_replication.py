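import itertools
import math

import numpy as np
import pandas as pd
import pytest

import rootcarto as rc
from rootcarto import ClusterDistribution, VoxelStack
from rootcarto.errors import PreconditionError
from rootcarto.replication import run_lengths

from oracles import run_lengths_oracle


# ------------------------------------------------------------ classification

def _tiny_stack(edu_values, mask):
    chans = {"dna": np.where(mask, 100.0, 0.0), "edu": edu_values}
    return VoxelStack(channels=chans, voxel_size=(1, 1, 1))


def test_zero_edu_is_s0():
    mask = np.zeros((10, 10, 10), bool)
    mask[3:7, 3:7, 3:7] = True
    labels = mask.astype(np.int32)
    stack = _tiny_stack(np.zeros(mask.shape), mask)
    calls, _ = rc.classify_all(stack, labels)
    assert calls["pattern"].tolist() == ["S0"]


def test_generator_patterns_recovered(noisy_root):
    stack, labels, truth = noisy_root
    calls, spots = rc.classify_all(stack, labels)
    m = calls.merge(truth[["id", "edu_pattern"]], on="id")
    assert (m["pattern"] == m["edu_pattern"]).mean() >= 0.95


def test_spot_counts_match_generation():
    """Round S2 nuclei report the generated focus count within ±1."""
    params = rc.SyntheticParams(
        files_per_layer={"cortex": 2}, columella_nuclei=0,
        edu_probs={z: (0.0, 0.0, 1.0) for z in ("PD", "TD", "EZ")},
        volume_growth_per_um={})
    stack, labels, truth = rc.generate_root(params, 3)
    calls, spots = rc.classify_all(stack, labels)
    m = calls.merge(truth[["id", "spot_count"]], on="id")
    ok = (m["n_spots"] - m["spot_count"]).abs() <= 1
    assert ok.mean() >= 0.9
    assert (m["pattern"] == "S2").all()
    # spot table is consistent with the calls
    assert len(spots) == m["n_spots"].sum()


def test_classification_invariant_to_intensity_rescaling(noisy_root):
    """Thresholds are background-calibrated, so scaling the EdU channel
    (signal and background together) changes no call."""
    stack, labels, truth = noisy_root
    calls1, _ = rc.classify_all(stack, labels)
    scaled = VoxelStack(
        channels={**stack.channels, "edu": stack.channel("edu") * 11.0},
        voxel_size=stack.voxel_size, bit_depth=stack.bit_depth * 11)
    calls2, _ = rc.classify_all(scaled, labels)
    assert (calls1["pattern"] == calls2["pattern"]).all()


def test_missing_edu_channel_is_an_error():
    mask = np.zeros((6, 6, 6), bool)
    mask[2:4, 2:4, 2:4] = True
    stack = VoxelStack(channels={"dna": mask.astype(float)}, voxel_size=(1, 1, 1))
    with pytest.raises(rc.ChannelError):
        rc.classify_all(stack, mask.astype(np.int32))


# --------------------------------------------------------------- time course

def test_identical_composition_is_homogeneous():
    calls = pd.DataFrame({"pattern": ["S0"] * 30 + ["S1"] * 15 + ["S2"] * 5})
    out = rc.pattern_timecourse({45: calls, 90: calls.copy(), 300: calls.copy()})
    assert out["statistic"] == pytest.approx(0.0)
    assert out["pvalue"] == pytest.approx(1.0)
    assert out["labeled_fraction_monotone"]


def test_hand_computed_two_by_two_homogeneity():
    """Counts ((20,80),(60,40)) give the classical χ² = 33.33 without
    continuity correction."""
    stat, dof, p = rc.chi2_homogeneity([20, 80], [60, 40])
    assert stat == pytest.approx(200 * (20 * 40 - 80 * 60) ** 2
                                 / (100 * 100 * 80 * 120))
    assert stat == pytest.approx(33.3333, rel=1e-4)
    assert dof == 1 and p < 1e-6


def test_labeled_fraction_rises_with_time():
    rng = np.random.default_rng(0)
    tables = {}
    for t, p_lab in [(45, 0.2), (90, 0.4), (300, 0.6)]:
        lab = rng.random(300) < p_lab
        pat = np.where(lab, np.where(rng.random(300) < 0.8, "S1", "S2"), "S0")
        tables[t] = pd.DataFrame({"pattern": pat})
    out = rc.pattern_timecourse(tables)
    assert out["pvalue"] < 1e-6
    assert out["labeled_fraction_monotone"]


def test_single_time_point_rejected():
    with pytest.raises(PreconditionError):
        rc.pattern_timecourse({45: pd.DataFrame({"pattern": ["S0"]})})


# -------------------------------------------------------------- mark overlap

def test_overlap_extremes_for_identical_and_disjoint_masks():
    shape = (8, 8, 16)
    mask = np.zeros(shape, bool)
    mask[2:6, 2:6, 2:14] = True
    labels = mask.astype(np.int32)
    edu = np.where(mask, 100.0, 0.0)
    identical = VoxelStack(channels={"edu": edu, "euchromatin": edu.copy(),
                                     "heterochromatin": np.zeros(shape)},
                           voxel_size=(1, 1, 1))
    calls = pd.DataFrame({"id": [1], "pattern": ["S1"]})
    out = rc.mark_overlap_by_pattern(calls, identical, labels)
    assert out["overlap_euchromatin"].iloc[0] == 1.0
    assert out["overlap_heterochromatin"].iloc[0] == 0.0


def test_s2_colocalizes_with_heterochromatin(noisy_root):
    """EdU foci sit on chromocenters, so S2×heterochromatin overlap
    exceeds S1×heterochromatin overlap."""
    stack, labels, truth = noisy_root
    calls, _ = rc.classify_all(stack, labels)
    overlap = rc.mark_overlap_by_pattern(calls, stack, labels)
    summary = rc.summarize_overlap(overlap)
    het = summary[summary["mark"] == "heterochromatin"].set_index("pattern")
    assert het.loc["S2", "mean_overlap"] > het.loc["S1", "mean_overlap"]


# ---------------------------------------------------------------- run lengths

def test_run_length_definition():
    assert run_lengths(["S1", "S1", "S0", "S1"]) == [("S1", 2), ("S0", 1), ("S1", 1)]


def test_exhaustive_oracle_up_to_length_12():
    for n in range(1, 13):
        for seq in itertools.product("ab", repeat=n):
            assert run_lengths(seq) == run_lengths_oracle(seq)


def _single_file_tables(patterns):
    n = len(patterns)
    ann = pd.DataFrame({"id": np.arange(n), "layer": "epidermis", "file": 0,
                        "z_cyl": np.arange(n, dtype=float)})
    calls = pd.DataFrame({"id": np.arange(n), "pattern": patterns})
    return ann, calls


def test_file_run_length_conservation(noisy_root):
    """Σ(length × count) per state equals the number of nuclei in that
    state — on generator truth, any zone restriction aside."""
    _, _, truth = noisy_root
    ann = truth.rename(columns={"s": "z_cyl"})[["id", "layer", "file", "z_cyl"]]
    calls = truth.rename(columns={"edu_pattern": "pattern"})[["id", "pattern"]]
    dist = rc.file_run_lengths(ann, calls)
    counts = calls["pattern"].value_counts()
    assert dist.nuclei("S0") == counts.get("S0", 0)
    assert dist.nuclei("S1+S2") == counts.get("S1", 0) + counts.get("S2", 0)


def test_iid_labeling_follows_geometric_law():
    """Bernoulli(p=0.3) labeling of 10⁴ nuclei: labeled run lengths match
    the geometric law within 3 SE per bin."""
    rng = np.random.default_rng(0)
    p = 0.3
    labels = rng.random(10_000) < p
    patterns = np.where(labels, "S1", "S0")
    ann, calls = _single_file_tables(patterns)
    dist = rc.file_run_lengths(ann, calls)
    hist = dist.histogram("S1+S2")
    n_runs = dist.total_runs("S1+S2")
    for k in range(1, 8):
        prob = p ** (k - 1) * (1 - p)
        expected = n_runs * prob
        se = math.sqrt(n_runs * prob * (1 - prob))
        assert abs(hist.get(k, 0) - expected) <= 3 * se


def test_block_labeling_lengthens_runs():
    """Generator-imposed clustering (block labeling) lifts the mean run
    length above the i.i.d. expectation 1/(1−p)."""
    rng = np.random.default_rng(1)
    blocks = []
    while len(blocks) < 5000:
        state = "S1" if rng.random() < 0.3 else "S0"
        blocks.extend([state] * rng.integers(2, 6))
    ann, calls = _single_file_tables(np.array(blocks[:5000]))
    dist = rc.file_run_lengths(ann, calls)
    p_hat = (np.array(blocks[:5000]) == "S1").mean()
    assert dist.mean_run_length("S1+S2") > 1 / (1 - p_hat)


def test_zone_restriction_applies_before_extraction():
    ann, calls = _single_file_tables(["S1"] * 4 + ["S0"] * 4)
    ann["zone"] = ["PD"] * 4 + ["EZ"] * 4
    dist = rc.file_run_lengths(ann, calls, zone="PD")
    assert dist.histogram("S1+S2") == {4: 1}
    assert dist.histogram("S0") == {}


# ------------------------------------------------- distribution comparison

def _dist_from_hist(hist):
    d = ClusterDistribution()
    for k, v in hist.items():
        for _ in range(v):
            d.add_run("S", k)
    return d


def test_identical_histograms_are_homogeneous():
    d = _dist_from_hist({1: 50, 2: 30, 3: 10})
    stat, dof, p = rc.compare_cluster_distributions(d, d, "S")
    assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)


def test_disjoint_histograms_reject():
    """{1:100} vs {5:100} pools to a 2×2 table with χ² = 200."""
    stat, dof, p = rc.compare_cluster_distributions(
        _dist_from_hist({1: 100}), _dist_from_hist({5: 100}), "S")
    assert stat == pytest.approx(200.0)
    assert p < 1e-6


def test_degenerate_single_bin_is_p_one():
    stat, dof, p = rc.compare_cluster_distributions(
        _dist_from_hist({1: 40}), _dist_from_hist({1: 60}), "S")
    assert p == 1.0


def test_homogeneity_type_one_error_is_nominal():
    """Two samples from one Bernoulli labeling process are called
    different at ~α."""
    rng = np.random.default_rng(2)
    n_sim, rejections = 300, 0
    for _ in range(n_sim):
        dists = []
        for _ in range(2):
            patterns = np.where(rng.random(400) < 0.3, "S1", "S0")
            ann, calls = _single_file_tables(patterns)
            dists.append(rc.file_run_lengths(ann, calls))
        _, _, p = rc.compare_cluster_distributions(dists[0], dists[1], "S1+S2")
        rejections += p < 0.05
    assert abs(rejections / n_sim - 0.05) < 0.03
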