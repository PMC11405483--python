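import math

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

import rootcarto as rc
from rootcarto.chromatin import ALL_JOINT_CODES, mark_orientation
from rootcarto.errors import PreconditionError

from conftest import qc_position


# ------------------------------------------------------ hue colocalization

def test_low_hue_pixels_count_as_exclusive_red():
    # g/r chosen so the composite hue is 10 on the 0–255 scale
    red = np.array([[100.0]])
    green = np.array([[100.0 * 10 / 42.5]])
    summary = rc.hue_overlap_fractions(red, green)
    assert summary.red_exclusive == 1.0


def test_pure_green_is_exclusive_green():
    summary = rc.hue_overlap_fractions(np.zeros((4, 4)), np.full((4, 4), 100.0))
    assert summary.fractions() == (0.0, 0.0, 1.0)


def test_identical_channels_fall_entirely_in_overlay():
    chan = np.random.default_rng(0).uniform(1, 50, (10, 10))
    summary = rc.hue_overlap_fractions(chan, chan)
    assert summary.overlap == 1.0


def test_fractions_sum_to_one_and_scale_invariant():
    rng = np.random.default_rng(1)
    for _ in range(10):
        red = rng.uniform(0, 100, (12, 12))
        green = rng.uniform(0, 100, (12, 12))
        s1 = rc.hue_overlap_fractions(red, green)
        assert sum(s1.fractions()) == pytest.approx(1.0)
        s2 = rc.hue_overlap_fractions(17.3 * red, 17.3 * green)
        assert s1.fractions() == pytest.approx(s2.fractions())


def test_empty_mask_is_an_error():
    with pytest.raises(PreconditionError):
        rc.hue_overlap_fractions(np.ones((3, 3)), np.ones((3, 3)),
                                 mask=np.zeros((3, 3), bool))


# ------------------------------------------------------ peripheral profiles

def _ball(radius=8, size=24):
    zz, yy, xx = np.mgrid[:size, :size, :size]
    c = (size - 1) / 2
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def test_uniform_intensity_gives_constant_profile():
    mask = _ball()
    arc, vals = rc.peripheral_profile(mask, np.where(mask, 50.0, 0.0))
    assert np.ptp(vals) <= 1e-9 or vals.std() / vals.mean() < 0.05


def test_single_chromocenter_peaks_at_its_azimuth():
    """One peripheral focus produces one profile peak within one arc step
    of the focus azimuth."""
    mask = _ball(radius=9)
    c = (24 - 1) / 2
    theta = 0.8
    cy = c + 7.5 * math.sin(theta)
    cx = c + 7.5 * math.cos(theta)
    zz, yy, xx = np.mgrid[:24, :24, :24]
    speck = ((zz - c) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) <= 4.0
    chan = np.where(mask & speck, 500.0, 0.0)
    arc, vals = rc.peripheral_profile(mask, chan, n_samples=72)
    # profile starts at the smallest polar angle; peak index → azimuth
    peak_frac = np.argmax(vals) / 72
    assert abs(peak_frac * 2 * math.pi - theta) < 2 * (2 * math.pi / 72) + 0.15


def test_profile_rotation_equivariance():
    """Rotating the nucleus by 90° in-plane shifts the profile circularly
    by a quarter of the samples (cross-correlation peak at the shift)."""
    rng = np.random.default_rng(2)
    mask = _ball(radius=9)
    chan = np.where(mask, rng.uniform(0, 100, mask.shape), 0.0)
    arc, p0 = rc.peripheral_profile(mask, chan, n_samples=72)
    mask_r = np.rot90(mask, k=1, axes=(1, 2))
    chan_r = np.rot90(chan, k=1, axes=(1, 2))
    _, p1 = rc.peripheral_profile(mask_r, chan_r, n_samples=72)
    xc = [np.corrcoef(np.roll(p1, -s), p0)[0, 1] for s in range(72)]
    best = int(np.argmax(xc))
    assert min(abs(best - 18), abs(best - 54)) <= 2


def test_shared_speckles_correlate_across_channels():
    """DNA and heterochromatin profiles of a nucleus with shared
    peripheral chromocenters correlate strongly (favourable geometry:
    large nucleus, peripheral foci on the reference line)."""
    params = rc.SyntheticParams(
        sigma=0.0, background=0.0,
        nucleus_semiaxes_um=(4.0, 4.0, 4.0), files_per_layer={"vascular": 1},
        columella_nuclei=0, spacing_um=12.0, shape=(64, 64, 128),
        chromocenter_peripherality=0.85, chromocenter_radius_um=1.0,
        config_distribution={"uniform_uniform": 1.0},  # unpolarized marks
        volume_growth_per_um={})
    stack, labels, truth = rc.generate_root(params, 1)
    objs = ndimage.find_objects(labels)
    corrs = []
    for nid in truth["id"]:
        sl = objs[int(nid) - 1]
        mask = labels[sl] == int(nid)
        _, p_dna = rc.peripheral_profile(mask, stack.channel("dna")[sl])
        _, p_het = rc.peripheral_profile(mask, stack.channel("heterochromatin")[sl])
        corrs.append(rc.profile_correlation(p_dna, p_het))
    assert np.median(corrs) >= 0.8


def test_degenerate_masks_rejected():
    thin = np.zeros((6, 12, 12), bool)
    thin[2, 5:7, 5:7] = True
    with pytest.raises(PreconditionError):
        rc.peripheral_profile(thin, np.ones_like(thin, float))
    assert math.isnan(rc.profile_correlation(np.ones(10), np.arange(10.0)))


# --------------------------------------------------- configuration codes

def _mark_cloud(side):
    """Voxel cloud of a ball with values confined to one axial half."""
    rng = np.random.default_rng(0)
    coords = rng.uniform(-5, 5, (4000, 3))
    coords = coords[np.linalg.norm(coords, axis=1) <= 5]
    vals = np.where(side * coords[:, 2] > 0, 10.0, 0.0)  # axial = column 2
    return coords, vals


def test_opposed_marks_code_definition():
    axial = np.array([1.0, 0, 0])
    lateral = np.array([0, 1.0, 0])
    coords_e = np.array([[1.0, 0, 0], [2.0, 0.5, 0]])   # shootward (+axial)
    coords_h = np.array([[-1.0, 0, 0], [-2.0, -0.5, 0]])
    centroid = np.zeros(3)
    e_code, _ = mark_orientation(coords_e, np.ones(2), centroid, axial, lateral, 0.55)
    h_code, _ = mark_orientation(coords_h, np.ones(2), centroid, axial, lateral, 0.55)
    assert (e_code, h_code) == ("2", "1")
    # mirrored input through the transverse plane swaps the codes
    e_m, _ = mark_orientation(coords_e * [-1, 1, 1], np.ones(2), centroid,
                              axial, lateral, 0.55)
    h_m, _ = mark_orientation(coords_h * [-1, 1, 1], np.ones(2), centroid,
                              axial, lateral, 0.55)
    assert (e_m, h_m) == ("1", "2")


def test_uniform_marks_are_uniform():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-5, 5, (5000, 3))
    vals = np.ones(len(coords))
    code, fracs = mark_orientation(coords, vals, coords.mean(axis=0),
                                   np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), 0.55)
    assert code == "uniform"
    assert fracs["1"] + fracs["2"] == pytest.approx(1.0)
    assert fracs["3"] + fracs["4"] == pytest.approx(1.0)


def test_mirror_antisymmetry_is_exact():
    """Mirroring any voxel cloud through the transverse plane maps axial
    codes 1↔2 and leaves lateral codes fixed."""
    rng = np.random.default_rng(4)
    axial = np.array([1.0, 0, 0])
    lateral = np.array([0, 1.0, 0])
    swap = {"1": "2", "2": "1", "3": "3", "4": "4", "uniform": "uniform"}
    for _ in range(20):
        coords = rng.uniform(-4, 4, (500, 3))
        vals = rng.uniform(0, 1, 500) * (rng.random(500) < 0.5)
        if vals.sum() == 0:
            continue
        centroid = np.zeros(3)
        code, _ = mark_orientation(coords, vals, centroid, axial, lateral, 0.55)
        mirrored = coords * np.array([-1, 1, 1])
        code_m, _ = mark_orientation(mirrored, vals, centroid, axial, lateral, 0.55)
        assert code_m == swap[code]


def test_configuration_recovery_on_raster(noisy_params, noisy_root, noisy_frame):
    """Generator nuclei polarized at enrichment 0.8 recover their joint
    code in ≥90% of cases at threshold 0.55."""
    stack, labels, truth = noisy_root
    frame, _ = noisy_frame
    ids = truth["id"].to_numpy()[:150]
    calls = rc.classify_configurations(stack, labels, frame, ids=ids)
    m = calls.merge(truth[["id", "config_code"]], on="id", suffixes=("", "_true"))
    assert (m["config_code"] == m["config_code_true"]).mean() >= 0.90


def test_zero_mark_signal_is_an_error():
    with pytest.raises(PreconditionError):
        mark_orientation(np.ones((5, 3)), np.zeros(5), np.zeros(3),
                         np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), 0.55)


# ----------------------------------------------------- frequency analysis

def _calls_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    codes = [c for code, n in counts.items() for c in [code] * n]
    return pd.DataFrame({"config_code": codes})


def test_uniform_counts_give_null_statistic():
    calls = _calls_from_counts({c: 25 for c in ("1_2", "2_1", "1_1", "2_2")})
    out = rc.configuration_frequencies(calls, codes=["1_2", "2_1", "1_1", "2_2"])
    assert out.statistic == pytest.approx(0.0)
    assert out.pvalue == pytest.approx(1.0)


def test_hand_computed_chi_squared():
    """Counts (70,10,10,10) over 4 codes: Σ(O−E)²/E with E=25 is 108."""
    calls = _calls_from_counts({"1_2": 70, "2_1": 10, "1_1": 10, "2_2": 10})
    out = rc.configuration_frequencies(calls, codes=["1_2", "2_1", "1_1", "2_2"])
    assert out.statistic == pytest.approx(108.0)
    assert out.pvalue < 1e-6
    q = out.table.set_index("code")["q_binom"]
    assert q["1_2"] < 0.01 and q["2_1"] > 0.5


def test_uniform_null_type_one_error_is_nominal():
    """Chi-squared GOF on uniform-null draws rejects at ~5%."""
    rng = np.random.default_rng(0)
    n_sim, n = 400, 160
    rejections = 0
    for _ in range(n_sim):
        codes = rng.choice(list(ALL_JOINT_CODES), size=n)
        out = rc.configuration_frequencies(pd.DataFrame({"config_code": codes}))
        rejections += out.pvalue < 0.05
    assert abs(rejections / n_sim - 0.05) < 0.03


def test_sparse_counts_use_exact_fallback():
    calls = _calls_from_counts({"1_2": 20, "2_1": 10})
    out = rc.configuration_frequencies(
        calls, codes=[f"{a}_{b}" for a in "1234" for b in "1234"]
        + [f"x{i}" for i in range(20)])
    assert out.method == "monte-carlo multinomial"
    assert out.pvalue < 0.05


def test_too_few_calls_is_an_error():
    with pytest.raises(PreconditionError):
        rc.configuration_frequencies(_calls_from_counts({"1_2": 5}))


# ------------------------------------------------- anaphase region profiles

def test_uniform_intensity_gives_equal_bins():
    mask = np.ones((6, 6, 10), bool)
    chan = np.full(mask.shape, 7.0)
    out = rc.anaphase_region_intensity(mask, chan, (4.5, 2.5, 2.5), (1, 0, 0),
                                       nbins=3)
    assert np.allclose(out["mean_intensity"], 7.0)
    assert not out.attrs["one_sided"]


def test_single_bin_equals_masked_mean_per_side():
    rng = np.random.default_rng(5)
    mask = rng.random((8, 8, 12)) < 0.6
    chan = rng.uniform(0, 10, mask.shape)
    point, normal = (5.5, 3.5, 3.5), (1.0, 0, 0)
    out = rc.anaphase_region_intensity(mask, chan, point, normal, nbins=1)
    zz, yy, xx = np.nonzero(mask)
    d = xx - 5.5
    for side, sel in (("minus", d < 0), ("plus", d >= 0)):
        expect = chan[zz[sel], yy[sel], xx[sel]].mean()
        got = out.loc[out["side"] == side, "mean_intensity"].iloc[0]
        assert got == pytest.approx(expect)


def test_distal_heterochromatin_exceeds_proximal():
    mask, chans, point, normal, vs = rc.generate_anaphase_pair()
    het = rc.anaphase_region_intensity(mask, chans["heterochromatin"], point,
                                       normal, nbins=3, voxel_size=vs)
    for side, grp in het.groupby("side"):
        vals = grp.sort_values("bin")["mean_intensity"].to_numpy()
        assert vals[-1] > vals[0]
    euch = rc.anaphase_region_intensity(mask, chans["euchromatin"], point,
                                        normal, nbins=3, voxel_size=vs)
    for side, grp in euch.groupby("side"):
        vals = grp.sort_values("bin")["mean_intensity"].to_numpy()
        assert vals[-1] < vals[0]


def test_one_sided_mask_is_flagged():
    mask = np.zeros((4, 4, 10), bool)
    mask[:, :, 6:] = True
    out = rc.anaphase_region_intensity(mask, np.ones(mask.shape), (1.0, 1.5, 1.5),
                                       (1, 0, 0), nbins=2)
    assert out.attrs["one_sided"]
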