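"""Vortex/helix pattern scoring, ROI summaries, resolution study."""
import numpy as np
import pytest

from archflow4d.core import VelocityField4D, VoxelMask
from archflow4d.patterns import (PatternMatchParams, ScoreMaps, build_roi,
                                 pattern_maps, resolution_difference,
                                 run_resolution_study, summarize)
from archflow4d.patterns_reference import pattern_maps_reference
from archflow4d.phantom import (ArchSpec, FlowSpec, build_arch_centerline,
                                mirror_field, synthesize_flow, voxelize_arch)
from conftest import random_tube_field


@pytest.fixture(scope="module")
def helix_field(roman_flow_mask, roman_centerline):
    return synthesize_flow(roman_flow_mask, roman_centerline,
                           FlowSpec(helix_ratio=0.5, noise_sd=0.0,
                                    n_frames=4, seed=1))


@pytest.fixture(scope="module")
def analytic_tree(roman_centerline):
    return roman_centerline.to_tree(0.25)


# --------------------------------------------------------------------------
# scoring
# --------------------------------------------------------------------------

def test_optimized_scores_equal_naive_reference():
    """The accumulator implementation must agree with a direct per-voxel
    evaluation of the score definitions on random fields."""
    for seed in (0, 1):
        fld = random_tube_field(seed)
        opt = pattern_maps(fld)
        ref = pattern_maps_reference(fld)
        for name in ("vortex", "rh_helix", "lh_helix"):
            a = getattr(opt, name).astype(float)
            b = getattr(ref, name).astype(float)
            assert np.abs(a - b).max() < 1e-6


def test_uniform_flow_has_zero_vortex_score():
    # an unbounded uniform stream: lumen covers the whole grid so there
    # is no wall shear and the vorticity vanishes identically
    n = 20
    mask = VoxelMask(np.ones((n, n, n), bool), (1, 1, 1), (0, 0, 0))
    w = np.full((1, n, n, n), 50.0, dtype=np.float32)
    z = np.zeros_like(w)
    fld = VelocityField4D(z, z.copy(), w, (1, 1, 1), 25.0, mask)
    maps = pattern_maps(fld)
    assert maps.vortex.max() == 0.0


def test_solid_body_rotation_scores_near_one():
    n = 32
    ax = np.arange(n) - n // 2
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    core = X ** 2 + Y ** 2 <= 25.0
    mask = VoxelMask(core, (1, 1, 1), (0, 0, 0))
    u = (-4.0 * Y * core).astype(np.float32)[None]
    v = (4.0 * X * core).astype(np.float32)[None]
    w = np.zeros_like(u)
    fld = VelocityField4D(u, v, w, (1, 1, 1), 25.0, mask)
    maps = pattern_maps(fld)
    inner = (X ** 2 + Y ** 2 <= 9.0) & (np.abs(Z) < 10)
    assert maps.vortex[0][inner].mean() >= 0.9


def test_scores_bounded_on_seeded_random_fields():
    for seed in range(100):
        maps = pattern_maps(random_tube_field(seed, n=16, radius=6.0))
        for name in ("vortex", "rh_helix", "lh_helix"):
            arr = getattr(maps, name)
            assert arr.min() >= 0.0 and arr.max() <= 1.0
        # a voxel cannot be right- and left-handed at once
        assert (maps.rh_helix * maps.lh_helix).max() == 0.0


def test_mirroring_swaps_helix_handedness_exactly(helix_field):
    mirrored = mirror_field(helix_field, axis=0)
    a = pattern_maps(helix_field)
    b = pattern_maps(mirrored)
    assert np.array_equal(a.rh_helix, np.flip(b.lh_helix, axis=1))
    assert np.array_equal(a.lh_helix, np.flip(b.rh_helix, axis=1))
    assert np.array_equal(a.vortex, np.flip(b.vortex, axis=1))


def test_scores_equivariant_under_quarter_rotation(helix_field):
    """Rotating grid and vectors by 90 degrees about the superior axis
    permutes the score maps exactly."""
    rot_mask = VoxelMask(np.rot90(helix_field.lumen_mask.data,
                                  axes=(0, 1)).copy(),
                         helix_field.lumen_mask.spacing,
                         helix_field.lumen_mask.origin)
    # (x, y) -> (-y, x): u' = -v, v' = u
    u = np.stack([np.rot90(f, axes=(0, 1)) for f in -helix_field.v])
    v = np.stack([np.rot90(f, axes=(0, 1)) for f in helix_field.u])
    w = np.stack([np.rot90(f, axes=(0, 1)) for f in helix_field.w])
    rot = VelocityField4D(u.copy(), v.copy(), w.copy(),
                          helix_field.spacing, helix_field.frame_duration,
                          rot_mask)
    a = pattern_maps(helix_field)
    b = pattern_maps(rot)
    back = np.stack([np.rot90(f, axes=(1, 0)) for f in b.rh_helix])
    assert np.abs(a.rh_helix - back).max() < 1e-6


def test_helix_score_monotone_in_helix_ratio(roman_flow_mask,
                                             roman_centerline,
                                             analytic_tree):
    roi = build_roi(analytic_tree, roman_flow_mask)
    for seed in (0, 1, 2):
        values = []
        for ratio in (0.0, 0.1, 0.2, 0.4, 0.8):
            fld = synthesize_flow(roman_flow_mask, roman_centerline,
                                  FlowSpec(helix_ratio=ratio, noise_sd=2.0,
                                           n_frames=4, seed=seed))
            summary = summarize(pattern_maps(fld), roi, fld.flux_curve)
            values.append(summary["rh_helix"]["systole_mean"])
        assert all(np.diff(values) > 0), values


def test_helix_phantom_scores_right_handed(helix_field, analytic_tree):
    """A right-handed screw field scores in the right-handed channel
    only; the expected level follows from the swirl fraction of the
    construction (tangential/axial ~ helix_ratio away from the axis)."""
    roi = build_roi(analytic_tree, helix_field.lumen_mask)
    summary = summarize(pattern_maps(helix_field), roi,
                        helix_field.flux_curve)
    rh = summary["rh_helix"]["systole_mean"]
    lh = summary["lh_helix"]["systole_mean"]
    assert lh <= 0.05
    # swirl fraction upper bound hr/sqrt(1+hr^2) = 0.447 at ratio 0.5
    assert 0.1 < rh < 0.5


def test_vortex_score_monotone_in_vortex_strength(roman_flow_mask,
                                                  roman_centerline,
                                                  analytic_tree):
    roi = build_roi(analytic_tree, roman_flow_mask)
    arc = analytic_tree.bifurcations[-1].arc_position + 8.0
    values = []
    for strength in (5.0, 15.0, 30.0, 60.0):
        fld = synthesize_flow(
            roman_flow_mask, roman_centerline,
            FlowSpec(vortex={"arc_center": arc, "strength": strength,
                             "core_radius": 3.0},
                     noise_sd=0.0, n_frames=4))
        summary = summarize(pattern_maps(fld), roi, fld.flux_curve)
        values.append(summary["vortex"]["systole_mean"])
    assert all(np.diff(values) > 0), values


# --------------------------------------------------------------------------
# ROI
# --------------------------------------------------------------------------

def test_roi_interval_follows_bifurcations(analytic_tree, roman_flow_mask):
    roi = build_roi(analytic_tree, roman_flow_mask)
    b2 = analytic_tree.bifurcations[1].arc_position
    b3 = analytic_tree.bifurcations[2].arc_position
    assert roi.start_mm == pytest.approx(b2 + 1.0)
    assert roi.end_mm == pytest.approx(min(b3 + 20.0,
                                           analytic_tree.total_length))
    member = roi.member_mask(roman_flow_mask.data.shape)
    assert np.all(roman_flow_mask.data[member])  # ROI subset of lumen


def test_bovine_roi_starts_after_common_trunk():
    spec = ArchSpec.canonical("roman", bovine=True)
    cl = build_arch_centerline(spec)
    tree = cl.to_tree(0.25)
    mask = voxelize_arch(cl, 1.0)
    roi = build_roi(tree, mask)
    assert roi.start_mm == pytest.approx(
        tree.bifurcations[0].arc_position + 1.0)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def _const_maps(shape4, value, lumen):
    arr = np.full(shape4, value, dtype=np.float32)
    return ScoreMaps(arr, arr.copy(), arr.copy(), lumen, (1, 1, 1))


def test_constant_score_gives_equal_summaries(analytic_tree,
                                              roman_flow_mask):
    roi = build_roi(analytic_tree, roman_flow_mask)
    shape4 = (6,) + roman_flow_mask.data.shape
    maps = _const_maps(shape4, 0.37, roman_flow_mask.data)
    flux = np.array([1.0, 4.0, 2.0, 0.1, 0.1, 0.1])
    s = summarize(maps, roi, flux)
    for key in ("cycle_mean", "systole_mean", "diastole_mean", "peak"):
        assert s["vortex"][key] == pytest.approx(0.37, abs=1e-6)


def test_single_systolic_frame_score(analytic_tree, roman_flow_mask):
    roi = build_roi(analytic_tree, roman_flow_mask)
    shape4 = (5,) + roman_flow_mask.data.shape
    arr = np.zeros(shape4, dtype=np.float32)
    arr[1] = 0.8
    maps = ScoreMaps(arr, arr.copy(), arr.copy(), roman_flow_mask.data,
                     (1, 1, 1))
    flux = np.array([0.0, 5.0, 0.0, 0.0, 0.0])
    s = summarize(maps, roi, flux)
    assert s["vortex"]["diastole_mean"] == 0.0
    assert s["vortex"]["peak"] == pytest.approx(0.8, abs=1e-6)
    assert list(s.systole_frames) == [1]


def test_peak_at_least_cycle_mean_on_random_maps(analytic_tree,
                                                 roman_flow_mask):
    roi = build_roi(analytic_tree, roman_flow_mask)
    rng = np.random.default_rng(0)
    shape4 = (8,) + roman_flow_mask.data.shape
    for _ in range(100):
        arr = rng.random(shape4, dtype=np.float32)
        maps = ScoreMaps(arr, arr, arr, roman_flow_mask.data, (1, 1, 1))
        flux = rng.random(8) + 0.1
        s = summarize(maps, roi, flux)
        for name in ("vortex", "rh_helix", "lh_helix"):
            assert s[name]["peak"] >= s[name]["cycle_mean"] - 1e-9


# --------------------------------------------------------------------------
# resolution differences
# --------------------------------------------------------------------------

def test_resolution_difference_formula():
    ref = np.array([0.2, 0.4, 0.3, 0.1])
    assert resolution_difference(ref, ref) == 0.0
    assert resolution_difference(0.96 * ref, ref) == pytest.approx(-4.0)
    delta = 0.05
    assert resolution_difference(ref + delta, ref) == pytest.approx(
        100.0 * delta / ref.mean())
    with pytest.raises(ValueError):
        resolution_difference(ref, np.zeros(4))


def test_identical_fields_give_zero_differences(helix_field,
                                                analytic_tree):
    table = run_resolution_study(
        helix_field, analytic_tree,
        resolutions={"a": (1.0, 1.0, 1.0), "b": (1.0, 1.0, 1.0),
                     "clinical": (1.0, 1.0, 1.0)})
    diffs = table["difference_percent"].dropna()
    assert np.abs(diffs).max() < 1e-9


def test_degrading_resolution_changes_scores_consistently(
        roman_flow_mask, roman_centerline, analytic_tree):
    """The coarse acquisitions differ less from the clinical protocol
    than the fine 1 mm acquisition does (the clinical voxel averages
    2-3.6 mm), mirroring the behaviour of a physical flow phantom."""
    fld = synthesize_flow(
        roman_flow_mask, roman_centerline,
        FlowSpec(helix_ratio=0.3, noise_sd=1.0, n_frames=4, seed=2,
                 vortex={"arc_center":
                         analytic_tree.bifurcations[-1].arc_position + 8,
                         "strength": 25.0, "core_radius": 3.0}))
    table = run_resolution_study(fld, analytic_tree)
    vort = table[table.pattern == "vortex"].set_index("resolution")
    d1 = abs(vort.loc["iso1", "difference_percent"])
    d2 = abs(vort.loc["iso2", "difference_percent"])
    assert d2 < d1
    assert vort.loc["clinical", "difference_percent"] == 0.0
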