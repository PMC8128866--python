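import numpy as np
import pytest

from ciliaquant.pairing import STATUS_CONFIRMED
from ciliaquant.quantify import measure_image
from ciliaquant.synthgen import (
    GroundTruth,
    SceneSpec,
    generate_plate,
    generate_scene,
)


def test_same_seed_renders_bit_identical_scenes():
    spec = SceneSpec(n_cells=12, noise_sigma=0.15, seed=99)
    a = generate_scene(spec)
    b = generate_scene(spec)
    for pa, pb in zip(a[:3], b[:3]):
        np.testing.assert_array_equal(pa.pixels, pb.pixels)
    assert a[3].basal_body_centers == b[3].basal_body_centers


def test_planted_counts_match_round_half_even():
    spec = SceneSpec(n_cells=10, ciliated_fraction=0.6, seed=7)
    _, _, _, truth = generate_scene(spec)
    assert len(truth.basal_body_centers) == 10
    assert truth.planted_ciliated_count == 6
    assert sum(c.attached_bb is not None for c in truth.cilium_polylines) == 6
    # banker's rounding at the .5 boundary
    assert SceneSpec(n_cells=10, ciliated_fraction=0.25).planted_ciliated_count == 2
    assert SceneSpec(n_cells=10, ciliated_fraction=0.35).planted_ciliated_count == 4


def test_zero_cells_renders_blank_scene():
    cilia, basal, nuclei, truth = generate_scene(SceneSpec(n_cells=0, distractor_rate=0))
    assert cilia.pixels.max() == 0 and basal.pixels.max() == 0
    assert truth.basal_body_centers == [] and truth.cilium_polylines == []
    assert truth.expected_percent is None


def test_attached_cilia_respect_planted_gap(default_params):
    cilia_p, bb_p = default_params
    spec = SceneSpec(n_cells=9, ciliated_fraction=1.0, seed=13)
    cilia, basal, _, truth = generate_scene(spec)
    m, cands, bbs, results = measure_image(cilia, basal, cilia_p, bb_p,
                                           return_details=True)
    lo, hi = spec.bb_cilium_gap_range
    for r in results:
        assert r.status == STATUS_CONFIRMED
        assert lo - 1.5 <= r.min_distance <= hi + 1.5


@pytest.mark.parametrize("gap_range,expect_confirmed", [
    ((2.0, 8.0), True),    # inside the 12 px rule
    ((16.0, 30.0), False),  # outside it
])
def test_gap_window_against_pairing_rule(default_params, gap_range, expect_confirmed):
    cilia_p, bb_p = default_params
    spec = SceneSpec(n_cells=6, ciliated_fraction=1.0, bb_cilium_gap_range=gap_range,
                     distractor_rate=0.0, seed=31)
    cilia, basal, _, truth = generate_scene(spec)
    m = measure_image(cilia, basal, cilia_p, bb_p)
    if expect_confirmed:
        assert m.n_cilia_confirmed == 6
    else:
        assert m.n_cilia_confirmed == 0
        assert m.n_too_far == 6


def test_mean_recovery_across_seeds(default_params):
    """Over 20 seeds the mean measured percent matches the planted
    fraction to within 2 points on noise-free renders."""
    cilia_p, bb_p = default_params
    diffs = []
    for seed in range(20):
        spec = SceneSpec(image_size=(600, 600), n_cells=16, ciliated_fraction=0.5,
                         seed=400 + seed)
        cilia, basal, _, truth = generate_scene(spec)
        m = measure_image(cilia, basal, cilia_p, bb_p)
        diffs.append(m.percent_ciliated - truth.expected_percent)
    assert abs(np.mean(diffs)) <= 2.0


def test_placement_capacity_error():
    with pytest.raises(ValueError, match="cannot place"):
        generate_scene(SceneSpec(image_size=(200, 200), n_cells=40))


def test_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(ciliated_fraction=1.5)
    with pytest.raises(ValueError):
        SceneSpec(cilium_length_range=(10.0, 5.0))
    with pytest.raises(ValueError):
        SceneSpec(n_cells=4, ciliated_fraction=0.5, n_multi_bb=3)


def test_ground_truth_json_round_trip(tmp_path):
    _, _, _, truth = generate_scene(SceneSpec(n_cells=6, ciliated_fraction=0.5,
                                              n_multi_bb=1, seed=2))
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = GroundTruth.from_json(p)
    assert back.basal_body_centers == truth.basal_body_centers
    assert back.planted_multi_bb_cases == truth.planted_multi_bb_cases
    assert back.expected_percent == truth.expected_percent
    np.testing.assert_allclose(back.cilium_polylines[0].polyline,
                               truth.cilium_polylines[0].polyline)


def test_plate_spikes_recorded_and_deterministic():
    wells, truth = generate_plate(n_wells=96, spike_z=[5.0, 5.0], seed=17)
    wells2, _ = generate_plate(n_wells=96, spike_z=[5.0, 5.0], seed=17)
    assert wells.equals(wells2)
    assert len(wells) == 96
    assert len(truth["spiked_compounds"]) == 2
    spiked = wells[wells.compound.isin(truth["spiked_compounds"])]
    assert np.allclose(spiked["percent_ciliated"], 20.0 + 5 * 4.0)


def test_single_well_plate_degenerates_downstream():
    from ciliaquant.screenstats import z_scores

    wells, _ = generate_plate(n_wells=1, seed=0)
    with pytest.raises(ValueError):
        z_scores(list(zip(wells["compound"], wells["percent_ciliated"])))


def test_plate_controls_appended():
    wells, _ = generate_plate(n_wells=24, pos_control=(60.0, 3.0, 4),
                              neg_control=(20.0, 3.0, 4), seed=1)
    assert (wells["role"] == "pos_control").sum() == 4
    assert (wells["role"] == "neg_control").sum() == 4
    assert len(wells) == 32
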