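import numpy as np
import pytest
from scipy.ndimage import label as cc_label

from conftest import single_object

from ciliaquant.morpho import (
    as_cilium_candidate,
    half_perimeter_length,
    measure_length,
    skeleton_length,
    thin_to_skeleton,
)
from ciliaquant.synthgen import render_cilium


def _skel_mask(coords, shape):
    m = np.zeros(shape, dtype=bool)
    m[coords[:, 0], coords[:, 1]] = True
    return m


def test_thin_rectangle_to_medial_line():
    # 3x11 rectangle thins to a 9-pixel medial line (endpoints retract by 1)
    m = np.zeros((7, 15), dtype=bool)
    m[2:5, 2:13] = True
    obj = single_object(m)
    skel = thin_to_skeleton(obj)
    expected = {(3, c) for c in range(3, 12)}
    assert set(map(tuple, skel.tolist())) == expected


@pytest.mark.parametrize("builder", [
    lambda: np.pad(np.ones((1, 10), bool), 2),                 # already a skeleton
    lambda: np.pad(np.ones((1, 1), bool), 2),                  # single pixel
    lambda: np.pad(np.ones((3, 11), bool), 2),                 # filled rectangle
    lambda: render_cilium((60, 20), 0.9, 30, 3, 0.15, (120, 120))[0],
    lambda: render_cilium((60, 20), 2.4, 45, 2, -0.1, (160, 160))[0],
])
def test_thinning_idempotent_subset_connected(builder):
    m = builder()
    obj = single_object(m)
    skel = thin_to_skeleton(obj)
    # subset of the mask
    assert set(map(tuple, skel.tolist())) <= obj.pixel_set
    # connected (topology preserved: one component stays one component)
    lab, n = cc_label(_skel_mask(skel, m.shape), structure=np.ones((3, 3)))
    assert n == 1
    # idempotent: thinning the skeleton changes nothing
    skel_obj = single_object(_skel_mask(skel, m.shape))
    skel2 = thin_to_skeleton(skel_obj)
    assert set(map(tuple, skel2.tolist())) == set(map(tuple, skel.tolist()))
    # no pixel has a fully-foreground 2x2 neighborhood (1-px wide)
    sm = _skel_mask(skel, m.shape)
    quad = sm[:-1, :-1] & sm[1:, :-1] & sm[:-1, 1:] & sm[1:, 1:]
    assert not quad.any()


def test_horizontal_line_lengths_are_exact():
    m = np.zeros((5, 14), dtype=bool)
    m[2, 2:12] = True  # 1x10 line
    c = as_cilium_candidate(single_object(m))
    assert c.length_half_perimeter == pytest.approx(9.0, abs=1e-9)
    assert c.length_skeleton == pytest.approx(9.0, abs=1e-9)


def test_single_pixel_has_zero_length():
    m = np.zeros((3, 3), dtype=bool)
    m[1, 1] = True
    c = as_cilium_candidate(single_object(m))
    assert measure_length(c, "half_perimeter") == 0.0
    assert measure_length(c, "skeleton") == 0.0


def test_diagonal_line_length_uses_sqrt2_steps():
    m = np.zeros((14, 14), dtype=bool)
    for i in range(10):
        m[2 + i, 2 + i] = True
    c = as_cilium_candidate(single_object(m))
    assert c.length_skeleton == pytest.approx(9 * np.sqrt(2), abs=1e-9)
    assert c.length_half_perimeter == pytest.approx(9 * np.sqrt(2), abs=1e-9)


@pytest.mark.parametrize("theta", [0.0, 0.4, np.pi / 4, 1.2, 1.9, 2.7])
@pytest.mark.parametrize("length,width,curv", [
    (10, 1, 0.0), (10, 3, 0.12), (25, 2, 0.0), (25, 3, 0.18),
    (40, 1, 0.1), (60, 3, 0.0), (60, 3, 0.15),
])
def test_length_accuracy_within_two_pixels(theta, length, width, curv):
    """Both estimators recover the rendered cilium's length to +-2 px."""
    mask, _, true_len = render_cilium((150, 30) if theta < np.pi / 2 else (200, 200),
                                      theta, length, width, curv, shape=(400, 400))
    c = as_cilium_candidate(single_object(mask))
    assert measure_length(c, "half_perimeter") == pytest.approx(true_len, abs=2.0)
    assert measure_length(c, "skeleton") == pytest.approx(true_len, abs=2.0)


def test_length_invariant_under_translation_and_rotation():
    mask, _, _ = render_cilium((80, 30), 0.7, 28, 3, 0.1, shape=(160, 160))
    c0 = as_cilium_candidate(single_object(mask))
    # translation: exact for both modes
    shifted = np.zeros((200, 200), dtype=bool)
    shifted[23:183, 11:171] = mask
    ct = as_cilium_candidate(single_object(shifted))
    assert ct.length_half_perimeter == c0.length_half_perimeter
    assert ct.length_skeleton == c0.length_skeleton
    # 90-degree rotations: half-perimeter exact; skeleton within 1 px
    # (directional thinning passes are not exactly rotation-equivariant)
    for k in (1, 2, 3):
        cr = as_cilium_candidate(single_object(np.rot90(mask, k)))
        assert cr.length_half_perimeter == pytest.approx(c0.length_half_perimeter, abs=1e-9)
        assert cr.length_skeleton == pytest.approx(c0.length_skeleton, abs=1.0)


def test_half_perimeter_of_rectangle():
    # 1x10 line: boundary loop runs 9 out + 9 back -> half is 9
    m = np.zeros((5, 14), dtype=bool)
    m[2, 2:12] = True
    assert half_perimeter_length(single_object(m)) == pytest.approx(9.0)


def test_measure_length_errors():
    m = np.zeros((5, 5), dtype=bool)
    m[2, 1:4] = True
    c = as_cilium_candidate(single_object(m))
    with pytest.raises(ValueError):
        measure_length(c, "geodesic")
    with pytest.raises(ValueError):
        skeleton_length(np.empty((0, 2)))
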