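import math

import numpy as np
import pytest

from conftest import bb_at, brute_force_classify, objects_from_mask, single_object

from ciliaquant.morpho import as_cilium_candidate
from ciliaquant.pairing import (
    STATUS_CONFIRMED,
    STATUS_MULTI_BB,
    STATUS_TOO_FAR,
    PairingParams,
    classify_cilia,
    min_boundary_to_center_distance,
)


def _cilium_from_pixels(pixels, canvas=(200, 200)):
    m = np.zeros(canvas, dtype=bool)
    for r, c in pixels:
        m[r, c] = True
    return as_cilium_candidate(single_object(m))


def test_min_distance_direct_arithmetic():
    c = _cilium_from_pixels([(0, 0), (0, 1)])
    assert min_boundary_to_center_distance(c, bb_at((0, 5))) == pytest.approx(4.0)
    assert min_boundary_to_center_distance(c, bb_at((0, 0))) == 0.0
    c2 = _cilium_from_pixels([(3, 4)])
    assert min_boundary_to_center_distance(c2, bb_at((0, 0))) == pytest.approx(5.0)  # 3-4-5


def test_confirmed_within_12_pixels():
    c = _cilium_from_pixels([(50, 50 + i) for i in range(10)])
    res = classify_cilia([c], [bb_at((50, 45))])  # boundary distance 5
    assert res[0].status == STATUS_CONFIRMED
    assert res[0].min_distance == pytest.approx(5.0)
    assert res[0].nearest_bb_label == 1
    assert res[0].n_bb_in_vicinity == 1


def test_too_far_beyond_12_pixels():
    c = _cilium_from_pixels([(50, 50 + i) for i in range(10)])
    res = classify_cilia([c], [bb_at((50, 30))])  # distance 20
    assert res[0].status == STATUS_TOO_FAR
    assert res[0].min_distance == pytest.approx(20.0)


def test_exactly_12_is_excluded_strict_inequality():
    c = _cilium_from_pixels([(50, 50 + i) for i in range(5)])
    res = classify_cilia([c], [bb_at((62.0, 50.0))])  # exactly 12.0
    assert res[0].min_distance == pytest.approx(12.0, abs=0)
    assert res[0].status == STATUS_TOO_FAR
    res2 = classify_cilia([c], [bb_at((61.999, 50.0))])
    assert res2[0].status == STATUS_CONFIRMED


def test_two_basal_bodies_in_vicinity_is_artifact():
    c = _cilium_from_pixels([(50, 50 + i) for i in range(10)])
    bbs = [bb_at((54, 50), label=1), bb_at((50, 41), label=2)]  # distances 4 and 9
    res = classify_cilia([c], bbs)
    assert res[0].status == STATUS_MULTI_BB
    assert res[0].n_bb_in_vicinity == 2
    assert res[0].min_distance == pytest.approx(4.0)


def test_no_basal_bodies_everything_too_far():
    cilia = [_cilium_from_pixels([(10, 10 + i) for i in range(5)]),
             _cilium_from_pixels([(100, 100 + i) for i in range(5)])]
    res = classify_cilia(cilia, [])
    assert all(r.status == STATUS_TOO_FAR for r in res)
    assert all(math.isinf(r.min_distance) for r in res)
    assert all(r.nearest_bb_label is None for r in res)


def test_single_bb_in_wide_vicinity_but_beyond_max_distance():
    c = _cilium_from_pixels([(50, 50 + i) for i in range(5)])
    params = PairingParams(max_distance=12.0, vicinity_distance=20.0)
    res = classify_cilia([c], [bb_at((65, 50))], params)  # d = 15 < 20 but >= 12
    assert res[0].n_bb_in_vicinity == 1
    assert res[0].status == STATUS_TOO_FAR


def test_raising_max_distance_never_loses_confirmations():
    rng = np.random.default_rng(11)
    cilia = [_cilium_from_pixels([(r0, c0 + i) for i in range(8)])
             for r0, c0 in rng.integers(20, 150, size=(6, 2))]
    bbs = [bb_at(tuple(p), label=i + 1) for i, p in
           enumerate(rng.uniform(10, 160, size=(6, 2)))]
    prev = -1
    for max_d in (4.0, 8.0, 12.0, 20.0, 40.0):
        res = classify_cilia(cilia, bbs, PairingParams(max_d, vicinity_distance=12.0))
        n = sum(r.status == STATUS_CONFIRMED for r in res)
        assert n >= prev
        prev = n


def test_joint_translation_invariance():
    rng = np.random.default_rng(4)
    offs = (17, 23)
    pix = [[(int(r), int(c) + i) for i in range(6)]
           for r, c in rng.integers(20, 120, size=(5, 2))]
    centers = rng.uniform(15, 130, size=(5, 2))
    cilia0 = [_cilium_from_pixels(p) for p in pix]
    cilia1 = [_cilium_from_pixels([(r + offs[0], c + offs[1]) for r, c in p]) for p in pix]
    bbs0 = [bb_at(tuple(c), label=i + 1) for i, c in enumerate(centers)]
    bbs1 = [bb_at((c[0] + offs[0], c[1] + offs[1]), label=i + 1)
            for i, c in enumerate(centers)]
    r0 = classify_cilia(cilia0, bbs0)
    r1 = classify_cilia(cilia1, bbs1)
    for a, b in zip(r0, r1):
        assert a.status == b.status
        assert a.min_distance == pytest.approx(b.min_distance, abs=0)


def test_matches_brute_force_on_random_scenes():
    """Vectorized classifier == pure-python all-pairs oracle."""
    rng = np.random.default_rng(2024)
    for _ in range(50):
        scene = np.zeros((120, 120), dtype=bool)
        n_cil = int(rng.integers(0, 6))
        for _k in range(n_cil):
            r, c = rng.integers(5, 100, size=2)
            h, w = rng.integers(1, 4), rng.integers(3, 12)
            scene[r:r + h, c:c + w] = True
        objs = objects_from_mask(scene)
        cilia = [as_cilium_candidate(o) for o in objs]
        centers = rng.uniform(0, 120, size=(int(rng.integers(0, 6)), 2))
        bbs = [bb_at(tuple(p), label=i + 1, canvas=(120, 120))
               for i, p in enumerate(centers)]
        got = [r.status for r in classify_cilia(cilia, bbs)]
        want = brute_force_classify(
            [c.base.boundary_points.tolist() for c in cilia],
            [b.center for b in bbs])
        assert got == want


def test_pairing_params_validation():
    with pytest.raises(ValueError):
        PairingParams(max_distance=0)
    with pytest.raises(ValueError):
        PairingParams(max_distance=12, vicinity_distance=-1)
    assert PairingParams(10.0).vicinity == 10.0
    assert PairingParams(10.0, 6.0).vicinity == 6.0
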