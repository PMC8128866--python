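import math

import numpy as np
import pytest

from ciliaquant.detect import BasalBody, SegmentationParams, segment_objects
from ciliaquant.io import IntensityImage


def objects_from_mask(mask, connectivity=8):
    """Segment a binary mask into LabeledObjects (amplitude 100, threshold 50)."""
    img = IntensityImage(np.asarray(mask, dtype=float) * 100.0)
    return segment_objects(img, SegmentationParams(50.0, min_size=1, connectivity=connectivity))


def single_object(mask, connectivity=8):
    objs = objects_from_mask(mask, connectivity)
    assert len(objs) == 1, f"expected one object, found {len(objs)}"
    return objs[0]


def bb_at(center, label=1, canvas=(200, 200)):
    """A BasalBody whose center is the given (row, col) point."""
    m = np.zeros(canvas, dtype=bool)
    r = min(max(int(round(center[0])), 0), canvas[0] - 1)
    c = min(max(int(round(center[1])), 0), canvas[1] - 1)
    m[r, c] = True
    obj = single_object(m)
    obj.label = label
    return BasalBody(base=obj, center=(float(center[0]), float(center[1])))


def brute_force_classify(boundaries, centers, max_distance=12.0, vicinity=None):
    """Pure-python all-pairs reference for the pairing rule.

    ``boundaries``: per-cilium iterable of (row, col) boundary points;
    ``centers``: basal-body centers.  Returns the list of statuses.
    """
    vicinity = max_distance if vicinity is None else vicinity
    statuses = []
    for pts in boundaries:
        dists = []
        for cen in centers:
            best = math.inf
            for p in pts:
                d = math.hypot(p[0] - cen[0], p[1] - cen[1])
                if d < best:
                    best = d
            dists.append(best)
        n_vic = sum(d < vicinity for d in dists)
        dmin = min(dists) if dists else math.inf
        if n_vic >= 2:
            statuses.append("multi_bb_artifact")
        elif n_vic == 1 and dmin < max_distance:
            statuses.append("cilium_confirmed")
        else:
            statuses.append("too_far")
    return statuses


@pytest.fixture(scope="session")
def default_params():
    from ciliaquant.synthgen import DEFAULT_BB_PARAMS, DEFAULT_CILIA_PARAMS

    return DEFAULT_CILIA_PARAMS, DEFAULT_BB_PARAMS
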