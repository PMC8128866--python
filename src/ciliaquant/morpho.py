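"""Skeletonization of cilium candidates and length measurement.

Each segmented cilium is reduced to a 1-pixel-wide, topology-preserving
skeleton by iterative morphological thinning (Zhang-Suen-class, via
scikit-image).  Two length estimates are computed:

``half_perimeter``
    Half the length of the closed boundary path traced around the
    object.  For an elongated object the boundary runs up one side and
    down the other, so half its length tracks the object's long axis.
    This is the headline length reported by default.

``skeleton``
    The arc length of the skeleton path, extended to the object's two
    extremal boundary pixels ("tips") to compensate for the 1-2 px of
    endpoint retraction intrinsic to thinning.

Both estimates measure digitized paths by chord resampling: summing raw
pixel steps (1 laterally, sqrt(2) diagonally) systematically
overestimates the length of digitized lines at intermediate angles by up
to ~8%, whereas chords spanning a few pixels recover the Euclidean
length of smooth curves to sub-pixel accuracy while remaining exact for
rectilinear and 45-degree paths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import depth_first_order, minimum_spanning_tree
from scipy.spatial.distance import cdist
from skimage.morphology import thin as _sk_thin

from .detect import LabeledObject

#: chord span (in path steps) used when resampling digitized paths
RESAMPLE_STEP = 4

LENGTH_MODES = ("half_perimeter", "skeleton")


@dataclass
class CiliumCandidate:
    """A segmented cilium with its skeleton and both length estimates
    (pixels).  ``skeleton_pixels`` is an (K, 2) array, a subset of the
    base object's pixels."""

    base: LabeledObject
    skeleton_pixels: np.ndarray
    length_half_perimeter: float
    length_skeleton: float

    @property
    def label(self) -> int:
        return self.base.label

    @property
    def skeleton_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.skeleton_pixels.tolist()))


def thin_to_skeleton(obj: LabeledObject) -> np.ndarray:
    """Thin a connected object to its skeleton.

    Returns the skeleton pixel coordinates (K, 2) in global image
    coordinates.  The result is a connected, 1-pixel-wide subset of the
    object, and thinning is idempotent: a shape that is already a
    skeleton comes back unchanged.
    """
    if obj.area == 0:
        raise ValueError("cannot thin an empty object")
    mask, (r0, c0) = obj.mask(pad=1)
    skel = _sk_thin(mask)
    coords = np.argwhere(skel) + np.array([r0, c0])
    return coords.astype(np.intp)


def _resampled_length(path: np.ndarray, step: int = RESAMPLE_STEP) -> float:
    """Arc length of an open pixel path: chords every ``step`` path steps,
    endpoints always included."""
    path = np.asarray(path, dtype=float)
    if len(path) < 2:
        return 0.0
    idx = list(range(0, len(path) - 1, step)) + [len(path) - 1]
    sel = path[idx]
    return float(np.linalg.norm(np.diff(sel, axis=0), axis=1).sum())


def _object_tips(obj: LabeledObject) -> tuple[np.ndarray, np.ndarray, int, int]:
    """The two most mutually distant boundary pixels of the object (its
    tips) and their positions in the closed boundary trace."""
    cyc = obj.boundary.astype(float)
    D = cdist(cyc, cyc)
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    if i > j:
        i, j = j, i
    return cyc[i], cyc[j], i, j


def half_perimeter_length(obj: LabeledObject, step: int = RESAMPLE_STEP) -> float:
    """Half the traced boundary length of the object.

    The closed boundary trace is split at the object's two tips into two
    side paths, each measured by chord resampling, and the mean of the
    two side lengths is returned.  Splitting at the tips keeps the
    chords from short-cutting across the fold the trace makes at the end
    of a thin object.  A single-pixel object has length 0.
    """
    cyc = obj.boundary
    if len(cyc) < 2:
        return 0.0
    _, _, i, j = _object_tips(obj)
    P = cyc.astype(float)
    leg_a = P[i:j + 1]
    leg_b = np.vstack([P[j:], P[:i + 1]])
    return 0.5 * (_resampled_length(leg_a, step) + _resampled_length(leg_b, step))


def _ordered_skeleton_path(pixels: np.ndarray) -> tuple[np.ndarray, float]:
    """Order skeleton pixels into a walk and return (path, fallback_length).

    The 8-adjacency graph of the skeleton is reduced to its minimum
    spanning tree (weights 1 / sqrt(2)), which drops redundant diagonal
    edges that cut corners.  A depth-first order from a degree-1 pixel
    gives the path.  If the skeleton is not a simple curve (branched or
    looped) the ordered walk is invalid and the MST total edge weight is
    returned as the length via the second element.
    """
    pts = np.asarray(pixels, dtype=float)
    D = cdist(pts, pts)
    adj = (D > 0) & (D < 1.5)
    W = sp.csr_matrix(np.where(adj, D, 0.0))
    mst = minimum_spanning_tree(W)
    und = mst + mst.T
    deg = np.asarray((und > 0).sum(axis=1)).ravel()
    ends = np.flatnonzero(deg == 1)
    start = int(ends[0]) if len(ends) else 0
    order, _ = depth_first_order(und, start, directed=False)
    path = pts[order]
    return path, float(mst.sum())


def skeleton_length(
    skeleton_pixels: np.ndarray,
    obj: LabeledObject | None = None,
    step: int = RESAMPLE_STEP,
) -> float:
    """Arc length of a skeleton, optionally extended to the object tips.

    With ``obj`` given, the measured path is extended from each skeleton
    endpoint to the nearer of the object's two extremal boundary pixels,
    recovering the endpoint retraction introduced by thinning.  For a
    1-pixel-wide object the tips coincide with the skeleton endpoints
    and the extension contributes nothing.
    """
    pts = np.asarray(skeleton_pixels)
    if len(pts) == 0:
        raise ValueError("skeleton_length: empty skeleton")
    tip_extension = 0.0
    if len(pts) == 1:
        core = 0.0
        end_a = end_b = pts[0].astype(float)
    else:
        path, mst_total = _ordered_skeleton_path(pts)
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        if np.any(steps > 1.5):  # branched/looped skeleton: no simple walk
            return mst_total
        core = _resampled_length(path, step)
        end_a, end_b = path[0], path[-1]
    if obj is not None and len(obj.boundary) >= 2:
        tip1, tip2, _, _ = _object_tips(obj)
        d1 = min(np.linalg.norm(tip1 - end_a), np.linalg.norm(tip1 - end_b))
        d2 = min(np.linalg.norm(tip2 - end_a), np.linalg.norm(tip2 - end_b))
        tip_extension = float(d1 + d2)
    return core + tip_extension


def as_cilium_candidate(obj: LabeledObject) -> CiliumCandidate:
    """Promote a segmented object to a cilium candidate: compute its
    skeleton and both length estimates."""
    skel = thin_to_skeleton(obj)
    return CiliumCandidate(
        base=obj,
        skeleton_pixels=skel,
        length_half_perimeter=half_perimeter_length(obj),
        length_skeleton=skeleton_length(skel, obj),
    )


def measure_length(c: CiliumCandidate, mode: str = "half_perimeter") -> float:
    """Return the cilium length in pixels under the requested mode."""
    if mode == "half_perimeter":
        return c.length_half_perimeter
    if mode == "skeleton":
        if len(c.skeleton_pixels) == 0:
            raise ValueError("skeleton mode requested but the skeleton is empty")
        return c.length_skeleton
    raise ValueError(f"unknown length mode {mode!r}; expected one of {LENGTH_MODES}")
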