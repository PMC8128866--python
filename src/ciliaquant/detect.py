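"""Segmentation of cilia and basal bodies by global thresholding.

Both marker channels are segmented the same way: pixels strictly above a
background intensity threshold are foreground, connected components are
extracted (8-connectivity by default, appropriate for thin diagonal
structures like cilia), and components outside a configured size window
are discarded.  No illumination correction or machine-learned
segmentation is attempted -- the method is deliberately a reproducible
global threshold whose value is configured in the image's native
intensity units.

Coordinates are 0-based ``(row, col)`` with pixel centers at integer
positions, so all downstream distances are unambiguous pixel distances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .io import IntensityImage

# clockwise Moore neighborhood, starting North
_NBR = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
_NBR_INDEX = {d: i for i, d in enumerate(_NBR)}


@dataclass(frozen=True)
class SegmentationParams:
    """Threshold-and-size-filter parameters for one marker channel.

    ``intensity_threshold`` is in native image units; pixels strictly
    greater than it are foreground.  ``min_size``/``max_size`` bound the
    accepted object area in pixels (``max_size=None`` means unbounded;
    an upper bound is useful for basal bodies, where it rejects
    aggregates).  ``connectivity`` is 4 or 8 (default 8).
    """

    intensity_threshold: float
    min_size: int
    max_size: Optional[int] = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be >= 0")
        if self.min_size <= 0:
            raise ValueError("min_size must be > 0")
        if self.max_size is not None and self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def skimage_connectivity(self) -> int:
        return 1 if self.connectivity == 4 else 2


@dataclass
class LabeledObject:
    """One segmented connected component.

    ``pixels`` is an (N, 2) integer array of (row, col) coordinates;
    ``boundary`` is the ordered closed Moore trace of the outer boundary
    (pixels may repeat along 1-px-wide stretches); ``boundary_points``
    are the unique boundary pixels in trace order, a subset of the
    object's pixels.
    """

    label: int
    pixels: np.ndarray
    centroid: tuple[float, float]
    boundary: np.ndarray
    boundary_points: np.ndarray

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def pixel_set(self) -> set[tuple[int, int]]:
        return set(map(tuple, self.pixels.tolist()))

    def mask(self, pad: int = 0) -> tuple[np.ndarray, tuple[int, int]]:
        """Binary crop of the object.  Returns (mask, (row0, col0)) where
        (row0, col0) is the global coordinate of mask[pad, pad]... i.e. of
        the crop origin."""
        r0, c0 = self.pixels.min(axis=0)
        r1, c1 = self.pixels.max(axis=0)
        m = np.zeros((r1 - r0 + 1 + 2 * pad, c1 - c0 + 1 + 2 * pad), dtype=bool)
        m[self.pixels[:, 0] - r0 + pad, self.pixels[:, 1] - c0 + pad] = True
        return m, (r0 - pad, c0 - pad)


@dataclass
class BasalBody:
    """A segmented basal-body punctum; ``center`` is the intensity-free
    area centroid used by the pairing rule."""

    base: LabeledObject
    center: tuple[float, float]

    @property
    def label(self) -> int:
        return self.base.label


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed trace of the outer boundary of a connected mask.

    Moore-neighbor tracing with Jacob's stopping criterion, walking the
    8-connected outer boundary clockwise from the raster-scan-first
    pixel.  For 1-pixel-wide stretches the trace runs out and back, so a
    pixel can appear twice; the full trace is what the perimeter is
    measured on.  A single-pixel mask yields a 1-point trace.
    """
    fg = np.argwhere(mask)
    if len(fg) == 0:
        raise ValueError("trace_boundary: empty mask")
    if len(fg) == 1:
        return fg
    # raster-scan first pixel; its west neighbor is background by construction
    start = (int(fg[0, 0]), int(fg[0, 1]))
    mask_set = set(map(tuple, fg.tolist()))
    bdir = 6  # direction (index into _NBR) from current pixel to its backtrack
    cur = start
    path = [start]
    first_move = None
    while True:
        nxt = None
        for k in range(1, 9):
            d = (bdir + k) % 8
            cand = (cur[0] + _NBR[d][0], cur[1] + _NBR[d][1])
            if cand in mask_set:
                nxt = cand
                break
        if nxt is None:  # isolated pixel inside a >1-px component: unreachable
            break
        move = (cur, nxt)
        if first_move is None:
            first_move = move
        elif move == first_move:
            path.pop()  # drop the re-appended start
            break
        prevd = (bdir + k - 1) % 8
        bg = (cur[0] + _NBR[prevd][0], cur[1] + _NBR[prevd][1])
        bdir = _NBR_INDEX[(bg[0] - nxt[0], bg[1] - nxt[1])]
        cur = nxt
        path.append(cur)
    return np.asarray(path, dtype=np.intp)


def _unique_in_order(points: np.ndarray) -> np.ndarray:
    seen: set[tuple[int, int]] = set()
    keep = []
    for p in map(tuple, points.tolist()):
        if p not in seen:
            seen.add(p)
            keep.append(p)
    return np.asarray(keep, dtype=np.intp)


def segment_objects(image: IntensityImage, params: SegmentationParams) -> list[LabeledObject]:
    """Threshold, label, and size-filter one channel.

    Foreground is ``pixels > intensity_threshold`` (strict).  Components
    are labeled under the configured connectivity and those with area
    outside ``[min_size, max_size]`` are dropped.  Surviving objects are
    relabeled 1..N in raster-scan order of their first pixel.
    """
    fg = image.pixels > params.intensity_threshold
    labels = measure.label(fg, connectivity=params.skimage_connectivity)
    out: list[LabeledObject] = []
    for region in measure.regionprops(labels):
        if region.area < params.min_size:
            continue
        if params.max_size is not None and region.area > params.max_size:
            continue
        pixels = np.asarray(region.coords, dtype=np.intp)
        crop = labels[region.slice] == region.label
        trace_local = trace_boundary(crop)
        offset = np.array([region.slice[0].start, region.slice[1].start], dtype=np.intp)
        trace = trace_local + offset
        obj = LabeledObject(
            label=len(out) + 1,
            pixels=pixels,
            centroid=(float(region.centroid[0]), float(region.centroid[1])),
            boundary=trace,
            boundary_points=_unique_in_order(trace),
        )
        out.append(obj)
    return out


def detect_basal_bodies(image: IntensityImage, params: SegmentationParams) -> list[BasalBody]:
    """Segment the basal-body channel and record each punctum's centroid,
    the center the pairing rule measures distances to."""
    return [BasalBody(base=obj, center=obj.centroid) for obj in segment_objects(image, params)]
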