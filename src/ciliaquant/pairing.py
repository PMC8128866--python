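"""Cilium / basal-body pairing by minimum Euclidean distance.

A cilium projects from a basal body, so a genuine cilium object should
lie close to exactly one basal-body punctum.  For every cilium
candidate the minimum Euclidean distance from its boundary pixels to
each basal-body center is computed; a candidate is confirmed as a
cilium when its nearest basal body is strictly closer than
``max_distance`` (12 px by default) and no second basal body lies
within the vicinity radius.  Two or more basal bodies in the vicinity
mark the candidate as an artifact (typically overlapping cells) and it
is excluded from counting.  Each candidate is classified independently:
there is no one-to-one assignment, so one basal body may confirm
several nearby candidates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .detect import BasalBody
from .morpho import CiliumCandidate

STATUS_CONFIRMED = "cilium_confirmed"
STATUS_TOO_FAR = "too_far"
STATUS_MULTI_BB = "multi_bb_artifact"


@dataclass(frozen=True)
class PairingParams:
    """Distance thresholds of the pairing rule, in pixels.

    ``max_distance``: a candidate is a cilium only if its boundary comes
    strictly closer than this to a basal-body center (default 12).
    ``vicinity_distance``: radius of the multi-basal-body artifact test;
    defaults to ``max_distance``.
    """

    max_distance: float = 12.0
    vicinity_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be > 0")
        if self.vicinity_distance is not None and self.vicinity_distance <= 0:
            raise ValueError("vicinity_distance must be > 0")

    @property
    def vicinity(self) -> float:
        return self.max_distance if self.vicinity_distance is None else self.vicinity_distance


@dataclass
class PairingResult:
    """Classification of one cilium candidate.

    ``min_distance`` is the minimum over all basal bodies (infinity when
    the image has none); ``nearest_bb_label`` identifies the closest
    basal body; ``n_bb_in_vicinity`` counts basal bodies strictly within
    the vicinity radius.
    """

    cilium: CiliumCandidate
    status: str
    min_distance: float
    nearest_bb_label: Optional[int]
    n_bb_in_vicinity: int


def min_boundary_to_center_distance(c: CiliumCandidate, b: BasalBody) -> float:
    """Minimum Euclidean distance from the cilium's boundary pixels to
    the basal body's center.  Zero iff the center coincides with a
    boundary pixel."""
    pts = c.base.boundary_points
    if len(pts) == 0:
        raise ValueError("cilium candidate has no boundary points")
    d = np.linalg.norm(pts.astype(float) - np.asarray(b.center, dtype=float), axis=1)
    return float(d.min())


def classify_cilia(
    cilia: list[CiliumCandidate],
    bbs: list[BasalBody],
    params: PairingParams = PairingParams(),
) -> list[PairingResult]:
    """Classify every cilium candidate against all basal bodies.

    Per candidate: let d_j be the minimum boundary-to-center distance to
    basal body j.  If two or more basal bodies have d_j strictly below
    the vicinity radius the candidate is a multi-basal-body artifact; if
    exactly one is in the vicinity and min_j d_j is strictly below
    ``max_distance`` the candidate is a confirmed cilium; otherwise it
    is too far.  With no basal bodies at all every candidate is too far
    (``min_distance`` = infinity).
    """
    if not bbs:
        return [
            PairingResult(c, STATUS_TOO_FAR, math.inf, None, 0)
            for c in cilia
        ]
    centers = np.asarray([b.center for b in bbs], dtype=float)
    results: list[PairingResult] = []
    for c in cilia:
        pts = c.base.boundary_points.astype(float)
        if len(pts) == 0:
            raise ValueError(f"cilium candidate {c.label} has no boundary points")
        d = cdist(pts, centers).min(axis=0)  # per-basal-body minimum
        nearest = int(np.argmin(d))
        dmin = float(d[nearest])
        n_vic = int(np.sum(d < params.vicinity))
        if n_vic >= 2:
            status = STATUS_MULTI_BB
        elif n_vic == 1 and dmin < params.max_distance:
            status = STATUS_CONFIRMED
        else:
            status = STATUS_TOO_FAR
        results.append(
            PairingResult(
                cilium=c,
                status=status,
                min_distance=dmin,
                nearest_bb_label=bbs[nearest].label,
                n_bb_in_vicinity=n_vic,
            )
        )
    return results


def pairing_table(results: list[PairingResult], length_mode: str = "half_perimeter"):
    """Per-candidate pairing table (one row per cilium candidate) as a
    pandas DataFrame ready for CSV export."""
    import pandas as pd

    from .morpho import measure_length

    rows = []
    for r in results:
        rows.append(
            {
                "cilium_label": r.cilium.label,
                "status": r.status,
                "min_distance": r.min_distance if math.isfinite(r.min_distance) else None,
                "nearest_bb_label": r.nearest_bb_label,
                "n_bb_in_vicinity": r.n_bb_in_vicinity,
                "length": measure_length(r.cilium, length_mode),
                "length_half_perimeter": r.cilium.length_half_perimeter,
                "length_skeleton": r.cilium.length_skeleton,
            }
        )
    cols = ["cilium_label", "status", "min_distance", "nearest_bb_label",
            "n_bb_in_vicinity", "length", "length_half_perimeter", "length_skeleton"]
    return pd.DataFrame(rows, columns=cols)
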