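"""Percentage-ciliated quantification and per-well aggregation.

The headline statistic is

    percentage ciliated = 100 * n_cilia / n_basal_bodies

with the number of confirmed cilia in the numerator and ALL detected
basal bodies in the denominator -- basal bodies are counted
independently of pairing, so puncta without a cilium and puncta caught
in multi-basal-body artifacts all contribute to the denominator (an
option flag excludes the artifact-involved ones).  A zero denominator
makes the percentage undefined; undefined values are carried as ``None``
and written as empty CSV cells, never as 0.

Wells pool counts across their images (100 * sum cilia / sum basal
bodies) rather than averaging per-image percentages, which weights each
image by its cell content; the unweighted mean of image percentages is
also emitted for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .detect import SegmentationParams, detect_basal_bodies, segment_objects
from .io import IntensityImage
from .morpho import as_cilium_candidate, measure_length
from .pairing import (
    STATUS_CONFIRMED,
    STATUS_MULTI_BB,
    STATUS_TOO_FAR,
    PairingParams,
    PairingResult,
    classify_cilia,
)


@dataclass
class ImageMeasurement:
    """Counts and statistics for one analyzed image."""

    image_id: str
    n_basal_bodies: int = 0
    n_cilia_confirmed: int = 0
    n_too_far: int = 0
    n_multi_bb_artifacts: int = 0
    percent_ciliated: Optional[float] = None
    mean_cilium_length: Optional[float] = None

    @property
    def n_candidates(self) -> int:
        return self.n_cilia_confirmed + self.n_too_far + self.n_multi_bb_artifacts


@dataclass
class WellMeasurement:
    """Aggregated counts for one well of a plate."""

    well_id: str
    compound: str = ""
    dose: Optional[float] = None
    role: str = "sample"
    n_images: int = 0
    n_basal_bodies: int = 0
    n_cilia_confirmed: int = 0
    percent_ciliated_pooled: Optional[float] = None
    percent_ciliated_mean: Optional[float] = None
    image_measurements: list = field(default_factory=list, repr=False)


def percentage_ciliated(n_cilia: int, n_basal_bodies: int) -> Optional[float]:
    """100 * n_cilia / n_basal_bodies; ``None`` (undefined) when the
    image contains no basal bodies."""
    if n_cilia < 0 or n_basal_bodies < 0:
        raise ValueError("counts must be non-negative")
    if n_basal_bodies == 0:
        return None
    return 100.0 * n_cilia / n_basal_bodies


def summarize_pairing(
    image_id: str,
    results: list[PairingResult],
    n_basal_bodies: int,
    length_mode: str = "half_perimeter",
    exclude_artifact_bbs: bool = False,
) -> ImageMeasurement:
    """Fold pairing results into an :class:`ImageMeasurement`.

    ``exclude_artifact_bbs`` removes basal bodies that sit in the
    vicinity of multi-basal-body artifacts from the denominator
    (counting each artifact's vicinity size); the default keeps the
    literal all-detected-puncta denominator.
    """
    n_conf = sum(r.status == STATUS_CONFIRMED for r in results)
    n_far = sum(r.status == STATUS_TOO_FAR for r in results)
    n_multi = sum(r.status == STATUS_MULTI_BB for r in results)
    denom = n_basal_bodies
    if exclude_artifact_bbs:
        denom -= sum(r.n_bb_in_vicinity for r in results if r.status == STATUS_MULTI_BB)
        denom = max(denom, 0)
    lengths = [measure_length(r.cilium, length_mode) for r in results
               if r.status == STATUS_CONFIRMED]
    return ImageMeasurement(
        image_id=image_id,
        n_basal_bodies=denom,
        n_cilia_confirmed=n_conf,
        n_too_far=n_far,
        n_multi_bb_artifacts=n_multi,
        percent_ciliated=percentage_ciliated(n_conf, denom),
        mean_cilium_length=float(np.mean(lengths)) if lengths else None,
    )


def measure_image(
    cilia_plane: IntensityImage,
    basal_plane: IntensityImage,
    cilia_params: SegmentationParams,
    bb_params: SegmentationParams,
    pairing_params: PairingParams = PairingParams(),
    image_id: str = "",
    length_mode: str = "half_perimeter",
    exclude_artifact_bbs: bool = False,
    return_details: bool = False,
):
    """Run the full per-image pipeline: segment both channels, skeletonize
    cilium candidates, classify them against the basal bodies, and
    compute the percentage-ciliated statistic.

    With ``return_details=True`` returns
    ``(measurement, candidates, basal_bodies, pairing_results)``.
    """
    if cilia_plane.shape != basal_plane.shape:
        raise ValueError("cilia and basal-body planes must share dimensions")
    candidates = [as_cilium_candidate(o) for o in segment_objects(cilia_plane, cilia_params)]
    bbs = detect_basal_bodies(basal_plane, bb_params)
    results = classify_cilia(candidates, bbs, pairing_params)
    m = summarize_pairing(image_id, results, len(bbs), length_mode, exclude_artifact_bbs)
    if return_details:
        return m, candidates, bbs, results
    return m


def aggregate_well(
    measurements: list[ImageMeasurement],
    well_id: str,
    compound: str = "",
    dose: Optional[float] = None,
    role: str = "sample",
) -> WellMeasurement:
    """Pool image measurements into a well summary.

    The pooled percentage is 100 * (sum of confirmed cilia) / (sum of
    basal bodies); undefined when every image has a zero denominator.
    The unweighted mean of the defined per-image percentages is reported
    alongside.
    """
    if not measurements:
        raise ValueError("aggregate_well requires at least one image measurement")
    n_cilia = sum(m.n_cilia_confirmed for m in measurements)
    n_bb = sum(m.n_basal_bodies for m in measurements)
    defined = [m.percent_ciliated for m in measurements if m.percent_ciliated is not None]
    return WellMeasurement(
        well_id=well_id,
        compound=compound,
        dose=dose,
        role=role,
        n_images=len(measurements),
        n_basal_bodies=n_bb,
        n_cilia_confirmed=n_cilia,
        percent_ciliated_pooled=percentage_ciliated(n_cilia, n_bb),
        percent_ciliated_mean=float(np.mean(defined)) if defined else None,
        image_measurements=list(measurements),
    )
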