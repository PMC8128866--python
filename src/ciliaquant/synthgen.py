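"""Ground-truth synthetic fluorescence scenes and screening plates.

The generator emulates the geometry of the ciliogenesis assay: each
"cell" contributes a compact basal-body punctum (pericentrin channel)
and, if ciliated, an elongated cilium (acetylated-tubulin channel)
whose proximal tip sits a few pixels from the basal-body center.  Cilia
are rendered as quadratic Bezier polylines dilated to the target width,
basal bodies as disks, nuclei as large dim ellipses; all structures are
softened with a small Gaussian blur (a crude stand-in for the
microscope PSF) and optionally overlaid with additive Gaussian sensor
noise.  Cells are laid out on a shuffled grid of tiles with a guard
margin wider than the pairing vicinity, so no structure of one cell can
fall inside another cell's pairing radius -- which is what makes the
planted ciliated fraction exactly recoverable on noise-free renders.

Every scene records its ground truth (basal-body centers, cilium
polylines and attachments, planted multi-basal-body artifact cases), so
end-to-end pipeline accuracy can be measured without any real imagery.

The default segmentation parameters exported here are calibrated to
this generator's rendering (amplitude 1, blur 0.7); they are starting
points for real data, not values taken from any screen.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage import draw
from skimage.morphology import disk as _disk

from .detect import SegmentationParams
from .io import IntensityImage

#: rendered signal amplitude (background is 0)
SIGNAL_AMPLITUDE = 1.0

#: segmentation defaults calibrated to this generator's rendering
DEFAULT_CILIA_PARAMS = SegmentationParams(intensity_threshold=0.5, min_size=8)
DEFAULT_BB_PARAMS = SegmentationParams(intensity_threshold=0.5, min_size=5, max_size=500)

_EDGE_MARGIN = 7  # px each cell keeps from its tile border; 2x > pairing radius 12


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene.

    Distances are pixels, intensities are in units of the rendered
    amplitude (1.0), so ``noise_sigma=0.2`` means noise at 20% of the
    signal amplitude.  ``seed`` fixes all randomness; the same spec
    always renders bit-identical images.
    """

    image_size: tuple[int, int] = (800, 800)
    n_cells: int = 20
    ciliated_fraction: float = 0.6
    cilium_length_range: tuple[float, float] = (12.0, 25.0)
    cilium_width: int = 3
    cilium_curvature: float = 0.12
    bb_radius: float = 3.0
    bb_cilium_gap_range: tuple[float, float] = (2.0, 8.0)
    distractor_rate: float = 4.0
    noise_sigma: float = 0.0
    blur_sigma: float = 0.7
    n_multi_bb: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ciliated_fraction <= 1.0):
            raise ValueError("ciliated_fraction must be in [0, 1]")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.bb_cilium_gap_range
        if lo < 0 or hi < lo:
            raise ValueError("bb_cilium_gap_range endpoints must satisfy 0 <= lo <= hi")
        lo, hi = self.cilium_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("cilium_length_range endpoints must satisfy 0 < lo <= hi")
        if self.cilium_width < 1:
            raise ValueError("cilium_width must be >= 1")
        if self.n_multi_bb > self.planted_ciliated_count:
            raise ValueError("n_multi_bb cannot exceed the planted ciliated count")

    @property
    def planted_ciliated_count(self) -> int:
        """Number of ciliated cells planted: round-half-even of
        ciliated_fraction * n_cells."""
        return int(round(self.ciliated_fraction * self.n_cells))


@dataclass
class PlantedCilium:
    """One planted cilium: its centerline polyline (float (M, 2)), the
    index of the basal body it is attached to (None for a free cilium),
    and the length of the rendered structure."""

    polyline: np.ndarray
    attached_bb: Optional[int]
    length: float


@dataclass
class GroundTruth:
    """Everything the generator planted in a scene."""

    basal_body_centers: list[tuple[float, float]]
    cilium_polylines: list[PlantedCilium]
    n_cells: int
    planted_ciliated_count: int
    planted_multi_bb_cases: list[tuple[int, int]] = field(default_factory=list)

    @property
    def true_ciliated_fraction(self) -> Optional[float]:
        if self.n_cells == 0:
            return None
        return self.planted_ciliated_count / self.n_cells

    @property
    def expected_percent(self) -> Optional[float]:
        """Percent ciliated the pairing rule should report: planted
        cilia minus multi-basal-body artifacts, over all planted
        basal-body puncta (artifact extras included)."""
        denom = len(self.basal_body_centers)
        if denom == 0:
            return None
        confirmed = self.planted_ciliated_count - len(self.planted_multi_bb_cases)
        return 100.0 * confirmed / denom

    def to_json(self, path) -> None:
        d = {
            "basal_body_centers": [list(c) for c in self.basal_body_centers],
            "cilium_polylines": [
                {
                    "polyline": c.polyline.tolist(),
                    "attached_bb": c.attached_bb,
                    "length": c.length,
                }
                for c in self.cilium_polylines
            ],
            "n_cells": self.n_cells,
            "planted_ciliated_count": self.planted_ciliated_count,
            "planted_multi_bb_cases": [list(p) for p in self.planted_multi_bb_cases],
            "expected_percent": self.expected_percent,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            basal_body_centers=[tuple(c) for c in d["basal_body_centers"]],
            cilium_polylines=[
                PlantedCilium(np.asarray(c["polyline"], dtype=float),
                              c["attached_bb"], c["length"])
                for c in d["cilium_polylines"]
            ],
            n_cells=d["n_cells"],
            planted_ciliated_count=d["planted_ciliated_count"],
            planted_multi_bb_cases=[tuple(p) for p in d["planted_multi_bb_cases"]],
        )


def _bezier_polyline(p0, p1, p2, arc_length: float, n_samples: int = 2000) -> np.ndarray:
    """Dense polyline along a quadratic Bezier, trimmed to ``arc_length``."""
    t = np.linspace(0.0, 1.0, n_samples)[:, None]
    pts = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * p1 + t ** 2 * p2
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts[s <= arc_length]


def _dilation_radius(width: int) -> float:
    if width <= 1:
        return 0.0
    if width == 2:
        return 0.5
    return float((width - 1) // 2)


def _rasterize_polyline(polyline: np.ndarray, width: int, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    ij = np.round(polyline).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, shape[1] - 1)
    mask[ij[:, 0], ij[:, 1]] = True
    if width == 2:
        mask = binary_dilation(mask, np.ones((2, 2), dtype=bool))
    elif width >= 3:
        mask = binary_dilation(mask, _disk((width - 1) // 2))
    return mask


def render_cilium(
    start,
    theta: float,
    length: float,
    width: int = 3,
    curvature: float = 0.0,
    shape=(200, 200),
) -> tuple[np.ndarray, np.ndarray, float]:
    """Render a single cilium and report its true length.

    The centerline is a quadratic Bezier leaving ``start`` in direction
    ``theta`` (radians; 0 points along +col) whose control point is
    displaced perpendicular to the chord by ``curvature * length``,
    trimmed to an arc length of ``length`` and dilated to ``width``.
    Returns ``(mask, polyline, true_length)`` where ``true_length`` is
    the tip-to-tip extent of the *rendered* structure: the centerline
    arc length plus the dilation radius protruding past each endpoint.
    """
    u = np.array([math.sin(theta), math.cos(theta)])
    nvec = np.array([math.cos(theta), -math.sin(theta)])
    p0 = np.asarray(start, dtype=float)
    p2 = p0 + length * u
    p1 = (p0 + p2) / 2.0 + curvature * length * nvec
    poly = _bezier_polyline(p0, p1, p2, length)
    mask = _rasterize_polyline(poly, width, shape)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
    true_length = float(seg + 2.0 * _dilation_radius(width))
    return mask, poly, true_length


def _grid_layout(spec: SceneSpec, rng: np.random.Generator):
    """Assign each cell a tile on a shuffled grid and return per-cell
    anchor (basal-body center) positions.  Raises when the cells cannot
    be placed without risking cross-cell pairing interference."""
    n = spec.n_cells
    if n == 0:
        return []
    g = math.ceil(math.sqrt(n))
    tile_r = spec.image_size[0] // g
    tile_c = spec.image_size[1] // g
    reach = (
        spec.bb_cilium_gap_range[1]
        + spec.cilium_length_range[1] * (1.0 + spec.cilium_curvature / 2.0)
        + spec.cilium_width
        + 2.0
    )
    slack = min(tile_r, tile_c) / 2.0 - reach - _EDGE_MARGIN
    if slack < 0:
        raise ValueError(
            f"cannot place {n} cells with reach {reach:.1f}px in a "
            f"{spec.image_size} image without overlap risk; enlarge the image "
            f"or shorten the cilia"
        )
    tiles = [(i, j) for i in range(g) for j in range(g)]
    order = rng.permutation(len(tiles))[:n]
    anchors = []
    for k in order:
        ti, tj = tiles[k]
        cr = ti * tile_r + tile_r / 2.0
        cc = tj * tile_c + tile_c / 2.0
        jitter = rng.uniform(-slack, slack, size=2)
        anchors.append((cr + jitter[0], cc + jitter[1]))
    return anchors


def _render_disk(img: np.ndarray, center, radius: float, amplitude: float) -> None:
    rr, cc = draw.disk(center, radius, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], amplitude)


def generate_scene(
    spec: SceneSpec,
) -> tuple[IntensityImage, IntensityImage, IntensityImage, GroundTruth]:
    """Render one synthetic scene: (cilia, basal-body, nuclei) planes
    plus its ground truth.  Deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_size)
    cilia = np.zeros(shape, dtype=np.float64)
    basal = np.zeros(shape, dtype=np.float64)
    nuclei = np.zeros(shape, dtype=np.float64)

    anchors = _grid_layout(spec, rng)
    n = spec.n_cells
    k = spec.planted_ciliated_count
    ciliated = np.zeros(n, dtype=bool)
    if n:
        ciliated[rng.permutation(n)[:k]] = True

    bb_centers: list[tuple[float, float]] = []
    planted: list[PlantedCilium] = []
    multi_cases: list[tuple[int, int]] = []
    r_dil = _dilation_radius(spec.cilium_width)
    n_multi_left = spec.n_multi_bb

    for i, anchor in enumerate(anchors):
        bb_centers.append(anchor)
        _render_disk(basal, anchor, spec.bb_radius, SIGNAL_AMPLITUDE)
        theta = rng.uniform(0.0, 2.0 * math.pi)
        u = np.array([math.sin(theta), math.cos(theta)])
        nvec = np.array([math.cos(theta), -math.sin(theta)])
        # dim nucleus behind the basal body (display only)
        nuc_center = np.asarray(anchor) - 10.0 * u
        rr, cc = draw.ellipse(nuc_center[0], nuc_center[1], 14, 10,
                              shape=shape, rotation=theta)
        nuclei[rr, cc] = np.maximum(nuclei[rr, cc], 0.35 * SIGNAL_AMPLITUDE)
        if not ciliated[i]:
            continue
        is_multi = n_multi_left > 0
        gap_lo, gap_hi = spec.bb_cilium_gap_range
        if is_multi:
            # keep the extra punctum's distance to the cilium safely < 12
            gap_hi = min(gap_hi, 5.0)
        gap = rng.uniform(gap_lo, gap_hi)
        length = rng.uniform(*spec.cilium_length_range)
        curv = rng.uniform(-spec.cilium_curvature, spec.cilium_curvature)
        # start the centerline one dilation radius further out so the
        # rendered proximal boundary sits ~gap from the basal-body center
        p0 = np.asarray(anchor) + (gap + r_dil) * u
        mask, poly, true_len = render_cilium(p0, theta, length, spec.cilium_width,
                                             curv, shape)
        cilia[mask] = SIGNAL_AMPLITUDE
        planted.append(PlantedCilium(polyline=poly, attached_bb=i, length=true_len))
        if is_multi:
            n_multi_left -= 1
            extra = np.asarray(anchor) + 8.0 * nvec
            bb_centers.append((float(extra[0]), float(extra[1])))
            _render_disk(basal, extra, spec.bb_radius, SIGNAL_AMPLITUDE)
            multi_cases.append((len(planted) - 1, len(bb_centers) - 1))

    # distractor puncta in the cilia channel, kept clear of real objects
    n_distr = int(rng.poisson(spec.distractor_rate)) if spec.distractor_rate > 0 else 0
    keepout = [np.asarray(c) for c in bb_centers]
    keepout += [p for c in planted for p in c.polyline[::20]]
    keepout = np.asarray(keepout) if keepout else np.empty((0, 2))
    for _ in range(n_distr):
        for _attempt in range(50):
            pos = rng.uniform([10, 10], [shape[0] - 10, shape[1] - 10])
            if len(keepout) == 0 or np.linalg.norm(keepout - pos, axis=1).min() >= 20:
                _render_disk(cilia, pos, 1.0, SIGNAL_AMPLITUDE)
                break

    if spec.blur_sigma > 0:
        cilia = gaussian_filter(cilia, spec.blur_sigma)
        basal = gaussian_filter(basal, spec.blur_sigma)
        nuclei = gaussian_filter(nuclei, spec.blur_sigma)
    if spec.noise_sigma > 0:
        cilia = cilia + rng.normal(0.0, spec.noise_sigma, shape)
        basal = basal + rng.normal(0.0, spec.noise_sigma, shape)
        nuclei = nuclei + rng.normal(0.0, spec.noise_sigma, shape)
        cilia = np.clip(cilia, 0.0, None)
        basal = np.clip(basal, 0.0, None)
        nuclei = np.clip(nuclei, 0.0, None)

    truth = GroundTruth(
        basal_body_centers=bb_centers,
        cilium_polylines=planted,
        n_cells=n,
        planted_ciliated_count=k,
        planted_multi_bb_cases=multi_cases,
    )
    return (
        IntensityImage(cilia),
        IntensityImage(basal),
        IntensityImage(nuclei),
        truth,
    )


# ---------------------------------------------------------------------------
# synthetic plates


def _well_ids(n_wells: int) -> list[str]:
    ncols = 24 if n_wells > 96 else 12
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    ids = []
    for i in range(n_wells):
        row, col = divmod(i, ncols)
        ids.append(f"{letters[row]}{col + 1:02d}")
    return ids


def generate_plate(
    n_wells: int = 384,
    null_mean: float = 20.0,
    null_sd: float = 4.0,
    spike_z: Sequence[float] = (),
    pos_control: Optional[tuple[float, float, int]] = None,
    neg_control: Optional[tuple[float, float, int]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a screening plate of percent-ciliated well readouts.

    Sample wells are i.i.d. normal(null_mean, null_sd); each entry of
    ``spike_z`` plants one randomly chosen sample well whose readout is
    set to ``null_mean + z * null_sd`` -- an active compound with a
    known displacement of z null SDs.  ``pos_control``/
    ``neg_control`` are optional ``(mean, sd, n)`` tuples appended as
    control wells.  Returns ``(wells, truth)``: a DataFrame with columns
    well, compound, dose, role, percent_ciliated, and a dict recording
    the spiked compounds and their true effect sizes.
    """
    rng = np.random.default_rng(seed)
    values = rng.normal(null_mean, null_sd, size=n_wells)
    spike_idx = rng.choice(n_wells, size=len(spike_z), replace=False) if spike_z else []
    for idx, z in zip(spike_idx, spike_z):
        values[idx] = null_mean + z * null_sd
    rows = []
    compounds = [f"CPD{i + 1:04d}" for i in range(n_wells)]
    for well, cpd, v in zip(_well_ids(n_wells), compounds, values):
        rows.append({"well": well, "compound": cpd, "dose": 1.0, "role": "sample",
                     "percent_ciliated": float(v)})
    for role, ctrl in (("pos_control", pos_control), ("neg_control", neg_control)):
        if ctrl is None:
            continue
        mean, sd, n_ctrl = ctrl
        vals = rng.normal(mean, sd, size=n_ctrl)
        start = len(rows)
        for j, v in enumerate(vals):
            rows.append({"well": _well_ids(start + n_ctrl)[start + j],
                         "compound": role, "dose": 0.0, "role": role,
                         "percent_ciliated": float(v)})
    wells = pd.DataFrame(rows, columns=["well", "compound", "dose", "role",
                                        "percent_ciliated"])
    truth = {
        "null_mean": null_mean,
        "null_sd": null_sd,
        "spiked_compounds": [compounds[i] for i in spike_idx],
        "spike_z": list(spike_z),
    }
    return wells, truth
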