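"""Image loading, channel mapping, and tabular output.

Microscopy exports arrive either as RGB rasters (cilia in green, basal
bodies in red, DAPI in blue) or as multi-channel TIFF stacks.  A
:class:`ChannelMap` names which plane plays which biological role; color
names are accepted for RGB(A) images, integer indices for anything.
Intensities are used in their native units -- no rescaling -- because
segmentation thresholds are configured in those same units.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

ChannelRef = Union[int, str]

_COLOR_INDEX = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class ChannelMap:
    """Assignment of image planes to biological roles.

    Parameters
    ----------
    cilia
        Plane holding the cilium marker (acetylated alpha-tubulin).
    basal_body
        Plane holding the basal-body marker (pericentrin).
    nuclei
        Optional plane holding the nuclear counterstain (DAPI).  The
        nuclear channel is display-only; it never enters quantification.

    Each entry is a 0-based integer index or one of ``"red"``,
    ``"green"``, ``"blue"`` (valid only for RGB(A) inputs).
    """

    cilia: ChannelRef
    basal_body: ChannelRef
    nuclei: Optional[ChannelRef] = None

    def __post_init__(self) -> None:
        for name, ref in (("cilia", self.cilia), ("basal_body", self.basal_body),
                          ("nuclei", self.nuclei)):
            if ref is None:
                continue
            if isinstance(ref, str):
                if ref not in _COLOR_INDEX:
                    raise ValueError(
                        f"channel {name!r}: unknown color name {ref!r} "
                        f"(expected one of {sorted(_COLOR_INDEX)})"
                    )
            elif isinstance(ref, (int, np.integer)):
                if ref < 0:
                    raise ValueError(f"channel {name!r}: index must be >= 0, got {ref}")
            else:
                raise TypeError(f"channel {name!r}: expected int or color name, got {ref!r}")

    def resolve(self, n_channels: int) -> tuple[int, int, Optional[int]]:
        """Map the three roles to concrete plane indices for an image with
        ``n_channels`` planes, enforcing distinctness of cilia/basal-body."""
        out = []
        for name, ref in (("cilia", self.cilia), ("basal_body", self.basal_body),
                          ("nuclei", self.nuclei)):
            if ref is None:
                out.append(None)
                continue
            if isinstance(ref, str):
                if n_channels not in (3, 4):
                    raise ValueError(
                        f"channel {name!r}: color name {ref!r} requires an RGB(A) "
                        f"image, but the input has {n_channels} channel(s)"
                    )
                idx = _COLOR_INDEX[ref]
            else:
                idx = int(ref)
            if idx >= n_channels:
                raise ValueError(
                    f"channel {name!r}: index {idx} out of range for an image "
                    f"with {n_channels} channel(s)"
                )
            out.append(idx)
        if out[0] == out[1]:
            raise ValueError("cilia and basal-body channels must be distinct")
        return out[0], out[1], out[2]


@dataclass
class IntensityImage:
    """A single grayscale plane with optional physical pixel size.

    ``pixels`` is a 2-D array of finite, non-negative intensities in
    native units.  ``pixel_size`` (um/pixel) is carried as metadata only;
    every measurement in the package is reported in pixels.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("IntensityImage requires a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("IntensityImage intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def _split_channels(arr: np.ndarray) -> tuple[np.ndarray, int]:
    """Return (planes stacked on axis 0, n_channels).

    Channel-axis heuristic: 2-D arrays are single-channel; for 3-D
    arrays a trailing axis of length 3 or 4 is treated as RGB(A)
    (channels-last, the PNG convention), otherwise a small leading axis
    is treated as the channel axis (the TIFF stack convention).
    """
    if arr.ndim == 2:
        return arr[None], 1
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4) and arr.shape[-1] < min(arr.shape[:2]):
            return np.moveaxis(arr, -1, 0), arr.shape[-1]
        if arr.shape[0] <= 16 and arr.shape[0] < min(arr.shape[1:]):
            return arr, arr.shape[0]
    raise ValueError(f"cannot interpret array of shape {arr.shape} as a 2-D multichannel image")


def load_image(
    path: Union[str, Path],
    channel_map: ChannelMap,
    pixel_size: Optional[float] = None,
) -> tuple[IntensityImage, IntensityImage, Optional[IntensityImage]]:
    """Load a raster and split it into (cilia, basal-body, nuclei) planes.

    Returns one grayscale :class:`IntensityImage` per mapped role; the
    nuclei element is ``None`` when the map has no nuclear channel.  All
    planes share the same dimensions.  Raises ``FileNotFoundError`` for a
    missing file and ``ValueError`` for an out-of-range or non-distinct
    channel assignment.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    arr = _read_raster(path)
    planes, n_channels = _split_channels(arr)
    ci, bi, ni = channel_map.resolve(n_channels)
    cilia = IntensityImage(planes[ci], pixel_size)
    basal = IntensityImage(planes[bi], pixel_size)
    nuclei = IntensityImage(planes[ni], pixel_size) if ni is not None else None
    return cilia, basal, nuclei


def write_image(path: Union[str, Path], planes: Sequence[np.ndarray]) -> None:
    """Write a multichannel TIFF with channels on axis 0."""
    import tifffile

    stack = np.stack([np.asarray(p) for p in planes])
    tifffile.imwrite(Path(path), stack, photometric="minisblack")


# ---------------------------------------------------------------------------
# tabular output


def _row_dict(row) -> dict:
    """Flatten a measurement dataclass to scalar CSV fields, dropping
    list-valued members (e.g. a well's per-image measurements)."""
    if dataclasses.is_dataclass(row):
        d = {f.name: getattr(row, f.name) for f in dataclasses.fields(row)}
    elif isinstance(row, dict):
        d = dict(row)
    else:
        raise TypeError(f"cannot serialize row of type {type(row)!r}")
    return {k: v for k, v in d.items() if not isinstance(v, (list, tuple, np.ndarray))}


def write_measurements(
    rows: Sequence,
    path: Union[str, Path],
    sort: bool = True,
    fields: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Write measurement rows to CSV with a stable header and row order.

    Rows must share a schema (same dataclass or same dict keys).  The
    table is sorted by its first column (image or well identifier) so the
    output is deterministic regardless of processing order.  ``None`` /
    undefined values are written as empty cells, never as 0.  An empty
    row list yields a header-only CSV, taking the header from ``fields``
    (or from the dataclass type passed as ``fields``).  Returns the
    DataFrame that was written.
    """
    path = Path(path)
    dicts = [_row_dict(r) for r in rows]
    if dicts:
        cols = list(dicts[0])
        for d in dicts[1:]:
            if list(d) != cols:
                raise ValueError("rows passed to write_measurements do not share a schema")
        df = pd.DataFrame(dicts, columns=cols)
        if sort:
            df = df.sort_values(cols[0], kind="stable").reset_index(drop=True)
    else:
        if fields is None:
            raise ValueError("empty row list: pass `fields` to emit a header-only CSV")
        if dataclasses.is_dataclass(fields):
            fields = [f.name for f in dataclasses.fields(fields)]
        df = pd.DataFrame(columns=list(fields))
    df.to_csv(path, index=False)
    return df


def header_only_csv(fields: Sequence[str], path: Union[str, Path]) -> None:
    """Write a CSV containing only the header row (empty measurement set)."""
    pd.DataFrame(columns=list(fields)).to_csv(Path(path), index=False)


def read_measurements(path: Union[str, Path], cls=None) -> list:
    """Read a measurement CSV back; inverse of :func:`write_measurements`.

    With ``cls`` given (a dataclass), rows are rebuilt as instances with
    empty cells restored to ``None``; otherwise a list of dicts is
    returned.
    """
    df = pd.read_csv(Path(path))
    records = df.to_dict(orient="records")
    cleaned = [{k: (None if (isinstance(v, float) and np.isnan(v)) else v)
                for k, v in rec.items()} for rec in records]
    if cls is None:
        return cleaned
    field_names = {f.name for f in dataclasses.fields(cls)}
    out = []
    for rec in cleaned:
        kwargs = {k: v for k, v in rec.items() if k in field_names}
        out.append(cls(**kwargs))
    return out
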