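"""Run configuration: channel map, thresholds, pairing distances.

A run is fully described by a :class:`RunConfig`, assembled from (in
increasing precedence) package defaults, a YAML/JSON config file, and
command-line flags.  The effective configuration is serialized into the
output directory so every result folder records how it was produced.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .detect import SegmentationParams
from .io import ChannelMap
from .morpho import LENGTH_MODES
from .pairing import PairingParams
from .synthgen import DEFAULT_BB_PARAMS, DEFAULT_CILIA_PARAMS


@dataclass
class RunConfig:
    """Validated configuration of an analysis run."""

    channel_map: ChannelMap = field(default_factory=lambda: ChannelMap("green", "red", "blue"))
    cilia: SegmentationParams = DEFAULT_CILIA_PARAMS
    basal_body: SegmentationParams = DEFAULT_BB_PARAMS
    pairing: PairingParams = field(default_factory=PairingParams)
    length_mode: str = "half_perimeter"
    exclude_artifact_bbs: bool = False

    def __post_init__(self) -> None:
        if self.length_mode not in LENGTH_MODES:
            raise ValueError(f"length_mode must be one of {LENGTH_MODES}")

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            return obj

        return enc(self)

    def dump(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")


def _seg_from_dict(d: dict, base: SegmentationParams) -> SegmentationParams:
    kwargs = {f.name: getattr(base, f.name) for f in dataclasses.fields(SegmentationParams)}
    kwargs.update({k: v for k, v in d.items() if k in kwargs})
    return SegmentationParams(**kwargs)


def load_config(path: Optional[Union[str, Path]] = None, overrides: Optional[dict] = None) -> RunConfig:
    """Build a RunConfig from defaults <- YAML/JSON file <- overrides.

    The file may contain keys ``channel_map`` (cilia / basal_body /
    nuclei), ``cilia`` and ``basal_body`` (segmentation parameters),
    ``pairing`` (max_distance / vicinity_distance), ``length_mode`` and
    ``exclude_artifact_bbs``.  ``overrides`` uses dotted keys, e.g.
    ``{"pairing.max_distance": 10}``; ``None``-valued overrides are
    ignored.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    cfg = RunConfig()
    cm = data.get("channel_map", {})
    channel_map = ChannelMap(
        cilia=cm.get("cilia", cfg.channel_map.cilia),
        basal_body=cm.get("basal_body", cfg.channel_map.basal_body),
        nuclei=cm.get("nuclei", cfg.channel_map.nuclei),
    )
    cilia = _seg_from_dict(data.get("cilia", {}), cfg.cilia)
    bb = _seg_from_dict(data.get("basal_body", {}), cfg.basal_body)
    pr = data.get("pairing", {})
    pairing = PairingParams(
        max_distance=pr.get("max_distance", 12.0),
        vicinity_distance=pr.get("vicinity_distance", None),
    )
    cfg = RunConfig(
        channel_map=channel_map,
        cilia=cilia,
        basal_body=bb,
        pairing=pairing,
        length_mode=data.get("length_mode", "half_perimeter"),
        exclude_artifact_bbs=bool(data.get("exclude_artifact_bbs", False)),
    )
    if overrides:
        cfg = _apply_overrides(cfg, overrides)
    return cfg


def _apply_overrides(cfg: RunConfig, overrides: dict) -> RunConfig:
    ov = {k: v for k, v in overrides.items() if v is not None}
    cm = cfg.channel_map
    if {"channel_map.cilia", "channel_map.basal_body", "channel_map.nuclei"} & ov.keys():
        cm = ChannelMap(
            cilia=ov.get("channel_map.cilia", cm.cilia),
            basal_body=ov.get("channel_map.basal_body", cm.basal_body),
            nuclei=ov.get("channel_map.nuclei", cm.nuclei),
        )
    cilia = _seg_from_dict(
        {k.split(".", 1)[1]: v for k, v in ov.items() if k.startswith("cilia.")}, cfg.cilia)
    bb = _seg_from_dict(
        {k.split(".", 1)[1]: v for k, v in ov.items() if k.startswith("basal_body.")},
        cfg.basal_body)
    pairing = PairingParams(
        max_distance=ov.get("pairing.max_distance", cfg.pairing.max_distance),
        vicinity_distance=ov.get("pairing.vicinity_distance", cfg.pairing.vicinity_distance),
    )
    return RunConfig(
        channel_map=cm,
        cilia=cilia,
        basal_body=bb,
        pairing=pairing,
        length_mode=ov.get("length_mode", cfg.length_mode),
        exclude_artifact_bbs=ov.get("exclude_artifact_bbs", cfg.exclude_artifact_bbs),
    )
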