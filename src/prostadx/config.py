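"""Run configuration: one nested JSON document covering every module.

Unknown keys are rejected so typos cannot silently fall back to defaults.
The canonical-JSON SHA-256 hash of a config is recorded in every report for
provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .fusion import FusionWeightTable
from .imaging import ImagingParams
from .mlp import NetworkConfig
from .panel import ReferenceRanges

__all__ = ["RunConfig", "config_hash"]

_MARKER_NET_DEFAULT = (6, 4, 1)
_IMAGE_NET_DEFAULT = (2, 3, 1)


def _kwargs_checked(cls, data: dict, section: str) -> dict:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise KeyError(f"unknown keys in config section {section!r}: {sorted(unknown)}")
    return data


@dataclass(frozen=True)
class RunConfig:
    imaging: ImagingParams = field(default_factory=ImagingParams)
    ranges: ReferenceRanges = field(default_factory=ReferenceRanges.default)
    marker_net: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(layer_sizes=_MARKER_NET_DEFAULT)
    )
    image_net: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(layer_sizes=_IMAGE_NET_DEFAULT)
    )
    fusion: FusionWeightTable = field(default_factory=FusionWeightTable)

    def to_dict(self) -> dict:
        return {
            "imaging": dataclasses.asdict(self.imaging),
            "ranges": self.ranges.to_dict(),
            "marker_net": self.marker_net.to_dict(),
            "image_net": self.image_net.to_dict(),
            "fusion": self.fusion.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"imaging", "ranges", "marker_net", "image_net", "fusion"}
        unknown = set(data) - known
        if unknown:
            raise KeyError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        if "imaging" in data:
            im = dict(data["imaging"])
            if "gray_weights" in im:
                im["gray_weights"] = tuple(im["gray_weights"])
            kwargs["imaging"] = ImagingParams(**_kwargs_checked(ImagingParams, im, "imaging"))
        if "ranges" in data:
            kwargs["ranges"] = ReferenceRanges.from_dict(data["ranges"])
        for key, default_sizes in (("marker_net", _MARKER_NET_DEFAULT), ("image_net", _IMAGE_NET_DEFAULT)):
            if key in data:
                nc = dict(data[key])
                nc.setdefault("layer_sizes", list(default_sizes))
                nc["layer_sizes"] = tuple(nc["layer_sizes"])
                kwargs[key] = NetworkConfig(**_kwargs_checked(NetworkConfig, nc, key))
        if "fusion" in data:
            kwargs["fusion"] = FusionWeightTable(
                **_kwargs_checked(FusionWeightTable, dict(data["fusion"]), "fusion")
            )
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @property
    def hash(self) -> str:
        return config_hash(self)


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
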