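"""Marker panels, reference ranges, validation, and input scaling.

The diagnostic model consumes two vectors: six serum markers
(TPSA, RBC, HB, FPSA, PAP, PSMA) and two image features (lesion area, mean
gray level).  This module assembles, cleans, validates, and min-max scales
them into the fixed-order 8-vector consumed by the networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from numbers import Real
from typing import Mapping

import numpy as np

__all__ = [
    "MARKERS",
    "FEATURES",
    "MarkerPanel",
    "ImageFeatures",
    "IndicatorRange",
    "ReferenceRanges",
    "ValidationReport",
    "validate_record",
    "largest_normal",
    "scale_inputs",
    "assemble_acp",
    "assemble_ahp",
]

MARKERS = ("tpsa", "rbc", "hb", "fpsa", "pap", "psma")
FEATURES = MARKERS + ("area", "gray_level")


@dataclass(frozen=True)
class MarkerPanel:
    """Six serum markers; ``None`` marks a missing value.

    Units: tpsa ng/ml, rbc g/100 ml, hb g/L, fpsa ug/L, pap ng/ml,
    psma ng/ml.  Units are carried opaquely and never converted.
    """

    tpsa: float | None = None
    rbc: float | None = None
    hb: float | None = None
    fpsa: float | None = None
    pap: float | None = None
    psma: float | None = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in MARKERS}


@dataclass(frozen=True)
class ImageFeatures:
    """Lesion area (pixels) and mean gray level in [0, 255]."""

    area: float
    gray_level: float


@dataclass(frozen=True)
class IndicatorRange:
    """(lower, upper, cap): the normal range [lower, upper] plus a
    plausibility cap above which a value is treated as a recording error."""

    lower: float
    upper: float
    cap: float

    def __post_init__(self):
        if not (self.lower <= self.upper < self.cap):
            raise ValueError(
                f"require lower <= upper < cap, got ({self.lower}, {self.upper}, {self.cap})"
            )


def _default_ranges() -> dict[str, IndicatorRange]:
    # Normal bounds follow the clinical reference table; plausibility caps
    # are configurable defaults (the source gives none).
    return {
        "tpsa": IndicatorRange(0.0, 4.0, 1000.0),
        "rbc": IndicatorRange(12.0, 15.0, 25.0),
        "hb": IndicatorRange(120.0, 165.0, 250.0),
        "fpsa": IndicatorRange(4.0, 20.0, 500.0),
        "pap": IndicatorRange(0.0, 3.5, 100.0),
        "psma": IndicatorRange(0.0, 4.0, 100.0),
        "area": IndicatorRange(0.0, 50.0, 4096.0),
        "gray_level": IndicatorRange(0.0, 180.0, 255.0),
    }


@dataclass(frozen=True)
class ReferenceRanges:
    """Per-indicator (lower, upper, cap) table."""

    ranges: Mapping[str, IndicatorRange] = field(default_factory=_default_ranges)

    def __getitem__(self, name: str) -> IndicatorRange:
        try:
            return self.ranges[name]
        except KeyError:
            raise KeyError(f"unknown indicator {name!r}") from None

    @classmethod
    def default(cls) -> "ReferenceRanges":
        return cls()

    @classmethod
    def from_dict(cls, data: Mapping) -> "ReferenceRanges":
        base = _default_ranges()
        for name, triple in data.items():
            if name not in base:
                raise KeyError(f"unknown indicator {name!r}")
            base[name] = IndicatorRange(*map(float, triple))
        return cls(ranges=base)

    def to_dict(self) -> dict:
        return {k: [v.lower, v.upper, v.cap] for k, v in self.ranges.items()}

    @classmethod
    def from_json(cls, path) -> "ReferenceRanges":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class ValidationReport:
    """Per-field status plus the overall accept/reject decision.

    Field statuses: ``ok``, ``out_of_range``, ``missing``, ``nonnumeric``.
    A record is accepted iff every field is present, numeric, nonnegative and
    at most the plausibility cap.  Values above the normal range but below
    the cap are accepted: they are disease signal, not recording errors.
    """

    record_id: str | None
    fields: Mapping[str, str]
    accepted: bool

    @property
    def status(self) -> str:
        return "accepted" if self.accepted else "rejected"


def _field_status(value, rng: IndicatorRange) -> str:
    if value is None:
        return "missing"
    if isinstance(value, bool) or not isinstance(value, Real):
        try:
            value = float(value)
        except (TypeError, ValueError):
            return "nonnumeric"
    value = float(value)
    if value != value:  # NaN
        return "nonnumeric"
    if value < 0 or value > rng.cap:
        return "out_of_range"
    return "ok"


def validate_record(
    panel: MarkerPanel,
    ranges: ReferenceRanges | None = None,
    record_id: str | None = None,
) -> ValidationReport:
    """Classify each marker as ok / out_of_range / missing / nonnumeric."""
    ranges = ranges or ReferenceRanges.default()
    statuses = {name: _field_status(getattr(panel, name), ranges[name]) for name in MARKERS}
    accepted = all(s == "ok" for s in statuses.values())
    return ValidationReport(record_id=record_id, fields=statuses, accepted=accepted)


def largest_normal(indicator: str, ranges: ReferenceRanges | None = None) -> float:
    """Upper bound of the indicator's normal range — the largest value the
    validator classifies as normal."""
    ranges = ranges or ReferenceRanges.default()
    return ranges[indicator].upper


def scale_inputs(
    panel: MarkerPanel,
    feats: ImageFeatures,
    ranges: ReferenceRanges | None = None,
) -> np.ndarray:
    """Min-max scale every feature to [0, 1] in the fixed order
    (tpsa, rbc, hb, fpsa, pap, psma, area, gray_level).

    Each value maps through ``(v - lower) / (cap - lower)`` and is clipped to
    [0, 1].  Raises on a panel the validator rejects.
    """
    ranges = ranges or ReferenceRanges.default()
    report = validate_record(panel, ranges)
    if not report.accepted:
        bad = {k: v for k, v in report.fields.items() if v != "ok"}
        raise ValueError(f"panel rejected by validator: {bad}")
    raw = dict(panel.as_dict())
    raw["area"] = feats.area
    raw["gray_level"] = feats.gray_level
    out = np.empty(len(FEATURES), dtype=float)
    for i, name in enumerate(FEATURES):
        r = ranges[name]
        out[i] = (float(raw[name]) - r.lower) / (r.cap - r.lower)
    return np.clip(out, 0.0, 1.0)


def assemble_acp(scaled: np.ndarray) -> np.ndarray:
    """First six entries: the serum-marker vector."""
    v = np.asarray(scaled, dtype=float)
    if v.shape != (8,):
        raise ValueError(f"expected a length-8 scaled vector, got shape {v.shape}")
    return v[:6].copy()


def assemble_ahp(scaled: np.ndarray) -> np.ndarray:
    """Last two entries: the image-feature vector."""
    v = np.asarray(scaled, dtype=float)
    if v.shape != (8,):
        raise ValueError(f"expected a length-8 scaled vector, got shape {v.shape}")
    return v[6:].copy()
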