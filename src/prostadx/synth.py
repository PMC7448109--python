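"""Reproducible synthetic cohorts: stage-labelled marker panels and lesion
images with exact ground truth.

The distributions are *fabricated defaults* shaped by qualitative clinical
anchors only: TPSA medians rise steeply with stage, the FPSA/TPSA ratio
falls below 0.1 by stage IV, HB/RBC decline mildly, PAP/PSMA rise, and
lesions grow larger and brighter with stage.  All draws are log-normal
(positive support, right-skewed lab values) and clipped to the validator's
plausibility caps.

Randomness flows from one root seed through named substreams (stages,
markers, geometry, noise) so the pieces can be tested in isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import write_image
from .panel import MarkerPanel, ReferenceRanges, validate_record

__all__ = [
    "MarkerModel",
    "LesionModel",
    "CohortSpec",
    "SyntheticPatient",
    "sample_marker_panel",
    "render_lesion_image",
    "generate_cohort",
    "cohort_frame",
    "write_cohort",
    "split_cohort",
]

STAGES = (1, 2, 3, 4)


@dataclass(frozen=True)
class MarkerModel:
    """Per-stage log-normal medians (index 0 = stage I) and a common
    log-scale sigma per marker.  FPSA is derived from TPSA via a declining
    ratio so the FPSA/TPSA trend is built in."""

    tpsa_medians: tuple[float, ...] = (5.0, 12.0, 30.0, 60.0)
    tpsa_sigma: float = 0.20
    ratio_medians: tuple[float, ...] = (0.30, 0.20, 0.13, 0.07)
    ratio_sigma: float = 0.15
    hb_medians: tuple[float, ...] = (145.0, 138.0, 130.0, 122.0)
    hb_sigma: float = 0.03
    rbc_medians: tuple[float, ...] = (14.5, 14.0, 13.4, 12.8)
    rbc_sigma: float = 0.03
    pap_medians: tuple[float, ...] = (1.5, 4.0, 10.0, 25.0)
    pap_sigma: float = 0.20
    psma_medians: tuple[float, ...] = (2.0, 6.0, 15.0, 35.0)
    psma_sigma: float = 0.20


@dataclass(frozen=True)
class LesionModel:
    """Per-stage ellipse semi-axis ranges (pixels), lesion/background
    intensities, and additive Gaussian noise scale."""

    axis_ranges: tuple[tuple[float, float], ...] = ((4.0, 6.0), (7.0, 9.0), (10.0, 12.0), (13.0, 16.0))
    intensities: tuple[float, ...] = (190.0, 200.0, 212.0, 225.0)
    background: float = 100.0
    noise_scale: float = 4.0


@dataclass(frozen=True)
class CohortSpec:
    n: int = 100
    stage_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    image_size: int = 64
    markers: MarkerModel = field(default_factory=MarkerModel)
    lesions: LesionModel = field(default_factory=LesionModel)

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("cohort size must be >= 1")
        mix = tuple(float(p) for p in self.stage_mix)
        if len(mix) != 4 or any(p < 0 for p in mix) or abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("stage_mix must be 4 nonnegative proportions summing to 1")
        object.__setattr__(self, "stage_mix", mix)
        lesions = self.lesions
        if lesions.background >= min(lesions.intensities):
            raise ValueError("lesion intensity must exceed background intensity")
        if not all(0 <= v <= 255 for v in lesions.intensities + (lesions.background,)):
            raise ValueError("intensities must lie in [0, 255]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        data = dict(data)
        if "markers" in data and isinstance(data["markers"], dict):
            mk = {
                k: (tuple(tuple(x) if isinstance(x, list) else x for x in v) if isinstance(v, list) else v)
                for k, v in data["markers"].items()
            }
            data["markers"] = MarkerModel(**mk)
        if "lesions" in data and isinstance(data["lesions"], dict):
            lk = dict(data["lesions"])
            if "axis_ranges" in lk:
                lk["axis_ranges"] = tuple(tuple(r) for r in lk["axis_ranges"])
            if "intensities" in lk:
                lk["intensities"] = tuple(lk["intensities"])
            data["lesions"] = LesionModel(**lk)
        if "stage_mix" in data:
            data["stage_mix"] = tuple(data["stage_mix"])
        return cls(**data)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass(frozen=True)
class SyntheticPatient:
    patient_id: str
    true_stage: int
    panel: MarkerPanel
    image: np.ndarray
    true_area_px: int
    true_mean_gray: float


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def sample_marker_panel(
    stage: int, model: MarkerModel | None = None, rng: np.random.Generator | None = None
) -> MarkerPanel:
    """Draw one stage-conditioned marker panel (clipped to plausibility caps)."""
    if stage not in STAGES:
        raise ValueError(f"invalid stage {stage!r}")
    model = model or MarkerModel()
    rng = rng if rng is not None else np.random.default_rng()
    i = stage - 1
    caps = ReferenceRanges.default()
    tpsa = _lognormal(rng, model.tpsa_medians[i], model.tpsa_sigma)
    ratio = _lognormal(rng, model.ratio_medians[i], model.ratio_sigma)
    values = {
        "tpsa": tpsa,
        "fpsa": ratio * tpsa,
        "hb": _lognormal(rng, model.hb_medians[i], model.hb_sigma),
        "rbc": _lognormal(rng, model.rbc_medians[i], model.rbc_sigma),
        "pap": _lognormal(rng, model.pap_medians[i], model.pap_sigma),
        "psma": _lognormal(rng, model.psma_medians[i], model.psma_sigma),
    }
    clipped = {k: min(v, caps[k].cap) for k, v in values.items()}
    return MarkerPanel(**clipped)


def render_lesion_image(
    stage: int,
    model: LesionModel | None = None,
    rng: np.random.Generator | None = None,
    image_size: int = 64,
) -> tuple[np.ndarray, int, float]:
    """Render one bright axis-aligned elliptical lesion on a noisy darker
    background.  Returns (RGB uint8 image, exact rasterized pixel area,
    mean gray over the true lesion mask)."""
    if stage not in STAGES:
        raise ValueError(f"invalid stage {stage!r}")
    model = model or LesionModel()
    rng = rng if rng is not None else np.random.default_rng()
    lo, hi = model.axis_ranges[stage - 1]
    a = float(rng.uniform(lo, hi))  # semi-axis along x (cols)
    b = float(rng.uniform(lo, hi))  # semi-axis along y (rows)
    margin = max(a, b) + 3.0
    if 2 * margin >= image_size:
        raise ValueError("lesion does not fit in the image")
    cx = float(rng.uniform(margin, image_size - margin))
    cy = float(rng.uniform(margin, image_size - margin))

    rr, cc = np.mgrid[0:image_size, 0:image_size]
    mask = ((cc - cx) / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0
    img = np.full((image_size, image_size), model.background, dtype=float)
    img[mask] = model.intensities[stage - 1]
    if model.noise_scale > 0:
        img += model.noise_scale * rng.standard_normal(img.shape)
    img = np.clip(img, 0, 255)
    true_area = int(mask.sum())
    true_gray = float(img[mask].mean())
    rgb = np.repeat(np.rint(img).astype(np.uint8)[:, :, None], 3, axis=2)
    return rgb, true_area, true_gray


def generate_cohort(spec: CohortSpec) -> list[SyntheticPatient]:
    """Fully seed-reproducible cohort of ``spec.n`` patients."""
    ss = np.random.SeedSequence(spec.seed)
    rng_stage, rng_marker, rng_geom = (np.random.default_rng(s) for s in ss.spawn(3))
    stages = rng_stage.choice(STAGES, size=spec.n, p=spec.stage_mix)
    patients = []
    width = max(4, len(str(spec.n)))
    for k, stage in enumerate(stages):
        stage = int(stage)
        pid = f"P{k + 1:0{width}d}"
        panel = sample_marker_panel(stage, spec.markers, rng_marker)
        image, area, gray = render_lesion_image(stage, spec.lesions, rng_geom, spec.image_size)
        patients.append(
            SyntheticPatient(
                patient_id=pid,
                true_stage=stage,
                panel=panel,
                image=image,
                true_area_px=area,
                true_mean_gray=gray,
            )
        )
    return patients


def cohort_frame(patients: list[SyntheticPatient]) -> pd.DataFrame:
    """Cohort table in the input schema (+ true_area_px ground truth)."""
    rows = []
    for p in patients:
        row = {"patient_id": p.patient_id}
        row.update(p.panel.as_dict())
        row["area"] = p.true_area_px
        row["gray_level"] = p.true_mean_gray
        row["stage"] = p.true_stage
        row["true_area_px"] = p.true_area_px
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(patients: list[SyntheticPatient], outdir, write_images: bool = True) -> Path:
    """Write cohort.csv plus one PNG per patient under images/."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / "cohort.csv"
    cohort_frame(patients).to_csv(csv_path, index=False)
    if write_images:
        imgdir = outdir / "images"
        imgdir.mkdir(exist_ok=True)
        for p in patients:
            write_image(imgdir / f"{p.patient_id}.png", p.image)
    return csv_path


def split_cohort(patients: list[SyntheticPatient], n_train: int):
    """Deterministic head/tail split."""
    if not (0 < n_train < len(patients)):
        raise ValueError("n_train must fall strictly inside the cohort")
    return patients[:n_train], patients[n_train:]
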