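"""Rule-based fusion of the two sub-model scores into a DPC score,
clinical stage, and treatment recommendation, plus classifier evaluation.

The fused score DPC = w_disease * disease_score + w_image * image_score with
w_image = 1 - w_disease.  The weight is picked by a four-case rule table
keyed on which band (EARLY = stages I-II, LATE = stages III-IV) each
sub-score falls in.  DPC maps to stage through the half-open bands
(0, 0.25] -> I, (0.25, 0.50] -> II, (0.50, 0.75] -> III, (0.75, 1.00] -> IV.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from . import mlp, panel as panel_mod

__all__ = [
    "Stage",
    "Band",
    "STAGE_MIDPOINTS",
    "FusionWeightTable",
    "DPCResult",
    "TreatmentPlan",
    "ConfusionCounts",
    "stage_of_score",
    "band_of",
    "select_weights",
    "combine_dpc",
    "recommend",
    "diagnose",
    "evaluate_classifier",
    "roc_points",
]


class Stage(enum.IntEnum):
    I = 1
    II = 2
    III = 3
    IV = 4


class Band(enum.Enum):
    EARLY = "early"  # stages I-II
    LATE = "late"  # stages III-IV


#: Midpoints of the four DPC bands, used as training targets per stage.
STAGE_MIDPOINTS = {Stage.I: 0.125, Stage.II: 0.375, Stage.III: 0.625, Stage.IV: 0.875}

_STAGE_BOUNDS = (0.25, 0.50, 0.75)

#: Verbatim treatment advice per stage.
TREATMENT_ADVICE = {
    Stage.I: "Pay attention to physical changes and observe carefully",
    Stage.II: "Prostatectomy, radioactive implantation",
    Stage.III: "Endocrine therapy, orchiectomy (nonsteroidal antiandrogen intermittent therapy)",
    Stage.IV: "Chemotherapy (CTX, 5-FU, ADM, VLB, and PTX)",
}


def stage_of_score(score: float) -> Stage:
    """Map a DPC score in (0, 1] to a stage; band boundaries belong to the
    lower stage (exact <= on the computed double, so 0.25 -> I)."""
    s = float(score)
    if not (0.0 < s <= 1.0):
        raise ValueError(f"DPC score must lie in (0, 1], got {s}")
    if s <= _STAGE_BOUNDS[0]:
        return Stage.I
    if s <= _STAGE_BOUNDS[1]:
        return Stage.II
    if s <= _STAGE_BOUNDS[2]:
        return Stage.III
    return Stage.IV


def band_of(stage: Stage) -> Band:
    stage = Stage(stage)
    return Band.EARLY if stage in (Stage.I, Stage.II) else Band.LATE


@dataclass(frozen=True)
class FusionWeightTable:
    """w_disease per (disease band, image band) case.

    Invariants follow the rule-table orderings: slightly disease-favouring
    when both bands are EARLY, slightly image-favouring when both are LATE,
    strongly disease-favouring (>= 0.75) when the disease score alone is
    LATE, strongly image-favouring (<= 0.25) when the image score alone is
    LATE.  ``w_image = 1 - w_disease`` always.
    """

    early_early: float = 0.6
    late_late: float = 0.4
    late_early: float = 0.8  # disease LATE, image EARLY
    early_late: float = 0.2  # disease EARLY, image LATE

    def __post_init__(self):
        for v in (self.early_early, self.late_late, self.late_early, self.early_late):
            if not (0.0 < v < 1.0):
                raise ValueError("fusion weights must lie in (0, 1)")
        if not self.early_early > 0.5:
            raise ValueError("case (EARLY, EARLY) requires w_disease > 0.5")
        if not self.late_late < 0.5:
            raise ValueError("case (LATE, LATE) requires w_disease < 0.5")
        if not self.late_early >= 0.75:
            raise ValueError("case (disease LATE, image EARLY) requires w_disease >= 0.75")
        if not self.early_late <= 0.25:
            raise ValueError("case (disease EARLY, image LATE) requires w_disease <= 0.25")

    def to_dict(self) -> dict:
        return {
            "early_early": self.early_early,
            "late_late": self.late_late,
            "late_early": self.late_early,
            "early_late": self.early_late,
        }


def select_weights(
    disease_band: Band, image_band: Band, table: FusionWeightTable | None = None
) -> tuple[float, float]:
    """Deterministic, conflict-free rule lookup: exactly one case fires."""
    table = table or FusionWeightTable()
    key = (Band(disease_band), Band(image_band))
    w_disease = {
        (Band.EARLY, Band.EARLY): table.early_early,
        (Band.LATE, Band.LATE): table.late_late,
        (Band.LATE, Band.EARLY): table.late_early,
        (Band.EARLY, Band.LATE): table.early_late,
    }[key]
    return w_disease, 1.0 - w_disease


@dataclass(frozen=True)
class DPCResult:
    dpc: float
    stage: Stage
    w_disease: float
    w_image: float
    disease_score: float
    image_score: float


@dataclass(frozen=True)
class TreatmentPlan:
    stage: Stage
    advice: str


def combine_dpc(
    disease_score: float, image_score: float, weights: tuple[float, float]
) -> DPCResult:
    """Convex combination of the two sub-scores; DPC lies between them."""
    d, i = float(disease_score), float(image_score)
    for v in (d, i):
        if not (0.0 < v < 1.0):
            raise ValueError(f"sub-model scores must lie in (0, 1), got {v}")
    w_d, w_i = weights
    if abs(w_d + w_i - 1.0) > 1e-12:
        raise ValueError("weights must sum to 1")
    dpc = w_d * d + w_i * i
    return DPCResult(
        dpc=dpc,
        stage=stage_of_score(dpc),
        w_disease=w_d,
        w_image=w_i,
        disease_score=d,
        image_score=i,
    )


def recommend(stage: Stage) -> TreatmentPlan:
    stage = Stage(stage)
    return TreatmentPlan(stage=stage, advice=TREATMENT_ADVICE[stage])


def diagnose(
    panel: panel_mod.MarkerPanel,
    feats: panel_mod.ImageFeatures,
    marker_net: mlp.Network,
    image_net: mlp.Network,
    ranges: panel_mod.ReferenceRanges | None = None,
    table: FusionWeightTable | None = None,
    record_id: str | None = None,
) -> dict:
    """Full diagnosis chain for one record.

    validate -> scale -> both sub-model scores -> band each -> rule weights
    -> DPC -> stage -> treatment advice.  Raises ``ValueError`` (tagged with
    the record id) when the validator rejects the record.
    """
    ranges = ranges or panel_mod.ReferenceRanges.default()
    report = panel_mod.validate_record(panel, ranges, record_id=record_id)
    if not report.accepted:
        bad = {k: v for k, v in report.fields.items() if v != "ok"}
        raise ValueError(f"record {record_id!r} rejected: {bad}")
    scaled = panel_mod.scale_inputs(panel, feats, ranges)
    d_score = mlp.predict_score(marker_net, panel_mod.assemble_acp(scaled))
    i_score = mlp.predict_score(image_net, panel_mod.assemble_ahp(scaled))
    weights = select_weights(
        band_of(stage_of_score(d_score)), band_of(stage_of_score(i_score)), table
    )
    result = combine_dpc(d_score, i_score, weights)
    plan = recommend(result.stage)
    return {
        "patient_id": record_id,
        "disease_score": result.disease_score,
        "image_score": result.image_score,
        "w_disease": result.w_disease,
        "w_image": result.w_image,
        "dpc": result.dpc,
        "stage": int(result.stage),
        "advice": plan.advice,
    }


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int


def evaluate_classifier(
    predicted,
    truth,
    positive_stages: frozenset = frozenset({Stage.III, Stage.IV}),
) -> dict:
    """Confusion counts plus TPR = TP/(TP+FN) and FPR = FP/(FP+TN).

    ``predicted``/``truth`` are equal-length stage sequences.  Undefined
    rates (zero denominator) are reported as ``None``, not 0.
    """
    pred = [Stage(p) for p in predicted]
    true = [Stage(t) for t in truth]
    if len(pred) == 0:
        raise ValueError("empty label sequences")
    if len(pred) != len(true):
        raise ValueError("label sequences differ in length")
    pos = {Stage(s) for s in positive_stages}
    tp = sum(1 for p, t in zip(pred, true) if p in pos and t in pos)
    fp = sum(1 for p, t in zip(pred, true) if p in pos and t not in pos)
    fn = sum(1 for p, t in zip(pred, true) if p not in pos and t in pos)
    tn = sum(1 for p, t in zip(pred, true) if p not in pos and t not in pos)
    tpr = tp / (tp + fn) if (tp + fn) else None
    fpr = fp / (fp + tn) if (fp + tn) else None
    return {"counts": ConfusionCounts(tp, fp, fn, tn), "tpr": tpr, "fpr": fpr}


def roc_points(dpc_scores, positive_truth, thresholds=None) -> list[tuple[float, float]]:
    """(FPR, TPR) pairs from binarizing DPC at a sweep of thresholds.

    ``positive_truth`` is a boolean sequence; a sample is predicted positive
    when its DPC >= threshold.  Points are returned sorted by FPR then TPR,
    so TPR is non-decreasing along the curve.
    """
    scores = np.asarray(dpc_scores, dtype=float)
    pos = np.asarray(positive_truth, dtype=bool)
    if scores.shape != pos.shape or scores.size == 0:
        raise ValueError("scores and truth must be nonempty and aligned")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0001, 101)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    pts = []
    for th in thresholds:
        call = scores >= th
        tp = int((call & pos).sum())
        fp = int((call & ~pos).sum())
        tpr = tp / n_pos if n_pos else 0.0
        fpr = fp / n_neg if n_neg else 0.0
        pts.append((fpr, tpr))
    return sorted(set(pts))
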