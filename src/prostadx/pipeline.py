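"""Cohort-level glue shared by the CLI and the acceptance tooling:
training both sub-model networks from a cohort table and batch diagnosis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fusion, mlp
from .config import RunConfig
from .panel import FEATURES, ImageFeatures, MarkerPanel, validate_record, scale_inputs, assemble_acp, assemble_ahp

__all__ = [
    "stage_targets",
    "scaled_matrix",
    "train_channels",
    "diagnose_frame",
]

_REQUIRED = ("patient_id",) + FEATURES


def _panel_of(row) -> MarkerPanel:
    def val(name):
        v = row.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return v

    return MarkerPanel(**{m: val(m) for m in ("tpsa", "rbc", "hb", "fpsa", "pap", "psma")})


def stage_targets(stages) -> np.ndarray:
    """Desired network outputs: the DPC-band midpoint of each stage."""
    return np.array([fusion.STAGE_MIDPOINTS[fusion.Stage(int(s))] for s in stages])


def scaled_matrix(df: pd.DataFrame, config: RunConfig) -> tuple[np.ndarray, list]:
    """Scale every accepted row to the 8-feature unit matrix.

    Returns (matrix over accepted rows, list of accepted row indices).
    """
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    rows, idx = [], []
    for i, row in df.iterrows():
        panel = _panel_of(row)
        if not validate_record(panel, config.ranges).accepted:
            continue
        feats = ImageFeatures(area=float(row["area"]), gray_level=float(row["gray_level"]))
        rows.append(scale_inputs(panel, feats, config.ranges))
        idx.append(i)
    return np.asarray(rows), idx


def train_channels(
    df: pd.DataFrame, config: RunConfig
) -> tuple[mlp.Network, mlp.Network, mlp.TrainResult, mlp.TrainResult]:
    """Train the marker (6-input) and image (2-input) networks on a cohort
    table with a ``stage`` column, targeting stage-band midpoints."""
    if "stage" not in df.columns:
        raise ValueError("training cohort needs a 'stage' column")
    X, idx = scaled_matrix(df, config)
    if len(idx) == 0:
        raise ValueError("no accepted records to train on")
    y = stage_targets(df.loc[idx, "stage"])
    marker0 = mlp.init_weights(config.marker_net)
    image0 = mlp.init_weights(config.image_net)
    marker_net, marker_res = mlp.train(marker0, X[:, :6], y, config.marker_net)
    image_net, image_res = mlp.train(image0, X[:, 6:], y, config.image_net)
    return marker_net, image_net, marker_res, image_res


def diagnose_frame(
    df: pd.DataFrame,
    marker_net: mlp.Network,
    image_net: mlp.Network,
    config: RunConfig,
) -> tuple[pd.DataFrame, list[dict]]:
    """Diagnose every row; returns (reports frame, rejected-record list)."""
    if marker_net.layer_sizes[0] != 6 or image_net.layer_sizes[0] != 2:
        raise ValueError(
            "network input sizes must be 6 (markers) and 2 (image features)"
        )
    reports, rejects = [], []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        panel = _panel_of(row)
        report = validate_record(panel, config.ranges, record_id=pid)
        if not report.accepted:
            rejects.append(
                {
                    "patient_id": pid,
                    "reason": {k: v for k, v in report.fields.items() if v != "ok"},
                }
            )
            continue
        feats = ImageFeatures(area=float(row["area"]), gray_level=float(row["gray_level"]))
        reports.append(
            fusion.diagnose(
                panel,
                feats,
                marker_net,
                image_net,
                ranges=config.ranges,
                table=config.fusion,
                record_id=pid,
            )
        )
    return pd.DataFrame(reports), rejects
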