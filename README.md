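# prostadx

A decision-support toolkit for prostate-lesion assessment. It combines:

- **`prostadx.imaging`** — lesion quantification from PNG/TIFF images:
  weighted grayscale conversion, Gaussian smoothing, a 2×2 finite-difference
  gradient, non-maximum suppression, double (hysteresis) thresholding,
  largest-component fill, Moore boundary tracing, and region area via an
  eight-direction Freeman chain code (discrete Green's theorem with a Pick
  boundary correction). Outputs the two image indicators: lesion pixel area
  and mean gray level.
- **`prostadx.panel`** — serum-marker panels (TPSA, RBC, HB, FPSA, PAP,
  PSMA): reference-range validation, plausibility screening, and min–max
  scaling into the fixed-order 8-feature input vector.
- **`prostadx.mlp`** — a from-scratch multilayer sigmoid perceptron (one
  6-input network for the markers, one 2-input network for the image
  features) trained by batch gradient descent with momentum and bold-driver
  learning-rate adaptation on the squared-error loss.
- **`prostadx.fusion`** — rule-based fusion of the two sub-model scores
  into a DPC score (`w_disease·d + w_image·i`, `w_image = 1 − w_disease`,
  four-case weight table keyed on EARLY/LATE score bands), staging through
  the bands (0, 0.25] → I … (0.75, 1] → IV, treatment recommendations, and
  TPR/FPR/ROC evaluation.
- **`prostadx.synth`** — reproducible synthetic cohorts: stage-conditioned
  log-normal marker panels (TPSA rising, FPSA/TPSA falling with stage) and
  elliptical-lesion images with exact ground-truth pixel areas. The
  distribution parameters are fabricated defaults shaped by qualitative
  clinical anchors; they are not measured values.
- **`prostadx.cli` / `prostadx.config`** — a `prostadx` command with
  `simulate`, `preprocess`, `train`, `diagnose`, and `evaluate`
  subcommands, driven by a single nested JSON config (unknown keys
  rejected, config hash recorded in every report).

## CLI walkthrough

```bash
# 1. generate a reproducible synthetic cohort (CSV + PNG lesion images)
prostadx simulate --out cohort/ --n 200 --seed 1

# 2. extract lesion metrics from the images
prostadx preprocess --images cohort/images --out metrics.csv

# 3. train the marker and image networks on the stage-labelled cohort
prostadx train --cohort cohort/cohort.csv --out-dir models/ --seed 1

# 4. diagnose: DPC score, stage, and treatment advice per record
prostadx diagnose --cohort cohort/cohort.csv \
    --marker-net models/marker_net.json --image-net models/image_net.json \
    --out reports.csv

# 5. score predictions against the ground truth
prostadx evaluate --reports reports.csv --truth cohort/cohort.csv \
    --out metrics.json
```

Exit codes: 0 success, 1 runtime failure, 2 usage error. Pass `--config
config.json` to any subcommand to override defaults (see
`prostadx.config.RunConfig`).

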