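# kneefit

Automatic implant-size selection for total knee replacement (TKR) from
bi-planar knee radiograph silhouettes.

Pre-operative templating picks the implant size whose footprint best matches
the patient's bone: a component that overhangs the cortical rim by more than
about 3 mm irritates soft tissue, while one that underhangs leaves cut bone
uncovered. `kneefit` automates this choice. It reconstructs the 3-D
distal-femur and proximal-tibia surfaces from two segmented silhouettes
(antero-posterior and lateral views) using a statistical shape model (SSM)
plus per-view profile depth models (PDMs), virtually fits **every size of
five commercial implant systems** (NexGen, Sigma, Legion, Freedom, Scorpio —
73 catalogue sizes in total), and reports the best size under two fit
metrics:

- **global RMSE** — root-mean-square closest-point distance between the
  component and the bone surface (femur) or resection outline (tibia);
- **max over/underhang (max OUH)** — directed Hausdorff distance from the
  component rim to the bone outline, the single worst rim mismatch.

Ties within 0.05 mm break toward the smaller size (the conservative surgical
choice). Because real imaging data cannot be redistributed, the package
includes a fully seeded synthetic bone generator (parametric femur/tibia
surfaces with four shape modes, surface noise, and rendered silhouette
masks) used for training, benchmarking, and all tests. See
[docs/methods.md](docs/methods.md) for the underlying model and its
limitations.

## Worked example

Select Smith & Nephew Legion sizes for a synthetic subject whose femur
measures 66 × 59 mm (ML × AP) and tibia 68 × 45 mm:

```python
from kneefit import generate_bone, load_size_charts, predict_sizes

charts = load_size_charts()
tibia = generate_bone("tibia", ML=68.0, AP=45.0, shape_coeffs=[0.5, -0.3, 0.2, 0.0],
                      noise_sd=0.3, seed=42)
femur = generate_bone("femur", ML=66.0, AP=59.0, shape_coeffs=[0.5, -0.3, 0.2, 0.0],
                      noise_sd=0.3, seed=42)

predictions = predict_sizes(femur, tibia, charts)
for pred in predictions:
    if pred.model != "Legion":
        continue
    print(f"{pred.manufacturer} {pred.model} ({pred.component}): "
          f"best by RMSE = size {pred.best_by_rmse}, "
          f"best by overhang = size {pred.best_by_ouh}")
    for fit in pred.all_fits:
        print(f"  size {fit.size_id:>3}: rmse={fit.rmse:6.2f} mm  "
              f"max_ouh={fit.max_ouh:6.2f} mm")
```

Output:

```
Smith & Nephew Legion (femur): best by RMSE = size 4, best by overhang = size 4
  size   2: rmse=  2.71 mm  max_ouh=  4.16 mm
  size   3: rmse=  1.23 mm  max_ouh=  2.03 mm
  size   4: rmse=  0.38 mm  max_ouh=  0.60 mm
  size   5: rmse=  1.60 mm  max_ouh=  2.75 mm
  size   6: rmse=  3.07 mm  max_ouh=  5.42 mm
  size   7: rmse=  4.87 mm  max_ouh=  9.11 mm
  size   8: rmse=  6.86 mm  max_ouh= 12.67 mm
Smith & Nephew Legion (tibia): best by RMSE = size 3, best by overhang = size 3
  size   1: rmse=  2.44 mm  max_ouh=  4.22 mm
  size   2: rmse=  1.18 mm  max_ouh=  2.22 mm
  size   3: rmse=  1.06 mm  max_ouh=  1.74 mm
  size   4: rmse=  2.09 mm  max_ouh=  2.77 mm
  size   5: rmse=  3.28 mm  max_ouh=  3.89 mm
  size   6: rmse=  4.47 mm  max_ouh=  5.24 mm
  size   7: rmse=  5.90 mm  max_ouh=  7.09 mm
  size   8: rmse=  7.62 mm  max_ouh=  8.98 mm
```

Both metrics pick Legion femur size 4 — its catalogue footprint is
66 × 59 mm, exactly the generated femur — and tibia size 3 (68 × 48 mm, the
closest ML match to the 68 × 45 mm plateau). Fit quality degrades
monotonically away from the best size, and every size from 6 up would
overhang by a clinically significant margin (> 3 mm).

## Command-line pipeline

The `kneefit` entry point chains the full study as five stages:

```bash
kneefit synth --n 50 --seed 101 --out data/train      # synthetic cohort
kneefit train --meshes data/train_femur --bone femur --out models
kneefit reconstruct --ap s0_femur_AP.png --lat s0_femur_lateral.png \
        --bone femur --ssm models/femur_model.npz --out recon/femur.stl
kneefit predict --femur recon/femur.stl --tibia recon/tibia.stl --out preds.json
kneefit evaluate --preds preds.json --gt-dir data/eval --out report.json
```

Every command accepts `--config file.json` (keys override same-named flags).
Exit code 2 signals a usage/configuration error, 1 a stage failure.

## Reproduction

All results are reproducible from seeds; identical seeds give byte-identical
data files and reports.

```bash
pip install --no-build-isolation -e .

# unit + acceptance test suite
python -m pytest -q

# acceptance benchmark: writes the headline quantities to JSON
python scripts/acceptance.py --seed 0 --out acceptance.json
```

The acceptance script recomputes, for the given seed: metric implementations
against brute-force references, ICP recovery of randomized rigid
perturbations, size-chart and component-geometry fidelity, size recovery on
catalogue-exact bones, the tibial resection-plane rule and its tilt
equivariance, SSM/PDM spectrum and held-out reconstruction error, a
50-subject end-to-end benchmark (train on one seeded cohort, evaluate
reconstruction-based size predictions against ground-truth-mesh selections
on another), and byte-level determinism. On the 50-subject benchmark the
pipeline reaches ≥ 95 % ±1-size accuracy for every (implant model,
component, metric) combination.

## Layout

- `src/kneefit/geometry.py` — meshes, contours, transforms, metrics, ICP
- `src/kneefit/implants.py` — size charts, component templates and scaling
- `src/kneefit/fitting.py` — virtual fitting and size selection
- `src/kneefit/reconstruction.py` — masks, contours, SSM/PDM, 2-D→3-D
- `src/kneefit/training.py` — correspondence, Procrustes, model training
- `src/kneefit/synthetic.py` — bone generator, demographics, silhouettes
- `src/kneefit/evaluation.py` — cohort scoring and reports
- `src/kneefit/io.py`, `src/kneefit/cli.py` — file formats and the CLI
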