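# ppgplus

Blood-pressure **level** classification from photoplethysmography (PPG).

Hypertension is largely asymptomatic, and cuff readings sample a patient's
pressure only at isolated moments. A PPG sensor — the optical pulse sensor in
most wearables — measures blood-volume change continuously, and the pulse
waveform's shape carries pressure information: with rising blood pressure the
tidal wave migrates toward the systolic (main) wave until it merges with it,
the descending branch steepens, and the spectral energy of the pulse shifts
toward higher instantaneous frequency. This package turns that observation
into a three-class screening task — normotension (NT), prehypertension (PHT),
hypertension (HT) under the JNC7 staging (HT if SBP ≥ 140 mmHg or
DBP ≥ 90 mmHg; PHT if SBP ≥ 120 or DBP ≥ 80; else NT) — learned from images
rather than hand-picked fiducial features.

## Pipeline

For paired 10-s PPG/ABP records sampled at 125 Hz:

1. **Conditioning** (`prep`) — zero-phase 0.4–8 Hz Butterworth bandpass,
   min–max normalization, segmentation into two 5-s halves.
2. **Denoising** (`emd`) — ensemble empirical mode decomposition (EEMD):
   the signal is sifted into intrinsic mode functions (IMFs); averaging the
   decompositions of white-noise-perturbed copies suppresses mode mixing.
   Reconstruction keeps only IMFs whose mean instantaneous frequency lies in
   0.4–13 Hz, discarding high-frequency artifact and baseline drift.
3. **Hilbert–Huang spectra** (`hht`) — each IMF's analytic signal
   `z(t) = x(t) + i·H[x](t)` yields instantaneous amplitude `|z|` and frequency
   `dφ/dt / 2π`; amplitudes are accumulated on a 0–13 Hz × 0–5 s grid and
   rendered as 1247 × 770 8-bit rasters.
4. **PPG+ images** (`dataset`) — the spectrograms of PPG, PPG′ and PPG″ (the
   derivative signals reflect vascular elasticity) become the R, G and B
   channels of one RGB image; network inputs are standardized 3 × 224 × 224
   tensors.
5. **Labels** (`labeling`) — each 5-s ABP segment's max/min give SBP/DBP,
   staged by JNC7 and attached to the time-aligned PPG segment.
6. **Training** (`train`, `models`) — backbones behind one interface
   (AlexNet, ResNet18/34 for architecture accounting and forward passes, and a
   CPU-trainable `small_cnn`), trained with Adam under stratified,
   record-grouped k-fold cross-validation; F1 / sensitivity (TPR) /
   specificity (TNR) / ROC reported per fold and averaged. The adapted AlexNet
   head (dropout + 4096 → 2) gives 57.01 M trainable parameters and 0.71 GMAC
   per 3 × 224 × 224 forward pass.

A synthetic cohort generator (`synthetic`) produces paired PPG/ABP records
with class-dependent beat morphology, prescribed systolic/diastolic extrema,
heart-rate jitter, noise and baseline drift, so the whole pipeline runs
without any data download.

## Worked example

```python
import numpy as np
from ppgplus import (CohortConfig, RunConfig, run)
from ppgplus.emd import EEMDConfig
from ppgplus.models import ModelSpec
from ppgplus.train import TrainConfig

report = run(RunConfig(
    cohort=CohortConfig(n_records=60, class_probs=(0.5, 0, 0.5),
                        exact_counts=(30, 0, 30), noise_std=0.0, seed=11),
    trial="nt-vs-ht",
    model=ModelSpec(backbone="small_cnn"),
    train=TrainConfig(learning_rate=0.003, epochs=10, seed=0),
    eemd=EEMDConfig(ensemble_size=8, seed=0),
    out_dir="ppgplus_run", seed=0,
))
print(report["segments_made"], report["mean"])
```

prints (about a minute on one CPU):

```
120 {'f1': 0.9882352941176471, 'tpr': 1.0, 'tnr': 0.975, 'auc': 1.0}
```

i.e. the 60 records became 120 labeled 5-s PPG+ images, and 5-fold
cross-validation of the small CNN separated normotensive from hypertensive
segments with mean F1 0.988, sensitivity 1.0 (all NT segments recognized) and
specificity 0.975 (2.5% of HT segments misread as NT). `ppgplus_run/report.json`
holds the stage counts and per-fold metrics, `epoch_accuracy.csv` the
per-epoch accuracy curves.

The same flow is available from the shell:

```
ppgplus simulate --n 60 --class-probs 0.5,0,0.5 --noise 0 --seed 11 --out-dir cohort/
ppgplus build-dataset --mode ppgplus --in-dir cohort/ --out-dir data/ --seed 0
ppgplus train --trial nt-vs-ht --backbone small_cnn --dataset-dir data/ --epochs 10 --seed 0
```

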