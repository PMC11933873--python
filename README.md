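# h2dcos

Cross-scale hyperspectral analysis of leaf superoxide dismutase (SOD)
activity: heterogeneous two-dimensional correlation spectroscopy (H2D-COS)
between microscopic and macroscopic hyperspectral measurements, CNN-LSTM
regression of SOD activity from spectra, and transfer of the regressor
between the two instruments on paired sensitive wavelengths.

## The problem

SOD is a front-line antioxidant enzyme; its activity in tomato leaves rises
with salt stress and growth stage, making it a readout of stress state.
Microscope-coupled hyperspectral imaging (MHSI) senses the subtle
cellular-scale absorption changes tied to SOD, but slicing leaves for the
microscope is destructive and slow; whole-leaf Vis–NIR imaging is fast and
non-destructive but less sensitive.  This package implements the analysis
that bridges the two scales:

1. **H2D-COS** treats the two instruments' spectra of the *same* leaves,
   ordered along the SOD perturbation, as one correlated system.  With
   dynamic spectra ỹ(v, p_j) = y(v, p_j) − ȳ(v), the synchronous and
   asynchronous maps are

       Φ(v1,v2) = 1/(N−1) Σ_j ỹ(v1,p_j) z̃(v2,p_j)
       Ψ(v1,v2) = 1/(N−1) Σ_j ỹ(v1,p_j) Σ_k M_jk z̃(v2,p_k)

   with the Hilbert–Noda matrix M_jk = 1/(π(k−j)) off-diagonal.  Slices of
   the cross-modality Φ locate the *sensitive wavelengths* of each
   instrument that respond jointly to SOD.
2. **CNN-LSTM regression** (1×2 conv kernels at stride 2 with 32/64/128
   feature maps, max pooling, an LSTM over the reduced band axis, a dense
   regression head — implemented from scratch in numpy) predicts SOD
   activity (U/mg) from preprocessed spectra; models are compared under
   raw / smoothed / baseline-corrected / first-derivative pretreatments
   with Pearson R and RMSE on calibration and prediction sets.
3. **Transfer learning** pairs the two modalities' sensitive wavelengths by
   rank and reuses the source-modality model on the target modality's
   bands, optionally fine-tuning the recurrent/dense head on a small
   labelled target subset; trained models render pixel-wise SOD activity
   maps from calibrated cubes.

Because no measured dataset is public, the package ships a first-class
synthetic generator (`h2dcos.synthetic`) producing paired micro/macro
datasets — 4 salt treatments × 3 stages × 27 plants, SOD-proportional
absorption features planted at known wavelengths, realistic baseline drift —
with full ground truth, so every stage is testable end to end.  See
`docs/methods.md` for the data model and all numerical choices.

## Worked example

```python
import numpy as np
from h2dcos import (
    GeneratorConfig, generate_dataset, truth_report,
    TrainConfig, ModelSpec, build_model, split_dataset, evaluate,
)
from h2dcos.pipeline import (
    pretreatment_comparison, recover_sensitive_peaks, recovery_counts,
    cross_scale_transfer,
)

ds = generate_dataset(GeneratorConfig(seed=0))      # 324 paired samples

# 1) which pretreatment gives the best SOD model on the micro spectra?
results = pretreatment_comparison(ds.micro, TrainConfig(seed=0))
for method, m in results.items():
    print(f"{method:10s} R_P {m['prediction'].r:.4f}  "
          f"RMSEP {m['prediction'].rmse:.4f} U/mg")

# 2) recover the sensitive wavelengths from the hetero sync map
rec = recover_sensitive_peaks(ds)
print(recovery_counts(ds, rec))

# 3) transfer the 10-band micro model to the macro instrument
truth = truth_report(ds)
src = np.sort(truth.loc[truth.modality == "micro", "grid_nm"])
tgt = np.sort(truth.loc[truth.modality == "macro", "grid_nm"])
res = cross_scale_transfer(ds, src, tgt, TrainConfig(seed=0))
print(f"transfer R_P {res.target_metrics.r:.4f}  "
      f"RMSEP {res.target_metrics.rmse:.4f} U/mg")
```

Output (seed 0, single CPU, a few minutes):

```
none       R_P 0.9780  RMSEP 0.0126 U/mg
smoothing  R_P 0.9867  RMSEP 0.0098 U/mg
baseline   R_P 0.9959  RMSEP 0.0055 U/mg
fd         R_P 0.9982  RMSEP 0.0040 U/mg
{'micro_planted': 10, 'micro_recovered': 10, 'micro_found': 19,
 'macro_planted': 10, 'macro_recovered': 10, 'macro_found': 12}
transfer R_P 0.9232  RMSEP 0.0238 U/mg
```

Reading this: the first-derivative (FD) pretreatment gives the best
prediction-set correlation, baseline correction is next, and the untreated /
merely smoothed spectra trail — the ranking expected when slowly varying
baseline drift, not white noise, is the dominant nuisance.  The hetero-map
slices recover all 10 planted sensitive wavelengths of each modality
(within one grid band; a few extra drift-induced peaks are also reported),
and the micro-trained 10-band model, fine-tuned on a quarter of the macro
calibration labels, predicts macro-set SOD with R_P ≈ 0.92.

A command-line layer wraps the same functions:

```bash
h2dcos simulate --out data/ --seed 7
h2dcos preprocess --method fd --in data/micro_spectra.csv --out data/micro_fd.csv
h2dcos h2dcos --micro data/micro_spectra.csv --macro data/macro_spectra.csv \
       --preprocess baseline --slice-at 682 --out maps.h5
h2dcos train --in data/micro_fd.csv --out model/
h2dcos map --cube data/micro_cube_00.img.hdr --model model/ --preprocess fd --out map.png
```

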