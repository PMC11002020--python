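# myot2 — muscle water-T2 mapping from multi-echo spin-echo MRI

Quantifying the transverse relaxation time of the *water* (myocytic)
component of skeletal muscle, T2w, is a key readout of disease activity in
neuromuscular disorders: unlike fat fraction, which marks irreversible fat
replacement, water T2 tracks inflammation and damage that may still respond
to therapy.  A plain monoexponential fit of a multi-echo spin-echo (MESE)
decay conflates the fat and water pools and is biased by stimulated echoes
from imperfect slice-selective refocusing.  `myot2` implements the standard
remedy — a two-pool extended-phase-graph (EPG) signal model with
slice-profile correction — together with three interchangeable voxel-wise
estimators and the full subject workflow.

## Model

The voxel signal at echo *n* is

S(n) = FF · EPG(T1f, T2f, B1, TE, EXprofile, REFprofile, ETL)
     + (1 − FF) · EPG(T1w, T2w, B1, TE, EXprofile, REFprofile, ETL)

where `EPG(...)` is the slice-profile-resolved echo amplitude obtained by
running the EPG recursion (RF mixing, relaxation, crusher dephasing) at each
sub-slice position of the excitation/refocusing profiles and summing the F0
states; T1f = 365 ms and T1w = 1400 ms are fixed; B1 is the refocusing
flip-angle efficiency; FF the fat signal fraction.  Slice profiles come from
Shinnar–Le Roux pulse designs (or user waveform files) Bloch-simulated
across the slice.

Estimators (all consume the same model):

* **nlsq** — bounded trust-region least squares with variable projection of
  the pool amplitudes;
* **dict** — exhaustive dot-product dictionary matching on dense parameter
  grids, optionally SVD-compressed;
* **nn** — Fat-Net and Muscle-Net, small fully connected regressors trained
  on noise-augmented synthetic EPG signals (NumPy, Adam, MAE loss).

The subject pipeline mirrors clinical practice: subcutaneous fat is
segmented by k-means on the first echo, the subject's fat T2 (T2f) is
calibrated there (fat grid with FF fixed at 0.9), and the muscle is mapped
voxel-wise with T2f held at the calibrated value.  Bland–Altman limits of
agreement and Lin's concordance quantify inter-method agreement.  A digital
thigh phantom with exact ground truth makes the whole chain testable
without scanner data.

## Worked example

```python
import numpy as np
from myot2 import SequenceConfig, TissueParams, mese_two_component
from myot2.rf_pulses import preset_profiles
from myot2.nlsq_fit import fit_muscle_voxel

ex, ref = preset_profiles("generic-siemens-like", n_bins=64)
seq = SequenceConfig(te_ms=7.5, etl=17, tr_ms=5633.0,
                     ex_profile=ex, ref_profile=ref)

truth = TissueParams(t2f_ms=151.0, t2w_ms=35.0, ff=0.30, b1=0.85)
signal = mese_two_component(truth, seq)

fit = fit_muscle_voxel(signal, t2f_ms=151.0, seq=seq)
print(f"T2w = {fit.t2w:.2f} ms   FF = {fit.ff:.3f}   B1 = {fit.b1:.3f}")
```

prints

```
T2w = 35.00 ms   FF = 0.300   B1 = 0.850
```

a perfect recovery of the simulated voxel (30% fat infiltration, 15%
under-flipped refocusing).  With Rician noise at first-echo SNR 100 the same
fit on 25 noisy replicates returns a mean T2w of 35.8 ms (SD 2.0 ms) —
voxel-level noise averages out over a muscle ROI.

The same works from the shell:

```bash
myot2 phantom --seed 3 --snr 80 --out subject/
myot2 build-dict --kind muscle --t2f 150 --out muscle.h5
myot2 fit --mese subject/mese.nii.gz --method dict --t2f 150 \
          --muscle-mask subject/muscle_labels.nii.gz --dict muscle.h5 --out maps/
myot2 roi-stats --map maps/t2w.nii.gz --labels subject/muscle_labels.nii.gz \
                --quality maps/quality.nii.gz --out stats.csv
```

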