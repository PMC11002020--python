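# Methods

## Signal model

A voxel is modeled as two non-exchanging pools, fat and water, each decaying
according to the extended-phase-graph (EPG) recursion of a CPMG multi-echo
spin-echo train.  Per sub-slice position the simulation applies the local
excitation flip (about x), then per echo: relaxation plus one crusher
dephasing cycle over half the echo spacing, the B1-scaled refocusing flip
(about y, CPMG phase convention), and a second relax/dephase half-cycle,
recording the F0 configuration state.  The echo amplitude is the magnitude
of the complex sum of F0 over sub-slice positions divided by the number of
positions, so ideal pulses give amplitudes in [0, 1] for unit equilibrium
magnetization.  The voxel signal is the fat-fraction-weighted sum of the two
pool signals and is exactly linear in FF.

Assumptions and deliberate simplifications:

* **No steady-state TR weighting.**  T2-mapping protocols use TRs of several
  seconds, long against both pools' T1 (365 / 1400 ms, fixed constants of
  the model), so saturation across excitations is negligible.  T1 relaxation
  *within* the echo train is modeled — it shapes stimulated-echo amplitudes.
* **B1 scales refocusing only.**  Excitation is assumed calibrated; a flag
  (`scale_excitation`) extends the efficiency factor to the excitation pulse.
* **State truncation at order ETL + 1** is exact for the recorded F0 states
  at this pulse count (higher orders cannot rephase within the train).
* **Magnitude at the end**: fitted data are magnitude images, so the
  slice-summed complex echo is reported as a magnitude.  Complex-vs-magnitude
  slice summation was an open choice; magnitude-of-complex-sum was selected
  and is what the isochromat cross-check validates.
* Not modeled: diffusion, magnetization transfer, multi-peak fat spectra,
  and the chemical-shift displacement of the fat slice profile.  The latter
  is the main known source of the systematic fat-fraction offset of
  MESE-EPG fitting relative to Dixon references.

Numerical core: the recursion runs as a numba-compiled kernel batched over
(T2, B1) pairs; dictionary construction factorizes the two-pool model so
each distinct single-pool train is simulated once and mixed linearly over
the FF axis.  The pure-NumPy operator implementations (`epg_rf_rotation`,
`epg_relax_shift`) define the semantics and are cross-checked against the
kernel in the tests.

## Validation oracle

`myot2.bloch.mese_bloch` is an independent time-domain isochromat
simulation: classical magnetization vectors on a uniform crusher-phase grid,
rotated and relaxed event by event.  With `n_dephase` exceeding the largest
coherence order (2·ETL + 1) the isochromat average is alias-free, so EPG and
Bloch must agree to numerical precision; the suite enforces 1e-3 relative
agreement over random (T2, B1, profile) cases and machine-precision
agreement in the CPMG limit, where the echo train collapses to
exp(−n·TE/T2).

## Slice profiles

Pulses are designed with the Shinnar–Le Roux transformation: an equiripple
(Parks–McClellan) beta filter with role-specific effective ripples
(excitation: δ1e = √(δ1/2), δ2e = δ2/√2; spin-echo refocusing: δ1e = δ1/4,
δ2e = √δ2; δ1 = δ2 = 0.01 default), a minimum-phase alpha from the cepstral
construction, and the inverse SLR recursion.  The beta polynomial is
rescaled so the on-axis flip equals the nominal flip exactly (a 1e-5
amplitude backoff keeps |β| < 1 for 180° pulses; < 0.3° at slice center).
Profiles are expressed as one effective flip angle per position,
2·asin|β(x)| — for refocusing this is precisely the angle whose EPG
refocusing efficiency matches the simulated |β|²; the EPG engine therefore
consumes a single real vector per pulse.

Profile positions are sampled at midpoints of uniform cells over ±1.5 slice
thicknesses (64 bins default), so refining the bin count approximates the
same through-slice integral: echo trains change by < 0.1% from 64 to 128
bins, and bins where both pulses fall below 0.5° can be truncated.

Vendor product pulses are proprietary; the presets
(`generic-siemens-like`: TBW 4.0/3.0, `generic-philips-like`: TBW 5.2/3.6,
256 samples) are plain SLR stand-ins and are labeled as such.  Using wrong
profiles biases T2w — for fidelity, load the true waveforms
(`load_waveform`, 1–2-column text) with their time-bandwidth products.

## Estimators

**Dictionary matching.**  Default grids: fat calibration T2f ∈ [50, 250] ms
step 0.25, T2w ∈ [10, 110] step 0.5, B1 ∈ [0.4, 1.2] step 0.025 (FF fixed
0.9); muscle FF ∈ [0, 1] step 0.015, T2w ∈ [10, 80] step 0.2, B1 step 0.025
(T2f fixed at the calibrated value).  The B1 step is dimensionless.  Atoms
are unit-norm, ordered lexicographically (recorded for reproducible
tie-breaking: lowest index wins); matching is the maximal raw dot product.
SVD compression stores the top-k right singular vectors; explained variance
is computed on the *uncentered* atom matrix, consistent with matching on
raw dot products (the mean-centered spectrum is reported alongside as a
diagnostic).  Three components retain > 99% of the total variance, but note
that rank-3 *matching* can still move individual parameter estimates by
several grid steps — the discriminative information lives partly in the
discarded tail.  Compression rank should be validated per application;
k = ETL is exactly lossless.

**Nonlinear least squares.**  Trust-region reflective bounded least squares
over the nonlinear parameters with the pool amplitudes eliminated in closed
form at each iterate (variable projection) — the same objective as an
explicit free amplitude, with exact scale equivariance and fewer nonlinear
dimensions.  Bounds mirror the grid/training ranges; muscle fits use a
three-point T2w multi-start {15, 35, 60} ms; tolerances 1e-8 (cost and
step).  Failures and all-zero voxels are flagged, never raised, so slice
processing survives bad voxels; FF > 0.95 carries a quality flag because
the water pool is then too weak to constrain T2w.

**Neural regressors.**  Fat-Net maps the unit-norm subcutaneous signal to
(T2f, T2w, B1); Muscle-Net maps the unit-norm muscle signal plus the
range-scaled calibrated T2f to (FF, T2w, B1).  Architecture: hidden widths
256-128-64-32-16 (ReLU) plus a linear 3-wide output — six weighted layers;
widths are configurable but must form a bottleneck.  Targets are scaled to
[0, 1] over their training ranges to balance the three-term MAE loss.
Training draws parameters uniformly over the physiological ranges
(100 000 signals, 500 epochs × 1000 Adam steps, batch 500 at full scale),
corrupting each batch with fresh two-channel Gaussian noise and taking the
magnitude (Rician, like acquired data) before renormalizing.  Noise levels
are anchored to the first-echo amplitude: Muscle-Net draws a variance
uniformly in [1e-7, 5e-5] relative to unit first echo, Fat-Net draws a
first-echo SNR uniformly in [1e3, 1e4] (subcutaneous fat is high-SNR).
Anchoring makes the noise condition independent of the simulator's
arbitrary amplitude convention.  Free optimization choices, fixed and
recorded in the bundle: exponential learning-rate decay 3e-3 → 3e-5, and a
fixed affine input standardization from the training pool.  A bundle stores
the sequence fingerprint and the pipeline refuses to apply it to a
different sequence — a new TE/ETL/pulse set requires retraining.

## Pipeline

Subcutaneous fat is segmented by Lloyd k-means (k = 3) on first-echo
intensities; among the brightest cluster's connected components only those
adjacent to the border-connected background are kept, which selects the
subcutaneous ring and rejects interior bright structures.  T2f calibration
aggregates per-voxel fat-mode estimates with the median (robust to mask
impurities; configurable), excluding poor fits (dictionary score < 0.98,
NLSQ relative residual > 10%); fewer than 50 valid voxels raises a warning
flag.  Mapping clips out-of-range estimates and flags rather than discards
them, so maps stay dense.  Masks must share the MESE voxel grid exactly —
registration and muscle segmentation are upstream responsibilities, and the
pipeline refuses rather than resamples.  A sensitivity helper sweeps the
assumed T2f and reports the induced mean-T2w shift, since calibration
errors of tens of ms move T2w by several ms.

Dixon reference fat fraction is the exact arithmetic If/(Iw + If)·100 with
zero-total voxels flagged invalid.  Agreement statistics: Bland–Altman with
sample-SD (n−1) limits of agreement, bias tested by a two-sided one-sample
t-test (α = 0.05 default, the customary choice); Lin's concordance uses
population (1/n) moments per its original definition — this matters at
small n and is fixed here.

## Digital phantom

The default phantom emulates a single mid-thigh slice on a 160×160 grid
(3×3×6 mm voxels): a subcutaneous ring (FF 0.9, shared T2f 150 ms), ten
elliptical muscle compartments with FF 0–0.8 and T2w 25–45 ms — assigned so
that truth T2w is exactly uncorrelated with FF, making the
fat-independence regression test meaningful — and a smooth linear B1+
gradient 0.8 → 1.1, as surface-coil transmit fields produce.  Noise is
Rician with per-voxel first-echo SNR equal to the requested value.
Compartments of ~110 voxels keep a full three-estimator evaluation within
desk-scale runtimes while the standard error of a compartment mean stays
well below the 2 ms recovery tolerance.

What the phantom does *not* emulate: anatomy-shaped ROIs, registration
error, chemical-shift and motion artifacts, spatially correlated noise, and
multi-peak fat spectra.  Passing phantom tests therefore demonstrates
correctness of the estimation chain under the stated model, not robustness
to every acquisition imperfection of real data.

## Problem sizes used in the checked examples

The shipped tests train the regressors at a reduced scale (20 000 signals,
30 epochs × 200 steps, batch 256) chosen as the package's standard quick
configuration; it reaches ~1.3 ms noiseless Muscle-Net T2w MAE (FF ≤ 0.8)
versus the sub-millisecond accuracy expected of the full-scale recipe.  The
compressibility check coarsens the muscle grid steps 4× (13 464 atoms); the
variance spectrum is insensitive to this.  All randomness is seeded.

## Known limitations

* Single-slice, single-coil abstraction; no parallel-imaging noise model.
* The dictionary memory guard (2e7 atoms) assumes float64 atoms; very fine
  custom grids should be built in coarser chunks.
* B1 > ~1 with near-ideal refocusing profiles is weakly identifiable
  (flip-angle reflection symmetry); realistic slice profiles mostly break
  the degeneracy, which is why recovery tests use them.
* Training reproducibility is exact under a fixed seed and BLAS, best-effort
  across numerical backends.
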