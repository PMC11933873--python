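# Methods

This note documents the models, numerical choices and known limits of the
`h2dcos` package: a pipeline that links microscopic and macroscopic
hyperspectral measurements of salt-stressed tomato leaves through
heterogeneous two-dimensional correlation spectroscopy (H2D-COS), predicts
leaf superoxide dismutase (SOD) activity with a CNN-LSTM spectral regressor,
and transfers that regressor across instruments on paired sensitive
wavelengths.

## The measurement model

Each leaf is characterized by one scalar label — SOD activity in units per
milligram of fresh weight, from the NBT photochemical-reduction assay

    SOD [U/mg] = ((A_s0 − A_s) · V_t) / (A_s0 · W · V_s · 0.5 · 1000),

where one unit is the enzyme amount inhibiting NBT photoreduction by 50% —
and by two reflectance spectra of the same leaf: a microscope-coupled
hyperspectral image ("micro") and a whole-leaf Vis–NIR image ("macro").
Cubes are converted to reflectance with the dark/white reference correction
R = (R₀ − D)/(W − D) and averaged over a region-of-interest mask to one
spectrum per leaf.

Two details of the assay formula are deliberately explicit rather than
assumed.  The grouping above is the standard 50%-inhibition form consistent
with the unit definition; and the fresh weight `W` is taken in grams by
default with an explicit `weight_unit="mg"` flag, since assays weigh a few
hundred milligrams but report per-milligram activity.

## 2D-COS and its heterogeneous form

With samples ordered along a perturbation p₁ ≤ … ≤ p_N (we order by measured
SOD activity; ordering by treatment code is available), the dynamic spectrum
is ỹ(v, p_j) = y(v, p_j) − ȳ(v) with ȳ the mean spectrum.  The synchronous
and asynchronous intensities are

    Φ(v1, v2) = 1/(N−1) Σ_j ỹ(v1, p_j) z̃(v2, p_j)          (= Y₁ᵀY₂/(N−1))
    Ψ(v1, v2) = 1/(N−1) Σ_j ỹ(v1, p_j) Σ_k M_jk z̃(v2, p_k)  (= Y₁ᵀMY₂/(N−1))

with the Hilbert–Noda matrix M_jk = 0 for j = k and 1/(π(k−j)) otherwise.
When z̃ comes from the second instrument these are the heterogeneous maps;
cross-peaks link wavelengths of the two modalities responding jointly to the
SOD perturbation.  The matrix forms are verified in the test suite against
direct double-loop summation of the defining sums at 1e-10.

Numerical conventions worth stating:

* One formula listing defines the reference spectrum with a 1/(N−1)
  prefactor, which is not the arithmetic mean it is described as.  The
  package uses the arithmetic mean by default and keeps the 1/(N−1) variant
  behind `reference="printed"`.
* Ties in the perturbation are broken stably by sample id and logged.
* Requested slice wavelengths snap to the nearest grid band; half-way ties
  snap downward.

### Sensitive-peak selection

Peaks are local maxima of |slice| of the synchronous map, with three rules
mirroring practice on real instruments: (i) `edge_bands` (default 5) bands
at each grid end are excluded (scan-end instability); (ii) bands above
`max_wavelength` (default 750 nm, where these leaf spectra carry little
SOD-related information) are dropped — except that a peak whose prominence
exceeds half the slice maximum is retained as an isolated genuine feature,
which is how a strong ~948 nm water-overtone band survives the cutoff;
(iii) peaks with prominence under 5% of the slice maximum are dropped.  All
thresholds are arguments and are recorded in the returned `PeakList`.

Where to slice is automated as the band of each axis whose row/column of
|Φ| has the largest L2 norm — the band most strongly correlated with the
other modality overall.

The correlation analysis runs on baseline-corrected spectra, not the first
derivative, even though the derivative gives the best regression models: a
derivative is zero at every absorption-feature centre, so derivative-domain
slice maxima sit at feature shoulders rather than centres, while detrended
reflectance keeps its extrema at the planted/true wavelengths.

## The CNN-LSTM regressor

Architecture: the spectrum enters as a 1×B matrix; three convolution blocks
(1×2 kernel, stride 2, max pooling; 32, 64, 128 feature maps) reduce the
band axis; the conv output is read as a sequence over the reduced band axis
with the filter dimension as features and fed to an LSTM; a dense layer and
a linear output head regress activity.  Blocks that would shrink the
sequence below 4 positions are dropped automatically and recorded in the
model summary, so the same specification runs on full spectra and on
10-band sensitive-wavelength subsets.

The implementation is pure numpy — forward, backpropagation (including
through time for the LSTM) and Adam.  Because the 1×2/stride-2 kernel has
non-overlapping receptive fields, convolution and pooling are reshapes plus
small matrix products; at this problem size (hundreds of samples, ≤ a few
hundred bands) training takes tens of seconds on one CPU and is
bit-deterministic under fixed seeds, which the determinism contracts in the
test suite rely on.  Gradients are verified against central differences.

Training defaults (standard small-data choices, all exposed in
`TrainConfig`): Adam, learning rate 1e-3,
300 epochs, batch 16, MSE loss on z-scored targets; inputs are per-band
z-scored on the calibration set.  The calibration/prediction split is
stratified by treatment × stage with the largest-remainder rule so the
global count is exactly ⌊0.75·N⌋ (81/27 at N = 108); strata smaller than 2
fall back to a random split with a warning.  Metrics are Pearson R and RMSE
(R_C/RMSEC on calibration, R_P/RMSEP on prediction).

## Cross-scale transfer

Sensitive peaks of the two modalities are paired by wavelength rank (i-th
sorted source peak ↔ i-th sorted target peak): several true cross-modality
pairs are not nearest neighbours in nm, so proximity matching would be
wrong; with unequal list lengths the code falls back to greedy
nearest-wavelength matching and drops leftovers with a warning.  Transfer
strategies:

* `zero_shot` — copy weights and scalers; exactly the source model.
* `feature_frozen_finetune` (default) — freeze the convolutional feature
  extractor, refit the input standardization and the LSTM/dense head on a
  small labelled target subset (25% of the target calibration set by
  default — the scarce-label regime that motivates transfer).
* `full_finetune` — fine-tune everything on the same subset.

The pipeline default direction is micro → macro; the reverse is obtained by
swapping arguments.  Transfer quality is evaluated on the target-modality
prediction set and compared side by side with a target-only model and with
a shuffled-label permutation null.

Pixel-wise activity maps apply preprocessing, band subset and model to every
pixel spectrum of a calibrated cube; maps are rendered blue (low) to red
(high), and a figure set shares one value scale so identical activities get
identical colours.

## The synthetic study

No measured data ships with the package, so a generator produces paired
datasets with the structure the analysis assumes.  Design: 4 NaCl treatments
(0/1/2/3 g/L) × 3 growth stages × 27 plants = 324 leaf samples; SOD =
0.10 + 0.04·conc + 0.05·stage + assay noise (U/mg), truncated at zero —
activity increases with both salt concentration and stage.  Spectra are a
smooth modality-specific baseline (micro: peaks near 480/560 nm, valleys
near 500/690 nm, low plateau past 700 nm; macro: green peak near 545 nm,
red edge to a high 755–900 nm plateau, small 950 nm water valley) plus
narrow SOD-proportional Gaussian dips at the modality's sensitive bands
(defaults: the ten micro bands 426–682 nm and ten macro bands 497–948 nm
the analysis is expected to recover; depth 0.25·SOD reflectance, widths
4 nm micro / 1.5 nm macro — the macro width is set by the 511/516 nm
doublet, which must remain resolvable on a 2.35 nm grid), plus per-sample
drift, plus i.i.d. band noise (sd 0.001).

The drift term is the deliberate difficulty in the data: a random offset,
tilt and curvature (sds 0.18/0.12/0.072 reflectance) and three random broad
Gaussian bumps (sd 0.04, widths 60–110 nm), emulating uncorrected
illumination/scattering variation between acquisitions.  Its structure is
what ranks the pretreatments: polynomial detrending
removes the polynomial part exactly but not the bumps; the derivative
suppresses the whole smooth drift and sharpens the narrow features;
smoothing removes neither and matters little because the i.i.d. noise floor
is low.  Hence FD ≥ baseline ≥ {raw, smoothing} in prediction R, which the
acceptance suite asserts on the default seeded study.  The two wavelength
grids differ on purpose (2 vs 2.35 nm) so every cross-modality code path
handles unequal band axes.  All stochastic terms scale with `noise_sd`;
`noise_sd=0` gives fully deterministic spectra, used by the zero-noise
contracts (monotone SOD in concentration, single-spectrum collapse, exact
planted-band correlation, cube pixel-mean identity).

Small image cubes (24×24 pixels) per modality replicate a sample's spectrum
per pixel with a planted spatial SOD gradient (span 0.08 U/mg) and pixel
noise, providing ground truth for the activity-map contract.

What the generator does *not* emulate: radiative transfer, leaf anatomy,
instrument point-spread functions, nonlinear concentration-reflectance
relationships, or spatial correlation between neighbouring leaf regions
beyond the planted gradient.  Passing tests therefore demonstrate that the
pipeline's machinery is correct and self-consistent under its assumed data
model — not that any real-data accuracy is attained; no measured dataset is
available to this package.

## Problem sizes and determinism

The default end-to-end study (324 samples, 301/256 bands, four pretreatment
models at 300 epochs, one 10-band transfer with reference models, one
pixel map) runs in a few minutes on a single CPU; unit tests use reduced
designs (coarser grids, 3–5 plants per cell).  Every stochastic step —
generation, splitting, initialization, batching, fine-tuning subset,
permutation null — takes an explicit seed, and pure-numpy training makes
repeat runs bit-identical on the same platform; across platforms metric
tolerances, not bit identity, are promised.

## Known limitations

* The LSTM consumes sequences of length ≤ 5 after three conv blocks; it is
  faithful to the stated architecture but adds little capacity over the
  dense head at these lengths.
* Rank pairing assumes the two sensitive-peak lists order consistently
  along wavelength; a modality whose peaks reorder would need manual pairs.
* `full_finetune` with very few target labels can overfit; no early
  stopping is implemented.
* The ENVI reader supports BSQ/BIL/BIP uncompressed integer/float files
  only — no band-interleave exotica, compression or BIL tiling.
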