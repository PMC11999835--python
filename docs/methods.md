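# Methods

This note documents the models implemented in `spectransfer`, the synthetic
data the package is validated on, and the numerical choices made where the
design was genuinely open.

## Problem setting

A discrimination model for meat species (chicken / beef / duck) is trained
on reflectance spectra from a benchtop *master* spectrometer and must remain
valid for a portable push-broom *slave* imager whose spectral response
differs (detector response, slit width, wavelength-calibration error).
Calibration transfer estimates, from a small *standard set* of samples
measured on both instruments, a map taking slave spectra into the master's
response space. The package implements the full chain: instrument
simulation, wavelength calibration, sample partitioning, three transfer
estimators, two classifiers, and pixel-wise adulteration mapping of
hyperspectral cubes.

## Synthetic reflectance model

Visible meat reflectance (400–800 nm) is dominated by haem pigments: the
Soret band near 420 nm, the oxymyoglobin doublet at 540/575 nm, and — in
beef — a weak metmyoglobin feature near 630 nm. Each species is modelled as

    r(λ) = level · [ b0 + b1 (λ − 600) − Σ_k d_k exp(−(λ − c_k)² / 2w_k²) ]

clipped to [0, 1], with multiplicative N(1, σ²) variability (σ = 0.05 by
default) on the overall level and on each band depth independently. Default
baselines make chicken distinctly brighter (0.63) than beef (0.46) and duck
(0.43), whose spectra are deliberately similar — the hard part of the
classification problem. Band positions are fixed at 420/540/575 (+630 nm
for beef); depths and widths are configurable. Line shapes are Gaussian:
only peak positions and the qualitative reflectance ordering are known, so
the simplest smooth dip was chosen.

## Instrument observation model

Observation is: Gaussian slit convolution (σ = FWHM/2.3548) on a dense
latent grid → sampling at `grid + wavelength_shift` → gain and offset →
additive Gaussian noise (default s.d. 0.003 reflectance). Defaults:

| parameter | master | slave |
|---|---|---|
| grid | 300–800 nm @ 1.3 nm | 400–800 nm @ 5 nm |
| FWHM | 1.3 nm | 5 nm |
| gain | 1 | response curve, mean ≈ 1.15 |
| offset | 0 | 0.03 |
| wavelength shift | 0 | +3 nm |

The slave's gain is a smooth wavelength-dependent response curve (linear
tilt plus localized deviations near 410 and 620 nm) with mean ≈ 1.15 rather
than a scalar: the spectral angle is invariant to any scalar gain, so a
purely scalar mismatch could not reproduce the ~8° master/slave disagreement
that makes transfer worthwhile; real instrument pairs differ in a
wavelength-dependent way, concentrated at the ends of the detector response.
The dense latent grid is 295–820 nm at 0.5 nm so that both instruments'
slit kernels and the master's full 300 nm edge are supported. Slit widths
far below the latent spacing degrade gracefully to no smoothing (the
identity-instrument limit).

Spliced-meat cubes assign contiguous vertical stripes (configurable to a
checkerboard) whose pixel counts realise a ratio triple exactly via the
largest-remainder rule; each pixel's spectrum is drawn from its class model
and observed through the slave.

What the generator does **not** emulate: radiometric units, dark/white
reference errors, bidirectional reflectance, spatial texture, freezing
biochemistry, heteroscedastic noise. Passing tests therefore demonstrate
correctness of the estimators and the qualitative transferability
structure, not field performance on real meat.

## Wavelength calibration

The pixel→wavelength map of the imager is two quadratics
λ(i) = a i² + b i + c joined at a breakpoint pixel (944 for the reference
design; segments cover (0, 944] and (944, 1870]), each fitted by ordinary
least squares from (pixel, wavelength) pairs. The fit audits monotonicity
over the pixel range and the segment gap at the breakpoint (warning above
1 nm); notably the reference design's own printed coefficients produce a
~0.1 nm non-monotone step at the joint, which the audit flags rather than
hides. FWHM of an emission line is measured after subtracting the scan
minimum (robust to detector offset) by linearly interpolating the
half-maximum crossing on each flank.

## Sample partitioning (SPXY)

SPXY selects training samples by a greedy max–min rule on the joint
distance d = d_X/max d_X + d_y/max d_y (Euclidean; class labels enter
one-hot, float-valued responses enter directly). The first two picks are
the farthest pair; ties break to the lowest index. Standard sets are the
SPXY-order prefix of the training set, making them deterministic and
nested in k. Standard-set sizing fits the transfer at each k and evaluates
the mean spectral angle on *held-out* samples (evaluating on the standards
themselves would reward overfitting).

## Transfer estimators

All three operate on a common grid: the slave's wavelengths restricted to
the 400–800 nm master/slave overlap (the coarser instrument bounds the
shared information), with the master resampled onto it by linear
interpolation.

**PDS.** For each wavelength index i, the master response is regressed on
the slave responses in the index window [i−w, i+w] (clipped at the ends;
window size 2w+1) by mean-centred PLS regression; the centring is folded
into a per-wavelength intercept. Defaults w = 12 (window 25) and 6
components; leave-one-out CV over a (w, components) grid is provided.

**SST.** The mean-centred standards are concatenated column-wise,
X_comb = [X_m X_s], and decomposed by PCA (via SVD). Splitting the loadings
into P_m, P_s gives the transfer matrix

    F = I + (P_sᵀ)⁺ (P_mᵀ − P_sᵀ),

applied as x → (x − c_s) F + c_m. With identical standards P_m = P_s and
F = I exactly. Default 6 components; 5-fold seeded CV provided.

**ATLD.** Standards from both instruments form an I×J×2 tensor factorised
as x_ijk = Σ_n a_in b_jn c_kn by alternating least squares on the three
matricised unfoldings with Moore–Penrose pseudoinverses (deterministic
initialisation: A, B from the SVD of the mean slice, C = 1; columns of B
and C renormalised each sweep). With F_k = diag(c_k) Bᵀ, a spectrum x from
instrument k1 maps to k2 as

    x_trans = x F_{k1}⁺ F_{k2} + (x − x F_{k1}⁺ F_{k1}),

i.e. the factor-space reconstruction on the target instrument plus the
unmodelled residual; identical instrument factors give the identity map.
Stopping: relative fit change < 1e-10 or 500 sweeps (a non-converged flag
is recorded; the objective is asserted non-increasing per sweep). Default
N = 2 factors.

Hyperparameter selections (PDS LOO grid, SST/ATLD 5-fold) minimise the
RMSE between master and transformed slave standards; cells within 1e-9
(absolute) of the minimum count as ties and the smallest parameter wins —
required so that degenerate cases (slave = master, RMSE ≈ machine noise
everywhere) resolve to the most parsimonious model deterministically.

## Classifiers

**PLS-DA**: one-hot indicator regression Y = X b + e with argmax decision.
Components are chosen by seeded stratified 10-fold CV; a held-out sample
counts as an error when its predicted score for the *true* class deviates
from the target 1 by more than 0.5 (a per-class decision threshold is
ill-defined for three classes, so the 0.5 threshold is used as the CV
error criterion and argmax as the decision rule). **SVM**: RBF kernel,
one-vs-one multiclass, seeded stratified grid-search CV on accuracy with
ties to smaller C then smaller gamma (delegates the solver to
scikit-learn; the contract here is the protocol, not the QP). Class order
is alphabetical (beef, chicken, duck) and recorded in every model. Spectra
enter raw — no derivative or scatter correction.

Confusion reports use one-vs-rest counts: accuracy = trace/total,
sensitivity = TP/(TP+FN), precision = TP/(TP+FP); the precision of a class
never predicted (TP+FP = 0) is reported as NaN rather than forced into
[0, 1]. The mean per-sample Pearson correlation r̄ is reported untruncated
(it can be negative for anti-correlated spectra even though a nominal
range of [0, 1] is often quoted for well-behaved transfers).

## Adulteration mapping

Cube pixels are flattened, interpolated onto the model grid if needed,
optionally transformed, classified, and reshaped; no spatial smoothing is
applied by default (a median filter is available but off). Proportions are
pixel fractions over the whole cube (synthetic cubes have no background; a
background mask can be applied to real data before counting).

## Problem sizes and reproducibility

The default experiment uses 144 samples (48 per species), a ~2:1 SPXY
train:prediction split, standard sets of 15/10/20 for PDS/SST/ATLD, and
three 60×60 spliced cubes at ratios 0.5:1:2, 1:1:1 and 2:1:1 — sizes at
which the full pipeline runs in seconds while keeping every estimator in
its intended regime. All randomness flows from explicit integer seeds
(sample draw, instrument noise, CV folds), and `run_experiment` writes a
manifest with a config hash so a run can be reproduced bit-for-bit.

## Known limitations

- The transfer maps are linear (affine); nonlinear instrument distortions
  are only locally approximated by PDS windows.
- ATLD with 2 factors under-fits spectra whose cross-instrument difference
  has higher rank — visible as its larger residual angle; this mirrors its
  role as the weakest of the three transfers.
- The simulator emits per-sample spectra directly; extraction of
  per-sample mean spectra from real cubes (ROI choice) is out of scope.
- Real-data effects listed above (illumination, surface moisture, texture)
  are not modelled; conclusions about rank ordering of methods on real
  instruments require real standards.
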