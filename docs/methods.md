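# Methods

## The problem

Spectral calibration sets in bioprocess monitoring are small: a handful of
chromatography runs, a few hundred fractionated samples, each pairing a
UV/Vis absorbance spectrum **x** (N wavelengths) with reference
concentrations **y** (P components) from fraction analytics.  Nonlinear
regression models such as 1-D CNNs need far more calibration data than such
sets provide.  `lsaspec` implements a generative augmentation method —
*local subset augmentation* (LSA) — that synthesises realistic in-silico
spectra from the experimental data, plus the surrounding workflow: CNN
training and cross-validation on augmented data, a NIPALS PLS baseline,
hyperparameter search with median pruning, per-wavelength attribution, and
an in-silico robustness study.

## Local subset augmentation

Under Beer–Lambert bilinearity a mixture spectrum is a concentration-
weighted sum of pure-component profiles, `x = S y`, with `S` (N×P) the
absorbance per unit concentration of each species.  LSA exploits this
structure locally:

1. **Concentration sampling.**  The marginal distribution of each
   component's concentration is estimated per column of Y (Gaussian KDE
   with Scott's-rule bandwidth by default; uniform-range and normal
   samplers are provided for comparison) and a vector `y*` is drawn.
   Components are sampled independently, so cross-component correlation in
   the calibration data is *not* preserved — a deliberate design that
   widens the sampled composition space beyond the correlated elution
   trajectories, and a documented limitation.  Negative draws are rejected
   and redrawn (≤ 100 rounds), then clamped to 0.
2. **Local subset selection.**  The `n_lsa` calibration samples nearest to
   `y*` in concentration space (l1 or l2 norm; exact ties broken by
   ascending row index) form a local subset (X̃, Ỹ).
3. **Spectrum synthesis.**  Pure-component profiles S̃ are estimated from
   the subset by classical least squares, `X̃ ≈ Ỹ S̃ᵀ`, solved as one
   independent P-dimensional problem per wavelength with either an OLS
   solver (minimum-norm solution on rank-deficient subsets, with a logged
   warning — near-duplicate compositions are common in elution fractions)
   or NNLS (every coefficient constrained ≥ 0).  The generated spectrum is
   `x* = S̃ y*`, perturbed by one wavelength shift δ ~ N(0, σ_shift) per
   spectrum (linear interpolation, edge values held) followed by i.i.d.
   white noise N(0, σ_noise) per feature.  The shift is applied before the
   noise so the noise statistics are unaffected by the shift.

Because the profiles are re-estimated per draw from the neighbourhood of
`y*`, the method adapts to concentration-dependent deviations from a single
global bilinear model.  With `n_lsa = M` the estimate coincides with the
global classical least-squares solution.

**Tuning.**  Augmentation quality is measured by leave-one-group-out
reconstruction: each experimental spectrum is re-synthesised at its
measured concentrations using only the other experiments' data, and the
residuals are pooled into an RMSECV.  `tune_lsa` grid-searches
`{n_lsa, l, solver, σ_noise, σ_shift}` against this criterion (ties:
smaller n_lsa, then l = 2, then listing order).  Group-wise hold-out was
chosen over single-sample hold-out to match the model cross-validation
scheme; the configured perturbation is applied during reconstruction by
default (identity at σ = 0), and both behaviours are exposed.  `n_lsa` is
capped at the retained sample count of a rotation (the cap equals global
estimation); the strict size error is available via `clamp_n_lsa=False`.

## The CNN family and training protocol

Networks map a length-N spectrum to P non-negative outputs: 1–3 'valid'
(no padding) convolutional layers (per layer 1–10 filters of odd width ≥ 3,
identity activation by default), max pooling of width 2 after layers 1 and
2 (the admissible filter width halves accordingly), one fully connected
layer (5–100 units, tanh), optional dropout after the FC layer, L2
regularisation on all weight matrices, and a ReLU output restricting
predictions to positive values.  Weights are initialised random-uniform in
±0.05 (a Glorot-uniform option exists); the output bias starts at +0.1 so
the output ReLU is active from the first step.  Training minimises the
mean MSE over responses with Adam (lr 1e-3, batch 100) for at most 100
epochs, stopping when the validation loss has not improved for `patience`
consecutive epochs (4 during search, 10 for final retraining) and restoring
the best-epoch weights.

The forward/backward passes are implemented directly in numpy: the networks
are at most a few thousand parameters, the implementation is fully
inspectable, and the last convolutional layer's feature maps and their
exact gradients — which Grad-CAM needs — are first-class outputs.

**Cross-validation.**  Leave-one-group-out over experiments; within each
rotation the in-silico calibration data are regenerated *from the retained
groups only*, the network trains exclusively on generated data while the
retained experimental data drive early stopping, and the held-out group is
predicted.  Held-out predictions are pooled across rotations before
computing per-component R² (pooling is the default; small groups make
per-rotation averages unstable).  The objective is ΣR²_CV (maximum P).
An unaugmented baseline protocol trains on the experimental data directly
(random 80/20 calibration/validation split, 300 epochs, early stopping
disabled, best-validation-epoch weights returned).

## PLS baseline

Single-response PLS1 per component, computed by NIPALS with deflation;
spectra are optionally Savitzky–Golay filtered (second-degree polynomial,
derivative order 0–2, odd window 3–31, derivative scaled by the wavelength
step) and mean-centered after filtering (filtering is linear, so the order
is immaterial for the fit; centering after keeps the stored means on the
filtered scale).  β = W(PᵀW)⁻¹q reproduces the score-space prediction
exactly.  Model selection grid-searches A ∈ [1,10] × deriv ∈ [0,2] × odd
window ∈ [3,31] against the degrees-of-freedom-scaled cross-validated SSE,
`Σ(ŷᵢ−yᵢ)²/(M−A−1)` with M the number of pooled CV predictions (ties:
smaller A, then smaller window, then lower derivative).

## Hyperparameter optimization

Each trial samples an architecture and `n_lsa` uniformly from declared
ranges (l2 factor log-uniformly; conditional per-layer parameters exist
only for sampled layers).  A single training run on all training groups
yields the intermediate objective ΣR²_train; once 100 trials have completed
(counting non-pruned trials), a trial is pruned when its intermediate value
falls strictly below the median of all previously reported intermediate
values — pruned trials never run the expensive cross-validation.  The
protocol's first 100 trials are random search, after which a model-based
(TPE) sampler would take over; no TPE backend ships with the package, so
the TPE phase delegates to the same seeded random sampler (requesting
`sampler='tpe'` warns).  Study state is append-only JSON lines and
resumable.  `select_and_retrain` ranks completed trials by ΣR²_CV, exposes
the top-k table, and retrains the best configuration for `repeats`
repetitions with patience 10 and fresh seeds.  The categorical choices the
single-factor study fixed (identity conv activation, tanh FC,
random-uniform init, Adam, lr 1e-3, batch 100) are defaults, not search
dimensions.  The `n_lsa` search range is a user input (default: tuned
initial value ± 5).

## Feature importance

* **Grad-CAM** — per filter k of the last conv layer,
  α_k = mean over positions of ∂output_c/∂(feature map k); the map is
  ReLU(Σ_k α_k · feature map k), linearly interpolated to N.  Non-negative
  by construction.  The gradients are exact backprop gradients of the
  post-ReLU output.
* **Permutation SHAP** — Shapley values estimated by walking random feature
  orderings forward and backward (antithetic pairs) and crediting each
  wavelength with its marginal change in the coalition value.  A coalition
  is valued as the *mean* prediction over the full background set with
  masked wavelengths replaced by background values (interventional
  replacement; true conditional densities are out of scope).  Local
  additivity Σφ = f(x) − E_bg[f] therefore holds exactly for every
  completed pair, not just in expectation.
* **VIP** — v_j = √(N Σ_a q_a² tᵃᵀtᵃ (w_aj/‖w_a‖)² / Σ_a q_a² tᵃᵀtᵃ),
  the conventional square-root form whose mean squared score is 1.
* **Coefficients** — β on the filtered-spectrum scale, with the
  preprocessing chain recorded in the result metadata.

## Robustness study

Two one-at-a-time sweeps: white-noise SDs (default
{0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1} absorbance units) and wavelength
shift SDs (default {0, 0.05, …, 0.3} wavelength units).  *Fixed* models are
trained once on unperturbed generated data and evaluated on evaluation
spectra perturbed at each level; *retrained* models are retrained at each
level on generated data perturbed at that level (and evaluated on equally
perturbed spectra).  Both model families are calibrated on LSA-generated
data so the comparison isolates the perturbation effect.  Cell summary:
sum over components of NRMSE (= RMSE / mean observed concentration).
PLS preprocessing is re-used across levels by default (a re-tune option
exists but is off).

## Synthetic data

The generator emulates fraction analytics of preparative chromatography:
Gaussian elution peaks per component and experiment over the fraction
index, pure spectra as sums of Gaussian absorption bands, Beer–Lambert
mixing, optional linear baseline (off by default, since LSA assumes
bilinearity), and homoscedastic Gaussian cell noise matching the
perturbation model of the robustness study.  An optional `conc_floor`
reports concentrations below a quantification limit as 0 (applied before
mixing, so the bilinear model stays exact w.r.t. reported values; default
off).

The `ds1_like` preset mirrors a three-protein UV/Vis calibration set:
3 components, 5 experiments × 45 fractions = 225 samples, 61 wavelengths
(240–300 nm at 1 nm), run-to-run retention shifts (+2 fractions per run)
and peak-height scaling (+10 % per run), default cell noise 0.001
absorbance units.  Elution peaks (width 6 fractions, retention 8/21/34)
span the fraction window, so every collected fraction carries appreciable
analyte (minimum concentration-vector norm ≈ 0.06) — fraction analytics
does not report pure-baseline samples, and compositions many orders of
magnitude below the quantification limit would make local least-squares
subsets artificially degenerate.

**What passing tests on these data do and do not show.**  The generator
satisfies exact bilinearity, so it validates the algebra (exact
reconstruction, profile recovery, noise floors) and the end-to-end
trainability of the workflow.  It does not emulate detector saturation,
scatter, IR backgrounds, correlated noise, or deviations from
Beer–Lambert — results on real spectra can differ, which is precisely why
the augmentation carries a reconstruction-CV diagnostic.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and the acceptance script:
n_gen = 10⁴ for end-to-end cross-validation on the ds1-like set, 10³ for
hyperparameter-study checks, 5×10³ for robustness cells; production-scale
runs would raise n_gen to 10⁵ (performance there plateaus), which is a
configuration value, not a code-path difference.  Key
numerical choices: profile estimates inside `augment_dataset` are memoised
per selected subset index set (exact, bit-identical); reconstruction and
augmentation derive all randomness from a single seeded generator;
rank-deficient OLS returns the minimum-norm solution with a warning rather
than failing; zero-variance concentration columns degrade the sampler to a
point mass with a warning; R² and NRMSE are NaN where undefined (zero
variance / zero mean) rather than raising.

## Known limitations

Per-component independent concentration sampling ignores cross-component
correlation; the TPE phase of the optimizer is random search unless an
external backend is wired in; Grad-CAM resolution is bounded by the pooled
feature length; permutation SHAP costs scale with
walks × (N+1) × background size; the CNN implementation is CPU/numpy and
deliberately limited to the small architecture family described above.
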