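# Methods

This note documents the models and numerical choices behind `libsclass`:
what each stage assumes, which parameters matter, and what the synthetic
data can and cannot tell you about measured spectra.

## The measurement model behind the simulator

A non-gated LIBS measurement integrates the plasma emission over its
whole lifetime, so the recorded spectrum is the sum of element-specific
emission lines and the early-plasma continuum (radiative recombination
and Bremsstrahlung). The simulator reproduces the *statistical shape* of
such spectra, not the plasma physics:

* **Lines** are unit-peak Gaussians: a line with amplitude *A*, center
  *λ₀* and width *w* (FWHM) contributes `A·exp(−4 ln2 (λ−λ₀)²/w²)`.
  Amplitude is peak height in arbitrary units. Widths default to
  0.8–1.5 nm, the resolution scale of a compact Czerny-Turner
  spectrograph. Lorentzian (Stark) wings are not modelled; at this
  resolution the instrument function dominates the observed shape.
* **Continuum** is `offset + a·exp(−(λ−c)²/2σ²)` with σ ≈ 120–140 nm —
  a smooth, broad, strictly positive curve. Only smoothness and breadth
  matter downstream (the baseline fit sees it as "anything an order-6
  polynomial can track"), so no physical emissivity model is used.
* **Noise** has three parts, mirroring the real error budget:
  * *Line scatter* — each line amplitude in each spectrum is multiplied
    by an independent lognormal variate with mean exactly 1 and
    coefficient of variation `line_scatter_sd` (default **0.15**,
    parameterized as σ² = ln(1+cv²), μ = −σ²/2). This emulates
    shot-to-shot variation in ablated mass and surface condition of a
    pressed pellet. Independence across lines is deliberate: a common
    per-spectrum factor would cancel under internal-standard
    normalization and contribute nothing.
  * *Fixed-pattern gain* — one multiplicative gain vector
    `1 + N(0, fixed_pattern_sd)` (default **0.03**) drawn once per
    dataset and applied to every spectrum, modelling static CCD pixel
    non-uniformity.
  * *Shot noise* — additive Gaussian with sd `shot_scale·√I` per channel
    (default **0.02**), the Gaussian approximation of Poisson counting
    noise at high signal levels.
* **Default dataset**: 100 spectra per class on a uniform 2068-channel
  350–900 nm grid, all seeded; identical seeds give bit-identical data.

Four formulation profiles share the same line positions (all classes
contain H, Cl, N, O — the elements are present in every formulation and
in ambient air) and differ in amplitude ratios and continuum parameters.
Two classes carry fluorine lines (685.6/690.2 nm, a simulator choice of
position). Two classes are constructed as a **hard pair**: every shared
line amplitude and the continuum amplitude agree within 10% relative,
with identical continuum shape. The hard pair is what makes the
classification problem non-trivial at default noise; classes differing
only in continuum amplitude (`continuum_contrast_profiles`) isolate the
question of whether background carries class information.

What the simulator does *not* emulate: wavelength-calibration drift,
detector saturation and nonlinearity, self-absorption of strong lines,
matrix effects coupling line ratios to ablation conditions, and
correlated (non-white) channel noise. Passing tests on synthetic data
therefore demonstrate the correctness and calibration of the
*algorithms*, not instrument-grade performance claims on real spectra.

## Preprocessing

The 30 nm band around the 532 nm excitation line is masked (closed
interval, full width ⇒ ±15 nm) and excluded from every downstream
computation — an invariant the test suite enforces by vandalizing masked
channels and asserting bit-identical results. Each spectrum is then
divided by its maximum valid intensity within ±2 nm of the Hα reference
line at 656.3 nm. Peak height (not area) is used as the internal
standard; the ±2 nm search window absorbs small calibration offsets. The
pipeline order is notch → normalize → outlier screening; normalization
first makes the outlier metric scale-free.

## Baseline estimation

The continuum estimator is the modified-polyfit family: iterate
least-squares polynomial fit (order 6 by default) and pointwise
min-clipping of the working vector, until the maximum change of the
fitted curve relative to its maximum magnitude falls below `tol = 1e-4`
or `max_iter = 100` is reached (non-convergence warns and returns the
last iterate; on noisy spectra the creep below `tol` can take a few
hundred iterations, and stopping early changes the baseline by well
under a percent). Wavelengths are affinely mapped to [−1, 1] before
fitting for conditioning. "Non-negativity" is applied to the corrected
spectrum: negative residuals are clipped to zero. The alternative
reading — constraining the polynomial itself to be non-negative — is
nonstandard in this algorithm family and was rejected. On peak-free
polynomial input of degree ≤ order the method is exact; planted-peak
recovery and ground-truth continuum recovery are tested against the
generator's truth sidecar.

## Outlier screening

Agglomerative clustering (Ward linkage on Euclidean distances — the
standard choice for spectra, and one that guarantees monotone merge
heights) is run **within each formulation**. A branch is *isolated* when
its size is at most `max_branch_size = 2` and it joins the rest of the
tree above `height_factor = 3` times the median merge height; its
members are discarded before class means or classifiers are computed.
Both parameters and a global (cross-class) mode are exposed.

The rule is calibrated so that a homogeneous class with light-tailed
noise is almost never flagged (≥ 99% of replicates clean). Under the
default *heavy-tailed* lognormal scatter, a few spectra per 400 are
flagged (typically 1–2%); these are genuine stragglers of the
inhomogeneity distribution — exactly what the screen exists to remove —
not false positives of the rule. Because "isolated branch" admits many
quantifications, absolute flag counts on other datasets depend on this
operationalization; the pipeline therefore reports counts rather than
asserting them.

## PCA

Mean-centering only, no unit-variance scaling: spectra are already on a
common scale after internal-standard normalization, and autoscaling
would inflate noise-only channels. The decomposition is the SVD of the
centered matrix over valid channels; variance fractions are squared
singular values over total variance. Component signs are fixed (largest
|loading| entry positive) so results are reproducible bit-for-bit.

## SIMCA

Per class: PCA submodel of rank `k_c`, the smallest rank whose
cumulative variance reaches `variance_target = 0.95`, capped at
`min(10, n_c − 1)`. The acceptance statistic is the orthogonal residual
distance only (no score/leverage term); the threshold is
`mean + 3·sd` of the training distances. When several classes accept a
spectrum, it is assigned to the one with the smallest *standardized*
distance `(d − mean)/sd` — this keeps misclassification possible in
principle while separable classes still yield a clean
(1, 0, 0) trichotomy.

A known limitation, visible in the tests' fixture design: the training
residual distances are in-sample. When class scatter is essentially
unstructured and tiny (near-noiseless data), high-dimensional norm
concentration makes the residual sd collapse while the out-of-sample
residuals sit systematically above the in-sample ones (the submodel
overfits its own training rows), and the 3σ band rejects nearly
everything. With realistic structured scatter (line-amplitude cv ≳ 0.1,
as in the default noise model) the low-rank submodels capture the
structure, the sd is dominated by genuine variability, and acceptance
behaves as intended. Cross-validated residuals would remove the bias at
the cost of a different (and less transparent) threshold definition.

## PLS-DA and ANN

PLS-DA regresses one-hot class indicators on mean-centered spectra by
NIPALS PLS2 and assigns by argmax of the predicted indicators (ties to
the lowest-index class; no rejection option, so its unclassification
rate is structurally zero). The number of latent variables, when not
fixed, is chosen by stratified 5-fold cross-validated accuracy on the
training split (cap 10, smallest count on ties) — deterministic, no
shuffling.

The ANN is intentionally minimal: inputs are the first 10 global PCA
scores (standardized with training statistics), one hidden layer of
width 8 with tanh, softmax output, cross-entropy minimized by full-batch
gradient descent (learning rate 0.5, 800 epochs, seeded initialization
`N(0, 1/√fan_in)`). Everything is deterministic under the seed. A
warning fires if the final mean cross-entropy stays above 0.5, i.e. the
network failed to learn.

## Evaluation protocol

Stratified splits put `round(n_c·0.7)` rows of each class into training
(round-half-up; at least one row on each side), the remainder into test.
100 iterations re-split with seeds `base_seed + i`, refit the classifier
from scratch, and classify the held-out spectra; reports carry per-class
and average (unweighted class mean) rate triples with means and sds plus
the per-iteration average-correct vector. For the background-removed
variant the baseline is estimated and subtracted once for the whole
dataset before splitting — it is a preprocessing step, not a
train-dependent transform. Raw and corrected runs are compared with a
Welch two-sample t test on the per-iteration average-correct vectors
(two identical zero-variance vectors give p = 1 by convention). The test
treats iterations as independent replicates; re-splits of one dataset
are not strictly independent, so the p-value is a descriptive effect
measure, as is conventional for this protocol.

## Problem sizes

The default study conditions are 4 × 100 spectra on a 2068-channel grid
with 100-iteration evaluations (`scripts/acceptance.py`, `analysis/`).
The test suite runs the same algorithms on reduced instances — an
800-channel grid, 25–60 spectra per class, 2–10 iterations — chosen so
that every statistical assertion retains comfortable margins while the
whole suite stays fast.
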