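# Methods

`facegeom` simulates and analyzes the population geometry of face coding in
high-level visual and medial-temporal face-selective neurons, focusing on how
personal familiarity modifies a linear feature code. This note documents the
generative model, the statistics, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## The axis code and its familiarity effects

Each cell's expected firing rate to a face with feature vector **f** (shape and
appearance coordinates of a parametric face space, treated as whitened,
i.i.d. standard normal per coordinate) is

    r_i = c0_i + g_i (c_i . f)

with a unit preferred axis `c_i`, an offset `c0_i` (Hz) and a gain `g_i`
(Hz per feature s.d.). On top of this unfamiliar-face code the generator
implements three independently switchable familiarity effects:

1. **Early subspace shift.** From `shift_onset_ms`, familiar-face responses
   receive an additive per-cell offset. The shift pattern is constructed in
   cell space orthogonal to the feature-encoding patterns (the columns of the
   axis matrix `C`, their gain-weighted and gain-squared-weighted versions) and
   to the uniform-rate and gain directions. It therefore carries the
   familiar/unfamiliar distinction without perturbing feature decoding or mean
   population rate. `shift_magnitude` is the shift vector's norm in units of
   the population signal s.d.: cell *i*'s rate shift is
   `sqrt(n_cells) * g_i * s_i` Hz with the stored loading vector *s*
   normalized to `||s|| = shift_magnitude`; in per-cell z-scored population
   space the shift's norm is then `shift_magnitude` times the norm of a
   typical signal fluctuation. At the default `shift_magnitude = 2` this
   produces per-cell familiar-minus-unfamiliar rate differences of roughly
   plus/minus one per-cell signal s.d. — a clearly bimodal distribution with
   many individually significant cells, matching the magnitudes seen in
   recordings. Constructing the orthogonal complement requires
   `n_cells > 3 * d_used + 2`; below that the shift is zeroed with a warning.
2. **Late axis rotation.** From `rotation_onset_ms`, each cell's familiar-face
   drive uses a rotated axis `c_i'`, obtained by rotating `c_i` by
   `rotation_angle_deg` toward an independent random direction orthogonal to
   it (a single controllable angle per cell). `familiar_gain` additionally
   scales the whole evoked familiar response (offset plus drive) in this
   epoch; values below 1 reproduce delayed familiarity suppression. The gain
   acts on the full evoked rate rather than the zero-mean drive because a
   mean-rate familiarity divergence requires a mean effect.
3. **Context gain.** In mixed-ratio experiments, the rarer familiarity class's
   post-onset rates are multiplied by `context_gain_rare`, modeling stronger
   responses to unexpected stimuli. The presentation ratio determines
   per-face trial counts (majority class at `n_trials` per face, minority
   faces proportionally fewer, floor one trial) and which class counts as
   rare.

Rates are floored at 0 before the noise draw (physical nonnegativity; the
induced rectification is a deliberate stress on the linear analyses and
truncates part of very large negative shifts). Spike counts are Poisson per
half-open `[t, t + bin_ms)` bin; `noise_model="gaussian"` substitutes a
rounded Gaussian with Poisson-matched variance, and `"none"` returns exact
expected counts for closed-form checks. Temporal structure uses two sharp
epochs rather than smooth ramps so that latency recovery has an unambiguous
ground truth. All randomness flows from `SimConfig.seed`; identical configs
give bit-identical tensors.

Default conditions mirror a face-screening experiment: 150 cells, 1,000
unfamiliar plus 36 familiar faces in a 120-dimensional face space of which the
top ten shape and ten appearance features are used for fitting (`d_used = 20`),
10 ms bins from -50 to 300 ms, visual onset 90 ms, shift onset 100 ms,
rotation onset 200 ms at 60 degrees, baseline 10 Hz, peak 50 Hz, ten trials
per stimulus.

## Rolling windows and latency statistics

All time-resolved statistics use causal rolling windows `[t - 50, t)` ms,
stepped by 10 ms and labeled by their trailing edge `t`. A detected latency is
therefore an upper bound on the true onset: a window labeled before the onset
contains no post-onset data and cannot fire. (Center-labeled symmetric windows
would systematically *pre-date* sharp onsets, because a window centered before
the onset already contains signal.) Latency requires the detection p-value to
fall below alpha for two consecutive windows; the two-in-a-row rule suppresses
single-window false positives at the cost of at most one 10 ms step of delay.
Response latency uses a one-tailed paired t-test across cells of window rate
against each cell's pre-onset baseline rate; familiarity divergence uses a
two-tailed paired t-test of per-cell familiar-minus-unfamiliar mean rates.
Cells as the unit of analysis matches s.e.m.-across-neurons error bars.

## Preferred-axis estimation and the UU/UF comparison

Axes are fit by ridge-regularized least squares of trial-averaged window rates
on column-standardized features (standardization computed on the fitting set
only). The default ridge is 1e-6 of the mean design eigenvalue — numerically
a hair above OLS, with `ridge=0` recovering the exact normal-equations
solution (rank-deficient designs then raise an error instructing a positive
ridge). Coefficients are reported in per-s.d. feature units; the offset is
mapped back to the raw feature scale.

The memory statistic compares, per cell, the cosine between a reference axis
(fit on the unfamiliar pool minus a held-out subset) and an axis fit on (a)
the 36 held-out unfamiliar faces — the noise ceiling, UU — or (b) a
matched-size draw of familiar faces — UF. Held-out subsets are redrawn
(default 20 resamples) and cosines averaged per cell.

**Raw versus reliability-corrected cosines.** Fitting 20 coefficients from 36
faces is a near-singular regime: each specific design matrix carries its own
noise-attenuation factor. The familiar design is fixed while held-out
unfamiliar designs are averaged over draws, so raw UU and UF means differ by a
dataset-specific attenuation offset (of order 0.02-0.05) even when the axes
are identical — a paired t-test across cells will flag it. Significance
decisions (the UU > UF test, the time-resolved divergence latency, the
contrast and nonlinearity controls) therefore use Spearman
attenuation-corrected cosines: axes are re-fit on split halves of the trials,
cross-set cosines are divided by the geometric mean of the two sets'
split-half reliabilities, cells with reliability products below 0.05 are
excluded, and corrected values are clipped at |3|. Under a per-cell gain or
contrast change the corrected UU and UF agree exactly; a true rotation
survives the correction. A monotone *nonlinearity* is subtler: its nonlinear
residual is deterministic in the fixed face sample, so the in-sample fitted
axis is genuinely deflected by a few percent in cosine — real, reliable, and
detectable at high power, but an order of magnitude smaller than a memory
rotation. The nonlinearity control therefore bounds the corrected UF/UU
ratio (near 1, versus cos(angle) for a rotation) rather than asserting a
null p-value. Raw cosines remain the reported
traces and satisfy the attenuation identity `E[UF] = E[UU] * cos(angle)`,
which is how the rotation angle is recovered.

## Alternative single-cell models

For each cell, four models of the familiar-face response are compared by
5-fold cross-validated R^2: a gain change along the fixed reference axis
(2 parameters), a monotone output nonlinearity (isotonic regression on the
reference projection — the weakest monotone assumption), a sparse nonnegative
per-feature sensitivity reweighting (positive Lasso), and a free re-fit of the
full axis. Selection uses the one-standard-error rule: the simplest model
within one SE of the best cross-validated score wins. The generator's
saturating nonlinearity is `s * tanh(x / s)` with `s = 0.4`, chosen so that a
linear readout of the transfer function leaves about 20% of its variance
unexplained — saturation strong enough to be identifiable yet smooth and
monotone.

## Population geometry

Geometry operations (centroid distances, d', familiarity classification) work
on trial-averaged per-face responses in per-cell z-scored population space, so
high-rate cells do not dominate Euclidean structure. Distances scale like
sqrt(n_cells) for i.i.d. populations and are comparable only within a fixed
population.

* **Familiarity decoding** uses a ridge classifier per window with folds split
  by face identity (no identity in both train and test), class balance by
  repeated majority-class subsampling (votes averaged), and balanced accuracy
  so chance stays at 0.5. The latency is the first window whose accuracy
  exceeds the 99th percentile of label-permutation nulls for two consecutive
  windows.
* **d'** projects held-out per-face responses onto the familiar-unfamiliar
  centroid-difference axis estimated with that face left out (leave-one-out:
  deterministic, no split randomness, no selection bias) and computes
  `|mu_F - mu_U| / sqrt((var_F + var_U)/2)`; the null repeats the identical
  procedure under label shuffles (default 1,000).
* **Centroid distance traces** report the familiar-versus-unfamiliar centroid
  distance alongside a matched-size unfamiliar-subset control. Because both
  curves share centroid sampling noise, the debiased quantity
  `sqrt(max(0, blue^2 - orange^2))` estimates the true shift norm; the
  recovery benchmark compares it against the achieved (post-rectification)
  shift computed from a noiseless twin simulation.
* **Feature decoding** is ridge regression from z-scored rates to the 20
  features, with an identity-shuffled-training null (10 repeats). In raw rate
  space (`normalize_cells=False`) an orthogonally constructed shift is exactly
  invisible to the decoder; under per-cell z-scoring the invisibility is
  approximate (the shift is additionally orthogonalized against the
  gain-rescaled patterns, leaving residual overlap well below estimation
  noise).
* **Familiarity-axis orthogonality** takes the cosine, in cell space, between
  the unit classifier weights and each unit feature-decoder row. For this
  readout the classifier uses heavier shrinkage (alpha 100), pulling the
  weights toward the class-centroid difference: with 72 balanced training
  faces and 200 cells, a lightly regularized classifier interpolates via
  low-variance noise directions and its weight *direction* is meaningless
  even when its accuracy is high.

## Stimulus matching

Matched familiar/unfamiliar subsets minimize the sum over features of the
two-sample Kolmogorov-Smirnov statistic between the subsets plus (weight
lambda = 1) the KS statistic between their pairwise Euclidean distance
distributions. Subset selection is discrete, so the search is greedy
accept-if-better single-member swaps: each iteration proposes 40 random swaps
on either side and accepts the best improving one; the accepted-objective
trace is nonincreasing and the best state ever visited is returned. The
achieved divergences, not the optimizer, are the contract.

## What the synthetic benchmarks show — and what they do not

The generator realizes exactly the structure the analyses assume: linear
tuning, i.i.d. whitened features, sharp effect onsets, Poisson noise,
stationary cells. Passing the recovery suite demonstrates that every stage is
implemented correctly and calibrated (false-positive rates at nominal levels,
effects recovered at ground-truth values, each effect switchable in
isolation). It does not demonstrate robustness to properties of real
recordings that the generator omits: correlated trial-to-trial noise, rate
drift and adaptation, non-Poisson dispersion, smooth response ramps,
eye-movement covariates, or non-whitened feature statistics. The empirical
feature covariance of real face spaces is handled only through the
distribution-matching control, not modeled.

Problem sizes in the test suite (tens to a couple hundred cells, a few
hundred to ~1,000 faces, 100-seed null batteries) were chosen so each detector
operates in the regime where its power analysis predicts reliable recovery,
and are stated in the tests themselves.
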