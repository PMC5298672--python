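# Methods

## The instrument and its data

The package models a low-cost handheld visible-range spectrometer: light
enters through a slit whose width is set by a control wheel, is collimated,
diffracted, and photographed by a cheap RGB camera. Each photograph shows a
bright circular aperture with a horizontal spectrum band in a fixed position
inside it; the aperture's centre and radius drift a little between shots
because the camera is occasionally re-seated. The band is 700–800 pixel
columns wide in practice, and its left and right edges are calibrated to
390 nm and 700 nm.

## Image → spectrum extraction

1. **Aperture detection.** The image is reduced to summed RGB (0–765) and
   thresholded at a fixed fraction of 765 (default 0.2; Otsu optional). The
   largest connected bright component is the aperture; if the two largest
   components differ in area by less than 10 % the image is rejected as
   ambiguous rather than guessed at. The aperture circle is the minimum
   enclosing circle of the component's convex hull.
2. **Band placement.** The band box is placed at fixed fractional
   coordinates relative to the circle — by default x ∈ [−0.8 r, +0.8 r],
   y ∈ [−0.1 r, +0.1 r]. This relation is a property of the device's
   optics, so it is exposed as calibration configuration rather than
   estimated per image; the synthetic renderer uses the same convention.
3. **Column means.** Each band column's mean summed-RGB intensity is taken
   as a reflectance proxy. No gamma correction is applied: the pixel sum is
   treated as linear in reflectance, which is the instrument's operating
   assumption, not a radiometric fact.
4. **Resampling to 1..1000.** Column *i* of *N* maps to position
   `round_half_up(1 + (i−1)·999/(N−1))`; the first and last columns land
   exactly on 1 and 1000. With the realistic N ≈ 750 this leaves ~250
   isolated single-position gaps; colliding columns are averaged.
5. **Gap filling.** Gaps are filled by linear interpolation between the
   flanking occupied positions, which reduces to the mean of the two
   neighbours for the single-position gaps the real device produces; a gap
   at either end copies the nearest occupied value. Occupied positions are
   never altered.

Position *p* corresponds to `390 + (p−1)·310/999` nm. Wavelength is assumed
to increase left→right; a configuration flag flips the column order for
devices built the other way around.

## Preprocessing

The preprocessing grid is {none, 1st derivative, 2nd derivative,
Savitzky–Golay 1st-order smoothing} × {with, without moving-window
subtraction}, always followed by normalisation to an absolute maximum of 1.

* Derivatives use central differences (one-sided/replicated at the ends).
* Savitzky–Golay smoothing fits a least-squares line over an 11-point
  window (width configurable) evaluated at the window centre. "First-order"
  is read as polynomial order 1 smoothing, not a smoothed derivative, since
  derivatives are separate grid entries. Edge windows shrink to fit instead
  of padding by reflection, so no data is invented beyond the measured
  range; the interior agrees with the classical convolution weights.
* Moving-window subtraction removes the mean of the surrounding ±20
  positions (the subtracted statistic is a design choice; the windowed mean
  is the standard local-baseline estimate).
* Normalisation divides by max |s|; it is idempotent and invariant to
  positive rescaling, which is exactly what makes spectra comparable across
  slit-wheel illumination levels. An all-zero series (e.g. a second
  derivative of a constant) is returned as zeros with a warning rather than
  an error.

## Clustering

Spectra are compared by Euclidean distance over the 1000 positions and
clustered agglomeratively. The linkage method is configurable with average
(UPGMA) as the default — the standard choice for profile similarity; any
reported tree states the linkage used. Dendrograms are written as Newick
with branch lengths equal to merge-height differences. `cluster_purity`
turns the visual "replicates cluster together" judgement into a number: the
fraction of classes whose members appear as the exact leaf set of some
subtree.

## Neural-network calibration

The calibration model is deliberately the classical recipe: a feed-forward
network with two hidden layers of 20 logistic-sigmoid nodes, sigmoid
outputs, squared-error loss, and plain online (per-sample) gradient descent
at a fixed learning rate of 0.05. Weights are initialised uniform(−0.5, 0.5)
from a seeded generator; sample order is reshuffled each epoch by the same
generator, so training is bit-reproducible given a seed. The default budget
is 5000 epochs; the cross-validation experiments shipped with the package
use 400 epochs (classification) and 800 (regression), sizes at which the
synthetic designs have converged. Mean epoch loss is recorded; divergence
to a non-finite loss raises, and a net loss increase over the run warns.

**Classification** uses one network with one output per crop class plus one
per cropping system; the target vector is one-hot within each block (both
blocks hot simultaneously) and errors backpropagate from all outputs
jointly. Prediction is winner-takes-all *within each block* independently,
ties to the lowest index.

**Regression** uses one output per soil property. Targets are min–max
scaled to [0, 1] with statistics from the training fold only — scaling on
the full set would leak the validation fold's range — and predictions are
inverse-scaled to physical units before metrics. A constant training target
maps to 0.5 and inverse-transforms back to the constant.

**Grouped cross-validation.** Spectra are captured in duplicate at each
sample location; the two twins are near-duplicates, so letting one into
training while the other is validated inflates validation scores. Distinct
`group_id`s are shuffled with a seeded RNG and dealt round-robin into k = 10
folds (sizes differ by at most one group), and all members of a group share
a fold. The deliberately leaky alternative (each sample its own group) is
retained behind `group_folds=False` for ablation studies, where it shows
the inflation the grouped design prevents.

## Evaluation

Confusion matrices are oriented rows = predicted, columns = true; user's
accuracy is diagonal/row total, producer's accuracy diagonal/column total,
and Cohen's κ = (p_o − p_e)/(1 − p_e) with p_e from the margins. Regression
is scored per property by r² and RMSE in original units. r² is the squared
Pearson correlation of targets and predictions (the r² of the fitted linear
regression between them), hence invariant to affine miscalibration of the
predictions; the residual-based 1 − SSE/SST definition is available as a
named option for users who want miscalibration penalised.

The published field-trial confusion matrices and the observed ranges of the
eighteen soil properties are shipped in `phylis.reference`; all summary
statistics quoted for the trial are recomputed from those counts, never
hard-coded.

## Synthetic data: what it emulates and what it does not

The renderer draws the dark frame, the aperture disc, and the band, with
per-channel Gaussian noise (SD 2 counts) and 8-bit quantisation. Column
intensities are sampled from the ground-truth curve at exactly the scale
positions the extractor assigns, so round-trip error isolates the
extraction chain itself. RGB is split by a piecewise-linear visible-hue map
blended toward neutral; when a channel would exceed 255 the excess is
redistributed to the others so the channel *sum* — the only quantity the
extractor uses — always encodes the target intensity. Default geometry
(radius 470 ± jitter in a 1400 × 1100 frame) reproduces the device's
700–800-column bands; aperture offsets of ±20 px and radius jitter of ±10 %
match the stated re-seating variability.

Labelled datasets use smooth Gaussian-bump class curves. The garden design
(12 crops × 2 replicates) scales within-class perturbations so the minimum
between-class distance exceeds twice the perturbation norm by a chosen
separation ratio (default 5), making the clustering recovery condition
explicit. The field design (4 crops × 24 spectra in 48 twinned pairs under
two systems) gives the two grain crops an identical mean curve — the
hypothesis that visible-range spectra separate broad crop types but not the
grain species — and gives the cropping system no spectral effect at all.
Soil datasets sample all eighteen properties uniformly within the observed
field ranges; a configurable subset (default: the nine nutrient properties
plausibly expressed in canopy reflectance) is imprinted on the spectrum as
`amplitude × (scaled value − 0.5) × smooth signature`, the rest left
uncoupled. The leaky design used for the cross-validation ablation gives
each of 24 locations a strong idiosyncratic spectral fingerprint and an
independent random property value: generalisation is impossible by
construction, so any skill under pair-splitting folds is pure twin leakage.
It uses 24 locations rather than the field campaign's 48 because the
demonstration requires the small network to memorise its training
fingerprints within the epoch budget.

None of this emulates real leaf optics: there is no radiative-transfer
model, no specular component, no illumination spectrum, no chromatic
aberration, and within-class variation is smooth and stationary. Passing
tests therefore demonstrate that the *pipeline* is correct and that the
*experimental designs* behave as intended (separable classes are separated,
indistinguishable ones are not, leakage inflates scores, uncoupled
properties are unrecoverable) — not that the instrument achieves any
particular accuracy on real crops or soils. The trial's published
field-data accuracies are fixed summary tables here, reproduced exactly
from their counts, and are not claimed to be re-derivable from synthetic
spectra.

## Numerical choices and degenerate inputs

* Round-half-up (`floor(x + 0.5)`) for column→position mapping: symmetric
  and endpoint-exact.
* Windowed operations use cumulative sums; constants are annihilated to
  ~1e−13, and tests assert closed forms at 1e−9 absolute tolerance.
* Zero margins in a confusion matrix yield NaN accuracies (flagged, not
  raised); κ raises only when expected agreement is exactly 1.
* r² returns 0 when either vector is constant (correlation undefined).
* Agglomeration ties follow the deterministic order of the underlying
  linkage implementation; repeated runs give identical trees.

## Problem sizes of the shipped experiments

Round trip: 20 photographs at 1400 × 1100. Clustering: 24 spectra.
Classification CV: 96 spectra × 10 folds × 400 epochs. Regression CV:
single-output recovery and 18-output null at 96 spectra (800 and 400
epochs), leakage ablation at 48 spectra × 800 epochs, run once grouped and
once split. The full acceptance run completes in a few minutes on one CPU.
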