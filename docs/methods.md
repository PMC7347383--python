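# Methods

## Expansion-microscopy synapse calling

### Model of the measurement

Expanded tissue is treated as isotropically scaled by a single factor
E (default 4.2, fixed by the 60 µm → 252 µm proximal-segment pair).
A two-channel confocal volume holds a cytoplasmic fill (channel 0) and a
pan-presynaptic marker (channel 1); voxels are 0.1 µm laterally and 0.6 µm
axially (post-expansion), matching 600 nm focus intervals. Because no
global post-synaptic marker exists, a synapse is operationalised from the
two available channels: a bouton apposing the labelled membrane is a
synapse when its intensity profile overlaps the cytoplasmic profile by
more than a threshold calibrated on marker-confirmed synapses.

### Pipeline steps and numerical choices

* **Punctum detection.** The presynaptic channel is lightly smoothed
  (σ = 0.05 µm), thresholded at 25 % of its maximum and labelled; each
  component is re-segmented at half its own peak (this also splits merged
  neighbours), the voxel count of the half-maximum support gives the
  equivalent-sphere diameter, and centroids are intensity-weighted.
  Diameters are stored pre-expansion (measured / E) and the bouton filter
  keeps diameters strictly greater than 0.4 µm. With mixed-brightness
  puncta the per-component half-max level is each component's own, so
  brightness variation does not bias the size estimate to first order.
* **Appositions.** A punctum is apposed when its surface-to-surface
  distance to the dendrite tube (centerline distance − tube radius −
  punctum radius) is at most 0.2 µm post-expansion. The nearest arc-length
  (pre-expansion) and the clamped membrane gap are recorded.
* **Orientation.** The axis from the membrane contact to the punctum
  centroid decides the viewing geometry: within 45° of the optical axis →
  face-on (scan along z, step 0.6 µm), otherwise side-on (scan in-plane,
  step 0.1 µm). The 45° boundary goes to face-on. When the centroid sits
  exactly on the membrane this axis is the zero vector, so the radial
  direction (centerline point → centroid), collinear with it whenever it
  is defined, is used throughout.
* **Profiles and overlap.** Both channels are sampled by linear
  interpolation over ±3 µm around the contact midpoint and normalised to
  their own window maximum ("relative fluorescence"). Overlap is the
  length of the intersection of the two channels' half-maximum supports,
  each taken as the contiguous interval around the channel's global peak
  with boundaries interpolated linearly; disjoint supports give overlap 0,
  and a multimodal channel contributes only the interval around its global
  peak (with a warning). Half-maximum support is the standard convention
  and reproduces "no overlap" for clearly separated profile pairs.
* **Calibration.** The threshold per orientation is the *minimum* overlap
  across profiles of marker-confirmed synapses — the floor of overlaps
  seen at real synapses. A confirmed synapse with zero overlap is an
  error, since it would contradict the premise of the definition. The
  published thresholds (0.23 µm side-on from 25 profiles, 0.42 µm face-on
  from 12) are available as defaults when no calibration set is supplied.
  Classification is strict (> θ), so an apposition exactly at threshold is
  not a synapse.
* **Density.** Dendrites are analysed as 60 µm (proximal) or 15 µm
  (distal) segments; density is 10 × contacts / (segments × length) with
  the contacted-only denominator by default — the convention consistent
  with the published distal value of 2.0 synapses/10 µm; an all-segments
  denominator is available by flag and is never larger. Displayed
  densities round to one decimal, and the distal:proximal ratio is formed
  from the displayed values (2.0 / 0.8 = 2.5), with the raw-value ratio
  reported alongside.

### Synthetic volumes and what recovery tests show

The generator renders a tube of the stated radius around a straight (or
optionally gently curved) centerline, places synapse puncta with centroids
*on* the membrane and decoy puncta offset outward by `decoy_gap`
(default 1 µm pre-expansion), renders puncta as isotropic Gaussians whose
FWHM equals the drawn lognormal diameter (mean 0.8 µm, sd 0.16 µm
pre-expansion), convolves with an anisotropic Gaussian PSF
(σ_xy = 0.07 µm, σ_z = 0.3 µm post-expansion — the ~70 nm effective
lateral resolution of expanded tissue taken as an order of magnitude, no
published PSF exists), and adds clipped Gaussian noise. Counts are Poisson
with the stated per-10 µm rates (an optional Neyman–Scott cluster mode
emulates clumped innervation at the same overall rate). Placement,
size and noise use separate seeded sub-streams so ground truth is stable
under noise changes.

For an on-membrane punctum the scan line crosses the tube surface exactly
at the punctum centroid, so the expected overlap is half the punctum
FWHM — a closed form the calibration tests check against. Recovery runs
(20 seeds, decoys at 1 µm, noise sd 0.02) score a truth punctum as called
when a called detection lies within the sum of the two bouton radii
(touching criterion); sensitivity and specificity both exceed 0.9, with
misses dominated by the intrinsic ~1/(n+1) floor-threshold miss rate on
the smallest boutons and by physically merged double-boutons.

What the synthetic model does *not* emulate: gelation distortion or
anisotropic expansion, multi-dendrite tangles, background immunoreactivity,
depth-dependent attenuation, or chromatic shifts. Passing recovery tests
therefore demonstrates the correctness of the geometry, profile and
threshold logic — not robustness to those real-tissue artifacts.

## LH pulse and surge analysis

### The pulse rule as a sequential algorithm

The published criterion — an increment from nadir to peak over 25 % —
names no algorithm. It is made sequential in the standard way: sweep left
to right holding the running nadir (minimum since the last confirmed
peak; the first sample can start a nadir but never be a peak), test each
local maximum, call a pulse when 100 × (peak − nadir)/nadir strictly
exceeds 25 % and the nadir is at or above the assay floor (0.02 ng/ml),
then restart the nadir search after the called peak. Local maxima are
runs of equal values strictly above both neighbours (series end: inner
neighbour only), represented by their earliest sample; treating plateau
*starts* of a still-rising ramp as maxima is thereby avoided. An
exhaustive test proves the sweep identical to an explicit search over all
(nadir, subsequent-local-maximum) pairs with non-overlapping reset for
every series up to length 12 over small value grids. The criterion is
scale-invariant by construction and additive shifts can only shrink
increments; both are property-tested.

Amplitude is peak − nadir (not absolute peak), the quantity the published
~3 ng/ml figure refers to; frequency is pulses per hour over the sampled
duration; zero calls report a missing (not zero) mean amplitude.

### The secretion simulator

Events follow a Gamma renewal process (shape 8, mean interval 15 min —
near-regular pulsing) with lognormal bolus amplitudes (mean 3 ng/ml,
CV 0.2). Between events the level above the 0.5 ng/ml baseline decays
exponentially with a 10 min clearance half-life; the series is sampled
every 3 min for 120 min with multiplicative lognormal noise and a
0.02 ng/ml assay floor (a generic ELISA detectability floor — no assay
LOD is published). None of the clearance parameters is a claim about
mouse physiology; they shape realistic-looking traces.

Amplitude semantics are chosen for commensurability with the analyzer:
within the sampling interval containing an event the sampled level rises
by exactly the bolus amplitude (secretion dominates clearance during the
brief event), so the nadir-to-peak rise the caller measures *is* the
generator's amplitude, and — like the published figure itself, which is a
peak-minus-nadir measurement — recovery is unbiased. The alternative
(instantaneous bolus decaying from the event time, with the ~2 ng/ml
nadir residual decaying over the nadir→peak sampling gap) makes the
measured amplitude systematically ~15–20 % low at these parameters and
would leave "amplitude" meaning a quantity nothing in the design
measures. Round-trip tests (20 seeds, low noise) recover the mean
inter-pulse interval and mean amplitude within 10 %, and pulse
sensitivity against true event times exceeds 0.9 at 5 % noise.

### Surge model and classifier

The surge generator produces a logistic rise of amplitude 6 ng/ml above
baseline with half-rise at onset + 2τ (onset 17.5 h, τ = 0.75 h), so the
16:00 baseline sample is still near baseline and the first clearly
elevated sample is 19:00; a suppressed mode returns baseline at all four
samples. The classifier — surge iff the maximum post-baseline sample
exceeds both 2× baseline and 1 ng/ml — is explicitly a package
convention (no numeric criterion is published); the raw fold rise is
always reported so users can re-threshold.

## Statistics

Mann-Whitney U uses exact enumeration when both groups have ≤ 8 values
and no ties (at most 12 870 splits), otherwise the tie-corrected normal
approximation; the exact path is verified against a full permutation
enumeration written independently in the tests. Holm-Sidak adjustment
implements the step-down formula directly (allowing a family size larger
than the number of supplied p-values) and is cross-checked against
statsmodels. Repeated-measures ANOVA is deliberately out of scope — it
is an off-the-shelf procedure available in any statistics package.

## Problem sizes

Default test and acceptance runs use 15 µm dendron segments (volumes of
roughly 700 × 230 × 40 voxels), 20-seed recovery experiments, and 20
simulated animals per pulse round trip; these sizes give sampling errors
comfortably inside the stated tolerances while keeping the full suite
fast.

## Known limitations

* The expansion factor is a single isotropic scalar; the printed
  0.23/0.95 µm pair implies E ≈ 4.13 rather than 4.2 and is treated as a
  rounded value.
* The per-component half-max detector under-segments boutons whose
  half-max supports genuinely merge; such double-boutons are counted once.
* Published density SEMs (±0.3, ±0.2) are not reproducible because the
  averaging unit (animal, dendrite or pooled) is not derivable from the
  printed counts; only the pooled arithmetic is implemented.
* The suppressed-pulse state is emulated simply by lowering bolus
  amplitude and rate; no mechanism of suppression is modelled.
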