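# Methods

`smstoich` analyses two-colour single-molecule TIRF experiments in which
surface-captured, Cy5-labelled RNA molecules (red channel) are probed for
binding by an mEGFP-tagged protein (green channel).  The number of
protein molecules bound to each RNA is read out by counting irreversible
photobleaching steps in the green intensity trace of every colocalized
spot, and corrected for partial labeling and protein dimerization.  This
note records the models, the defaults and the reasoning behind the open
design choices.

## Acquisition model

A field is 50 red frames followed by 250 green frames, 50 ms each, so the
green record spans 12.5 s.  Both fluorophores bleach completely within
their irradiation windows; recording is continuous.  Histograms pool
three experiments of ~50 fields (configurable; the test suite uses far
fewer fields at higher per-field occupancy to keep runtimes short — the
statistics, not the geometry, are what matter downstream).

## Labeling / dimerization model

Each of the `k` binding events on an RNA is independently a monomer
(probability `1 − d`) or a dimer (`d`); every protomer carries a
fluorescent tag independently with probability `p_label`.  The labelled
count per event is therefore distributed

    q0 = (1−d)(1−p) + d(1−p)²,  q1 = (1−d)p + 2dp(1−p),  q2 = dp²

and the observed step count for `k` events is the k-fold convolution of
`(q0, q1, q2)`, conditioned on at least one label (zero-label complexes
are invisible).  The dimer fraction is not observed directly: protein-only
control spots (single binding event) that bleach in two steps occur with
conditional probability

    f2 = d·p / (1 + d(1−p)),

which inverts in closed form, `d = f2 / (p − f2(1−p))`.  At the reference
control values `p = 0.58`, `f2 = 0.12` this gives `d ≈ 0.2266`, and the
conditional step distribution for `k = 2` becomes
(0.470, 0.425, 0.098, 0.007) for 1–4 steps — a two-step/one-step ratio of
≈ 90%.  `f2` is attainable only up to `p/(2−p)`; larger inputs raise an
error rather than clip.  mEGFP misfolding is fixed at 0 (exposed as a
parameter via `p_label`, which absorbs any non-fluorescent fraction).

The mixture model (`StoichiometryMixtureModel`) fits simplex weights over
candidate `k` values (optionally plus a truncated-geometric background
component over classes 2–5) to the observed class counts by multinomial
maximum likelihood (Nelder–Mead on softmax/logit parameters, multiple
starts).  Two weight vectors are reported: `observed_weights` over
visible complexes, and `population_weights`, which rescales each
stoichiometry component by 1/P(visible | k) to estimate weights over all
complexes.  The fit assumes classification losses ("x" spots, crowding
exclusions) are independent of `k`; residual dependence — brighter spots
blink more often in total — is the main known bias and is kept small by
the classification choices below.

## Synthetic data

The generator emulates the acquisition: uniformly placed complexes, one
Cy5 per RNA, green fluorophores drawn through the labeling model,
pixel-sampled symmetric Gaussian PSF (σ = 1.2 px), Gaussian read noise
plus an optional signal-proportional (shot) variance term, and a small
affine chromatic offset between channels.  Photophysics is simulated per
fluorophore in discrete frames: an irreversible bleach clock (exponential,
default lifetime one third of the channel's irradiation window, so > 95%
bleach on record) runs only while the fluorophore emits; a reversible
dark state is entered at 0.08 s⁻¹ (≈ one excursion per trace) with
exponential dwell of mean 1.5 s.  Discretization to 50 ms frames biases
the realized mean dwell by ~dt/2 (< 2%).

Not emulated: stage drift, uneven illumination, astigmatism, multi-state
photophysics, camera gain register details.  Passing tests therefore
demonstrate correctness of the analysis chain under idealized optics, not
robustness to instrument drift.

## Spot detection

Candidate peaks must exceed the field mean by `threshold_k` (default 4)
field SDs; candidates are rejected if their scan square (7 px) holds a
second peak above half the peak height, and must fit 1-D Gaussians in
both axes with R² ≥ 0.7 and a plausible width.  Thresholding, peak
finding and the single-peak test run on a lightly smoothed working image
(Gaussian, σ = 1 px, configurable off): without it, single-pixel noise
excursions above half-height masquerade as second peaks and reject a
large fraction of genuine spots at moderate SNR.  Profile fits also use
the working image — the smoothing is then removed from the fitted widths
in quadrature and from the amplitude analytically — because 7-point raw
profiles at SNR 5 yield width estimates too unstable to gate on.
Localization is exact on noiseless Gaussians (sub-0.05 px bias) since
smoothing preserves the centre.  Coordinates are 0-based, pixel-centre.
Traces are extracted as aperture sums (radius 3 px) minus aperture-area ×
median of a 5–7 px annulus; spots whose annulus leaves the image are
excluded with an explicit error, never silently truncated.

## Step counting

Traces are modelled as piecewise-constant with Gaussian noise.  The
marginal likelihood of a constant segment integrates mean and variance
out under a conjugate normal–inverse-gamma prior whose hyperparameters
come from robust whole-trace statistics (prior mean = median, prior scale
= noise variance from median absolute successive differences, weak
strengths κ₀ = 10⁻³, a₀ = 1).  This makes scores comparable across
segmentations and the result invariant under trace rescaling.

Recursive binary segmentation accepts a changepoint when the evidence for
"one changepoint somewhere in this segment" — the split likelihood
averaged over a uniform prior on position, so scanning many positions
earns no multiplicity advantage — beats the unsplit marginal times the
prior odds (default 1).  Accepted positions are then jointly refined
(coordinate-wise and pairwise exact search) and re-tested in their final
context, pruning weakest-first.  The pairwise refinement matters: two
changepoints bracketing one true step are a local optimum that
single-coordinate moves cannot escape when `min_segment` (default 3
frames) blocks the true position.

On 64-frame traces the recursion agrees with an exhaustive
dynamic-programming search under the same score on ≥ 98% of random
noisy traces; the remainder are zero-evidence-margin configurations where
the local and global position priors legitimately rank two models
oppositely.  The benchmark for exact-count recovery (≥ 95% for k = 1–5 at
step-height/noise = 3) places steps with a minimum separation of 10
frames: with exponential bleach lifetimes, coincident bleaching within a
few frames is common for high k and is an "x"/undetermined outcome of the
assay, not a property of the detector this benchmark measures.

## Classification

Before counting, reversible dark-state dips — a segment below both
neighbours that returns to the prior level within 2 noise SDs — are
merged when shorter than the blink window.  The window defaults to 4 s
(80 frames): with an exponential 1.5 s dwell, a 2 s window would leave a
quarter of excursions unmerged, and those either inflate the count by one
or land in "x" at a rate growing with the true fluorophore number, which
skews the mixture fit.  A spot is classified "x" (undetermined) when an
upward step reaches the scale of the median downward step (within 2
noise SDs — such a step is an unresolved dark excursion, not bleaching),
when the final level sits more than 3 noise SDs above background
(incomplete bleaching), or when no downward step survives merging.
Tolerances are floored at 10⁻³ of the largest level change so noiseless
traces are not judged at machine precision.  Otherwise the downward-step
count maps to classes 1–5 or ">5".

## Registration, colocalization, coincidence

The chromatic map is affine, fitted by least squares to fiducial pairs
(≥ 3 non-collinear; translation-only fallback below that, flagged).
Pairing is greedy shortest-distance-first within a 2 px radius, each spot
used once, ties broken by index; at the occupancies of interest this is
indistinguishable from optimal assignment.  Chance colocalization is
estimated analytically as `1 − exp(−ρ_green·π·r²)` per image (an
empirical torus-translation mode cross-checks it) and is reported but not
subtracted from colocalized fractions; subtraction exists as an
off-by-default option.  Colocalized fractions are summarized as mean ±
SEM over experiments; histogram counts are pooled by summation, with
binomial error bars `100·√(N·p·(1−p))/N` per class.

In the pipeline, paired spots with another detected green spot within
9 px (aperture radius plus rendered PSF reach) are excluded from step
counting and counted separately: inside that radius aperture photometry
mixes neighbouring traces and any step count would be unreliable.

## Problem sizes

The test suite runs the full chain on eight 512×512 fields of 250
complexes (2,000 total) at SNR 5, recovering a 60/40 mixture of one- and
two-molecule complexes within ±0.05; the step-counter benchmark uses
1,000 traces per true count; detection benchmarks use three 512×512
fields of 160 spots.  These sizes were chosen to hold Monte-Carlo error
comfortably below the tolerances being asserted.

## Known limitations

- Classification losses are assumed stoichiometry-independent by the
  mixture fit; the residual dependence biases recovered weights by ~0.02
  at the benchmark conditions.
- The greedy changepoint search is not a global optimizer; disagreements
  with exhaustive search (~1% of marginal traces) flip between adjacent
  model orders of nearly equal evidence.
- Close pairs of emitters (closer than about half the scan square) are
  rejected by design, so the analysed population excludes crowded
  regions; density should be kept low enough that this exclusion is
  small.
- Three-colour experiments are not supported.
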