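# Methods

`vocamap` quantifies differences between the vocal repertoires of two groups
of mice (e.g. two genotypes) from the frequency contours of their ultrasonic
vocalizations (USVs).  This note describes the models and procedures, the
parameters that matter, the synthetic-data generator used to test and
calibrate the pipeline, and the numerical choices behind each stage.

## Data model

A syllable is a uniformly sampled frequency contour: samples in kHz at a
fixed hop (default 1 ms), with metadata naming the emitting individual and
its group.  Duration is `(n − 1) · hop` (fence-post convention).  Syllables
whose source audio reached the recorder's amplitude limit are flagged
`clipped` and excluded from every analysis.  Within a collection all
contours share one hop; mixed-hop inputs must be resampled (linear
interpolation) first.

## Contour extraction (optional audio front-end)

Overlapping frames (default 0.5 ms, 50 % overlap) are tapered with discrete
prolate spheroidal sequences (NW = 3, 5 tapers) and Thomson's harmonic
F-test is evaluated at each time–frequency bin; bins with
F > F₍crit₎(2, 2K−2) at p < 0.01 inside the 35–115 kHz band are kept, with
the threshold applied per bin (no multiplicity correction).  Per frame the
highest-F significant bin gives the contour sample; unvoiced gaps up to
`max_gap` (10 ms) are bridged by interpolation, longer gaps split syllables,
and syllables shorter than `min_duration` (5 ms) are dropped.  This is a
deliberately simple single-contour tracer: no harmonic merging, no manual
correction.  Frequency resolution is set by the FFT length (512 points at
250 kHz ≈ 0.5 kHz bins); the round-trip tests bound the resulting median
frequency error at < 2 kHz.

## Repertoire distances

Contours are mean-frequency subtracted, so that distance reflects contour
shape rather than register, and every pair is compared by dynamic time
warping with squared-difference local cost and the symmetric unit-weight
step pattern (match/insert/delete), no window constraint.  The
dissimilarity is the accumulated cost of the optimal boundary-to-boundary
path divided by the path length (a mean squared error, kHz²), which keeps
scores comparable across durations without length-normalizing the contours
themselves — duration differences are absorbed by warping and analyzed
separately.  Among equal-cost paths the shortest is used, making the value a
well-defined function of the pair; the dynamic program carries (cost,
length) lexicographically and is verified exactly against a brute-force
enumeration of all warping paths on short inputs.  The all-pairs stage
performs n(n−1)/2 alignments (numba-accelerated; a pure-numpy fallback
exists) and stores the condensed matrix as float32 with a JSON sidecar
recording the syllable order.

## Embedding

The distance matrix is embedded in 2-D with t-SNE (scikit-learn,
`metric="precomputed"`).  The neighborhood size is parameterized as the
transition entropy H in bits — the Shannon entropy of each point's
transition distribution — with perplexity = 2^H; the default H = 5
corresponds to perplexity 32.  For tiny collections the perplexity is capped
at (n−1)/3.  Initialization is a deterministic classical-MDS projection of
the distances (seeded Gaussian fallback when the Gram matrix is degenerate),
so a given seed reproduces the map exactly.  scikit-learn's optimizer does
not expose a relative-KL stopping tolerance; the requested tolerance is
recorded in the map's parameters for provenance and the library's own
convergence controls (default 1000 iterations, early exaggeration 12) are
used.  Map axes are arbitrary — any rigid rotation or reflection is an
equivalent solution — and every downstream statistic (densities, entropy,
significance masks, step labels) is invariant to such transforms up to grid
discretization.

## Density maps and the significance map

Each group's embedded points are smoothed into a probability density on a
regular grid (default 100×100 covering the map plus a 3σ margin) with an
isotropic Gaussian of width σ = 4 map units (σ, not FWHM; the smoothing
scale should resolve the island structure of the map at hand — 4 units
suits maps spanning roughly ±40 units, and the tests use proportionally
smaller σ on smaller maps).  The point-estimate density sums exact Gaussian
kernels; bootstrap replicates use the equivalent histogram-plus-convolution
route for speed (identical up to cell-width binning error, verified < 5 %
relative at high-density cells).  Densities are renormalized to integrate to
1 on the grid.

Sampling variability is estimated by resampling each group's points with
replacement `n_boot` times (default 1000; 500 in the reduced-scale
calibration runs; 10,000 reproduces the original study's setting) and
smoothing each resample.  At every grid cell the n_boot density values are
summarized by a univariate Gaussian mixture with 1–3 components chosen by
minimizing AIC; a zero-variance cell becomes a point mass.  The EM fits are
deterministic (quantile initialization), variance-floored, capped at 25
iterations with a 10⁻⁵ relative log-likelihood stop — model selection is
insensitive to tighter settings but runtime is not.

The per-cell statistic is P_HT(x, y) = Prob(ρ_HT > ρ_WT) under independence
of the two fitted cell models.  Because both models are Gaussian mixtures,
this probability has an exact closed form, a weighted sum of Φ terms with
ties between point masses counted ½; the closed form is the default route,
and a 2048-point trapezoidal integrator over the joint quantile span is
provided as a cross-check (the two agree to < 10⁻⁴ in tests).  Cells are
flagged where P_HT < α′ or P_HT > 1 − α′ with the Šidák level
α′ = 1 − (1 − α)^(1/m), α = 0.05.  The effective comparison count m = 2^H
uses the entropy (bits) of the pooled density ρ = ½(ρ_HT + ρ_WT),
discretized as cell probabilities p_i = ρ_i · cell area:
H = −Σ p_i log₂ p_i.  This discrete entropy depends on the grid resolution,
so the resolution is fixed (100×100) and recorded with the outputs; m is
used unrounded.

Calibration: when the two "groups" are random halves of one repertoire, the
mean fraction of flagged cells stays below α and is typically ≈ 0 (checked
over 20 seeded label-shuffle replicates of one embedded collection — the
same null as regenerating both groups from one distribution, at a fraction
of the cost).

## Step classification and the contingency test

Step (jump/punctuated) syllables contain an abrupt frequency discontinuity:
any adjacent-sample change ≥ 10 kHz at the 1 ms hop.  The 10 kHz default
cleanly separates sweep slopes (≲ 2 kHz per 1 ms sample) from genuine
jumps; when contours are judged at a finer hop the change should be
measured across an equivalent ~1 ms span.  Group comparison is blind to
genotype: the pooled map density is watershed-segmented from its local
maxima (cells jointly holding the lowest 1 % of mass are background;
vocalizations landing there are assigned to the nearest region), each
region is classified step/non-step by the majority step status of its
member contours, and every vocalization inherits its region's class.  The
per-group step/non-step counts form a 2×2 table tested with Pearson's
chi-squared.  The Yates continuity correction is the default because it is
the variant that reproduces the reference statistic (400.42 for the counts
3257/4718 vs 2073/4295; the uncorrected closed form gives 401.29); the
uncorrected statistic is available by flag.

## Simple acoustic statistics

Duration, bandwidth (max − min contour frequency) and mean frequency
(unweighted mean of contour samples — contours carry no amplitude) are
computed per syllable, averaged within each individual, and compared across
groups by one-way ANOVA on the individual means: with 5 + 6 individuals the
test has df = (1, 9) no matter how many calls were recorded.  The three
measures are tested separately without multiplicity correction.

## Synthetic repertoires

The generator emulates pup isolation-call repertoires: four non-step
template families (flat ~70 kHz; linear up/down sweeps of ±25 kHz; a
parabolic chevron of +18 kHz) with durations of 20–120 ms, plus step
syllables built as two plateaus separated by a single discontinuity drawn
from 12–40 kHz.  Frequencies stay inside 35–115 kHz.  Group structure
enters only through the per-group step probability (defaults 0.69 vs 0.48,
the step prevalences of the reference wild-type vs heterozygous data);
individuals add a clipped Gaussian base-frequency offset (SD 3 kHz) and
every sample carries clipped jitter (SD 0.5 kHz, bounded at ±3 kHz).  The
bounds make the families separable by construction: non-step contours can
never reach the 10 kHz detection threshold and step contours always exceed
it.  Seeding is hierarchical — one global seed spawns an independent stream
per individual — so adding individuals never perturbs existing ones.  The
template frequencies and durations are literature-typical choices, not
estimates from the reference recordings (which report no per-family
parameters).

What the generator does *not* emulate: amplitude structure, harmonics and
noise in real recordings, within-bout temporal dependence between calls,
multi-step syllables, and the continuous morphological gradation between
call types.  Passing tests therefore demonstrate that the pipeline recovers
known repertoire composition differences of realistic magnitude under
realistic variability — not that it reproduces any specific colony's map,
which depends on the recordings themselves.  The audio synthesizer renders
contours as analytic FM tones (silence-padded, Nyquist-checked) for
round-trip testing of the extraction front-end; it makes no attempt at
vocal-tract realism.

## Problem sizes used in the tests

The bundled checks run at desk scale, chosen to exercise every stage at
full grid resolution: effect recovery uses 20 seeded repertoires of 500
calls per group (5 individuals each) with 500 bootstrap replicates on the
100×100 grid; null calibration uses 20 label-shuffled splits of one 600-call
repertoire; the extraction round trip uses 50 synthesized syllables.  A
full-scale run (≈ 9000 calls, 10,000 bootstrap replicates) uses the same
code paths via the `--nboot` and collection-size parameters.

## Known limitations

* The DTW step pattern, windowing and normalization, the exact t-SNE
  implementation, the smoothing width's units, and the chi-squared variant
  are not uniquely determined by the original study's description; the
  choices above are documented defaults (the chi-squared variant is pinned
  by reproducing the published statistic), and no bit-compatibility with
  the original Ax/MATLAB tooling is claimed.
* The discrete map entropy H — and hence the Šidák comparison count
  m = 2^H — scales with grid resolution; results quote the grid alongside H.
* Watershed segmentation can over-segment a noisy density; this is benign
  for step classification (regions vote independently) but region counts
  should not be interpreted as call-type counts.
* At a few hundred calls per group the per-cell significance map is
  conservative: real composition differences concentrated in low-density
  map territory may fail the Šidák-corrected per-cell test even when the
  2×2 step test detects them decisively.
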