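# Methods

This note documents the models implemented in `smlife`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that matter for reproducibility.

## Single-molecule lifetime pipeline

### Detection, linking, consensus positions

Spots are local maxima of a scale-normalized Laplacian-of-Gaussian
response at blob radius 1.5 px (`sigma = radius/sqrt(2)`), refined to
subpixel precision by a 3×3 intensity centroid, with duplicates within one
radius suppressed. The response threshold is a required configuration
value: it depends on camera gain and illumination and must be chosen per
dataset. Detections are linked frame-to-frame by greedy nearest-neighbour
assignment (candidate pairs taken in ascending distance, ties by lower
track id) with a 3-px linking distance and gap closing across up to 10
missing frames. Track mean positions within 3 px are combined by
single-pass single-linkage into consensus spots at the track-length
weighted mean position; processing order is fixed by sorting on (row, col)
so the partition is deterministic. Merging does not iterate after new
averages are computed. Consensus spots whose rounded position is not on a
nonzero mask label are discarded. Coordinates are 0-based (row, col) with
pixel centers on integers.

No motion-model tracking is attempted: downstream analysis needs only a
stable position per binding site, because bound subunits are quasi-static
relative to the PSF over their dwell.

### Traces

Per frame, the trace value is the mean of the 5×5 window centred on the
rounded consensus position minus the mean of the surrounding 2-px-thick
square annulus (9×9 minus 5×5, corners included). The subtraction removes
any constant offset exactly and linear background ramps by symmetry.
Windows at image borders use only in-bounds pixels; traces whose full 9×9
footprint never fits are flagged and excluded. Traces whose maximum never
exceeds 500 counts (strict inequality) are dropped as containing no
single-molecule signal.

### HMM segmentation and model selection

Each trace is fit with Gaussian-emission hidden Markov models of 1–4
states by expectation–maximization (scaled forward–backward, numba-
accelerated). Model order is selected by the BIC-penalized likelihood,
`evidence = logL − ½·p·ln(T)` with `p = K² + 2K − 1`; only traces whose
best model has two states enter the dwell analysis (one state = no event;
three or more = overlapping molecules). EM runs from a deterministic
initialization with means at the min-to-max quantiles of the trace — so
rare extreme levels always receive a component — plus four seeded restarts
with means drawn from random data points; the best likelihood wins.
Variances are floored at (10⁻³ counts)²; fits where a state loses all
responsibility or two means collapse are flagged. States are decoded by
posterior mode (per-frame most probable state), and relabeling cannot
change the result because events are defined on the higher-mean state
after sorting.

### Event extraction and filters

From each accepted two-state fit, maximal runs of the fluorescent state
become dwell events with `duration = frames × Δt`. The filter rules:

* traces whose state means differ by < 60 counts are discarded entirely;
* events touching the first or last frame are censored and dropped;
* dwell times < 2 s are dropped (strict: a 2.0-s / 4-frame event is kept);
* traces with more than two events lose all their events. The count
  compared against the limit is the number of *uncensored* events before
  the duration cut — one of several defensible readings, fixed here for
  reproducibility.

### Lifetime estimation

Accepted dwells are modeled as draws from an exponential left-truncated
at the 2-s cutoff. By memorylessness the excess over the cutoff is again
exponential with the same mean, so the MLE is the closed form
`τ̂ = mean(dwells) − truncation`; ignoring truncation would bias τ̂ upward
by exactly the cutoff. The 95% CI is a nonparametric percentile bootstrap
over events (default 10,000 resamples, seeded). MLE on durations was
chosen over least squares on a histogram; the histogram plus fitted
density are still produced for plotting. Right-censoring is not modeled
because censored events are discarded; this leaves a mild downward bias
when τ approaches the trace length. Two small, unavoidable selection
effects at desk scale remain: durations are whole frames (discretization),
and longer dwells are more likely to overlap the end of the movie and be
discarded as censored (length-biased censoring). Monte Carlo of the
sampling model puts the combined expectation of τ̂ at 2.72 / 4.66 / 7.47 s
for true τ = 3 / 5 / 8 s with 240-s movies at Δt = 0.5 s — a 7–10%
downward offset, well inside the pipeline's 20% recovery tolerance and
common to all conditions, so rank order across conditions is preserved.

The photobleaching control compares lifetimes at two frame intervals with
equal exposure. Bleaching is per exposure, so at constant exposure the
bleach-limited lifetime scales with the frame interval while the true
dwell does not; a shorter apparent τ at the faster frame rate therefore
flags a bleach-limited measurement. The report carries both estimates, a
bootstrap CI and two-sided p-value for the difference, and a
`bleach_limited` flag raised when τ_fast < τ_slow beyond the difference CI.

## Z-ring morphometry

Cell lengths are the pixel extent of each mask label projected on its
principal axis (plus one pixel), converted by the pixel size; labels
touching the image border are excluded from all statistics because their
length cannot be measured. Midlines may be supplied; otherwise the
principal-axis polyline of the label is used, which is adequate for rod
shaped cells (curved-cell meshing is out of scope). Profiles average the
image along ±4 px of the local normal at 1-px arclength steps, restricted
to the cell's own label (bilinear image interpolation, nearest-neighbour
mask lookup).

Profiles are smoothed with a centered moving average (default window
0.3 µm; the smoothing method is a package choice) and rings are called by
prominence-based peak detection; the prominence threshold is a
configuration value. Per-ring FWHM is the width at half prominence by
linear interpolation, **corrected for the known smoothing-kernel
broadening**: a width-w boxcar adds variance `(w²−1)·step²/12`, which is
subtracted in quadrature under a near-Gaussian peak approximation. Without
this correction the default smoothing inflates a 0.471-µm FWHM ridge to
~0.51 µm. Peaks closer than one FWHM are merged keeping the higher.

The condition-level width aligns a 1-µm window on every ring, averages the
windows, and reports the FWHM of the averaged peak above the window
baseline (rings whose window leaves their profile are skipped and
counted). Ring frequency is total rings over total measured cell length
(ring-less cells count in the denominator); a per-cell count table and a
ring-position histogram along the normalized cell axis are also returned,
the latter as the auxiliary reading of "frequency along the cell".

## Hill dose-response

The 4-parameter Hill equation is fit by bounded least squares on the
linear dose scale from a multi-start grid: K log-spaced over the positive
dose range crossed with n ∈ {0.5, 1, 2, 4} — robust across dose ranges
spanning orders of magnitude. The 95% CI on n is a parametric bootstrap:
residuals are resampled onto the fitted curve and the model refit from
the point estimate (default 2,000 resamples, seeded). A fit is flagged
"could not saturate" when the fitted K exceeds the largest tested dose,
in which case max and n are unreliable. Derived metrics: dynamic range =
fitted max / fitted leak (infinite and flagged when leak is 0), leakiness
= fitted leak as % of a reference promoter's maximum, fold induction =
ratio of extreme observed responses. Defining dynamic range as max/leak is
the only choice arithmetically consistent with reporting it alongside
leakiness; it is a package convention. Responses are fit as provided — no
per-plate normalization is attempted. The 2-D grid summary fits the
translational (nsAA) axis at each transcriptional (IPTG) level and reports
the overall fold induction between the extreme grid cells.

## Synthetic data generator

The generator emulates the study conditions the pipeline targets:

* **Acquisition**: 480 frames at 0.5 s/frame or 240 frames at 1 s/frame
  (4 min total either way), exposure equal to the frame interval,
  0.1 µm/px (not stated by any instrument table; a typical 100× value —
  every physical output scales through it), PSF sigma 1.3 px.
* **Dwell model**: exponential with mean τ, or the deterministic
  treadmilling dwell L/v. No filament kinetics (nucleation, hydrolysis)
  are simulated; the dwell model abstracts the lifetime ≈ length/velocity
  relation, and an inhibitor dose enters only as the user's choice of τ.
* **Photophysics**: spot PSF peak 2500 counts on a 100-count background
  with 20-count read noise and Poisson shot noise — synthetic conventions
  (not measurements) chosen so the 500-count trace filter and 60-count
  separation rule operate in a realistic regime; after 5×5 window
  averaging the trace amplitude is ~1000 counts. Bound molecules flicker
  frame-to-frame with a mean-one lognormal factor (CV 0.15), emulating
  apparent-brightness fluctuations of real fluorophores; without it,
  noiseless edge frames (partial temporal overlap) form a genuine third
  intensity level and the order-selection step rejects clean traces.
  Photobleaching is Bernoulli per exposure — per exposure, not per unit
  time, precisely so the frame-interval control has something to detect.
* **Geometry**: cells are axis-aligned spherocylinder rods (4 × 0.9 µm by
  default) packed on a jittered grid; midlines are therefore analytic.
  Binding sites keep ≥ 12 px separation — sparse labeling as in real
  single-molecule imaging, and necessary because sites closer than the
  9×9 annulus contaminate each other's background estimate while sites
  within 3 px merge into one consensus spot. Bind times are uniform over
  the movie; edge events are censored and filtered exactly as in real
  data.
* **Rings**: additive Gaussian ridges transverse to the cell axis
  (sigma in µm recorded in the manifest together with the implied FWHM
  `2·sqrt(2 ln 2)·sigma`), on a uniform cytoplasmic signal.
* **Titration**: Hill-equation means with mean-corrected multiplicative
  lognormal noise of a given CV, so the expected response equals the
  model value at every dose including zero.

Everything rendered is recorded in a JSON-serializable manifest (per
molecule: position, bind/unbind/bleach times; per cell: label, length,
ring positions), and every generator call is a pure function of its
parameters and seed; zero-noise renders are bit-for-bit reproducible.

What the generator does **not** emulate: cell curvature and segmentation
errors, focus drift, non-uniform illumination beyond linear ramps, EM-gain
excess noise, fluorophore blinking with resolvable dark states, molecule
mobility while bound, and overlapping binding events at one site closer
than the separation limit. Passing tests therefore certify the analysis
logic — filters, estimators, calibration — on data that match the model
assumptions, not robustness to every real-data pathology.

## Problem sizes and numerical conventions

Full-pipeline recovery is exercised with ~500-molecule movies (168 cells ×
3 molecules, 512×720 px, 480 frames) at τ = 3, 5 and 8 s, recovering each
within 20% and in rank order; the acceptance script uses 252-molecule
movies per τ for the same check. Bootstrap sizes: 10,000 (lifetime CI),
2,000 (Hill CI) by default, reduced in tests where only calibration is
probed. A single global seed fans out to per-trace HMM restarts and all
bootstraps through `numpy.random.SeedSequence`, making every end-to-end
run byte-identical under a fixed (input, config, seed) triple. All
tunables live in `PipelineConfig`, whose defaults are the analysis recipe
(1.5-px detection radius, 3-px link distance, 10-frame gap, 5×5/2-px
windows, 500-count trace filter, 60-count separation, 2-s minimum dwell,
2-event limit, 2-s truncation); `PipelineConfig.paper_defaults()` is an
alias making that explicit.

## Known limitations

* The trace-level HMM assumes Gaussian emissions with per-state variance;
  strongly non-Gaussian noise (EM gain at low photon counts) may shift
  the 60-count separation rule's effective stringency.
* Frame discretization biases τ̂ downward by a few percent at Δt = 0.5 s
  (see above); treating durations as interval-censored would remove this
  but is not what the dwell-measurement convention specifies.
* The Hill CI resamples response/fit ratios (titration noise is
  proportional to signal; additive residual resampling undercovered to
  79–88% in calibration runs). Measured coverage at the calibration
  design (below; 8 doses × 3 replicates, 10% CV) pools to ~96% over
  n ∈ {1, 2, 3}, ranging ~93–99% per n.
* Hill-coefficient recovery depends on dose placement: with half-log
  spacing across two orders of magnitude, data at n = 3 are nearly
  indistinguishable from a step function and n̂ occasionally diverges to
  its bound. The recovery/calibration experiments therefore use a
  cooperativity-informative design — doses concentrated within a few-fold
  of K plus zero and saturation anchors (0, 0.2, 0.4, 0.7, 1, 1.5, 2.5,
  10 for K = 1) — standard optimal-design practice when the Hill
  coefficient is the quantity of interest. Wide titration ranges remain
  the right choice for measuring dynamic range and leakiness, and the
  fitting code flags, rather than hides, unsaturated or weakly identified
  fits via the saturation flag and wide CIs.
* Ring FWHM de-broadening assumes near-Gaussian peaks; heavily aberrant
  (plateau-like) rings are reported at their smoothed width.
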