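# Methods

`gridphase` implements a single-run analysis of theta phase precession in
grid cells recorded in one- and two-dimensional environments, together with
a ground-truth synthetic-data generator and three oscillatory-interference
models against which the analysis can be compared.  This note documents the
models, procedures, parameter choices and known limitations.

## The analysis model

A grid cell's spikes within one traversal ("run") of one firing field are
modelled as a circular response to a linear covariate:

    phi_k = 2*pi*a*x_k + phi_0   (mod 2*pi),

where `phi_k` is the theta phase of spike k, `x_k` the distance traveled
along the animal's path since field entry (or time since entry, for the
time-resolved variant), `m = 360*a` the phase-precession slope in deg/cm
(negative = precession) and `phi_0` the phase offset at entry.  The slope is
estimated by maximizing the mean resultant length of the phase residuals,

    R(a) = | n^-1 sum_k exp(i*(phi_k - 2*pi*a*x_k)) |,

over a bounded slope range (default [-60, 60] deg/cm; phase-time fits use
[-1500, 1500] deg/s).  `R(a)` is multimodal, so the optimizer evaluates a
dense grid (0.1 deg/cm; 2.5 deg/s for time) and refines the best grid point
by bounded scalar minimization.  Exact ties are broken toward the smaller
`|m|`: with few spikes the resultant surface can have symmetric maxima, and
the steeper of two equally good helices is the less parsimonious reading.

Association strength is the circular-circular correlation `r` between the
observed phases and `theta_k = 2*pi*|a|*x_k (mod 2*pi)`, computed from the
sine moments about the circular sample means; `r` is negative for
precession by construction.  Its significance uses the large-sample normal
statistic `z = r * sqrt(n * lam20 * lam02 / lam22)` with
`lam_ij = n^-1 sum sin^i(phi-phi_bar) sin^j(theta-theta_bar)` and
`p = erfc(|z|/sqrt(2))`.

Two calibration caveats are verified by the test suite:

- The analytic `p` is well calibrated (empirical type-I error 0.047-0.055 at
  nominal 0.05 for n = 10/30/100) **for a given slope mapping**.  Computing
  `r` at the resultant-maximizing slope and then testing it is a two-stage
  selection procedure and is anti-conservative (about 0.20 at n = 10).  The
  per-run `p` values reported by the pipeline are therefore descriptive, as
  in the method they implement; calibration checks fix the slope.
- The analytic `p` agrees with a 10 000-draw permutation oracle within a
  factor of two at n = 10 and 30.

### Time bounds and theta aliasing

Spikes recur roughly once per theta cycle, so phase-versus-time data are
nearly periodic samples: slopes separated by about `360 * f_theta` deg/s
(~2900 deg/s at 8 Hz) are close to indistinguishable.  The time-fit bounds
default to +-1500 deg/s — below half the aliasing distance and above any
plausible `speed x distance-slope` product — which removes the alias branch
that otherwise captures a large fraction of noisy fits.

## Rate maps, fields, gridness

Rate maps use 1 cm bins.  Spike-count and occupancy histograms are smoothed
*separately* with the same Gaussian kernel (sigma 5 cm) and then divided;
reflecting boundary conditions conserve spike mass (verified to 1%), and
unvisited bins are missing (NaN), never zero.  The alternative
(smooth-after-division) is available behind a flag.

Field segmentation is two-stage: 8-connected components above 20% of the
map peak seed candidate fields; each candidate is grown by geodesic
dilation restricted to bins above 20% of its own peak, iterated to
stability.  Bins reachable from more than one seed are assigned to the
nearest seed (Euclidean distance transform) — the growth step is otherwise
ambiguous when neighbouring fields merge.  Fields with area < 200 cm^2 or
boundary-edge circumference > 160 cm are excluded.  The circumference is
the count of 4-connected boundary edges times the bin size; under this
metric a digitized disk of radius r has perimeter exactly 8r, so the
160 cm limit corresponds to a circular field of radius 20 cm.  The seed
threshold is configurable (0.15/0.20/0.25) for robustness checks.

The gridness score is `min(corr60, corr120) - max(corr30, corr90, corr150)`
over an annulus of the spatial autocorrelogram (missing-aware Pearson at
every lag, computed with FFT cross-correlations).  The annulus excludes the
central peak (inner radius at the first local minimum of the radial
profile) and includes the six nearest surrounding peaks (outer radius 1.25x
the six-peak ring).  When six peaks cannot be found the result carries a
`degenerate` flag and a fallback annulus; an isotropic single-bump map
scores near zero and is flagged.

## Theta phase

The LFP (250 Hz) is band-pass filtered at 6-11 Hz with a 4th-order
Butterworth applied forward-backward (zero net phase; order configurable),
and the instantaneous phase comes from the Hilbert analytic signal.  The
convention sets 0 deg at the ascending zero-crossing, 90 deg at the peak.
Spikes receive the circularly interpolated phase (unwrapped interpolation,
re-wrapped).  Intervals whose theta amplitude falls below 10% of the
session median are flagged and their spikes excluded; a session with a flat
filtered trace yields no valid phases rather than noise.

## Runs and path properties

A run is a maximal contiguous passage through one field mask, with entry
and exit interpolated onto the mask boundary (32-fold segment subdivision)
so path lengths are continuous rather than bin-quantized.  Any exit
terminates the run.  Per run: path length (polyline from entry to exit),
tortuosity (path length / entry-exit chord, >= 1; < 1.4 tags a "straight"
run), eccentricity (minimum point-to-segment distance from the field peak
to the path), mean speed (path length / duration), entry direction, theta
cycle count (unwrapped phase span / 360), and minimum instantaneous speed
(central differences, no extra smoothing — tracking at 50 Hz is already
effectively smooth).  The primary filter keeps runs with **more than** 4
spikes (strict, configurable 3-6); an optional robustness filter further
requires >= 3 theta cycles and instantaneous speed never below 1 cm/s.
Long runs (> 60 cm) can be split at half their path length for
first-half/second-half slope comparisons; a spike exactly at the midpoint
belongs to the first half.

## Synthetic data

The generator produces the statistical structure the analysis assumes, with
every latent variable exposed for test assertions:

- **Foraging path**: Ornstein-Uhlenbeck angular velocity (heading
  diffusion) and OU log-speed, sampled at 50 Hz in a 1 m^2 box with
  specular wall reflection.  Defaults: median speed 19.5 cm/s with broad
  log-normal spread (sigma_log 0.55, relaxation 1.5 s), turning sigma 1.2
  rad/sqrt(s).  Per-run average speeds then span roughly 5-45 cm/s.
- **Linear track**: back-and-forth laps, one speed draw per lap.
- **Theta LFP**: instantaneous frequency performs a random walk (default
  0.5 Hz/sqrt(s)) reflected at the 6-11 Hz band edges around f0 = 8 Hz;
  the voltage is `amplitude * sin(phase) + noise` at 250 Hz, so the
  ground-truth phase follows the analysis convention exactly.
- **Grid spikes**: field centers on a hexagonal lattice (two 60-degree
  lattice vectors; spacing 50 cm, orientation 0 by default), Gaussian
  spatial envelope with sigma 7 cm so the 20%-level field diameter is
  ~25 cm.  An inhomogeneous Poisson process (peak 15 Hz) is thinned by a
  von Mises factor centred on the target phase
  `phi_entry + m*d` (kappa 4 by default; entry phase uniform-random per
  run, or fixed for pooled-versus-single-run contrasts).  With
  `kappa = inf` spikes are placed exactly where the LFP phase crosses the
  target phase, giving noise-free phase laws for exact recovery tests.
  A saturating phase-law variant caps the total range at
  `Rmax (1 - exp(-|m| d / Rmax))` with Rmax = 210 deg, emulating
  precession that starts steep and flattens.

What the generator does **not** emulate: real occupancy inhomogeneity and
thigmotaxis, theta-skipping and across-cycle spike correlations, rate
remapping, conjunctive head-direction tuning, and measurement noise in
tracking.  Passing tests therefore demonstrate correctness of the analysis
machinery under the model's assumptions, not robustness to every artifact
of real recordings.

Default study conditions used by the acceptance checks: 600 s sessions;
recovery sweeps true slopes of -4/-8/-12 deg/cm at kappa 4; the
saturating-law analyses use kappa 16 (the length-dependence signal is a
small correlation, ~0.1 at realistic noise — detecting it needs either low
noise or thousands of runs, exactly as in real data) pooled over several
sessions.

## Oscillatory-interference models

Each velocity-controlled oscillator i has frequency
`omega_i = omega_b + beta * s * cos(theta_dir - theta_i)` (baseline theta
omega_b = 2*pi*8 Hz, speed gain beta = 0.21 rad/cm by default, giving
~30 cm beat wavelength).  Phases are trapezoidal integrals on a 1 kHz grid,
initialized from the start position so a grid vertex sits at a known
location; the voltage is the superposition of the oscillators' cosines,
spikes are upward threshold crossings, and spike phases are read off the
baseline oscillation (the baseline can also be added as a summed term via a
flag, off by default).  No refractoriness.

- **Variant 1** (three oscillators 60 degrees apart): hexagonal pattern
  with direction-dependent phase coding, including recession (positive
  slope) along some directions.
- **Variant 2** (three oscillators 120 degrees apart): for any movement
  direction at least one oscillator falls below baseline; central runs
  show non-monotonic, precess-then-recess phase profiles.
- **Variant 3** (three opposed pairs, six oscillators, frequency increment
  half-wave rectified so no oscillator falls below theta): within each
  pair the phase difference evolves with pure displacement, which anchors
  a stable hexagonal envelope; precession occurs for runs in any
  direction at a roughly constant rate (~ -4 deg/cm at the default beta).

Variant-3 population statistics are obtained by simulating the model along
foraging trajectories and running the spikes through the *full* data
pipeline (rate map, field segmentation, run segmentation, circular-linear
fits) with a pure-cosine LFP at the baseline frequency, so model and data
are analysed identically.  Across ~460 pipeline-analysed runs the fitted
slope is uncorrelated with tortuosity (-0.03), speed (0.05) and path
length (-0.06), but retains a weak negative correlation with eccentricity
(about -0.17): grazing traversals fit slightly steeper because the fitted
phase profile of a crossing is sigmoidal (saturating), a second-order
property of the sum-of-six formulation.  This is reported as measured; it
is the one respect in which this implementation's variant 3 is not fully
path-property-independent.

## Numerical choices and degenerate inputs

- Angles are degrees at every interface and radians internally.
- Fits require n >= 2 and a non-constant covariate; correlations require
  n >= 3; a circularly constant variable yields r = 0 with a degeneracy
  flag rather than an error.
- The Rayleigh test uses the standard finite-sample exponential
  approximation; vector strength is the mean resultant length.
- The direction analysis (linear-circular correlation of entry direction
  with per-field slope) uses the Zar/Berens multiple-correlation statistic
  with the chi-squared(2) approximation, which is conservative below ~8
  runs per field; callers enforce the more-than-four-runs rule.
- The 4-way path-property ANOVA compares the full additive linear model
  against each reduced model by F-test on residual sums of squares; a
  constant predictor gives F = 0, p = 1, and ill-conditioned designs warn.
- All generators are deterministic under a seed (child seeds via
  `SeedSequence.spawn`).

## Problem sizes

Test-suite and acceptance-script simulations use 600-900 s sessions (one
to ten per analysis), 1500-4000 replicates for calibration loops, and
10 000-draw permutation oracles — sizes at which every reported statistic
is stable to well within its acceptance tolerance while the whole suite
runs in minutes on one core.

## Known limitations

- Real-data ingestion of the original recordings' proprietary format is
  out of scope; inputs are plain TSV.
- Anatomical layer analyses are supported only as grouping by a free-form
  metadata label.
- The p-values attached to per-run fits inherit the two-stage selection
  issue described above, as in the method this package implements.
- The variant-3 model's residual eccentricity dependence, discussed above.
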