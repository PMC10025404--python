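# Methods

This note records the model assumptions, parameter choices, and numerical
decisions behind `gaeeg`, and what the synthetic-data validation does and
does not establish about real recordings.

## Signal model and preprocessing

The pipeline assumes a four-channel frontal montage (F7, Fp1, Fp2, F8) in
microvolts at ≥128 Hz.  Motion artifacts are flagged per channel on 10 s
windows with 50 % overlap by a robust one-sided rule: a window whose mean
power exceeds the median window power by more than three median absolute
deviations is an artifact.  The rule is deliberately one-sided — motion
artifacts are high-power events, and a two-sided rule would flag
iso-electric epochs and hand them to the correction stage, inflating
suppressed segments before segmentation.  The rule also presumes that the
recording is dominated by a power-stationary regime (a long maintenance
phase, as in clinical sessions); on a recording that is mostly low-power
recovery the median shifts and genuine anesthesia epochs can be flagged.

Flagged intervals are corrected by wavelet quantile normalization: the
interval and an equal-length clean reference (nearest preceding unflagged
stretch, else nearest following) are decomposed with a discrete wavelet
transform (Haar, 5 levels by default); at each level the artifact
coefficients' magnitudes are remapped through the empirical quantile
function of the reference coefficients, signs preserved.  This caps every
corrected coefficient at the reference maximum and is idempotent up to a
small tolerance.  The wavelet family, level count, and reference policy
are configuration points; the implementation is isolated behind one
function so a different port of the published algorithm can be swapped in.

## Spectral descriptors

The time–frequency representation is a short-time PSD on a 20 s Hann
window with 75 % overlap, giving 0.05 Hz bins and a 5 s hop.  The taper
and resolution are implementation choices; the 20 s/75 % geometry is part
of the method.  Channels are combined as a weighted mean halving F7 and
F8 (frontal origin of the anesthetic α rhythm), normalized by the weight
sum 3.  Band powers are trapezoidal integrals over δ = [0.1, 4] Hz and
α = [8, 12] Hz; relative powers divide by the [0.1, 45] Hz integral and
are reported in percent.  Peak-frequency tracks take the argmax over the
band per frame (ties to the lowest bin), are undefined inside suppression
epochs (IES ∪ αS for the α track, IES for the δ track), and are smoothed
by a gap-aware first-order Savitzky–Golay filter: an order-1 local
regression over a 2 min window evaluated every 5 s, fitted only on
defined samples; windows with fewer than two defined samples stay
undefined.  On a gap-free uniform track this is exactly the classical
first-order SG filter; the local-regression form is what lets it smooth
across suppression-punctured tracks.

## Suppression segmentation

Envelopes are linear interpolations through strict local maxima/minima
(linear rather than spline: the envelope feeds a median and a threshold
comparison, where interpolation order is immaterial, and linear never
overshoots).  The segmentation thresholds the instantaneous envelope
*widths* rather than the raw trace — a raw |S(t)| test would fire at
every zero crossing.  Thresholds: T_IES = min(8 µV, median D(t)) and
T_α = min(0.25, median D_α(t)), medians over the whole recording.  The
8–16 Hz filter is a 4th-order zero-phase Butterworth; RMS normalization
uses the whole recording.

Mask smoothing uses a 0.5 s flat structuring element but composes erosion
and dilation differently per mask.  The IES condition (both widths below
threshold) is deeply satisfied inside genuine flat epochs, so the IES mask
is opened then closed: erosion first removes sub-element false candidates.
The αS condition sits *between* two thresholds (D ≥ T_IES and D_α < T_α)
and chatters at the sample level — the broadband width has brief Rayleigh
dips — so the αS mask is closed then opened: sub-element dropouts inside
genuine epochs are bridged before erosion.  Opening-first on the αS mask
demonstrably shreds planted 30 s suppressions into fragments.  Both
compositions remove every feature shorter than the element; mutual
exclusivity is enforced afterwards (αS minus IES).  S_IES sums IES time
over induction + maintenance; L_IES is the longest IES within induction
(the bolus context); both clip intervals to the phase window.

## Emergence markers

Band powers over the final 20 min are fitted with
S(t) = a/(1 + e^{c(t−t0)}) + b by bounded trust-region least squares
(a ≥ 0, c ∈ (0, 10] s⁻¹ — c > 0 encodes decay, so no post-hoc
re-parameterization is needed), multi-started over five t0 quantiles of
the window and c ∈ {0.005, 0.02, 0.1} s⁻¹ with amplitude/baseline seeded
from the series quartiles; the best fit by residual sum of squares wins.
A fit whose amplitude is below 5 % of the series range is flagged
`no_transition`.  Markers are the λ = 0.05 crossings (5 % of the
transition remaining): t_in on the δ fit — the δ plateau has essentially
vanished — and t_out on the α fit — the α power reaches its lower
plateau.  This pairing is the only one that makes t_out the arrival at
the α lower plateau and keeps Δt_ROC positive; both λ values and the
curve assignment are configurable.  f_max at a marker uses the nearest
defined smoothed sample within ±30 s, else linear interpolation across
the gap.

## Total variation

Within each suppression-free segment the smoothed track is discretized at
its local extrema (strict sign changes of consecutive differences; the
first sample of a plateau stands for the plateau; both endpoints
included).  The statistic sums |Δf| over the extrema and divides by the
summed segment spans in minutes.  For any sampled track this extremum sum
equals the plain sum of absolute consecutive differences (monotone runs
telescope), which is the independent oracle used in the tests.  Segments
shorter than the smoothing window (2 min) carry no reliable smoothed
samples and are dropped from the segment count.

## Bayesian correlation analysis

The Bayes factor favoring the null of no correlation uses the
Zellner–Siow setup: slope prior b | g, σ² ~ N(0, g σ² (xᵀx)⁻¹), reference
prior 1/σ² on (a, σ²), and mixing density
π(g) = √(n/2)/Γ(½) · g^{−3/2} e^{−n/(2g)}.  The exponent in π(g) is
negative — the positive sign makes the integral diverge — and with it the
marginal-likelihood ratio reduces to a one-dimensional integral in g that
depends on the data only through r² and n.  Quadrature substitutes
g = u/(1−u) onto (0, 1), evaluates the integrand in log space, and uses
adaptive Gauss–Kronrod integration at a relative tolerance of 1e-10; a
fixed-grid Romberg implementation in the test suite provides the
independent oracle (agreement to 4 significant digits across an (r, n)
grid).  Partial correlations are computed by correlating residuals of
least-squares projections onto [1, covariates] (equivalent to the
single-covariate recursion, asserted in tests); their Bayes factors are
nested-model ratios of two g-prior integrals with the reduced and full
coefficients of determination, p and p′ = p + 1 covariates.  P-values use
the exact t-transform with n − 2 degrees of freedom (n − 2 − k when k
covariates are controlled).  Gender enters covariate sets as 0/1.  The
cohort report applies α = 0.05 with no multiplicity correction, and the
conditional-probability analysis thresholds at the 70th percentile
(bolus threshold fixed at 0.5 min) — both mirroring the analysis this
package implements rather than best statistical practice.

## The synthetic cohort generator

Each patient is a sum of narrowband components over a three-phase plan:
an amplitude-modulated δ tone (default 21.5 µV at ~1.2 Hz), a
channel-common θ tone (10 µV at ~6 Hz — the slow rhythm prominent under
GABAergic anesthetics; it persists through αS and decays with δ during
recovery), an α tone (8.3 µV) whose peak frequency wanders slowly and
ramps upward during recovery, background noise with a 1/f spectrum up to
a 10 Hz knee and 1/f³ above (anesthesia EEG background falls much faster
than 1/f beyond the α range), and small (0.3 µV) fast broadband
components.  Amplitudes were calibrated analytically so a maintenance
epoch's relative powers land near clinical values (δ ≈ 73 %, α ≈ 11 % of
[0.1, 45] Hz energy); the analytic energy budget is exposed and checked
against the pipeline's measurement in the tests.  Inside planted IES the
whole signal is scaled to 1 % amplitude with 0.2 s cosine edges; inside
planted αS only the α component collapses.  Artifacts are 1–5 s broadband
(0.5–40 Hz) bursts at ~10× background RMS.

Recovery plants an exact truth: δ and α band *powers* decay as logistic
functions whose 5 %-remaining crossings define t_in and the nominal
t_out; the α peak frequency ramps linearly between them.  When the ramp
carries the peak past the 12 Hz band edge, the 8–12 Hz band power
collapses before the amplitude transition completes — this is real
physics of the "zip", not an estimator artifact — so the recorded truth
t_out is the 5 % crossing of the planted *in-band* α power (amplitude
sigmoid × band occupancy of the peak), evaluated on the slow component of
the frequency track; it coincides with the amplitude crossing whenever
the ramp stays in-band.  True Δf_ROC is the planted slow-track frequency
difference between the two truth times.

Cohort priors (per group) draw Δt_ROC and Δf_ROC from clipped log-normals
whose medians and spreads follow published pediatric/adult cohort
summaries (children: 7.8 min, 3.3 Hz; adults: 7.3 min, 1.9 Hz; σ from the
interquartile ratios), suppression counts from Poisson distributions with
log-normal durations (children get a propofol-bolus IES near the end of
induction; adults, induced by target-controlled infusion, do not), and
demographics from clipped normals.  Sampling rate defaults to 250 Hz.

### What the generator does and does not establish

Passing the recovery tests shows the estimators are unbiased and precise
*under the generator's assumptions*: tonal bands, logistic power decays,
a linear frequency ramp, stationary noise.  Real EEG has broadband
rhythms, multi-peaked α structure, drifting noise floors, and
non-logistic transitions.  Three known consequences:

* The peak-frequency instability V is driven here solely by the planted
  slow wander (σ = 0.5 Hz at a 30 s scale), giving V ≈ 0.3 Hz/min —
  below clinically reported medians (~0.6), because a single clean
  spectral peak lacks the argmax competition between sub-peaks that
  inflates real tracks.  Pushing the wander high enough to match would
  break the 8–12 Hz band constraint.  The statistic itself is validated
  exactly against a brute-force oracle.
* Relative-power truths are expectations over a clean epoch; the measured
  maintenance means include suppression epochs (as the method specifies),
  whose gated edges leak δ power out of band, so heavily suppressed
  patients read a few points below the analytic truth.
* The artifact rule's median baseline assumes maintenance-dominated
  recordings (see above).

## Problem sizes

The simulation-backed checks use scaled recordings chosen to keep the
default test run compact while preserving the regimes that matter:
emergence recovery uses 50 patients with 2 min induction + 4 min
maintenance + 20 min recovery at 250 Hz (the fit window is the final
20 min, so maintenance length is irrelevant to the markers); suppression
recovery uses 20 patients with 14 min records; the null-calibration check
draws 500 feature tables of n = 50 directly, with no signal rendering;
prior-calibration medians use truth-table-only cohort draws.

## Known limitations

* Real-data phase boundaries must be supplied externally (an events
  table); the package does not detect loss of consciousness.
* EDF files can be read (via mne) but not written; the native format is
  delimited text with a sampling-rate header.
* Burst-suppression ratio, spectral entropy, connectivity measures, and
  posterior estimation of correlation magnitude are out of scope.
* The Bayes-factor integrand limit at g → ∞ is finite only for p = 1;
  the implementation handles general p through the adaptive quadrature,
  but the Romberg oracle's endpoint formula assumes p = 1.
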