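# Methods

`trackephys` re-implements, as a tested library, the analysis chain of a
rodent electrophysiology experiment in which a rat runs back and forth for
reward on a 3.5 m C-shaped track in two sessions (PRE and POST, the second
following a drug manipulation) while CA1 and visual-cortex (VC) units, LFPs
from both regions, and a neck-muscle EMG are recorded. Because such
recordings are not bundled with the package, every analysis is validated
against a synthetic session generator with full ground truth. This note
documents the models, the parameter choices, and what the validation does
and does not establish.

## Session model (synthetic generator)

**Behavior.** The animal alternates reward-site immobility bouts
(gamma-distributed, mean 6 s, minimum 2 s) with track traversals at a
per-lap cruise speed drawn from N(40, 6) cm/s, following a trapezoidal
speed profile with 1 s acceleration/deceleration ramps; 15 % of laps
contain a mid-track stop (exponential, mean 3 s, minimum 1.5 s). Positions
are emitted at 33 Hz with ~1 pixel (0.25 cm) tracking jitter and 0.25 cm
quantization; the 2-D embedding is a three-segment C-shaped polyline with
arm lengths 2:3:2. The ramps matter: with instantaneous stops, the 0.5 s
speed-smoothing window biases detected immobility boundaries by several
hundred milliseconds and short bouts are missed entirely.

**Spiking.** Spikes are drawn exactly from an inhomogeneous Poisson process
by per-bin Poisson sampling of a piecewise-constant intensity on a 1 ms
grid. For a CA1 unit the running intensity is

    lambda(t) = [ peak * G_dir(x) + b + g*v ] * (1 + m cos(theta - phi(x))) * s(t)

with `G_dir` a Gaussian place field per running direction (sigma 7–11 cm,
peak 4–14 Hz, centers uniform on the track interior), baseline b = 0.1 Hz,
speed gain g = 0.02 Hz/(cm/s), theta modulation depth m = 0.5, and a shared
slow modulation `s(t)` (Gaussian process, sigma 0.2 s, depth 0.35) common
to all CA1 and VC units — the source of CA1–VC co-fluctuation during
running. The directionality factor d in [0, 1] mixes the two directions'
fields: the reverse-direction curve is `d*G2 + (1-d)*G1`, so d = 0 gives
identical curves in both directions and d = 1 independent fields (the PRE
default, matching strongly directional CA1 place fields). The preferred
theta phase advances linearly with distance traveled through the field
(default −6 deg/cm), producing phase precession; theta frequency is
speed-dependent (8 Hz + 0.02 Hz per cm/s). During immobility CA1 units fire
at 0.25 Hz. VC units carry broad (sigma 60 cm), weak (depth 0.5),
direction-independent spatial modulation on a 2–8 Hz base rate.

**Drug effects (POST).** `rate_scale` multiplies the whole CA1 intensity
and the shared-modulation depth (so both single-unit rates and CA1–VC MUA
coupling weaken); `directionality_shift` replaces d;
`hvs_boost` multiplies the HVS rate; `coactivity_decouple` breaks the
CA1–VC (not CA1–CA1) coupling of ripple content (below). PRE and POST share
unit identities because all unit parameters derive from the seed alone.

**Events.** Ripples are 80 ms, 175 Hz bursts with a Gaussian
(spindle-shaped) envelope scaled to 10 baseline SD of the 100–250 Hz band,
injected during immobility at 10/min of immobility. The Gaussian envelope
is deliberate: with a flat-topped envelope, noise can displace the deepest
trough (the detector's peak time) by two carrier cycles. Each ripple
carries a replayed track location; CA1 units burst within the ripple with
probability increasing near that location (participation kernel twice the
field width plus a 0.15 baseline), and each unit's burst time is offset in
proportion to its field's distance from the replayed location (0.6 ms/cm,
clipped at ±30 ms) — the time-compressed replay order. This timing
structure is what a within-event shuffle null can detect; per-event
participation alone is invisible to it, since the shuffle preserves
per-event spike counts. VC units respond around each ripple according to
their tuning at the replayed location, with gain proportional to the
square root of their base rate — the shuffle-Z of a burst against a
Poisson background grows as burst/sqrt(background), so this keeps
ripple-response Z roughly homogeneous across units instead of installing a
unit-level gain common to running and ripple coactivity (which would
correlate across pairs even without content coupling). VC modulation
centers are kept one tuning width away from the track ends for the same
reason. Under `coactivity_decouple` the VC response uses an independently
drawn location per ripple.
HVS events are 8-cycle, 8 Hz spike-and-wave trains (tukey envelope, 10 SD
of the 6–12 Hz band) with VC bursts at every trough; eHTs are 250 ms,
40 Hz EMG bursts (12 SD of the 20–60 Hz band) with two sub-burst envelope
peaks > 0.1 s apart — a single smooth envelope cannot satisfy the
detector's two-peak rule, and real head twitches are multi-deflection.

Identical (config, seed) pairs produce byte-identical bundles; all
randomness flows through spawned `numpy` generators in fixed order.

## Analysis chain

**Behavior.** Speed: centered finite differences smoothed by a Gaussian
window (sigma 0.5 s, truncated ±4 sigma, edge-renormalized). Linearization:
projection onto the track polyline; direction = sign of the smoothed 1-D
velocity thresholded at ±2 cm/s; projection outliers (> 5 cm) are
undefined. Immobility: speed below the mean speed within ±10 cm of the
reward sites (threshold estimated in PRE and reused for POST), sub-0.5 s
gaps merged. Sustained-slow exclusion: < 10 cm/s for ≥ 0.5 s. Laps: maximal
excursions from within 10 cm of one end to within 10 cm of the other. eHT:
20–60 Hz band, ≥ 2 rectified peaks > 8 SD with inter-peak time ≥ 0.1 s
(closer peaks count as one; peaks within 0.5 s group into one event),
start/end at the 3.5 SD crossings of the analytic envelope. Baseline SD is
the full-session filtered-trace SD; an event-excluded variant is a flag.

**Spatial coding.** Rate curves: 1 cm bins over each direction's laps with
stop periods removed; spike-count and occupancy maps smoothed separately
(Gaussian, sigma 3 bins) before division (a ratio-smoothing variant is a
flag); bins within 10 cm of reward sites masked. Spatial information is the
Skaggs bits/spike form. Stability (PRE vs POST, same trajectory) and
directionality (two trajectories, same session) are Pearson correlations
over jointly valid bins with the stated inclusion rules (active ≥ 0.5 Hz on
one side, ≥ 1 spike on the other); constant curves return missing. Place
fields: local peaks ≥ 3 Hz extended to 10 % of peak, gaps < 5 cm merged.
Speed-residual rates: lap-by-lap rate regressed on lap speed jointly over
PRE+POST laps (so residuals are comparable across sessions), residuals
averaged per session; the within-field variant restricts both to the field
boundaries. Burst index: fraction of running spikes within 10 ms of another
spike (bidirectional).

**Population vectors.** Per spatial bin, the across-unit vector of smoothed
rates of units active (≥ 0.5 Hz) on the trajectory in either session; bins
need ≥ 5 units above 0.5 Hz at that bin (the same rate criterion that
defines an active cell, applied per bin) in both matrices being compared.
Cross-session and cross-trajectory PV correlations are Pearson across
units, averaged over eligible bins.

**Events.** Ripples: 100–250 Hz band, troughs beyond 6 SD, edges at the
2.5 SD crossings of the Hilbert envelope, < 30 ms gaps merged, 30–400 ms
duration; peak = deepest trough. HVS: 6–12 Hz band, ≥ 4 troughs beyond
6 SD with inter-trough intervals ≤ 250 ms, 2.5 SD envelope edges, < 0.5 s
gaps merged; attributes include trough count, deepest-trough amplitude (SD
units), and mean inter-trough frequency. Both detectors are SD-relative and
hence amplitude-scale invariant. HVS occupancy is the percentage of
immobility time inside HVS events; POST immobility metrics are restricted
to the first 30 minutes.

**Pairwise.** Spike-count cross-correlograms in 10 ms bins within
behavioral events, normalized per lag as a Z-score against 200 event-wise
shuffles in which both trains are independently circularly shifted within
each event. Implementation: shifts are quantized to whole bins; for events
much longer than the lag span (≥ 4× the lag window) the correlogram is
computed circularly and the shuffle uses the exact rotation identity
(`roll(C, ka−kb)`), which reduces the cost per shuffle to a gather; shorter
events (e.g., ripples) use the literal linear correlogram recomputed per
shuffle. A `method="rebin"` path implements continuous-offset re-binning
for cross-checking. Observed and shuffled correlograms are smoothed
identically (boxcar ±10 bins for running, ±4 for ripple contexts) before
normalization. Coactivity is the mean Z around lag 0 (±100 ms running,
±50 ms within-ripple CA1, ±100 ms CA1–VC in ±1 s windows around ripple
peaks). Awake reactivation correlates running coactivity with ripple
coactivity across eligible pairs. MUA: all of a region's spikes in 10 ms
bins, normalized to [0, 1], Gaussian-smoothed (sigma 3 bins); CA1–VC MUA
correlation is computed per running period (≥ 2 s) at lags ±1 s and
averaged. Triggered averages support continuous signals, re-zeroed 1-D
position, and across-cell mean rates (50 ms bins), dropping partial
windows.

**Theta.** Multitaper spectra (time-bandwidth 3, 5 tapers, 2 s windows,
0.25 Hz grid via zero-padding) per running-speed band (< 20, 20–40, 40–60,
> 60 cm/s, minimum 2 s); theta peak frequency is the 6–10 Hz argmax and
theta power the band integral. CA1–VC coherence averages the multitaper
magnitude-squared coherence over 6–10 Hz. Spike theta phase uses
peak(0°)/trough(180°) anchoring with linear interpolation — not the
analytic-signal angle. Phase precession is fit by maximizing the mean
resultant length of slope-detrended phases over a −15..15 deg/cm grid
(0.1 steps) and reported with the slope-signed circular correlation; two
simpler variants (slope-scan or offset-scan maximization of a plain linear
correlation) were rejected because the former saturates trivially at
extreme slopes and the latter is biased by the within-theta-cycle stripe
structure of precessing spikes. Theta sequences: for field pairs closer
than 40 cm, the running cross-correlogram peak lag within ±125 ms is
regressed on signed field distance.

**Statistics.** Rank-sum / Mann-Whitney / Kruskal-Wallis / t tests delegate
to scipy. Two correlation coefficients are compared by the Fisher r-to-z
two-sample test. Rate-matched downsampling resamples the larger pair set to
the smaller's size within pooled rate-decile bins, without replacement.

## Validation experiments and problem sizes

The validation suite (`trackephys.validation`, exercised by the test suite
and `scripts/acceptance.py`) uses deliberately compact problem sizes —
4–6 min sessions, 6–45 CA1 units — so a full pass completes in minutes:

- detector recovery: 3 sessions × 6 min, events at the amplitudes above;
  recall/precision and ripple/eHT peak-time errors are reported.
- null calibration: 50 seeds of independent 5 Hz Poisson pairs over 20×5 s
  events; pooled Z mean/SD. False-positive rates: 50 × 2 min of Gaussian
  noise per detector.
- effect recovery: 50 experiments (4 min sessions, 45 CA1 + 10 VC units)
  with POST rate × 0.5 and directionality 1 → 0.5; fractions reporting the
  four signatures (within-field rate decrease and directionality-
  correlation increase at alpha = 0.05 by rank-sum; cross-trajectory PV
  increase; MUA peak decrease).
- confound removal: 50 paired sessions with flat place fields, rate = 0.5 +
  0.08·speed, PRE at 45 cm/s vs POST at 25 cm/s; the residual-rate
  difference is compared with 2× an experiment-level bootstrap SE in which
  laps are resampled once per draw and shared across units (units share
  behavior and the common slow modulation, so per-unit bootstraps
  underestimate the SE of the across-unit mean).
- reactivation dissociation: 50 decoupled POST sessions (5 min, 15 CA1 +
  8 VC, 20 ripples/min of immobility). A caveat this experiment exposes:
  the across-pair Pearson significance test for reactivation treats cell
  pairs as independent, but pairs share units, and both running and
  within-ripple coactivity Z scale multiplicatively with unit rate
  sensitivities. Even with replay content fully decoupled, these shared
  gains leave a small (~+0.1) across-pair correlation, so the CA1-VC
  "no reactivation" call is made in roughly 85 % rather than 95 % of
  simulated sessions; pooling more pairs sharpens, not shrinks, this
  residual. Rate-matched downsampling (provided in the stats module) is
  the appropriate control when comparing such correlations across
  conditions.

What passing shows — and does not. The synthetic sessions reproduce the
statistical structure the analyses assume (Gaussian directional fields,
Poisson spiking, linear speed modulation, sinusoidal theta, stereotyped
event waveforms, stationary noise). They do not model electrode drift,
sorting errors, non-Poisson bursting beyond the injected events, multiple
fields per cell, realistic LFP spectra (1/f background, gamma), or
behavioral idiosyncrasies; passing therefore demonstrates correctness of
the implementations and recoverability of effects under the stated model,
not robustness to every property of real recordings.

## Numerical choices and degenerate inputs

Half-open `[start, end)` intervals and half-open binning throughout.
Zero-phase 4th-order Butterworth for every band-pass. Gaussian smoothing is
edge-renormalized. Constant inputs to correlations return missing rather
than NaN-propagate; zero-occupancy bins are excluded from correlations;
all-identical lap speeds make the speed regression fall back to slope 0
with a degeneracy flag. Shuffle Z is missing where the shuffle SD is zero.
Event detectors reject sampling rates below 2.4× the upper band edge.
Seeds: every stochastic routine takes a `numpy` Generator or an integer
seed; child seeds are spawned deterministically and kept below 2^31.
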