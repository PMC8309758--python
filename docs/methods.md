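# Methods

## Problem and model

Two body-worn accelerometers (e.g. hip and wrist) record the same person
for a week, each timestamping its data with its own real-time clock
(RTC). Consumer RTC crystals are accurate to about ±20 ppm, so a single
device accumulates up to ~12 s of clock error over 7 days and a pair of
devices up to ~24 s relative to each other. Joint processing of the two
streams (sensor fusion, activity-type classification on 2–10 s windows)
is invalid at that level of misalignment.

Each clock is modelled as C(t) = f·t + θ: a constant skew f (close to 1;
deviations measured in ppm) and an offset θ at time zero. The relative
clock between the two devices is the same form, so the sample lag between
the streams is **linear in time**:

    lag(i) = β₁·time(i) + β₀

with β₁ the drift in samples/s and β₀ the initial offset in samples (at
the 30 Hz working rate; β₀/30 gives seconds). The accumulated drift over
a 7-day wear period, the quantity used for reporting, is

    day-7 drift [s] = β₁ · 30⁻¹ · 86 400 · 7.

Temperature affects crystal frequency by about −0.04 ppm/°C²; wear-site
temperature differences of ±5 °C therefore contribute only ~1 ppm and are
deliberately **not** modelled — the linear model is the method's core
assumption. Sudden sampling halts (a known firmware fault) violate it;
estimates whose |day-7 drift| exceeds 24 s are flagged for manual review
rather than silently corrected.

## The three-stage pipeline

**Stage I — per-hour lag estimation.** Both streams are resampled to
30 Hz (linear interpolation, mirroring the vendor export path — no
anti-alias filter, a documented fidelity-over-textbook choice) and
reduced to a single movement channel: signed ENMO (√(x²+y²+z²) − 1),
dead-band (|v| ≤ 0.068 g → 0), zero-phase band-pass (Butterworth,
0.1–7 Hz, total order 4, applied forward-backward via `sosfiltfilt` so no
group delay can bias a lag), then rectification — strictly in that order
(the dead-band acts on signed ENMO before filtering; the order is
observable and tested). The signals are cut into non-overlapping 1-h
blocks. A block is used only when the mean absolute raw ENMO of **both**
devices strictly exceeds 0.01 g — a cross-correlation needs movement in
both channels. For each usable block the lag is the argmax of the
coefficient-normalized cross-correlogram within ±1000 samples (±33.3 s);
positive lag means the secondary stream runs late. Ties are broken toward
the smallest |lag|, then the negative one.

Each observation is timestamped at the **activity-weighted centroid** of
its block (config `block_time_mode`; 'start' and 'midpoint' are also
available). The lag of a block is physically measured at the time of the
shared movement inside it, so a fixed anchor biases β₀ by up to
drift × 3600 s (~5 samples at 30 s/7 d) when movement sits late in its
hour; the centroid removes this. The slope is invariant to the choice.

**Stage II — robust linear fit.** Ordinary least squares of lag on time,
with iterative outlier exclusion: at iteration k every point whose
standardized residual (residual / residual standard error) exceeds the
threshold t_k is dropped and the model refit, with t₀ = 1 and
t_{k+1} = exp(t_k) (1, 2.72, 15.15, …). Blocks whose movement is not
actually shared between wear sites (independent arm activity) produce
lags that are invalid rather than noisy, which is why they are excluded
outright instead of down-weighted. The loop stops when an iteration
excludes nothing, when residuals are exactly zero (guard at RMSE <
1e−12, which also makes exact-line input terminate immediately), or when
fewer than two points would remain (previous fit kept, `degenerate`
flag). RMSE is reported as √(SSE/(n−2)) and R² from the final fit.

*Known limitation (masking):* because the threshold explodes after two
iterations, four or more simultaneous gross outliers combined with very
small inlier variance can leave one outlier standing (its |sr| ≈ 4 is
below the third threshold 15.15). Up to about three simultaneous gross
outliers per fit are handled reliably. An optional `min_peak_corr` gate
on the correlogram peak (off by default) is available as a second line of
defence.

**Stage III — alignment.** The secondary recording is corrected by (1)
trimming ⌊β₀⌋ samples from its start (negative offset: prepending copies
of the first sample — a gravity-consistent hold, since zero-g triples
would corrupt downstream ENMO), and (2) resampling on the warped grid:
output sample n reads source position n·(1 + β₁/30) + φ, where φ is the
fractional part of β₀ (folded into the warp to avoid a half-sample bias;
`round_offset: true` restores plain integer trimming). Interpolation is
'previous' (previous-neighbour hold) by default — it preserves the
original amplitude set, and with it amplitude-sensitive intensity
metrics — with 'linear' and 'cubic' available for waveform-shape
applications.

## Synthetic data

The generator produces the study conditions under which every claim is
tested. The reference device samples the ideal clock; the secondary takes
its sample n at true time (1 + skew_ppm·10⁻⁶)·n/30 + offset_s, so the
implied ground truth is β₀ = −offset·30 and β₁ = −skew·10⁻⁶·30
(first-order in ppm; the quadratic correction is < 10⁻⁷ samples/s at
realistic skews). A scripted schedule places movement segments on a
sedentary baseline of white noise (SD 0.008 g per axis, chosen so purely
sedentary hours sit just below the 0.01 g gate — mean |ENMO| of Gaussian
noise is ≈ 0.8σ):

* **walk/run** — shared gait: a train of Gaussian heel-strike impulses at
  the step frequency (default 2 Hz, impulse width σ = 0.14 step periods
  — spectrally a fundamental plus ~1:0.3:0.05 harmonics), per-step random
  amplitudes (±50%, shared between channels) so the correlogram's central
  peak strictly dominates the ±0.5 s side peaks, and channel asymmetry on
  the secondary (amplitude ×0.75, per-burst timing jitter SD 10 ms —
  the per-block lag noise source, ~0.3 samples).
* **unshared** — both channels active but moving independently
  (different random impulse trains and cadences): these blocks pass both
  activity gates yet correlate spuriously, producing the gross lag
  outliers the robust fit must reject.
* an optional mid-recording **sampling halt** of the secondary device
  reproduces the firmware fault behind abnormal (> 24 s) apparent drift.

The default free-living schedule is 3 ten-minute walks per day at
realistic hours with ±18 min jitter and amplitudes of 0.25–0.5 g; the
closed-loop evaluations add 2 uncorrelated-movement hours per week. What
the generator does **not** emulate: biomechanically realistic limb
kinematics, temperature-dependent skew, autocalibration error, non-wear.
Passing tests therefore demonstrate correct recovery of linear clock
error under shared-burst conditions, not performance on arbitrary real
data — though the pipeline constants are exactly those used on real
recordings.

## Numerical choices

* A deterministic in-band dither of 1e−10 g is added before zero-phase
  filtering: dead-banded signals are mostly exact zeros and the decaying
  IIR state otherwise enters subnormal floats, slowing filtering by ~7×.
  The dither is eight orders of magnitude below any real acceleration.
* Cross-correlation uses the FFT path for full-size blocks; an
  independent direct-summation oracle checks exact agreement in tests.
* "Total order 4" band-pass means two poles per edge (`butter(2, …)`
  band-pass); the per-edge-order reading can be selected via `bp_order`.
* Correlogram peak ties (rare, logged) break toward small |lag|, the
  safer prior early in a recording.
* Blocks are paired index-aligned on the nominal timebase; the true
  misalignment between paired blocks (≤ tens of seconds) is far inside
  the ±33.3 s search window.

## Problem sizes used in the checks

The closed-loop evaluation runs 20 random week-long 30 Hz pairs
(~18.1 M samples per device) with injected offsets in ±10 s and day-7
drifts in ±30 s, requiring the re-estimated residual to stay below 2
samples of offset and 0.5 s of day-7 drift. Correlogram morphology is
measured on 10 one-hour pairs containing a 20-min walk; oracle
equivalence on 200 random blocks of up to 2000 samples. The acceptance
script (`scripts/acceptance.py`) recomputes the gait side-peak spacing
from 10 fresh synthetic pairs per run.
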