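# Methods

## The recording model

The unit of analysis is a *session*: a `[site × sample]` matrix in mV from a
linear probe in DC-coupled mode, plus the probe geometry, a layer map,
whisker-stimulus times and the KCl-application time.  Site 0 is the most
superficial contact and depths grow downward; this coordinate convention is
declared, not inferred — acquisition systems differ in which connector pin
is "channel 1", so the loader simply documents the assumption.  Default
layer boundaries, 600 µm (L2/3|L4) and 1000 µm (L4|L5/6) for a 1700 µm
insertion, follow standard adult-rat barrel-cortex laminar depths and are
configurable per session.

All DC/LFP analysis runs on a decimated copy of the signal (polyphase FIR
resampling with unity DC gain and edge padding; no high-pass anywhere, since
the slow negative shift *is* the signal).  The default DC rate is 1 kHz;
spreading-depression dynamics live below 1 Hz, so the long-session analyses
in the test and reproduction scripts use 100 Hz without loss.  MUA always
uses the full-rate wideband signal.

## CSD detection

Manual scoring ("a wave is obvious on the DC trace") is automated in two
stages.  A *candidate* stage low-pass filters each channel at 1 Hz — an
order-1 Butterworth applied forward-backward, whose effective kernel is a
positive double exponential; this matters, because a filter with step
overshoot would bias the trough of plateau-shaped waves — and flags
episodes where the trace stays ≥2 mV below a running baseline for ≥5 s.
The running baseline is the 80th percentile of the smoothed trace in a
180 s window, computed on a 1 Hz grid: waves are negative excursions
occupying well under half of any window, so a high percentile tracks the
resting level and slow drift straight through them.  The 2 mV threshold
sits far below the smallest layer-mean wave amplitude (~8 mV) and far above
the smoothed noise floor (≈0.01 mV at 0.2 mV wideband noise), so candidate
detection is effectively error-free in the regimes the generator covers.

The *refinement* stage estimates, per channel, the onset as the most
negative local minimum of the first time-derivative within 20 s before the
trough, with ties broken toward the latest time (the steepest point of the
front).  The baseline is the trace mean over 20–10 s before the **onset**
estimate — anchoring it to the trough instead would let the window overlap
the descending front of slow waves.  Amplitude, half-duration and rise time
are then read off the smoothed trace with linear interpolation between
samples.  Per-channel events co-occurring within 60 s are grouped into one
wave: CSD crosses the 1.5 mm probe span in seconds-to-tens-of-seconds, so a
minute covers any physiological propagation delay while staying well inside
the shortest credible inter-wave interval.

A caveat worth knowing: on a front with *constant* slope the derivative
minimum is degenerate, and under noise its argmin is roughly uniform over
the front.  Onset estimates on the piecewise-linear waveform family are
therefore only sample-accurate in the noiseless case; quantities that
difference two onsets (the generation period) are unaffected because the
bias is common to all waves.  Real CSD fronts are sigmoidal, where the rule
is well-behaved; the generator's sigmoid family exists for exactly that
check.

## The synthetic generator

The generator's job is to carry the statistical structure the analysis
assumes, with ground truth for every measurable, not to be biophysical.
What it emulates: per-layer DC wave excursions with controllable (A, T1/2,
RT) and layer-limited propagation (a reach list per wave and a fixed onset
delay per site, default 0.3 s/100 µm — a placeholder, since laminar CSD
propagation speed along a column is not well constrained); cosine SEP
templates with per-layer onset/peak latency and amplitude; inhomogeneous
Poisson MUA; Gaussian wideband noise and slow DC drift (30 s knots).  What
it does not: ionic/reaction-diffusion wave mechanics, realistic spike
waveform diversity, vascular signals, electrode drift or artifacts.
Passing tests therefore demonstrate that the estimators invert the assumed
signal model at realistic SNR — not that they are robust to every artifact
of real recordings.

The default wave family is piecewise linear: a descent ramp of duration
RT/0.6 (a linear ramp's 20–80 % span is 0.6 of its duration), a plateau at
−A sized so the half-amplitude width equals T1/2, and a mirror-image
recovery ramp.  This family is chosen *because* the morphometry operators
invert it exactly, which makes the generator/measurer acceptance checks
sharp; the sigmoid family is provided without that guarantee.  Validity
requires RT ≤ 0.6·T1/2 — satisfied by every published layer mean.

Spike trains are Poisson with a hard 2 ms minimum inter-spike interval
(non-paralyzable dead time) and intensity compensated to λ/(1−λd), so the
realized rate is unbiased for the nominal rate; the 2 ms floor is twice the
detector dead time, keeping rendered spikes fully resolvable.  Spikes are
rendered as 1 ms single-cycle negative-first transients at 8× the noise SD
(configurable; an absolute 0.05 mV floor applies in noiseless sessions).
Rate profiles are piecewise constant: per-layer background, an additive
onset burst for 10 s from the wave front, multiplicative post-wave
suppression 1−s·exp(−t/τ) (discretized at 1 s), and additive
stimulus-locked rates in the 0–20 and 20–520 ms windows.  Evoked-response
suppression after waves follows the same exponential form.

Two presets encode the study conditions as ground truth.  *Control*: 19
waves spanning 86 min, full-column propagation, amplitudes
8.8/12.9/16.7 mV, T1/2 23.2/25.6/19.01 s, RT 3.2/4.1/5.4 s (L2/3, L4,
L5/6), background MUA 1.9/19.4/26.0 s⁻¹, onset bursts 60/95/146 s⁻¹, SEP
latencies 11.55/10.24/9.95 ms and amplitudes 1017/1174/963 µV, suppression
0.3 recovering with τ = 120 s.  *hHCY* (hyperhomocysteinemia group): 26
waves spanning 69 min, with propagation limited to L4-and-deeper after
~17 min and L5/6-only after ~35 min; amplitudes 7.8/9.8/10.3 mV, T1/2
36.1/38.4/36.9 s, RT 7.1/6.3/5.6 s, background 2.2/32.0/37.9 s⁻¹, bursts
98/195/165 s⁻¹, and suppression 0.9 with an effectively infinite recovery
time constant, which reproduces the 5–20 % MUA recovery at +5 min.
Wideband noise defaults to 0.2 mV SD and drift to 0.3 mV SD.

## MUA

Zero-phase band-pass (Butterworth order 3, 300–3000 Hz, `sosfiltfilt`) so
spike times carry no filter latency relative to SEP windows.  The noise SD
is the MAD/0.6745 of the filtered trace over the 60 s before KCl (falling
back to the whole recording with a warning): a robust scale keeps bursts
from inflating the threshold.  The default threshold is 5 SD; figure
conventions elsewhere sometimes use 8 SD, so the multiplier is exposed
(`mua_threshold_sd`).  Events are timestamped at the local minimum of each
sub-threshold excursion with a 1 ms dead time.  At 5 SD the Gaussian
false-positive rate is ~0.005 events/s/channel at 32 kHz; 8×-SD spikes are
detected with ≈100 % efficiency and sub-millisecond timing.

Layer rates average per-channel count/duration over the layer's channels;
an empty layer is reported missing, never zero.  The onset increment uses
each channel's own onset when a detected wave is supplied, since the front
reaches channels at different times.  SEP-window rates pool counts across
stimuli; the window anchor (stimulus time plus a conduction/onset delay) is
a parameter, because the measured SEP onset is only available when the
evoked analysis has run.

## Evoked potentials

Stimulus-triggered averages subtract the mean of the 1 s pre-stimulus
segment per channel, making amplitude and latency exactly invariant to
channel-wise DC offsets.  Stimuli inside caller-supplied exclusion spans
(e.g. wave troughs) are dropped from pre-CSD reference averages — but *not*
from the recovery timeline, where the suppressed responses are the object
of study.  The trough search runs over 0–100 ms post-stimulus; the peak is
the most negative sample (no sub-sample refinement — at the 4 kHz DC rate
used for SEP analysis this bounds latency error at 0.25 ms).  The SEP
onset rule — "where the front leaves the baseline" — has no standard
threshold, so it is operationalized as the last pre-peak time inside a
±2 SD band of the pre-stimulus residual: reproducible and scale-free.  A
channel whose trough never leaves the band is non-responsive (missing).
The principal whisker maximizes amplitude, then shortest latency;
a conflict between the two winners resolves to amplitude with a logged
warning.

The source-density map defaults to sink-negative (−∂²V/∂z², the standard
current-source-density sign up to the conductivity factor); the plain
second difference is available via `sink_negative=False` for comparison
with toolchains using the opposite convention.  Only the second-difference
estimator is implemented — no inverse/spline (kCSD-style) variants.

## Lesion volume

Slab rule: Σ areaᵢ × thickness, matching "area in successive slices" ×
400 µm; trapezoidal interpolation between slices was deliberately not used
(the slab rule is what the area-per-slice protocol defines; the difference
is below the segmentation error for any realistic stack).  Areas come from
a CSV or from binary masks via pixel counting, so no imaging dependency is
mandatory.

## Statistics

Mann–Whitney (two independent groups), Kruskal–Wallis (>2), Wilcoxon
signed-rank (paired); exact p where n ≤ 20/25 without ties, asymptotic
otherwise, with the method recorded per row.  All summaries are M ± m
(mean ± SEM).  No multiple-testing correction is applied, matching the
source analysis conventions; the comparisons table should be read
accordingly.  Group means are unweighted means of per-session values; the
per-layer SEM can be taken over sessions or over channels — both
aggregations are computed and labeled (`pool=` in `summarize_csd`), since
the choice materially changes the n.

## Problem sizes and tolerances

The test suite and `scripts/acceptance.py` choose sizes where the targeted
effect is resolved with wide margin: 2 h wave-count sessions are generated
at 500 Hz and analysed at a 100 Hz DC rate (the wave band is <1 Hz; counts
and the 86 min period are insensitive to rate, and the period tolerance of
0.1 min is ~15× the observed error); MUA sessions use the full 32 kHz for
300 s (rate SE ≈ 0.16 s⁻¹ at 32 s⁻¹) or shorter windows for the onset
increment; SEP sessions are generated natively at 4 kHz with 50 stimuli.
Morphometry checks on noiseless waveforms assert to one 1 kHz sample
(amplitude to 0.01 mV); stochastic rate recoveries assert to 3 standard
errors of the generated quantity.

## Known limitations

- Onset localization is degenerate on constant-slope fronts (above).
- The recovery timeline measures single-trial amplitudes; at realistic
  noise it needs per-minute binning to be readable, and a layer with no
  responsive channels yields NaN bins rather than zeros.
- No artifact rejection beyond QC flags; no electrode-drift correction; no
  2-D wavefront reconstruction (the probe is 1-D); no spike sorting — MUA
  only, by design.
- `detect_mua` requires a sample rate ≥ twice the band's upper edge and
  refuses low-rate sessions rather than silently narrowing the band.
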