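# Methods

`pwavekit` implements the analysis chain for pontine P-waves (PGO-type
field deflections) and their state-dependent coupling to hippocampal
sharp wave-ripples (SWRs) and theta oscillations, together with a
synthetic-session generator that provides ground truth for every stage.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## Coordinate and labelling conventions

Time is continuous seconds from session start (`t0 = 0` by default).
Epochs, episodes and events are half-open intervals `[onset, offset)`;
an event exactly on a 4-s epoch boundary belongs to the later epoch.
Each detected event carries the vigilance state (WAKE/NREM/REM) of the
epoch containing its peak time. The assignment rule for
boundary-spanning events is a package convention — upstream literature
does not fix one — and only affects events within one envelope window of
an epoch edge.

## P-wave detection

The two pontine electrodes are subtracted (removing volume-conducted
activity), band-passed 5–30 Hz with a zero-phase third-order Butterworth
filter, and reduced to a 10-ms non-overlapping RMS envelope. The
detection threshold is mean + 5 SD of the envelope over the *longest
NREM episode*, the cleanest available estimate of the noise floor.
Maximal supra-threshold envelope periods become candidates; candidates
separated by less than `merge_gap` (default 50 ms — short enough to
preserve the ~150 ms doublets that real P-wave clusters produce) are
fused. A candidate is vetoed as a movement artifact if the EMG 10-ms RMS
envelope exceeds mean + 3 SD (statistics from the same NREM segment)
anywhere within ±50 ms of the candidate. The event time is the most
negative filtered sample within the candidate (P-waves are
trough-dominant on the differential derivation); the amplitude is that
trough value.

Because every threshold is derived from the data, the detected event set
is invariant under a common positive rescaling of all inputs and shifts
exactly under a common delay — both are enforced by tests.

Whether the original analyses thresholded the instantaneous filtered
amplitude or its RMS envelope is ambiguous; both are supported
(`threshold_mode`), the envelope being the default since the threshold
itself is defined in envelope units.

A note on false positives: with a mean + 5 SD envelope threshold,
band-limited Gaussian noise alone crosses at a small but nonzero rate
(~1e-4 per window), i.e. a handful of spurious detections per 10 minutes
of pure noise. This is intrinsic to the rule, not a bug; tests bound the
false-positive rate rather than asserting zero.

## SWR detection

CA1 LFP is band-passed 80–250 Hz (zero-phase third-order Butterworth)
and converted to a centered 20-ms sliding RMS envelope at sample stride,
so onset/offset resolution equals the sampling period; edge windows are
truncated. Envelope mean/SD over the whole recording define two
thresholds: mean + 5 SD seeds candidates, mean + 2 SD sets their
boundaries (searched at most 500 ms from the seed to bound pathological
low-variance stretches). Overlapping candidate intervals are merged with
the peak at the envelope maximum of the merged span, and — last, after
merging — events shorter than 20 ms or longer than 200 ms are discarded.
Whether the original envelope statistics were global or per-state is not
documented; global is the default, with a per-state option
(`stats_state`).

For multichannel probes, `select_channel` runs the detector per channel
and picks the channel maximizing the NREM/REM SWR-rate ratio (the CA1
pyramidal-layer signature); zero REM rate counts as infinitely
preferred, ties break toward the higher absolute NREM rate.

`coupled_swr_partition` splits SWRs by whether a P-wave falls within a
window (default 30 ms, boundary-inclusive, peak-to-peak) and supports a
window sweep (20–60 ms) for robustness checks.

## Coupling statistics

**Theta phase.** Two hippocampal channels are subtracted, filtered with
a linear-phase Kaiser FIR (4–10 Hz pass band, 1 Hz transitions, 0.01 dB
pass-band ripple, 50 dB stop-band attenuation; the Kaiser design couples
the two ripple specifications, so the stricter one is used) applied
forward–backward, and the instantaneous phase taken from the analytic
signal. Convention: phase 0 at filtered-signal peaks, ±π at troughs,
increasing in time. Since phase conventions differ across studies (and
phase preference varies across electrodes in vivo), only
within-convention comparisons are meaningful. The FIR is applied by FFT
convolution; at 1 kHz the design is ~3500 taps, far too long for
direct-form filtering over hour-long traces.

**Circular statistics.** The resultant vector length r is the magnitude
of the mean unit phasor; the Rayleigh test uses Z = n r² with the
standard finite-n series approximation for p. Tests verify r against a
brute-force phasor sum to machine precision, the Bessel-ratio limit
r → I₁(κ)/I₀(κ) for von Mises samples, and uniformity of p under the
null (KS test over 1000 replicates).

**Band power and event-triggered profiles.** Band power is the squared
sliding RMS of the band-filtered trace (20 ms window for 80–250 Hz;
one cycle of the low band edge for theta). Event-triggered profiles are
averaged over events in a (−3, +3) s window and z-scored by the mean/SD
of the *averaged* profile in the (−3, −2) s baseline (per-event
normalization is available); theta-power comparisons use the
(−1000, −500) ms vs (−250, +250) ms window means. Asymmetry and
modulation indices are (post − pre)/(post + pre) over ±250 ms, with
pre/post averaged across events before indexing; the index is NaN when
pre + post = 0. Negative values mean suppression after the event.

**PETHs.** Per-unit event-aligned rates use 10-ms bins (optionally
smoothed with a 20-ms Gaussian, a display convention) and are z-scored
against the unit's own whole-window profile — the normalization baseline
is not documented upstream, so whole-window is the default. Sort orders
by peak latency and by first-PC score are returned.

**SDR.** For each event, Welch PSDs (128-sample segments, 50% overlap at
1 kHz; segment length shrinks with the snippet) of the ±250 ms X and Y
snippets give S_XX, S_YY, and

    rho_X→Y = <S_YY> / (<S_XX> · <S_YY/S_XX>),

with ⟨·⟩ the mean over frequencies and frequencies where the denominator
PSD falls below 1e-6 of its maximum excluded. The printed source formula
for this statistic is typographically corrupt; this reconstruction is the
one consistent with the spectral-independence-criterion construction,
gives exactly (1, 1) for identical traces, is scale-invariant, and
recovers the true direction in ~100% of simulated causal pairs. By
Cauchy–Schwarz, rho ≤ 1 for the anti-causal direction when X is
white-like, which is what makes the decision rule work.

**Episode-duration model.** Episode duration is regressed on event rate
with a per-recording random intercept (y = Xβ + Zb + ε), fit by maximum
likelihood through `statsmodels MixedLM`. Simulation shows nominal ~95%
CI coverage of the true slope (β = 60 recovered in ≥90/100 datasets of
8 recordings × 20 episodes).

## Photometry

Interleaved 470/405 nm excitation at an effective 40 Hz is reduced to
one median per LED pulse (robust to within-pulse glitches). Each channel
is de-bleached by subtracting a least-squares single exponential
a·exp(−t/τ)+c (fallback: linear detrend, flagged; near-constant traces
are flagged unidentifiable), low-passed below 4 Hz (zero-phase FIR), and
the isosbestic channel regressed out by OLS. The output is
470 − (slope·405 + intercept), so calcium transients are positive — the
source text's subtraction order would invert polarity relative to its
own figures, and the positive convention is used deliberately.
Event-triggered responses are z-scored per event over the display window
(|z| = 1.96 bounding pointwise p = 0.05).

## The synthetic session generator

`synth.generate_session` builds every channel the pipeline consumes,
with the generating parameters as ground truth. The defaults encode the
study conditions the analyses assume:

- **States**: semi-Markov sequence, exponential episode durations
  rounded to 4-s epochs (means WAKE 120 s, NREM 160 s, REM 60 s —
  plausible head-fixed mouse sleep architecture), with a
  WAKE→NREM→REM ordering bias (NREM→REM probability 0.6).
- **Background**: 1/f Gaussian noise (α = 1, SD 1) per channel.
- **P-waves**: Poisson per state at 0.8 Hz (REM) / 0.09 Hz (NREM) /
  0 (WAKE) — the empirically reported rates — with 25% doublets at
  150 ms spacing and a 120 ms minimum separation. The waveform is a
  trough-dominant difference of Gaussians, ~100 ms total width, injected
  on one pontine channel so the differential isolates it. Amplitude is
  specified as the *filtered* trough depth in units of the 5–30 Hz
  background RMS (the detection filter attenuates the raw template
  roughly twofold, so calibrating after filtering is what fixes the
  operating point); the default (8×) sits near twice the detection
  threshold, matching the visual prominence of real P-waves. During REM,
  event times are nudged within one theta cycle so their phases follow a
  von Mises law (default μ = 1 rad, κ = 1); κ = 0 yields uniform phases.
  An optional linear within-episode rate ramp reproduces the rise of
  P-wave frequency across REM episodes.
- **Ripples**: Poisson in NREM (0.5 Hz; 0.02 Hz REM), 150 Hz bursts of
  40–120 ms on a slow sharp-wave deflection, amplitude 12× the 80–250 Hz
  background RMS. Bursts use a short-taper Tukey envelope rather than a
  full raised cosine: a sharp rise keeps the injected onset/offset
  physically well defined, so boundary-timing recovery (±10 ms) is a
  meaningful test. Decoy bursts of 10 ms (at reduced, 6×, energy — as
  brief spurious transients are) and 250 ms (full amplitude) are planted
  as negative controls for the candidate threshold and the duration
  filter. Optional coupling mechanisms: a fraction of NREM P-waves can
  be relocated into ripples, and co-occurring ripples truncated just
  after the P-wave — the mechanism hypothesized to shorten coupled SWRs.
- **EMG**: mains-locked pickup plus broadband noise, amplitude-modulated
  by slow muscle tone with state-dependent levels (WAKE 1.3, NREM 1.0,
  REM 0.6 — REM atonia), plus phasic WAKE bursts (0.2 Hz, 0.5–2 s, 4×).
  The composition matters: it makes the 10-ms window RMS vary with
  physiology rather than with the RMS estimator's own sampling noise,
  as in real recordings, so the mean + 3 SD veto threshold sits well
  above quiet-sleep fluctuations.
- **Photometry**: 40 Hz traces with bleaching a = 5, τ = 600 s, c = 1;
  transients (1 − e^{−t/0.1})e^{−t/1.5} at 0.05 Hz, amplitude 0.3; a
  <1 Hz shared motion artifact (SD 0.05, scaled 0.8 on the 405 channel);
  white measurement noise SD 0.01.

`generate_bilateral` shares a configurable fraction of P-waves across
hemispheres under Gaussian timing jitter; `generate_coupled_pair`
produces Y = IIR/FIR-filtered X (stability-checked) plus noise for
directionality tests.

### What the synthetic validation does and does not show

The generator reproduces the *statistical structure* the analyses
assume — state-dependent rates, clustering, phase locking, burst
morphology in the right bands, shared artifacts — under stationary
Gaussian backgrounds with known, well-separated events. It does not
model electrode drift, non-stationary noise, spike contamination of
LFPs, theta frequency/amplitude meandering, overlapping ripple chains,
or real sleep-architecture statistics. Passing tests therefore establish
correctness of the algorithms at their stated operating points (e.g.
troughs ≳ 1.5× threshold), not detector performance on marginal-SNR
in-vivo data, and the package deliberately does not attempt to reproduce
any specific in-vivo summary values.

## Numerical choices and degenerate inputs

- Zero-phase filtering via `sosfiltfilt` (IIR) or symmetric-FIR FFT
  convolution with odd reflection padding; both square the magnitude
  response, which is immaterial for envelope thresholds (data-derived)
  and phase (zero net).
- Non-overlapping RMS windows drop a trailing partial window; sliding
  RMS truncates edge windows (divisor = samples actually present).
- States with zero duration yield NaN rates (undefined ≠ 0); fewer than
  two events yield an empty interval vector with NaN median; zero
  variance yields NaN correlations or excluded units, always counted.
- Poisson thinning enforces minimum separations; injected event counts
  therefore sit a few percent below the nominal rate×duration, and
  doublets add ~doublet_prob extra events per primary — tests account
  for both.
- Problem sizes: the reference validation session is 1 h at 1 kHz
  (~500 P-waves, ~700 ripples); simulation-based checks use 100
  replicates (SDR pairs, mixed-model datasets, Rayleigh nulls), and
  mechanism-specific sessions are 25 min. These sizes give binomial
  uncertainties comfortably inside the asserted margins.
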