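# pwavekit

Detection and state-dependent coupling analysis of **pontine P-waves**
(PGO-type field potentials), **hippocampal sharp wave-ripples (SWRs)**
and **theta oscillations** in rodent sleep electrophysiology.

P-waves are ~100 ms trough-dominant deflections generated in the pons,
classically during REM sleep but also present, sparsely, in NREM sleep.
Their interplay with hippocampal rhythms is state-dependent: during REM
they phase-lock to theta (4–10 Hz), while during NREM they coincide with
— and appear to cut short — sharp wave-ripples (80–250 Hz, 20–200 ms),
events central to memory consolidation. `pwavekit` is aimed at sleep /
systems-neuroscience groups who record pontine EEG/LFP together with
hippocampal LFP, EMG, spike trains and fiber photometry, and want a
tested, scriptable version of this analysis chain.

## What it implements

- **Detectors.**
  - *P-waves*: bipolar subtraction → zero-phase 5–30 Hz band-pass →
    10 ms RMS envelope → threshold at mean + 5 SD of the envelope over
    the longest NREM episode; candidates merged across <50 ms gaps,
    vetoed when the EMG RMS envelope exceeds mean + 3 SD nearby; event
    time at the filtered trough.
  - *SWRs*: 80–250 Hz third-order Butterworth → 20 ms sliding RMS →
    dual thresholds (mean + 5 SD seeds, mean + 2 SD bounds) → merge →
    keep durations in [20, 200] ms; CA1 channel chosen by the NREM/REM
    SWR-rate ratio.
- **Coupling statistics.** Hilbert theta phase of a Kaiser-FIR-filtered
  differential LFP; resultant vector length *r* and Rayleigh test;
  event-triggered band-power profiles z-scored on a −3…−2 s baseline;
  asymmetry/modulation indices (X_post − X_pre)/(X_post + X_pre) over
  ±250 ms; spike PETHs with peak-latency and PC-score sort orders;
  within-episode quartile rate profiles; the spectral dependency ratio
  ρ_X→Y = ⟨S_YY⟩/(⟨S_XX⟩·⟨S_YY/S_XX⟩) from Welch PSDs of ±250 ms
  snippets; and a random-intercept mixed model relating episode duration
  to event rate.
- **Photometry.** Interleaved 470/405 nm processing: per-pulse medians
  (40 Hz), single-exponential de-bleaching, <4 Hz low-pass, isosbestic
  regression, event-triggered z-scored responses.
- **Synthetic sessions.** `pwavekit.synth` generates full multichannel
  sessions (pontine pair, hippocampal pair, EMG, hypnogram, photometry)
  with every injected structure recorded as ground truth — the basis of
  the entire test suite. See `docs/methods.md` for the generative model.

## Worked example

```python
import numpy as np
from pwavekit import synth
from pwavekit.core import REM, NREM, event_rate_by_state
from pwavekit.pwave_detect import run_pwave_detection
from pwavekit.swr_detect import detect_swrs, coupled_swr_partition
from pwavekit.coupling import theta_phase, phase_locking

cfg = synth.SessionConfig(duration=1200.0, seed=2)
ses = synth.generate_session(cfg)

pwaves = run_pwave_detection(ses.signals["pons_a"], ses.signals["pons_b"],
                             ses.signals["emg"], ses.hypnogram)
swrs = detect_swrs(ses.signals["hpc_a"], ses.hypnogram)
rates = event_rate_by_state(pwaves.select_state(NREM, REM), ses.hypnogram)
print(f"P-waves: {len(pwaves)} detected ({len(ses.truth.pwave_times)} injected)")
print(f"  rate REM = {rates[REM]:.2f} Hz, NREM = {rates[NREM]:.3f} Hz")
print(f"SWRs: {len(swrs)} detected, median duration {np.median(swrs.durations)*1000:.0f} ms")

phase = theta_phase(ses.signals["hpc_a"], ses.signals["hpc_b"])
lock = phase_locking(phase, pwaves.select_state(REM))
print(f"theta locking: r = {lock.r:.2f}, mean phase = {lock.mean_phase:.2f} rad, "
      f"Rayleigh p = {lock.p:.2g} (n = {len(lock.phases)})")

coupled, _ = coupled_swr_partition(swrs, pwaves, window=0.030)
print(f"coupled SWRs: {len(coupled)}/{len(swrs)} within 30 ms of a P-wave")
```

Output:

```
P-waves: 147 detected (149 injected)
  rate REM = 0.78 Hz, NREM = 0.099 Hz
SWRs: 308 detected, median duration 79 ms
theta locking: r = 0.47, mean phase = 0.78 rad, Rayleigh p = 1.9e-08 (n = 78)
coupled SWRs: 6/308 within 30 ms of a P-wave
```

Reading it: the detector recovered essentially all injected P-waves; the
REM rate is an order of magnitude above the NREM rate (the generator's
study conditions, 0.8 vs 0.09 Hz); REM P-waves are significantly
phase-locked to theta (r = 0.47 against the injected von Mises coupling
at μ = 1 rad); and only ~2% of SWRs coincide with a P-wave within
30 ms — chance-level coupling, since this configuration injects no
P-wave/ripple dependency.

A command-line interface mirrors the library
(`pwavekit simulate | detect-pwaves | detect-swrs | couple | photometry`);
e.g. `pwavekit simulate --seed 3 --out session/` writes signals,
hypnogram and ground truth in the package's on-disk formats.

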