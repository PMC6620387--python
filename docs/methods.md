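# Methods

This note documents the models and procedures implemented in `lateralize`,
the defaults that matter, the design choices made where the published
procedures leave room, and what the synthetic validation studies do and do
not establish.

## Task model and behavioral event definitions

The right–left pedal task is represented by per-pedal relative position
traces in % of full range on a uniform grid (default 1000 Hz).  The task
rules implemented:

- **Holding period**: both pedals inside the holding area (0–30 %,
  boundary inclusive) continuously for at least 1.0 s.
- **Release event**: first sample after the holding interval at which
  either pedal exceeds 30 %.  A simultaneous dual-pedal crossing is labeled
  bilateral and excluded from unilateral analyses.
- **Release onset**: scanning backward from the event, the start of the
  final contiguous run of samples exceeding (pre-release baseline + 5
  percentage points).  The baseline is the mean position over the 200-ms
  window ending 100 ms before the release event.  Ending the window 100 ms
  before the event (rather than at the end of the holding interval) keeps
  the early part of the release ramp — which is still inside the holding
  area — out of the baseline; with a ~150-ms release ramp, a baseline
  window touching the event would inflate the baseline by several percent
  and bias the onset late.  Both window ends are parameters.
- **Outcomes**: attempts shorter than 1 s are immature; completed attempts
  are correct iff the chosen pedal matches the block side.  Block
  completion requires ≥ 30 correct trials and ≥ 8 of the last 10 correct;
  trials-to-criterion counts post-change trials until the trailing-10
  correct rate first reaches 50 %.

## Spike-train analyses

All event-aligned analyses use release onset as time 0 and the window
−1.0…+0.5 s with 20-ms bins.  Ongoing rate excludes −1…+0.5 s around each
movement (overlaps merged).  Spikes within 1 s after any optical stimulus
are removed first.  ISI CV uses the population SD over all post-exclusion
intervals.  Waveform metrics: onset is the first sample exceeding 5 % of
the absolute peak; duration runs from onset to the first positive peak;
width is the time above half of the positive peak; RS iff duration
> 0.6 ms (strict).

**Task relevance.** Spike positions inside the window are pooled across
trials and compared against the uniform distribution on the window with a
one-sample KS test; the p-value is the task relevance index and p < 10⁻⁶
marks task-related activity.  (A one-sample test replaces a two-sample
comparison against sampled uniform surrogates: it is deterministic and
asymptotically equivalent, which matters next to a hard 10⁻⁶ threshold.)
Units need ≥ 20 trials and ≥ 250 in-window spikes per side; failing units
are excluded with a reason code.  The analysis window for the uniform
reference is the same −1.0…+0.5 s used everywhere else.

**Hold/Go typing.** Units whose PETH peak falls after release onset are
Go (post-movement).  For the rest, trials of the preferred side are split
by holding time (1.0–1.5, 1.5–2.0, 2.0–2.5, 2.5–3.0 s) and the time each
holding-bin PETH first crosses 75 % of the pooled PETH peak is regressed
on the bin center; slope < 0.5 → Hold, otherwise Go.  Two implementation
choices deserve note:

- Per-bin PETHs are built **release-aligned** over [−bin_lo, +0.5] s and
  the crossing is then re-referenced to holding onset by adding the bin
  center.  Aligning trials on holding onset directly would smear the
  movement-locked bump by the within-bin holding-time spread (0.5 s),
  pushing it below any 75 % level.  In this frame a holding-locked step
  crosses at a constant time (slope ≈ 0) and a movement-locked bump
  crosses one second later per second of holding (slope ≈ 1), matching
  the direction of the 0.5 threshold.
- The crossing detector smooths the per-bin PETH with a σ = 40 ms Gaussian
  and requires the level to be exceeded for ≥ 80 ms.  The display
  smoothing elsewhere stays at the conventional σ = 12.5 ms; the heavier
  smoothing here reflects that each holding bin holds only a quarter of
  the trials, and a first-crossing detector is an extreme-value statistic
  that needs baseline noise held well below the level.  With these
  defaults, step- vs bump-profile units with 15 Hz modulation and 40
  trials/side are typed with ≥ 95 % accuracy; both constants are
  parameters.

**Laterality.** For Go-type units, per side: FR_peak is the mean rate
over the 15-bin (±150 ms) window centered at the PETH maximum (located
independently per side, truncated at window edges, earliest bin on ties);
FR_baseline is the mean rate over −1000…−700 ms.  c and i are
FR_peak/FR_baseline − 1 for contralateral and ipsilateral trials and the
index follows the piecewise formula (ratio branch when both are positive,
±1 when only one side is excited, undefined — excluded with a reason
code — when both are suppressed; boundary cases with c or i = 0 fall to
the ratio branch as its continuous limit).  By default FR_baseline pools
both sides' trials: holding-period activity precedes the side choice, so
the per-side baselines estimate the same quantity, and the shared
denominator cancels correlated error in c and i.  At 60 trials/side and
5 Hz baseline this halves the recovery error of the index
(median |error| ~0.06 vs ~0.11 per-side on the 200-unit validation grid);
`baseline_mode="per_side"` restores the per-side variant.

## Collision-test identification

For each stimulated unit and site: the detection window is where the
averaged control trace diverges from the averaged collision-test trace by
more than 3× the test-trace SD (earliest contiguous lobe, padded 0.5 ms;
manual override accepted).  The ROC cutoff on the most-negative in-window
amplitude maximizes Youden's J (the operating-point rule is not published;
J is the symmetric default).  Eligibility: control spike probability
≥ 0.5 (inclusive) and test probability below half of control.  The
collision itself is confirmed by a Pearson χ² (no continuity correction)
on the 2×2 spike/no-spike × control/test table at p < 0.05.  Latency is
the median and jitter the Q3−Q1 range (linear-interpolation quantiles) of
detected peak positions, with the constant-latency test at 0.5 ms.
Frequency-following requires the second pulse of 100- and 200-Hz pairs to
be answered at ≥ 50 % of the first pulse's probability; an untested pair
skips the test without failing the unit.  A unit passing from both sites
is flagged as a conflict and excluded from the IT/PT groups.

## Synthetic-session generator

The generator emulates the study conditions and is itself tested code:

- **Behavior**: alternating reward blocks (default 4 blocks × 30 completed
  trials; 80 % correct, 10 % immature attempts), holding times uniform on
  1–3 s, 150-ms release ramps, ±0.5 % slow within-hold pedal movement.
  Ground-truth release onsets/events are computed analytically from the
  ramp and the same baseline definition the parser uses.
- **Spikes**: inhomogeneous Poisson by thinning with a 2-ms absolute
  refractory period (the simplest process matching CV ≈ 1 regimes and the
  sorting refractory criterion).  Go units add a Gaussian rate bump
  (default σ 50 ms, centered 50 ms before release onset) with per-side
  amplitudes; Hold units add a rate step spanning the holding period;
  untuned units are homogeneous.  Ground-truth laterality is computed
  analytically from the configured profile *through the analysis
  definitions* (the mean of a Gaussian bump over the ±150-ms peak window
  is 0.42× its center amplitude, so the true index reduces to
  (A_c − A_i)/(A_c + A_i) on the ratio branch) — making recovery unbiased
  up to Poisson noise rather than conflating definition and estimator.
- **Stimulation**: snippet-level simulation (30 ms at 20 kHz) with a
  negative-going template at the unit's antidromic latency.  Control
  events avoid spontaneous spikes in the preceding latency + refractory
  window and contain the spike with the configured reliability (default
  0.9, a free parameter: reliability distributions are not published).
  Test events are triggered 1 ms after a spontaneous spike; the antidromic
  spike is annihilated whenever trigger_delay < latency + refractory —
  always, with these defaults.  Orthodromic (non-projection) responders
  carry 1-ms latency jitter and weak paired-pulse following (0.2).
  Stimulation occupies a dedicated post-task epoch so the 1-s post-stimulus
  blanking does not consume trial spikes.  Default latencies: IT 11.7 ms,
  PT 6.9 ms.
- **EMG**: Gaussian noise whose SD is scaled by a burst envelope starting
  250 ms before each release onset (10× baseline SD for 0.5 s, decaying),
  at 10 kHz.  The envelope switch-on is the ground-truth onset.
- **LFP**: 1/f-amplitude (pink) background at 1000 Hz plus a 20-Hz
  sinusoid whose amplitude depends on condition — defaults H 0.5, NL 0.5,
  L 0.7 a.u., reproducing the ~1.9× lesioned/non-lesioned β-power ratio —
  and a shared pink component (weight 0.4) controlling inter-areal
  coherence.
- **Determinism**: each component (behavior, spikes, snippets, EMG, LFP)
  draws from its own stream split off the session seed; a fixed config and
  seed reproduce the session exactly, and toggling one component leaves
  the others untouched.

For condition-level studies, `condition_unit_specs` draws true laterality
indices from N(μ_cond, 0.3) clipped to ±0.9 with μ = {H: 0.38, NL: 0.40,
L: 0.05}, patterned qualitatively on the published M1 regular-spiking
group means (lesion abolishes most of the contralateral preference; the
non-lesioned hemisphere keeps or slightly strengthens it).

## Signal processing choices

- "EMG power" per 1-ms bin is the mean rectified amplitude in the bin (no
  bin-level definition is published).
- LFP spectra: one Hann-windowed periodogram per 2-s segment, averaged;
  β-band power is the integral of the PSD over 15–35 Hz (sum of bins ×
  Δf; a mean-over-bins option exists).  Parseval holds within windowing
  tolerance (~5 %).
- Segments are bandpassed 0.5–100 Hz (4th-order Butterworth, zero-phase)
  and rectified by default, following the published order; rectification
  is unconventional for spectral analysis (it moves a 20-Hz sinusoid's
  energy to 0/40/80 Hz), so `do_rectify=False` disables it and the
  β-scaling validation uses raw segments.
- Wavelet coherence: complex Morlet CWT (PyWavelets `cmor1.5-1.0`, 40
  log-spaced frequencies 4–100 Hz), cross/auto spectra smoothed over time
  (Gaussian, one cycle per scale) and across 5 adjacent scales, clipped to
  [0, 1].  Identical or proportional signals give exactly 1; independent
  noise averages ≈ 0.3 at these smoothing spans (the bias of smoothed
  coherence estimates, not a defect — comparisons should be relative).

## Validation studies and their scope

`scripts/acceptance.py` (and `tests/test_acceptance.py`) run: the
laterality branch values; self-coherence normalization; 200-unit
laterality recovery (grid of true indices in ±0.8, 60 trials/side,
baseline 5 Hz, max modulation 25 Hz → median |error| ≈ 0.06); Hold/Go
typing of 30+30 step/bump units (15 Hz modulation, 40 trials/side);
the task-relevance false-positive rate on 1000 untuned units; collision
identification of 25 IT + 25 PT + 50 orthodromic units (50 control +
50 test events each) with the PT < IT latency ordering; the closed-form
χ² = 64 table; EMG onset recovery at 8× SD bursts plus the false-onset
rate on 1000 noise draws; β-power quadratic scaling; and the H/NL/L
contrast with 100 units per condition.  Problem sizes are chosen so the
whole battery runs in well under a minute of CPU apiece.

These studies validate the *estimators against the generator's ground
truth*.  The generator's Poisson spiking, noise-free-ish pedal
trajectories, stationary baselines, template-in-noise snippets and
burst-envelope EMG are idealizations: passing them shows the analysis
recovers what it is defined to recover, not that real tetrode recordings
meet the assumptions (spike-sorting errors, non-stationary baselines,
stimulus artifacts and movement artifacts are out of scope, as are
spike sorting itself and histology).

## Known limitations

- The laterality index is undefined for units suppressed on both sides;
  such units are counted and excluded, not imputed.
- The automated detection-window rule (3× SD dissociation) stands in for
  the published by-inspection procedure; a manual window override is
  accepted.
- Bilateral-movement trials are not simulated by default and bilateral
  releases are excluded from analysis rather than modeled.
- Group statistics assume independent units; no multiple-testing
  correction is applied across units (the fixed 10⁻⁶ threshold is the
  published rule).
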