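# lateralize

Analysis of lateralized motor-cortex activity in the rat **right–left pedal
task**, built for systems neuroscientists studying how primary (M1) and
secondary (M2) motor cortex represent contralateral versus ipsilateral
forelimb movements — in healthy animals and in the unilateral 6-OHDA
(hemiparkinsonian) model, where the normal contralateral preference
degrades.  Because the original recordings are not publicly deposited, the
package ships a first-class synthetic-session generator with per-unit
ground truth, so every analysis stage is testable end to end.

## What it computes

A session consists of pedal-position traces (0–100 % of range), isolated
single units (spike times + mean waveforms), optogenetic stimulation logs,
and optional EMG/LFP.  The pipeline:

1. **Behavior** — holding periods (both pedals ≤ 30 % for ≥ 1 s), release
   events (first crossing above 30 %), release onsets (last time the pedal
   first exceeded its pre-release baseline by 5 percentage points), trial
   outcomes (correct / error / immature), choice-rate series, block rules
   and trials-to-criterion.
2. **EMG / LFP** — rectified EMG onset (first run of ≥ 10 consecutive 1-ms
   bins above baseline mean + 5 SD, baseline −1000…−700 ms), EMG peak
   change; LFP ±1 s segments around release, FFT power spectra with β-band
   (15–35 Hz) power, and Morlet wavelet coherence between M1 and M2.
3. **Unit metrics** — ongoing rate (excluding −1…+0.5 s around movements),
   ISI CV, spike duration/width with the RS/FS rule (RS iff duration
   > 0.6 ms), 20-ms-bin PETHs over −1.0…+0.5 s around release onset.
4. **Task classification** — the task relevance index (one-sample KS
   p-value of pooled in-window spike positions against uniformity;
   task-related iff p < 10⁻⁶ on either side), contralateral / ipsilateral /
   bilateral categories, and Hold/Go typing: units peaking after release
   are Go (post-movement); otherwise the slope of the 75 %-of-peak crossing
   time against holding time (bins 1.0–1.5…2.5–3.0 s) decides, with
   slope < 0.5 → Hold.
5. **Laterality** — per side, c, i = FR_peak / FR_baseline − 1 with
   FR_peak the mean rate over peak ± 150 ms and FR_baseline over
   −1000…−700 ms, and

   ```
                ⎧ (c − i)/(c + i)   if c > 0 and i > 0
   laterality = ⎨ +1                if c > 0 and i < 0
                ⎩ −1                if c < 0 and i > 0
   ```

   ranging from −1 (ipsilateral) to +1 (contralateral preference).
6. **Projection identification** — the light-induced spike-collision
   (Multi-Linc) pipeline: detection window from control/test trace
   dissociation, ROC amplitude cutoff, control/test spike probabilities
   (eligible iff p_control ≥ 0.5 and p_test < p_control/2), 2×2 χ²
   collision test (p < 0.05), constant-latency test (quartile jitter
   ≤ 0.5 ms) and frequency-following (paired pulses at 100/200 Hz).
   Contralateral-cortex stimulation identifies IT neurons, ipsilateral-pons
   stimulation identifies PT neurons.

Group-level comparisons (t, Mann–Whitney, Wilcoxon, χ², KS,
Kruskal–Wallis + Dunn, ANOVA + Tukey–Kramer) are thin wrappers over
scipy/statsmodels.

## Worked example

```python
from lateralize import SessionAnalysis, SimConfig, StimSpec

model = SessionAnalysis.from_simulation(SimConfig(seed=1, stim_spec=StimSpec()))
results = model.fit()
print(results.summary())
```

```
Session analysis summary
========================
area/condition: M1/H
trials: 131 total, 120 completed, correct rate 83.3%
right bias: +0.8%
units: 11
task-related: 9 (Go 7, Hold 2)
RS units: 8
FS units: 3
laterality index (Go): mean +0.422 (n=7)
identified projections: IT 1, PT 1
```

The session held 131 attempts (120 completed at 83.3 % correct, near the
80 % generator setting), nine of eleven units passed the p < 10⁻⁶ task
relevance threshold, and the two simulated projection units were correctly
identified by the collision test.  `results.units` is a per-unit DataFrame
(classification, laterality, identification evidence):

```
        cell_class functional_type  side_category  laterality_index projection_class
unit_id
u000            RS              Go  contralateral          0.464706         untested
u001            RS              Go  contralateral          0.727273         untested
u002            RS              Go    ipsilateral         -0.445055         untested
u003            RS              Go      bilateral          0.072398         untested
u004            FS              Go  contralateral          0.713483         untested
u005            RS            Hold      bilateral               NaN         untested
```

(Hold-type units get no laterality index: only the phasic activity of
Go-type units is lateralized.)  A thin CLI wraps the same pipeline:
`lateralize simulate`, `lateralize analyze`, `lateralize report`.

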