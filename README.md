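# dfssmvep

Dual-frequency steady-state motion visual evoked potential (SSmVEP)
stimulus coding and bifold canonical correlation decoding for visual
brain-computer interfaces.

Motion-based SSmVEP stimuli (a circle that periodically resizes or
rotates) avoid the eye strain of flickering SSVEP targets, but pay for it
with lower recognition accuracy and information transfer rate (ITR).  One
way to claw that back is to embed **two simultaneous motions — hence two
stimulation frequencies — in a single target**, without lengthening the
trial.  This package implements that paradigm end to end for researchers
and BCI engineers:

- **Stimulus coding** — binary frame sequences `S(f, i) = square(2π f i / Rr)`
  realisable on a monitor with refresh rate `Rr` (representable
  frequencies bounded by `f ≤ Rr/k` for `k` frames per half-cycle), and the
  dual-frequency coding algorithm: given base frequencies
  `f₁ < … < f_N` (N ≥ 5), midpoints `gᵢ = (fᵢ + fᵢ₊₁)/2` (plus
  `g_N = f_N + M`, `M = min gap/2`) are paired to targets as
  `a = (f₁, f₃, …, f_N, f₂)`, `b = (g_{N−1}, g₁, …, g_{N−2}, g_N)`, so that
  no two targets share more than one spectrally adjacent frequency
  (checked by an explicit adjacency audit).
- **Preprocessing** — zero-phase Chebyshev type-I band-pass (2–40 Hz) and
  half-open epoch windows.
- **Decoding** — standard CCA against sin/cos harmonic references

  `y_f = [cos 2πft, sin 2πft, …, cos 2πN_h ft, sin 2πN_h ft]ᵀ`,

  and **bifold CCA (BCCA)**: each target `(f₁, f₂)` owns the triplet
  `y₁`, `y₂`, and `y_c = [y₁; y₂; cos 2π(f₁+f₂)t; sin 2π(f₁+f₂)t]`; the
  target score is `ρ_a = (ρ₁ + ρ₂ + ρ_c)/3` and the prediction the argmax
  over targets.  Welch-PSD utilities support choosing `N_h` empirically.
- **Evaluation** — ITR
  `(60/T)[log₂K + σ log₂σ + (1−σ) log₂((1−σ)/(K−1))]` in bits/min,
  K×K confusion matrices with per-class sensitivity, specificity,
  precision and accuracy, and accuracy/ITR sweeps over epoch windows.
- **Synthetic EEG** — a ground-truthed generator emulating a 10-subject ×
  2-session × 5-target × 4-trial protocol (3.5 s trials, 500 Hz, channels
  Po3 Po4 Po7 Po8 Pz Oz): harmonic evoked components at both pair
  frequencies inside pink + white + alpha background noise with spatial
  correlation across channels, so the whole pipeline is testable with no
  recorded data.

## Worked example

Derive the plan for base frequencies 5–9 Hz, then simulate and decode a
small two-subject dataset at −8 dB SNR:

```sh
dfssmvep code-frequencies --freqs 5,6,7,8,9
```

prints the pair assignment (primary, secondary):

```json
{"base_frequencies": [5, 6, 7, 8, 9], "midpoints": [5.5, 6.5, 7.5, 8.5, 9.5],
 "margin": 0.5, "adjacency_audit": "pass",
 "pairs": [[5, 8.5], [7, 5.5], [8, 6.5], [9, 7.5], [6, 9.5]]}
```

Each target oscillates at one base frequency (radial zoom) and one
midpoint (rotation); the margin M = 0.5 Hz keeps all ten frequencies
distinct, and the audit confirms no two targets share more than one
adjacent frequency.  From Python:

```python
from dfssmvep import run_pipeline

report = run_pipeline({
    "plan": {"base_frequencies": [5, 6, 7, 8, 9]},
    "simulation": {"snr_db": -8.0, "seed": 42, "n_subjects": 2,
                   "n_sessions": 2, "n_trials_per_target": 4},
    "method": "bcca", "nh": 2, "windows": [1.0, 2.0, 3.5],
    "output_dir": "demo_out",
})
```

which writes `predictions.csv` / `report.json` and yields

```
window  accuracy  itr (bits/min)
1.0 s     0.6375      39.13
2.0 s     0.7625      31.68
3.5 s     0.8375      23.26
```

accuracy climbs with window length while ITR per selection falls — the
usual speed/accuracy trade governed by `ITR ∝ bits(σ)/T`.  At 0 dB SNR the
same pipeline decodes all 80 trials correctly (ITR 39.8 bits/min at
3.5 s, the K = 5 ceiling `60/3.5·log₂5`).

The CLI mirrors the library: `make-stimulus`, `simulate`, `decode`, `psd`,
`evaluate`, and `run` (YAML-driven pipeline); `--help` on any command.

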