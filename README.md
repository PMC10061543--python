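# cisim — simulated cochlear-implant psychoacoustics

`cisim` is an end-to-end computational model of hearing with a cochlear
implant (CI), built to run closed-set psychoacoustic experiments entirely in
software.  It answers questions of the form *"how does neural degeneration,
or a change of stimulation strategy, move a listener's threshold?"* for two
classic paradigms:

* **SMT** — the spectral modulation threshold: the smallest spectral ripple
  depth (dB) distinguishable from flat noise at 79.4% correct;
* **SRT** — the speech reception threshold: the signal-to-noise ratio at
  which 50% of matrix-sentence words are recognized.

The model chain is:

1. **Sound coding** — an F120-style current-steering strategy: 16
   electrodes, 15 virtual channels, 8 steering positions per channel,
   cathodic-leading biphasic pulses (18 µs/phase) at a constant 1852
   pulses/s per channel, in sequential (S), paired (P) or triplet (T)
   stimulation.  Amplitudes in clinical units, `I = cu/6000 · 2040 µA ·
   229/phase_µs`.
2. **Electrode–nerve interface** — a parametric 3D spiral cochlea: 42 mm of
   basilar membrane over 900°, 9001 auditory nerve fibers at 0.1° spacing,
   each a 30-node chain (200 µm internodal).  Degeneration removes the
   `α_f` most peripheral segments per fiber, `α_f ~ round(N(mean, 3))`
   clipped to [0, 20]; presets: healthy (5), moderate (10), severe (15).
3. **Excitation** — point-source potentials `U = ρ_ext I/(4πd)` with
   ρ_ext = 3 Ωm; the activation function is the second spatial difference of
   `U` along the fiber divided by `R_i = 4L_i r/(πD²) ≈ 63.7 MΩ`; the
   induced current is `I = M_C · A(a_max)` at the node of maximum absolute
   combined activation (`M_C = 89.525·10⁶`).
4. **Fiber population** — per fiber, two adaptive leaky integrate-and-fire
   circuits (cathodic- and anodic-excitatory, capacitances 856.96 nF and
   1772.4 nF, opposite phase compressed by β = 0.75) coupled by an OR, with
   a 500 µs absolute refractory period, adaptation and noise currents.
5. **Internal representation** — spikes grouped into 16–39 auditory filters
   along the membrane, binned at 10 kHz, Gaussian-smoothed (τ = 1 ms),
   forward-masked, and reduced to 100 Hz feature frames.
6. **Recognizer** — whole-stimulus 8-state left-to-right HMMs with single
   Gaussian emissions, trained by segmental k-means; binary decoding for
   SMT, a five-slot word grammar for SRT.
7. **Psychometrics** — per-condition scores fitted with
   `Ps(x) = p_chance + p_range/(1+e^{−s(x−x_o)})` and inverted in closed
   form at the task criterion.

Virtual **fitting** closes the clinical loop: each channel's most
comfortable level (MCL) is the clinical-unit level at which a 200 ms pulse
train makes the channel's 858-fiber fitting group fire on 75% of pulses;
T = 10% of MCL.  All stimuli (ripple noise, a 50-word synthetic
matrix-sentence corpus, speech-shaped noise) are generated internally — no
recordings or downloads.

See `docs/methods.md` for assumptions, parameter tables and limitations.

## Worked example

A reduced SMT experiment (201-fiber model, sequential coding, healthy
nerves — `examples/smt_experiment.py`, a minute or two on one CPU):

```bash
$ python examples/smt_experiment.py
 contrast_db  n  percent_correct
         2.0  6        50.000000
         4.0  6        50.000000
         7.0  6        83.333333
        11.0  6       100.000000
        14.0  6       100.000000
        20.0  6       100.000000
p_max = 100.0%  R^2 = 1.000
SMT = 6.94 dB spectral contrast (smallest ripple depth discriminated at 79.4% correct)
```

Reading the output: each row is the percent of correct ripple-vs-flat
decisions at one spectral contrast; the logistic psychometric function
fitted to those scores rises from the 50% chance floor toward `p_max`, and
the SMT is where it crosses 79.4% — here between the 4 dB ripples (at
chance) and the 7 dB ripples (mostly detected).  At this miniature corpus
size (six decisions per contrast) the scores are binomially noisy and the
threshold is indicative only; the `desk` and `full` profiles run the same
experiment at 10× and 100× the corpus.

Other entry points: `examples/` has one short script per capability (pulse
tables, tone encoding, fitting, ripple statistics, corpus construction), and
the `cisim` command-line tool wraps the experiment runners
(`cisim run-smt`, `cisim run-srt`, `cisim run-matrix`, `cisim fit`,
`cisim build-geometry`, `cisim synth-corpus`).

```python
from cisim import Pipeline, run_srt

pipe = Pipeline("T", "severe", profile="desk", master_seed=7)
result = run_srt(pipe)
print(result.threshold_db, result.psychometric.r_squared)
```

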