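# Methods

`cisim` simulates the hearing of a cochlear-implant (CI) listener well enough
to run two closed-set psychoacoustic experiments *in silico*: spectral
modulation detection and matrix-sentence speech reception.  This note
documents the model stages, their assumptions, the parameters that matter,
and what the synthetic setup can and cannot say about real listeners.

## Sound coding

The coder is an F120-style current-steering strategy on a 16-electrode
array.  Fifteen virtual channels are formed by adjacent electrode pairs;
within a pair the channel current is split `(1-c, c)` over the apical and
basal contact at one of eight steering positions.  Three variants differ
only in the stimulation schedule: sequential (one channel per slot), paired
(channels `{i, i+8}` simultaneously), triplet (`{i, i+5, i+10}`).  Every
channel is stimulated exactly once per 540 us cycle (~1852 pulses/s); for
the simultaneous variants, zero-current gaps after each group absorb the
remaining cycle time.  The per-channel period is the primary constraint: for
the paired variant the literal "gap = one biphasic pulse" reading would
stretch the cycle to 576 us, so the gaps are 31.5 us instead; the triplet
gaps come out at exactly two pulse durations.

Pulses are cathodic-leading biphasic, 18 us per phase.  Amplitudes are in
clinical units (CU, 1..471), converted to microamps by
`I = cu/6000 * 2040 uA * 229/phase_us`.

The analysis front half (not specified by the device literature at this
level) is a 15-band log-spaced filterbank over 350-5600 Hz with Hilbert
envelopes; the steering position is the quantized upper-half-band energy
fraction; envelopes map logarithmically onto the channel's T..MCL range over
a 60 dB input dynamic range referenced to a configurable ceiling
(-44 dBFS).  All of this sits in `CoderConfig`.  Level convention
throughout: `dBFS = 20 log10(RMS * sqrt(2))`, i.e. a full-scale sine is
0 dBFS; experiments present stimuli around -49 dBFS.

## Electrode-nerve interface

The cochlea is a parametric logarithmic spiral: 42 mm of basilar membrane
(BM) over 900 degrees (2.5 turns), radius tapering by the configured ratio,
with a modest axial rise.  9001 auditory nerve fibers (ANFs) sit every
0.1 degree, indexed base to apex.  Each fiber is a chain of 30 nodes with
200 um internodal spacing: it leaves its BM terminal along a cubic-Bezier
bend in the radial/axial plane (heading down and inward, joining the nerve
trunk tangentially -- polyline corners would create artificial curvature
hotspots in the activation function) and then descends parallel to the
modiolar axis at the trunk radius.

The electrode template carries 22 contacts spanning insertion angles
20-380 degrees (almost one turn); template contacts 11, 13, 15, 17, 19, 21
are removed, leaving the 16 modeled contacts, each offset radially inward
(0.9 mm) and axially below (1.2 mm) the BM spiral, i.e. inside the scala
tympani.  Contacts are treated as point sources, consistent with the
point-source potential formula below.  All radii, offsets and the insertion
span are config; the default values were chosen once so that fitted
most-comfortable levels (MCLs) land inside the device's compliance range
under every neural-health condition (see Calibration).

Degeneration removes the `alpha_f` most peripheral segments of fiber `f`;
`alpha_f ~ round(N(mean, 3))` clipped to [0, 20].  Health presets: healthy
(mean 5), moderate (10), severe (15); `ideal` (0) and `total` (20) exist for
reference.  Fibers keep at least 10 nodes.

## Excitation

Electrode `n` at current `I_n` produces the extracellular potential
`U = rho_ext I_n / (4 pi d)` at distance `d`, with `rho_ext = 3 Ohm m`
(homogeneous medium).  The activation function at interior node `a` is the
second difference `(U_{a-1} - 2 U_a + U_{a+1}) / R_i` with
`R_i = 4 L_i r / (pi D^2) ~ 63.66 MOhm` (L_i = 200 um, D = 2 um,
r = 1 Ohm m); it carries ampere units because the membrane capacitance is
applied inside the neuron model.  Terminal nodes -- including the new
most-peripheral node after degeneration -- are excluded from the activation
function: a one-sided end treatment can *increase* activation as segments
are removed, inverting the intended monotone loss of excitability, and is
deliberately not used.

The induced current driving a fiber's point neuron is
`I = M_C * A(a_max)` where `A` is the activation summed over simultaneously
active electrodes and `a_max` is the node with the largest absolute
*combined* activation at that instant.  Choosing `a_max` on the combined
profile (rather than per electrode) makes simultaneous channels interact:
opposite-sign activations cancel and attenuate the drive, the signature
effect of paired/triplet stimulation.  `M_C` defaults to 89.525e6.

Because the stimulation waveform is piecewise constant, excitation is
evaluated per pulse phase, never on a dense 1 MHz grid.  For single-channel
slots the argmax node is amplitude-independent and precomputed; for
simultaneous slots the combined profile is formed per cycle.  A generic
path (`excitation.induced_current`) computes the same quantity for
arbitrary electrodograms and is cross-checked against the fast path in the
tests.

## Fiber model

Each ANF is a pair of adaptive leaky integrate-and-fire circuits coupled by
a logical OR: cathodic-excitatory (C = 856.96 nF) and anodic-excitatory
(C = 1772.4 nF).  The circuit-specific drive compresses the opposite phase
by `beta = 0.75`: cathodic drive `-(I^- + 0.75 I^+)`, anodic drive
`I^+ + 0.75 I^-`.  Both integrate `C dV/dt = h(V) - I_sub - I_supra +
I_noise + I_stim`; a threshold crossing in either circuit emits one spike,
resets both and silences the fiber for a 500 us absolute refractory period.

The internal processes are deliberately simple first-order dynamics with
config-exposed defaults:

| parameter | default | meaning |
|---|---|---|
| `tau_m_us` | 200 | membrane time constant; `h(V) = -V C / tau_m` |
| `v_threshold` | 0.040 V | spike threshold (calibration, see below) |
| `a_sub`, `tau_sub_us` | 5 mS, 50 ms | subthreshold adaptation toward `a_sub V` |
| `b_supra_a`, `tau_supra_us` | 0.6 uA, 100 ms | per-spike adaptation increment |
| `noise_sd_a`, `tau_noise_us` | 80 uA, 100 us | Ornstein-Uhlenbeck noise current |

Adaptation currents persist through the refractory period; the noise is
refreshed on a ~90 us clock from per-fiber seeded streams, so any fiber's
spike train depends only on the master seed and its own global index
(adding or removing fibers never perturbs the others).

Integration is exact per constant-current segment (exponential step with an
analytic within-segment threshold-crossing time), which matches a 0.1 us
explicit-Euler reference to well under 2 us without a microsecond grid.

## Fitting and calibration

The clinical fitting loop is closed through spike counts: for each virtual
channel, 200 ms pulse trains (540 us period, 10 ms margins) are presented at
1..471 CU in 30-CU steps; the MCL is the level (linearly interpolated
between sweep points, averaged over >= 3 noise seeds) at which the mean
per-pulse, per-fiber firing probability of the channel's fitting group
crosses 75%.  The group is the 858 fibers (rescaled proportionally for
smaller populations) with the highest absolute activation for that channel.
T = 10% of MCL (a 20 dB electric dynamic range).  The 75% criterion is read
as a group-mean per-pulse probability; an "any fiber fires" reading
saturates immediately with hundreds of fibers.

Calibration: `M_C` is fixed at its published default; the neuron threshold
(and the noise/adaptation amplitudes scaled with it) is the free constant of
this model family and was set once, together with the geometry offsets, so
that (i) healthy-condition MCLs stay below 250 CU on all channels (stimulating
above that limit would be out of compliance), (ii) severe degeneration still
fits within the 471 CU range, and (iii) MCLs rise monotonically with mean
degeneration.  At total degeneration (`alpha = 20` everywhere) several basal
channels exceed the range and are reported as disabled -- the qualitative
behavior expected of an essentially denervated cochlea.  `calibrate_mc`
optionally re-derives `M_C` against a user-supplied rate-level target by
bisection.

## Internal representation

Population spikes become recognizer features in five steps: (1) fibers are
grouped into auditory filters by their strongest electrode (argmax of
|unit activation|, majority-smoothed over 5 fibers); contiguous runs merge
apically if narrower than 1.1 mm of BM and split basal-first if wider than
2.6 mm (the final cut shrinks when a remainder would fall below the
minimum), keeping 16..39 filters; (2) spikes are binned at 10 kHz and summed
per filter; (3) each filter is convolved with an area-normalized
Gaussian-shaped kernel, width set by the 1 ms time constant at 10 kHz
(truncated at four standard deviations); (4) a forward-masking envelope
rises toward the signal with a 5 ms attack and decays with a 50 ms release;
the representation is the pointwise maximum of envelope and signal; (5) a
10 ms block mean reduces the rate to 100 Hz.  The kernel width and masking
constants are config: the source descriptions leave the exact kernel
normalization and masker constants open, so they are defaults, not claims.

## Recognizer

Each stimulus class is an 8-state left-to-right HMM with one diagonal
Gaussian per state, trained by segmental k-means (uniform segmentation,
Viterbi realignment, exact ML updates; deterministic; variances floored at
1e-4 of the global feature variance).  The spectral task compares two
whole-stimulus models (ripple vs flat) by Viterbi log-likelihood.  The
sentence task decodes a five-slot grammar -- silence, then one of ten word
models per category slot, silence between words -- with a vectorized Viterbi
over the composite state space; scoring is words correct out of five.

Word models are trained on word-aligned feature segments.  The alignment is
exact because the corpus generator controls concatenation times; embedded
(flat-start) training is not implemented.  Training pools all SNR conditions
into one model set.

## Stimuli

All audio is synthetic, 17.4 kHz.  Ripple noise: random-phase spectrum with
`|F| = 10^(C_t/2 sin(2 pi log2(f/350) f_RPO + theta_0)/20)` inside
350-5600 Hz, zero outside; 0.4 s; `f_RPO = 0.5` (two ripple periods over the
4-octave band); `theta_0` and the component phases are randomized per
stimulus.  Loudness roving draws the presentation level uniformly from a
0.5 dB grid spanning -49 +/- 5 dBFS.

The matrix corpus is 5 categories x 10 words; sentences take one word per
category in fixed order; stacking independent per-category permutations
balances the corpus exactly (every word appears `n/10` times).  Word audio
is formant synthesis: a glottal pulse train (per-word fundamental and duty
cycle, seeded +/-1% pitch jitter) through three resonators whose center
frequencies form a unique (F1, F2) pair per word, with per-word F2 glides,
durations of 250-500 ms, optional fricative-like onset bursts and one- or
two-syllable envelopes, radiation pre-emphasis, and band-limiting to the
transmitted band.  Sentences concatenate words with 50 ms gaps and 100 ms
edge silences.  Speech-shaped noise copies the corpus long-term spectrum
(random-phase synthesis from the inventory-average power spectrum); mixing
fixes speech at -49 dBFS and scales a random noise excerpt to the requested
SNR.

What the generator does *not* emulate: coarticulation, speaker variability,
natural prosody, reverberation, and any open-set vocabulary.  Passing
experiments therefore demonstrate that the model chain transmits and the
back-end exploits spectro-temporal structure under controlled conditions --
not that absolute thresholds match any clinical population.

## Experiments

SMT: training corpus of ripples at random integer contrasts 2..20 dB plus
flat references (1000 + 1000 at full scale); test corpus of 10 contrasts
{2,3,4,5,7,9,11,14,17,20} dB x (50 ripple + 50 flat); percent correct per
contrast is fitted with the logistic psychometric function
`Ps(x) = p_chance + p_range / (1 + exp(-s(x - x_o)))` with `p_chance` fixed
at 50%; the SMT is the closed-form inversion at 79.4%.

SRT: the 100-sentence balanced corpus mixed at training SNRs 0..18 dB in
3 dB steps plus clean (80 instances per word) and tested at -9..18 dB
(5000 words at full scale); `p_chance = 10%`; the SRT is the inversion at
50% words correct.

Three built-in profiles scale the computation; the experiment structure is
identical in all of them:

| profile | fibers | SMT train/test | SRT sentences / conditions |
|---|---|---|---|
| `full` | 9001 | 1000+1000 / 50 per condition | 100 / 8 train + 10 test |
| `desk`  | 901  | 100+100 / 5 per condition    | 10 / 8 train + 10 test |
| `smoke` | 201  | 30+30 / 3 per condition, 6 contrasts | 10 / 5 train + 8 test |

The `full` profile reproduces the full experiment sizes and is
cluster-scale; `desk` and `smoke` are the sizes used by the test suite and
the acceptance script.  At these reduced sizes per-condition scores carry
binomial noise of several percentage points, so thresholds are meaningful to
roughly +/-1-2 dB.

**What reduced-scale runs resolve.**  With ~200 fibers the per-filter
feature values are on the order of one spike per 10 ms frame, so the
recognizer operates in a count-noise-limited regime.  In that regime the
broader excitation of degenerated fibers acts as spatial smoothing that
*averages down* the count noise, and the severe condition can come out at a
slightly *better* (lower) SRT than the healthy condition -- by a few tenths
of a dB up to ~1 dB across configurations and seeds.  The inversion shrinks
as the population grows (at ~450 fibers the two conditions are within
0.1 dB of each other), while the ceiling of the psychometric function
(performance in quiet) already shows the expected degradation under severe
degeneration at these scales.  The healthy-vs-severe SRT ordering itself is
a full-scale property: resolving a ~1.5 dB effect against the reduced-scale
noise floor requires fiber counts and corpus sizes in the `desk`-to-`full`
range and multi-hour runs.  Reduced-scale SRT comparisons in the test suite
and the acceptance script are therefore reported as measured, and their
direction should not be read as the model's full-scale prediction.

Every stochastic stage draws its seed deterministically from one master
seed (CRC-derived sub-seeds per stage, stimulus and fiber), so a run is
reproducible bit for bit given the same configuration.

## Numerical choices and degenerate inputs

* Segment-exact exponential integration; spike times solved analytically
  within a segment; ties between the two circuits resolved toward the
  earlier crossing (cathodic first at exact ties).
* Psychometric fitting uses bounded least squares with multi-start slopes
  {0.2, 0.5, 1, 2} and the empirical mid-range crossing as the offset start;
  flat-at-chance score tables collapse to `p_range = 0` (parsimony rule);
  a criterion at or above `p_max` raises a threshold-undefined error rather
  than returning NaN.
* Empty audio encodes to an empty electrodogram; digital silence stimulates
  at T level.  Channels that cannot reach the 75% criterion at 471 CU are
  reported and disabled (zero amplitude), and the remaining channels stay
  usable.
* Viterbi ties break toward the lower state index (argmax on the advanced
  branch only when strictly larger).

## Known limitations

* The voltage spread is inverse-distance (homogeneous medium); real cochleae
  show a flatter, exponential-like decay, so channel interaction here is
  weaker than in vivo and differences between the coding variants are
  correspondingly compressed.
* The geometry is a parametric stand-in; absolute MCLs, thresholds and their
  deltas depend on it and are not clinically calibrated.  Only their
  directions (degeneration raises MCLs and SRTs) are design targets.
* The internal representation is highly correlated across filters and
  carries no explicit spectral-shape contrast, which caps spectral-task
  performance regardless of the front end.
* One fiber = one point process; no latency/jitter of conduction, no
  multi-compartment dynamics, no diameter-based degeneration.
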