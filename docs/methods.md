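# Methods

## The analysis

The pipeline quantifies directional propagation of population spiking
across cortical depth and between the two primary somatosensory cortices.
Population spikes are unsorted multi-unit events: negative threshold
crossings of bandpassed extracellular signal. The core statistic is the
*next-spike delay*: for a spike at time *t* on one (hemisphere, layer)
channel, the delay Δt to the earliest spike on each of the other 11
channels with 0 < Δt ≤ 30 ms, within the same epoch. Cell-wise means over
(spike layer → target layer) form two 6×6 matrices per spike hemisphere —
one for targets in the spike's own hemisphere (*spike S1*; diagonal
undefined) and one for the opposite hemisphere (*other S1*). Because
delays following spikes in either hemisphere behave alike, the two spike
hemispheres are pooled by count-weighted averaging (equivalent to pooling
spike pairs) before summaries.

Summaries: *upward mean* (cells whose target layer is more superficial
than the spike layer), *downward mean* (the complementary triangle),
interhemispheric *deep* (targets L4–L6) and *superficial* (targets L1–L3)
means, and the *delay ratio* — mean delay after deep-layer spikes divided
by mean after superficial-layer spikes, which exceeds 1 when upward lags
dominate.

Averaging hierarchy: spike pair → within-animal cell mean → across-animal
mean. Cells with zero pairs are undefined and excluded, never imputed.

### Rate control

Higher firing rates mechanically shorten next-spike delays, so the layer
pattern of delays could in principle reflect rates alone. The control
permutes the 12 channel labels uniformly at random across all of one
animal's spikes (times fixed; 1000 permutations by default), preserving
per-channel spike counts while destroying temporal structure. Delay
matrices and ratios recomputed under permutation give the rate-only
expectation. Note that even under pure rate heterogeneity the delay ratio
sits slightly above 1 because the spike-S1 matrix excludes its diagonal:
deep-spike rows contain three low-rate (superficial) targets while
superficial-spike rows contain only two. The informative comparison is
therefore observed ratio vs shuffled ratio, not observed ratio vs 1.

### Inference

Contrasts between conditions use a paired nonparametric percentile
bootstrap across animals (n = 5000 resamples): animals are resampled with
replacement keeping each animal's paired values together; the 95% CI is
the 2.5/97.5-percentile interval of the resampled mean differences, and a
contrast is flagged significant when the CI excludes zero. This matches
small samples with no distributional assumptions, but the percentile
interval is known to under-cover at very small n: for six normal
per-animal differences its true coverage is ≈ 87% rather than the nominal
95% (approximately P(|t₅| ≤ 1.96·√(5/6))). Monte-Carlo runs in the test
suite reproduce this. The method is kept as-is because it is the intended
estimator; its CIs at n = 6 should be read as slightly liberal.

### Velocity and model comparison

Upward velocity comes from ordinary least squares of mean delay (ms) on
target depth (mm) for each spike layer; a delay-vs-depth slope has units
ms/mm, so velocity is 1/|slope| (mm/ms ≡ m/s). In the spike S1 only spike
layers L4–L6 are fitted (3–5 upward targets; fewer points make a line
meaningless); toward the other S1 all six target layers are used. The
spike's own point (zero delay at its own depth) is never included. The
default predictor depths are the equally spaced per-layer depths (0.28 mm
per step), under which a noiseless constant-lag cascade recovers
spacing/lag exactly; the geometry is fully overridable.

Whether upward propagation is step-wise across layers or continuous
through tissue is tested by fitting the same delays against two predictor
sets — equally spaced layer depths (M₁) versus the unequally spaced actual
recording depths (M₂: −0.10, −0.25, −0.50, −0.75, −1.10, −1.50 mm) — and
comparing with the BIC approximation of the Bayes factor,

    B₁₂ = exp(−(BIC₁ − BIC₂)/2),  BIC = n·ln(RSS/n) + k·ln(n),  k = 2.

Both models have identical complexity, so residual variance is the only
discriminator and all additive BIC constants cancel. B₁₂ is computed per
animal and averaged arithmetically (robust to a single extreme animal,
unlike multiplying evidence). B₁₂ > 3 (resp. < 1/3) is read as positive
evidence for the layer (resp. depth) model. A caveat inherited from the
source geometry: the recording-depth list for L2–L4 (−0.25, −0.50,
−0.75 mm) disagrees with the histological electrode depths (0.3, 0.5,
0.8 mm); the model-comparison values are used as printed, and the
geometry object accepts any override.

## Detection

Multi-unit activity is isolated with a zero-phase (forward–backward)
Butterworth bandpass, 500–3000 Hz by default (a 750–2000 Hz preset,
`FIG1_BAND`, is also shipped; the narrower band stems from an
illustration-oriented setting). Zero-phase filtering keeps event
timestamps free of group-delay bias. The per-channel threshold is
−5 × noise scale; the default noise estimator is the spike-robust
median(|x|)/0.6745 (0.6745 = Φ⁻¹(0.75), consistent for Gaussian noise),
with the plain sample SD available. The threshold is estimated over the
whole signal excluding post-stimulus artifact windows. Events are
timestamped at the crossing sample; crossings within a 1 ms dead time of
the previous event are suppressed (prevents one transient being counted
at several consecutive samples); events within 0–5 ms of any stimulus
onset are removed (mechanical stimulator artifacts). Constant (zero-noise)
channels yield no events. Detection equals a naive sample-by-sample scan
exactly, is invariant to global signal scaling, and its event count is
non-increasing in the threshold multiplier.

## The synthetic generator

The generator emulates the statistical structure of anesthetized
two-hemisphere laminar recordings at the event level:

* **Background rates** (Hz, L1→L6): 2, 4, 6, 10, 14, 8 per hemisphere —
  sparse superficial layers, densest L5.
* **Evoked regime**: 200 stimulus epochs per animal, analysed in a
  half-open [5, 60) ms post-stimulus window. Each epoch carries a
  contralateral volley at 6.5 ms: a cascade that starts at L6 and climbs
  one layer per `cascade_lag_ms` (default 0.4 ms, implying 0.28/0.4 =
  0.7 m/s), each layer participating probabilistically (0.40, 0.50, 0.60,
  0.90, 0.95, 0.85 for L1…L6) with Gaussian timing jitter (0.3 ms SD).
  Under `depth_linear` mode the per-step lag instead scales with the
  actual inter-electrode distances (constant tissue velocity).
* **Interhemispheric relay**: the other hemisphere replays the cascade
  starting at L6 after `relay_delay_ms` (9 ms), with
  `relay_superficial_increment_ms` (1.6 ms) added per layer upward —
  the slow apparent upward spread seen from the opposite hemisphere
  (0.28/1.6 ≈ 0.18 m/s).
* **Active periods**: from each layer's cascade time the channel fires
  Poisson at `active_gain` × its background rate for
  `active_duration_ms` (evoked: 40× for 25 ms; spontaneous: 20× for
  150 ms). This reproduces the joint pattern of real matrices: downward
  delays short and rate-driven, upward delays longer and graded by the
  cascade, and a delay ratio above its shuffled counterpart.
* **Spontaneous regime**: 7 s epochs; up-state onsets are Poisson at
  0.3 /s (the onset process is a modelling choice — nothing constrains
  it beyond stationarity), each triggering a slower cascade (1.1 ms/step
  ≈ 0.25 m/s) from a randomly chosen source hemisphere plus its relay
  (8 ms, 0.75 ms/step).
* **Continuous fixtures**: Gaussian noise per channel at 6250 Hz plus a
  Gabor-shaped biphasic transient (dominant negative phase, ~1500 Hz,
  unit peak at the event time) scaled to a configured multiple of the
  noise SD.

Reproducibility: one RNG stream is derived per (seed, animal, regime,
epoch) through `numpy` SeedSequence spawning, so identical configurations
give byte-identical outputs regardless of generation order or subsetting.

`generate_rate_only_null` builds the rate-only hypothesis directly: 12
mutually independent stationary Poisson trains with the configured rates
and no cross-channel structure.

`cascade_recovery_config` defines the estimator-recovery scenario used in
validation: a clean layer-step cascade (default 0.3 ms/step, 0.1 ms
jitter, 200 epochs), uniform low background (2 Hz), full participation,
no active periods, and a relay that climbs at the same per-layer lag as
the source cascade so both hemispheres carry the configured velocity and
the collapsed matrices inherit it. On this scenario the upward cells
grade monotonically and the fitted velocity (averaged over spike layers
L4–L6) lands within a few percent of truth; the residual upward bias of
the slope comes from occasional jitter-induced order swaps at small lags,
which replace a 0.3 ms cascade pair with a long background delay.

### What the generator does not emulate

No biophysics: no LFP/CSD structure, no conduction delays through axonal
geometry, no anesthesia-depth dynamics, no refractory interactions between
cascade and background spikes, no multi-column spatial structure. Spike
counts are Poisson, not bursty beyond the active-period construction.
Consequently, passing tests certify the *analysis* — detection, delay
bookkeeping, controls, fits, and model comparison — on data with known
structure; they do not certify that real cortex behaves like the
generator. One visible artifact: in the spontaneous regime the long
inter-up-state background dilutes the cascade's contribution, so the
spontaneous delay ratio does not exceed its shuffled counterpart the way
a recording with strongly clustered activity would.

## Numerical and design choices

* Delays are strictly positive; simultaneous spikes never count as
  "next" (ties are a sampling artifact of digitization).
* Epoch windows are half-open ([5, 60) ms evoked; [2, 9) s spontaneous)
  to avoid double counting at boundaries; delays never cross epochs.
* Label shuffles pool all of an animal's spikes across epochs (per-epoch
  shuffling is available as an option).
* The collapse of contra- and ipsi-spike matrices is count-weighted
  pooling (equivalent to pooling pairs); configurable by collapsing
  upstream objects differently.
* Velocity/BF fits run on the collapsed (within-animal averaged)
  matrices; velocities and Bayes factors are computed per animal and then
  averaged, rather than fitted on grand-average delays.
* BIC of a numerically perfect fit (RSS ≤ 1e-12 relative) is −∞ and the
  Bayes factor of two perfect fits is defined as 1.
* n (number of animals) is always taken from the data, never assumed.
* Pipeline scale: the default scenario (6 animals × 200 epochs × 2
  regimes, 1000 shuffles/animal, 5000 bootstrap resamples) was chosen to
  mirror the study design while remaining a ~1 minute single-CPU run;
  every stage is deterministic given (config, seed) and outputs embed the
  seed and a config hash.

## Known limitations

* Percentile-bootstrap CIs under-cover at n = 6 (see Inference above).
* The delay ratio's rate-composition offset (diagonal exclusion) means
  "ratio > 1" alone is not evidence of upward propagation; always compare
  against the shuffle control.
* Next-spike delays saturate at the 30 ms horizon; channels with very low
  rates contribute few pairs and their cells carry large standard errors
  (counts are reported alongside every mean for this reason).
* Detection assumes the artifact window and threshold conventions above;
  no spike sorting is attempted (population spikes are multi-unit events
  by design).
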