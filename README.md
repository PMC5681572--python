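# lamidelay

Spike-to-spike delay analysis of laminar population activity in the two
primary somatosensory cortices (S1). The package takes continuous laminar
recordings (2 hemispheres × 6 depth channels) or event-level spike tables
and quantifies how population spiking propagates across cortical layers and
between hemispheres:

1. **Detection** — population spikes as negative threshold crossings of
   500–3000 Hz bandpassed multi-unit activity, with a per-channel
   data-driven threshold (5 noise-scale units) and exclusion of a 0–5 ms
   post-stimulus artifact window.
2. **Delay matrices** — for every spike at time *t*, the delay Δt to the
   next spike in each of the other 11 (hemisphere, layer) channels, with
   0 < Δt ≤ 30 ms and never across epoch boundaries; averaged per
   (spike layer → target layer) cell within animal, separately for the
   spike hemisphere (*spike S1*) and the other hemisphere (*other S1*).
3. **Rate control** — the 12 channel labels shuffled uniformly across all
   spikes (times fixed, 1000 permutations), which preserves per-channel
   spike counts but destroys temporal structure; compared through the
   *delay ratio* (mean delay after deep-layer spikes L4–L6 ÷ after
   superficial-layer spikes L1–L3, > 1 when upward lags dominate).
4. **Inference** — paired nonparametric percentile bootstrap (n = 5000)
   of mean differences across animals, 95% CI.
5. **Propagation velocity** — ordinary least squares of mean delay (ms) on
   cortical depth (mm) per spike layer; the slope is in ms/mm, so velocity
   is reported as 1/|slope| (mm/ms ≡ m/s). Within the spike S1 only spikes
   in L4–L6 have enough upward targets (3–5 points).
6. **Layer vs depth model comparison** — two linear models differing only
   in predictor depths: equally spaced per-layer depths
   (−0.10, −0.38, −0.66, −0.94, −1.22, −1.50 mm; step-wise *layer* model M₁)
   versus the unequally spaced actual recording depths
   (−0.10, −0.25, −0.50, −0.75, −1.10, −1.50 mm; continuous *depth* model
   M₂), compared by the BIC-approximated Bayes factor
   B₁₂ = exp(−(BIC₁ − BIC₂)/2) with BIC = n ln(RSS/n) + k ln n, k = 2,
   per animal, then averaged arithmetically. B₁₂ > 3 is read as positive
   evidence for step-wise layer propagation.

A synthetic generator (`lamidelay.synthgen`) produces two-hemisphere,
six-layer spike data with the structure the analysis assumes — per-layer
heterogeneous rates (sparsest L1, densest L5), stimulus-locked volleys in
contralateral S1 followed by an upward cascade with a constant per-layer
lag, an interhemispheric relay arriving first in deep layers of the other
hemisphere, and spontaneous up-state-like cascades — plus continuous-signal
fixtures with injected spike transients for the detector. All tests and the
reproduction script run on these synthetic scenarios.

## Worked example

```python
import dataclasses
from lamidelay import (
    paper_like_config, generate_events, delay_matrices,
    collapse_references, summarize, fit_velocities,
)

cfg = dataclasses.replace(paper_like_config("evoked", seed=1), n_animals=1)
events, truth = generate_events(cfg)          # one animal, 200 stimulus epochs
mats = delay_matrices(events)                 # keyed by (spike hemisphere, reference)
same = collapse_references(mats[("contra", "same_S1")], mats[("ipsi", "same_S1")])
other = collapse_references(mats[("contra", "other_S1")], mats[("ipsi", "other_S1")])
s = summarize(same, other)
print(f"upward {s.upward_mean_ms:.2f} ms vs downward {s.downward_mean_ms:.2f} ms")
print(f"other-S1 deep {s.deep_mean_ms:.2f} ms vs superficial {s.superficial_mean_ms:.2f} ms")
print(f"delay ratio (spike S1) {s.delay_ratio_same:.3f}")
for f in fit_velocities(same):
    print(f"spike L{f.spike_layer}: velocity {f.velocity_m_per_s:.2f} m/s")
```

prints

```
upward 4.78 ms vs downward 2.92 ms
other-S1 deep 4.08 ms vs superficial 7.85 ms
delay ratio (spike S1) 1.167
spike L4: velocity 0.16 m/s
spike L5: velocity 0.17 m/s
spike L6: velocity 0.20 m/s
```

Upward delays exceed downward delays (activity propagates toward the pia),
interhemispheric delays are shorter onto deep than superficial layers (the
relay targets infragranular layers first), and the delay ratio is above 1.
The velocities here mix the time-locked cascade with the rate-driven delay
floor of the dense synthetic evoked response; the clean recovery scenario
(`cascade_recovery_config`) recovers a configured cascade velocity to
within a few percent.

There is also a CLI:

```bash
lamidelay simulate --regime evoked --seed 1 --out events.tsv
lamidelay delays --events events.tsv --out-prefix delays
lamidelay run --seed 1 --out results/run1
```

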