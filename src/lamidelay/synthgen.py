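"""Synthetic two-hemisphere, six-layer laminar spike data.

The generator emulates the statistical structure that the delay analysis
assumes in barrel-cortex recordings under anesthesia:

* heterogeneous per-layer background rates (sparser superficial layers,
  densest L5);
* in the evoked regime, a stimulus-locked volley in the contralateral S1
  shortly after stimulation, followed by an upward step-wise cascade with a
  constant per-layer lag (or a lag proportional to inter-electrode distance
  under ``depth_linear`` mode);
* an interhemispheric relay: the cascade is replayed in the other
  hemisphere starting at L6 after ``relay_delay_ms``, with delays growing
  toward superficial layers;
* in the spontaneous regime, up-state-like cascades at random onsets on top
  of the Poisson background, typically with slower upward propagation.

Each cascade also opens a per-layer *active period*: from a layer's cascade
time onward the channel fires Poisson at ``active_gain`` times its
background rate for ``active_duration_ms``. Because deep layers start
earlier and have higher rates, downward next-spike delays come out short
and rate-driven while upward delays are longer and graded by the cascade —
the joint structure the delay analysis reports in real recordings.

Epochs are generated independently; one RNG stream is derived per
(seed, animal, regime, epoch) so identical configurations reproduce
byte-identical outputs regardless of generation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import (
    EVENT_COLUMNS,
    HEMISPHERES,
    LAYER_MODEL_DEPTHS_MM,
    LAYERS,
    N_LAYERS,
    RECORDING_DEPTHS_MM,
    LaminarRecording,
    empty_events,
    validate_events,
)

#: Default per-layer background rates (Hz), L1..L6. Superficial layers are
#: sparse; L5 carries the densest multi-unit activity.
DEFAULT_RATES_HZ = (2.0, 4.0, 6.0, 10.0, 14.0, 8.0)

#: Default probability that a layer emits a spike in a given cascade;
#: decreasing from L5 upward, mirroring the sparser supragranular activity.
DEFAULT_PARTICIPATION = {1: 0.40, 2: 0.50, 3: 0.60, 4: 0.90, 5: 0.95, 6: 0.85}

_LAYER_STEP_MM = 0.28  # spacing of the equally spaced layer-model depths

_REGIME_CODE = {"evoked": 0, "spontaneous": 1}


class ConfigurationError(ValueError):
    """Raised for invalid scenario parameters."""


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic scenario (a set of animals in one regime).

    Times are milliseconds; rates Hz. ``cascade_lag_ms`` is the upward lag
    per layer step under ``layer_step`` mode; under ``depth_linear`` the
    per-step lag is scaled by the actual inter-electrode distance so that
    propagation is constant through tissue.
    """

    n_animals: int = 6
    n_epochs: int = 200
    regime: str = "evoked"
    rates_hz: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {h: DEFAULT_RATES_HZ for h in HEMISPHERES}
    )
    cascade_lag_ms: float = 0.4
    cascade_mode: str = "layer_step"  # or "depth_linear"
    cascade_origin_layer: int = 6
    participation: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PARTICIPATION)
    )
    relay_delay_ms: float = 9.0
    relay_superficial_increment_ms: float = 1.6
    evoked_onset_ms: float = 6.5
    evoked_window_ms: tuple[float, float] = (5.0, 60.0)
    spont_duration_ms: float = 7000.0
    upstate_rate_hz: float = 0.4
    active_gain: float = 40.0
    active_duration_ms: float = 25.0
    jitter_sd_ms: float = 0.3
    # continuous-signal parameters
    sampling_rate_hz: float = 6250.0
    noise_sd: float = 1.0
    spike_amplitude_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.n_epochs < 1:
            raise ConfigurationError("n_animals and n_epochs must be >= 1")
        if self.regime not in _REGIME_CODE:
            raise ConfigurationError(f"unknown regime {self.regime!r}")
        if self.cascade_mode not in ("layer_step", "depth_linear"):
            raise ConfigurationError(f"unknown cascade_mode {self.cascade_mode!r}")
        if self.cascade_lag_ms < 0:
            raise ConfigurationError("cascade_lag_ms must be >= 0")
        for h, r in self.rates_hz.items():
            if len(r) != N_LAYERS:
                raise ConfigurationError(f"rates for {h} must list 6 layers")
            if any(x < 0 for x in r):
                raise ConfigurationError("rates must be >= 0")
        if self.jitter_sd_ms < 0:
            raise ConfigurationError("jitter_sd_ms must be >= 0")
        if self.evoked_window_ms[0] >= self.evoked_window_ms[1]:
            raise ConfigurationError("evoked window start must precede end")
        if self.spont_duration_ms <= 0:
            raise ConfigurationError("spont_duration_ms must be > 0")
        if self.cascade_origin_layer not in LAYERS:
            raise ConfigurationError("cascade_origin_layer must be in 1..6")
        if self.active_gain < 0 or self.active_duration_ms < 0:
            raise ConfigurationError("active period parameters must be >= 0")

    @property
    def epoch_window_ms(self) -> tuple[float, float]:
        if self.regime == "evoked":
            return self.evoked_window_ms
        return (0.0, self.spont_duration_ms)

    @property
    def true_velocity_m_per_s(self) -> float:
        """Ground-truth upward velocity implied by the cascade lag.

        Under both cascade modes the cascade traverses one 0.28 mm model
        layer step per ``cascade_lag_ms`` on average, i.e. v = 0.28/lag
        (mm/ms = m/s).
        """
        if self.cascade_lag_ms == 0:
            return math.inf
        return _LAYER_STEP_MM / self.cascade_lag_ms


def paper_like_config(regime: str = "evoked", seed: int = 0) -> ScenarioConfig:
    """Default scenario emulating the study conditions of the two regimes.

    Evoked: 200 stimulus epochs per animal, contralateral volley at 6.5 ms,
    fast upward cascade (0.4 ms/step, ~0.7 m/s) and a 9 ms interhemispheric
    relay arriving first in L6. Spontaneous: 7 s epochs with up-states at
    0.4 /s, slower cascades (1.1 ms/step, ~0.25 m/s) and a slightly faster,
    flatter relay.
    """
    if regime == "evoked":
        return ScenarioConfig(regime="evoked", seed=seed)
    return ScenarioConfig(
        regime="spontaneous",
        cascade_lag_ms=1.1,
        relay_delay_ms=8.0,
        relay_superficial_increment_ms=0.75,
        upstate_rate_hz=0.3,
        active_gain=20.0,
        active_duration_ms=150.0,
        seed=seed,
    )


def cascade_recovery_config(
    cascade_lag_ms: float = 0.3,
    jitter_sd_ms: float = 0.1,
    n_epochs: int = 200,
    seed: int = 0,
) -> ScenarioConfig:
    """Clean single-animal cascade scenario for estimator-recovery studies.

    Uniform low background (2 Hz), full cascade participation, no active
    periods, and a relay that propagates upward at the same per-layer lag
    as the source cascade, so both hemispheres carry the configured
    velocity and the collapsed matrices inherit it.
    """
    return ScenarioConfig(
        n_animals=1,
        n_epochs=n_epochs,
        regime="evoked",
        rates_hz={h: (2.0,) * 6 for h in HEMISPHERES},
        cascade_lag_ms=cascade_lag_ms,
        jitter_sd_ms=jitter_sd_ms,
        participation={layer: 1.0 for layer in LAYERS},
        relay_superficial_increment_ms=cascade_lag_ms,
        active_gain=0.0,
        seed=seed,
    )


@dataclass
class GroundTruth:
    """Pre-jitter event times and the true propagation parameters."""

    events: pd.DataFrame  # columns: animal_id, epoch, hemisphere, layer, time_ms
    true_velocity_m_per_s: float
    true_relay_delay_ms: np.ndarray  # per layer L1..L6, relative to cascade onset


def _epoch_rng(seed: int, animal: int, regime: str, epoch: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(animal), _REGIME_CODE[regime], int(epoch)])
    )


def _cascade_times(config: ScenarioConfig, onset_ms: float) -> list[tuple[int, float]]:
    """Ideal (pre-jitter) cascade times in the source hemisphere."""
    origin = config.cascade_origin_layer
    out = []
    t = onset_ms
    out.append((origin, t))
    for layer in range(origin - 1, 0, -1):  # upward
        if config.cascade_mode == "layer_step":
            step = config.cascade_lag_ms
        else:
            gap_mm = RECORDING_DEPTHS_MM[layer - 1] - RECORDING_DEPTHS_MM[layer]
            step = config.cascade_lag_ms * gap_mm / _LAYER_STEP_MM
        t = t + step
        out.append((layer, t))
    return out


def _relay_times(config: ScenarioConfig, onset_ms: float) -> list[tuple[int, float]]:
    """Ideal relay cascade times in the other hemisphere (L6 first)."""
    return [
        (
            layer,
            onset_ms
            + config.relay_delay_ms
            + config.relay_superficial_increment_ms * (6 - layer),
        )
        for layer in range(6, 0, -1)
    ]


def true_relay_delays(config: ScenarioConfig) -> np.ndarray:
    """Relay delay per target layer (L1..L6) relative to the cascade onset."""
    return np.array(
        [
            config.relay_delay_ms + config.relay_superficial_increment_ms * (6 - layer)
            for layer in LAYERS
        ]
    )


def _background(
    rng: np.random.Generator, config: ScenarioConfig, window: tuple[float, float]
) -> list[tuple[str, int, float]]:
    lo, hi = window
    dur_s = (hi - lo) / 1000.0
    out = []
    for hemi in HEMISPHERES:
        for layer in LAYERS:
            rate = config.rates_hz[hemi][layer - 1]
            n = rng.poisson(rate * dur_s)
            if n:
                times = rng.uniform(lo, hi, size=n)
                out.extend((hemi, layer, float(t)) for t in times)
    return out


def _emit_cascade(
    rng: np.random.Generator,
    config: ScenarioConfig,
    source_hemi: str,
    onset_ms: float,
    window: tuple[float, float],
    rows: list,
    truth_rows: list,
    animal: int,
    epoch: int,
) -> None:
    other = "ipsi" if source_hemi == "contra" else "contra"
    planned = [(source_hemi, layer, t) for layer, t in _cascade_times(config, onset_ms)]
    planned += [(other, layer, t) for layer, t in _relay_times(config, onset_ms)]
    lo, hi = window
    for hemi, layer, t_true in planned:
        # time-locked cascade spike, probabilistic per layer
        if rng.random() < config.participation.get(layer, 1.0):
            t = t_true
            if config.jitter_sd_ms > 0:
                t = t + rng.normal(0.0, config.jitter_sd_ms)
            if lo <= t < hi:
                truth_rows.append((animal, epoch, hemi, layer, t_true))
                rows.append((animal, epoch, config.regime, hemi, layer, t))
        # active period: elevated Poisson firing from this layer's onset
        if config.active_gain > 0 and config.active_duration_ms > 0:
            a_lo = max(t_true, lo)
            a_hi = min(t_true + config.active_duration_ms, hi)
            if a_hi > a_lo:
                extra = config.rates_hz[hemi][layer - 1] * (config.active_gain - 1.0)
                n = rng.poisson(max(extra, 0.0) * (a_hi - a_lo) / 1000.0)
                for t in rng.uniform(a_lo, a_hi, size=n):
                    rows.append((animal, epoch, config.regime, hemi, layer, float(t)))


def generate_events(config: ScenarioConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate epoch-limited spike events for all animals of a scenario.

    Returns the canonical event table plus the ground truth (pre-jitter
    cascade times, true velocity, true per-layer relay delays).
    """
    rows: list = []
    truth_rows: list = []
    window = config.epoch_window_ms
    for animal in range(config.n_animals):
        for epoch in range(config.n_epochs):
            rng = _epoch_rng(config.seed, animal, config.regime, epoch)
            rows.extend(
                (animal, epoch, config.regime, h, l, t)
                for h, l, t in _background(rng, config, window)
            )
            if config.regime == "evoked":
                _emit_cascade(
                    rng, config, "contra", config.evoked_onset_ms, window,
                    rows, truth_rows, animal, epoch,
                )
            else:
                dur_s = (window[1] - window[0]) / 1000.0
                n_up = rng.poisson(config.upstate_rate_hz * dur_s)
                onsets = np.sort(rng.uniform(window[0], window[1], size=n_up))
                for onset in onsets:
                    source = HEMISPHERES[int(rng.integers(0, 2))]
                    _emit_cascade(
                        rng, config, source, float(onset), window,
                        rows, truth_rows, animal, epoch,
                    )
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS)) if rows else empty_events()
    events = validate_events(events)
    truth = pd.DataFrame(
        truth_rows, columns=["animal_id", "epoch", "hemisphere", "layer", "time_ms"]
    ).sort_values(["animal_id", "epoch", "time_ms"], kind="stable").reset_index(drop=True)
    return events, GroundTruth(
        events=truth,
        true_velocity_m_per_s=config.true_velocity_m_per_s,
        true_relay_delay_ms=true_relay_delays(config),
    )


def generate_rate_only_null(config: ScenarioConfig) -> pd.DataFrame:
    """12 mutually independent stationary Poisson trains, no propagation.

    Serves as the direct construction of the rate-only null that the label
    shuffle approximates: per-channel rates are preserved but no temporal
    structure links the channels.
    """
    rows: list = []
    window = config.epoch_window_ms
    for animal in range(config.n_animals):
        for epoch in range(config.n_epochs):
            rng = _epoch_rng(config.seed, animal, config.regime, epoch)
            rows.extend(
                (animal, epoch, config.regime, h, l, t)
                for h, l, t in _background(rng, config, window)
            )
    events = pd.DataFrame(rows, columns=list(EVENT_COLUMNS)) if rows else empty_events()
    return validate_events(events)


def spike_kernel(sampling_rate_hz: float, f0_hz: float = 1500.0, tau_ms: float = 0.25) -> np.ndarray:
    """Biphasic population-spike transient with a dominant negative phase.

    A Gabor-like waveform (Gaussian-windowed cosine, negated) whose negative
    peak sits at the kernel centre, so injected event times coincide with
    the extremum. Unit peak amplitude.
    """
    half_ms = 4.0 * tau_ms
    n_half = int(round(half_ms / 1000.0 * sampling_rate_hz))
    t = np.arange(-n_half, n_half + 1) / sampling_rate_hz  # seconds
    w = -np.exp(-(t**2) / (2 * (tau_ms / 1000.0) ** 2)) * np.cos(2 * np.pi * f0_hz * t)
    return w.astype(np.float64)


def synthesize_recording(
    event_table: pd.DataFrame,
    duration_ms: float,
    channels: list[tuple[str, int, float]],
    sampling_rate_hz: float,
    noise_sd: float,
    amplitude_sd: float,
    stimulus_onsets_ms: np.ndarray,
    rng: np.random.Generator,
) -> LaminarRecording:
    """Gaussian background noise plus injected spike transients.

    ``event_table`` needs columns hemisphere, layer, time_ms (absolute, ms).
    Transient amplitude is ``amplitude_sd`` multiples of the noise SD.
    """
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be > 0")
    if amplitude_sd <= 0:
        raise ConfigurationError("spike amplitude must be > 0")
    n_samp = int(round(duration_ms / 1000.0 * sampling_rate_hz))
    sig = rng.normal(0.0, noise_sd, size=(len(channels), n_samp))
    kernel = spike_kernel(sampling_rate_hz) * amplitude_sd * noise_sd
    half = len(kernel) // 2
    idx_of = {(h, l): i for i, (h, l, _) in enumerate(channels)}
    for _, row in event_table.iterrows():
        ch = idx_of[(row["hemisphere"], int(row["layer"]))]
        centre = int(round(row["time_ms"] / 1000.0 * sampling_rate_hz))
        lo, hi = centre - half, centre + half + 1
        klo, khi = max(0, -lo), len(kernel) - max(0, hi - n_samp)
        lo, hi = max(lo, 0), min(hi, n_samp)
        if lo < hi:
            sig[ch, lo:hi] += kernel[klo:khi]
    return LaminarRecording(
        samples=sig.astype(np.float32),
        sampling_rate_hz=sampling_rate_hz,
        channels=channels,
        stimulus_onsets_ms=np.asarray(stimulus_onsets_ms, dtype=float),
    )


def default_channels() -> list[tuple[str, int, float]]:
    """12 channels at the histology-informed recording depths."""
    return [
        (hemi, layer, float(RECORDING_DEPTHS_MM[layer - 1]))
        for hemi in HEMISPHERES
        for layer in LAYERS
    ]


def generate_continuous(
    config: ScenarioConfig,
    n_stimuli: int | None = None,
    isi_ms: float = 200.0,
) -> tuple[LaminarRecording, GroundTruth]:
    """Continuous recording for one animal of an evoked scenario.

    Stimuli are placed ``isi_ms`` apart (compact relative to the 9 s
    experimental inter-stimulus interval, which only sets the spontaneous
    gap length); the evoked event structure of each epoch is placed after
    each onset. Returns ground truth in absolute recording time.
    """
    if config.regime != "evoked":
        raise ConfigurationError("generate_continuous expects an evoked scenario")
    n_stim = n_stimuli if n_stimuli is not None else config.n_epochs
    sub = replace(config, n_animals=1, n_epochs=n_stim)
    events, truth = generate_events(sub)
    onsets = 50.0 + isi_ms * np.arange(n_stim)
    duration_ms = onsets[-1] + isi_ms if n_stim else 100.0
    abs_events = events.copy()
    abs_events["time_ms"] = abs_events["time_ms"] + onsets[abs_events["epoch"].to_numpy()]
    truth_events = truth.events.copy()
    if len(truth_events):
        truth_events["time_ms"] = (
            truth_events["time_ms"] + onsets[truth_events["epoch"].to_numpy()]
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 999]))
    rec = synthesize_recording(
        abs_events,
        duration_ms,
        default_channels(),
        config.sampling_rate_hz,
        config.noise_sd,
        config.spike_amplitude_sd,
        onsets,
        rng,
    )
    return rec, GroundTruth(
        events=truth_events,
        true_velocity_m_per_s=truth.true_velocity_m_per_s,
        true_relay_delay_ms=truth.true_relay_delay_ms,
    )
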