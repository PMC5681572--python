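"""Shared containers and conventions for the laminar delay analysis.

Conventions used throughout the package:

* Hemispheres are labelled ``"contra"`` (contralateral to whisker
  stimulation) and ``"ipsi"``.
* Cortical layers are numbered 1 (most superficial, at the pia) to 6
  (deepest). "Upward" propagation means toward smaller layer numbers.
* A *channel* is a (hemisphere, layer) pair; the 12 channels are indexed
  ``hemisphere_index * 6 + (layer - 1)``.
* Spike times are stored in milliseconds, epoch-relative; depths in mm,
  negative below the pia.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("contra", "ipsi")
LAYERS = (1, 2, 3, 4, 5, 6)
N_LAYERS = 6
N_CHANNELS = 12

#: Canonical column order of a spike-event table.
EVENT_COLUMNS = ("animal_id", "epoch", "regime", "hemisphere", "layer", "time_ms")

#: Equally spaced per-layer depths (mm below pia, negative) of the
#: step-wise "layer" propagation model; 0.28 mm per layer step.
LAYER_MODEL_DEPTHS_MM = np.array([-0.10, -0.38, -0.66, -0.94, -1.22, -1.50])

#: Unequally spaced actual recording depths (mm) of the continuous
#: "depth" propagation model.
RECORDING_DEPTHS_MM = np.array([-0.10, -0.25, -0.50, -0.75, -1.10, -1.50])


def channel_index(hemisphere: str, layer: int) -> int:
    """Flat index (0..11) of a (hemisphere, layer) channel."""
    return HEMISPHERES.index(hemisphere) * N_LAYERS + (layer - 1)


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Check schema and value ranges of an event table; return it canonically sorted.

    Raises ``ValueError`` naming the offending column/values.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table is missing columns: {missing}")
    if len(events):
        bad_layer = ~events["layer"].isin(LAYERS)
        if bad_layer.any():
            rows = events.index[bad_layer][:5].tolist()
            raise ValueError(f"layer outside 1-6 at rows {rows}")
        bad_hemi = ~events["hemisphere"].isin(HEMISPHERES)
        if bad_hemi.any():
            rows = events.index[bad_hemi][:5].tolist()
            raise ValueError(f"unknown hemisphere at rows {rows}")
        if not np.isfinite(events["time_ms"].to_numpy(float)).all():
            raise ValueError("non-finite time_ms values")
    out = events.loc[:, list(EVENT_COLUMNS)].sort_values(
        ["animal_id", "epoch", "time_ms", "hemisphere", "layer"], kind="stable"
    )
    return out.reset_index(drop=True)


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal_id": pd.Series(dtype=int),
            "epoch": pd.Series(dtype=int),
            "regime": pd.Series(dtype=str),
            "hemisphere": pd.Series(dtype=str),
            "layer": pd.Series(dtype=int),
            "time_ms": pd.Series(dtype=float),
        }
    )


@dataclass
class LaminarRecording:
    """Continuous multichannel laminar signal.

    ``samples`` is channel-major, shape (n_channels, n_samples), arbitrary
    voltage units.  ``channels`` lists (hemisphere, layer, depth_mm) in the
    row order of ``samples``.  Stimulus onsets are in milliseconds from the
    start of the recording.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    channels: list[tuple[str, int, float]]
    stimulus_onsets_ms: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float32)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x samples)")
        if self.samples.shape[0] != len(self.channels):
            raise ValueError("channel metadata does not match sample rows")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        self.stimulus_onsets_ms = np.asarray(self.stimulus_onsets_ms, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_samples / self.sampling_rate_hz * 1000.0


@dataclass
class DelayMatrix:
    """Mean next-spike delays per (spike layer -> target layer) cell.

    ``mean_delay_ms[s-1, t-1]`` is the within-animal mean delay from a spike
    in layer ``s`` to the next spike in layer ``t`` of the reference
    hemisphere (``same_S1`` or ``other_S1``); NaN where ``count`` is 0.
    The same-hemisphere diagonal is never defined.
    """

    reference: str  # "same_S1" | "other_S1"
    spike_hemisphere: str  # "contra" | "ipsi" | "collapsed"
    mean_delay_ms: np.ndarray  # (6, 6) float, NaN = undefined
    count: np.ndarray  # (6, 6) int
    max_delay_ms: float = 30.0
    animal_id: int | None = None
    regime: str | None = None

    def __post_init__(self) -> None:
        self.mean_delay_ms = np.asarray(self.mean_delay_ms, dtype=float)
        self.count = np.asarray(self.count, dtype=np.int64)
        if self.mean_delay_ms.shape != (N_LAYERS, N_LAYERS):
            raise ValueError("mean_delay_ms must be 6x6")
        if self.count.shape != (N_LAYERS, N_LAYERS):
            raise ValueError("count must be 6x6")
        defined = self.count > 0
        with np.errstate(invalid="ignore"):
            if np.any(defined & ~np.isfinite(self.mean_delay_ms)):
                raise ValueError("cells with count > 0 must have finite means")
            if np.any(defined & (self.mean_delay_ms <= 0)):
                raise ValueError("defined mean delays must be > 0")
            if np.any(defined & (self.mean_delay_ms > self.max_delay_ms + 1e-9)):
                raise ValueError("mean delay exceeds max_delay_ms")

    def to_long(self) -> pd.DataFrame:
        """Long-format dump with one row per (spike_layer, target_layer) cell."""
        rows = []
        for s in LAYERS:
            for t in LAYERS:
                rows.append(
                    {
                        "reference": self.reference,
                        "spike_hemisphere": self.spike_hemisphere,
                        "spike_layer": s,
                        "target_layer": t,
                        "mean_delay_ms": self.mean_delay_ms[s - 1, t - 1],
                        "count": int(self.count[s - 1, t - 1]),
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DelaySummary:
    """Triangle and deep/superficial summaries of a matrix pair."""

    upward_mean_ms: float
    downward_mean_ms: float
    deep_mean_ms: float
    superficial_mean_ms: float
    delay_ratio_same: float
    delay_ratio_other: float

    @property
    def delay_ratio(self) -> float:
        """Deep/superficial spike-layer delay ratio in the spike S1."""
        return self.delay_ratio_same


@dataclass
class LikelihoodProfile:
    """Per-layer probability of >=1 spike per time bin, across trials."""

    hemisphere: str
    bin_edges_ms: np.ndarray
    likelihood: np.ndarray  # (6, n_bins) in [0, 1]
    peak_latency_ms: np.ndarray  # (6,) bin centres, NaN if no spikes
    n_trials: int


@dataclass
class EpochSpec:
    """Epoch extraction window relative to each stimulus onset.

    Evoked: ``window_ms`` (half-open, default [5, 60) ms).
    Spontaneous: ``offset_s`` + ``duration_s`` (default [2, 9) s).
    """

    regime: str
    window_ms: tuple[float, float] | None = None
    offset_s: float | None = None
    duration_s: float | None = None

    def bounds_ms(self) -> tuple[float, float]:
        if self.regime == "evoked":
            win = self.window_ms or (5.0, 60.0)
        else:
            off = 2.0 if self.offset_s is None else self.offset_s
            dur = 7.0 if self.duration_s is None else self.duration_s
            win = (off * 1000.0, (off + dur) * 1000.0)
        if win[0] >= win[1]:
            raise ValueError("epoch window start must precede end")
        return win


@dataclass
class ShuffleResult:
    """Label-shuffle rate control for one animal's epoch-limited events."""

    n_shuffles: int
    seed: int
    mean_matrix_same: DelayMatrix
    mean_matrix_other: DelayMatrix
    ratio_same: np.ndarray  # per-shuffle deep/superficial delay ratios
    ratio_other: np.ndarray


@dataclass
class BootstrapResult:
    """Percentile-bootstrap mean difference with 95% CI."""

    mean_difference: float
    ci_95: tuple[float, float]
    n_boot: int
    seed: int
    n: int

    @property
    def significant(self) -> bool:
        lo, hi = self.ci_95
        return not (lo <= 0.0 <= hi)


@dataclass
class VelocityFit:
    """Least-squares delay-vs-depth fit for one spike layer."""

    spike_layer: int
    reference: str
    slope_ms_per_mm: float
    intercept_ms: float
    velocity_m_per_s: float  # 1/|slope|; NaN if slope == 0
    n_points: int
    rss: float


@dataclass
class BayesFactorResult:
    """BIC-approximated Bayes factor: step-wise layer model vs depth model.

    ``bf > 1`` favours the layer model; ``bf > 3`` is conventionally taken
    as positive evidence.
    """

    spike_layer: int | None
    reference: str
    bic_layer: float
    bic_depth: float
    bf: float


@dataclass
class LayerGeometry:
    """Predictor depth sets for the two propagation models."""

    layer_depths_mm: np.ndarray = field(
        default_factory=lambda: LAYER_MODEL_DEPTHS_MM.copy()
    )
    recording_depths_mm: np.ndarray = field(
        default_factory=lambda: RECORDING_DEPTHS_MM.copy()
    )

    def __post_init__(self) -> None:
        self.layer_depths_mm = np.asarray(self.layer_depths_mm, dtype=float)
        self.recording_depths_mm = np.asarray(self.recording_depths_mm, dtype=float)
        for name, d in (
            ("layer_depths_mm", self.layer_depths_mm),
            ("recording_depths_mm", self.recording_depths_mm),
        ):
            if d.shape != (N_LAYERS,):
                raise ValueError(f"{name} must have 6 entries")
            if not np.all(np.diff(d) < 0):
                raise ValueError(f"{name} must strictly decrease from L1 to L6")


def mean_over_defined(values: np.ndarray, counts: np.ndarray, mask: np.ndarray) -> float:
    """Unweighted mean of matrix cells selected by ``mask`` that are defined.

    Returns NaN when no selected cell is defined (the caller flags this).
    """
    sel = mask & (counts > 0)
    if not sel.any():
        return float("nan")
    return float(values[sel].mean())
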