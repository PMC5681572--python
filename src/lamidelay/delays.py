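"""Epoch-limited next-spike delay matrices and their summaries.

For every spike at time t, the delay Δt to the next spike in each of the
other 11 (hemisphere, layer) channels is recorded, provided 0 < Δt <= a
30 ms horizon and both spikes fall in the same epoch. Delays are averaged
per (spike layer -> target layer) cell within animal, separately for the
hemisphere where the spike occurred (``same_S1``) and the other hemisphere
(``other_S1``), and separately per spike hemisphere until collapsed.

Simultaneous spikes never count as "next" (Δt must be strictly positive);
the same-hemisphere same-layer diagonal is not computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import (
    HEMISPHERES,
    LAYERS,
    N_CHANNELS,
    N_LAYERS,
    DelayMatrix,
    DelaySummary,
    EpochSpec,
    LikelihoodProfile,
    mean_over_defined,
)

DEFAULT_MAX_DELAY_MS = 30.0


def _channel_arrays(events: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(times_ms, channel_idx, epoch_idx) arrays from an event table."""
    hemi_idx = events["hemisphere"].map({h: i for i, h in enumerate(HEMISPHERES)})
    chan = hemi_idx.to_numpy(np.int64) * N_LAYERS + events["layer"].to_numpy(np.int64) - 1
    return (
        events["time_ms"].to_numpy(float),
        chan,
        events["epoch"].to_numpy(np.int64),
    )


def delay_sums_by_channel(
    times_ms: np.ndarray,
    channel_idx: np.ndarray,
    epoch_idx: np.ndarray,
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """12x12 (sum of delays, pair counts) over all next-spike pairs.

    Vectorised core shared by the analysis and the shuffle control: epochs
    are made non-interacting by a time offset larger than any epoch span
    plus the horizon, then for each target channel the next spike after
    every source spike is located with a sorted search. A strict inequality
    (``side="right"``) excludes simultaneous spikes.
    """
    sums = np.zeros((N_CHANNELS, N_CHANNELS))
    counts = np.zeros((N_CHANNELS, N_CHANNELS), dtype=np.int64)
    n = len(times_ms)
    if n == 0:
        return sums, counts
    span = float(times_ms.max()) + max_delay_ms + 1.0
    t = times_ms + epoch_idx * span
    order = np.argsort(t, kind="stable")
    t = t[order]
    chan = channel_idx[order]
    for target in range(N_CHANNELS):
        tc = t[chan == target]
        if tc.size == 0:
            continue
        pos = np.searchsorted(tc, t, side="right")
        valid = pos < tc.size
        delta = np.full(n, np.nan)
        delta[valid] = tc[pos[valid]] - t[valid]
        ok = valid & (delta <= max_delay_ms)
        if ok.any():
            sums[:, target] = np.bincount(
                chan[ok], weights=delta[ok], minlength=N_CHANNELS
            )
            counts[:, target] = np.bincount(chan[ok], minlength=N_CHANNELS)
    return sums, counts


def matrices_from_sums(
    sums: np.ndarray,
    counts: np.ndarray,
    spike_hemisphere: str,
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS,
    animal_id: int | None = None,
    regime: str | None = None,
) -> tuple[DelayMatrix, DelayMatrix]:
    """Split 12x12 sums into (same_S1, other_S1) matrices for one spike hemisphere."""
    h = HEMISPHERES.index(spike_hemisphere)
    out = []
    for reference, target_h in (("same_S1", h), ("other_S1", 1 - h)):
        s = sums[h * 6 : h * 6 + 6, target_h * 6 : target_h * 6 + 6].copy()
        c = counts[h * 6 : h * 6 + 6, target_h * 6 : target_h * 6 + 6].copy()
        if reference == "same_S1":
            np.fill_diagonal(s, 0.0)
            np.fill_diagonal(c, 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(c > 0, s / np.maximum(c, 1), np.nan)
        out.append(
            DelayMatrix(
                reference=reference,
                spike_hemisphere=spike_hemisphere,
                mean_delay_ms=mean,
                count=c,
                max_delay_ms=max_delay_ms,
                animal_id=animal_id,
                regime=regime,
            )
        )
    return out[0], out[1]


def next_spike_delays(
    events: pd.DataFrame,
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS,
    spike_hemisphere: str = "contra",
) -> tuple[DelayMatrix, DelayMatrix]:
    """(same_S1, other_S1) delay matrices for spikes of one hemisphere.

    ``events`` must be epoch-limited (one animal; epoch-relative times).
    Delays never cross epoch boundaries.
    """
    times, chan, epoch = _channel_arrays(events)
    sums, counts = delay_sums_by_channel(times, chan, epoch, max_delay_ms)
    animal = int(events["animal_id"].iloc[0]) if len(events) else None
    regime = str(events["regime"].iloc[0]) if len(events) else None
    return matrices_from_sums(
        sums, counts, spike_hemisphere, max_delay_ms, animal, regime
    )


def delay_matrices(
    events: pd.DataFrame, max_delay_ms: float = DEFAULT_MAX_DELAY_MS
) -> dict[tuple[str, str], DelayMatrix]:
    """All four matrices keyed by (spike_hemisphere, reference)."""
    times, chan, epoch = _channel_arrays(events)
    sums, counts = delay_sums_by_channel(times, chan, epoch, max_delay_ms)
    animal = int(events["animal_id"].iloc[0]) if len(events) else None
    regime = str(events["regime"].iloc[0]) if len(events) else None
    out: dict[tuple[str, str], DelayMatrix] = {}
    for hemi in HEMISPHERES:
        same, other = matrices_from_sums(
            sums, counts, hemi, max_delay_ms, animal, regime
        )
        out[(hemi, "same_S1")] = same
        out[(hemi, "other_S1")] = other
    return out


def collapse_references(matrix_a: DelayMatrix, matrix_b: DelayMatrix) -> DelayMatrix:
    """Pool the contra- and ipsi-spike matrices of one reference.

    Count-weighted pooling, equivalent to pooling the underlying spike
    pairs; used because delays following spikes in either hemisphere are
    treated as exchangeable.
    """
    if matrix_a.reference != matrix_b.reference:
        raise ValueError("cannot collapse matrices with different references")
    if matrix_a.regime != matrix_b.regime:
        raise ValueError("cannot collapse matrices from different regimes")
    ca, cb = matrix_a.count, matrix_b.count
    c = ca + cb
    s = np.where(ca > 0, matrix_a.mean_delay_ms * ca, 0.0) + np.where(
        cb > 0, matrix_b.mean_delay_ms * cb, 0.0
    )
    with np.errstate(invalid="ignore"):
        mean = np.where(c > 0, s / np.maximum(c, 1), np.nan)
    return DelayMatrix(
        reference=matrix_a.reference,
        spike_hemisphere="collapsed",
        mean_delay_ms=mean,
        count=c,
        max_delay_ms=matrix_a.max_delay_ms,
        animal_id=matrix_a.animal_id,
        regime=matrix_a.regime,
    )


def average_matrices(matrices: list[DelayMatrix]) -> DelayMatrix:
    """Across-animal grand average: unweighted cell-wise mean of defined cells."""
    if not matrices:
        raise ValueError("no matrices to average")
    stack = np.stack([m.mean_delay_ms for m in matrices])
    counts = np.stack([m.count for m in matrices])
    defined = counts > 0
    n_def = defined.sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(
            n_def > 0,
            np.nansum(np.where(defined, stack, 0.0), axis=0) / np.maximum(n_def, 1),
            np.nan,
        )
    return DelayMatrix(
        reference=matrices[0].reference,
        spike_hemisphere=matrices[0].spike_hemisphere,
        mean_delay_ms=mean,
        count=counts.sum(axis=0),
        max_delay_ms=matrices[0].max_delay_ms,
        animal_id=None,
        regime=matrices[0].regime,
    )


_UPWARD = np.fromfunction(lambda s, t: t < s, (N_LAYERS, N_LAYERS), dtype=int)
_DOWNWARD = np.fromfunction(lambda s, t: t > s, (N_LAYERS, N_LAYERS), dtype=int)
_DEEP_TARGET = np.zeros((N_LAYERS, N_LAYERS), dtype=bool)
_DEEP_TARGET[:, 3:] = True  # target layers L4-L6
_SUP_TARGET = ~_DEEP_TARGET  # target layers L1-L3
_DEEP_SPIKE = np.zeros((N_LAYERS, N_LAYERS), dtype=bool)
_DEEP_SPIKE[3:, :] = True  # spike layers L4-L6
_SUP_SPIKE = ~_DEEP_SPIKE


def delay_ratio(matrix: DelayMatrix) -> float:
    """Mean delay after deep-layer spikes / after superficial-layer spikes.

    Exceeds 1 when upward delays dominate; near 1 when delays only reflect
    target-layer spike rates.
    """
    deep = mean_over_defined(matrix.mean_delay_ms, matrix.count, _DEEP_SPIKE)
    sup = mean_over_defined(matrix.mean_delay_ms, matrix.count, _SUP_SPIKE)
    return deep / sup


def summarize(matrix_same: DelayMatrix, matrix_other: DelayMatrix) -> DelaySummary:
    """Triangle means (spike S1), deep/superficial means (other S1), ratios.

    Upward cells are those whose target layer is more superficial than the
    spike layer. Cells with zero count are excluded, not imputed; an empty
    partition yields NaN.
    """
    up = mean_over_defined(matrix_same.mean_delay_ms, matrix_same.count, _UPWARD)
    down = mean_over_defined(matrix_same.mean_delay_ms, matrix_same.count, _DOWNWARD)
    deep = mean_over_defined(matrix_other.mean_delay_ms, matrix_other.count, _DEEP_TARGET)
    sup = mean_over_defined(matrix_other.mean_delay_ms, matrix_other.count, _SUP_TARGET)
    return DelaySummary(
        upward_mean_ms=up,
        downward_mean_ms=down,
        deep_mean_ms=deep,
        superficial_mean_ms=sup,
        delay_ratio_same=delay_ratio(matrix_same),
        delay_ratio_other=delay_ratio(matrix_other),
    )


def epoch_events(
    events: pd.DataFrame,
    spec: EpochSpec,
    stimulus_onsets_ms: np.ndarray,
) -> pd.DataFrame:
    """Cut absolute-time events into stimulus-aligned epochs.

    Events outside every window are dropped; kept events get the epoch
    index of their stimulus and a time re-referenced to that stimulus
    onset (so an evoked spike 59.9 ms after its stimulus has
    time_ms = 59.9). Windows are half-open [start, end).
    """
    onsets = np.asarray(stimulus_onsets_ms, dtype=float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("stimulus onsets must be sorted")
    start, end = spec.bounds_ms()
    if len(onsets) > 1 and np.any(np.diff(onsets) < end):
        raise ValueError("epoch windows overlap adjacent stimuli")
    t = events["time_ms"].to_numpy(float)
    # index of the last onset at or before each event
    idx = np.searchsorted(onsets, t, side="right") - 1
    rel = np.where(idx >= 0, t - onsets[np.clip(idx, 0, None)], np.nan)
    keep = (idx >= 0) & (rel >= start) & (rel < end)
    out = events.loc[keep].copy()
    out["epoch"] = idx[keep]
    out["time_ms"] = rel[keep]
    out["regime"] = spec.regime
    return out.sort_values(
        ["animal_id", "epoch", "time_ms", "hemisphere", "layer"], kind="stable"
    ).reset_index(drop=True)


def spike_likelihood(
    events: pd.DataFrame,
    bin_ms: float = 1.0,
    n_trials: int | None = None,
    window_ms: tuple[float, float] | None = None,
    peak_search_ms: dict[str, tuple[float, float]] | None = None,
) -> dict[str, LikelihoodProfile]:
    """Per-layer probability across trials of >=1 spike per time bin.

    ``n_trials`` defaults to the number of distinct epochs present.
    ``peak_search_ms`` restricts where the peak latency is looked up;
    by default the contralateral peak is searched below 10 ms (the early
    evoked response) and the ipsilateral over the whole window.
    """
    if n_trials is None:
        n_trials = int(events["epoch"].nunique())
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if window_ms is None:
        t = events["time_ms"].to_numpy(float)
        window_ms = (0.0, float(t.max()) + bin_ms if len(t) else bin_ms)
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms, bin_ms)
    if peak_search_ms is None:
        peak_search_ms = {"contra": (window_ms[0], 10.0), "ipsi": window_ms}
    profiles: dict[str, LikelihoodProfile] = {}
    for hemi in HEMISPHERES:
        lik = np.zeros((N_LAYERS, len(edges) - 1))
        for layer in LAYERS:
            sub = events[(events["hemisphere"] == hemi) & (events["layer"] == layer)]
            if len(sub):
                grp = sub.groupby("epoch")["time_ms"]
                hit = np.zeros(len(edges) - 1)
                for _, times in grp:
                    h, _ = np.histogram(times.to_numpy(float), bins=edges)
                    hit += h > 0
                lik[layer - 1] = hit / n_trials
        centres = (edges[:-1] + edges[1:]) / 2.0
        lo, hi = peak_search_ms.get(hemi, window_ms)
        search = (centres >= lo) & (centres < hi)
        peak = np.full(N_LAYERS, np.nan)
        for layer in LAYERS:
            row = lik[layer - 1]
            if search.any() and row[search].max() > 0:
                sub_idx = np.flatnonzero(search)
                peak[layer - 1] = centres[sub_idx[np.argmax(row[search])]]
        profiles[hemi] = LikelihoodProfile(
            hemisphere=hemi,
            bin_edges_ms=edges,
            likelihood=lik,
            peak_latency_ms=peak,
            n_trials=n_trials,
        )
    return profiles
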