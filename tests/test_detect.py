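"""Detection: filtering, thresholds, crossing logic, oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from lamidelay.detect import (
    DetectionParams,
    DegenerateSignalError,
    ParameterError,
    bandpass,
    detect_spikes,
    estimate_threshold,
)
from lamidelay.synthgen import default_channels, synthesize_recording
from lamidelay.types import LaminarRecording

FS = 6250.0


def one_channel_recording(x, onsets=()):
    return LaminarRecording(
        samples=np.asarray(x, dtype=np.float32)[None, :],
        sampling_rate_hz=FS,
        channels=[("contra", 4, -0.75)],
        stimulus_onsets_ms=np.asarray(onsets, dtype=float),
    )


def test_bandpass_attenuates_stopband_and_preserves_passband():
    t = np.arange(int(FS)) / FS
    slow = np.sin(2 * np.pi * 10 * t)
    fast = np.sin(2 * np.pi * 1000 * t)
    out_slow = bandpass(one_channel_recording(slow), 500, 3000).samples[0]
    out_fast = bandpass(one_channel_recording(fast), 500, 3000).samples[0]
    mid = slice(int(FS * 0.2), int(FS * 0.8))  # avoid filter edge transients
    assert np.abs(out_slow[mid]).max() < 0.01
    assert np.abs(out_fast[mid]).max() == pytest.approx(1.0, rel=0.05)


def test_bandpass_reduces_white_noise_variance():
    rng = np.random.default_rng(0)
    x = rng.normal(size=20000)
    out = bandpass(one_channel_recording(x), 500, 3000).samples[0]
    assert out.var() < x.var()


def test_band_outside_nyquist_rejected():
    with pytest.raises(ParameterError):
        bandpass(one_channel_recording(np.zeros(100)), 500, 4000)


def test_threshold_matches_sample_sd_and_scales_homogeneously():
    rng = np.random.default_rng(1)
    x = rng.normal(0, 1, 200_000)
    thr = estimate_threshold(x, 5.0, "plain_sd")
    assert thr == pytest.approx(-5.0, rel=0.02)
    assert estimate_threshold(2 * x, 5.0, "plain_sd") == pytest.approx(2 * thr)
    robust = estimate_threshold(x, 5.0, "robust_median")
    assert robust == pytest.approx(thr, rel=0.05)


def test_constant_signal_threshold_is_degenerate():
    with pytest.raises(DegenerateSignalError):
        estimate_threshold(np.ones(100), 5.0, "plain_sd")


def naive_detection_scan(x, threshold, dead_samples):
    """Sample-by-sample reference detector."""
    out, last = [], None
    for i in range(len(x)):
        prev_below = i > 0 and x[i - 1] < threshold
        if x[i] < threshold and not prev_below:
            if last is None or i - last > dead_samples:
                out.append(i)
                last = i
    return out


def test_detection_matches_naive_scan_exactly():
    rng = np.random.default_rng(2)
    for _ in range(5):
        x = rng.normal(0, 1, 5000)
        rec = one_channel_recording(x)
        params = DetectionParams(apply_bandpass=False, threshold_multiplier=2.0,
                                 noise_estimator="plain_sd")
        events = detect_spikes(rec, params)
        thr = estimate_threshold(x.astype(np.float32).astype(float), 2.0, "plain_sd")
        dead = int(round(1.0 / 1000 * FS))
        expected = naive_detection_scan(rec.samples[0].astype(float), thr, dead)
        got = np.round(events.time_ms.to_numpy() / 1000 * FS).astype(int)
        np.testing.assert_array_equal(np.sort(got), expected)


def test_flat_signal_yields_no_events():
    events = detect_spikes(one_channel_recording(np.zeros(1000)),
                           DetectionParams(apply_bandpass=False))
    assert len(events) == 0


def test_event_count_non_increasing_in_threshold_multiplier():
    rng = np.random.default_rng(3)
    rec = one_channel_recording(rng.normal(0, 1, 20000))
    counts = [
        len(detect_spikes(rec, DetectionParams(apply_bandpass=False,
                                               threshold_multiplier=m,
                                               noise_estimator="plain_sd")))
        for m in (1.5, 2.0, 2.5, 3.0, 4.0)
    ]
    assert counts == sorted(counts, reverse=True)


def test_detection_equivariant_to_global_scaling():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 20000)
    p = DetectionParams(apply_bandpass=False, threshold_multiplier=3.0)
    a = detect_spikes(one_channel_recording(x), p)
    b = detect_spikes(one_channel_recording(7.5 * x), p)
    pd.testing.assert_frame_equal(a, b)


def test_injected_transients_recovered_and_artifact_window_excluded():
    rng = np.random.default_rng(5)
    times = np.sort(rng.uniform(100, 4900, 30))
    onset = 2000.0
    times = times[np.abs(times - onset) > 40]  # keep clear of the stimulus
    probe = np.array([onset + 3.0])  # inside the 0-5 ms artifact window
    all_times = np.sort(np.concatenate([times, probe]))
    ev = pd.DataFrame({"hemisphere": "contra", "layer": 4, "time_ms": all_times})
    rec = synthesize_recording(ev, 5000.0, default_channels(), FS, 1.0, 10.0,
                               np.array([onset]), rng)
    det = detect_spikes(rec, DetectionParams(apply_bandpass=False))
    det = det[(det.hemisphere == "contra") & (det.layer == 4)]
    assert len(det) == len(times)
    assert np.abs(det.time_ms.to_numpy() - times).max() <= 1000.0 / FS + 1e-9
    assert not ((det.time_ms > onset) & (det.time_ms < onset + 5.0)).any()
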