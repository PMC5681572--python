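"""Delay matrices: oracle equivalence, summaries, epoching, likelihoods."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lamidelay.delays import (
    collapse_references,
    delay_matrices,
    delay_ratio,
    epoch_events,
    next_spike_delays,
    spike_likelihood,
    summarize,
)
from lamidelay.types import (
    DelayMatrix,
    EpochSpec,
    HEMISPHERES,
    channel_index,
)
from conftest import make_events, random_events


def brute_force_sums(events, max_delay_ms=30.0):
    """Per-spike double-loop oracle: 12x12 delay sums and counts."""
    sums = np.zeros((12, 12))
    counts = np.zeros((12, 12), dtype=int)
    recs = [
        (int(r.epoch), channel_index(r.hemisphere, int(r.layer)), float(r.time_ms))
        for r in events.itertuples()
    ]
    for ep_i, ch_i, t_i in recs:
        for target in range(12):
            best = None
            for ep_j, ch_j, t_j in recs:
                if ep_j != ep_i or ch_j != target:
                    continue
                dt = t_j - t_i
                if 0 < dt <= max_delay_ms and (best is None or dt < best):
                    best = dt
            if best is not None:
                sums[ch_i, target] += best
                counts[ch_i, target] += 1
    return sums, counts


def matrices_from_brute_force(events, spike_hemisphere, max_delay_ms=30.0):
    sums, counts = brute_force_sums(events, max_delay_ms)
    h = HEMISPHERES.index(spike_hemisphere)
    blocks = {}
    for ref, th in (("same_S1", h), ("other_S1", 1 - h)):
        s = sums[h * 6 : h * 6 + 6, th * 6 : th * 6 + 6].copy()
        c = counts[h * 6 : h * 6 + 6, th * 6 : th * 6 + 6].copy()
        if ref == "same_S1":
            np.fill_diagonal(s, 0)
            np.fill_diagonal(c, 0)
        blocks[ref] = (s, c)
    return blocks


def assert_matches_oracle(events, max_delay_ms=30.0):
    for hemi in HEMISPHERES:
        same, other = next_spike_delays(events, max_delay_ms, spike_hemisphere=hemi)
        blocks = matrices_from_brute_force(events, hemi, max_delay_ms)
        for mat, ref in ((same, "same_S1"), (other, "other_S1")):
            s, c = blocks[ref]
            np.testing.assert_array_equal(mat.count, c)
            got_sums = np.where(c > 0, mat.mean_delay_ms * c, 0.0)
            np.testing.assert_allclose(got_sums, s, rtol=0, atol=1e-9)


def test_single_pair_example():
    events = make_events([("contra", 5, 10.0), ("contra", 4, 12.0)])
    same, _ = next_spike_delays(events)
    assert same.mean_delay_ms[4, 3] == pytest.approx(2.0)
    assert same.count[4, 3] == 1
    assert same.count.sum() == 1  # nothing follows the L4 spike


def test_delay_beyond_horizon_is_dropped():
    events = make_events([("contra", 5, 10.0), ("contra", 4, 45.1)])
    same, _ = next_spike_delays(events, max_delay_ms=30.0)
    assert same.count.sum() == 0


def test_simultaneous_spikes_do_not_count_as_next():
    events = make_events([("contra", 5, 10.0), ("contra", 4, 10.0), ("contra", 4, 11.0)])
    same, _ = next_spike_delays(events)
    assert same.mean_delay_ms[4, 3] == pytest.approx(1.0)
    assert same.count[4, 3] == 1


def test_delays_never_cross_epoch_boundaries():
    events = make_events([("contra", 5, 55.0, 0), ("contra", 4, 2.0, 1)])
    same, _ = next_spike_delays(events)
    assert same.count.sum() == 0


def test_matches_brute_force_oracle_on_random_events():
    rng = np.random.default_rng(10)
    for _ in range(5):
        events = random_events(rng, n=150, n_epochs=4, span_ms=80.0)
        assert_matches_oracle(events)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(2, 60),
    horizon=st.sampled_from([5.0, 15.0, 30.0]),
)
def test_oracle_equivalence_property(seed, n, horizon):
    events = random_events(np.random.default_rng(seed), n=n, n_epochs=3, span_ms=40.0)
    assert_matches_oracle(events, horizon)


def test_results_invariant_to_input_record_order():
    rng = np.random.default_rng(11)
    events = random_events(rng, n=200)
    shuffled = events.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a_same, a_other = next_spike_delays(events)
    b_same, b_other = next_spike_delays(shuffled)
    np.testing.assert_array_equal(a_same.count, b_same.count)
    np.testing.assert_allclose(a_same.mean_delay_ms, b_same.mean_delay_ms)
    np.testing.assert_allclose(a_other.mean_delay_ms, b_other.mean_delay_ms)


def test_shrinking_horizon_never_increases_counts():
    rng = np.random.default_rng(12)
    events = random_events(rng, n=300)
    wide, _ = next_spike_delays(events, max_delay_ms=30.0)
    for horizon in (20.0, 10.0, 5.0, 1.0):
        narrow, _ = next_spike_delays(events, max_delay_ms=horizon)
        assert (narrow.count <= wide.count).all()
        wide = narrow


def _matrix(mean, count, reference="same_S1"):
    return DelayMatrix(
        reference=reference, spike_hemisphere="collapsed",
        mean_delay_ms=np.asarray(mean, float), count=np.asarray(count, int),
    )


def test_collapse_is_count_weighted_pooling():
    m = np.full((6, 6), np.nan)
    c = np.zeros((6, 6), int)
    m2, c2 = m.copy(), c.copy()
    m[1, 0], c[1, 0] = 2.0, 1
    m2[1, 0], c2[1, 0] = 4.0, 1  # balanced -> 3
    m[2, 0], c[2, 0] = 2.0, 3
    m2[2, 0], c2[2, 0] = 6.0, 1  # weighted -> 3
    m[3, 0], c[3, 0] = 5.0, 2  # other matrix empty -> 5
    a = _matrix(m, c)
    b = _matrix(m2, c2)
    pooled = collapse_references(a, b)
    assert pooled.mean_delay_ms[1, 0] == pytest.approx(3.0)
    assert pooled.mean_delay_ms[2, 0] == pytest.approx(3.0)
    assert pooled.mean_delay_ms[3, 0] == pytest.approx(5.0)
    assert pooled.count[2, 0] == 4


def test_collapse_rejects_mismatched_references():
    a = _matrix(np.full((6, 6), np.nan), np.zeros((6, 6)), "same_S1")
    b = _matrix(np.full((6, 6), np.nan), np.zeros((6, 6)), "other_S1")
    with pytest.raises(ValueError):
        collapse_references(a, b)


def test_uniform_matrix_summary_is_flat_with_unit_ratio():
    mean = np.full((6, 6), 4.0)
    np.fill_diagonal(mean, np.nan)
    count = np.ones((6, 6), int)
    np.fill_diagonal(count, 0)
    same = _matrix(mean, count)
    other = _matrix(np.full((6, 6), 4.0), np.ones((6, 6), int), "other_S1")
    s = summarize(same, other)
    assert s.upward_mean_ms == pytest.approx(4.0)
    assert s.downward_mean_ms == pytest.approx(4.0)
    assert s.delay_ratio_same == pytest.approx(1.0)
    assert s.delay_ratio_other == pytest.approx(1.0)


def test_graded_upward_cells_raise_upward_mean_and_ratio():
    mean = np.full((6, 6), np.nan)
    count = np.zeros((6, 6), int)
    for s_l in range(1, 7):
        for t_l in range(1, 7):
            if t_l < s_l:
                mean[s_l - 1, t_l - 1] = abs(s_l - t_l) * 1.0
            elif t_l > s_l:
                mean[s_l - 1, t_l - 1] = 1.0
            else:
                continue
            count[s_l - 1, t_l - 1] = 1
    same = _matrix(mean, count)
    s = summarize(same, same)
    assert s.upward_mean_ms > s.downward_mean_ms
    assert delay_ratio(same) > 1.0


def test_summary_flags_empty_partition_as_nan():
    mean = np.full((6, 6), np.nan)
    count = np.zeros((6, 6), int)
    mean[0, 1], count[0, 1] = 2.0, 1  # only a downward cell
    same = _matrix(mean, count)
    s = summarize(same, _matrix(mean, count, "other_S1"))
    assert np.isnan(s.upward_mean_ms)
    assert s.downward_mean_ms == pytest.approx(2.0)


def abs_events(times):
    return pd.DataFrame(
        {
            "animal_id": 0, "epoch": -1, "regime": "raw",
            "hemisphere": "contra", "layer": 4, "time_ms": times,
        }
    )


def test_evoked_epoching_window_and_rereferencing():
    onsets = np.array([100.0, 1500.0])
    out = epoch_events(abs_events([104.0, 159.9, 160.0, 1495.0, 1507.0]),
                       EpochSpec("evoked"), onsets)
    # +4 ms dropped (window starts at 5), +59.9 kept, +60.0 dropped (half-open)
    np.testing.assert_allclose(out.time_ms.to_numpy(), [59.9, 7.0])
    assert out.epoch.tolist() == [0, 1]


def test_spontaneous_epoching_starts_2s_after_stimulus():
    onsets = np.array([100.0])
    out = epoch_events(abs_events([100 + 1500.0, 100 + 2500.0, 100 + 9500.0]),
                       EpochSpec("spontaneous"), onsets)
    assert out.time_ms.tolist() == [2500.0]


def test_overlapping_epoch_windows_rejected():
    with pytest.raises(ValueError):
        epoch_events(abs_events([10.0]), EpochSpec("spontaneous"),
                     np.array([0.0, 5000.0]))


def test_spike_likelihood_certain_bin_and_peak_center():
    events = make_events([("contra", 4, 8.2, e) for e in range(10)])
    prof = spike_likelihood(events, bin_ms=1.0, n_trials=10, window_ms=(0.0, 20.0))
    lik = prof["contra"].likelihood[3]
    assert lik[8] == pytest.approx(1.0)
    assert lik.sum() == pytest.approx(1.0)
    assert prof["contra"].peak_latency_ms[3] == pytest.approx(8.5)


def test_spike_likelihood_empty_layer_has_undefined_peak():
    events = make_events([("contra", 4, 8.2, 0)])
    prof = spike_likelihood(events, bin_ms=1.0, n_trials=5, window_ms=(0.0, 20.0))
    assert np.isnan(prof["ipsi"].peak_latency_ms).all()
    assert prof["ipsi"].likelihood.sum() == 0


def test_evoked_granular_layers_peak_no_later_than_supragranular(recovery_data):
    _, events, _ = recovery_data
    prof = spike_likelihood(events, bin_ms=1.0, n_trials=200, window_ms=(5.0, 60.0))
    peaks = prof["contra"].peak_latency_ms
    assert max(peaks[3], peaks[4]) <= min(peaks[0], peaks[1], peaks[2])


def test_grand_average_matrix_is_cellwise_mean_of_defined_cells():
    from lamidelay.delays import average_matrices

    m1 = np.full((6, 6), np.nan); c1 = np.zeros((6, 6), int)
    m2 = np.full((6, 6), np.nan); c2 = np.zeros((6, 6), int)
    m1[1, 0], c1[1, 0] = 2.0, 5
    m2[1, 0], c2[1, 0] = 4.0, 1
    m1[2, 0], c1[2, 0] = 3.0, 2  # defined in one animal only
    avg = average_matrices([_matrix(m1, c1), _matrix(m2, c2)])
    assert avg.mean_delay_ms[1, 0] == pytest.approx(3.0)  # unweighted across animals
    assert avg.mean_delay_ms[2, 0] == pytest.approx(3.0)
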