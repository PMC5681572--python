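"""Label-shuffle rate control and animal-level percentile bootstrap.

The shuffle control permutes the 12 (hemisphere, layer) labels uniformly at
random across all spikes of one animal (times fixed), destroying temporal
structure while preserving per-channel spike counts. Delay matrices
recomputed from shuffled data therefore reflect spike rates only; delay
ratios near 1 under shuffling indicate that an observed ratio above 1 is
not a rate artifact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .delays import (
    DEFAULT_MAX_DELAY_MS,
    _channel_arrays,
    collapse_references,
    delay_ratio,
    delay_sums_by_channel,
    matrices_from_sums,
)
from .types import BootstrapResult, DelayMatrix, N_CHANNELS, ShuffleResult


def _collapsed_matrices(sums, counts, max_delay_ms, animal_id, regime):
    same_c, other_c = matrices_from_sums(sums, counts, "contra", max_delay_ms, animal_id, regime)
    same_i, other_i = matrices_from_sums(sums, counts, "ipsi", max_delay_ms, animal_id, regime)
    return collapse_references(same_c, same_i), collapse_references(other_c, other_i)


def shuffle_labels(
    events: pd.DataFrame,
    n_shuffles: int = 1000,
    seed: int = 0,
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS,
    per_epoch: bool = False,
) -> ShuffleResult:
    """Expected delay matrices and ratio distribution under label exchange.

    Labels are permuted across all of one animal's spikes, pooled over
    epochs (``per_epoch=True`` instead permutes within each epoch). Each
    permutation preserves the multiset of labels and of spike times
    exactly. Matrices returned are averaged cell-wise over shuffles after
    collapsing the two spike hemispheres.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    times, chan, epoch = _channel_arrays(events)
    animal = int(events["animal_id"].iloc[0]) if len(events) else None
    regime = str(events["regime"].iloc[0]) if len(events) else None
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    mean_stack_same = np.zeros((6, 6))
    ndef_same = np.zeros((6, 6))
    count_same = np.zeros((6, 6), dtype=np.int64)
    mean_stack_other = np.zeros((6, 6))
    ndef_other = np.zeros((6, 6))
    count_other = np.zeros((6, 6), dtype=np.int64)
    ratios_same = np.full(n_shuffles, np.nan)
    ratios_other = np.full(n_shuffles, np.nan)
    for k in range(n_shuffles):
        if per_epoch:
            shuf = chan.copy()
            for e in np.unique(epoch):
                m = epoch == e
                shuf[m] = rng.permutation(chan[m])
        else:
            shuf = rng.permutation(chan)
        sums, counts = delay_sums_by_channel(times, shuf, epoch, max_delay_ms)
        same, other = _collapsed_matrices(sums, counts, max_delay_ms, animal, regime)
        for mat, acc, nd, ct, ratios in (
            (same, mean_stack_same, ndef_same, count_same, ratios_same),
            (other, mean_stack_other, ndef_other, count_other, ratios_other),
        ):
            defined = mat.count > 0
            acc[defined] += mat.mean_delay_ms[defined]
            nd += defined
            ct += mat.count
            ratios[k] = delay_ratio(mat)
    def finish(acc, nd, ct, reference):
        with np.errstate(invalid="ignore"):
            mean = np.where(nd > 0, acc / np.maximum(nd, 1), np.nan)
        ct = ct // n_shuffles  # per-shuffle average pair count
        return DelayMatrix(
            reference=reference,
            spike_hemisphere="collapsed",
            mean_delay_ms=mean,
            count=ct,
            max_delay_ms=max_delay_ms,
            animal_id=animal,
            regime=regime,
        )
    return ShuffleResult(
        n_shuffles=n_shuffles,
        seed=seed,
        mean_matrix_same=finish(mean_stack_same, ndef_same, count_same, "same_S1"),
        mean_matrix_other=finish(mean_stack_other, ndef_other, count_other, "other_S1"),
        ratio_same=ratios_same,
        ratio_other=ratios_other,
    )


def bootstrap_diff(
    per_animal_a: np.ndarray,
    per_animal_b: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
) -> BootstrapResult:
    """Paired nonparametric bootstrap of a mean difference across animals.

    Animals are resampled with replacement, keeping each animal's paired
    (a, b) values together; the 95% CI is the 2.5/97.5 percentile interval
    of the resampled mean differences. Suited to small samples with no
    distributional assumption.
    """
    a = np.asarray(per_animal_a, dtype=float)
    b = np.asarray(per_animal_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired per-animal value arrays must match in length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 animals for resampling")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    diffs = a - b
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = diffs[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return BootstrapResult(
        mean_difference=float(diffs.mean()),
        ci_95=(float(lo), float(hi)),
        n_boot=n_boot,
        seed=seed,
        n=n,
    )
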