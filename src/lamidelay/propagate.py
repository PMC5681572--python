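"""Propagation velocity and layer-vs-depth model comparison.

Upward propagation velocity is estimated by ordinary least squares of mean
next-spike delay (ms) on cortical depth (mm); the fitted slope has units
ms/mm, so velocity is reported as 1/|slope| (mm/ms, numerically equal to
m/s). Within the spike hemisphere only spikes in L4-L6 have enough upward
target layers (3-5 points) for a line; toward the other hemisphere all six
target layers are available for every spike layer.

Whether the upward progression is step-wise across layers or continuous
through tissue is decided by comparing two linear models that differ only
in their predictor depths — equally spaced per-layer depths (layer model,
M1) versus the unequally spaced actual recording depths (depth model, M2).
With least-squares fits and a Gaussian residual model, evidence is
summarised by the BIC-approximated Bayes factor

    B12 = exp(-(BIC1 - BIC2) / 2),

B12 > 1 favouring the layer model, and B12 > 3 (resp. < 1/3) conventionally
read as positive evidence for the layer (resp. depth) model. Both models
share k = 2 parameters, so the residual variance is the only discriminator.
"""

from __future__ import annotations

import math

import numpy as np

from .types import BayesFactorResult, DelayMatrix, LayerGeometry, VelocityFit


class FitError(ValueError):
    pass


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, rss)."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(resid @ resid)


def upward_targets(spike_layer: int) -> np.ndarray:
    """Indices (0-based) of target layers above a spike layer."""
    return np.arange(0, spike_layer - 1)


def fit_velocity(
    delay_row: np.ndarray,
    spike_layer: int,
    reference: str,
    geometry: LayerGeometry | None = None,
    depths: np.ndarray | None = None,
) -> VelocityFit:
    """Fit delay vs depth for one spike layer and report the velocity.

    ``delay_row`` holds the mean delay to each target layer L1..L6 (NaN
    where undefined). For the spike hemisphere only upward targets are
    used and ``spike_layer`` must be 4-6; toward the other hemisphere all
    defined targets are used. The spike's own point (zero delay at its own
    depth) is never included. Default predictor depths are the equally
    spaced layer-model depths.
    """
    geometry = geometry or LayerGeometry()
    x_all = geometry.layer_depths_mm if depths is None else np.asarray(depths, float)
    row = np.asarray(delay_row, dtype=float)
    if reference == "same_S1":
        if spike_layer < 4:
            raise FitError("spike layers L4-L6 required in the spike hemisphere")
        sel = upward_targets(spike_layer)
    elif reference == "other_S1":
        sel = np.arange(6)
    else:
        raise FitError(f"unknown reference {reference!r}")
    sel = sel[np.isfinite(row[sel])]
    if sel.size < 3:
        raise FitError(f"need >= 3 defined target delays, got {sel.size}")
    slope, intercept, rss = _ols(row[sel], x_all[sel])
    velocity = math.nan if slope == 0 else 1.0 / abs(slope)
    return VelocityFit(
        spike_layer=spike_layer,
        reference=reference,
        slope_ms_per_mm=slope,
        intercept_ms=intercept,
        velocity_m_per_s=velocity,
        n_points=int(sel.size),
        rss=rss,
    )


def bic_linear_fit(delay_row: np.ndarray, predictor_depths: np.ndarray) -> tuple[float, float]:
    """(rss, BIC) of a straight-line fit under a Gaussian residual model.

    BIC = n ln(rss/n) + k ln(n) with k = 2 (slope, intercept); additive
    constants cancel in BIC differences. A perfect fit (rss = 0) yields
    -inf, flagged to the caller by the value itself.
    """
    y = np.asarray(delay_row, dtype=float)
    x = np.asarray(predictor_depths, dtype=float)
    if y.shape != x.shape:
        raise FitError("delays and predictor depths must align")
    n = y.size
    k = 2
    if n <= k:
        raise FitError(f"need more than {k} points for a meaningful BIC, got {n}")
    _, _, rss = _ols(y, x)
    if rss <= 1e-12 * max(1.0, float(y @ y)):  # numerically perfect fit
        return 0.0, -math.inf
    bic = n * math.log(rss / n) + k * math.log(n)
    return rss, bic


def bayes_factor(
    delay_row: np.ndarray,
    geometry: LayerGeometry | None = None,
    spike_layer: int | None = None,
    reference: str = "other_S1",
) -> BayesFactorResult:
    """Layer-vs-depth Bayes factor for one spike layer's delay row.

    The layer model is fitted on the equally spaced depths, the depth model
    on the actual recording depths, at the same target layers; the two
    models are assumed equally likely a priori.
    """
    geometry = geometry or LayerGeometry()
    row = np.asarray(delay_row, dtype=float)
    if reference == "same_S1":
        if spike_layer is None or spike_layer < 4:
            raise FitError("spike layers L4-L6 required in the spike hemisphere")
        sel = upward_targets(spike_layer)
    else:
        sel = np.arange(6)
    sel = sel[np.isfinite(row[sel])]
    if sel.size < 3:
        raise FitError(f"need >= 3 defined target delays, got {sel.size}")
    _, bic_layer = bic_linear_fit(row[sel], geometry.layer_depths_mm[sel])
    _, bic_depth = bic_linear_fit(row[sel], geometry.recording_depths_mm[sel])
    if math.isinf(bic_layer) and math.isinf(bic_depth):
        bf = 1.0
    else:
        bf = math.exp(-(bic_layer - bic_depth) / 2.0)
    return BayesFactorResult(
        spike_layer=spike_layer,
        reference=reference,
        bic_layer=bic_layer,
        bic_depth=bic_depth,
        bf=bf,
    )


def velocity_row(matrix: DelayMatrix, spike_layer: int) -> np.ndarray:
    """Target-layer delay row (L1..L6) of one matrix for a given spike layer."""
    return matrix.mean_delay_ms[spike_layer - 1].copy()


def fit_velocities(
    matrix: DelayMatrix, geometry: LayerGeometry | None = None
) -> list[VelocityFit]:
    """Velocity fits for every admissible spike layer of one delay matrix."""
    layers = (4, 5, 6) if matrix.reference == "same_S1" else (1, 2, 3, 4, 5, 6)
    fits = []
    for s in layers:
        try:
            fits.append(
                fit_velocity(velocity_row(matrix, s), s, matrix.reference, geometry)
            )
        except FitError:
            continue
    return fits


def bayes_factors(
    matrix: DelayMatrix, geometry: LayerGeometry | None = None
) -> list[BayesFactorResult]:
    """Bayes factors for every admissible spike layer of one delay matrix."""
    layers = (4, 5, 6) if matrix.reference == "same_S1" else (1, 2, 3, 4, 5, 6)
    out = []
    for s in layers:
        try:
            out.append(
                bayes_factor(velocity_row(matrix, s), geometry, s, matrix.reference)
            )
        except FitError:
            continue
    return out


def mean_bayes_factor(per_animal: list[BayesFactorResult]) -> float:
    """Arithmetic mean of per-animal Bayes factors (robust to single outliers
    relative to multiplying evidence across animals)."""
    if not per_animal:
        return math.nan
    return float(np.mean([r.bf for r in per_animal]))
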