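"""Separate the T2* and T1 contributions of a dual-gradient-echo signal.

With two gradient echoes acquired per excitation the mono-exponential TE decay
``S(TE, t) = T1w(t) * exp(-TE * R2*(t))`` can be solved per voxel and frame:

* ``R2*(t) = ln(S1(t)/S2(t)) / (TE2 - TE1)`` — the transverse relaxation rate,
  whose change from its pre-bolus baseline is the pure T2* contribution,
  insensitive to any common signal scaling.
* ``T1w(t) = S1(t) * (S1(t)/S2(t)) ** (TE1/(TE2-TE1))`` — the signal
  extrapolated to TE = 0, the isolated T1-weighted contribution.

All curve functions accept either a single time curve (1D) or a stacked array
of curves whose last axis is time.
"""

from __future__ import annotations

import numpy as np

from .params import AcquisitionParams

#: Fraction of invalid timepoints above which a voxel is rejected outright.
INVALID_FRACTION_LIMIT = 0.20


def _validate_pair(e1: np.ndarray, e2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e1 = np.asarray(e1, dtype=float)
    e2 = np.asarray(e2, dtype=float)
    if e1.shape != e2.shape:
        raise ValueError(f"echo shapes differ: {e1.shape} vs {e2.shape}")
    return e1, e2


def compute_r2star_curve(
    e1: np.ndarray, e2: np.ndarray, params: AcquisitionParams
) -> np.ndarray:
    """Per-voxel change in transverse relaxation rate, ΔR2*(t) [s^-1].

    Baseline-centred: the mean over ``params.baseline_window`` is subtracted,
    so the returned curve averages zero pre-bolus by construction. Frames with
    a non-positive signal in either echo are NaN; voxels with more than 20 %
    invalid frames are fully NaN.
    """
    e1, e2 = _validate_pair(e1, e2)
    start, stop = params.baseline_window
    valid = (e1 > 0) & (e2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2star = np.where(valid, np.log(e1 / e2), np.nan) / (params.te2 - params.te1)
    baseline = np.nanmean(r2star[..., start:stop], axis=-1, keepdims=True)
    delta = r2star - baseline
    frac_invalid = 1.0 - valid.mean(axis=-1)
    delta[frac_invalid > INVALID_FRACTION_LIMIT] = np.nan
    return delta


def compute_t1w_curve(
    e1: np.ndarray, e2: np.ndarray, params: AcquisitionParams
) -> np.ndarray:
    """Signal extrapolated to TE = 0, T1w(t) [arbitrary units].

    For a mono-exponential pair ``S(TE) = M * exp(-TE*R2*)`` this returns M
    exactly. Scales linearly with any common gain applied to both echoes.
    """
    e1, e2 = _validate_pair(e1, e2)
    valid = (e1 > 0) & (e2 > 0)
    expo = params.te1 / (params.te2 - params.te1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1w = np.where(valid, e1 * (e1 / e2) ** expo, np.nan)
    frac_invalid = 1.0 - valid.mean(axis=-1)
    t1w[frac_invalid > INVALID_FRACTION_LIMIT] = np.nan
    return t1w


def baseline_mean(curve: np.ndarray, params: AcquisitionParams) -> np.ndarray:
    """Mean of a time curve over the pre-bolus baseline window (NaN-aware)."""
    start, stop = params.baseline_window
    curve = np.asarray(curve, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.nanmean(curve[..., start:stop], axis=-1)


def delta_t2star_curve(
    e1: np.ndarray, e2: np.ndarray, params: AcquisitionParams
) -> np.ndarray:
    """ΔT2*(t) [s] visualization curve: 1/R2*(t) - 1/R2*_baseline.

    Undefined (NaN) wherever R2*(t) <= 0.
    """
    e1, e2 = _validate_pair(e1, e2)
    start, stop = params.baseline_window
    valid = (e1 > 0) & (e2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2star = np.where(valid, np.log(e1 / e2), np.nan) / (params.te2 - params.te1)
        r2star = np.where(r2star > 0, r2star, np.nan)
        base = np.nanmean(r2star[..., start:stop], axis=-1, keepdims=True)
        return 1.0 / r2star - 1.0 / base


def delta_t1w_curve(
    e1: np.ndarray, e2: np.ndarray, params: AcquisitionParams
) -> np.ndarray:
    """ΔT1w(t) visualization curve: T1w(t) minus its baseline mean."""
    t1w = compute_t1w_curve(e1, e2, params)
    return t1w - baseline_mean(t1w, params)[..., None]


def detect_bolus_arrival(
    mean_curve: np.ndarray, params: AcquisitionParams, n_sd: float = 3.0
) -> int | None:
    """First frame after the baseline window where the whole-brain mean ΔR2*
    exceeds its baseline mean by ``n_sd`` baseline standard deviations.

    Returns None when the threshold is never exceeded (flat or noise-only
    curve); callers then fall back to a configured fixed index.
    """
    mean_curve = np.asarray(mean_curve, dtype=float)
    if mean_curve.ndim != 1:
        raise ValueError("mean_curve must be 1D (already averaged over voxels)")
    start, stop = params.baseline_window
    base = mean_curve[start:stop]
    mu = np.nanmean(base)
    sd = np.nanstd(base, ddof=0)
    threshold = mu + n_sd * sd
    after = mean_curve[stop:]
    exceed = np.nonzero(after > threshold)[0]
    if exceed.size == 0:
        return None
    return stop + int(exceed[0])
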