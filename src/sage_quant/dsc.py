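"""Classic DSC metrics from echo 2: PSR and leakage-corrected (n)rCBV.

Percentage of signal recovery (PSR) summarizes the balance between T1 and T2*
leakage effects on the raw second-echo signal:

    PSR = 100 * (S_post - S_min) / (S_pre - S_min)

with S_pre the baseline mean, S_min the first-pass minimum and S_post the
steady-state tail mean. PSR > 100 % (T1-dominant overshoot) is admissible.

Relative cerebral blood volume integrates the ΔR2*(t) curve after removing
contrast-extravasation bias with the bidirectional leakage-correction model:

    ΔR2*_meas(t) ≈ K1 * xbar(t) - K2 * ∫0..t xbar(τ) exp(-kep_m (t-τ)) dτ

where xbar(t) is the mean ΔR2* over non-enhancing reference voxels. K1 and K2
are solved by linear least squares on a grid of efflux rates kep_m; the
unidirectional (Boxerman–Weisskoff) variant fixes kep_m = 0. The corrected
curve adds the estimated leakage term back, and rCBV is its trapezoidal
integral; normalization by the brain-median rCBV yields nrCBV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import AcquisitionParams
from .steady_state import tail_average

DEFAULT_KEP_GRID = np.arange(0.0, 0.1 + 1e-12, 0.002)  # s^-1


def compute_psr(
    e2: np.ndarray,
    params: AcquisitionParams,
    bolus_index: int,
) -> np.ndarray:
    """Percentage of signal recovery of the second-echo signal [percent].

    ``e2`` is a single time curve or an array with time last. S_min is
    searched in ``[bolus_index, end)``; voxels without a first-pass dip
    (S_min >= S_pre) are NaN.
    """
    e2 = np.asarray(e2, dtype=float)
    if not 0 <= bolus_index < e2.shape[-1]:
        raise ValueError(f"bolus_index {bolus_index} outside acquisition")
    start, stop = params.baseline_window
    s_pre = np.nanmean(e2[..., start:stop], axis=-1)
    s_min = np.nanmin(e2[..., bolus_index:], axis=-1)
    s_post = tail_average(e2, params.n_tail)
    with np.errstate(invalid="ignore", divide="ignore"):
        psr = 100.0 * (s_post - s_min) / (s_pre - s_min)
        psr = np.where(s_min < s_pre, psr, np.nan)
    return psr


def exp_weighted_integral(curve: np.ndarray, kep: float, dt: float) -> np.ndarray:
    """Causal trapezoidal integral ∫0..t curve(τ) exp(-kep (t-τ)) dτ.

    Evaluated with the exact recursion of the exponential kernel so the cost
    is linear in the number of frames.
    """
    curve = np.asarray(curve, dtype=float)
    n = curve.shape[-1]
    out = np.zeros_like(curve)
    decay = np.exp(-kep * dt)
    for i in range(1, n):
        increment = 0.5 * dt * (curve[..., i] + decay * curve[..., i - 1])
        out[..., i] = decay * out[..., i - 1] + increment
    return out


@dataclass
class LeakageCorrectionFit:
    """Per-voxel leakage-model coefficients.

    ``k1`` is the dimensionless perfusion gain, ``k2`` the leakage coefficient
    and ``kep_m`` the efflux rate (0 in unidirectional mode). Arrays share the
    voxel shape of the fitted curves; scalars for a single curve.
    """

    k1: np.ndarray
    k2: np.ndarray
    kep_m: np.ndarray
    reference_curve: np.ndarray
    residual: np.ndarray
    dt: float


def fit_leakage_model(
    delta_r2star: np.ndarray,
    reference: np.ndarray,
    dt: float,
    mode: str = "bidirectional",
    kep_grid: np.ndarray | None = None,
) -> LeakageCorrectionFit:
    """Fit the (bi)directional leakage model to ΔR2* voxel curves.

    For each candidate kep on the grid the model is linear in (K1, K2) and is
    solved in closed form for every voxel at once; the grid point minimizing
    the residual sum of squares wins per voxel. ``mode='unidirectional'``
    fixes kep = 0 (no back-flux), the classic single-parameter correction.
    """
    curves = np.atleast_2d(np.asarray(delta_r2star, dtype=float))
    single = np.asarray(delta_r2star).ndim == 1
    reference = np.asarray(reference, dtype=float)
    if reference.ndim != 1 or reference.shape[0] != curves.shape[-1]:
        raise ValueError("reference curve must be 1D on the same time base")
    if not np.any(reference != 0):
        raise ValueError("reference curve empty")
    if mode not in ("unidirectional", "bidirectional"):
        raise ValueError(f"unknown mode {mode!r}")
    grid = (
        np.array([0.0])
        if mode == "unidirectional"
        else (DEFAULT_KEP_GRID if kep_grid is None else np.asarray(kep_grid, float))
    )

    vox = curves.reshape(-1, curves.shape[-1])
    finite = np.isfinite(vox)
    y = np.where(finite, vox, 0.0)

    best_rss = np.full(vox.shape[0], np.inf)
    best = np.zeros((3, vox.shape[0]))
    for kep in grid:
        conv = exp_weighted_integral(reference, kep, dt)
        # design columns a = xbar, b = -conv; closed-form 2x2 normal equations
        a = np.where(finite, reference, 0.0)
        b = np.where(finite, -conv, 0.0)
        saa = (a * a).sum(1)
        sbb = (b * b).sum(1)
        sab = (a * b).sum(1)
        say = (a * y).sum(1)
        sby = (b * y).sum(1)
        det = saa * sbb - sab * sab
        with np.errstate(divide="ignore", invalid="ignore"):
            k1 = np.where(det != 0, (sbb * say - sab * sby) / det, say / np.where(saa == 0, np.nan, saa))
            k2 = np.where(det != 0, (saa * sby - sab * say) / det, 0.0)
        fitted = k1[:, None] * a + k2[:, None] * b
        rss = ((y - fitted) ** 2 * finite).sum(1)
        better = rss < best_rss - 1e-15
        best_rss = np.where(better, rss, best_rss)
        best[0] = np.where(better, k1, best[0])
        best[1] = np.where(better, k2, best[1])
        best[2] = np.where(better, kep, best[2])

    shape = curves.shape[:-1]
    k1, k2, kep_m = (best[i].reshape(shape) for i in range(3))
    rss = best_rss.reshape(shape)
    if single:
        k1, k2, kep_m, rss = (float(v[0]) for v in (k1, k2, kep_m, rss))
    return LeakageCorrectionFit(
        k1=k1, k2=k2, kep_m=kep_m, reference_curve=reference, residual=rss, dt=dt
    )


def correct_and_integrate_rcbv(
    delta_r2star: np.ndarray,
    fit: LeakageCorrectionFit,
    integration_window: tuple[int, int],
) -> np.ndarray:
    """Leakage-corrected rCBV: trapezoidal integral of the corrected ΔR2*.

    The corrected curve restores the extravasation term:
    ``corrected = measured + K2 * ∫ xbar exp(-kep_m (t-τ))``.
    """
    curves = np.asarray(delta_r2star, dtype=float)
    n = curves.shape[-1]
    start, stop = integration_window
    if not 0 <= start < stop <= n:
        raise ValueError(f"integration window {integration_window} outside acquisition")
    k2 = np.asarray(fit.k2, dtype=float)
    kep = np.asarray(fit.kep_m, dtype=float)
    # group voxels by their (few) distinct kep grid values to reuse the kernel
    corrected = curves.copy()
    for kep_val in np.unique(kep[np.isfinite(kep)]):
        conv = exp_weighted_integral(fit.reference_curve, float(kep_val), fit.dt)
        sel = kep == kep_val
        if corrected.ndim == 1:
            corrected = corrected + float(k2) * conv
            break
        corrected[sel] += np.asarray(k2)[sel][..., None] * conv
    return np.trapezoid(corrected[..., start:stop], dx=fit.dt, axis=-1)


def normalize_rcbv(
    rcbv: np.ndarray, brain_mask: np.ndarray, min_voxels: int = 1000
) -> np.ndarray:
    """Normalize rCBV by its brain-mask median (NaNs excluded) -> nrCBV."""
    rcbv = np.asarray(rcbv, dtype=float)
    brain_mask = np.asarray(brain_mask, dtype=bool)
    vals = rcbv[brain_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < min_voxels:
        raise ValueError(
            f"only {vals.size} finite voxels in normalization mask (need {min_voxels})"
        )
    med = np.median(vals)
    if med <= 0:
        raise ValueError("degenerate normalization: nonpositive median rCBV")
    return rcbv / med
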