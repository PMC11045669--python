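"""Pharmacokinetic (DCE) analysis: vascular input function and Tofts fits.

The standard Tofts model describes contrast exchange between plasma and the
extravascular extracellular space:

    Ct(t) = Ktrans * ∫0..t Cp(τ) exp(-(Ktrans/ve) (t-τ)) dτ

with Ktrans the volume transfer constant (reported in min^-1) and ve the
extravascular extracellular volume fraction. The input function Cp(t) is
extracted from a venous-sinus ROI of the dynamic T1-weighted (TE = 0
extrapolated) series via the SPGR inversion; no hematocrit or delay
correction is applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .params import AcquisitionParams, RelaxometryConfig
from . import decomposition, relaxometry

KTRANS_BOUNDS = (1e-5, 5.0)  # min^-1
VE_BOUNDS = (1e-3, 1.0)
PRIMARY_INIT = (0.1, 0.3)  # Ktrans [min^-1], ve
MULTISTART_INITS = ((0.1, 0.3), (0.02, 0.1), (0.5, 0.6))


@dataclass
class InputFunction:
    """Sampled plasma concentration curve Cp(t) [mM]."""

    times: np.ndarray  # seconds
    cp: np.ndarray  # mM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.times.shape != self.cp.shape or self.times.ndim != 1:
            raise ValueError("times and cp must be matching 1D arrays")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class ToftsFit:
    """Result of a voxelwise Tofts fit."""

    ktrans: float  # min^-1
    ve: float  # fraction
    rss: float
    status: str  # converged | bound-hit | failed


def extract_aif(
    t1w_series: np.ndarray,
    aif_roi: np.ndarray,
    params: AcquisitionParams,
    cfg: RelaxometryConfig | None = None,
    hematocrit: float | None = None,
) -> InputFunction:
    """Input function from the ROI-mean T1w(t) of the venous sinus.

    The ROI mean is SPGR-inverted to ΔR1(t) and scaled by the relaxivity to
    Cp(t). ``hematocrit`` optionally rescales blood to plasma concentration
    (Cp / (1 - Hct)); off by default. An ROI whose inversion clamps at more
    than half of the timepoints is rejected as saturated.
    """
    if cfg is None:
        cfg = RelaxometryConfig.from_acquisition(params)
    t1w_series = np.asarray(t1w_series, dtype=float)
    aif_roi = np.asarray(aif_roi, dtype=bool)
    if not aif_roi.any():
        raise ValueError("aif_roi is empty")
    roi_mean = np.nanmean(t1w_series[aif_roi], axis=0)
    base = decomposition.baseline_mean(roi_mean, params)
    inv = relaxometry.invert_spgr_to_r1(roi_mean, cfg, base)
    if inv.clamped.mean() > 0.5:
        raise ValueError(
            "input-function ROI saturated at more than 50% of timepoints; "
            "revise the ROI placement"
        )
    cp = relaxometry.concentration_from_r1(inv.delta_r1, cfg)
    if np.nanmax(np.abs(cp)) < 0.01:
        warnings.warn(
            "flat input function: ROI shows no enhancement", UserWarning,
            stacklevel=2,
        )
    if hematocrit is not None:
        cp = cp / (1.0 - hematocrit)
    return InputFunction(times=params.times, cp=cp)


def _conv_exp(cp: np.ndarray, kep: float, dt: float) -> np.ndarray:
    """Trapezoidal causal convolution of cp with exp(-kep t)."""
    n = cp.shape[0]
    out = np.zeros(n)
    decay = np.exp(-kep * dt)
    for i in range(1, n):
        out[i] = decay * out[i - 1] + 0.5 * dt * (cp[i] + decay * cp[i - 1])
    return out


def tofts_forward(ktrans: float, ve: float, cp: InputFunction) -> np.ndarray:
    """Tissue concentration Ct(t) [mM] for Ktrans [min^-1] and ve [fraction].

    Discrete causal convolution on the input-function time base (trapezoidal
    kernel); Ct(0) = 0.
    """
    if ve <= 0:
        if ktrans > 0:
            raise ValueError("ve must be positive when ktrans > 0")
        return np.zeros_like(cp.cp)
    ktrans_s = ktrans / 60.0
    kep = ktrans_s / ve
    return ktrans_s * _conv_exp(cp.cp, kep, cp.dt)


def tofts_fit(
    ct: np.ndarray,
    cp: InputFunction,
    multistart: bool = True,
) -> ToftsFit:
    """Bounded nonlinear least-squares fit of the Tofts model to Ct(t).

    Starts at (Ktrans, ve) = (0.1 min^-1, 0.3); on poor convergence two more
    fixed starts are tried and the best residual wins. Parameters at a bound
    are reported with status ``bound-hit``.
    """
    ct = np.asarray(ct, dtype=float)
    finite = np.isfinite(ct)
    if finite.sum() < 30:
        return ToftsFit(np.nan, np.nan, np.nan, "failed")
    y = ct[finite]

    def residuals(theta):
        return tofts_forward(theta[0], theta[1], cp)[finite] - y

    lo = np.array([KTRANS_BOUNDS[0], VE_BOUNDS[0]])
    hi = np.array([KTRANS_BOUNDS[1], VE_BOUNDS[1]])

    def run(x0):
        try:
            return least_squares(
                residuals, np.clip(np.asarray(x0, float), lo, hi), bounds=(lo, hi),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            return None

    def hits_bound(r):
        return bool(np.any(np.isclose(r.x, lo)) or np.any(np.isclose(r.x, hi)))

    res = run(PRIMARY_INIT)
    results = [res] if res is not None and res.success else []
    # poor convergence: outright failure or a parameter pinned at a bound
    poor = not results or hits_bound(results[0])
    if multistart and poor:
        for x0 in MULTISTART_INITS[1:]:
            r = run(x0)
            if r is not None and r.success:
                results.append(r)
    if not results:
        return ToftsFit(np.nan, np.nan, np.nan, "failed")
    best = min(results, key=lambda r: r.cost)
    ktrans, ve = float(best.x[0]), float(best.x[1])
    rss = float(2 * best.cost)
    def near(x, b):
        return abs(x - b) <= 1e-9 + 1e-6 * abs(b)

    at_bound = any(
        near(v, b)
        for v, bounds in ((ktrans, KTRANS_BOUNDS), (ve, VE_BOUNDS))
        for b in bounds
    )
    status = "bound-hit" if at_bound else "converged"
    return ToftsFit(ktrans=ktrans, ve=ve, rss=rss, status=status)


def fit_voxelwise(
    ct_curves: np.ndarray,
    cp: InputFunction,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tofts fit over an array of concentration curves (time last).

    Returns (ktrans, ve, status_code) arrays of the voxel shape; voxels
    outside ``mask`` are NaN with status 0. Status codes: 1 converged,
    2 bound-hit, -1 failed.
    """
    ct_curves = np.asarray(ct_curves, dtype=float)
    shape = ct_curves.shape[:-1]
    ktrans = np.full(shape, np.nan)
    ve = np.full(shape, np.nan)
    status = np.zeros(shape, dtype=np.int8)
    codes = {"converged": 1, "bound-hit": 2, "failed": -1}
    it = np.ndindex(shape) if mask is None else zip(*np.nonzero(mask))
    for idx in it:
        fit = tofts_fit(ct_curves[idx], cp)
        ktrans[idx] = fit.ktrans
        ve[idx] = fit.ve
        status[idx] = codes[fit.status]
    return ktrans, ve, status
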