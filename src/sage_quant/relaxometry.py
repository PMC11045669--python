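"""SPGR signal inversion: T1w(t) -> R1(t), ΔR1(t) and concentration C(t).

The spoiled-gradient-echo steady-state signal at TE = 0 is

    S = S0 * sin(a) * (1 - E) / (1 - cos(a) * E),      E = exp(-TR * R1)

With a fixed pre-contrast T1 (T10) the unknown proportionality S0*sin(a)
cancels in the ratio rho(t) = T1w(t) / T1w_baseline, giving a closed-form
inversion valid for any flip angle a:

    g(t) = rho(t) * (1 - E0) / (1 - cos(a) * E0),      E0 = exp(-TR / T10)
    E(t) = (1 - g) / (1 - g * cos(a))
    R1(t) = -ln(E(t)) / TR,   ΔR1(t) = R1(t) - 1/T10

Concentration follows linearly from the contrast agent's longitudinal
relaxivity: C(t) = ΔR1(t) / r1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import RelaxometryConfig


@dataclass
class InversionResult:
    """R1/ΔR1 curves plus a per-timepoint clamp flag (saturated samples)."""

    r1: np.ndarray
    delta_r1: np.ndarray
    clamped: np.ndarray  # boolean, same shape

    @property
    def n_clamped(self) -> int:
        return int(self.clamped.sum())


def spgr_signal(r1: np.ndarray, cfg: RelaxometryConfig, s0: float = 1.0) -> np.ndarray:
    """Forward SPGR signal (TE = 0) for a given R1 [s^-1]."""
    r1 = np.asarray(r1, dtype=float)
    a = np.deg2rad(cfg.flip_angle)
    e = np.exp(-cfg.tr * r1)
    return s0 * np.sin(a) * (1.0 - e) / (1.0 - np.cos(a) * e)


def invert_spgr_to_r1(
    t1w: np.ndarray, cfg: RelaxometryConfig, baseline_mean: np.ndarray | float
) -> InversionResult:
    """Invert T1w(t) to R1(t) and ΔR1(t) assuming a fixed baseline T1.

    ``baseline_mean`` is the pre-bolus mean of T1w (scalar, or an array
    broadcastable against ``t1w`` without its time axis). Signal ratios beyond
    the saturation bound (E <= 0) are clamped to ``cfg.clamp_epsilon`` and
    flagged; ratios below baseline are allowed (negative ΔR1 can arise from
    residual T2* weighting upstream) but E is kept below 1 - clamp_epsilon.
    """
    t1w = np.asarray(t1w, dtype=float)
    base = np.asarray(baseline_mean, dtype=float)
    if np.any(base[np.isfinite(base)] <= 0):
        raise ValueError("baseline mean must be positive where defined")
    if base.ndim and base.ndim == t1w.ndim - 1:
        base = base[..., None]

    a = np.deg2rad(cfg.flip_angle)
    cos_a = np.cos(a)
    e0 = np.exp(-cfg.tr / cfg.t10)
    rho = t1w / base
    g = rho * (1.0 - e0) / (1.0 - cos_a * e0)
    with np.errstate(invalid="ignore", divide="ignore"):
        e = (1.0 - g) / (1.0 - g * cos_a)
    lo, hi = cfg.clamp_epsilon, 1.0 - cfg.clamp_epsilon
    clamped = (e <= lo) | (e >= hi)
    clamped &= np.isfinite(e)
    e = np.clip(e, lo, hi)
    with np.errstate(invalid="ignore"):
        r1 = -np.log(e) / cfg.tr
    delta_r1 = r1 - 1.0 / cfg.t10
    return InversionResult(r1=r1, delta_r1=delta_r1, clamped=clamped)


def concentration_from_r1(delta_r1: np.ndarray, cfg: RelaxometryConfig) -> np.ndarray:
    """Contrast-agent concentration C(t) [mM] = ΔR1(t) / r1. NaN propagates."""
    return np.asarray(delta_r1, dtype=float) / cfg.r1_relaxivity
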