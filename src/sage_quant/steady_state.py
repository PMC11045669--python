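"""Steady-state leakage-effect maps and transverse relaxivity at equilibrium.

Once the contrast agent approaches compartmental equilibrium near the end of
the acquisition, the tail averages of ΔR2*(t), ΔR1(t) and C(t) yield the
steady-state maps ΔR2,ss*, ΔR1,ss and Css. Their ratio

    TRATE = ΔR2,ss* / Css    [mM^-1 s^-1]

is the transverse relaxivity at tracer equilibrium — the T2* leakage effect
normalized to the extravasated tracer concentration, a cytoarchitecture-
sensitive biomarker. TRATE is only defined where enough tracer accumulated;
below ``css_floor`` the ratio is masked to NaN.
"""

from __future__ import annotations

import numpy as np

#: Minimum steady-state concentration [mM] for a defined TRATE.
DEFAULT_CSS_FLOOR = 0.01


def tail_average(curve: np.ndarray, n_tail: int) -> np.ndarray:
    """Arithmetic mean of the final ``n_tail`` samples along the time axis.

    NaN samples are excluded; the result is NaN only if the whole tail is NaN.
    Works on a single curve or any array with time as the last axis.
    """
    curve = np.asarray(curve, dtype=float)
    if n_tail < 1 or n_tail > curve.shape[-1]:
        raise ValueError(
            f"n_tail={n_tail} out of range for curve length {curve.shape[-1]}"
        )
    tail = curve[..., -n_tail:]
    count = np.sum(~np.isnan(tail), axis=-1)
    total = np.nansum(tail, axis=-1)
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return out


def compute_trate(
    delta_r2star_ss: np.ndarray,
    c_ss: np.ndarray,
    css_floor: float = DEFAULT_CSS_FLOOR,
) -> np.ndarray:
    """TRATE = ΔR2,ss* / Css, NaN wherever Css <= css_floor."""
    delta_r2star_ss = np.asarray(delta_r2star_ss, dtype=float)
    c_ss = np.asarray(c_ss, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        trate = np.where(c_ss > css_floor, delta_r2star_ss / c_ss, np.nan)
    return trate
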