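"""Acquisition and relaxometry parameter containers.

Defaults reproduce a dual-gradient-echo dynamic SAGE-EPI brain-tumor protocol:
TE1 = 14 ms, TE2 = 34.1 ms, TR = 2 s, 90 repetitions, 90 deg flip angle, a fixed
baseline tissue T1 of 1.4 s and a gadobutrol longitudinal relaxivity of
5.0 mM^-1 s^-1 at 3 T.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class AcquisitionParams:
    """Dual-echo dynamic acquisition parameters.

    Attributes
    ----------
    te1, te2 : float
        Echo times of gradient echo 1 and 2, in seconds. ``te1 < te2``.
    tr : float
        Repetition time in seconds; also the dynamic sampling interval.
    flip_angle : float
        Excitation flip angle in degrees, in ``(0, 90]``.
    n_timepoints : int
        Number of dynamic frames.
    t10 : float
        Assumed pre-contrast tissue T1 in seconds (no T1 mapping is done).
    r1_relaxivity : float
        Contrast-agent longitudinal relaxivity in mM^-1 s^-1.
    n_tail : int
        Number of final frames averaged for steady-state (equilibrium) maps.
    baseline_window : tuple[int, int]
        Half-open ``[start, stop)`` frame range used as the pre-bolus baseline.
        The first frames are excluded so longitudinal magnetization can reach
        steady state.
    """

    te1: float = 0.014
    te2: float = 0.0341
    tr: float = 2.0
    flip_angle: float = 90.0
    n_timepoints: int = 90
    t10: float = 1.4
    r1_relaxivity: float = 5.0
    n_tail: int = 10
    baseline_window: tuple[int, int] = (5, 25)

    def __post_init__(self) -> None:
        if not self.te1 < self.te2:
            raise ValueError(f"te1 ({self.te1}) must be < te2 ({self.te2})")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip_angle must be in (0, 90] degrees")
        if self.n_timepoints < 2:
            raise ValueError("n_timepoints must be >= 2")
        if not 1 <= self.n_tail <= self.n_timepoints:
            raise ValueError("n_tail must be in [1, n_timepoints]")
        start, stop = self.baseline_window
        if not 0 <= start < stop <= self.n_timepoints:
            raise ValueError(f"invalid baseline_window {self.baseline_window}")
        if stop > self.n_timepoints - self.n_tail:
            raise ValueError(
                "baseline_window overlaps the final n_tail steady-state frames"
            )

    @property
    def dt(self) -> float:
        """Dynamic sampling interval in seconds (equals TR)."""
        return self.tr

    @property
    def times(self):
        import numpy as np

        return np.arange(self.n_timepoints) * self.tr

    def with_(self, **kwargs) -> "AcquisitionParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RelaxometryConfig:
    """Parameters of the spoiled-gradient-echo (SPGR) signal inversion."""

    t10: float = 1.4
    r1_relaxivity: float = 5.0
    flip_angle: float = 90.0
    tr: float = 2.0
    clamp_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if self.t10 <= 0:
            raise ValueError("t10 must be positive")
        if self.r1_relaxivity <= 0:
            raise ValueError("r1_relaxivity must be positive")
        if not 0 < self.flip_angle <= 90:
            raise ValueError("flip_angle must be in (0, 90] degrees")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0 < self.clamp_epsilon < 0.5:
            raise ValueError("clamp_epsilon must be a small positive number")

    @classmethod
    def from_acquisition(cls, params: AcquisitionParams) -> "RelaxometryConfig":
        return cls(
            t10=params.t10,
            r1_relaxivity=params.r1_relaxivity,
            flip_angle=params.flip_angle,
            tr=params.tr,
        )
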