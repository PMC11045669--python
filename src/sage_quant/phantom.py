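"""Digital reference object for the dual-echo dynamic pipeline.

Forward-simulates the full acquisition from known ground truth so every
pipeline stage has an exact oracle:

1. A parametric plasma input function Cp(t): gamma-variate first pass plus a
   smooth approach to a steady equilibrium tail.
2. Per-tissue-class curves: tissue concentration Ct(t) from the Tofts model,
   longitudinal relaxation R1(t) = R10 + r1*Ct(t), transverse relaxation
   R2*(t) = R20* + cbv_amp*k_iv*Cp(t) + trate_true*Ct(t) — an intravascular
   susceptibility first-pass term plus the extravascular leakage effect whose
   equilibrium relaxivity is TRATE.
3. SPGR x T2*-decay rendering at the two echo times,
   S(TE, t) = S0 sin(a) (1-E)/(1-cos(a) E) exp(-TE R2*(t)), E = exp(-TR R1),
   with optional seeded Rician or Gaussian noise at a configured baseline SNR.

Sinus (input-function ROI) voxels are rendered with R1(t) = R10 + r1*Cp(t)
and no transverse bolus term, giving the AIF extraction a clean target. The
layout is axis-aligned blocks (background, normal tissue, tumor variants,
sinus stripe) so masks are trivially auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .params import AcquisitionParams
from .io import EchoSeries, MaskSet
from .dce import InputFunction, tofts_forward
from .relaxometry import spgr_signal
from .params import RelaxometryConfig

Block = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class AifParams:
    """Parametric input function: gamma-variate bolus + steady tail."""

    amplitude: float = 2.0  # peak plasma concentration, mM
    arrival: float = 60.0  # bolus arrival time t0, s
    alpha: float = 3.0  # gamma-variate shape
    beta: float = 4.0  # gamma-variate time scale, s
    tail: float = 0.3  # steady-state plasma concentration, mM
    tail_midpoint: float = 45.0  # s after arrival where the tail half-rises
    tail_width: float = 12.0  # s, rise width of the tail step


@dataclass(frozen=True)
class NoiseParams:
    snr: float | None = None  # baseline-signal SNR; None = noiseless
    model: str = "rician"  # rician | gaussian | none


@dataclass(frozen=True)
class TissueClass:
    """One homogeneous tissue block of the phantom."""

    label: str
    region: Block | None  # None = fills everything not claimed by others
    cbv_amp: float = 1.0  # blood-volume amplitude, arbitrary units
    ktrans: float = 0.0  # min^-1
    ve: float = 0.3  # fraction
    trate_true: float = 0.0  # mM^-1 s^-1
    r10: float = 1.0 / 1.4  # s^-1
    r20star: float = 20.0  # s^-1
    is_sinus: bool = False


@dataclass(frozen=True)
class PhantomSpec:
    grid: tuple[int, int, int] = (32, 32, 8)
    tissue_classes: tuple[TissueClass, ...] = ()
    aif: AifParams = field(default_factory=AifParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    seed: int = 0
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    k_iv: float = 2.5  # intravascular susceptibility coefficient, s^-1 per mM
    s0: float = 1000.0  # proton-density signal scale, arbitrary units
    brain_margin: int = 2  # background border thickness in x/y (1 in z)

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


def default_tissue_classes() -> tuple[TissueClass, ...]:
    """Default layout: normal tissue, three tumor variants, sinus stripe.

    Tumor parameters bracket enhancing-glioma values: a treatment-naive
    aggressive block (high TRATE, moderate Ktrans), a lower-grade-like block
    and a treated-like block (lower TRATE, higher Ktrans and ve).
    """
    return (
        TissueClass(label="normal", region=None, cbv_amp=1.0, ktrans=0.0),
        TissueClass(
            label="tumor_naive", region=((6, 12), (6, 12), (2, 6)),
            cbv_amp=3.0, ktrans=0.16, ve=0.28, trate_true=153.0,
        ),
        TissueClass(
            label="tumor_lowgrade", region=((14, 20), (6, 12), (2, 6)),
            cbv_amp=1.5, ktrans=0.06, ve=0.48, trate_true=86.0,
        ),
        TissueClass(
            label="tumor_treated", region=((6, 12), (14, 20), (2, 6)),
            cbv_amp=2.0, ktrans=0.22, ve=0.49, trate_true=85.0,
        ),
        TissueClass(
            label="sinus", region=((26, 29), (4, 28), (2, 6)), is_sinus=True,
        ),
    )


def default_spec(**overrides) -> PhantomSpec:
    spec = PhantomSpec(tissue_classes=default_tissue_classes())
    return spec.with_(**overrides) if overrides else spec


@dataclass
class PhantomTruth:
    """Ground-truth maps and curves, regenerable bit-exactly from (spec, seed)."""

    label_map: np.ndarray  # int map, -1 = background, else tissue-class index
    cbv_amp: np.ndarray
    ktrans: np.ndarray
    ve: np.ndarray
    trate_true: np.ndarray
    r10: np.ndarray
    r20star: np.ndarray
    delta_r1_ss: np.ndarray  # tail-average truth, s^-1
    c_ss: np.ndarray  # tail-average truth, mM
    delta_r2star_ss: np.ndarray  # extravascular tail-average truth, s^-1
    cp: np.ndarray  # mM
    ct_by_class: dict[str, np.ndarray]
    delta_r2star_iv_by_class: dict[str, np.ndarray]
    delta_r2star_ev_by_class: dict[str, np.ndarray]


@dataclass
class PhantomDataset:
    e1: EchoSeries
    e2: EchoSeries
    masks: MaskSet
    truth: PhantomTruth
    spec: PhantomSpec
    t1w_pre: np.ndarray | None = None
    t1w_post: np.ndarray | None = None


def generate_input_function(aif: AifParams, times: np.ndarray) -> np.ndarray:
    """Plasma concentration Cp(t) [mM]: zero before arrival, gamma-variate
    first pass peaking at the configured amplitude, smooth rise to the tail.
    """
    times = np.asarray(times, dtype=float)
    if not times[0] <= aif.arrival <= times[-1]:
        raise ValueError("bolus arrival outside the acquisition window")
    if aif.amplitude < 0 or aif.tail < 0:
        raise ValueError("amplitude and tail must be nonnegative")
    if aif.amplitude > 0 and aif.tail > aif.amplitude:
        raise ValueError("steady tail exceeds the bolus peak")
    tau = times - aif.arrival
    cp = np.zeros_like(times)
    after = tau > 0
    t_a = tau[after]
    if aif.amplitude > 0:
        # gamma variate normalized so its maximum (at t = alpha*beta) is 1
        peak = (aif.alpha * aif.beta) ** aif.alpha * np.exp(-aif.alpha)
        gamma = t_a**aif.alpha * np.exp(-t_a / aif.beta) / peak
        cp[after] += aif.amplitude * gamma
    if aif.tail > 0:
        step = 0.5 * (1.0 + np.tanh((t_a - aif.tail_midpoint) / aif.tail_width))
        cp[after] += aif.tail * step
    return cp


def _label_map(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """(label_map, brain_mask). label -1 = background."""
    nx, ny, nz = spec.grid
    m = spec.brain_margin
    brain = np.zeros(spec.grid, dtype=bool)
    brain[m : nx - m, m : ny - m, 1 : nz - 1] = True
    labels = np.full(spec.grid, -1, dtype=int)
    filler = None
    for i, tc in enumerate(spec.tissue_classes):
        if tc.region is None:
            filler = i
            continue
        (x0, x1), (y0, y1), (z0, z1) = tc.region
        labels[x0:x1, y0:y1, z0:z1] = i
    if filler is not None:
        labels[(labels == -1) & brain] = filler
    labels[~brain] = -1
    return labels, brain


def simulate_tissue_curves(
    spec: PhantomSpec, cp: np.ndarray
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-class time curves: Ct, R1, R2*, and the split ΔR2* IV/EV terms.

    Returns dicts keyed by tissue label: (ct, r1, r2star, extras) where
    extras holds ('iv', 'ev') tuples.
    """
    acq = spec.acquisition
    cp_fn = InputFunction(times=acq.times, cp=cp)
    ct, r1, r2star, iv, ev = {}, {}, {}, {}, {}
    for tc in spec.tissue_classes:
        if tc.is_sinus:
            c = np.zeros_like(cp)
            r1[tc.label] = tc.r10 + acq.r1_relaxivity * cp
            r2star[tc.label] = np.full_like(cp, tc.r20star)
            iv[tc.label] = np.zeros_like(cp)
            ev[tc.label] = np.zeros_like(cp)
        else:
            c = (
                tofts_forward(tc.ktrans, tc.ve, cp_fn)
                if tc.ktrans > 0
                else np.zeros_like(cp)
            )
            r1[tc.label] = tc.r10 + acq.r1_relaxivity * c
            iv[tc.label] = tc.cbv_amp * spec.k_iv * cp
            ev[tc.label] = tc.trate_true * c
            r2star[tc.label] = tc.r20star + iv[tc.label] + ev[tc.label]
        ct[tc.label] = c
    return ct, r1, r2star, {"iv": iv, "ev": ev}


def _spgr_te(r1: np.ndarray, r2star: np.ndarray, te: float, spec: PhantomSpec) -> np.ndarray:
    cfg = RelaxometryConfig.from_acquisition(spec.acquisition)
    return spgr_signal(r1, cfg, s0=spec.s0) * np.exp(-te * r2star)


def _apply_noise(
    signal: np.ndarray, sigma: np.ndarray | float, noise: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    if noise.model == "none" or noise.snr is None:
        return signal
    if noise.model == "gaussian":
        return signal + rng.normal(0.0, sigma, size=signal.shape)
    if noise.model == "rician":
        re = signal + rng.normal(0.0, sigma, size=signal.shape)
        im = rng.normal(0.0, sigma, size=signal.shape)
        return np.sqrt(re**2 + im**2)
    raise ValueError(f"unknown noise model {noise.model!r}")


def render_echo_signals(
    spec: PhantomSpec,
    r1_by_class: dict[str, np.ndarray],
    r2star_by_class: dict[str, np.ndarray],
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the two 4D echo volumes from per-class relaxation curves.

    Noise sigma is the class's noiseless echo-1 baseline mean divided by the
    configured SNR, applied independently per voxel/frame/echo; all
    randomness comes from ``rng`` (derived from spec.seed when omitted).
    """
    acq = spec.acquisition
    labels, _ = _label_map(spec)
    nt = acq.n_timepoints
    e1 = np.zeros(spec.grid + (nt,))
    e2 = np.zeros(spec.grid + (nt,))
    sigma1 = np.zeros(spec.grid + (1,))
    sigma2 = np.zeros(spec.grid + (1,))
    b0, b1 = acq.baseline_window
    for i, tc in enumerate(spec.tissue_classes):
        sel = labels == i
        if not sel.any():
            continue
        s1 = _spgr_te(r1_by_class[tc.label], r2star_by_class[tc.label], acq.te1, spec)
        s2 = _spgr_te(r1_by_class[tc.label], r2star_by_class[tc.label], acq.te2, spec)
        e1[sel] = s1
        e2[sel] = s2
        if spec.noise.snr is not None:
            sigma1[sel] = s1[b0:b1].mean() / spec.noise.snr
            sigma2[sel] = s2[b0:b1].mean() / spec.noise.snr
    if spec.noise.snr is not None and spec.noise.model != "none":
        if rng is None:
            rng = np.random.default_rng(spec.seed)
        e1 = _apply_noise(e1, np.broadcast_to(sigma1, e1.shape), spec.noise, rng)
        e2 = _apply_noise(e2, np.broadcast_to(sigma2, e2.shape), spec.noise, rng)
    return e1, e2


def render_t1w_pair(
    spec: PhantomSpec, r1_by_class: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless pre/post-contrast T1-weighted 3D volumes.

    Pre uses the baseline R1 (first frame), post the steady-state tail mean —
    a minimal stand-in for the anatomical pair feeding the >= 10 % rule.
    """
    labels, _ = _label_map(spec)
    acq = spec.acquisition
    pre = np.zeros(spec.grid)
    post = np.zeros(spec.grid)
    cfg = RelaxometryConfig.from_acquisition(spec.acquisition)
    for i, tc in enumerate(spec.tissue_classes):
        sel = labels == i
        r1 = r1_by_class[tc.label]
        pre[sel] = spgr_signal(r1[0], cfg, s0=spec.s0)
        post[sel] = spgr_signal(r1[-acq.n_tail :].mean(), cfg, s0=spec.s0)
    return pre, post


def generate_phantom(spec: PhantomSpec | None = None, with_t1w: bool = False) -> PhantomDataset:
    """Run the full forward simulation and assemble the dataset + truth."""
    if spec is None:
        spec = default_spec()
    acq = spec.acquisition
    labels, brain = _label_map(spec)
    cp = generate_input_function(spec.aif, acq.times)
    ct, r1c, r2c, extras = simulate_tissue_curves(spec, cp)
    rng = np.random.default_rng(spec.seed)
    e1, e2 = render_echo_signals(spec, r1c, r2c, rng=rng)

    shape = spec.grid
    maps = {
        name: np.full(shape, np.nan)
        for name in (
            "cbv_amp", "ktrans", "ve", "trate_true", "r10", "r20star",
            "delta_r1_ss", "c_ss", "delta_r2star_ss",
        )
    }
    lesion = np.zeros(shape, dtype=bool)
    aif_roi = np.zeros(shape, dtype=bool)
    n_tail = acq.n_tail
    for i, tc in enumerate(spec.tissue_classes):
        sel = labels == i
        if not sel.any():
            continue
        maps["cbv_amp"][sel] = tc.cbv_amp
        maps["ktrans"][sel] = tc.ktrans
        maps["ve"][sel] = tc.ve
        maps["trate_true"][sel] = tc.trate_true
        maps["r10"][sel] = tc.r10
        maps["r20star"][sel] = tc.r20star
        css = float(ct[tc.label][-n_tail:].mean())
        maps["c_ss"][sel] = css
        maps["delta_r1_ss"][sel] = acq.r1_relaxivity * css
        maps["delta_r2star_ss"][sel] = float(extras["ev"][tc.label][-n_tail:].mean())
        if tc.is_sinus:
            aif_roi |= sel
        elif tc.label.startswith("tumor"):
            lesion |= sel

    truth = PhantomTruth(
        label_map=labels, cp=cp, ct_by_class=ct,
        delta_r2star_iv_by_class=extras["iv"],
        delta_r2star_ev_by_class=extras["ev"],
        **maps,
    )
    affine = np.eye(4)
    masks = MaskSet(brain=brain, aif_roi=aif_roi, lesion=lesion if lesion.any() else None)
    ds = PhantomDataset(
        e1=EchoSeries(voxels=e1, affine=affine, te=acq.te1),
        e2=EchoSeries(voxels=e2, affine=affine, te=acq.te2),
        masks=masks, truth=truth, spec=spec,
    )
    if with_t1w:
        ds.t1w_pre, ds.t1w_post = render_t1w_pair(spec, r1c)
    return ds
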