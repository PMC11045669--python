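"""End-to-end pipeline: dual-echo dynamic series -> quantitative maps.

Stages (each logged with its parameters and invalidated-voxel counts):

1. dual-echo decomposition        -> ΔR2*(t), T1w(t) per voxel
2. SPGR inversion + relaxivity    -> ΔR1(t), C(t)
3. steady-state tail averages     -> ΔR2,ss*, ΔR1,ss, Css, TRATE
4. classic DSC from echo 2        -> PSR, leakage-corrected rCBV, nrCBV
5. venous input function + Tofts  -> Ktrans, ve (optional, needs an AIF ROI)

All maps are NaN outside the brain mask or where a stage invalidated the
voxel; two runs on identical inputs are bitwise identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import dce, decomposition, dsc, relaxometry, steady_state
from .io import EchoSeries, MaskSet
from .params import AcquisitionParams, RelaxometryConfig

log = logging.getLogger("sage_quant")


@dataclass
class PipelineOptions:
    dce_enabled: bool = True
    css_floor: float = steady_state.DEFAULT_CSS_FLOOR
    kep_grid: np.ndarray | None = None
    leakage_mode: str = "bidirectional"
    fallback_bolus_index: int | None = None
    dce_fit_mask: str = "enhancing"  # enhancing | lesion | brain
    hematocrit: float | None = None
    reference_min_voxels: int = 100


@dataclass
class QuantMaps:
    """The eight 3D output maps plus bookkeeping."""

    delta_r2star_ss: np.ndarray
    delta_r1_ss: np.ndarray
    c_ss: np.ndarray
    trate: np.ndarray
    psr: np.ndarray
    nrcbv: np.ndarray
    ktrans: np.ndarray | None = None
    ve: np.ndarray | None = None
    rcbv: np.ndarray | None = None
    fit_status: np.ndarray | None = None
    bolus_index: int | None = None
    input_function: dce.InputFunction | None = None

    def as_dict(self) -> dict[str, np.ndarray]:
        out = {
            "delta_r2star_ss": self.delta_r2star_ss,
            "delta_r1_ss": self.delta_r1_ss,
            "c_ss": self.c_ss,
            "trate": self.trate,
            "psr": self.psr,
            "nrcbv": self.nrcbv,
        }
        if self.ktrans is not None:
            out["ktrans"] = self.ktrans
            out["ve"] = self.ve
        return out


def _mask_to_brain(arr: np.ndarray, brain: np.ndarray) -> np.ndarray:
    out = np.where(brain, arr, np.nan)
    return out


def run_pipeline(
    e1: EchoSeries,
    e2: EchoSeries,
    masks: MaskSet,
    params: AcquisitionParams,
    options: PipelineOptions | None = None,
) -> QuantMaps:
    """Compute every quantitative map from the two echo series."""
    opts = options or PipelineOptions()
    if e1.shape != e2.shape:
        raise ValueError(f"echo shapes differ: {e1.shape} vs {e2.shape}")
    if e1.n_timepoints != params.n_timepoints:
        raise ValueError("echo time axis does not match acquisition parameters")
    if masks.brain.shape != e1.shape[:3]:
        raise ValueError("brain mask does not match echo geometry")
    if opts.dce_enabled and (masks.aif_roi is None or not masks.aif_roi.any()):
        raise ValueError("DCE requested but no input-function (aif_roi) mask given")

    brain = masks.brain
    cfg = RelaxometryConfig.from_acquisition(params)

    # stage 1: dual-echo decomposition (restricted to brain voxels)
    s1 = e1.voxels[brain]
    s2 = e2.voxels[brain]
    log.info("decomposition: te1=%g te2=%g baseline=%s", params.te1, params.te2,
             params.baseline_window)
    dr2s = decomposition.compute_r2star_curve(s1, s2, params)
    t1w = decomposition.compute_t1w_curve(s1, s2, params)
    n_invalid = int(np.isnan(dr2s).all(axis=-1).sum())
    log.info("decomposition: %d voxels fully invalidated", n_invalid)

    # stage 2: SPGR inversion to ΔR1(t) and C(t)
    t1w_base = decomposition.baseline_mean(t1w, params)
    ok = np.isfinite(t1w_base) & (t1w_base > 0)
    inv_dr1 = np.full_like(t1w, np.nan)
    clamp_count = 0
    if ok.any():
        inv = relaxometry.invert_spgr_to_r1(t1w[ok], cfg, t1w_base[ok])
        inv_dr1[ok] = inv.delta_r1
        clamp_count = inv.n_clamped
    conc = relaxometry.concentration_from_r1(inv_dr1, cfg)
    log.info("relaxometry: t10=%g r1=%g fa=%g; %d clamped voxel-timepoints",
             cfg.t10, cfg.r1_relaxivity, cfg.flip_angle, clamp_count)

    # stage 3: steady-state maps
    shape = brain.shape
    def to_map(vox_vals: np.ndarray) -> np.ndarray:
        out = np.full(shape, np.nan)
        out[brain] = vox_vals
        return out

    dr2s_ss = to_map(steady_state.tail_average(dr2s, params.n_tail))
    dr1_ss = to_map(steady_state.tail_average(inv_dr1, params.n_tail))
    c_ss = to_map(steady_state.tail_average(conc, params.n_tail))
    trate = steady_state.compute_trate(dr2s_ss, c_ss, opts.css_floor)
    log.info("steady_state: n_tail=%d css_floor=%g; trate defined in %d voxels",
             params.n_tail, opts.css_floor, int(np.isfinite(trate).sum()))

    # stage 4: classic DSC from echo 2
    mean_dr2s = np.nanmean(dr2s, axis=0)
    bolus = decomposition.detect_bolus_arrival(mean_dr2s, params)
    if bolus is None:
        bolus = opts.fallback_bolus_index
        if bolus is None:
            raise RuntimeError(
                "stage dsc: no bolus detected and no fallback_bolus_index configured"
            )
        log.warning("dsc: bolus not detected, using fallback index %d", bolus)
    psr = to_map(dsc.compute_psr(s2, params, bolus))
    log.info("dsc: bolus index %d; %d voxels without first-pass dip",
             bolus, int(np.isnan(psr[brain]).sum()))

    reference = _reference_curve(dr2s, dr1_ss[brain], masks, opts)
    if np.any(np.nan_to_num(reference) != 0):
        fit = dsc.fit_leakage_model(
            dr2s, reference, params.dt, mode=opts.leakage_mode, kep_grid=opts.kep_grid
        )
        rcbv_vox = dsc.correct_and_integrate_rcbv(
            dr2s, fit, (bolus, params.n_timepoints)
        )
    else:
        # no vascular signal in the reference tissue (e.g. a leakage-only
        # phantom): skip the correction, integrate the raw curves
        log.warning("dsc: reference curve is zero; leakage correction skipped")
        rcbv_vox = np.trapezoid(dr2s[..., bolus:], dx=params.dt, axis=-1)
    rcbv = to_map(rcbv_vox)
    try:
        nrcbv = dsc.normalize_rcbv(rcbv, brain, min_voxels=min(1000, int(brain.sum())))
    except ValueError as exc:
        log.warning("dsc: %s; nrcbv left undefined", exc)
        nrcbv = np.full(shape, np.nan)
    log.info("dsc: leakage mode=%s; rcbv integrated over [%d, %d)",
             opts.leakage_mode, bolus, params.n_timepoints)

    maps = QuantMaps(
        delta_r2star_ss=dr2s_ss, delta_r1_ss=dr1_ss, c_ss=c_ss, trate=trate,
        psr=psr, nrcbv=nrcbv, rcbv=rcbv, bolus_index=bolus,
    )

    # stage 5: DCE (Tofts) — optional
    if opts.dce_enabled:
        t1w_full = np.full(shape + (params.n_timepoints,), np.nan)
        t1w_full[brain] = t1w
        aif = dce.extract_aif(t1w_full, masks.aif_roi, params, cfg,
                              hematocrit=opts.hematocrit)
        conc_map = np.full(shape + (params.n_timepoints,), np.nan)
        conc_map[brain] = conc
        fit_sel = _dce_fit_mask(c_ss, masks, opts)
        ktrans, ve, status = dce.fit_voxelwise(conc_map, aif, mask=fit_sel)
        maps.ktrans = _mask_to_brain(ktrans, brain)
        maps.ve = _mask_to_brain(ve, brain)
        maps.fit_status = status
        maps.input_function = aif
        log.info("dce: fit %d voxels (%s mask); %d failed",
                 int(fit_sel.sum()), opts.dce_fit_mask, int((status == -1).sum()))
    return maps


def _reference_curve(
    dr2s_vox: np.ndarray, dr1_ss_vox: np.ndarray, masks: MaskSet,
    opts: PipelineOptions,
) -> np.ndarray:
    """Mean ΔR2*(t) over non-enhancing reference voxels.

    Brain voxels excluding the lesion and excluding the top decile of ΔR1,ss
    (an enhancement proxy), so contrast extravasation does not contaminate
    the reference.
    """
    sel = np.ones(dr2s_vox.shape[0], dtype=bool)
    if masks.lesion is not None:
        sel &= ~masks.lesion[masks.brain]
    finite = np.isfinite(dr1_ss_vox)
    if finite.any():
        p90 = np.nanpercentile(dr1_ss_vox[sel & finite], 90)
        sel &= ~(dr1_ss_vox > p90)
    if sel.sum() < opts.reference_min_voxels:
        raise RuntimeError(
            f"stage dsc: only {int(sel.sum())} reference voxels "
            f"(need {opts.reference_min_voxels})"
        )
    return np.nanmean(dr2s_vox[sel], axis=0)


def _dce_fit_mask(c_ss: np.ndarray, masks: MaskSet, opts: PipelineOptions) -> np.ndarray:
    if opts.dce_fit_mask == "brain":
        sel = masks.brain.copy()
    elif opts.dce_fit_mask == "lesion" and masks.lesion is not None:
        sel = masks.lesion.copy()
    else:
        # default: voxels with measurable tracer accumulation
        with np.errstate(invalid="ignore"):
            sel = masks.brain & (c_ss > opts.css_floor)
    if masks.aif_roi is not None:
        sel &= ~masks.aif_roi  # the vascular input region is not tissue
    return sel
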