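# Methods

This note documents the models implemented in `sage_quant`, the numerical
choices behind them, what the digital phantom does and does not emulate, and
the known limitations of both.

## Signal model and dual-echo decomposition

A dual-gradient-echo dynamic acquisition samples the same excitation at two
echo times (defaults TE₁ = 14 ms, TE₂ = 34.1 ms; TR = 2 s; 90 frames; flip
angle 90°). Assuming mono-exponential transverse decay per frame,

    S(TE, t) = T1w(t) · exp(−TE · R2*(t)),

two echoes determine both unknowns exactly:

    R2*(t) = ln(S₁/S₂) / (TE₂ − TE₁)
    T1w(t) = S₁ · (S₁/S₂)^(TE₁/(TE₂−TE₁))        (extrapolation to TE = 0)

ΔR2*(t) is R2*(t) minus its mean over the pre-bolus baseline window and is
invariant to any common gain on the two echoes; T1w(t) scales linearly with
that gain, which is why everything downstream of it works on the ratio to
its own baseline. The baseline window defaults to frames `[5, 25)`: the
first five frames are discarded while longitudinal magnetization approaches
steady state (standard dynamic-imaging practice; the acquisition itself does
not mark a steady-state frame), and the bolus in a 90-frame, TR = 2 s
protocol arrives after frame 25 in the bundled phantom. Frames where either
echo is non-positive are invalidated (NaN); a voxel with more than 20 % of
its frames invalid is rejected outright rather than silently interpolated.

## SPGR inversion and concentration

The T1-weighted contribution is converted to longitudinal relaxation via the
spoiled-gradient-echo steady-state equation with a fixed pre-contrast T1
(T₁₀ = 1.4 s; no T1 mapping is attempted, for tissue and the input-function
ROI alike). Writing E = exp(−TR·R1) and ρ(t) = T1w(t)/T1w_baseline,

    g(t) = ρ(t) · (1 − E₀)/(1 − cos α · E₀),   E₀ = exp(−TR/T₁₀)
    E(t) = (1 − g)/(1 − g cos α),   R1(t) = −ln E(t)/TR,
    ΔR1(t) = R1(t) − 1/T₁₀,         C(t) = ΔR1(t)/r₁

with r₁ = 5.0 mM⁻¹s⁻¹ (gadobutrol at 3 T). The general-α form is kept so a
30° low-flip-angle protocol variant is a pure configuration change. At
α = 90° the expression reduces to R1 = −ln[1 − ρ(1−E₀)]/TR; both paths agree
to machine precision and are covered by a forward/inverse identity test over
R1 ∈ [0.2, 5] s⁻¹.

**Saturation.** At TR = 2 s the longitudinal signal is nearly fully
recovered, so the SPGR curve compresses hard: the signal ratio has a finite
supremum 1/(1−E₀) ≈ 1.313 at α = 90°, reached already near R1 ≈ 10 s⁻¹
(≈ 2 mM of agent). Ratios at or beyond the bound are clamped to
`clamp_epsilon` and flagged rather than erroring, so maps stay computable in
hot vascular voxels; clamp counts go to the log. A practical consequence,
discussed under Limitations: concentrations above roughly 0.5 mM are not
reliably invertible in the presence of noise with this protocol.

## Steady-state maps and TRATE

ΔR2,ss*, ΔR1,ss and Css are the arithmetic means of the final `n_tail = 10`
frames of the respective curves (NaN-aware). The transverse relaxivity at
tracer equilibrium is their ratio,

    TRATE = ΔR2,ss* / Css     [mM⁻¹ s⁻¹],

the T2* leakage effect normalized to the extravasated tracer concentration —
a quantity sensitive to tissue cytoarchitecture rather than to acquisition
settings. Because it is a ratio, it diverges at vanishing enhancement;
TRATE is therefore masked to NaN wherever Css ≤ `css_floor` (default
0.01 mM), which operationalizes "enhancing tissue only" voxelwise. The floor
is a repository policy, not an estimate from data.

## Classic DSC metrics (echo 2)

**PSR.** Percentage of signal recovery uses three windows on the raw E2
signal: the baseline mean S̄_pre, the post-bolus minimum S_min (searched from
the detected bolus frame onward), and the steady-state tail mean S̄_post over
the final `n_tail` frames:

    PSR = 100 · (S̄_post − S_min)/(S̄_pre − S_min).

Values above 100 % (T1-dominant overshoot) are admissible. Voxels without a
first-pass dip (S_min ≥ S̄_pre) are NaN and counted in the log. Bolus arrival
is detected on the brain-mean ΔR2* curve as the first post-baseline frame
exceeding the baseline mean by 3 baseline SDs, with a configurable fixed
fallback when no bolus is found.

**Leakage-corrected rCBV.** Contrast extravasation biases the ΔR2* integral.
The bidirectional model regresses each voxel curve on a non-enhancing
reference curve x̄(t) and its efflux-weighted running integral:

    ΔR2*_meas(t) ≈ K₁ x̄(t) − K₂ ∫₀ᵗ x̄(τ) e^(−kep_m (t−τ)) dτ.

For fixed kep_m the model is linear in (K₁, K₂) and solved in closed form
for all voxels simultaneously; kep_m is chosen by residual scan over a grid
(default 0–0.1 s⁻¹ in 0.002 s⁻¹ steps, covering physiologic efflux at this
sampling rate). The unidirectional variant fixes kep_m = 0; since 0 is on
the grid, the bidirectional residual can never exceed the unidirectional one
(a tested invariant). The corrected curve restores the leakage term and is
integrated trapezoidally from the bolus frame to the end of acquisition —
with the correction in place the tail is unbiased, so the full window is
used rather than first-pass-only (configurable). The reference curve is the
mean ΔR2* over brain voxels excluding the lesion and excluding the top
decile of ΔR1,ss (an enhancement proxy). nrCBV divides by the whole-brain
median rCBV; the "cerebral median" mask is not precisely defined upstream,
and using normal-appearing tissue instead would rescale all nrCBV values by
a common factor.

If the reference curve is identically zero (possible in leakage-only
phantoms with no vascular term), the pipeline logs a warning, skips the
correction and integrates the raw curves; if the brain-median rCBV is not
positive, nrCBV is left undefined rather than aborting the run.

## Permeability (Tofts) analysis

The vascular input function is the ROI-mean T1w(t) of a venous-sinus mask,
inverted to concentration exactly as tissue is. No hematocrit scaling and no
delay/dispersion correction are applied by default (a hematocrit factor is
available but off). The standard Tofts model

    Ct(t) = Kᵗʳᵃⁿˢ ∫₀ᵗ Cp(τ) e^(−(Kᵗʳᵃⁿˢ/vₑ)(t−τ)) dτ

is evaluated with an exact exponential-kernel recursion (trapezoidal
quadrature, cost linear in frames; verified against a brute-force double
loop to 1e−10 and against the boxcar closed form to 0.5 % at dt = 2 s).
Time is handled in seconds internally; Kᵗʳᵃⁿˢ is reported in min⁻¹.

The fit is bounded nonlinear least squares on the concentration curve
(Kᵗʳᵃⁿˢ ∈ [1e−5, 5] min⁻¹, vₑ ∈ [1e−3, 1]), started at (0.1 min⁻¹, 0.3);
on failure or a bound-hit two further fixed starts are tried and the best
residual wins. The model is fit to C(t) derived deterministically from
T1w(t) — the same information under the fixed-T₁₀ SPGR model — so that the
model is expressed in concentration units. By default the pipeline fits only
brain voxels whose tail concentration clears `css_floor` (excluding the
input-function ROI): the model is unidentifiable where no tracer arrives,
and fitting such voxels would only produce bound-pinned noise.

**Identifiability.** On noiseless data the grid Kᵗʳᵃⁿˢ ∈ {0.02…0.3} min⁻¹ ×
vₑ ∈ {0.1…0.5} is recovered to < 1 %. Under noise, vₑ is poorly identified
when kep·T_acq ≲ 1 (slow washout over a ~3 min acquisition): errors at
Kᵗʳᵃⁿˢ = 0.02 min⁻¹ are several times larger than elsewhere, and vₑ drifts
toward its upper bound. This is a property of the short protocol, not of the
optimizer, and is visible in the Monte-Carlo numbers the acceptance script
reports.

## Enhancing-tumor segmentation

Pre- and post-contrast T1-weighted volumes are each normalized by their
brain-median intensity (making the rule invariant to independent global
gains), subtracted, and thresholded: a voxel enhances when the normalized
increase is at least 10 % of its normalized pre-contrast value, restricted
to a lesion outline supplied as input (drawing the outline is an upstream
manual step). Connected components smaller than `min_cluster = 5` voxels
(26-connectivity) are removed as salt-and-pepper noise. An empty mask is a
valid result (non-enhancing lesion), returned with a warning.

## The digital phantom

The phantom forward-simulates everything the pipeline consumes from known
ground truth: axis-aligned blocks (background, normal tissue, three tumor
variants, a sinus stripe) on a 32×32×8 grid; a plasma input
Cp(t) = gamma-variate first pass + smooth rise to an equilibrium tail;
tissue curves Ct(t) from the Tofts model; relaxation
R1(t) = R₁₀ + r₁·Ct(t) and R2*(t) = R₂₀* + cbv_amp·k_iv·Cp(t) +
TRATE_true·Ct(t); SPGR × T2*-decay rendering at both echo times; optional
seeded Rician (or Gaussian) noise with σ = baseline signal / SNR. Sinus
voxels carry R1(t) = R₁₀ + r₁·Cp(t) and no transverse bolus term, giving the
input-function extraction a clean target. All randomness flows from the
single spec seed; noiseless output and ground truth are bit-reproducible.

Parameter choices: tumor Kᵗʳᵃⁿˢ/vₑ/TRATE values bracket enhancing-glioma
ranges (e.g. 0.16 min⁻¹ / 0.28 / 153 mM⁻¹s⁻¹ for the aggressive
treatment-naive block). The intravascular susceptibility coefficient k_iv
is a free calibration constant, set to 2.5 s⁻¹/mM so normal-tissue
first-pass ΔR2* peaks near 5 s⁻¹; no vascular-network biophysics is
simulated — the phantom's job is pipeline testing, not mesoscopic realism.
The default bolus amplitude is 2.0 mM with a 0.3 mM equilibrium tail:
venous-sinus concentrations are partial-volume diluted relative to arterial
blood, and 2.0 mM is the largest peak the TR = 2 s / 90° SPGR inversion can
recover to numerical precision (see Saturation above); larger boluses would
render a sinus whose signal cannot represent its own concentration.

What the phantom does **not** emulate: motion, registration error, B1 and
B0 inhomogeneity, EPI distortion and susceptibility artifacts, water
exchange, measured T1 maps, intravascular T1 contribution in tissue voxels,
vessel-size-dependent susceptibility physics, and realistic anatomical
geometry. Passing the phantom oracles therefore demonstrates the numerical
correctness and internal consistency of every processing stage under the
stated signal model — not robustness to the full physics of patient data.

## Validation experiments (`sage_quant.experiments`)

* **pipeline_recovery** — noiseless leakage-only phantom (k_iv = 0)
  end-to-end; curve recovery is exact to rounding and the steady-state
  lesion medians match truth to ≪ 0.5 % (the tail-equilibrium average is
  compared against the identically-defined truth tail average, so no
  equilibration bias enters).
* **tofts_recovery** — the parameter grid, noiseless and with 100 voxels
  per cell at baseline SNR 50. Rician noise is injected on the T1w(t)
  series, the signal the permeability stage consumes; re-deriving T1w from
  two noisy echoes would additionally carry the decomposition's fixed noise
  amplification factor √((1+γ)² + γ²) ≈ 1.83 (γ = TE₁/(TE₂−TE₁)) and
  conflate two stages that are validated separately.
* **leakage_correction** — paired leaky/leak-free voxel twins over
  K₂ ∈ ±[0.005, 0.05], noiseless and at SNR 50. At SNR 50 the comparison is
  between ensemble medians of 100 paired voxels per K₂ (the twins share
  noise draws): a single voxel's rCBV at this SNR has ~20 % thermal spread,
  which would measure noise rather than the correction.
* **cohort_direction** — two simulated cohorts of 10 subjects
  (treatment-naive aggressive: high TRATE, slow transfer; treated: lower
  TRATE, faster transfer, larger interstitial fraction), each subject a
  seeded noisy phantom run end-to-end, lesion medians compared by
  Mann-Whitney. Group parameters encode the qualitative contrast only and
  are sized, together with a 10 % inter-subject lognormal spread, to be
  separable at n = 10; real cohorts are far more dispersed, and with
  realistic spreads some of these contrasts are *not* significant at this
  sample size. The cohort input function uses the diluted venous regime
  (0.5 mM peak) so that per-subject input-function scale errors do not
  dominate the transfer-constant medians.
* **operating_point** — a constructed 9-positive/10-negative cohort
  evaluated at the fixed cutoff 142 mM⁻¹s⁻¹, by construction 8/9 above and
  8/10 below: sensitivity 88.9 %, specificity 80.0 %.

## Statistics layer

Lesion records are ROI **medians** (NaNs dropped). Pearson correlation with
R² = r² and a two-sided t-test p (n−2 df); Mann-Whitney U two-sided, exact
null enumeration for pooled n ≤ 20 without ties, tie-corrected normal
approximation otherwise; ROC AUC from the rank statistic (equal to the
trapezoidal area under the empirical curve, a tested identity), with either
a fixed operating cutoff (default "metric > 142" orientation) or the
Youden-optimal one. The proliferation index (Ki67) is binarized at 10 %.
The significance threshold is 0.05 with no multiple-testing correction.

## Known limitations

* Fixed T₁₀ everywhere; no B1 correction or water-exchange modelling.
* The venous input function is used without hematocrit, delay or dispersion
  correction; at this TR and flip angle its first-pass peak saturates the
  SPGR signal, so absolute Kᵗʳᵃⁿˢ scales inherit input-function uncertainty.
* TRATE below the Css floor is undefined by policy; whether to floor before
  taking lesion medians is a convention, and medians over barely-enhancing
  lesions are sensitive to it.
* The nrCBV normalization mask (whole brain) is a convention; alternatives
  rescale all values by a constant.
* Motion correction and inter-sequence registration are assumed done
  upstream; inputs must already be co-registered.
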