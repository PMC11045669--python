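"""Input-function extraction and Tofts model fitting."""

import numpy as np
import pytest

from sage_quant import dce, phantom
from sage_quant.params import AcquisitionParams, RelaxometryConfig


@pytest.fixture(scope="module")
def cp_fn(acq):
    cp = phantom.generate_input_function(phantom.AifParams(), acq.times)
    return dce.InputFunction(times=acq.times, cp=cp)


def brute_force_convolution(ktrans_per_min, ve, cp_fn):
    """Double-loop trapezoidal convolution (the independent oracle)."""
    kt = ktrans_per_min / 60.0
    kep = kt / ve
    t = cp_fn.times
    n = t.size
    out = np.zeros(n)
    for i in range(n):
        integrand = cp_fn.cp[: i + 1] * np.exp(-kep * (t[i] - t[: i + 1]))
        out[i] = kt * np.trapezoid(integrand, t[: i + 1]) if i else 0.0
    return out


class TestToftsForward:
    def test_zero_ktrans_gives_zero(self, cp_fn):
        assert np.all(dce.tofts_forward(0.0, 0.3, cp_fn) == 0.0)

    def test_matches_brute_force_convolution(self, cp_fn):
        """Recursive exponential convolution vs explicit double loop."""
        for kt, ve in [(0.02, 0.1), (0.16, 0.28), (0.3, 0.5)]:
            fast = dce.tofts_forward(kt, ve, cp_fn)
            slow = brute_force_convolution(kt, ve, cp_fn)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_matches_brute_force_on_random_input(self, acq):
        rng = np.random.default_rng(11)
        cp = dce.InputFunction(times=acq.times, cp=rng.random(acq.n_timepoints))
        fast = dce.tofts_forward(0.12, 0.25, cp)
        slow = brute_force_convolution(0.12, 0.25, cp)
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_impulse_response_decays_exponentially(self, acq):
        cp = np.zeros(acq.n_timepoints)
        cp[20] = 1.0
        fn = dce.InputFunction(times=acq.times, cp=cp)
        ct = dce.tofts_forward(0.12, 0.3, fn)
        kep = 0.12 / 60.0 / 0.3
        tail = ct[25:60]
        ratio = tail[1:] / tail[:-1]
        np.testing.assert_allclose(ratio, np.exp(-kep * acq.dt), rtol=1e-9)

    def test_boxcar_closed_form(self, acq):
        """Ct = ve*(1 - exp(-kep t)) during a unit boxcar input."""
        kt, ve = 0.3, 0.4
        kep = kt / 60.0 / ve
        cp = np.zeros(acq.n_timepoints)
        cp[0:45] = 1.0  # boxcar from t=0
        fn = dce.InputFunction(times=acq.times, cp=cp)
        ct = dce.tofts_forward(kt, ve, fn)
        expected = ve * (1 - np.exp(-kep * acq.times[:45]))
        err = np.abs(ct[1:45] - expected[1:45]) / expected[1:45].max()
        assert err.max() < 0.005  # trapezoidal kernel at dt = 2 s

    def test_ve_zero_with_positive_ktrans_rejected(self, cp_fn):
        with pytest.raises(ValueError):
            dce.tofts_forward(0.1, 0.0, cp_fn)


class TestToftsFit:
    def test_noiseless_recovery(self, cp_fn):
        ct = dce.tofts_forward(0.16, 0.28, cp_fn)
        fit = dce.tofts_fit(ct, cp_fn)
        assert fit.status == "converged"
        assert fit.ktrans == pytest.approx(0.16, rel=1e-3)
        assert fit.ve == pytest.approx(0.28, rel=1e-3)

    def test_zero_curve_hits_lower_bound(self, cp_fn):
        fit = dce.tofts_fit(np.zeros(cp_fn.times.size), cp_fn)
        assert fit.status == "bound-hit"
        assert fit.ktrans <= dce.KTRANS_BOUNDS[0] * 1.01

    def test_grid_recovery_noiseless(self, cp_fn):
        """< 1 % relative error over the parameter grid."""
        for kt in (0.02, 0.06, 0.16, 0.3):
            for ve in (0.1, 0.3, 0.5):
                ct = dce.tofts_forward(kt, ve, cp_fn)
                fit = dce.tofts_fit(ct, cp_fn)
                assert abs(fit.ktrans - kt) / kt < 0.01
                assert abs(fit.ve - ve) / ve < 0.01

    def test_noisy_recovery_median_error(self, cp_fn):
        """SNR-ish Gaussian concentration noise: median error < 10 %."""
        rng = np.random.default_rng(5)
        ct = dce.tofts_forward(0.1, 0.3, cp_fn)
        errs_kt, errs_ve = [], []
        for _ in range(60):
            noisy = ct + rng.normal(0, 0.002, ct.size)
            fit = dce.tofts_fit(noisy, cp_fn)
            errs_kt.append(abs(fit.ktrans - 0.1) / 0.1)
            errs_ve.append(abs(fit.ve - 0.3) / 0.3)
        assert np.median(errs_kt) < 0.10 and np.median(errs_ve) < 0.10

    def test_multistart_never_worse(self, cp_fn):
        rng = np.random.default_rng(9)
        ct = dce.tofts_forward(0.4, 0.6, cp_fn) + rng.normal(0, 0.01, cp_fn.times.size)
        single = dce.tofts_fit(ct, cp_fn, multistart=False)
        multi = dce.tofts_fit(ct, cp_fn, multistart=True)
        assert multi.rss <= single.rss + 1e-12

    def test_too_few_samples_fail(self, cp_fn):
        ct = np.full(cp_fn.times.size, np.nan)
        ct[:20] = 0.1
        assert dce.tofts_fit(ct, cp_fn).status == "failed"


class TestExtractAif:
    def test_phantom_sinus_recovery(self, noiseless_phantom):
        """Noiseless forward-model sinus: Cp recovered to < 1e-6 mM."""
        ds = noiseless_phantom
        acq = ds.spec.acquisition
        from sage_quant import decomposition

        brain = ds.masks.brain
        t1w = np.full(ds.e1.shape, np.nan)
        t1w[brain] = decomposition.compute_t1w_curve(
            ds.e1.voxels[brain], ds.e2.voxels[brain], acq
        )
        aif = dce.extract_aif(t1w, ds.masks.aif_roi, acq)
        assert np.abs(aif.cp - ds.truth.cp).max() < 1e-6

    def test_empty_roi_rejected(self, noiseless_phantom):
        ds = noiseless_phantom
        empty = np.zeros(ds.masks.brain.shape, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            dce.extract_aif(ds.e1.voxels, empty, ds.spec.acquisition)

    def test_flat_roi_warns(self, acq):
        t1w = np.full((4, 4, 2, acq.n_timepoints), 500.0)
        roi = np.ones((4, 4, 2), dtype=bool)
        with pytest.warns(UserWarning, match="flat input function"):
            fn = dce.extract_aif(t1w, roi, acq)
        np.testing.assert_allclose(fn.cp, 0.0, atol=1e-9)

    def test_saturated_roi_rejected(self, acq):
        cfg = RelaxometryConfig.from_acquisition(acq)
        e0 = np.exp(-cfg.tr / cfg.t10)
        sat = 1.0 / (1 - e0) + 0.1
        t1w = np.full((2, 2, 1, acq.n_timepoints), 100.0)
        t1w[..., 30:] = 100.0 * sat  # beyond saturation for > 50 % of frames
        roi = np.ones((2, 2, 1), dtype=bool)
        with pytest.raises(ValueError, match="saturated"):
            dce.extract_aif(t1w, roi, acq)

    def test_hematocrit_scaling(self, noiseless_phantom):
        ds = noiseless_phantom
        acq = ds.spec.acquisition
        from sage_quant import decomposition

        brain = ds.masks.brain
        t1w = np.full(ds.e1.shape, np.nan)
        t1w[brain] = decomposition.compute_t1w_curve(
            ds.e1.voxels[brain], ds.e2.voxels[brain], acq
        )
        plain = dce.extract_aif(t1w, ds.masks.aif_roi, acq)
        scaled = dce.extract_aif(t1w, ds.masks.aif_roi, acq, hematocrit=0.45)
        np.testing.assert_allclose(scaled.cp, plain.cp / 0.55, rtol=1e-12)
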