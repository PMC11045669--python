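import numpy as np
import pytest

from sage_quant import phantom, pipeline
from sage_quant.params import AcquisitionParams


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Leakage-only noiseless phantom (no intravascular susceptibility)."""
    return phantom.generate_phantom(phantom.default_spec(k_iv=0.0))


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom):
    ds = noiseless_phantom
    return pipeline.run_pipeline(
        ds.e1, ds.e2, ds.masks, ds.spec.acquisition,
        pipeline.PipelineOptions(fallback_bolus_index=30),
    )


@pytest.fixture(scope="session")
def default_phantom():
    """Full noiseless phantom including the intravascular first pass."""
    return phantom.generate_phantom(phantom.default_spec())


@pytest.fixture(scope="session")
def default_maps(default_phantom):
    ds = default_phantom
    return pipeline.run_pipeline(ds.e1, ds.e2, ds.masks, ds.spec.acquisition)


def mono_exp_pair(m, r2star, acq):
    """Echo signals for a mono-exponential TE decay with amplitude m."""
    m = np.asarray(m, dtype=float)
    r2star = np.asarray(r2star, dtype=float)
    return m * np.exp(-acq.te1 * r2star), m * np.exp(-acq.te2 * r2star)
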