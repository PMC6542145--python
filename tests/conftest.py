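import numpy as np
import pytest

from liverdki.models import DKIParams, dki_forward
from liverdki.scheme import AcquisitionScheme


@pytest.fixture()
def scheme() -> AcquisitionScheme:
    return AcquisitionScheme()


@pytest.fixture()
def rician_voxels():
    """Factory: replicate Rician-noise signal vectors for a fixed truth."""

    def make(params: DKIParams, scheme: AcquisitionScheme, snr: float,
             n: int, seed: int, ref_s0: float | None = None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        clean = dki_forward(params, scheme.b)
        sigma = (ref_s0 if ref_s0 is not None else params.s0) / snr
        shape = (n, len(scheme))
        return np.sqrt(
            (clean[None, :] + rng.normal(0, sigma, shape)) ** 2
            + rng.normal(0, sigma, shape) ** 2
        )

    return make
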