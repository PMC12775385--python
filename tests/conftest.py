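import numpy as np
import pytest

import spasquant as sq


@pytest.fixture(scope="session")
def default_truth():
    """One default uncompressed phantom, shared read-only across tests."""
    return sq.generate_phantom(sq.PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def reference_render(default_truth):
    return sq.render_image(default_truth, sq.ImagingMode.reference())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def single_spas_truth(d_long_mm: float, d_trans_mm: float,
                      matrix_hu: float = -700.0) -> sq.PhantomTruth:
    """Section containing exactly one centered elliptical air space."""
    spec = sq.PhantomSpec(n_spas=0, matrix_hu=matrix_hu, seed=0)
    truth = sq.generate_phantom(spec)
    s = sq.Spas(0, spec.width_mm / 2, spec.height_mm / 2,
                d_long_mm, d_trans_mm,
                np.pi / 4 * d_long_mm * d_trans_mm)
    truth.spas.append(s)
    return truth
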