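import numpy as np
import pytest

import healtheff as h


@pytest.fixture(scope="session")
def reference_corr():
    """Packaged 13x13 indicator correlation matrix (2 inputs + 11 outputs)."""
    return h.load_reference_correlations()


@pytest.fixture(scope="session")
def output_corr(reference_corr):
    """11x11 output-indicator submatrix (NC ... ADH)."""
    labels = [c for c in reference_corr.labels if c not in ("PPP", "EXP")]
    return reference_corr.submatrix(labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def random_technology(rng, n=8, m=2, q=2, rts="crs"):
    X = rng.uniform(0.5, 5.0, size=(m, n))
    Y = rng.uniform(0.5, 5.0, size=(q, n))
    return h.DEATechnology(X, Y, rts=rts)


@pytest.fixture
def toy_panel():
    """3 DMUs x 3 periods x (1 input, 1 output), strictly positive."""
    rng = np.random.default_rng(7)
    X = rng.uniform(1.0, 3.0, size=(3, 3, 1))
    Y = rng.uniform(1.0, 3.0, size=(3, 3, 1))
    return h.PanelDataset.from_arrays(X, Y, regions={"DMU01": "E", "DMU02": "W",
                                                     "DMU03": "C"})
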