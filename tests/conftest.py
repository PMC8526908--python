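import numpy as np
import pytest

from mirtox import ExpressionMatrix


@pytest.fixture
def toy_rpkm():
    """4 genes x 5 cells with known structure for essential-gene calling."""
    values = np.array(
        [
            [1.0, 2.0, 0.8, 1.5, 0.9],   # ubiquitous, well above any toy cutoff
            [0.6, 0.6, 0.6, 0.6, 0.6],   # ubiquitous, just above 0.5
            [0.2, 0.2, 0.0, 0.2, 0.2],   # zero in one cell
            [0.05, 0.05, 0.05, 0.05, 0.05],  # below 0.1 everywhere
        ]
    )
    return ExpressionMatrix(
        genes=["UBIQ1", "UBIQ2", "DROPPY", "FAINT"],
        cells=[f"c{i}" for i in range(5)],
        values=values,
        unit="rpkm",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
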