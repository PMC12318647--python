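import numpy as np
import pandas as pd
import pytest

from ftirdae.spectra_io import SpectraSet, WavenumberGrid


@pytest.fixture
def small_grid():
    return WavenumberGrid(np.arange(950.0, 3051.0, 2.0))


@pytest.fixture
def tiny_spectra():
    """Three samples on a 5-point grid with full metadata."""
    grid = WavenumberGrid(np.array([1000.0, 1500.0, 2000.0, 2500.0, 3000.0]))
    absorbance = np.array(
        [
            [0.1, 0.5, 0.05, 0.2, 0.3],
            [0.2, 0.4, 0.06, 0.1, 0.2],
            [0.3, 0.6, 0.04, 0.3, 0.1],
        ]
    )
    meta = pd.DataFrame(
        {
            "label": [1, 0, 1],
            "age": [70.0, 60.0, 65.0],
            "sex": ["F", "M", "M"],
            "bmi": [25.0, 27.0, 24.0],
            "stage": ["II", "unknown", "IV"],
        },
        index=pd.Index(["S1", "S2", "S3"], name="sample_id"),
    )
    return SpectraSet(grid, absorbance, ["S1", "S2", "S3"], meta)
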