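import numpy as np
import pytest

from benthosens import EnvGrid, GridSpec


@pytest.fixture
def spec() -> GridSpec:
    return GridSpec(n_rows=4, n_cols=5, cell_size_deg=0.03,
                    origin_lon=-1.0, origin_lat=50.0)


@pytest.fixture
def make_grid(spec):
    def _make(values, mask=None, name="layer", units=""):
        return EnvGrid(spec=spec, values=np.asarray(values, dtype=float),
                       mask=mask, name=name, units=units)
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
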