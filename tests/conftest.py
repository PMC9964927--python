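import numpy as np
import pytest

from tdaf.core import Phase, Tissue, Treatment, VoltageSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def short_series(rng):
    """A 5-minute control series at 62.5 Hz for fast pipeline tests."""
    return VoltageSeries(
        samples=rng.standard_normal(int(300 * 62.5)),
        fs=62.5,
        treatment=Treatment.CONTROL,
        tissue=Tissue.LOCAL,
        phase=Phase.BEFORE,
        series_id="short0",
    )
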