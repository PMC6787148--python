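import numpy as np
import pytest

from actifractal.series import ActivityCountSeries


@pytest.fixture
def make_counts():
    """Factory for count series with minimal boilerplate."""

    def _make(values, delta=60, **kwargs):
        return ActivityCountSeries(np.asarray(values), delta, **kwargs)

    return _make
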