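import numpy as np
import pytest

from blinkscore.ear import EARSeries


def series_from(values, fps=30.0):
    """EARSeries from a plain list (None -> missing)."""
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    return EARSeries(ear=arr, fps=fps)


@pytest.fixture
def pilot_records():
    from blinkscore.datasets import pilot_participants

    return pilot_participants()
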