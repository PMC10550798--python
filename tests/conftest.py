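import logging

import numpy as np
import pandas as pd
import pytest

from qpcrarray.core import CqMatrix

# the window-fallback message is routine for deliberately degenerate test
# curves; keep test output clean
logging.getLogger("qpcrarray.calling").setLevel(logging.ERROR)


@pytest.fixture
def small_matrix() -> CqMatrix:
    """3 targets x 4 samples, one missing cell in target T2."""
    values = pd.DataFrame(
        {
            "s1": [20.0, 25.0, 30.0],
            "s2": [20.5, 25.5, 30.5],
            "s3": [21.0, np.nan, 31.0],
            "s4": [21.5, 26.5, 31.5],
        },
        index=["T1", "T2", "T3"],
    )
    groups = {"s1": "case", "s2": "case", "s3": "control", "s4": "control"}
    return CqMatrix(values, groups)
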