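import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from coretrn.containers import ExpressionMatrix

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_expression(values, groups, symbols=None, detection=None, log_scale=False):
    """Build an ExpressionMatrix from a 2-D array.

    ``groups`` maps group label -> number of replicate columns, e.g.
    {"A": 3, "B": 3}; columns are named A_1..A_3, B_1..B_3.
    """
    values = np.asarray(values, dtype=float)
    cols, group_map = [], {}
    for g, n in groups.items():
        for r in range(n):
            name = f"{g}_{r + 1}"
            cols.append(name)
            group_map[name] = g
    probes = [f"probe{i + 1}" for i in range(values.shape[0])]
    df = pd.DataFrame(values, index=probes, columns=cols)
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, dtype=float), index=probes, columns=cols)
    return ExpressionMatrix(
        values=df,
        symbols=pd.Series(symbols if symbols is not None else probes, index=probes),
        sample_groups=group_map,
        detection_pvals=det,
        log_scale=log_scale,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
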