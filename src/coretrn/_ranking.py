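"""Competition ("minimum") ranking used by every ranked table.

Tied items share the smallest rank of their tie group and the next
distinct item is ranked as if all preceding items were distinct, e.g.
counts (5, 3, 3, 0) rank as (1, 2, 2, 4).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["competition_rank"]


def competition_rank(values, descending: bool = True) -> np.ndarray:
    """Integer competition ranks of ``values``.

    Parameters
    ----------
    values : array-like of real numbers
    descending : rank 1 goes to the largest value when true (default).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("competition_rank expects a 1-D array")
    if descending:
        arr = -arr
    return rankdata(arr, method="min").astype(int)
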