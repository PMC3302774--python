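"""Expression profiling: normalization, detection filtering, differential
statistics and fold-change ranking of transcription factors.

This is the expression arm of the core-element selection workflow: bead-array
signal for the target cell type (e.g. CD14+ monocytes) and the source cell
type (dermal fibroblasts) is quantile normalized, probes never detected above
background are dropped, per-probe fold changes and t-test p-values are
computed between the two cell types, and TF probes passing the
fold-change/p-value gate are ranked by descending fold change (rank ``rfc``).
"""

from __future__ import annotations

from collections.abc import Collection

import numpy as np
import pandas as pd
from scipy import stats

from ._ranking import competition_rank
from .containers import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "detection_filter",
    "differential_stats",
    "rank_tfs_by_fold_change",
]

#: Linear-signal floor used in fold-change denominators/numerators so that a
#: group mean of zero cannot produce an infinite or undefined ratio.  Bead
#: array background is tens of units, so 1.0 is far below any real signal.
SIGNAL_FLOOR = 1.0


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize samples so all columns share one distribution.

    Each column's sorted values are replaced by the across-column mean of
    values at the same rank; row order is preserved.  Ties within a column
    are resolved by stable sort order, which keeps the transform idempotent.
    """
    if matrix.values.shape[0] == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    vals = matrix.values.to_numpy(dtype=float)
    order = np.argsort(vals, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(vals, order, axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        out[order[:, j], j] = rank_means
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with_values(values)


def detection_filter(matrix: ExpressionMatrix, alpha: float = 0.01) -> ExpressionMatrix:
    """Drop probes never detected above background.

    A probe is retained when its detection p-value is below ``alpha`` in at
    least one sample (i.e. the probe is expressed somewhere); all other
    probes are removed.  Requires ``detection_pvals``.
    """
    if matrix.detection_pvals is None:
        raise ValueError("detection_filter requires detection p-values")
    detected = (matrix.detection_pvals.to_numpy(dtype=float) < alpha).any(axis=1)
    keep = matrix.values.index[detected]
    return matrix.subset_probes(keep)


def differential_stats(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    log_transform: bool = True,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-probe differential expression between two sample groups.

    Fold change is the ratio of linear group means (floored at
    ``SIGNAL_FLOOR``), group A over group B; the two-sided two-sample
    t-test (Welch by default) is run on log2 signal when ``log_transform``
    is set, otherwise on the raw values.  No multiplicity adjustment is
    applied.

    Returns a DataFrame indexed by probe with columns ``symbol``,
    ``mean_a``, ``mean_b``, ``fold_change``, ``log2_fc``, ``p_value``.
    """
    cols_a = matrix.group_samples(group_a)
    cols_b = matrix.group_samples(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both groups need at least two samples for a t-test")
    a = matrix.values[cols_a].to_numpy(dtype=float)
    b = matrix.values[cols_b].to_numpy(dtype=float)

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    fold = np.maximum(mean_a, SIGNAL_FLOOR) / np.maximum(mean_b, SIGNAL_FLOOR)

    if log_transform:
        ta = np.log2(np.maximum(a, SIGNAL_FLOOR))
        tb = np.log2(np.maximum(b, SIGNAL_FLOOR))
    else:
        ta, tb = a, b
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(ta, tb, axis=1, equal_var=equal_var)
    # zero variance in both groups with equal means -> NaN from the test;
    # the data show no difference, so report p = 1
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    return pd.DataFrame(
        {
            "symbol": matrix.symbols.to_numpy(),
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "log2_fc": np.log2(fold),
            "p_value": pvals,
        },
        index=matrix.values.index,
    )


def rank_tfs_by_fold_change(
    stats_table: pd.DataFrame,
    tf_symbols: Collection[str],
    min_fold: float = 2.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Rank TF probes by descending fold change (competition ranks).

    TF probes passing ``fold_change >= min_fold`` and ``p_value <= max_p``
    receive rank ``rfc`` 1..n by descending fold change, ties sharing the
    minimum rank.  TF probes failing the gate all share the sentinel rank
    ``n_passing + 1``.  Non-TF probes get ``rfc`` = NA.

    Returns a copy of ``stats_table`` with ``is_tf`` and ``rfc`` columns.
    """
    if not tf_symbols:
        raise ValueError("tf_symbols must be non-empty")
    out = stats_table.copy()
    tf_set = {s.upper() for s in tf_symbols}
    is_tf = out["symbol"].astype(str).str.upper().isin(tf_set).to_numpy()
    out["is_tf"] = is_tf

    rfc = np.full(len(out), np.nan)
    passing = is_tf & (out["fold_change"].to_numpy() >= min_fold) & (out["p_value"].to_numpy() <= max_p)
    n_pass = int(passing.sum())
    if n_pass:
        rfc[passing] = competition_rank(out.loc[passing, "fold_change"].to_numpy(), descending=True)
    rfc[is_tf & ~passing] = n_pass + 1
    out["rfc"] = rfc
    return out
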