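"""Reciprocal-rank integration of expression and literature evidence.

A TF probe ranked ``rfc`` by differential fold change and ``rco`` by
literature co-occurrence gets importance score

    IS = 1/rfc + 1/rco

and the top-K records by IS are selected as the core regulatory-network
elements of the target cell type.  IS lives in (0, 2]; a probe must be
near the top of at least one evidence stream to score highly, which is
what lets literature evidence rescue TFs whose transcript-level contrast
is modest (and vice versa).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["importance_score", "integrate_rankings", "select_core_elements"]


def importance_score(rfc: int, rco: int) -> float:
    """Importance score ``1/rfc + 1/rco`` for one (rfc, rco) rank pair."""
    if rfc < 1 or rco < 1:
        raise ValueError("ranks must be integers >= 1")
    return 1.0 / rfc + 1.0 / rco


def integrate_rankings(
    fc_table: pd.DataFrame,
    cooccur_table: pd.DataFrame,
) -> pd.DataFrame:
    """Join the fold-change and co-occurrence rankings per TF probe.

    ``fc_table`` is the output of
    :func:`coretrn.expression.rank_tfs_by_fold_change` (probe-indexed, with
    ``symbol``, ``is_tf`` and ``rfc``); ``cooccur_table`` the output of
    :func:`coretrn.mining.rank_cooccurrence` (symbol-indexed, with ``rco``).
    TF probes whose symbol is missing from the co-occurrence table are
    dropped with the rest of the non-TF probes.

    Returns a probe-indexed DataFrame with ``symbol``, ``rfc``, ``rco``
    and ``is`` columns.
    """
    tf_rows = fc_table[fc_table["is_tf"].astype(bool)].copy()
    rco_by_symbol = cooccur_table["rco"]
    sym_upper = tf_rows["symbol"].astype(str).str.upper()
    rco_map = {str(s).upper(): int(r) for s, r in rco_by_symbol.items()}
    tf_rows = tf_rows[sym_upper.isin(rco_map)].copy()
    rfc = tf_rows["rfc"].astype(int).to_numpy()
    rco = np.array([rco_map[s] for s in tf_rows["symbol"].astype(str).str.upper()])
    return pd.DataFrame(
        {
            "symbol": tf_rows["symbol"].to_numpy(),
            "rfc": rfc,
            "rco": rco,
            "is": 1.0 / rfc + 1.0 / rco,
        },
        index=tf_rows.index,
    )


def select_core_elements(
    table: pd.DataFrame,
    k: int = 20,
    collapse_genes: bool = False,
) -> pd.DataFrame:
    """Select the ``k`` records with the highest importance score.

    Ties at the selection boundary are broken by lower ``rfc``, then lower
    ``rco``, then lexicographic probe identifier, so selection is invariant
    to input record order.  With ``collapse_genes`` only the best probe per
    gene symbol is kept before selection; by default duplicate symbols stay
    as separate probe records.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if table.empty:
        raise ValueError("cannot select from an empty table")
    work = table.copy()
    work["_probe"] = work.index.astype(str)
    work = work.sort_values(
        by=["is", "rfc", "rco", "_probe"],
        ascending=[False, True, True, True],
        kind="mergesort",
    )
    if collapse_genes:
        work = work.loc[~work["symbol"].duplicated(keep="first")]
    return work.head(k).drop(columns="_probe")
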