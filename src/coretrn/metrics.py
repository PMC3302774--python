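"""Reconstruction metrics: how far a reprogrammed expression profile moves
toward the target cell type, plus local gene-set enrichment.

Given target- and source-specific gene signatures (defined by fold-change
and t-test thresholds between the two reference cell types), each probe in
a transduced-vs-mock contrast is categorized Up / Down / NC, coverage
fractions of the signatures are computed, category shifts are tested by
Wilcoxon rank-sum / signed-rank statistics, and gene-set enrichment uses
the two-sided Fisher exact test against a user-supplied annotation table.
"""

from __future__ import annotations

import warnings
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .expression import differential_stats

__all__ = [
    "CellTypeSignature",
    "define_specific_genes",
    "classify_regulation",
    "coverage_fractions",
    "category_shift_test",
    "paired_target_shift_test",
    "enrichment_test",
]

#: Sample-size bound below which the rank-sum test uses the exact null
#: distribution; above it a normal approximation with continuity
#: correction is used.
EXACT_N_MAX = 25


class CellTypeSignature:
    """Disjoint target- and source-specific probe sets with the thresholds
    that defined them."""

    def __init__(
        self,
        target_specific_genes: set,
        source_specific_genes: set,
        fold_threshold: float = 2.0,
        p_threshold: float = 0.03,
    ) -> None:
        if fold_threshold <= 0 or p_threshold <= 0:
            raise ValueError("thresholds must be positive")
        overlap = set(target_specific_genes) & set(source_specific_genes)
        if overlap:
            raise ValueError(f"signature sets must be disjoint, overlap: {sorted(overlap)[:5]}")
        self.target_specific_genes = set(target_specific_genes)
        self.source_specific_genes = set(source_specific_genes)
        self.fold_threshold = fold_threshold
        self.p_threshold = p_threshold


def _merged_two_group(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two single-condition matrices into one
    two-group matrix with groups "a" and "b"."""
    if not expr_a.values.index.equals(expr_b.values.index):
        raise ValueError("matrices must share an identical probe set")
    va = expr_a.values.add_prefix("a::")
    vb = expr_b.values.add_prefix("b::")
    groups = {c: "a" for c in va.columns}
    groups.update({c: "b" for c in vb.columns})
    return ExpressionMatrix(
        values=pd.concat([va, vb], axis=1),
        symbols=expr_a.symbols,
        sample_groups=groups,
        log_scale=expr_a.log_scale,
    )


def define_specific_genes(
    expr_target: ExpressionMatrix,
    expr_source: ExpressionMatrix,
    fold: float = 2.0,
    max_p: float = 0.03,
) -> CellTypeSignature:
    """Define target-/source-specific probes from the reference contrast.

    Target-specific: fold_change >= ``fold`` and p < ``max_p`` in target vs
    source; source-specific symmetrically (fold_change <= 1/``fold``).
    """
    merged = _merged_two_group(expr_target, expr_source)
    st = differential_stats(merged, "a", "b")
    fc = st["fold_change"].to_numpy()
    p = st["p_value"].to_numpy()
    target = set(st.index[(fc >= fold) & (p < max_p)])
    source = set(st.index[(fc <= 1.0 / fold) & (p < max_p)])
    return CellTypeSignature(target, source, fold_threshold=fold, p_threshold=max_p)


def classify_regulation(
    expr_test: ExpressionMatrix,
    expr_mock: ExpressionMatrix,
    fold: float = 2.0,
    max_p: float = 0.05,
) -> pd.DataFrame:
    """Categorize every probe as Up / Down / NC in test vs mock.

    Up: fold >= ``fold`` and p < ``max_p``; Down: fold <= 1/``fold`` and
    p < ``max_p``; otherwise NC.  Returns a probe-indexed DataFrame with
    ``category``, ``fold_vs_mock`` and ``p_vs_mock``.
    """
    merged = _merged_two_group(expr_test, expr_mock)
    st = differential_stats(merged, "a", "b")
    fc = st["fold_change"].to_numpy()
    p = st["p_value"].to_numpy()
    category = np.where(
        (fc >= fold) & (p < max_p), "Up", np.where((fc <= 1.0 / fold) & (p < max_p), "Down", "NC")
    )
    return pd.DataFrame(
        {"category": category, "fold_vs_mock": fc, "p_vs_mock": p}, index=st.index
    )


def coverage_fractions(
    calls: pd.DataFrame,
    signature: CellTypeSignature,
) -> tuple[float, float]:
    """Percent of the target signature induced and source signature repressed.

    induced = 100 * |Up ∩ target_specific| / |target_specific|;
    repressed = 100 * |Down ∩ source_specific| / |source_specific|.
    """
    if not signature.target_specific_genes or not signature.source_specific_genes:
        raise ValueError("signature sets must be non-empty")
    up = set(calls.index[calls["category"] == "Up"])
    down = set(calls.index[calls["category"] == "Down"])
    induced = 100.0 * len(up & signature.target_specific_genes) / len(signature.target_specific_genes)
    repressed = 100.0 * len(down & signature.source_specific_genes) / len(signature.source_specific_genes)
    return induced, repressed


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p: exact null for small tie-free
    samples, normal approximation with continuity correction otherwise."""
    exact = (
        max(len(x), len(y)) <= EXACT_N_MAX
        and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
    )
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.pvalue)


def category_shift_test(
    calls: pd.DataFrame,
    reference_expr: pd.Series,
) -> dict[tuple[str, str], float]:
    """Rank-sum tests on reference-cell expression between call categories.

    For each pair among Up/NC, Down/NC and Up/Down, compares the
    target-cell (log) expression of the probes in the two categories with
    a two-sided Wilcoxon rank-sum test.  Empty categories are skipped with
    a warning.
    """
    values = {
        cat: reference_expr.reindex(calls.index[calls["category"] == cat]).dropna().to_numpy()
        for cat in ("Up", "Down", "NC")
    }
    results: dict[tuple[str, str], float] = {}
    for a, b in (("Up", "NC"), ("Down", "NC"), ("Up", "Down")):
        if len(values[a]) == 0 or len(values[b]) == 0:
            warnings.warn(f"category pair {(a, b)} skipped: empty category", stacklevel=2)
            continue
        results[(a, b)] = _rank_sum_p(values[a], values[b])
    return results


def paired_target_shift_test(
    fc_single: pd.Series,
    fc_multi: pd.Series,
    target_probes: set,
) -> float:
    """Wilcoxon signed-rank p for a paired shift on a target-gene set.

    Tests whether fold changes under the multi-factor condition differ from
    the single-factor condition over ``target_probes`` (two-sided).  Zero
    differences are dropped (Wilcoxon's original rule); with fewer than six
    pairs the test is undefined and an error is raised.
    """
    probes = sorted(target_probes)
    if len(probes) < 6:
        raise ValueError("need at least 6 target probes for the signed-rank test")
    x = fc_multi.reindex(probes).to_numpy(dtype=float)
    y = fc_single.reindex(probes).to_numpy(dtype=float)
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("fold changes must be defined on every target probe")
    d = x - y
    if np.all(d == 0):
        return 1.0
    n_nonzero = int(np.count_nonzero(d))
    method = "exact" if n_nonzero <= EXACT_N_MAX else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.pvalue)


def enrichment_test(
    study_set: set,
    universe: set,
    annotation: Mapping[str, Sequence],
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment of ``study_set`` within ``universe``.

    For each annotation term a 2x2 table (in/out of study x in/out of term,
    restricted to the universe) is tested with the two-sided Fisher exact
    test (the p-value is the hypergeometric tail mass of tables no more
    probable than the observed one).  No multiplicity adjustment by
    default; pass the result through a BH step separately if needed.

    Returns a DataFrame indexed by term with columns ``study_in``,
    ``study_out``, ``rest_in``, ``rest_out``, ``odds_ratio``, ``p_value``.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    study = set(study_set) & set(universe)
    if set(study_set) - set(universe):
        raise ValueError("study_set must be a subset of the universe")
    rows = {}
    n_universe = len(universe)
    for term, genes in annotation.items():
        term_genes = set(genes) & set(universe)
        a = len(study & term_genes)
        b = len(study) - a
        c = len(term_genes) - a
        d = n_universe - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows[term] = {
            "study_in": a,
            "study_out": b,
            "rest_in": c,
            "rest_out": d,
            "odds_ratio": odds,
            "p_value": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("term")
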