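"""End-to-end workflows tying the pipeline stages together.

``run_select``    expression + literature evidence -> ranked core elements
``run_perturb``   perturbation matrix -> regulatory graph and top-line set
``run_evaluate``  reconstruction metrics + motif activities

Each function works on in-memory objects and optionally writes flat-text
outputs into an output directory; the CLI wraps these with file readers.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import pandas as pd

from . import io as cio
from .config import PipelineConfig
from .containers import ExpressionMatrix
from .expression import (
    detection_filter,
    differential_stats,
    quantile_normalize,
    rank_tfs_by_fold_change,
)
from .metrics import (
    CellTypeSignature,
    classify_regulation,
    coverage_fractions,
    category_shift_test,
    enrichment_test,
)
from .mining import Corpus, count_cooccurrence, filter_corpus, rank_cooccurrence
from .motifs import build_site_count_matrix, fit_motif_activities
from .perturbation import PerturbationMatrix, identify_top_line, infer_edges, rank_by_out_degree
from .selection import integrate_rankings, select_core_elements

logger = logging.getLogger("coretrn")

__all__ = ["run_select", "run_perturb", "run_evaluate"]


def _maybe_write(df: pd.DataFrame, out_dir, name: str) -> None:
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / name, sep="\t")


def run_select(
    config: PipelineConfig,
    expr_target: ExpressionMatrix,
    expr_source: ExpressionMatrix,
    corpus: Corpus,
    tf_table: dict[str, list[str]],
    group_target: str,
    group_source: str,
    out_dir=None,
) -> pd.DataFrame:
    """Core-element selection: normalize -> filter -> rank by fold change,
    mine -> rank by co-occurrence, integrate reciprocal ranks, take top-K.

    The two matrices are column-concatenated and quantile normalized
    together so both cell types share one signal distribution.
    """
    logger.info(
        "select: fold>=%g p<=%g top_k=%d keywords=%s cell_term=%s",
        config.fold_threshold, config.p_threshold, config.top_k,
        list(config.keywords), config.cell_term,
    )
    merged = ExpressionMatrix(
        values=pd.concat([expr_target.values, expr_source.values], axis=1),
        symbols=expr_target.symbols,
        sample_groups={**expr_target.sample_groups, **expr_source.sample_groups},
        detection_pvals=(
            None
            if expr_target.detection_pvals is None or expr_source.detection_pvals is None
            else pd.concat([expr_target.detection_pvals, expr_source.detection_pvals], axis=1)
        ),
    )
    merged = quantile_normalize(merged)
    if merged.detection_pvals is not None:
        merged = detection_filter(merged, alpha=config.detection_alpha)
    stats = differential_stats(merged, group_target, group_source)
    stats = rank_tfs_by_fold_change(
        stats, set(tf_table), min_fold=config.fold_threshold, max_p=config.p_threshold
    )

    filtered = filter_corpus(corpus, keywords=config.keywords)
    if len(filtered) == 0:
        warnings.warn("no abstract passed the keyword filter; all co-occurrence counts are 0", stacklevel=2)
    counts = rank_cooccurrence(count_cooccurrence(filtered, tf_table, cell_term=config.cell_term))

    integrated = integrate_rankings(stats, counts)
    selected = select_core_elements(integrated, k=config.top_k)
    _maybe_write(stats, out_dir, "differential_stats.tsv")
    _maybe_write(counts, out_dir, "cooccurrence.tsv")
    _maybe_write(integrated.sort_values("is", ascending=False), out_dir, "ranked_tfs.tsv")
    _maybe_write(selected, out_dir, "core_elements.tsv")
    return selected


def run_perturb(
    config: PipelineConfig,
    matrix: PerturbationMatrix,
    out_dir=None,
):
    """Hierarchy inference from a perturbation matrix: edge rule, top-line
    identification and out-degree ranking."""
    logger.info("perturb: edge threshold %g", config.edge_threshold)
    graph = infer_edges(matrix, threshold=config.edge_threshold)
    measured_only = set(matrix.measured_elements) - set(matrix.transduced_elements)
    top_line = identify_top_line(graph, measured_only_elements=measured_only)
    degree_rank = rank_by_out_degree(graph)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cio.write_edge_list(graph, out / "edges.tsv")
        (out / "top_line.txt").write_text("\n".join(sorted(map(str, top_line))) + "\n")
        pd.DataFrame(degree_rank, columns=["element", "out_degree"]).to_csv(
            out / "out_degree.tsv", sep="\t", index=False
        )
    return graph, top_line, degree_rank


def run_evaluate(
    config: PipelineConfig,
    expr_target: ExpressionMatrix,
    expr_source: ExpressionMatrix,
    test_bundles: dict[str, ExpressionMatrix],
    expr_mock: ExpressionMatrix,
    annotation: dict[str, list[str]] | None = None,
    promoters=None,
    pwms=None,
    out_dir=None,
) -> dict:
    """Reconstruction evaluation of one or more transduced conditions.

    For each condition in ``test_bundles``: Up/Down/NC calls vs mock,
    coverage of the target/source signatures, category shift tests against
    target-cell expression, optional gene-set enrichment of Up calls and
    optional motif-activity fitting (skipped with a warning when promoter
    sequences or PWMs are missing).
    """
    from .metrics import define_specific_genes

    signature = define_specific_genes(
        expr_target, expr_source, fold=config.fold_threshold, max_p=config.signature_p_threshold
    )
    import numpy as np

    # target-cell log2 expression per probe, used by the category shift tests
    reference_log = np.log2(np.maximum(expr_target.values.mean(axis=1), 1.0))

    results: dict = {"signature": signature, "conditions": {}}
    rows = []
    for name, expr_test in test_bundles.items():
        calls = classify_regulation(
            expr_test, expr_mock, fold=config.fold_threshold, max_p=config.p_threshold
        )
        induced, repressed = coverage_fractions(calls, signature)
        shifts = category_shift_test(calls, reference_log)
        cond: dict = {
            "calls": calls,
            "induced_fraction": induced,
            "repressed_fraction": repressed,
            "category_shift_p": shifts,
        }
        if annotation:
            up = set(calls.index[calls["category"] == "Up"])
            universe = set(calls.index)
            cond["enrichment"] = enrichment_test(up, universe, annotation)
        results["conditions"][name] = cond
        rows.append({"condition": name, "induced_pct": induced, "repressed_pct": repressed})
        logger.info("evaluate[%s]: induced %.1f%%, repressed %.1f%%", name, induced, repressed)

    if promoters is not None and pwms is not None:
        site_counts = build_site_count_matrix(promoters, pwms, prior=config.prior)
        for name, expr_test in test_bundles.items():
            log_expr = expr_test
            if not log_expr.log_scale:
                log_expr = ExpressionMatrix(
                    values=np.log2(np.maximum(expr_test.values, 1.0)),
                    symbols=expr_test.symbols,
                    sample_groups=dict(expr_test.sample_groups),
                    log_scale=True,
                )
            aligned = site_counts.reindex(log_expr.values.index).fillna(0.0)
            profile = fit_motif_activities(log_expr, aligned, regularization=config.regularization)
            results["conditions"][name]["motif_activities"] = profile
    else:
        warnings.warn("promoters or PWMs missing; motif-activity stage skipped", stacklevel=2)

    summary = pd.DataFrame(rows).set_index("condition")
    _maybe_write(summary, out_dir, "coverage.tsv")
    if out_dir is not None:
        for name, cond in results["conditions"].items():
            _maybe_write(cond["calls"], out_dir, f"calls_{name}.tsv")
            if "enrichment" in cond:
                _maybe_write(cond["enrichment"], out_dir, f"enrichment_{name}.tsv")
            if "motif_activities" in cond:
                _maybe_write(
                    cond["motif_activities"].activities, out_dir, f"motif_activities_{name}.tsv"
                )
    results["summary"] = summary
    return results
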