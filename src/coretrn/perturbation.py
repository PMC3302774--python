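"""Perturbation-matrix analysis of the regulatory hierarchy.

Each candidate core element is over-expressed one at a time in the source
cell type and the endogenous transcripts of all candidate elements are
measured by qRT-PCR.  Expression of measured element *i* under transduced
element *j*, relative to its level in the reference (target) cell type,
fills the perturbation matrix.  An edge *j -> i* is drawn when the relative
expression exceeds a threshold (5% of the reference level by default, and
above the mock-transduction baseline); elements that no transduced factor
can induce — zero in-degree nodes — are the "top-line" network inducers.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import math

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PerturbationMatrix",
    "delta_delta_ct",
    "build_perturbation_matrix",
    "infer_edges",
    "identify_top_line",
    "rank_by_out_degree",
]


@dataclass
class PerturbationMatrix:
    """Relative expression of measured elements (rows) under each
    transduced element (columns), with an optional mock baseline column.

    The measured set may strictly contain the transduced set (elements can
    be assayed without ever being over-expressed)."""

    relative_expression: pd.DataFrame
    mock: pd.Series | None = None

    def __post_init__(self) -> None:
        df = self.relative_expression
        if not df.index.is_unique or not df.columns.is_unique:
            raise ValueError("measured and transduced identifiers must be unique")
        if (df.to_numpy(dtype=float) < 0).any():
            raise ValueError("relative expression must be non-negative")
        if self.mock is not None:
            self.mock = self.mock.reindex(df.index)

    @property
    def measured_elements(self) -> list[str]:
        return list(self.relative_expression.index)

    @property
    def transduced_elements(self) -> list[str]:
        return list(self.relative_expression.columns)


def delta_delta_ct(
    ct_target_sample: float,
    ct_ref_gene_sample: float,
    ct_target_calibrator: float,
    ct_ref_gene_calibrator: float,
) -> float:
    """Relative quantification by the 2^-ddCt method.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator); returns 2^-ddCt.
    """
    cts = (ct_target_sample, ct_ref_gene_sample, ct_target_calibrator, ct_ref_gene_calibrator)
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_gene_sample) - (ct_target_calibrator - ct_ref_gene_calibrator)
    return float(2.0 ** (-ddct))


def build_perturbation_matrix(
    fold_tables: Mapping[str, Mapping[str, Sequence[float]]],
    reference_quantities: Mapping[str, float],
    mock_quantities: Mapping[str, Sequence[float]] | None = None,
) -> PerturbationMatrix:
    """Assemble the relative-expression matrix from replicate quantities.

    ``fold_tables[j][i]`` holds the replicate quantities of measured
    element *i* in cells transduced with *j* (same units as
    ``reference_quantities[i]``, e.g. 2^-dCt relative to the housekeeping
    gene).  Entry (i, j) is the replicate mean divided by the reference
    quantity of *i* in the target cell type.  Rows cover every element
    measured under any transduction; missing measurements become NaN-free
    zeros only if explicitly provided — otherwise the row simply lacks that
    column's observation and an error is raised.
    """
    measured = sorted({i for tab in fold_tables.values() for i in tab})
    transduced = list(fold_tables)
    for i in measured:
        ref = reference_quantities.get(i)
        if ref is None or not math.isfinite(ref) or ref <= 0:
            raise ValueError(f"measured element {i!r} needs a positive reference quantity")
    data = np.full((len(measured), len(transduced)), np.nan)
    for jx, j in enumerate(transduced):
        for ix, i in enumerate(measured):
            if i not in fold_tables[j]:
                raise ValueError(f"element {i!r} not measured under transduction {j!r}")
            reps = np.asarray(fold_tables[j][i], dtype=float)
            data[ix, jx] = reps.mean() / reference_quantities[i]
    rel = pd.DataFrame(data, index=pd.Index(measured, name="measured"), columns=pd.Index(transduced, name="transduced"))
    mock = None
    if mock_quantities is not None:
        mock = pd.Series(
            {i: np.mean(mock_quantities[i]) / reference_quantities[i] for i in measured if i in mock_quantities}
        )
    return PerturbationMatrix(relative_expression=rel, mock=mock)


def infer_edges(
    matrix: PerturbationMatrix,
    threshold: float = 0.05,
    require_above_mock: bool = True,
) -> nx.DiGraph:
    """Infer the regulatory graph by the relative-expression edge rule.

    Edge ``j -> i`` (transduced *j* induces measured *i*) exists iff
    ``relative_expression[i, j] > threshold`` (strict), ``i != j``, and —
    when a mock baseline is available and ``require_above_mock`` — the
    entry also exceeds the mock level of *i*.  Nodes carry a boolean
    ``transduced`` attribute; edges carry ``relative_expression``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    rel = matrix.relative_expression
    g = nx.DiGraph()
    transduced = set(rel.columns)
    for node in rel.index.union(rel.columns):
        g.add_node(node, transduced=node in transduced)
    for j in rel.columns:
        for i in rel.index:
            if i == j:
                continue  # exogenous transcript cannot induce its own locus
            val = float(rel.at[i, j])
            if val <= threshold:
                continue
            if require_above_mock and matrix.mock is not None:
                baseline = matrix.mock.get(i)
                if baseline is not None and not np.isnan(baseline) and val <= baseline:
                    continue
            g.add_edge(j, i, relative_expression=val)
    return g


def identify_top_line(
    graph: nx.DiGraph,
    measured_only_elements: frozenset | set = frozenset(),
    include_measured_only: bool = False,
) -> set:
    """Nodes with zero in-degree: the top-line network inducers.

    ``measured_only_elements`` are elements assayed but never transduced;
    they cannot show their upstream position (nothing could have induced
    them by construction) so they are excluded unless
    ``include_measured_only`` is set.
    """
    top = {n for n in graph.nodes if graph.in_degree(n) == 0}
    if not include_measured_only:
        top -= set(measured_only_elements)
    return top


def rank_by_out_degree(graph: nx.DiGraph) -> list[tuple[str, int]]:
    """Nodes sorted by descending out-degree, ties by identifier."""
    return sorted(
        ((n, graph.out_degree(n)) for n in graph.nodes),
        key=lambda item: (-item[1], str(item[0])),
    )
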