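"""Shared in-memory containers for expression data.

The central object is :class:`ExpressionMatrix`, a thin wrapper around a
probes x samples :class:`pandas.DataFrame` of non-negative linear signal
intensities, carrying probe annotation (gene symbols), a sample -> group
mapping and, optionally, per-probe detection p-values as produced by
bead-array scanners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Probes x samples signal matrix with annotation.

    Parameters
    ----------
    values
        DataFrame indexed by unique probe identifiers, one column per
        sample.  Entries must be finite; on the linear-signal scale they
        are additionally required to be non-negative (``log_scale=False``,
        the default).
    symbols
        Gene symbol for every probe, aligned with ``values.index``.
    sample_groups
        Mapping from sample (column) name to group label, e.g.
        ``{"mono_1": "monocyte", ...}``.  Every column must be present.
    detection_pvals
        Optional DataFrame of per-probe, per-sample detection p-values in
        [0, 1], same shape and labels as ``values``.
    log_scale
        Set when ``values`` holds log2 intensities (used by the motif
        activity model); lifts the non-negativity requirement.
    """

    values: pd.DataFrame
    symbols: pd.Series
    sample_groups: dict[str, str]
    detection_pvals: pd.DataFrame | None = None
    log_scale: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.values.shape[1] == 0:
            raise ValueError("expression matrix must have at least one sample")
        if not self.values.index.is_unique:
            raise ValueError("probe identifiers must be unique")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if not self.log_scale and (arr < 0).any():
            raise ValueError("linear-scale expression values must be non-negative")
        self.symbols = pd.Series(self.symbols, index=self.values.index, dtype=object)
        missing = [s for s in self.values.columns if s not in self.sample_groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if self.detection_pvals is not None:
            dp = self.detection_pvals
            if dp.shape != self.values.shape or not dp.index.equals(self.values.index):
                raise ValueError("detection_pvals must be aligned with values")
            dparr = dp.to_numpy(dtype=float)
            if ((dparr < 0) | (dparr > 1)).any():
                raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        """Sample names belonging to ``group`` (column order preserved)."""
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``probe_ids`` (order as given)."""
        return ExpressionMatrix(
            values=self.values.loc[probe_ids],
            symbols=self.symbols.loc[probe_ids],
            sample_groups=dict(self.sample_groups),
            detection_pvals=None if self.detection_pvals is None else self.detection_pvals.loc[probe_ids],
            log_scale=self.log_scale,
        )

    def copy_with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy with ``values`` replaced (annotation shared)."""
        return ExpressionMatrix(
            values=values,
            symbols=self.symbols,
            sample_groups=dict(self.sample_groups),
            detection_pvals=self.detection_pvals,
            log_scale=self.log_scale,
        )
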