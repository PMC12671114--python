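"""Compositional transforms feeding every downstream analysis.

Relative abundances live on the simplex; analyses that assume Euclidean
geometry need a transform first.  Two are used here: the centered log-ratio
(clr), which maps each sample to log(proportion / geometric mean) after a
pseudocount, and the square-root transform followed by per-feature
autoscaling (mean 0, unit variance), the input convention for the PCA-based
cohort-angle analysis.

Each output carries a ``transform_tag`` so downstream stages can refuse the
wrong transform: angles require ``sqrt_autoscaled``; associations and
redundancy analysis require ``clr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AbundanceTable, GutcompassError

__all__ = ["TransformedMatrix", "clr_transform", "sqrt_autoscale", "autoscale_frame"]


@dataclass
class TransformedMatrix:
    """A samples x features real matrix with transform provenance."""

    data: pd.DataFrame
    transform_tag: str  # one of {relabund, sqrt, sqrt_autoscaled, clr}
    pseudocount: float | None = None
    constant_features: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_labels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def require_tag(self, tag: str) -> "TransformedMatrix":
        if self.transform_tag != tag:
            raise GutcompassError(
                f"expected a '{tag}' matrix, got '{self.transform_tag}'"
            )
        return self


def default_pseudocount(proportions: np.ndarray) -> float:
    """Half the smallest nonzero proportion in the whole table."""
    nonzero = proportions[proportions > 0]
    if nonzero.size == 0:
        raise GutcompassError("table has no nonzero entries")
    return float(nonzero.min() / 2.0)


def clr_transform(table: AbundanceTable, pseudocount: float | None = None) -> TransformedMatrix:
    """Centered log-ratio transform of per-sample proportions.

    Per sample: add ``pseudocount`` to the proportions, re-close, then take
    ln(x_i / geometric mean(x)).  Rows of the result sum to 0.  The default
    pseudocount is half the smallest nonzero proportion in the table, a
    scale-aware convention for tables whose zeros are detection limits.
    """
    props = table.proportions().to_numpy()
    if (props < 0).any():
        raise GutcompassError("negative abundances cannot be clr-transformed")
    if pseudocount is None:
        pseudocount = default_pseudocount(props)
    if pseudocount <= 0:
        raise GutcompassError("pseudocount must be positive")
    x = props + pseudocount
    x = x / x.sum(axis=1, keepdims=True)
    logx = np.log(x)
    clr = logx - logx.mean(axis=1, keepdims=True)
    return TransformedMatrix(
        data=pd.DataFrame(clr, index=table.data.index, columns=table.data.columns),
        transform_tag="clr",
        pseudocount=pseudocount,
    )


def autoscale_frame(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Center each column and divide by its sample (n-1) standard deviation.

    Constant columns are set to all zeros and returned as flagged names.
    """
    vals = df.to_numpy(dtype=float)
    mean = vals.mean(axis=0, keepdims=True)
    sd = vals.std(axis=0, ddof=1, keepdims=True)
    constant = (sd[0] == 0) | ~np.isfinite(sd[0])
    sd_safe = np.where(constant, 1.0, sd)
    scaled = (vals - mean) / sd_safe
    scaled[:, constant] = 0.0
    flagged = [df.columns[i] for i in np.flatnonzero(constant)]
    return pd.DataFrame(scaled, index=df.index, columns=df.columns), flagged


def sqrt_autoscale(table: AbundanceTable) -> TransformedMatrix:
    """Element-wise square root of proportions, then per-feature autoscaling."""
    props = table.proportions()
    root = np.sqrt(props)
    scaled, flagged = autoscale_frame(root)
    return TransformedMatrix(
        data=scaled, transform_tag="sqrt_autoscaled", constant_features=flagged
    )
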