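"""Pre-processing of raw counts/abundances into the [0,1] range.

Two steps: a log2(x+1) transform (proportional rather than additive changes,
and taming extreme counts), then per-gene scaling by the row maximum so every
value lies in the range of the sigmoid output layer the autoencoder uses.
No library-size normalization or highly-variable-gene selection is performed:
the method deliberately uses all genes.
"""

from __future__ import annotations

import numpy as np

from .io import ExpressionMatrix

__all__ = ["log_transform", "row_max_scale", "preprocess", "all_zero_genes"]


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace every entry x by log2(x + 1); zeros stay zero."""
    if (m.values < 0).any():
        raise ValueError("log transform requires non-negative values")
    return ExpressionMatrix(list(m.genes), list(m.conditions), np.log2(m.values + 1.0))


def row_max_scale(m: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene's row by its own maximum.

    Every row with any signal attains max exactly 1; all-zero rows are left
    untouched (no division), so the output is always finite and in [0,1].
    """
    if (m.values < 0).any():
        raise ValueError("row-max scaling requires non-negative values")
    row_max = m.values.max(axis=1, keepdims=True)
    scaled = np.divide(
        m.values, row_max, out=np.zeros_like(m.values), where=row_max > 0
    )
    return ExpressionMatrix(list(m.genes), list(m.conditions), scaled)


def all_zero_genes(m: ExpressionMatrix) -> list[str]:
    """Genes with no signal in any condition; their pair scores are undefined
    downstream and such genes are excluded from pair scoring."""
    zero = ~m.values.any(axis=1)
    return [g for g, z in zip(m.genes, zero) if z]


def preprocess(m: ExpressionMatrix, log: bool = True) -> ExpressionMatrix:
    """Full pre-processing: optional log2(x+1), then row-max scaling.

    Set ``log=False`` for matrices that are already log-scaled (common for
    proteomics intensity exports).
    """
    return row_max_scale(log_transform(m) if log else m)
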