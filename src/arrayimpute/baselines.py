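"""Reference imputers used as controls in the benchmark.

``row_mean_impute`` is the classical fill-with-the-gene-average baseline
every model-based method is expected to beat.  ``oracle_impute`` writes
back the hidden truth; it is a validation control for the benchmark
machinery (it must always score NRMSE 0 and rank first), never a method.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ValidationError
from .masking import MaskedDataset
from .matrix import ExpressionMatrix
from .results import ImputationResult


def row_mean_impute(m: ExpressionMatrix, cfg=None) -> ImputationResult:
    """Replace each missing entry with its gene's average observed value."""
    if not (~m.missing_mask).any(axis=1).all():
        raise ValidationError("row_mean: a gene has no observed entries")
    W = m.values.copy()
    miss = m.missing_mask
    if miss.any():
        row_means = np.nanmean(m.values, axis=1)
        W[miss] = np.broadcast_to(row_means[:, None], W.shape)[miss]
    return ImputationResult(imputed=m.with_values(W), algorithm="row_mean")


def oracle_impute(m: ExpressionMatrix, cfg=None, *,
                  masked: MaskedDataset | None = None) -> ImputationResult:
    """Fill masked entries with their true values (benchmark control only)."""
    if masked is None:
        raise ValidationError("oracle_impute needs the MaskedDataset carrying the truth")
    W = m.values.copy()
    for (i, j) in masked.positions:
        W[i, j] = masked.complete.values[i, j]
    miss = np.isnan(W)
    if miss.any():  # entries missing in the input but not tracked by the mask
        row_means = np.nanmean(W, axis=1)
        W[miss] = np.broadcast_to(row_means[:, None], W.shape)[miss]
    return ImputationResult(imputed=m.with_values(W), algorithm="oracle")
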