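"""Shared result container for all imputation algorithms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .exceptions import ValidationError
from .masking import MaskedDataset
from .matrix import ExpressionMatrix


@dataclass
class ImputationResult:
    """A completed matrix plus provenance and convergence diagnostics.

    Invariants enforced at construction: the imputed matrix contains no
    missing and no non-finite values.  Observed-entry preservation is
    guaranteed structurally by the imputers (they only ever write into
    originally-missing slots) and re-checked by :func:`check_preserves`.
    """

    imputed: ExpressionMatrix
    algorithm: str
    params: dict[str, Any] = field(default_factory=dict)
    n_iterations: int = 0
    converged: bool = True
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.imputed.values).all():
            raise ValidationError(
                f"{self.algorithm}: imputed matrix contains missing/non-finite entries"
            )

    def y_guess(self, masked: MaskedDataset) -> np.ndarray:
        """Imputed values at the masked canonical positions."""
        if not masked.positions:
            return np.empty(0)
        idx = np.array(masked.positions)
        return self.imputed.values[idx[:, 0], idx[:, 1]].copy()


def relative_change(old: np.ndarray, new: np.ndarray) -> float:
    """Norm-relative change of the imputed vector between two sweeps.

    ||new - old||_2 / max(||old||_2, 1e-12): robust to individual entries
    near zero, which dominate a per-entry relative criterion on
    log-ratio data.
    """
    old = np.asarray(old, dtype=float).ravel()
    new = np.asarray(new, dtype=float).ravel()
    return float(np.linalg.norm(new - old) / max(np.linalg.norm(old), 1e-12))


def check_preserves(result: ImputationResult, original: ExpressionMatrix) -> bool:
    """True iff the result agrees exactly with the input at observed entries."""
    obs = ~original.missing_mask
    return bool(np.array_equal(result.imputed.values[obs], original.values[obs]))
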