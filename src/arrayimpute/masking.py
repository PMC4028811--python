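"""Missing-completely-at-random masking of complete matrices.

The benchmark protocol starts from a complete matrix, hides a known
fraction of entries uniformly at random, and keeps the hidden truth
(``y_answer``) so imputed guesses can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import MaskingError, ParameterError, ValidationError
from .matrix import ExpressionMatrix

MAX_RETRIES = 1000


def derive_seed(master_seed: int, *keys) -> int:
    """A stable, collision-resistant child seed below 2**31.

    Mixes the master seed with integer keys (round number, rate in parts
    per million, a role tag hashed to an int ...) through numpy's
    SeedSequence so every (round, rate, role) combination gets an
    independent, reproducible stream.
    """
    ints = []
    for k in keys:
        if isinstance(k, float):
            ints.append(int(round(k * 1_000_000)))
        elif isinstance(k, str):
            ints.append(int.from_bytes(k.encode()[:8].ljust(8, b"\0"), "little") % (2**31))
        else:
            ints.append(int(k))
    ss = np.random.SeedSequence([int(master_seed)] + ints)
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)


@dataclass
class MaskedDataset:
    """A complete matrix plus the positions hidden from the imputers.

    ``positions`` are (gene index, sample index) pairs in canonical
    row-major order; ``y_answer[i]`` is the true value at ``positions[i]``.
    """

    complete: ExpressionMatrix
    positions: list[tuple[int, int]]
    rate: float
    seed: int

    def __post_init__(self) -> None:
        if not self.complete.is_complete:
            raise ValidationError("MaskedDataset.complete must have no missing entries")
        G, S = self.complete.shape
        seen = set()
        for (i, j) in self.positions:
            if not (0 <= i < G and 0 <= j < S):
                raise ValidationError(f"position {(i, j)} out of bounds for {G}x{S}")
            if (i, j) in seen:
                raise ValidationError(f"duplicate masked position {(i, j)}")
            seen.add((i, j))
        self.positions = sorted(self.positions)  # row-major canonical order

    @property
    def y_answer(self) -> np.ndarray:
        """True values at the masked positions, canonical order."""
        if not self.positions:
            return np.empty(0)
        idx = np.array(self.positions)
        return self.complete.values[idx[:, 0], idx[:, 1]].copy()

    @property
    def n_masked(self) -> int:
        return len(self.positions)


def inject_missing(complete: ExpressionMatrix, rate: float, seed: int) -> MaskedDataset:
    """Hide ``round(rate * G * S)`` entries uniformly at random.

    Draws are without replacement and re-drawn (up to a bounded number of
    retries) if any gene row or sample column would end up entirely
    missing — several imputers are undefined in that case.  Identical
    (matrix, rate, seed) always yields identical positions.
    """
    if not (0.0 <= rate <= 0.5):
        raise ParameterError(f"missing rate must be in [0, 0.5], got {rate}")
    if not complete.is_complete:
        raise ValidationError("inject_missing requires a complete matrix")
    G, S = complete.shape
    n = int(round(rate * G * S))
    if n == 0:
        return MaskedDataset(complete=complete, positions=[], rate=rate, seed=seed)

    rng = np.random.default_rng(seed)
    for _ in range(MAX_RETRIES):
        flat = rng.choice(G * S, size=n, replace=False)
        rows, cols = np.unravel_index(flat, (G, S))
        row_counts = np.bincount(rows, minlength=G)
        col_counts = np.bincount(cols, minlength=S)
        if (row_counts < S).all() and (col_counts < G).all():
            positions = sorted(zip(rows.tolist(), cols.tolist()))
            return MaskedDataset(complete=complete, positions=positions, rate=rate, seed=seed)
    raise MaskingError(
        f"could not draw {n} positions without a fully-masked row/column "
        f"after {MAX_RETRIES} retries ({G}x{S} at rate {rate})"
    )


def apply_mask(masked: MaskedDataset) -> ExpressionMatrix:
    """The matrix the imputers see: complete values with positions blanked."""
    out = masked.complete.copy()
    for (i, j) in masked.positions:
        out.values[i, j] = np.nan
    return out
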