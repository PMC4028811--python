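"""Synthetic expression matrices with controlled structure.

These generators emulate the structural features of published two-colour
microarray compendia — low-rank gene-gene correlation, smooth cell-cycle
style time courses, cluster structure, and two-group differential
expression — at desk scale, so every imputer and index can be exercised
without any external download.  Ground truth (factors, labels, DE sets)
is always returned alongside the matrix.  All generators are
deterministic given their seed and return complete matrices, ready for
missing-value injection.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError
from .matrix import ExpressionMatrix


def _ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def make_lowrank(n_genes: int, n_samples: int, rank: int, noise_sd: float = 0.0,
                 seed: int = 0, dataset_type: str = "non_time_series"
                 ) -> tuple[ExpressionMatrix, tuple[np.ndarray, np.ndarray]]:
    """values = U V^T + noise with standard-normal factors.

    noise_sd = 0 gives exactly rank-``rank`` data.  Returns the factors
    as ground truth.
    """
    if not (1 <= rank <= min(n_genes, n_samples)):
        raise ParameterError(f"rank must be in [1, {min(n_genes, n_samples)}], got {rank}")
    rng = np.random.default_rng(seed)
    U = rng.standard_normal((n_genes, rank))
    V = rng.standard_normal((n_samples, rank))
    X = U @ V.T
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
    m = ExpressionMatrix(gene_ids=_ids("g", n_genes), sample_ids=_ids("s", n_samples),
                         values=X, dataset_type=dataset_type)
    return m, (U, V)


def make_timeseries(n_genes: int, n_samples: int, n_phase_groups: int = 4,
                    period: float | None = None, noise_sd: float = 0.1,
                    seed: int = 0) -> ExpressionMatrix:
    """Cell-cycle-like smooth profiles with shared phase groups.

    Each gene is amplitude * sin(2*pi*t/period + phase) + noise, with the
    phase drawn from a small set of shared values so genes within a phase
    group are strongly correlated.  Default period is one full cycle over
    the time course.
    """
    if n_samples < 4:
        raise ParameterError("time-series fixtures need at least 4 samples")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples, dtype=float)
    if period is None:
        period = float(n_samples)
    phases = rng.uniform(0, 2 * np.pi, size=n_phase_groups)
    group = rng.integers(0, n_phase_groups, size=n_genes)
    amplitude = rng.uniform(0.5, 2.0, size=n_genes)
    X = amplitude[:, None] * np.sin(2 * np.pi * t[None, :] / period + phases[group][:, None])
    if noise_sd > 0:
        X = X + noise_sd * rng.standard_normal(X.shape)
    return ExpressionMatrix(gene_ids=_ids("g", n_genes), sample_ids=_ids("s", n_samples),
                            values=X, dataset_type="time_series")


def make_twogroup(n_genes: int, n_samples: int, n_de: int, effect_size: float,
                  noise_sd: float = 1.0, seed: int = 0
                  ) -> tuple[ExpressionMatrix, dict[str, str], set[str]]:
    """Two-class design with planted differential expression.

    The first ``n_de`` genes get a mean shift of effect_size * noise_sd
    in group 2; samples split in half.  Returns (matrix, labels, true DE
    gene set).
    """
    if n_samples % 2 != 0:
        raise ParameterError("n_samples must be even")
    if n_de > n_genes:
        raise ParameterError("n_de cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    X = noise_sd * rng.standard_normal((n_genes, n_samples))
    half = n_samples // 2
    X[:n_de, half:] += effect_size * noise_sd
    gene_ids = _ids("g", n_genes)
    sample_ids = _ids("s", n_samples)
    labels = {s: ("group1" if j < half else "group2") for j, s in enumerate(sample_ids)}
    m = ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, values=X,
                         dataset_type="non_time_series", class_labels=labels)
    return m, labels, set(gene_ids[:n_de])


def make_clustered(n_genes: int, n_samples: int, n_clusters: int,
                   separation: float = 10.0, noise_sd: float = 1.0, seed: int = 0
                   ) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Gene clusters around well-separated centres; round-robin assignment.

    Centres are re-drawn until every pairwise distance is at least
    separation * noise_sd, so with a generous separation k-means recovery
    of the generating partition is forced.
    """
    if n_clusters > n_genes:
        raise ParameterError("n_clusters cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    scale = max(separation * noise_sd, 1.0)
    for _ in range(1000):
        centers = rng.standard_normal((n_clusters, n_samples)) * scale
        if n_clusters == 1:
            break
        d = np.sqrt(((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() >= separation * noise_sd:
            break
    assignment = np.arange(n_genes) % n_clusters
    X = centers[assignment] + noise_sd * rng.standard_normal((n_genes, n_samples))
    gene_ids = _ids("g", n_genes)
    m = ExpressionMatrix(gene_ids=gene_ids, sample_ids=_ids("s", n_samples), values=X)
    return m, {g: int(c) + 1 for g, c in zip(gene_ids, assignment)}
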