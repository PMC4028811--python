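"""K-nearest-neighbour imputation: plain (KNN), sequential (SKNN), iterative (IKNN).

All three share one per-entry estimator: the k candidate genes closest in
(pairwise-deletion) Euclidean distance contribute their value at the
missing column through inverse-distance weights, so every estimate is a
convex combination of candidate values.  Distances over partially-shared
columns are scaled to a per-column root-mean-square so candidates with few
shared columns are comparable to candidates with many.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError
from .matrix import ExpressionMatrix
from .results import ImputationResult, relative_change

logger = logging.getLogger(__name__)


@dataclass
class NeighborConfig:
    """Settings for the KNN family.

    k defaults to 15; microarray practice uses k = 10 for time-series
    data under the sequential variant (pass explicitly or use the
    algorithm registry, which applies the dataset-type default).
    """

    k: int = 15
    distance: str = "euclidean"
    weighting: str = "inverse_distance"
    tol: float = 1e-6
    max_iter: int = 100
    eps: float = 1e-12
    trace: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.distance != "euclidean" or self.weighting != "inverse_distance":
            raise ValidationError("only euclidean distance / inverse-distance weights supported")


def _check_preconditions(m: ExpressionMatrix) -> None:
    obs = ~m.missing_mask
    if not obs.any(axis=1).all():
        bad = [m.gene_ids[i] for i in np.flatnonzero(~obs.any(axis=1))[:3]]
        raise ValidationError(f"gene(s) with no observed entries: {bad}")
    if not obs.any(axis=0).all():
        bad = [m.sample_ids[j] for j in np.flatnonzero(~obs.any(axis=0))[:3]]
        raise ValidationError(f"sample(s) with no observed entries: {bad}")


def _scaled_distances(X: np.ndarray, obs: np.ndarray, g: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column RMS distance from gene g to every gene, over columns observed in both.

    Returns (distances, n_shared); distance is inf where nothing is shared.
    """
    shared = obs & obs[g]
    diff = X - X[g]
    sq = np.where(shared, diff * diff, 0.0)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.sqrt(sq.sum(axis=1) / n_shared)
    d[n_shared == 0] = np.inf
    return d, n_shared


def _knn_estimate(d: np.ndarray, cand_idx: np.ndarray, col_values: np.ndarray,
                  k: int, eps: float) -> float | None:
    """Inverse-distance-weighted mean of the k nearest candidates' values.

    Exact matches (zero distance) short-circuit to the plain mean of the
    zero-distance candidates.  Returns None when no candidate exists.
    """
    if cand_idx.size == 0:
        return None
    dd = d[cand_idx]
    order = np.argsort(dd, kind="stable")[: min(k, cand_idx.size)]
    sel = cand_idx[order]
    dsel = d[sel]
    if dsel[0] == 0.0:
        zero = sel[dsel == 0.0]
        return float(np.mean(col_values[zero]))
    w = 1.0 / (dsel + eps)
    return float(np.sum(w * col_values[sel]) / np.sum(w))


def _identity_result(m: ExpressionMatrix, algorithm: str, cfg) -> ImputationResult:
    return ImputationResult(imputed=m.copy(), algorithm=algorithm,
                            params=asdict(cfg), n_iterations=0, converged=True)


def knn_impute(m: ExpressionMatrix, cfg: NeighborConfig | None = None) -> ImputationResult:
    """Plain KNN imputation against the originally observed entries only."""
    cfg = cfg or NeighborConfig()
    if m.is_complete:
        return _identity_result(m, "knn", cfg)
    _check_preconditions(m)
    X = m.values
    obs = ~m.missing_mask
    W = X.copy()
    fallbacks = 0
    for g in np.flatnonzero(m.missing_mask.any(axis=1)):
        d, n_shared = _scaled_distances(X, obs, g)
        valid = (n_shared > 0)
        valid[g] = False
        for s in np.flatnonzero(m.missing_mask[g]):
            cand_idx = np.flatnonzero(valid & obs[:, s])
            est = _knn_estimate(d, cand_idx, X[:, s], cfg.k, cfg.eps)
            if est is None:
                est = float(np.nanmean(X[g]))
                fallbacks += 1
                logger.warning("knn: no candidate for (%s, %s); row-average fallback",
                               m.gene_ids[g], m.sample_ids[s])
            W[g, s] = est
    return ImputationResult(imputed=m.with_values(W), algorithm="knn", params=asdict(cfg),
                            n_iterations=1, converged=True,
                            diagnostics={"fallbacks": fallbacks})


def sknn_impute(m: ExpressionMatrix, cfg: NeighborConfig | None = None) -> ImputationResult:
    """Sequential KNN: genes imputed in order of ascending missing count.

    The candidate pool starts with the originally complete genes; each
    imputed gene immediately joins the pool and may serve as a neighbour
    for genes imputed later.
    """
    cfg = cfg or NeighborConfig()
    if m.is_complete:
        return _identity_result(m, "sknn", cfg)
    _check_preconditions(m)
    X = m.values
    obs = ~m.missing_mask
    W = X.copy()
    miss_count = m.missing_mask.sum(axis=1)
    targets = np.flatnonzero(miss_count > 0)
    targets = targets[np.argsort(miss_count[targets], kind="stable")]
    pool = ~m.missing_mask.any(axis=1)
    fallbacks = 0
    pool_trace: dict[str, list[str]] = {}
    for g in targets:
        if cfg.trace:
            pool_trace[m.gene_ids[g]] = [m.gene_ids[i] for i in np.flatnonzero(pool)]
        og = obs[g]
        cand_idx = np.flatnonzero(pool)
        if cand_idx.size:
            diff = W[cand_idx][:, og] - X[g, og]
            d_sub = np.sqrt(np.mean(diff * diff, axis=1))
            d = np.full(X.shape[0], np.inf)
            d[cand_idx] = d_sub
        else:
            d = np.full(X.shape[0], np.inf)
        for s in np.flatnonzero(m.missing_mask[g]):
            est = _knn_estimate(d, cand_idx, W[:, s], cfg.k, cfg.eps)
            if est is None:
                est = float(np.nanmean(X[g]))
                fallbacks += 1
                logger.warning("sknn: empty candidate pool for %s; row-average fallback",
                               m.gene_ids[g])
            W[g, s] = est
        pool[g] = True
    diagnostics = {"fallbacks": fallbacks,
                   "order": [m.gene_ids[g] for g in targets]}
    if cfg.trace:
        diagnostics["candidate_pool"] = pool_trace
    return ImputationResult(imputed=m.with_values(W), algorithm="sknn", params=asdict(cfg),
                            n_iterations=1, converged=True, diagnostics=diagnostics)


def iknn_impute(m: ExpressionMatrix, cfg: NeighborConfig | None = None) -> ImputationResult:
    """Iterative KNN: row-average start, then repeated KNN passes.

    Each pass recomputes every originally-missing entry by KNN against the
    current fully complete matrix, with distances over all columns, until
    the norm-relative change of the imputed vector drops below tol.
    """
    cfg = cfg or NeighborConfig()
    if m.is_complete:
        return _identity_result(m, "iknn", cfg)
    _check_preconditions(m)
    S = m.n_samples
    miss = m.missing_mask
    W = m.values.copy()
    row_means = np.nanmean(m.values, axis=1)
    W[miss] = np.broadcast_to(row_means[:, None], W.shape)[miss]
    targets = np.flatnonzero(miss.any(axis=1))
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        D = cdist(W, W) / np.sqrt(S)
        new_W = W.copy()
        for g in targets:
            d = D[g].copy()
            d[g] = np.inf
            cand_idx = np.argsort(d, kind="stable")[: cfg.k]
            for s in np.flatnonzero(miss[g]):
                new_W[g, s] = _knn_estimate(d, cand_idx, W[:, s], cfg.k, cfg.eps)
        rel = relative_change(W[miss], new_W[miss])
        W = new_W
        if rel < cfg.tol:
            converged = True
            break
    return ImputationResult(imputed=m.with_values(W), algorithm="iknn", params=asdict(cfg),
                            n_iterations=it, converged=converged)
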