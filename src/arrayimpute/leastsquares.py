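"""Local least-squares imputation: LLS, SLLS, ILLS, and the adaptive LS blend.

For a target gene with observed columns O and missing columns M, the LLS
estimator regresses the target on its k most similar genes over O and
extrapolates the fitted combination to M.  Similarity is absolute Pearson
correlation by default.  The sequential variant (SLLS) imputes genes in
order of ascending missing count, letting already-imputed genes serve as
regressors; the iterative variant (ILLS) repeats whole-matrix passes from
a row-average start until the imputed entries stabilise.  The adaptive
method (LSA, historically published as "LS") blends a gene-wise and an array-wise
univariate-regression estimate with a weight fitted on held-out probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace

import numpy as np

from .exceptions import ParameterError, ValidationError
from .masking import derive_seed
from .matrix import ExpressionMatrix
from .results import ImputationResult, relative_change

logger = logging.getLogger(__name__)

DEFAULT_K_CANDIDATES = (5, 10, 15, 20, 50, 100, 150, 200)


@dataclass
class LeastSquaresConfig:
    """Settings for the least-squares family.

    ``k`` may be the string ``"auto"``, in which case the neighbour count
    is chosen by masking a small probe fraction of observed entries and
    minimising the probe reconstruction error over ``k_candidates``.
    """

    k: int | str = 15
    similarity: str = "pearson_abs"
    ridge: float = 1e-8
    tol: float = 1e-6
    max_iter: int = 100
    probe_fraction: float = 0.01
    k_candidates: tuple[int, ...] = DEFAULT_K_CANDIDATES
    lsa_neighbors: int = 10
    seed: int = 0
    trace: bool = False

    def __post_init__(self) -> None:
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValidationError(f"k must be a positive int or 'auto', got {self.k!r}")
        elif self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")
        if self.similarity not in ("pearson_abs", "euclidean"):
            raise ValidationError(f"unknown similarity {self.similarity!r}")
        if self.ridge < 0:
            raise ValidationError("ridge must be nonnegative")


def _check_preconditions(m: ExpressionMatrix) -> None:
    obs = ~m.missing_mask
    if (obs.sum(axis=1) < 2).any():
        bad = [m.gene_ids[i] for i in np.flatnonzero(obs.sum(axis=1) < 2)[:3]]
        raise ValidationError(f"gene(s) with fewer than 2 observed entries: {bad}")


def _row_average_fill(m: ExpressionMatrix) -> np.ndarray:
    W = m.values.copy()
    miss = m.missing_mask
    if miss.any():
        row_means = np.nanmean(m.values, axis=1)
        W[miss] = np.broadcast_to(row_means[:, None], W.shape)[miss]
    return W


def _similarity_to_target(sub: np.ndarray, target: np.ndarray, kind: str) -> np.ndarray:
    """Similarity of every row of ``sub`` to ``target`` (higher = more similar)."""
    if kind == "euclidean":
        d = np.sqrt(np.mean((sub - target) ** 2, axis=1))
        return -d
    tc = target - target.mean()
    nt = np.sqrt(np.sum(tc * tc))
    rowc = sub - sub.mean(axis=1, keepdims=True)
    nr = np.sqrt(np.sum(rowc * rowc, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rowc @ tc) / (nr * nt)
    r[~np.isfinite(r)] = 0.0
    return np.abs(r)


def _solve_lls(A: np.ndarray, b: np.ndarray, B: np.ndarray, ridge: float) -> np.ndarray | None:
    """x = argmin ||A^T x - b||^2 (ridge-stabilised); returns B^T x, or None if degenerate."""
    if not np.any(A):
        return None
    if ridge == 0.0:
        # min-norm least squares == pseudo-inverse solution
        x = np.linalg.lstsq(A.T, b, rcond=None)[0]
        return B.T @ x
    k = A.shape[0]
    M = A @ A.T + ridge * np.eye(k)
    try:
        x = np.linalg.solve(M, A @ b)
    except np.linalg.LinAlgError:
        x = np.linalg.lstsq(A.T, b, rcond=None)[0]
    return B.T @ x


def _lls_estimate_gene(W_cand: np.ndarray, sim_matrix_row: np.ndarray,
                       cand_idx: np.ndarray, O: np.ndarray, M: np.ndarray,
                       b: np.ndarray, k: int, ridge: float) -> np.ndarray | None:
    """Top-k-neighbour least-squares estimate for one gene; None if degenerate."""
    if cand_idx.size == 0:
        return None
    order = np.argsort(-sim_matrix_row[cand_idx], kind="stable")
    sel = cand_idx[order[: min(k, cand_idx.size)]]
    A = W_cand[sel][:, O]
    B = W_cand[sel][:, M]
    return _solve_lls(A, b, B, ridge)


def _resolve_k(m: ExpressionMatrix, cfg: LeastSquaresConfig) -> tuple[int, LeastSquaresConfig]:
    if cfg.k == "auto":
        k = estimate_k_auto(m, cfg, lls_impute)
        return k, replace(cfg, k=k)
    return int(cfg.k), cfg


def lls_impute(m: ExpressionMatrix, cfg: LeastSquaresConfig | None = None) -> ImputationResult:
    """Local least squares against the originally observed data."""
    cfg = cfg or LeastSquaresConfig()
    if m.is_complete:
        return ImputationResult(imputed=m.copy(), algorithm="lls", params=asdict(cfg))
    _check_preconditions(m)
    k, cfg = _resolve_k(m, cfg)
    X = m.values
    obs = ~m.missing_mask
    Xfill = _row_average_fill(m)
    W = X.copy()
    fallbacks = relaxed = 0
    for g in np.flatnonzero(m.missing_mask.any(axis=1)):
        O = obs[g]
        M = m.missing_mask[g]
        need = O | M  # columns the regression touches
        eligible = obs[:, need].all(axis=1)
        eligible[g] = False
        if eligible.sum() < k:
            # too few fully-observed candidates: admit row-average-filled ones
            relaxed += 1
            eligible = np.ones(X.shape[0], dtype=bool)
            eligible[g] = False
        cand_idx = np.flatnonzero(eligible)
        if cand_idx.size < k:
            logger.warning("lls: only %d candidates for %s (k=%d); shrinking",
                           cand_idx.size, m.gene_ids[g], k)
        sim = _similarity_to_target(Xfill[:, O], Xfill[g, O], cfg.similarity)
        est = _lls_estimate_gene(Xfill, sim, cand_idx, O, M, X[g, O], k, cfg.ridge)
        if est is None:
            est = np.full(int(M.sum()), np.nanmean(X[g]))
            fallbacks += 1
            logger.warning("lls: degenerate design for %s; row-average fallback", m.gene_ids[g])
        W[g, M] = est
    return ImputationResult(imputed=m.with_values(W), algorithm="lls", params=asdict(cfg),
                            n_iterations=1, converged=True,
                            diagnostics={"fallbacks": fallbacks, "relaxed": relaxed})


def slls_impute(m: ExpressionMatrix, cfg: LeastSquaresConfig | None = None) -> ImputationResult:
    """Sequential LLS: ascending-missing-count order, imputed genes re-enter the pool."""
    cfg = cfg or LeastSquaresConfig()
    if m.is_complete:
        return ImputationResult(imputed=m.copy(), algorithm="slls", params=asdict(cfg))
    _check_preconditions(m)
    k, cfg = _resolve_k(m, cfg)
    X = m.values
    obs = ~m.missing_mask
    W = _row_average_fill(m)  # pool rows are exact; target rows re-imputed below
    out = X.copy()
    miss_count = m.missing_mask.sum(axis=1)
    targets = np.flatnonzero(miss_count > 0)
    targets = targets[np.argsort(miss_count[targets], kind="stable")]
    pool = ~m.missing_mask.any(axis=1)
    fallbacks = 0
    pool_trace: dict[str, list[str]] = {}
    for g in targets:
        if cfg.trace:
            pool_trace[m.gene_ids[g]] = [m.gene_ids[i] for i in np.flatnonzero(pool)]
        O = obs[g]
        M = m.missing_mask[g]
        cand_idx = np.flatnonzero(pool)
        sim = _similarity_to_target(W[:, O], X[g, O], cfg.similarity)
        est = _lls_estimate_gene(W, sim, cand_idx, O, M, X[g, O], k, cfg.ridge)
        if est is None:
            est = np.full(int(M.sum()), np.nanmean(X[g]))
            fallbacks += 1
            logger.warning("slls: no usable candidates for %s; row-average fallback",
                           m.gene_ids[g])
        out[g, M] = est
        W[g] = out[g]
        pool[g] = True
    diagnostics = {"fallbacks": fallbacks, "order": [m.gene_ids[g] for g in targets]}
    if cfg.trace:
        diagnostics["candidate_pool"] = pool_trace
    return ImputationResult(imputed=m.with_values(out), algorithm="slls", params=asdict(cfg),
                            n_iterations=1, converged=True, diagnostics=diagnostics)


def ills_impute(m: ExpressionMatrix, cfg: LeastSquaresConfig | None = None) -> ImputationResult:
    """Iterative LLS: row-average start, whole-matrix LLS passes until stable.

    Within a pass, similarity is computed over all columns of the current
    completed matrix; each target's regression is still fitted on its
    originally observed columns only.
    """
    cfg = cfg or LeastSquaresConfig()
    if m.is_complete:
        return ImputationResult(imputed=m.copy(), algorithm="ills", params=asdict(cfg),
                                n_iterations=0, converged=True)
    _check_preconditions(m)
    k, cfg = _resolve_k(m, cfg)
    X = m.values
    obs = ~m.missing_mask
    miss = m.missing_mask
    W = _row_average_fill(m)
    targets = np.flatnonzero(miss.any(axis=1))
    all_idx = np.arange(X.shape[0])
    converged = False
    it = 0
    fallbacks = 0
    for it in range(1, cfg.max_iter + 1):
        new_W = W.copy()
        for g in targets:
            O = obs[g]
            M = miss[g]
            cand_idx = all_idx[all_idx != g]
            sim = _similarity_to_target(W, W[g], cfg.similarity)  # all columns
            est = _lls_estimate_gene(W, sim, cand_idx, O, M, X[g, O], k, cfg.ridge)
            if est is None:
                est = np.full(int(M.sum()), np.nanmean(X[g]))
                fallbacks += 1
            new_W[g, M] = est
        rel = relative_change(W[miss], new_W[miss])
        W = new_W
        if rel < cfg.tol:
            converged = True
            break
    return ImputationResult(imputed=m.with_values(W), algorithm="ills", params=asdict(cfg),
                            n_iterations=it, converged=converged,
                            diagnostics={"fallbacks": fallbacks})


# ---------------------------------------------------------------------------
# Adaptive least squares (the method historically published as "LS")
# ---------------------------------------------------------------------------

def _pairwise_regression_stats(X: np.ndarray, obs: np.ndarray, g: int):
    """Per-candidate Pearson r, slope and intercept of target g on each gene.

    Statistics use the columns observed in both rows (pairwise deletion);
    candidates with <2 shared columns or zero variance get r = NaN.
    """
    shared = obs & obs[g]
    n_sh = shared.sum(axis=1)
    Xs = np.where(shared, X, 0.0)
    tg = np.where(shared, X[g], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mc = Xs.sum(axis=1) / n_sh
        mg = tg.sum(axis=1) / n_sh
        dc = np.where(shared, X - mc[:, None], 0.0)
        dg = np.where(shared, X[g] - mg[:, None], 0.0)
        cov = (dc * dg).sum(axis=1) / n_sh
        var_c = (dc * dc).sum(axis=1) / n_sh
        var_g = (dg * dg).sum(axis=1) / n_sh
        r = cov / np.sqrt(var_c * var_g)
        slope = cov / var_c
    intercept = mg - slope * mc
    bad = (n_sh < 2) | ~np.isfinite(r)
    r[bad] = np.nan
    slope[bad] = np.nan
    intercept[bad] = np.nan
    return r, slope, intercept


def _lsa_route(X: np.ndarray, obs: np.ndarray, entries: list[tuple[int, int]],
               n_neighbors: int) -> np.ndarray:
    """Correlation-weighted univariate-regression estimates for ``entries``.

    ``entries`` are (row, col) pairs in the orientation of ``X``; call with
    transposed inputs for the array-wise route.
    """
    est = np.empty(len(entries))
    by_row: dict[int, list[int]] = {}
    for i, (g, s) in enumerate(entries):
        by_row.setdefault(g, []).append(i)
    for g, idxs in by_row.items():
        r, slope, intercept = _pairwise_regression_stats(X, obs, g)
        r[g] = np.nan
        usable = np.isfinite(r)
        w_all = (r**2 / (1.0 - r**2 + 1e-6)) ** 2
        for i in idxs:
            s = entries[i][1]
            cand = np.flatnonzero(usable & obs[:, s])
            if cand.size == 0:
                est[i] = np.nanmean(np.where(obs[g], X[g], np.nan))
                logger.warning("lsa: no usable candidate for entry (%d, %d); row-average", g, s)
                continue
            order = np.argsort(-np.abs(r[cand]), kind="stable")
            sel = cand[order[: min(n_neighbors, cand.size)]]
            preds = intercept[sel] + slope[sel] * X[sel, s]
            w = w_all[sel]
            if w.sum() <= 0:
                est[i] = float(np.mean(preds))
            else:
                est[i] = float(np.sum(w * preds) / np.sum(w))
    return est


def _probe_positions(obs: np.ndarray, frac: float, rng: np.random.Generator
                     ) -> list[tuple[int, int]]:
    """Seeded probe entries among the observed ones, keeping >=2 observed per row."""
    rows, cols = np.nonzero(obs)
    n_obs = rows.size
    n_probe = max(1, int(round(frac * n_obs)))
    row_obs = obs.sum(axis=1)
    for _ in range(100):
        pick = rng.choice(n_obs, size=min(n_probe, n_obs - 1), replace=False)
        loss = np.bincount(rows[pick], minlength=obs.shape[0])
        if ((row_obs - loss) >= 2).all():
            return list(zip(rows[pick].tolist(), cols[pick].tolist()))
    # fall back to probing only rows with plenty of observations
    rich = row_obs[rows] >= 4
    pick = rng.choice(np.flatnonzero(rich), size=min(n_probe, int(rich.sum())), replace=False)
    return list(zip(rows[pick].tolist(), cols[pick].tolist()))


def lsa_impute(m: ExpressionMatrix, cfg: LeastSquaresConfig | None = None) -> ImputationResult:
    """Adaptive least squares: blend of gene-wise and array-wise estimates.

    The mixing weight p (gene weight) is fitted once per matrix by hiding
    ``probe_fraction`` of the observed entries and minimising the blend's
    squared error over the grid p = 0, 0.05, ..., 1.
    """
    cfg = cfg or LeastSquaresConfig()
    if m.n_samples < 3:
        raise ValidationError("adaptive least squares requires at least 3 samples")
    if m.is_complete:
        return ImputationResult(imputed=m.copy(), algorithm="lsa", params=asdict(cfg))
    _check_preconditions(m)
    X = m.values
    obs = ~m.missing_mask
    entries = [tuple(p) for p in np.argwhere(m.missing_mask)]
    K = cfg.lsa_neighbors

    # fit the blend weight on held-out probes
    rng = np.random.default_rng(derive_seed(cfg.seed, "lsa_probe"))
    probes = _probe_positions(obs, cfg.probe_fraction, rng)
    obs_probe = obs.copy()
    pr = np.array(probes)
    obs_probe[pr[:, 0], pr[:, 1]] = False
    Xp = np.where(obs_probe, X, np.nan)
    truth = X[pr[:, 0], pr[:, 1]]
    gene_p = _lsa_route(Xp, obs_probe, probes, K)
    arr_p = _lsa_route(Xp.T, obs_probe.T, [(s, g) for (g, s) in probes],
                       min(K, m.n_samples - 1))
    grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
    errs = [float(np.sum((p * gene_p + (1 - p) * arr_p - truth) ** 2)) for p in grid]
    p_opt = float(grid[int(np.argmin(errs))])

    Xm = np.where(obs, X, np.nan)
    gene_est = _lsa_route(Xm, obs, entries, K)
    arr_est = _lsa_route(Xm.T, obs.T, [(s, g) for (g, s) in entries],
                         min(K, m.n_samples - 1))
    blend = p_opt * gene_est + (1 - p_opt) * arr_est
    W = X.copy()
    idx = np.array(entries)
    W[idx[:, 0], idx[:, 1]] = blend
    return ImputationResult(imputed=m.with_values(W), algorithm="lsa", params=asdict(cfg),
                            n_iterations=1, converged=True,
                            diagnostics={"p_gene": p_opt, "n_probes": len(probes)})


def estimate_k_auto(m: ExpressionMatrix, cfg: LeastSquaresConfig, impute_fn) -> int:
    """Probe-based automatic neighbour count.

    Hides ``probe_fraction`` of the observed entries (seeded), runs
    ``impute_fn`` at every candidate k, and returns the k with the lowest
    probe reconstruction error; ties go to the smallest k.
    """
    from .metrics import nrmse  # local import avoids a cycle at module load

    obs = ~m.missing_mask
    rng = np.random.default_rng(derive_seed(cfg.seed, "auto_k"))
    probes = _probe_positions(obs, cfg.probe_fraction, rng)
    pr = np.array(probes)
    Xp = m.values.copy()
    Xp[pr[:, 0], pr[:, 1]] = np.nan
    m_probe = m.with_values(Xp)
    truth = m.values[pr[:, 0], pr[:, 1]]

    G = m.n_genes
    cands = sorted({min(int(k), G - 1) for k in cfg.k_candidates if min(int(k), G - 1) >= 1})
    best_k, best_err = None, np.inf
    errors: dict[int, float] = {}
    for k in cands:
        try:
            res = impute_fn(m_probe, replace(cfg, k=k))
        except Exception as exc:  # a candidate failing is logged, not fatal
            logger.warning("estimate_k_auto: k=%d failed (%s)", k, exc)
            continue
        guess = res.imputed.values[pr[:, 0], pr[:, 1]]
        if truth.size >= 2 and np.var(truth) > 0:
            err = nrmse(guess, truth)
        else:
            err = float(np.sqrt(np.mean((guess - truth) ** 2)))
        errors[k] = err
        if err < best_err:
            best_k, best_err = k, err
    if best_k is None:
        raise ParameterError("automatic k estimation failed for every candidate")
    logger.info("estimate_k_auto: chose k=%d (probe errors %s)", best_k, errors)
    return best_k
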