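"""Global low-rank imputation: iterative SVD completion and Bayesian PCA.

SVD imputation alternates a truncated SVD of the current completed matrix
with per-gene regressions onto the leading right-singular vectors
("eigengenes"), refitting each incomplete gene on its observed columns
only.  Bayesian PCA treats genes as i.i.d. draws from a probabilistic PCA
model with an automatic-relevance-determination (ARD) prior on the
loading columns, so uninformative principal axes are shrunk away and the
effective dimensionality is selected automatically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np

from .exceptions import NumericalError, ParameterError, ValidationError
from .matrix import ExpressionMatrix
from .results import ImputationResult, relative_change

logger = logging.getLogger(__name__)


@dataclass
class GlobalConfig:
    """Settings for the global imputers.

    ``n_components``: integer, or ``"auto"``.  For the SVD imputer the
    fixed default is 15 (clamped to the matrix size) and ``auto`` selects
    ~20% of the available eigengenes, the classic recommendation for
    expression data.  For BPCA ``auto`` means min(G, S) - 1 with ARD
    pruning doing the actual selection.  ``max_iter`` defaults per
    algorithm (SVD 100, BPCA 200) when left as None.
    """

    n_components: int | str = 15
    tol: float = 1e-6
    max_iter: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.n_components, str):
            if self.n_components != "auto":
                raise ValidationError("n_components must be a positive int or 'auto'")
        elif self.n_components < 1:
            raise ParameterError(f"n_components must be >= 1, got {self.n_components}")


def _check_rows_cols(m: ExpressionMatrix) -> None:
    obs = ~m.missing_mask
    if not obs.any(axis=1).all():
        raise ValidationError("every gene needs at least one observed entry")
    if not obs.any(axis=0).all():
        raise ValidationError("every sample needs at least one observed entry")


def _row_average_fill(m: ExpressionMatrix) -> np.ndarray:
    W = m.values.copy()
    miss = m.missing_mask
    if miss.any():
        row_means = np.nanmean(m.values, axis=1)
        W[miss] = np.broadcast_to(row_means[:, None], W.shape)[miss]
    return W


def svd_impute(m: ExpressionMatrix, cfg: GlobalConfig | None = None) -> ImputationResult:
    """Iterative truncated-SVD completion with per-gene eigengene regression."""
    cfg = cfg or GlobalConfig()
    max_iter = cfg.max_iter if cfg.max_iter is not None else 100
    if m.is_complete:
        return ImputationResult(imputed=m.copy(), algorithm="svd", params=asdict(cfg),
                                n_iterations=0, converged=True)
    _check_rows_cols(m)
    G, S = m.shape
    if cfg.n_components == "auto":
        q = max(1, int(round(0.2 * min(G, S))))
    else:
        q = int(cfg.n_components)
        if q > min(G, S):
            logger.warning("svd: n_components=%d clamped to %d", q, min(G, S))
            q = min(G, S)

    miss = m.missing_mask
    obs = ~miss
    X = m.values
    W = _row_average_fill(m)
    targets = np.flatnonzero(miss.any(axis=1))
    converged = False
    it = 0
    objective: list[float] = []
    for it in range(1, max_iter + 1):
        _, _, Vt = np.linalg.svd(W, full_matrices=False)
        V = Vt[:q]  # q x S eigengenes
        new_W = W.copy()
        sse_obs = 0.0
        for g in range(G):
            O = obs[g]
            if miss[g].any():
                coef, *_ = np.linalg.lstsq(V[:, O].T, X[g, O], rcond=None)
                fit_obs = coef @ V[:, O]
                new_W[g, miss[g]] = coef @ V[:, miss[g]]
            else:
                coef, *_ = np.linalg.lstsq(V.T, X[g], rcond=None)
                fit_obs = coef @ V[:, O]
            sse_obs += float(np.sum((X[g, O] - fit_obs) ** 2))
        objective.append(sse_obs)
        rel = relative_change(W[miss], new_W[miss])
        W = new_W
        if rel < cfg.tol:
            converged = True
            break
    if not converged:
        logger.warning("svd: not converged after %d iterations; best iterate returned", it)
    return ImputationResult(imputed=m.with_values(W), algorithm="svd", params=asdict(cfg),
                            n_iterations=it, converged=converged,
                            diagnostics={"n_components": q, "objective": objective})


def bpca_impute(m: ExpressionMatrix, cfg: GlobalConfig | None = None) -> ImputationResult:
    """Bayesian PCA imputation with automatic relevance determination.

    Variational EM on the model y = W x + mu + eps, with x ~ N(0, I_q),
    isotropic noise precision tau, and per-column Gaussian priors
    w_j ~ N(0, alpha_j^{-1} I) whose precisions alpha_j are re-estimated
    each sweep — columns that do not help explain the data are driven to
    zero.  Missing entries are replaced by their posterior predictive
    mean given the current parameters.  Deterministic given seed.
    """
    cfg = cfg or GlobalConfig(n_components="auto")
    max_iter = cfg.max_iter if cfg.max_iter is not None else 200
    if m.is_complete:
        return ImputationResult(imputed=m.copy(), algorithm="bpca", params=asdict(cfg),
                                n_iterations=0, converged=True)
    if m.n_samples < 3:
        raise ValidationError("bpca requires at least 3 samples")
    _check_rows_cols(m)
    G, S = m.shape
    qmax = min(G, S) - 1
    if cfg.n_components == "auto":
        q = qmax
    else:
        q = min(int(cfg.n_components), qmax)

    miss = m.missing_mask
    obs = ~miss
    X = m.values
    Y = _row_average_fill(m)
    rng = np.random.default_rng(cfg.seed)

    mu = Y.mean(axis=0)
    Yc = Y - mu
    U, sv, Vt = np.linalg.svd(Yc, full_matrices=False)
    W = (Vt[:q].T * (sv[:q] / np.sqrt(G)))  # S x q loadings
    W = W + 1e-4 * rng.standard_normal(W.shape)  # seeded jitter to break ties
    resid_var = float(np.sum(sv[q:] ** 2) / (G * S)) + 1e-8
    tau = 1.0 / resid_var
    alpha = S / (np.sum(W * W, axis=0) + 1e-8)

    targets = np.flatnonzero(miss.any(axis=1))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: posterior of scores per gene; refill missing entries
        Xbar = np.empty((G, q))
        SigSum = np.zeros((q, q))
        trace_term = 0.0
        WtW = W.T @ W
        Sig_full = np.linalg.inv(np.eye(q) + tau * WtW)
        for g in range(G):
            o = obs[g]
            if o.all():
                Sig = Sig_full
                Wo = W
                yo = Y[g] - mu
            else:
                Wo = W[o]
                Sig = np.linalg.inv(np.eye(q) + tau * (Wo.T @ Wo))
                yo = Y[g, o] - mu[o]
            xb = tau * (Sig @ (Wo.T @ yo))
            Xbar[g] = xb
            SigSum += Sig
            trace_term += float(np.trace(W @ Sig @ W.T))
        # refill missing with posterior predictive mean
        old_fill = Y[miss].copy()
        for g in targets:
            mcols = miss[g]
            Y[g, mcols] = W[mcols] @ Xbar[g] + mu[mcols]
        rel = relative_change(old_fill, Y[miss])

        # M-step
        mu = (Y - Xbar @ W.T).mean(axis=0)
        Yc = Y - mu
        Sxx = Xbar.T @ Xbar + SigSum
        A = Sxx + (1.0 / tau) * np.diag(alpha)
        try:
            W = np.linalg.solve(A.T, (Yc.T @ Xbar).T).T
        except np.linalg.LinAlgError as exc:
            raise NumericalError("bpca: singular loading update",
                                 {"iteration": it, "alpha": alpha.tolist()}) from exc
        resid = Yc - Xbar @ W.T
        sse = float(np.sum(resid * resid)) + trace_term
        tau = (G * S) / max(sse, 1e-12)
        alpha = S / (np.sum(W * W, axis=0) + 1e-8)
        if not (np.isfinite(W).all() and np.isfinite(tau) and np.isfinite(alpha).all()):
            raise NumericalError("bpca: non-finite parameter update",
                                 {"iteration": it, "tau": float(tau)})
        if tau <= 0:
            raise NumericalError("bpca: noise precision collapsed", {"iteration": it})
        if rel < cfg.tol:
            converged = True
            break

    out = X.copy()
    out[miss] = Y[miss]
    col_norms = np.sqrt(np.sum(W * W, axis=0))
    return ImputationResult(imputed=m.with_values(out), algorithm="bpca", params=asdict(cfg),
                            n_iterations=it, converged=converged,
                            diagnostics={"n_components": q,
                                         "loading_column_norms": col_norms.tolist(),
                                         "effective_dim": int(np.sum(col_norms > 1e-3)),
                                         "tau": float(tau)})
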