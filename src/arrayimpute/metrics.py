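"""Performance indices for imputation benchmarking.

Three complementary views of imputation quality:

* NRMSE — sqrt(mean squared error / variance of the truth) over the
  masked entries; 0 is perfect, ~1 is no better than guessing the mean.
* CPP (cluster pair proportions) — the fraction of gene pairs co-clustered
  in the complete-data k-means partition that are still co-clustered after
  imputation; measures how much of the clustering structure survives.
* BLCI (biomarker list concordance index) — agreement between the
  differentially-expressed-gene lists called on complete vs imputed data:
  n(B_CD & B_ID)/n(B_CD) + n(~B_CD & ~B_ID)/n(~B_CD) - 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import comb
from sklearn.cluster import KMeans

from .exceptions import DesignError, MetricUndefinedError, ParameterError, ValidationError
from .masking import MaskedDataset, derive_seed
from .matrix import ExpressionMatrix
from .results import ImputationResult
from .sam import DEGeneSet, sam_de_genes

logger = logging.getLogger(__name__)


def nrmse(y_guess, y_answer) -> float:
    """Root mean squared error normalised by the variance of the truth.

    Uses population variance (divide by n).  Affine-invariant: applying
    the same a*v+b to both vectors leaves the value unchanged.
    """
    y_guess = np.asarray(y_guess, dtype=float)
    y_answer = np.asarray(y_answer, dtype=float)
    if y_guess.shape != y_answer.shape:
        raise ValidationError(f"length mismatch: {y_guess.shape} vs {y_answer.shape}")
    if y_answer.size < 2:
        raise MetricUndefinedError("need at least 2 masked values")
    if not (np.isfinite(y_guess).all() and np.isfinite(y_answer).all()):
        raise ValidationError("non-finite values in metric vectors")
    var = float(np.var(y_answer))
    if var == 0.0:
        raise MetricUndefinedError("variance of the true values is zero")
    return float(np.sqrt(np.mean((y_guess - y_answer) ** 2) / var))


@dataclass
class Clustering:
    """A gene partition: labels map gene_id -> cluster index in 1..n_clusters."""

    labels: dict[str, int]
    n_clusters: int
    seed: int
    inertia: float = 0.0


def kmeans_clusters(m: ExpressionMatrix, n_clusters: int = 10, seed: int = 0) -> Clustering:
    """k-means over gene rows (Euclidean, k-means++ seeding, 10 restarts)."""
    if not m.is_complete:
        raise ValidationError("kmeans_clusters requires a complete matrix")
    if m.n_genes < n_clusters:
        raise ParameterError(f"{m.n_genes} genes < {n_clusters} clusters")
    km = KMeans(n_clusters=n_clusters, init="k-means++", n_init=10, random_state=seed)
    lab = km.fit_predict(m.values)
    return Clustering(labels={g: int(c) + 1 for g, c in zip(m.gene_ids, lab)},
                      n_clusters=n_clusters, seed=seed, inertia=float(km.inertia_))


def cpp(c_complete: Clustering, c_imputed: Clustering) -> float:
    """Proportion of complete-data co-clustered gene pairs preserved after imputation.

    Label-permutation invariant by construction; 1 by convention when the
    complete clustering has no co-clustered pair at all.
    """
    genes = sorted(c_complete.labels)
    if set(c_imputed.labels) != set(genes):
        raise ValidationError("clusterings cover different gene universes")
    a = np.array([c_complete.labels[g] for g in genes])
    b = np.array([c_imputed.labels[g] for g in genes])
    # contingency counts: pairs co-clustered in both = sum C(n_ij, 2)
    pair_ids = a.astype(np.int64) * (b.max() + 1) + b
    n_both = int(comb(np.bincount(pair_ids), 2).sum())
    n_complete = int(comb(np.bincount(a), 2).sum())
    if n_complete == 0:
        return 1.0
    return n_both / n_complete


def blci(b_cd: DEGeneSet, b_id: DEGeneSet) -> float:
    """Biomarker list concordance between complete-data and imputed-data calls."""
    if b_cd.universe != b_id.universe:
        raise ValidationError("DE gene sets cover different universes")
    U = b_cd.universe
    n_cd = len(b_cd.significant)
    if n_cd == 0 or n_cd == len(U):
        raise MetricUndefinedError(
            "BLCI undefined: complete-data significant set is empty or the whole universe")
    comp_cd = U - b_cd.significant
    comp_id = U - b_id.significant
    return (len(b_cd.significant & b_id.significant) / n_cd
            + len(comp_cd & comp_id) / len(comp_cd) - 1.0)


@dataclass
class ScoreRecord:
    """Per-round, per-algorithm index values (None = undefined that round)."""

    algorithm: str
    dataset: str
    rate: float
    round: int
    nrmse: float | None = None
    cpp: float | None = None
    blci: float | None = None
    meta: dict = field(default_factory=dict)


def score_round(masked: MaskedDataset, result: ImputationResult,
                labels: Mapping[str, str] | None = None, seed: int = 0,
                dataset: str = "dataset", round_no: int = 0,
                n_clusters: int = 10,
                indices: tuple[str, ...] = ("nrmse", "cpp", "blci")) -> ScoreRecord:
    """Score one imputation result against its masked dataset.

    The same k-means seed is used for the complete and the imputed
    clusterings so CPP isolates the effect of imputation from k-means
    initialisation noise.  Metric failures are recorded as None for that
    field, never raised.
    """
    rec = ScoreRecord(algorithm=result.algorithm, dataset=dataset,
                      rate=masked.rate, round=round_no,
                      meta={"seed": seed, "n_clusters": n_clusters})
    if "nrmse" in indices:
        try:
            rec.nrmse = nrmse(result.y_guess(masked), masked.y_answer)
        except (MetricUndefinedError, ValidationError) as exc:
            logger.warning("nrmse undefined for %s round %d: %s",
                           result.algorithm, round_no, exc)
    if "cpp" in indices:
        try:
            km_seed = derive_seed(seed, "kmeans")
            c_complete = kmeans_clusters(masked.complete, n_clusters, km_seed)
            c_imputed = kmeans_clusters(result.imputed, n_clusters, km_seed)
            rec.cpp = cpp(c_complete, c_imputed)
        except (ParameterError, ValidationError) as exc:
            logger.warning("cpp undefined for %s round %d: %s",
                           result.algorithm, round_no, exc)
    if "blci" in indices:
        if labels is None:
            logger.info("blci skipped: no class labels supplied")
        else:
            try:
                sam_seed = derive_seed(seed, "sam")
                b_cd = sam_de_genes(masked.complete, labels, seed=sam_seed)
                b_id = sam_de_genes(result.imputed, labels, seed=sam_seed)
                rec.blci = blci(b_cd, b_id)
                rec.meta["sam"] = b_cd.threshold_meta
            except (MetricUndefinedError, ValidationError, DesignError) as exc:
                logger.warning("blci undefined for %s round %d: %s",
                               result.algorithm, round_no, exc)
    return rec
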