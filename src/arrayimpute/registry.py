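"""Name-based registry of the imputation algorithms.

Maps short algorithm identifiers to (callable, default-config factory).
The defaults follow standard microarray practice: k = 15 for the KNN
family (k = 10 for sequential KNN on time-series data), the probe-based
automatic k for the LLS family, ~20% of the eigengenes for SVD, and
automatic dimensionality (ARD) for BPCA.
"""

from __future__ import annotations

from typing import Callable

from .baselines import oracle_impute, row_mean_impute
from .exceptions import ParameterError
from .leastsquares import LeastSquaresConfig, ills_impute, lls_impute, lsa_impute, slls_impute
from .lowrank import GlobalConfig, bpca_impute, svd_impute
from .matrix import ExpressionMatrix
from .neighbors import NeighborConfig, iknn_impute, knn_impute, sknn_impute

ALGORITHMS: dict[str, tuple[Callable, Callable]] = {
    "knn": (knn_impute, lambda: NeighborConfig(k=15)),
    "sknn": (sknn_impute, lambda: NeighborConfig(k=15)),
    "iknn": (iknn_impute, lambda: NeighborConfig(k=15)),
    "lls": (lls_impute, lambda: LeastSquaresConfig(k="auto")),
    "slls": (slls_impute, lambda: LeastSquaresConfig(k="auto")),
    "ills": (ills_impute, lambda: LeastSquaresConfig(k="auto")),
    "lsa": (lsa_impute, lambda: LeastSquaresConfig()),
    "svd": (svd_impute, lambda: GlobalConfig(n_components="auto")),
    "bpca": (bpca_impute, lambda: GlobalConfig(n_components="auto")),
    "row_mean": (row_mean_impute, lambda: None),
    "oracle": (oracle_impute, lambda: None),
}

#: Algorithms that need the hidden truth (controls, not methods).
NEEDS_TRUTH = {"oracle"}

#: The nine methods of the comparison study, in canonical order.
STUDY_ALGORITHMS = ("knn", "iknn", "sknn", "lsa", "lls", "ills", "slls", "bpca", "svd")

ALIASES = {"ls": "lsa", "svdimpute": "svd"}


def resolve(name: str) -> str:
    key = ALIASES.get(name.lower(), name.lower())
    if key not in ALGORITHMS:
        raise ParameterError(f"unknown algorithm {name!r}; known: {sorted(ALGORITHMS)}")
    return key


def default_config(name: str, dataset_type: str = "unknown"):
    """Default config for ``name``, honouring dataset-type conventions
    (sequential KNN uses k = 10 on time-series data, 15 otherwise)."""
    key = resolve(name)
    cfg = ALGORITHMS[key][1]()
    if key == "sknn" and dataset_type == "time_series":
        cfg.k = 10
    return cfg


def get_algorithm(name: str):
    """(canonical name, impute callable) for ``name``."""
    key = resolve(name)
    return key, ALGORITHMS[key][0]


def impute(m: ExpressionMatrix, algorithm: str, cfg=None, *, masked=None):
    """Run one algorithm by name; thin convenience wrapper."""
    key, fn = get_algorithm(algorithm)
    if cfg is None:
        cfg = default_config(key, m.dataset_type)
    if key in NEEDS_TRUTH:
        return fn(m, cfg, masked=masked)
    return fn(m, cfg) if cfg is not None else fn(m)
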