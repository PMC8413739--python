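"""Group-level structural covariance network construction.

Edges are pairwise partial correlations between regional volumes given the
nuisance covariates (age, sex by default): each region's percent-of-TIV
volume vector is residualized on an intercept plus the covariates by
ordinary least squares, and edge (i, j) is the Pearson correlation of the
two residual vectors.  This is the convention used by group-level
structural-covariance toolboxes; full inverse-covariance partialling over
all 56 regions is not estimable at cohort sizes of a few dozen subjects.

A weight policy then maps correlations to non-negative edge weights
(default: negative correlations are zeroed), and fixed-density binary
graphs are derived by keeping the strongest edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atlas import CohortTable

logger = logging.getLogger("scnet.networks")

__all__ = [
    "GroupNetwork",
    "BinaryNetwork",
    "NetworkConstructionError",
    "WEIGHT_POLICIES",
    "residualize",
    "residuals_from_arrays",
    "pcorr_weights",
    "partial_correlation_network",
    "apply_weight_policy",
    "threshold_by_density",
]

WEIGHT_POLICIES: tuple[str, ...] = ("zero_negative", "absolute", "keep")

DEFAULT_COVARIATES: tuple[str, ...] = ("age", "sex")


class NetworkConstructionError(ValueError):
    """Raised when a network cannot be built from the given cohort/group."""


@dataclass(frozen=True)
class GroupNetwork:
    """Symmetric weighted undirected connectivity matrix for one group."""

    group: str
    weights: np.ndarray  # (N, N) symmetric, zero diagonal
    names: tuple[str, ...]
    covariates: tuple[str, ...]
    weight_policy: str
    n_subjects: int

    def __post_init__(self) -> None:
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise NetworkConstructionError("weights must be square")
        if not np.array_equal(w, w.T):
            raise NetworkConstructionError("weights must be exactly symmetric")
        if np.any(np.diag(w) != 0):
            raise NetworkConstructionError("diagonal must be exactly zero")
        if self.weight_policy in ("zero_negative", "absolute"):
            if w.min() < 0 or w.max() > 1:
                raise NetworkConstructionError(
                    f"{self.weight_policy} weights must lie in [0, 1]"
                )

    @property
    def size(self) -> int:
        return self.weights.shape[0]


@dataclass(frozen=True)
class BinaryNetwork:
    """Binary undirected graph obtained at a fixed edge density."""

    group: str
    adjacency: np.ndarray  # (N, N) 0/1, symmetric, zero diagonal
    density: float
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = self.adjacency
        if not np.array_equal(a, a.T):
            raise NetworkConstructionError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise NetworkConstructionError("adjacency must be 0/1")
        if np.any(np.diag(a) != 0):
            raise NetworkConstructionError("diagonal must be zero")
        if not 0 < self.density < 1:
            raise NetworkConstructionError("density must lie in (0, 1)")

    @property
    def size(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


# ---------------------------------------------------------------------------
# Residualization and partial correlation
# ---------------------------------------------------------------------------


def _design_matrix(X: np.ndarray, covariates: tuple[str, ...]) -> np.ndarray:
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    # a covariate constant within the group makes the design rank-deficient
    for k, name in enumerate(covariates):
        if np.ptp(X[:, k]) == 0:
            raise NetworkConstructionError(
                f"covariate {name!r} is constant within the group "
                "(rank-deficient design)"
            )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise NetworkConstructionError(
            f"design matrix with covariates {covariates} is rank-deficient"
        )
    return design


def residuals_from_arrays(
    Y: np.ndarray,
    X: np.ndarray,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> np.ndarray:
    """OLS residuals of each column of ``Y`` on intercept + columns of
    ``X`` (array-level core shared with the permutation engine)."""
    n = Y.shape[0]
    if n < X.shape[1] + 2:
        raise NetworkConstructionError(
            f"need at least {X.shape[1] + 2} subjects to fit "
            f"{X.shape[1]} covariates + intercept, got {n}"
        )
    design = _design_matrix(X, covariates)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ beta


def residualize(
    cohort: CohortTable,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    group: str | None = None,
) -> np.ndarray:
    """OLS residuals of every region's volume on intercept + covariates.

    Returns a subjects x regions matrix; each column has mean ~0 (the
    intercept absorbs it).  Estimated within ``group`` if given, otherwise
    over the whole cohort.
    """
    if not cohort.normalized:
        raise NetworkConstructionError(
            "cohort must be TIV-normalized before residualization"
        )
    covariates = tuple(covariates)
    Y = cohort.volumes_matrix(group)
    X = cohort.covariate_matrix(covariates, group)
    return residuals_from_arrays(Y, X, covariates)


def pcorr_weights(
    Y: np.ndarray,
    X: np.ndarray,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    weight_policy: str = "zero_negative",
    region_names: tuple[str, ...] | None = None,
    label: str = "",
) -> np.ndarray:
    """Partial-correlation weight matrix from raw arrays.

    Residualizes every column of ``Y`` (subjects x regions) on an intercept
    plus ``X``, correlates residual columns pairwise, mirrors the upper
    triangle for exact symmetry, and applies the weight policy.
    """
    n = Y.shape[0]
    if n < X.shape[1] + 3:
        raise NetworkConstructionError(
            f"group {label!r}: need at least {X.shape[1] + 3} subjects, "
            f"got {n}"
        )
    resid = residuals_from_arrays(Y, X, covariates)
    sd = resid.std(axis=0)
    # scale-aware: a constant region leaves only rounding noise (~1e-17)
    degenerate = sd <= 1e-12 * max(1.0, float(np.abs(Y).max()))
    if np.any(degenerate):
        idx = int(np.argmax(degenerate))
        name = region_names[idx] if region_names else f"index {idx}"
        raise NetworkConstructionError(
            f"region {name!r} has zero residual variance in group {label!r}"
        )
    corr = np.clip(np.corrcoef(resid, rowvar=False), -1.0, 1.0)
    iu = np.triu_indices_from(corr, k=1)
    weights = np.zeros_like(corr)
    weights[iu] = corr[iu]
    weights = weights + weights.T
    return apply_weight_policy(weights, weight_policy)


def partial_correlation_network(
    cohort: CohortTable,
    group: str,
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
    weight_policy: str = "zero_negative",
) -> GroupNetwork:
    """Build the group's weighted network of covariate-adjusted correlations.

    Edge (i, j) is the Pearson correlation between region i's and region j's
    OLS residuals given the covariates (partial correlation given age and
    sex; regions are never conditioned on each other).
    """
    if not cohort.normalized:
        raise NetworkConstructionError(
            "cohort must be TIV-normalized before network construction"
        )
    covariates = tuple(covariates)
    Y = cohort.volumes_matrix(group)
    X = cohort.covariate_matrix(covariates, group)
    weights = pcorr_weights(Y, X, covariates, weight_policy,
                            region_names=cohort.atlas.names, label=group)
    return GroupNetwork(
        group=group,
        weights=weights,
        names=cohort.atlas.names,
        covariates=covariates,
        weight_policy=weight_policy,
        n_subjects=Y.shape[0],
    )


def apply_weight_policy(weights: np.ndarray, policy: str) -> np.ndarray:
    """Map signed correlation weights to the configured edge-weight scale.

    ``zero_negative`` clips negatives to 0 (default: negative covariance
    carries no path semantics in the weighted metrics), ``absolute`` takes
    magnitudes, ``keep`` leaves values signed.  The diagonal is forced to 0
    in every policy.
    """
    if policy not in WEIGHT_POLICIES:
        raise NetworkConstructionError(
            f"unknown weight policy {policy!r}; expected one of "
            f"{WEIGHT_POLICIES}"
        )
    w = np.asarray(weights, dtype=float).copy()
    if policy == "zero_negative":
        w = np.maximum(w, 0.0)
    elif policy == "absolute":
        w = np.abs(w)
    np.fill_diagonal(w, 0.0)
    return w


# ---------------------------------------------------------------------------
# Density thresholding
# ---------------------------------------------------------------------------


def threshold_by_density(
    network: GroupNetwork | np.ndarray,
    density: float,
    *,
    group: str = "",
    names: tuple[str, ...] = (),
) -> BinaryNetwork:
    """Binarize a weighted network keeping the strongest edges.

    Exactly ``round(density * N(N-1)/2)`` edges are kept (fewer, with a
    logged warning, if the network has fewer positive-weight edges).  Ties
    at the cutoff are broken deterministically by ascending (i, j) index
    order among equal weights.
    """
    if isinstance(network, GroupNetwork):
        weights = network.weights
        group = group or network.group
        names = names or network.names
    else:
        weights = np.asarray(network, dtype=float)
    if not 0 < density < 1:
        raise NetworkConstructionError(
            f"density must lie in (0, 1), got {density}"
        )
    if weights.min() < 0:
        raise NetworkConstructionError(
            "thresholding requires non-negative weights; apply the "
            "zero_negative or absolute weight policy first"
        )
    n = weights.shape[0]
    n_possible = n * (n - 1) // 2
    k = round(density * n_possible)
    if k == 0:
        raise NetworkConstructionError(
            f"density {density} yields 0 edges for {n} nodes"
        )
    ii, jj = np.triu_indices(n, k=1)
    w = weights[ii, jj]
    positive = w > 0
    n_positive = int(positive.sum())
    if k > n_positive:
        logger.warning(
            "density %.2f requests %d edges but only %d positive-weight "
            "edges exist in group %r; using all positive edges",
            density, k, n_positive, group,
        )
        k = n_positive
        if k == 0:
            raise NetworkConstructionError(
                f"group {group!r}: no positive-weight edges to threshold"
            )
    # sort by (-weight, i, j): strongest first, lexicographic tie-break
    order = np.lexsort((jj, ii, -w))
    keep = order[:k]
    adjacency = np.zeros((n, n), dtype=int)
    adjacency[ii[keep], jj[keep]] = 1
    adjacency = adjacency + adjacency.T
    return BinaryNetwork(group=group, adjacency=adjacency,
                         density=density, names=tuple(names))
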