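"""Permutation-based comparison of group-level network measures.

Network measures here exist only at the group level (one covariance network
per group), so group differences are tested nonparametrically: subjects are
repeatedly reassigned to pseudo-groups of the original sizes, the entire
estimation pipeline (covariate residualization -> partial-correlation
network -> measure) is re-run on each relabeling, and the observed
difference is referred to the permutation distribution.  The two-sided
p-value uses the add-one estimator ``(1 + #{|d_perm| >= |d_obs|}) /
(n_perm + 1)``, so p is never exactly 0; the reported interval is the
2.5th/97.5th percentile band of the permuted differences (it brackets 0
under the null).

Local (per-node) betweenness comparisons are corrected across regions by
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import CohortTable
from .metrics import (
    GLOBAL_MEASURES,
    MEASURE_DISPLAY_NAMES,
    betweenness_centrality,
    global_measure_values,
)
from .networks import (
    DEFAULT_COVARIATES,
    NetworkConstructionError,
    pcorr_weights,
    threshold_by_density,
)

logger = logging.getLogger("scnet.inference")

__all__ = [
    "PermutationResult",
    "InferenceError",
    "permutation_test",
    "compare_all_global",
    "compare_local_betweenness",
    "fdr_adjust",
    "clinical_correlations",
    "density_sweep_comparison",
    "DEFAULT_DENSITIES",
]

DEFAULT_DENSITIES: tuple[float, ...] = tuple(
    round(0.1 * k, 2) for k in range(1, 10)
)


class InferenceError(ValueError):
    """Raised for invalid inference inputs (bad p-values, constant
    clinical variables, unknown groups...)."""


@dataclass(frozen=True)
class PermutationResult:
    """Observed group difference for one measure with its permutation null.

    ``difference = value_b - value_a``; ``ci_lower``/``ci_upper`` are the
    2.5th/97.5th percentiles of the permuted differences.
    """

    measure: str
    value_a: float
    value_b: float
    difference: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise InferenceError("ci_lower must be <= ci_upper")
        if not 0 < self.p_value <= 1:
            raise InferenceError("p_value must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Permutation engine
# ---------------------------------------------------------------------------


def _resolve_groups(
    cohort: CohortTable, group_a: str | None, group_b: str | None
) -> tuple[str, str]:
    names = cohort.group_names()
    if group_a is None and group_b is None:
        if len(names) != 2:
            raise InferenceError(
                f"cohort has groups {names}; pass group_a and group_b "
                "explicitly"
            )
        return names[0], names[1]
    if group_a is None or group_b is None:
        raise InferenceError("pass both group_a and group_b or neither")
    for g in (group_a, group_b):
        if g not in names:
            raise InferenceError(f"unknown group {g!r}; cohort has {names}")
    return group_a, group_b


@dataclass(frozen=True)
class _EngineResult:
    values_a: np.ndarray  # observed measure vector, group a
    values_b: np.ndarray
    null_diffs: np.ndarray  # (n_perm, n_measures)
    n_redrawn: int
    seed: int
    n_perm: int

    @property
    def differences(self) -> np.ndarray:
        return self.values_b - self.values_a

    @property
    def p_values(self) -> np.ndarray:
        obs = np.abs(self.differences)
        exceed = (np.abs(self.null_diffs) >= obs).sum(axis=0)
        return (1.0 + exceed) / (self.n_perm + 1.0)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = np.percentile(self.null_diffs, [2.5, 97.5], axis=0)
        return np.atleast_1d(lo), np.atleast_1d(hi)


def _run_permutations(
    cohort: CohortTable,
    group_a: str,
    group_b: str,
    stat_fn,
    n_perm: int,
    seed: int,
    covariates: tuple[str, ...],
    weight_policy: str,
) -> _EngineResult:
    """Shared engine: rebuild residuals + network + measure per relabeling.

    ``stat_fn(weights, eval_seed) -> 1-D array`` evaluates the measure(s)
    on one pseudo-group network.  A permutation whose pseudo-group yields a
    degenerate network (zero-variance region, no positive edges) is redrawn
    with a logged count.  Deterministic for a fixed seed.
    """
    if not cohort.normalized:
        raise InferenceError("cohort must be TIV-normalized before inference")
    if n_perm < 1:
        raise InferenceError("n_perm must be >= 1")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values are coarse", n_perm)
    covariates = tuple(covariates)
    mask = cohort.data["group"].isin([group_a, group_b]).to_numpy()
    sub = cohort.data.loc[mask]
    Y = sub.loc[:, list(cohort.atlas.names)].to_numpy(dtype=float)
    X = sub.loc[:, list(covariates)].to_numpy(dtype=float)
    is_a = (sub["group"] == group_a).to_numpy()
    n_a = int(is_a.sum())
    n_total = len(sub)
    names = cohort.atlas.names

    rng = np.random.default_rng(seed)

    def build(idx: np.ndarray, label: str) -> np.ndarray:
        return pcorr_weights(Y[idx], X[idx], covariates, weight_policy,
                             region_names=names, label=label)

    idx_a = np.flatnonzero(is_a)
    idx_b = np.flatnonzero(~is_a)
    values_a = np.atleast_1d(
        stat_fn(build(idx_a, group_a), int(rng.integers(2**31 - 1))))
    values_b = np.atleast_1d(
        stat_fn(build(idx_b, group_b), int(rng.integers(2**31 - 1))))

    null = np.empty((n_perm, len(values_a)))
    n_redrawn = 0
    max_attempts = 10 * n_perm + 100
    attempts = 0
    k = 0
    while k < n_perm:
        attempts += 1
        if attempts > max_attempts:
            raise InferenceError(
                f"too many degenerate permutations ({n_redrawn} redraws); "
                "the cohort is too small or too collinear to permute"
            )
        perm = rng.permutation(n_total)
        seed_a = int(rng.integers(2**31 - 1))
        seed_b = int(rng.integers(2**31 - 1))
        try:
            wa = build(perm[:n_a], f"perm{k}:a")
            wb = build(perm[n_a:], f"perm{k}:b")
            null[k] = np.atleast_1d(stat_fn(wa, seed_a))
            null[k] = np.atleast_1d(stat_fn(wb, seed_b)) - null[k]
        except NetworkConstructionError as exc:
            n_redrawn += 1
            logger.debug("redrawing degenerate permutation %d: %s", k, exc)
            continue
        k += 1
    if n_redrawn:
        logger.info("redrew %d degenerate permutations", n_redrawn)
    return _EngineResult(values_a=values_a, values_b=values_b,
                         null_diffs=null, n_redrawn=n_redrawn,
                         seed=seed, n_perm=n_perm)


# ---------------------------------------------------------------------------
# Public comparisons
# ---------------------------------------------------------------------------


def permutation_test(
    cohort: CohortTable,
    group_a: str | None = None,
    group_b: str | None = None,
    measure: str = "mean_clustering_coefficient",
    n_perm: int = 1000,
    seed: int = 0,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    weight_policy: str = "zero_negative",
    n_null_graphs: int = 20,
) -> PermutationResult:
    """Permutation test of one global measure between two groups.

    ``measure`` is a global-measure name, or a callable
    ``f(weights, seed) -> float`` for custom statistics.
    """
    group_a, group_b = _resolve_groups(cohort, group_a, group_b)
    if callable(measure):
        stat_fn = lambda w, s: np.atleast_1d(float(measure(w, s)))  # noqa: E731
        name = getattr(measure, "__name__", "custom")
    else:
        if measure not in GLOBAL_MEASURES:
            raise InferenceError(
                f"unknown measure {measure!r}; expected one of "
                f"{GLOBAL_MEASURES} or a callable"
            )
        name = measure
        stat_fn = lambda w, s: global_measure_values(  # noqa: E731
            w, (measure,), seed=s, n_null=n_null_graphs)
    res = _run_permutations(cohort, group_a, group_b, stat_fn, n_perm, seed,
                            covariates, weight_policy)
    lo, hi = res.ci
    return PermutationResult(
        measure=name,
        value_a=float(res.values_a[0]),
        value_b=float(res.values_b[0]),
        difference=float(res.differences[0]),
        ci_lower=float(lo[0]),
        ci_upper=float(hi[0]),
        p_value=float(res.p_values[0]),
        n_permutations=n_perm,
        seed=seed,
    )


def compare_all_global(
    cohort: CohortTable,
    n_perm: int = 1000,
    seed: int = 0,
    group_a: str | None = None,
    group_b: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    weight_policy: str = "zero_negative",
    n_null_graphs: int = 20,
) -> pd.DataFrame:
    """All 13 global measures tested on one shared permutation stream.

    Every measure is evaluated on the same relabelings (a coherent joint
    null at the cost of one pipeline run per permutation).  Returns a
    13-row table with the report measure names.
    """
    group_a, group_b = _resolve_groups(cohort, group_a, group_b)
    stat_fn = lambda w, s: global_measure_values(  # noqa: E731
        w, GLOBAL_MEASURES, seed=s, n_null=n_null_graphs)
    res = _run_permutations(cohort, group_a, group_b, stat_fn, n_perm, seed,
                            covariates, weight_policy)
    lo, hi = res.ci
    table = pd.DataFrame(
        {
            "measure": [MEASURE_DISPLAY_NAMES[m] for m in GLOBAL_MEASURES],
            f"value_{group_a}": res.values_a,
            f"value_{group_b}": res.values_b,
            "difference": res.differences,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": res.p_values,
        }
    )
    table.attrs.update(group_a=group_a, group_b=group_b, seed=seed,
                       n_permutations=n_perm, n_redrawn=res.n_redrawn)
    return table


def compare_local_betweenness(
    cohort: CohortTable,
    n_perm: int = 1000,
    seed: int = 0,
    group_a: str | None = None,
    group_b: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    weight_policy: str = "zero_negative",
) -> pd.DataFrame:
    """Per-region permutation tests on betweenness centrality, with
    Benjamini-Hochberg q-values across the atlas regions.

    One row per region in atlas order: observed values, difference
    (``group_b - group_a``), permutation CI, raw p, q, and direction.
    """
    group_a, group_b = _resolve_groups(cohort, group_a, group_b)
    stat_fn = lambda w, s: betweenness_centrality(w)  # noqa: E731
    res = _run_permutations(cohort, group_a, group_b, stat_fn, n_perm, seed,
                            covariates, weight_policy)
    lo, hi = res.ci
    p = res.p_values
    q = fdr_adjust(p)
    diff = res.differences
    direction = np.where(
        diff > 0, f"greater_in_{group_b}",
        np.where(diff < 0, f"greater_in_{group_a}", "equal"),
    )
    table = pd.DataFrame(
        {
            "region": list(cohort.atlas.names),
            f"value_{group_a}": res.values_a,
            f"value_{group_b}": res.values_b,
            "difference": diff,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    )
    table.attrs.update(group_a=group_a, group_b=group_b, seed=seed,
                       n_permutations=n_perm, n_redrawn=res.n_redrawn)
    return table


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InferenceError("p_values must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise InferenceError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def clinical_correlations(
    cohort: CohortTable,
    clinical_vars: tuple[str, ...] = ("age",),
    group: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each region's volume with each clinical
    variable (two-sided t-based p), within one group.

    ``group`` defaults to the first group in the cohort (the clinical
    variables — onset age, disease duration — exist only for patients).
    """
    if group is None:
        group = cohort.group_names()[0]
    if group not in cohort.group_names():
        raise InferenceError(f"unknown group {group!r}")
    sub = cohort.data[cohort.data["group"] == group]
    rows = []
    for var in clinical_vars:
        if var not in sub.columns:
            raise InferenceError(f"clinical variable {var!r} not in cohort")
        x = sub[var].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise InferenceError(
                f"clinical variable {var!r} is constant in group {group!r}"
            )
        for region in cohort.atlas.names:
            y = sub[region].to_numpy(dtype=float)
            r, p = stats.pearsonr(x, y)
            rows.append(
                {
                    "region": region,
                    "variable": var,
                    "r": float(r),
                    "p_value": float(p),
                    "significant": bool(p < alpha),
                }
            )
    table = pd.DataFrame(rows,
                         columns=["region", "variable", "r", "p_value",
                                  "significant"])
    table.attrs.update(group=group, alpha=alpha)
    return table


def density_sweep_comparison(
    cohort: CohortTable,
    densities: tuple[float, ...] = DEFAULT_DENSITIES,
    measure: str = "mean_clustering_coefficient",
    n_perm: int = 1000,
    seed: int = 0,
    group_a: str | None = None,
    group_b: str | None = None,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    weight_policy: str = "zero_negative",
    n_null_graphs: int = 20,
) -> pd.DataFrame:
    """Permutation comparison of one measure on fixed-density binary graphs.

    For each density the weighted pseudo-group networks are binarized by
    keeping the strongest edges and the measure recomputed, sharing one
    permutation stream across densities.  One row per density with the
    observed values, difference, permutation CI, and p.
    """
    group_a, group_b = _resolve_groups(cohort, group_a, group_b)
    if not densities:
        raise InferenceError("densities must be non-empty")
    for d in densities:
        if not 0 < d < 1:
            raise InferenceError(f"density {d} outside (0, 1)")
    if measure not in GLOBAL_MEASURES:
        raise InferenceError(f"unknown measure {measure!r}")

    def stat_fn(w: np.ndarray, s: int) -> np.ndarray:
        out = np.empty(len(densities))
        for i, d in enumerate(densities):
            binary = threshold_by_density(w, d)
            out[i] = global_measure_values(
                binary.adjacency.astype(float), (measure,),
                seed=s, n_null=n_null_graphs,
            )[0]
        return out

    res = _run_permutations(cohort, group_a, group_b, stat_fn, n_perm, seed,
                            covariates, weight_policy)
    lo, hi = res.ci
    table = pd.DataFrame(
        {
            "density": list(densities),
            f"value_{group_a}": res.values_a,
            f"value_{group_b}": res.values_b,
            "difference": res.differences,
            "ci_lower": lo,
            "ci_upper": hi,
            "p_value": res.p_values,
        }
    )
    table.attrs.update(group_a=group_a, group_b=group_b, seed=seed,
                       n_permutations=n_perm, measure=measure,
                       n_redrawn=res.n_redrawn)
    return table
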