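"""Geographical-detector analysis: natural breaks, factor q and interaction detector.

The factor detector measures how much of a response variable's spatial
heterogeneity a categorical driver explains:

    q = 1 - sum_m N_m sigma_m^2 / (N sigma^2),

with m indexing the L strata of the driver, N_m and sigma_m^2 the count and
population variance of the response within stratum m, and N, sigma^2 the
whole-region count and population variance.  With population variances the
within/total decomposition is exact, so q is always in [0, 1]: q = 0 when
strata explain nothing, q = 1 when the response is constant within every
stratum.  Significance uses the noncentral-F test of the geographical
detector: F = (N - L)/(L - 1) * q/(1 - q) ~ F(L-1, N-L; lambda) with
noncentrality lambda computed from the stratum means.

Continuous drivers are discretized into k classes (5 by default) by Jenks
natural breaks — the optimal one-dimensional partition minimizing the
within-class sum of squared deviations, computed exactly by Fisher's
dynamic program.

The interaction detector compares q of the cross-classification A-and-B
with the individual q's:

    q(A^B) < min(qA, qB)            -> nonlinear weakening
    min <= q(A^B) <= max            -> single-factor nonlinear weakening
    max < q(A^B) < qA + qB          -> two-factor enhancement
    q(A^B) = qA + qB  (tolerance)   -> independence
    q(A^B) > qA + qB                -> nonlinear enhancement
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StratifiedVariable",
    "FactorResult",
    "InteractionResult",
    "GeodetectorReport",
    "jenks_breaks",
    "factor_q",
    "interaction_q",
    "classify_interaction",
    "run_geodetector",
]

#: q(A^B) = qA + qB equality tolerance for the independence class.
INDEPENDENCE_TOL = 1e-9


@dataclass(frozen=True)
class StratifiedVariable:
    labels: np.ndarray  # per-point stratum in 1..n_strata
    n_strata: int
    source: str = ""
    breaks: tuple[float, ...] = ()  # class boundaries when Jenks-derived


@dataclass(frozen=True)
class FactorResult:
    q: float
    p: float
    stratum_counts: np.ndarray  # N_m
    stratum_variances: np.ndarray  # sigma_m^2 (population)
    stratum_means: np.ndarray
    n: int
    total_variance: float  # sigma^2 (population)
    source: str = ""


@dataclass(frozen=True)
class InteractionResult:
    q_a: float
    q_b: float
    q_ab: float
    classification: str


def jenks_breaks(values, k: int) -> StratifiedVariable:
    """Jenks/Fisher optimal 1-D classification into k classes.

    Minimizes the within-class sum of squared deviations over all ordered
    partitions (exact dynamic program, O(k n^2)).  Labels are ordered by
    value (class 1 = lowest).  If there are fewer than k distinct values,
    k is reduced with a warning.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k < 2:
        raise ValueError(f"need k >= 2 classes, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    distinct = np.unique(x)
    if len(distinct) < 2:
        raise ValueError("constant input cannot be classified")
    if len(distinct) < k:
        warnings.warn(
            f"only {len(distinct)} distinct values; reducing k from {k}",
            stacklevel=2,
        )
        k = len(distinct)

    order = np.argsort(x, kind="stable")
    xs = x[order]
    # prefix sums for O(1) within-segment SSD
    cs = np.concatenate([[0.0], np.cumsum(xs)])
    cs2 = np.concatenate([[0.0], np.cumsum(xs**2)])

    def ssd(i, j):  # segment xs[i:j], j exclusive
        s, s2, m = cs[j] - cs[i], cs2[j] - cs2[i], j - i
        return s2 - s * s / m

    INF = np.inf
    cost = np.full((k + 1, n + 1), INF)
    back = np.zeros((k + 1, n + 1), dtype=np.intp)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + ssd(i, j)
                if v < best:  # strict: ties keep the lower (earlier) break
                    best, arg = v, i
            cost[c, j] = best
            back[c, j] = arg

    # recover segment boundaries
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = int(back[c, j])
        bounds.append(j)
    bounds = bounds[::-1]  # 0 = bounds[0] < ... < bounds[k] = n

    labels_sorted = np.empty(n, dtype=np.intp)
    for c in range(k):
        labels_sorted[bounds[c] : bounds[c + 1]] = c + 1
    labels = np.empty(n, dtype=np.intp)
    labels[order] = labels_sorted
    breaks = tuple(float(xs[b - 1]) for b in bounds[1:])  # upper bound of each class
    return StratifiedVariable(labels=labels, n_strata=k, breaks=breaks)


def _decompose(y: np.ndarray, labels: np.ndarray):
    """Per-stratum counts, population variances and means; empty strata dropped."""
    strata, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=y) / counts
    # two-pass variances for numerical accuracy
    variances = np.bincount(inv, weights=(y - means[inv]) ** 2) / counts
    return strata, counts, variances, means


def factor_q(y_values, strata: StratifiedVariable | np.ndarray) -> FactorResult:
    """Factor-detector q with its noncentral-F p-value.

    Strata with no points are dropped (with a warning when label gaps exist
    in a :class:`StratifiedVariable`).  Requires N >= L + 1 and a
    non-degenerate response.
    """
    y = np.asarray(y_values, dtype=float)
    if isinstance(strata, StratifiedVariable):
        labels = strata.labels
        source = strata.source
        declared = strata.n_strata
    else:
        labels = np.asarray(strata)
        source = ""
        declared = len(np.unique(labels))
    if len(y) != len(labels):
        raise ValueError("y and strata must be aligned")

    ids, counts, variances, means = _decompose(y, labels)
    L = len(ids)
    if L < declared:
        warnings.warn(f"{declared - L} declared strata are empty; dropped", stacklevel=2)
    n = len(y)
    if n < L + 1:
        raise ValueError(f"need N >= L + 1 points (N={n}, L={L})")
    # exact decomposition N sigma^2 = within + between makes the q = 0 and
    # q = 1 limits exact (a single stratum gives between = 0 identically)
    within = float(np.sum(counts * variances))
    grand_mean = float(np.sum(counts * means)) / n
    between = float(np.sum(counts * (means - grand_mean) ** 2))
    total = within + between
    if total == 0:
        raise ValueError("zero total variance: q is degenerate")
    total_var = total / n  # population sigma^2
    q = between / total

    # noncentral-F significance test of the geographical detector
    if L < 2:
        p = 1.0
    elif q >= 1.0 - 1e-15:
        p = 0.0
    else:
        f_stat = (n - L) / (L - 1) * q / (1.0 - q)
        lam = (
            np.sum(means**2) - (np.sum(np.sqrt(counts) * means)) ** 2 / n
        ) / total_var
        lam = max(float(lam), 0.0)
        p = float(stats.ncf.sf(f_stat, L - 1, n - L, lam))
    return FactorResult(
        q=q,
        p=p,
        stratum_counts=counts,
        stratum_variances=variances,
        stratum_means=means,
        n=n,
        total_variance=total_var,
        source=source,
    )


def classify_interaction(q_a: float, q_b: float, q_ab: float) -> str:
    """Five-way interaction class from (qA, qB, q of the cross-classification)."""
    lo, hi = min(q_a, q_b), max(q_a, q_b)
    total = q_a + q_b
    if abs(q_ab - total) <= INDEPENDENCE_TOL:
        return "independence"
    if q_ab > total:
        return "nonlinear_enhancement"
    if q_ab < lo:
        return "nonlinear_weakening"
    if q_ab <= hi:
        return "single_factor_nonlinear_weakening"
    return "two_factor_enhancement"


def interaction_q(y_values, strata_a, strata_b) -> InteractionResult:
    """Interaction detector: q of the pairwise cross-classification of A and B."""
    la = strata_a.labels if isinstance(strata_a, StratifiedVariable) else np.asarray(strata_a)
    lb = strata_b.labels if isinstance(strata_b, StratifiedVariable) else np.asarray(strata_b)
    if len(la) != len(lb):
        raise ValueError("strata must be aligned")
    # unique label per (A, B) cell
    _, cross = np.unique(np.column_stack([la, lb]), axis=0, return_inverse=True)
    if len(np.unique(cross)) < 2:
        raise ValueError("cross-classification has fewer than 2 nonempty strata")
    q_a = factor_q(y_values, la).q
    q_b = factor_q(y_values, lb).q
    q_ab = factor_q(y_values, cross + 1).q
    return InteractionResult(
        q_a=q_a, q_b=q_b, q_ab=q_ab,
        classification=classify_interaction(q_a, q_b, q_ab),
    )


@dataclass(frozen=True)
class GeodetectorReport:
    factors: pd.DataFrame  # one row per driver: q, p, n_strata; ranked by q desc
    interactions: pd.DataFrame  # rows (driver_a, driver_b, q_a, q_b, q_ab, classification)
    strata: dict[str, StratifiedVariable]


def run_geodetector(
    table: pd.DataFrame,
    y_service: str,
    driver_names: list[str],
    k: int = 5,
    p_threshold: float = 0.1,
) -> GeodetectorReport:
    """Factor and interaction detection of every driver against one response.

    Integer / categorical driver columns are used as strata directly;
    continuous ones are discretized by Jenks natural breaks into ``k``
    classes.  Factors are ranked by q descending; all unordered driver
    pairs enter the interaction matrix.
    """
    if y_service not in table.columns:
        raise KeyError(f"response column {y_service!r} missing from table")
    missing = [d for d in driver_names if d not in table.columns]
    if missing:
        raise KeyError(f"driver columns missing from table: {missing}")
    y = table[y_service].to_numpy(dtype=float)

    strata: dict[str, StratifiedVariable] = {}
    rows = []
    for name in driver_names:
        col = table[name]
        if pd.api.types.is_integer_dtype(col) or isinstance(col.dtype, pd.CategoricalDtype):
            codes = col.astype("category").cat.codes.to_numpy() + 1
            sv = StratifiedVariable(
                labels=codes, n_strata=int(codes.max()), source=name
            )
        else:
            sv = jenks_breaks(col.to_numpy(dtype=float), k)
            sv = StratifiedVariable(
                labels=sv.labels, n_strata=sv.n_strata, source=name, breaks=sv.breaks
            )
        strata[name] = sv
        res = factor_q(y, sv)
        rows.append(
            {
                "driver": name,
                "q": res.q,
                "p": res.p,
                "significant": res.p < p_threshold,
                "n_strata": len(res.stratum_counts),
            }
        )
    factors = (
        pd.DataFrame(rows).sort_values("q", ascending=False).reset_index(drop=True)
    )

    inter_rows = []
    for i, a in enumerate(driver_names):
        for b in driver_names[i + 1 :]:
            res = interaction_q(y, strata[a], strata[b])
            inter_rows.append(
                {
                    "driver_a": a,
                    "driver_b": b,
                    "q_a": res.q_a,
                    "q_b": res.q_b,
                    "q_ab": res.q_ab,
                    "classification": res.classification,
                }
            )
    interactions = pd.DataFrame(
        inter_rows,
        columns=["driver_a", "driver_b", "q_a", "q_b", "q_ab", "classification"],
    )
    return GeodetectorReport(factors=factors, interactions=interactions, strata=strata)
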