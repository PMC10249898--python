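"""Distribution diagnostics, Min-Max normalization and the composite ES score.

Ecosystem services come in incommensurable units (kg of carbon, m^3 of
avoided runoff, g of pollutants), so services are made dimensionless by
Min-Max normalization

    X'_i = (X_i - X_min) / (X_max - X_min)

before aggregation.  The composite score normalizes each service, sums the
normalized columns with equal weight (configurable), and Min-Max normalizes
the sum again, yielding a composite in [0, 1] that attains both endpoints.

Kriging assumes approximate normality, so skewness and kurtosis (Pearson,
normal ~ 3) are reported for raw and log-transformed values to justify the
log transform used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DistributionDiagnostics",
    "CompositeResult",
    "distribution_diagnostics",
    "min_max_normalize",
    "composite_es",
]


class DegenerateRangeError(ValueError):
    """Raised when Min-Max normalization meets a constant column."""


@dataclass(frozen=True)
class DistributionDiagnostics:
    skewness: float
    kurtosis: float  # Pearson convention: m4/m2^2, normal ~ 3
    transform: str  # "none" | "log"
    n: int


@dataclass(frozen=True)
class CompositeResult:
    """Normalized service columns, the composite column and the bounds used."""

    normalized: pd.DataFrame  # one column per input service, each in [0, 1]
    composite: pd.Series  # in [0, 1], named "composite_es"
    bounds: dict[str, tuple[float, float]]  # (Xmin, Xmax) per column incl. the summed score
    weights: dict[str, float]


def distribution_diagnostics(values, transform: str = "none") -> DistributionDiagnostics:
    """Moment-based skewness g1 and Pearson kurtosis m4/m2^2 (not excess).

    With ``transform="log"`` the diagnostics are computed on log(values);
    all values must then be strictly positive.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError(f"need at least 3 values, got {x.size}")
    if transform == "log":
        if np.any(x <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.log(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    m = x.mean()
    m2 = np.mean((x - m) ** 2)
    if m2 == 0:
        raise ValueError("zero variance: distribution diagnostics are degenerate")
    m3 = np.mean((x - m) ** 3)
    m4 = np.mean((x - m) ** 4)
    return DistributionDiagnostics(
        skewness=float(m3 / m2**1.5),
        kurtosis=float(m4 / m2**2),
        transform=transform,
        n=int(x.size),
    )


def min_max_normalize(values) -> tuple[np.ndarray, tuple[float, float]]:
    """Map values linearly onto [0, 1]: min -> 0, max -> 1.

    Returns the normalized array and the (Xmin, Xmax) bounds used.
    Raises :class:`DegenerateRangeError` on constant input.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateRangeError(
            f"constant input (all values = {lo}); Min-Max normalization undefined"
        )
    return (x - lo) / (hi - lo), (lo, hi)


def composite_es(
    table: pd.DataFrame,
    service_names: list[str],
    weights: dict[str, float] | None = None,
) -> CompositeResult:
    """Equal-weight composite ES score over the named service columns.

    Each service is Min-Max normalized, the normalized columns are combined
    as a weighted sum (equal weights by default) and the sum is Min-Max
    normalized again.  The result is order-preserving in each service and
    invariant to positive affine rescaling of any input column.
    """
    if len(service_names) < 2:
        raise ValueError("composite needs at least 2 services")
    missing = [s for s in service_names if s not in table.columns]
    if missing:
        raise KeyError(f"service columns missing from table: {missing}")
    if weights is None:
        w = {s: 1.0 for s in service_names}
    else:
        w = {s: float(weights[s]) for s in service_names}
        if any(v < 0 for v in w.values()):
            raise ValueError("weights must be nonnegative")

    bounds: dict[str, tuple[float, float]] = {}
    normalized = pd.DataFrame(index=table.index)
    for s in service_names:
        try:
            col, bnd = min_max_normalize(table[s].to_numpy())
        except DegenerateRangeError as exc:
            raise DegenerateRangeError(f"service column {s!r}: {exc}") from exc
        normalized[s] = col
        bounds[s] = bnd

    summed = sum(w[s] * normalized[s].to_numpy() for s in service_names)
    comp, bnd = min_max_normalize(summed)
    bounds["__sum__"] = bnd
    return CompositeResult(
        normalized=normalized,
        composite=pd.Series(comp, index=table.index, name="composite_es"),
        bounds=bounds,
        weights=w,
    )
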