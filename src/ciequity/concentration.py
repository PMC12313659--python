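"""Weighted fractional ranks and the concentration index.

The concentration index of a variable h against a socio-economic ordering is

    C = 2 * cov_w(h, r) / mu,

where r is the weighted fractional rank (each unit sits at the midpoint of
its cumulative weight interval, so the weighted mean rank is exactly 1/2),
mu is the weighted mean of h, and cov_w is the weighted *population*
covariance.  C runs from -1 (h fully concentrated among the lowest-ranked,
"pro-poor") to +1 ("pro-rich"); 0 is proportional equality.  An equivalent
"convenient regression" route estimates C as the WLS slope of
2*var_w(r)*(h_i/mu) on r_i, and is kept as a second method so the two can be
cross-checked.  For zero-mean quantities (regression residuals) the
generalized concentration index 2*cov_w(e, r) drops the mean normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .panel_io import REGION, WEIGHT, YEAR, PanelTable, VariableRoles

import logging

logger = logging.getLogger("ciequity")


class RankingDegenerateError(ValueError):
    """All ranking values identical: no socio-economic ordering exists."""


class UndefinedIndexError(ValueError):
    """The concentration index is undefined (zero mean)."""


class InsufficientDataError(ValueError):
    """Too few observations."""


@dataclass
class FractionalRanks:
    """Per-observation weighted fractional ranks in (0, 1)."""

    rank: np.ndarray
    order_var: str = ""
    tie_policy: str = "midrank"

    def __len__(self) -> int:
        return len(self.rank)


@dataclass
class CIResult:
    """A concentration index with its context.

    value is dimensionless in [-1, 1] for nonnegative variables; mu is the
    weighted mean of the indexed variable in its own units.
    """

    value: float
    mu: float
    n: int
    method: str = "covariance"
    group: Optional[int] = None
    outcome: Optional[str] = None


def _normalize_weights(w: Optional[Sequence[float]], n: int) -> np.ndarray:
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    if w.shape != (n,):
        raise ValueError("weights not aligned with values")
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("weights must sum to a positive total")
    return w / total


def weighted_mean(x: np.ndarray, w: np.ndarray) -> float:
    return float(np.dot(w, x))


def weighted_cov(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted population covariance (denominator = total weight)."""
    mx = np.dot(w, x)
    my = np.dot(w, y)
    return float(np.dot(w, (x - mx) * (y - my)))


def fractional_rank(
    values: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    tie_policy: str = "midrank",
    order_var: str = "",
) -> FractionalRanks:
    """Weighted fractional ranks by ascending value.

    With normalized weights w and observations sorted ascending, unit i gets
    r_i = (sum of weights before i) + w_i/2.  Tied values share the midpoint
    of their group's cumulative-weight interval, which equals the weighted
    mean of the ranks they would occupy without ties and preserves the
    mean-rank-1/2 identity.
    """
    if tie_policy != "midrank":
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise InsufficientDataError("fractional ranks need at least 2 observations")
    if np.isnan(x).any():
        raise ValueError("ranking values must be non-missing")
    w = _normalize_weights(weights, len(x))
    if np.all(x == x[0]):
        raise RankingDegenerateError(
            f"all values of {order_var or 'ranking variable'} identical"
        )
    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    # cumulative weight interval per tied group; each member gets the midpoint
    ranks_sorted = np.empty(len(x))
    start = 0
    cum = 0.0
    while start < len(x):
        stop = start
        while stop < len(x) and xs[stop] == xs[start]:
            stop += 1
        gw = ws[start:stop].sum()
        ranks_sorted[start:stop] = cum + gw / 2.0
        cum += gw
        start = stop
    ranks = np.empty(len(x))
    ranks[order] = ranks_sorted
    return FractionalRanks(rank=ranks, order_var=order_var, tie_policy=tie_policy)


def concentration_index(
    h: Sequence[float],
    ranks: FractionalRanks,
    weights: Optional[Sequence[float]] = None,
    method: str = "covariance",
    group: Optional[int] = None,
    outcome: Optional[str] = None,
) -> CIResult:
    """Concentration index of h against the given fractional ranks.

    ``covariance`` evaluates 2*cov_w(h, r)/mu directly; ``convenient_regression``
    recovers the same number as the slope of the weighted least-squares fit of
    2*var_w(r)*h_i/mu on r_i.  Positive values mean h is concentrated among
    higher-ranked (richer) units.
    """
    x = np.asarray(h, dtype=float)
    r = ranks.rank
    if x.shape != r.shape:
        raise ValueError("h not aligned with ranks")
    if len(x) < 3:
        raise InsufficientDataError("concentration index needs at least 3 observations")
    w = _normalize_weights(weights, len(x))
    mu = weighted_mean(x, w)
    if mu == 0:
        raise UndefinedIndexError("mean of the indexed variable is zero")
    if method == "covariance":
        value = 2.0 * weighted_cov(x, r, w) / mu
    elif method == "convenient_regression":
        var_r = weighted_cov(r, r, w)
        lhs = 2.0 * var_r * x / mu
        fit = sm.WLS(lhs, sm.add_constant(r), weights=w).fit()
        value = float(fit.params[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return CIResult(value=value, mu=mu, n=len(x), method=method, group=group,
                    outcome=outcome)


def generalized_ci(
    e: Sequence[float],
    ranks: FractionalRanks,
    weights: Optional[Sequence[float]] = None,
) -> float:
    """Generalized concentration index 2*cov_w(e, r); no mean normalization,
    so it stays defined for zero-mean residuals."""
    x = np.asarray(e, dtype=float)
    if x.shape != ranks.rank.shape:
        raise ValueError("e not aligned with ranks")
    w = _normalize_weights(weights, len(x))
    return 2.0 * weighted_cov(x, ranks.rank, w)


def ci_by_year(
    table: PanelTable,
    outcome: str,
    roles: Optional[VariableRoles] = None,
    method: str = "covariance",
) -> list[CIResult]:
    """One within-year concentration index per calendar year.

    Regions are re-ranked each year by the registry's ranking variable, so a
    region's socio-economic position may move across years.  Years where the
    index is undefined (degenerate ranking, zero mean, too few rows) are
    skipped and logged.
    """
    roles = roles or table.roles
    results: list[CIResult] = []
    for year, grp in table.data.groupby(YEAR):
        sub = grp.dropna(subset=[outcome, roles.rank_var])
        try:
            ranks = fractional_rank(
                sub[roles.rank_var].to_numpy(dtype=float),
                weights=sub[WEIGHT].to_numpy(dtype=float),
                order_var=roles.rank_var,
            )
            res = concentration_index(
                sub[outcome].to_numpy(dtype=float),
                ranks,
                weights=sub[WEIGHT].to_numpy(dtype=float),
                method=method,
                group=int(year),
                outcome=outcome,
            )
        except (ValueError, InsufficientDataError) as exc:
            logger.warning("ci_by_year: skipping %s for %s: %s", year, outcome, exc)
            continue
        results.append(res)
    return results


def ci_results_to_frame(results: Sequence[CIResult]) -> pd.DataFrame:
    """Tabulate CIResults as (year, outcome, ci, mu, n, method)."""
    return pd.DataFrame(
        [
            {"year": r.group, "outcome": r.outcome, "ci": r.value,
             "mu": r.mu, "n": r.n, "method": r.method}
            for r in results
        ]
    )
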