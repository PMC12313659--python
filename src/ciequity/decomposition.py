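"""Decomposition of the concentration index into determinant contributions.

For a linear model y_i = alpha + sum_k beta_k x_ki + eps_i fitted by OLS,
the concentration index of y decomposes exactly as

    C = sum_k (beta_k * xbar_k / mu) * C_k  +  GC_eps / mu,

where C_k is determinant k's own concentration index against the same
socio-economic ranks, beta_k*xbar_k/mu is the elasticity of y with respect
to k at the means, and GC_eps is the generalized concentration index of the
residual.  Each product elasticity*C_k is determinant k's contribution to
the inequality in y; the residual term is the part the model leaves
unexplained and should be near zero under correct specification.

Contribution rates normalize contributions by the sum of their absolute
values so the rates always total 100% in magnitude — including when the
overall CI is zero, where the traditional contribution/total ratio blows
up.  The contribution's sign is carried onto the normalized magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .concentration import (
    CIResult,
    concentration_index,
    fractional_rank,
    generalized_ci,
    weighted_cov,
    weighted_mean,
)
from .panel_io import REGION, WEIGHT, YEAR, PanelTable, VariableRoles
from .standardization import _check_collinearity, _complete_rows

import logging

logger = logging.getLogger("ciequity")


class UndefinedRatesError(ValueError):
    """All contributions are zero; rates are undefined."""


@dataclass
class DecompositionRow:
    """One determinant's share of the outcome's concentration index."""

    determinant: str
    role: str                      # "need" | "non_need" | "year_effect"
    beta: float                    # outcome units per determinant unit
    beta_se: float                 # standard error of beta under the chosen cov
    mean_x: float                  # determinant units
    elasticity: float              # beta*mean_x/mu, dimensionless
    det_ci: float                  # determinant's own CI (NaN if mean_x == 0)
    contribution: float            # elasticity * det_ci
    cr_signed: float = float("nan")   # % with the contribution's sign
    cr_abs: float = float("nan")      # |contribution|/sum|contribution| * 100
    degenerate: bool = False       # constant determinant, excluded from fit


@dataclass
class DecompositionResult:
    outcome: str
    total_ci: CIResult
    rows: list[DecompositionRow]
    residual_contribution: float   # GC_eps / mu
    explained_ci: float            # sum of contributions
    r_squared: float
    f_stat: float
    f_pvalue: float
    n_obs: int
    cr_denominator: str = "determinants_only"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "outcome": self.outcome,
                    "determinant": r.determinant,
                    "role": r.role,
                    "beta": r.beta,
                    "beta_se": r.beta_se,
                    "mean_x": r.mean_x,
                    "elasticity": r.elasticity,
                    "det_ci": r.det_ci,
                    "contribution": r.contribution,
                    "cr_signed": r.cr_signed,
                    "cr_abs": r.cr_abs,
                    "degenerate": r.degenerate,
                }
                for r in self.rows
            ]
        )


def decompose_ci(
    table: PanelTable,
    outcome: str,
    roles: Optional[VariableRoles] = None,
    year_effects: bool = False,
    cluster_by_region: bool = False,
    cr_denominator: str = "determinants_only",
) -> DecompositionResult:
    """Pooled OLS decomposition of the outcome's concentration index.

    All region-years are pooled with a single fractional ranking by the
    registry's ranking variable, consistent with the pooled regression.
    Constant determinants cannot enter the fit (they are collinear with the
    intercept); they are reported with zero contribution and a degenerate
    flag.  ``year_effects`` adds year-dummy regressors whose contributions
    are reported as extra rows so the adding-up identity still closes.
    Clustered (by region) covariance for the F test is optional; the point
    decomposition is unaffected.
    """
    roles = roles or table.roles
    determinants = list(roles.determinants)
    cols = [outcome] + determinants + [roles.rank_var]
    used = _complete_rows(table.data, cols)
    if len(used) < len(determinants) + 2:
        raise ValueError(
            f"need at least {len(determinants) + 2} complete rows, have {len(used)}"
        )
    w = used[WEIGHT].to_numpy(dtype=float)
    wn = w / w.sum()
    ranks = fractional_rank(
        used[roles.rank_var].to_numpy(dtype=float), weights=w,
        order_var=roles.rank_var,
    )
    y = used[outcome].to_numpy(dtype=float)
    mu = weighted_mean(y, wn)
    total = concentration_index(y, ranks, weights=w, outcome=outcome)

    role_of = {v: ("need" if v in roles.need else "non_need") for v in determinants}
    active = [v for v in determinants if used[v].nunique() > 1]
    degenerate = [v for v in determinants if v not in active]
    for v in degenerate:
        logger.warning("decompose_ci: determinant %s is constant; contribution 0", v)

    names = list(active)
    X = used[names].to_numpy(dtype=float)
    if year_effects:
        years = sorted(used[YEAR].unique())
        for yr in years[1:]:
            names.append(f"year_{yr}")
            X = np.column_stack([X, (used[YEAR] == yr).to_numpy(dtype=float)])
            role_of[f"year_{yr}"] = "year_effect"
    _check_collinearity(np.column_stack([np.ones(len(X)), X]), ["const"] + names)
    if cluster_by_region:
        fit = sm.WLS(y, sm.add_constant(X), weights=w).fit(
            cov_type="cluster", cov_kwds={"groups": used[REGION]}
        )
    else:
        fit = sm.WLS(y, sm.add_constant(X), weights=w).fit()
    betas = dict(zip(names, fit.params[1:]))
    beta_ses = dict(zip(names, fit.bse[1:]))
    resid = y - fit.fittedvalues

    rows: list[DecompositionRow] = []
    for name in names + degenerate:
        if name in degenerate:
            xbar = weighted_mean(used[name].to_numpy(dtype=float), wn)
            rows.append(
                DecompositionRow(
                    determinant=name, role=role_of[name], beta=float("nan"),
                    beta_se=float("nan"), mean_x=xbar, elasticity=0.0,
                    det_ci=float("nan"), contribution=0.0, degenerate=True,
                )
            )
            continue
        xk = (
            used[name].to_numpy(dtype=float)
            if name in used.columns
            else X[:, names.index(name)]
        )
        xbar = weighted_mean(xk, wn)
        gc_k = 2.0 * weighted_cov(xk, ranks.rank, wn)
        beta = float(betas[name])
        # contribution beta*xbar*C_k/mu written as beta*GC_k/mu so it stays
        # defined when xbar == 0 (the xbar in C_k's denominator cancels)
        contribution = beta * gc_k / mu
        det_ci = gc_k / xbar if xbar != 0 else float("nan")
        rows.append(
            DecompositionRow(
                determinant=name, role=role_of[name], beta=beta,
                beta_se=float(beta_ses[name]), mean_x=xbar,
                elasticity=beta * xbar / mu, det_ci=det_ci,
                contribution=contribution,
            )
        )
    residual_contribution = generalized_ci(resid, ranks, weights=w) / mu
    explained = float(sum(r.contribution for r in rows))
    gap = explained + residual_contribution - total.value
    if abs(gap) > 1e-8 * max(1.0, abs(total.value)):
        raise AssertionError(f"adding-up identity violated by {gap:.3e}")
    result = DecompositionResult(
        outcome=outcome, total_ci=total, rows=rows,
        residual_contribution=residual_contribution, explained_ci=explained,
        r_squared=float(fit.rsquared), f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue), n_obs=int(fit.nobs),
        cr_denominator=cr_denominator,
    )
    try:
        result = contribution_rates(result, denominator=cr_denominator)
    except UndefinedRatesError:
        logger.warning("decompose_ci: all contributions zero; rates left NaN")
    return result


def contribution_rates(
    result: DecompositionResult,
    denominator: str = "determinants_only",
) -> DecompositionResult:
    """Normalize contributions by the sum of absolute contributions.

    cr_abs_k = |contribution_k| / sum|contribution| * 100, so the magnitudes
    always total 100%; cr_signed carries the contribution's sign onto the
    magnitude.  ``include_residual`` adds |residual contribution| to the
    denominator, in which case determinant magnitudes total less than 100%
    whenever the residual is nonzero.
    """
    if denominator not in ("determinants_only", "include_residual"):
        raise ValueError(f"unknown denominator {denominator!r}")
    total_abs = sum(abs(r.contribution) for r in result.rows)
    if denominator == "include_residual":
        total_abs += abs(result.residual_contribution)
    if total_abs == 0:
        raise UndefinedRatesError("all contributions are zero")
    rows = [
        replace(
            r,
            cr_abs=abs(r.contribution) / total_abs * 100.0,
            cr_signed=float(np.sign(r.contribution)) * abs(r.contribution)
            / total_abs * 100.0,
        )
        for r in result.rows
    ]
    return replace(result, rows=rows, cr_denominator=denominator)


def legacy_contribution_rates(result: DecompositionResult) -> pd.DataFrame:
    """Traditional rates contribution_k / total_CI * 100, for comparison.

    These can exceed +/-100% and are undefined when the total CI is zero —
    the failure mode the absolute-sum normalization avoids.
    """
    if result.total_ci.value == 0:
        raise ZeroDivisionError(
            "total concentration index is zero; legacy rates undefined"
        )
    return pd.DataFrame(
        [
            {
                "determinant": r.determinant,
                "cr_legacy": r.contribution / result.total_ci.value * 100.0,
            }
            for r in result.rows
        ]
    )
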