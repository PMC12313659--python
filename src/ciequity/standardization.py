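"""Indirect need-standardization and the need-standardized CI (ISCI).

The outcome is regressed on need variables x_j (what legitimately drives
healthcare demand) while controlling for non-need variables z_k:

    y_i = alpha + sum_j beta_j x_ji + sum_k gamma_k z_ki + eps_i   (OLS)

The need-expected outcome holds every non-need variable at its sample mean,

    yhat^x_i = alpha + sum_j beta_j x_ji + sum_k gamma_k zbar_k,

and the indirectly standardized outcome recentres actual-minus-expected by
the sample mean, yhat^IS_i = y_i - yhat^x_i + ybar.  The concentration index
of yhat^IS (computed with the same socio-economic ranks as the raw CI) is
the ISCI: the inequality left after equal-need adjustment, i.e. horizontal
inequity attributable to socio-economic position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

from .concentration import CIResult, FractionalRanks, concentration_index, fractional_rank
from .panel_io import WEIGHT, YEAR, PanelTable, VariableRoles

import logging

logger = logging.getLogger("ciequity")


class CollinearityError(ValueError):
    """The regression design is rank deficient."""


@dataclass
class StandardizationModel:
    """A fitted need/non-need OLS with what standardization needs to reuse."""

    outcome: str
    intercept: float
    need_coefs: dict[str, float]
    non_need_coefs: dict[str, float]
    non_need_means: dict[str, float]
    y_bar: float
    r_squared: float
    f_stat: float
    f_pvalue: float
    n_obs: int
    row_index: pd.Index = field(repr=False, default=None)


@dataclass
class StandardizedOutcome:
    """Need-expected and indirectly standardized outcomes plus their ISCI."""

    y_expected: pd.Series
    y_standardized: pd.Series
    y_bar: float
    isci: CIResult


def _check_collinearity(X: np.ndarray, names: list[str]) -> None:
    """Raise CollinearityError naming dependent columns (QR with pivoting)."""
    rank = np.linalg.matrix_rank(X)
    if rank >= X.shape[1]:
        return
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.max() > 0 else 0.0
    bad = [names[piv[j]] for j in range(len(names)) if j >= rank or diag[j] <= tol]
    raise CollinearityError(f"collinear regressor columns: {sorted(set(bad))}")


def _complete_rows(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    return df.dropna(subset=cols)


def fit_standardization(
    table: PanelTable,
    outcome: str,
    roles: Optional[VariableRoles] = None,
    year: Optional[int] = None,
) -> StandardizationModel:
    """OLS of the outcome on need + non-need variables.

    Rows with any missing regressor or outcome are dropped (listwise) and
    counted; pass ``year`` to restrict the fit to one cross-section.
    """
    roles = roles or table.roles
    df = table.data if year is None else table.data[table.data[YEAR] == year]
    cols = [outcome] + roles.need + roles.non_need
    used = _complete_rows(df, cols)
    dropped = len(df) - len(used)
    if dropped:
        logger.info("fit_standardization: dropped %d incomplete rows", dropped)
    k = len(roles.need) + len(roles.non_need)
    if len(used) < k + 2:
        raise ValueError(
            f"need at least {k + 2} complete rows to fit, have {len(used)}"
        )
    names = roles.need + roles.non_need
    X = used[names].to_numpy(dtype=float)
    _check_collinearity(np.column_stack([np.ones(len(X)), X]), ["const"] + names)
    y = used[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = dict(zip(names, fit.params[1:]))
    return StandardizationModel(
        outcome=outcome,
        intercept=float(fit.params[0]),
        need_coefs={v: float(coefs[v]) for v in roles.need},
        non_need_coefs={v: float(coefs[v]) for v in roles.non_need},
        non_need_means={v: float(used[v].mean()) for v in roles.non_need},
        y_bar=float(np.mean(y)),
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue) if k else float("nan"),
        f_pvalue=float(fit.f_pvalue) if k else float("nan"),
        n_obs=int(fit.nobs),
        row_index=used.index,
    )


def standardize(
    table: PanelTable,
    model: StandardizationModel,
    outcome: Optional[str] = None,
    roles: Optional[VariableRoles] = None,
    ranks: Optional[FractionalRanks] = None,
) -> StandardizedOutcome:
    """Apply a fitted model to produce yhat^x, yhat^IS and the ISCI.

    The rows used are the model's fitting rows, so the recentring identity
    mean(yhat^IS) = mean(y) holds exactly (OLS residuals average zero).
    The ISCI uses the same ranking variable (and weights) as the raw CI;
    precomputed ranks may be passed to guarantee rank reuse.
    """
    roles = roles or table.roles
    outcome = outcome or model.outcome
    used = table.data.loc[model.row_index]
    need_part = sum(
        b * used[v].to_numpy(dtype=float) for v, b in model.need_coefs.items()
    )
    z_part = sum(
        g * model.non_need_means[v] for v, g in model.non_need_coefs.items()
    )
    y_expected = model.intercept + need_part + z_part
    y = used[outcome].to_numpy(dtype=float)
    y_is = y - y_expected + model.y_bar
    w = used[WEIGHT].to_numpy(dtype=float)
    if ranks is None:
        ranks = fractional_rank(
            used[roles.rank_var].to_numpy(dtype=float), weights=w,
            order_var=roles.rank_var,
        )
    isci = concentration_index(y_is, ranks, weights=w, outcome=outcome)
    return StandardizedOutcome(
        y_expected=pd.Series(y_expected, index=used.index),
        y_standardized=pd.Series(y_is, index=used.index),
        y_bar=model.y_bar,
        isci=isci,
    )


def isci_by_year(
    table: PanelTable,
    outcome: str,
    roles: Optional[VariableRoles] = None,
    pooled_fit: bool = False,
) -> pd.DataFrame:
    """Per-year CI, ISCI and the horizontal-inequity difference CI - CI(yhat^x).

    By default the standardization regression is refit within each year, so
    each year's ISCI reflects contemporaneous need-outcome relationships;
    ``pooled_fit`` fits once on all years and standardizes each year with the
    pooled coefficients (non-need means then also pooled).  Years whose fit
    or index fails are skipped and logged.
    """
    roles = roles or table.roles
    pooled_model = (
        fit_standardization(table, outcome, roles) if pooled_fit else None
    )
    rows = []
    for year in table.years:
        try:
            if pooled_fit:
                model = pooled_model
                # restrict application rows to this year's fitting-eligible rows
                df = table.data[table.data[YEAR] == year]
                cols = [outcome] + roles.need + roles.non_need + [roles.rank_var]
                used_idx = _complete_rows(df, cols).index
                model = StandardizationModel(
                    **{**model.__dict__, "row_index": used_idx}
                )
            else:
                model = fit_standardization(table, outcome, roles, year=year)
            used = table.data.loc[model.row_index]
            w = used[WEIGHT].to_numpy(dtype=float)
            ranks = fractional_rank(
                used[roles.rank_var].to_numpy(dtype=float), weights=w,
                order_var=roles.rank_var,
            )
            std = standardize(table, model, outcome, roles, ranks=ranks)
            ci = concentration_index(
                used[outcome].to_numpy(dtype=float), ranks, weights=w,
                group=int(year), outcome=outcome,
            )
            ci_expected = concentration_index(
                std.y_expected.to_numpy(dtype=float), ranks, weights=w,
            )
            rows.append(
                {
                    "year": int(year),
                    "outcome": outcome,
                    "ci": ci.value,
                    "isci": std.isci.value,
                    "hi_difference": ci.value - ci_expected.value,
                    "n_used": len(used),
                }
            )
        except ValueError as exc:
            logger.warning("isci_by_year: skipping %s for %s: %s", year, outcome, exc)
    return pd.DataFrame(rows, columns=["year", "outcome", "ci", "isci",
                                       "hi_difference", "n_used"])
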