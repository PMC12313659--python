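"""Reading, validation, cleaning and writing of region-year panel tables.

A panel table holds one row per (region, year) with numeric columns for the
registered variables (outcomes, need, non-need, socio-economic ranking
variable) and an optional nonnegative observation weight.  Cleaning follows
the usual yearbook-data screen: cross-sectional IQR winsorization within each
variable x year group, within-region time-series imputation, and rule-based
consistency reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("ciequity")

REGION = "region"
YEAR = "year"
WEIGHT = "weight"

#: strings treated as missing on input
NA_VALUES = ["", "NA"]


class PanelError(Exception):
    """Base class for panel-table errors."""


class StructuralError(PanelError):
    """The table violates a structural invariant (duplicates, bad year...)."""


class RegistryError(PanelError):
    """A registered variable does not resolve to a column."""


class VariableTypeError(PanelError):
    """A registered variable is not numeric where a numeric one is required."""


@dataclass
class VariableRoles:
    """Registry mapping variable names to their role in the analysis.

    Parameters
    ----------
    outcomes
        Resource-allocation variables whose inequality is measured
        (e.g. institutions/beds/doctors/technicians/nurses per 1,000 people).
    need
        Legitimate drivers of healthcare demand (population size/density,
        maternal and perinatal mortality, low-birth-weight rate).
    non_need
        Socio-economic determinants whose association with resources is
        read as inequitable (income, expenditure, urbanization, ...).
    rank_var
        The variable that orders regions by socio-economic position
        (conventionally per-capita GDP).
    categorical
        Optional encodings, ``{column: {label: code}}``, applied at read
        time so every registered column is numeric downstream (e.g.
        geographic location east=1, central=2, west=3).
    """

    outcomes: list[str]
    need: list[str]
    non_need: list[str]
    rank_var: str
    categorical: dict[str, dict[str, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rank_var in self.outcomes:
            raise RegistryError(f"rank_var {self.rank_var!r} may not be an outcome")
        sets = {
            "outcomes": set(self.outcomes),
            "need": set(self.need),
            "non_need": set(self.non_need),
        }
        for a in sets:
            for b in sets:
                if a < b and sets[a] & sets[b]:
                    raise RegistryError(
                        f"variable sets {a} and {b} overlap: {sorted(sets[a] & sets[b])}"
                    )

    @property
    def determinants(self) -> list[str]:
        """Need then non-need variables, the regressors of the decomposition."""
        return list(self.need) + list(self.non_need)

    @property
    def all_variables(self) -> list[str]:
        names = self.determinants + list(self.outcomes)
        if self.rank_var not in names:
            names.append(self.rank_var)
        return names

    @classmethod
    def from_yaml(cls, path: str | Path) -> "VariableRoles":
        with open(path, "r", encoding="utf-8") as fh:
            spec = yaml.safe_load(fh)
        return cls(
            outcomes=list(spec["outcomes"]),
            need=list(spec.get("need", [])),
            non_need=list(spec.get("non_need", [])),
            rank_var=spec["rank_var"],
            categorical={k: dict(v) for k, v in (spec.get("categorical") or {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        spec = {
            "outcomes": list(self.outcomes),
            "need": list(self.need),
            "non_need": list(self.non_need),
            "rank_var": self.rank_var,
            "categorical": {k: dict(v) for k, v in self.categorical.items()},
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(spec, fh, sort_keys=False)


@dataclass
class PanelTable:
    """A validated long-format region-year table plus its variable registry.

    ``data`` has columns ``region`` (string label), ``year`` (int),
    ``weight`` (nonnegative float, default 1) and one numeric column per
    registered variable; missing values are NaN.
    """

    data: pd.DataFrame
    roles: VariableRoles

    def __post_init__(self) -> None:
        df = self.data
        for col in (REGION, YEAR):
            if col not in df.columns:
                raise StructuralError(f"panel is missing the {col!r} column")
        if df.duplicated([REGION, YEAR]).any():
            dups = df.loc[df.duplicated([REGION, YEAR]), [REGION, YEAR]]
            raise StructuralError(
                f"duplicate (region, year) rows: {dups.values.tolist()[:5]}"
            )
        missing = [v for v in self.roles.all_variables if v not in df.columns]
        if missing:
            raise RegistryError(f"registered variables missing from table: {missing}")
        if WEIGHT not in df.columns:
            df = df.copy()
            df[WEIGHT] = 1.0
            self.data = df
        w = df[WEIGHT].to_numpy(dtype=float)
        if (w < 0).any():
            raise StructuralError("weights must be nonnegative")
        if not (w > 0).any():
            raise StructuralError("weights must not all be zero")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def years(self) -> list[int]:
        return sorted(self.data[YEAR].unique().tolist())

    @property
    def regions(self) -> list[str]:
        return sorted(self.data[REGION].unique().tolist())

    def replace_data(self, data: pd.DataFrame) -> "PanelTable":
        return PanelTable(data=data, roles=self.roles)


def read_panel(path: str | Path, roles: VariableRoles) -> PanelTable:
    """Read a CSV panel and validate it against the registry.

    Unparseable numeric cells become missing and are counted in the log;
    categorical columns are mapped to their numeric codes.
    """
    df = pd.read_csv(path, na_values=NA_VALUES, keep_default_na=False)
    if YEAR not in df.columns:
        raise StructuralError("panel file has no 'year' column")
    try:
        df[YEAR] = df[YEAR].astype(int)
    except (ValueError, TypeError) as exc:
        raise StructuralError(f"year column not parseable as integer: {exc}") from exc
    df[REGION] = df[REGION].astype(str)

    n_coerced = 0
    for name in roles.all_variables:
        if name not in df.columns:
            continue  # caught by PanelTable validation with a clear message
        if name in roles.categorical:
            col = df[name]
            if not pd.api.types.is_numeric_dtype(col):
                df[name] = col.map(roles.categorical[name]).astype(float)
            continue
        before = df[name].notna().sum()
        df[name] = pd.to_numeric(df[name], errors="coerce")
        n_coerced += int(before - df[name].notna().sum())
    if n_coerced:
        logger.warning("read_panel: %d non-numeric cells set to missing", n_coerced)
    return PanelTable(data=df, roles=roles)


def write_panel(table: PanelTable, path: str | Path) -> None:
    """Write the panel back to CSV (missing values as empty cells)."""
    table.data.to_csv(path, index=False, na_rep="")


# ---------------------------------------------------------------------------
# Cleaning: IQR winsorization


def iqr_outlier_correct(
    table: PanelTable,
    variables: Sequence[str] | None = None,
    k: float = 1.5,
) -> tuple[PanelTable, pd.DataFrame]:
    """Winsorize per-variable, per-year outliers to the Tukey fences.

    Within each variable x year group the fences are
    ``[Q1 - k*IQR, Q3 + k*IQR]`` with linear-interpolation ("type 7")
    quartiles; values strictly outside are set to the nearer fence.  Groups
    with fewer than 4 non-missing values are skipped with a warning.

    Returns the corrected table and a log with one row per corrected cell
    (region, year, variable, old, new).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if variables is None:
        variables = table.roles.all_variables
    df = table.data.copy()
    records: list[dict] = []
    for name in variables:
        if not pd.api.types.is_numeric_dtype(df[name]):
            raise VariableTypeError(f"variable {name!r} is not numeric")
        for year, grp in df.groupby(YEAR):
            vals = grp[name]
            ok = vals.notna()
            if ok.sum() < 4:
                logger.warning(
                    "iqr_outlier_correct: skipping %s in %s (<4 values)", name, year
                )
                continue
            q1, q3 = np.quantile(vals[ok].to_numpy(dtype=float), [0.25, 0.75])
            lo, hi = q1 - k * (q3 - q1), q3 + k * (q3 - q1)
            for idx in grp.index[ok]:
                old = df.at[idx, name]
                if old < lo or old > hi:
                    new = lo if old < lo else hi
                    df.at[idx, name] = new
                    records.append(
                        {
                            REGION: df.at[idx, REGION],
                            YEAR: year,
                            "variable": name,
                            "old": old,
                            "new": new,
                        }
                    )
    log = pd.DataFrame(records, columns=[REGION, YEAR, "variable", "old", "new"])
    return table.replace_data(df), log


# ---------------------------------------------------------------------------
# Cleaning: imputation


def impute_missing(
    table: PanelTable,
    variable: str,
    method: str = "linear_interpolation",
) -> tuple[PanelTable, pd.DataFrame]:
    """Fill interior gaps in each region's time series for one variable.

    ``linear_interpolation`` interpolates on the year axis;
    ``neighbor_mean`` fills a gap with the mean of the nearest non-missing
    earlier and later years (a deterministic stand-in for donor-based
    predictive mean matching) and records the relative fluctuation against
    the earlier neighbor, mirroring the adjacent-year validation screen.
    Leading/trailing gaps are never extrapolated; they are logged as left
    missing.  Non-missing cells are never altered.
    """
    if variable not in table.data.columns:
        raise RegistryError(f"variable {variable!r} not in table")
    if method not in ("linear_interpolation", "neighbor_mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    df = table.data.copy()
    records: list[dict] = []
    for region, grp in df.groupby(REGION):
        grp = grp.sort_values(YEAR)
        series = pd.Series(grp[variable].to_numpy(dtype=float), index=grp[YEAR])
        if series.isna().all():
            logger.warning(
                "impute_missing: %s entirely missing for %s; left as is", variable, region
            )
            records.append(
                {REGION: region, YEAR: None, "variable": variable,
                 "value": np.nan, "status": "all_missing", "fluctuation": np.nan}
            )
            continue
        if method == "linear_interpolation":
            filled = series.interpolate(method="index", limit_area="inside")
        else:
            filled = series.copy()
            prev = series.ffill()
            nxt = series.bfill()
            interior = series.isna() & prev.notna() & nxt.notna()
            filled[interior] = (prev[interior] + nxt[interior]) / 2.0
        for year in series.index[series.isna()]:
            if pd.isna(filled.loc[year]):
                records.append(
                    {REGION: region, YEAR: int(year), "variable": variable,
                     "value": np.nan, "status": "left_missing", "fluctuation": np.nan}
                )
            else:
                prev_vals = series.loc[: year - 1].dropna()
                fluct = (
                    abs(filled.loc[year] - prev_vals.iloc[-1]) / abs(prev_vals.iloc[-1])
                    if len(prev_vals) and prev_vals.iloc[-1] != 0
                    else np.nan
                )
                records.append(
                    {REGION: region, YEAR: int(year), "variable": variable,
                     "value": filled.loc[year], "status": "imputed", "fluctuation": fluct}
                )
        df.loc[grp.index, variable] = filled.to_numpy()
    log = pd.DataFrame(
        records, columns=[REGION, YEAR, "variable", "value", "status", "fluctuation"]
    )
    return table.replace_data(df), log


# ---------------------------------------------------------------------------
# Quality control: consistency rules


_RELATIONS = {
    "<=": np.less_equal,
    "<": np.less,
    ">=": np.greater_equal,
    ">": np.greater,
    "==": np.equal,
}


def consistency_check(
    table: PanelTable,
    rules: Iterable[tuple[str, str, str] | tuple[str, str, str, float]],
) -> pd.DataFrame:
    """Report rows violating cross-variable rules; the data are not mutated.

    Each rule is ``(lhs, relation, rhs)`` or ``(lhs, relation, rhs, factor)``
    asserting ``lhs relation factor*rhs`` row-wise, e.g.
    ``("BPK", "<=", "IPK", 1000.0)`` to cap beds by institution capacity.
    Rows where either side is missing are not reported.
    """
    df = table.data
    records: list[dict] = []
    for rule in rules:
        lhs, rel, rhs, *rest = rule
        factor = float(rest[0]) if rest else 1.0
        for col in (lhs, rhs):
            if col not in df.columns:
                raise RegistryError(f"consistency rule references unknown column {col!r}")
        fn = _RELATIONS.get(rel)
        if fn is None:
            raise ValueError(f"unknown relation {rel!r}")
        a = df[lhs].to_numpy(dtype=float)
        b = factor * df[rhs].to_numpy(dtype=float)
        bad = ~fn(a, b) & ~np.isnan(a) & ~np.isnan(b)
        for idx in df.index[bad]:
            records.append(
                {
                    REGION: df.at[idx, REGION],
                    YEAR: df.at[idx, YEAR],
                    "rule": f"{lhs} {rel} {factor}*{rhs}",
                    "lhs_value": df.at[idx, lhs],
                    "rhs_value": factor * df.at[idx, rhs],
                }
            )
    return pd.DataFrame(
        records, columns=[REGION, YEAR, "rule", "lhs_value", "rhs_value"]
    )
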