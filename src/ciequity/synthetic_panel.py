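"""Synthetic province-year panels with known generative structure.

The generator emulates the statistical shape the equity analysis assumes:
~31 regions observed over ~13 years; a right-skewed socio-economic ranking
variable (log-normal per-capita GDP with persistent region effects and mild
growth); continuous determinants built as monotone mixtures of the pooled
socio-economic rank and independent noise, with the mixing weight tuned by
bisection so each determinant's realized concentration index hits a target
derived from its rank association; a reversed-tercile geographic code (less
developed regions get the higher code, so its CI is negative); and a linear
outcome with known coefficients and controllable noise.  Ground truth
(coefficients and realized concentration indices) is returned alongside the
panel so parameter-recovery and adding-up tests can run without external
data.

The module also packages, as an in-repo fixture, the published 31-province
table of healthcare resource levels (institutions/beds/doctors/technicians/
nurses per 1,000 people) for 2009, 2013, 2017 and 2021, together with the
national-average and rise-rate arithmetic reported with it.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .concentration import FractionalRanks, fractional_rank, weighted_cov
from .panel_io import REGION, WEIGHT, YEAR, PanelTable, VariableRoles


class CalibrationWarning(UserWarning):
    """A determinant's realized CI missed its target beyond tolerance."""


#: determinants conventionally treated as need variables
NEED_VARS = ("PS", "PD", "MMR", "RBWL25", "PMR")

#: scale mapping rank_assoc in [-1, 1] to a target concentration index
CI_SCALE = 0.3

_DEFAULT_BETA = {
    "PS": 0.4, "PD": -0.3, "MMR": -0.5, "RBWL25": 0.3, "PMR": -0.2,
    "UL": 0.8, "GHE": 0.5, "GL": -0.15,
}
_DEFAULT_RANK_ASSOC = {
    "PS": 0.15, "PD": -0.55, "MMR": -0.70, "RBWL25": 0.27, "PMR": -0.40,
    "UL": 0.35, "GHE": 0.70,
}


@dataclass
class SyntheticPanelConfig:
    """Ground-truth generative parameters for a synthetic panel.

    beta maps determinants to true outcome coefficients; rank_assoc maps
    continuous determinants to a rank association in [-1, 1] whose product
    with CI_SCALE is the determinant's target concentration index.  GL (the
    geographic code) is assigned by reversed rank terciles rather than
    calibrated.  noise_sd is the outcome noise scale; with
    noise_relative=True it is a fraction of the systematic outcome sd.
    """

    n_regions: int = 31
    n_years: int = 13
    first_year: int = 2009
    beta: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_BETA))
    rank_assoc: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_RANK_ASSOC)
    )
    noise_sd: float = 0.1
    noise_relative: bool = True
    gl_levels: int = 3
    seed: int = 0
    year_trend: float = 0.0
    alpha: float = 2.0
    outcome_name: str = "Y"
    rank_var: str = "PCGDP"
    need_vars: tuple[str, ...] = NEED_VARS

    def __post_init__(self) -> None:
        if self.n_regions < 3:
            raise ValueError("n_regions must be >= 3")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for k, a in self.rank_assoc.items():
            if abs(a) > 1:
                raise ValueError(f"rank_assoc[{k!r}]={a} outside [-1, 1]")

    def roles(self) -> VariableRoles:
        need = [k for k in self.beta if k in self.need_vars]
        non_need = [k for k in self.beta if k not in self.need_vars]
        return VariableRoles(
            outcomes=[self.outcome_name], need=need, non_need=non_need,
            rank_var=self.rank_var,
        )


@dataclass
class GroundTruth:
    """What the generator actually produced, for recovery testing."""

    alpha: float
    beta: dict[str, float]
    noise_sd_abs: float
    target_det_ci: dict[str, float]
    realized_det_ci: dict[str, float]
    realized_total_ci: float
    rank_var_ci: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "determinant": k,
                    "beta": self.beta[k],
                    "target_ci": self.target_det_ci.get(k, np.nan),
                    "realized_ci": self.realized_det_ci[k],
                }
                for k in self.beta
            ]
        )


def _realized_ci(x: np.ndarray, ranks: np.ndarray) -> float:
    n = len(x)
    w = np.full(n, 1.0 / n)
    return 2.0 * weighted_cov(x, ranks, w) / float(x.mean())

_NOISE_MIX = 0.15  # sd of a determinant's idiosyncratic part, relative to its mean


def _calibrated_determinant(
    rng: np.random.Generator,
    ranks: np.ndarray,
    target_ci: float,
    tol: float = 0.02,
    name: str = "",
) -> tuple[np.ndarray, float]:
    """Monotone rank mixture 1 + a*(rank - 1/2) + noise, a tuned by bisection
    on the realized (same-draw) concentration index."""
    eps = rng.standard_normal(len(ranks))

    def build(a: float) -> np.ndarray:
        return np.clip(1.0 + a * (ranks - 0.5) + _NOISE_MIX * eps, 0.05, None)

    lo, hi = -6.0, 6.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _realized_ci(build(mid), ranks) < target_ci:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    x = build(a)
    achieved = _realized_ci(x, ranks)
    if abs(achieved - target_ci) > tol:
        warnings.warn(
            f"determinant {name or '?'}: realized CI {achieved:.4f} missed "
            f"target {target_ci:.4f} beyond +/-{tol}",
            CalibrationWarning,
            stacklevel=2,
        )
    return x, achieved


def generate_panel(
    config: SyntheticPanelConfig | None = None,
) -> tuple[PanelTable, GroundTruth]:
    """Generate a region-year panel plus its ground truth; seed-reproducible."""
    cfg = config or SyntheticPanelConfig()
    rng = np.random.default_rng(cfg.seed)
    regions = [f"R{i:02d}" for i in range(1, cfg.n_regions + 1)]
    years = list(range(cfg.first_year, cfg.first_year + cfg.n_years))
    idx = pd.MultiIndex.from_product(
        [regions, years], names=[REGION, YEAR]
    ).to_frame(index=False)
    n = len(idx)

    # socio-economic ranking variable: log-normal, persistent region effects,
    # mild common growth so re-ranking is stable but not frozen
    u_region = rng.normal(0.0, 0.4, cfg.n_regions)
    u = np.repeat(u_region, cfg.n_years)
    t = np.tile(np.arange(cfg.n_years), cfg.n_regions)
    pcgdp = np.exp(1.0 + 0.05 * t + u + rng.normal(0.0, 0.15, n))
    pooled_ranks = fractional_rank(pcgdp, order_var=cfg.rank_var).rank

    data = idx.copy()
    data[cfg.rank_var] = pcgdp
    target_ci: dict[str, float] = {}
    realized_ci: dict[str, float] = {}
    for name in cfg.beta:
        if name == "GL":
            order = np.argsort(np.argsort(-u_region))  # 0 = richest region
            codes = 1 + (order * cfg.gl_levels) // cfg.n_regions
            data[name] = np.repeat(codes.astype(float), cfg.n_years)
            realized_ci[name] = _realized_ci(data[name].to_numpy(), pooled_ranks)
            continue
        tci = cfg.rank_assoc.get(name, 0.0) * CI_SCALE
        x, achieved = _calibrated_determinant(rng, pooled_ranks, tci, name=name)
        data[name] = x
        target_ci[name] = tci
        realized_ci[name] = achieved

    X = data[list(cfg.beta)].to_numpy(dtype=float)
    betas = np.array([cfg.beta[k] for k in cfg.beta])
    systematic = cfg.alpha + X @ betas + cfg.year_trend * t
    sd = cfg.noise_sd * float(systematic.std()) if cfg.noise_relative else cfg.noise_sd
    y = systematic + rng.normal(0.0, sd, n) if sd > 0 else systematic
    data[cfg.outcome_name] = y
    data[WEIGHT] = 1.0

    truth = GroundTruth(
        alpha=cfg.alpha,
        beta=dict(cfg.beta),
        noise_sd_abs=sd,
        target_det_ci=target_ci,
        realized_det_ci=realized_ci,
        realized_total_ci=_realized_ci(y, pooled_ranks),
        rank_var_ci=_realized_ci(pcgdp, pooled_ranks),
    )
    return PanelTable(data=data, roles=cfg.roles()), truth


# ---------------------------------------------------------------------------
# Published 31-province fixture (2009/2013/2017/2021)

# Values per province: IPK, BPK, DPK, TPK, NPK for 2009, 2013, 2017, 2021.
# The source table prints both Shanxi and Shaanxi as "Shanxi"; the second is
# disambiguated here by its standard romanization.
_TABLE2_CSV = """\
region,IPK_2009,IPK_2013,IPK_2017,IPK_2021,BPK_2009,BPK_2013,BPK_2017,BPK_2021,DPK_2009,DPK_2013,DPK_2017,DPK_2021,TPK_2009,TPK_2013,TPK_2017,TPK_2021,NPK_2009,NPK_2013,NPK_2017,NPK_2021
Beijing,0.55,0.46,0.46,0.49,5.13,4.92,5.56,5.95,4.70,5.85,4.10,5.14,12.92,15.46,11.30,13.20,4.95,6.36,4.80,5.67
Tianjin,0.35,0.32,0.36,0.44,3.77,3.92,4.39,5.00,2.59,3.18,2.50,3.77,6.90,8.05,6.50,8.87,2.34,2.95,2.50,3.41
Hebei,1.15,1.07,1.08,1.18,3.31,4.14,5.25,6.11,1.32,2.00,2.00,3.41,3.71,4.44,5.00,7.51,1.04,1.49,2.10,3.02
Shanxi,1.16,1.11,1.15,1.18,4.22,4.76,5.34,6.58,2.02,2.50,2.20,3.26,5.38,5.77,6.30,8.09,1.65,2.12,2.60,3.57
Neimenggu,0.92,0.93,0.96,1.04,3.56,4.81,5.94,6.94,2.48,2.52,2.40,3.51,5.50,6.01,7.10,8.82,1.44,2.12,2.80,3.71
Liaoning,0.80,0.81,0.82,0.78,4.41,5.51,6.83,7.67,1.98,2.44,2.40,3.12,5.32,6.01,6.70,7.90,1.99,2.44,2.90,3.61
Jilin,0.68,0.72,0.77,1.07,3.95,4.84,5.66,7.43,1.94,2.31,2.30,3.68,4.87,5.45,6.20,9.15,1.56,1.97,2.50,4.12
Heilongjiang,0.57,0.56,0.54,0.66,3.83,4.93,6.38,8.34,1.62,2.13,2.00,3.10,4.56,5.49,6.10,7.95,1.45,1.96,2.40,3.43
Shanghai,0.20,0.20,0.21,0.25,4.51,4.73,5.57,6.44,3.46,4.05,2.70,3.38,9.48,10.97,7.70,9.20,3.73,4.74,3.50,4.17
Jiangsu,0.39,0.39,0.40,0.43,3.21,4.64,5.84,6.45,1.50,2.23,2.30,3.21,4.16,5.63,6.80,8.13,1.50,2.29,3.00,3.63
Zhejiang,0.56,0.55,0.57,0.54,3.23,4.18,5.54,5.66,1.98,2.86,2.70,3.56,5.65,7.30,8.10,8.85,1.87,2.75,3.30,3.83
Anhui,0.40,0.41,0.39,0.48,2.85,3.91,4.89,6.72,0.94,1.42,1.60,2.82,3.07,3.66,5.00,7.12,1.03,1.49,2.20,3.29
Fujian,0.73,0.75,0.70,0.69,2.84,4.14,4.66,5.35,1.34,2.00,1.90,2.65,3.74,5.44,5.90,7.03,1.37,2.20,2.60,3.11
Jiangxi,0.77,0.86,0.82,0.81,2.60,3.85,5.06,6.80,1.09,1.46,1.50,2.47,3.25,3.94,5.10,6.77,1.16,1.62,2.30,3.10
Shandong,0.86,0.77,0.79,0.84,4.65,5.03,5.84,6.63,1.54,2.41,2.30,3.37,4.39,6.21,6.90,8.39,1.48,2.50,2.90,3.70
Henan,0.80,0.76,0.74,0.79,3.19,4.57,5.85,7.30,1.01,1.64,1.70,3.01,3.38,4.24,6.10,7.65,1.05,1.60,2.50,3.32
Hubei,0.57,0.61,0.62,0.63,3.27,4.97,6.37,7.44,1.34,1.90,2.10,2.91,4.02,5.01,6.80,7.83,1.42,2.07,3.10,3.68
Hunan,0.86,0.93,0.85,0.84,3.31,4.69,6.59,8.04,1.13,1.78,1.90,2.91,3.62,4.52,6.10,7.64,1.19,1.76,2.50,3.61
Guangdong,0.44,0.45,0.45,0.46,2.68,3.55,4.41,4.64,1.56,2.40,1.90,2.52,5.04,6.32,6.30,6.88,1.83,2.48,2.80,3.17
Guangxi,0.67,0.72,0.70,0.68,2.71,3.97,4.94,6.33,1.02,1.54,1.70,2.62,3.32,4.44,6.20,7.82,1.21,1.75,2.70,3.62
Hainan,0.54,0.56,0.56,0.62,2.72,3.59,4.53,6.02,1.24,1.84,1.90,2.91,4.30,5.29,6.50,7.89,1.73,2.30,3.10,3.77
Chongqing,0.58,0.64,0.64,0.67,3.24,4.96,6.71,7.50,1.00,1.64,1.80,2.87,3.05,4.23,6.20,7.68,0.97,1.65,2.80,3.55
Sichuan,0.89,0.99,0.97,0.96,3.36,5.26,6.79,7.91,1.21,1.90,2.00,2.99,3.37,4.68,6.40,8.04,1.01,1.74,2.80,3.66
Guizhou,0.70,0.83,0.78,0.76,2.76,4.76,6.51,7.71,0.81,1.31,1.70,2.74,2.37,3.64,6.30,8.03,0.78,1.37,2.70,3.68
Yunnan,0.49,0.52,0.51,0.57,3.07,4.48,5.72,7.04,1.12,1.63,1.60,2.68,3.02,4.20,5.90,8.12,1.04,1.59,2.70,3.89
Xizang,1.67,2.16,2.03,1.89,2.86,3.53,4.78,5.37,1.20,1.63,1.70,2.90,3.49,3.67,4.90,7.00,0.69,0.76,1.30,2.13
Shaanxi,0.91,0.99,0.94,0.88,3.61,4.92,6.29,7.20,1.49,1.88,2.00,3.05,4.46,6.04,8.10,9.32,1.42,2.26,3.30,4.03
Gansu,0.99,1.03,1.10,1.03,3.19,4.49,5.58,7.36,1.13,1.65,1.70,2.84,3.38,4.33,5.60,8.07,0.98,1.50,2.20,3.68
Qinghai,1.07,1.04,1.07,1.08,3.45,5.11,6.41,7.10,1.58,2.31,2.20,3.16,4.43,5.66,7.00,8.70,1.44,2.01,2.80,3.59
Ningxia,0.66,0.65,0.63,0.63,3.54,4.76,5.84,5.68,1.70,2.14,2.40,3.11,4.48,5.58,7.30,8.36,1.55,2.09,3.20,3.76
Xinjiang,0.66,0.82,0.77,0.66,4.97,6.06,6.85,7.19,1.79,2.34,2.10,2.73,5.47,6.43,7.10,7.74,1.92,2.05,2.90,3.30
"""

FIXTURE_OUTCOMES = ("IPK", "BPK", "DPK", "TPK", "NPK")
FIXTURE_YEARS = (2009, 2013, 2017, 2021)


def make_table2_fixture() -> PanelTable:
    """The published 31-province resource-level panel as a PanelTable.

    Contains the five per-1,000-people outcome variables for 2009, 2013,
    2017 and 2021 only (no ranking variable or determinants are published at
    province level, so concentration indices cannot be computed from it).
    """
    wide = pd.read_csv(io.StringIO(_TABLE2_CSV))
    long = wide.melt(id_vars=[REGION], var_name="var_year", value_name="value")
    long[["variable", YEAR]] = long["var_year"].str.rsplit("_", n=1, expand=True)
    long[YEAR] = long[YEAR].astype(int)
    data = (
        long.pivot(index=[REGION, YEAR], columns="variable", values="value")
        .reset_index()
    )
    data.columns.name = None
    roles = VariableRoles(
        outcomes=list(FIXTURE_OUTCOMES), need=[], non_need=[], rank_var=REGION,
    )
    # the fixture has no numeric ranking variable; register region as a
    # placeholder so the table validates (rank-based analyses refuse to run)
    return PanelTable(data=data, roles=roles)


def national_average(fixture: PanelTable, outcome: str, year: int) -> float:
    """Unweighted mean over regions, rounded to 2 decimals as printed."""
    df = fixture.data
    if year not in set(df[YEAR]):
        raise ValueError(f"year {year} not in fixture")
    if outcome not in df.columns:
        raise ValueError(f"outcome {outcome!r} not in fixture")
    return round(float(df.loc[df[YEAR] == year, outcome].mean()), 2)


def rise_rate(avg_start: float, avg_end: float) -> float:
    """Percentage growth 100*(end - start)/start, rounded to 2 decimals."""
    if avg_start <= 0:
        raise ValueError("starting average must be positive")
    return round(100.0 * (avg_end - avg_start) / avg_start, 2)
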