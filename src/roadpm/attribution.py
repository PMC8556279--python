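"""From local coefficients to contribution shares and attributable deaths.

The chain: the GTWR local slope of PM2.5 on on-road CO2 per km2 converts a
county-year's emission level into the concentration share attributable to
on-road transportation (a percentage, clamped to [0, 100]); a baseline year
of PM2.5-attributable premature deaths is propagated to other years through
the concentration-change recursion

    MAP_t = MAP_{t-1} * (1 + CPD * (AP_t - AP_{t-1}))

with CPD the fractional change in deaths per 1 ug/m3 of annual PM2.5
(default 0.012); multiplying by the clamped share gives the on-road
attributable deaths and their national percentage. A separate conversion
expresses CO2 masses as passenger-vehicle kilometres (404 g CO2 per mile,
1.61 km per mile).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gtwr import GTWRResults
from .panel_data import CountyPanel, MortalityPanel

__all__ = [
    "ConversionConstants",
    "ContributionSurface",
    "AttributionResult",
    "co2_to_mileage",
    "mileage_per_unit_pm25",
    "contribution",
    "clamp_contribution",
    "propagate_mortality",
    "attributable_deaths",
]


@dataclass(frozen=True)
class ConversionConstants:
    """Passenger-vehicle CO2 emission factors."""

    grams_co2_per_mile: float = 404.0
    km_per_mile: float = 1.61

    def __post_init__(self) -> None:
        if self.grams_co2_per_mile <= 0 or self.km_per_mile <= 0:
            raise ValueError("conversion constants must be strictly positive")


def co2_to_mileage(mass_tons: float, constants: ConversionConstants = ConversionConstants()) -> float:
    """Vehicle-kilometres equivalent to a CO2 mass in metric tons."""
    if mass_tons < 0:
        raise ValueError("CO2 mass must be nonnegative")
    grams = mass_tons * 1e6
    return grams / constants.grams_co2_per_mile * constants.km_per_mile


def mileage_per_unit_pm25(
    beta_total: float, constants: ConversionConstants = ConversionConstants()
) -> float:
    """Billion vehicle-km per km2 associated with 1 ug/m3 of PM2.5.

    ``beta_total`` is the total (direct + indirect) effect of on-road CO2,
    in ug/m3 per (10^6 t CO2/km2). Inverting it and converting the CO2 mass
    to mileage gives the headline mileage-equivalent slope.
    """
    if beta_total <= 0:
        raise ValueError("beta must be positive: association direction undefined")
    gkm_per_million_tons = co2_to_mileage(1e6, constants) / 1e9
    return gkm_per_million_tons / beta_total


@dataclass
class ContributionSurface:
    """Raw and clamped contribution shares per county-year (percent)."""

    df: pd.DataFrame  # columns: county_id, year, con_raw, con_clamped

    def __post_init__(self) -> None:
        need = {"county_id", "year", "con_raw"}
        if not need.issubset(self.df.columns):
            raise ValueError(f"contribution table needs columns {sorted(need)}")

    @property
    def clamped(self) -> pd.Series:
        return self.df["con_clamped"]

    def yearly_mean(self) -> pd.Series:
        return self.df.groupby("year")["con_clamped"].mean()


def contribution(
    gtwr_fit: GTWRResults,
    panel: CountyPanel,
    co2_averaging: str = "yearly",
) -> ContributionSurface:
    """Share of each county-year's PM2.5 attributed to on-road CO2.

    ``con_raw = beta_it * CO2_it / concentration_it * 100`` with the local
    GTWR slope of ``co2_per_km2``. ``co2_averaging="period-mean"`` replaces
    the year-specific emission by the county's study-period mean. The
    clamped column is attached immediately.
    """
    if co2_averaging not in ("yearly", "period-mean"):
        raise ValueError(f"unknown co2_averaging {co2_averaging!r}")
    betas = gtwr_fit.coefficients("co2_per_km2")
    df = panel.df[["county_id", "year", "co2_per_km2", "pm25"]].copy()
    df = df.set_index(["county_id", "year"])
    if not betas.index.isin(df.index).all():
        raise ValueError("GTWR fit and panel are not aligned on (county, year)")
    df = df.loc[betas.index]
    bad = df["pm25"] <= 0
    if bad.any():
        offenders = [f"{c}/{y}" for c, y in df.index[bad][:10]]
        raise ValueError(f"nonpositive PM2.5 concentration at county-years: {offenders}")
    co2 = df["co2_per_km2"]
    if co2_averaging == "period-mean":
        co2 = co2.groupby(level="county_id").transform("mean")
    con = (betas * co2 / df["pm25"] * 100.0).rename("con_raw")
    out = con.reset_index()
    out["con_clamped"] = np.clip(out["con_raw"], 0.0, 100.0)
    return ContributionSurface(out)


def clamp_contribution(surface: ContributionSurface) -> ContributionSurface:
    """Clamp raw shares into [0, 100] percent (idempotent)."""
    df = surface.df.copy()
    df["con_clamped"] = np.clip(df["con_raw"], 0.0, 100.0)
    return ContributionSurface(df)


def propagate_mortality(
    baseline: MortalityPanel,
    panel: CountyPanel,
    cpd: float = 0.012,
    anchor_year: int | None = None,
    level: str = "county",
) -> MortalityPanel:
    """Fill every panel year from the anchor-year death counts.

    Forward years apply ``MAP_t = MAP_{t-1} (1 + CPD dAP)``; years before
    the anchor apply the exact algebraic inverse, so a forward-backward
    round trip reproduces the anchor. ``level="national"`` propagates the
    national total using population-weighted mean concentrations and
    redistributes by the anchor-year county shares.
    """
    if level not in ("county", "national"):
        raise ValueError(f"unknown level {level!r}")
    years = panel.years
    if anchor_year is None:
        if len(baseline.years) != 1:
            raise ValueError("ambiguous anchor year; pass anchor_year explicitly")
        anchor_year = baseline.years[0]
    anchor_year = int(anchor_year)
    if anchor_year not in years:
        raise ValueError(f"anchor year {anchor_year} not in panel years")
    base = baseline.df[baseline.df["year"] == anchor_year].set_index("county_id")["map_deaths"]
    cids = panel.county_ids
    missing = [c for c in cids if c not in base.index]
    if missing:
        raise ValueError(f"baseline missing counties: {missing[:10]}")
    ap = panel.wide("pm25")  # years x counties

    if level == "national":
        w = (
            panel.wide("pop_density_1k_km2")
            if "pop_density_1k_km2" in panel.df.columns
            else None
        )
        ap_nat = (ap * w).sum(axis=1) / w.sum(axis=1) if w is not None else ap.mean(axis=1)
        totals = _propagate_series(
            ap_nat.loc[years].to_numpy(), years.index(anchor_year),
            float(base.loc[cids].sum()), cpd,
        )
        shares = (base.loc[cids] / base.loc[cids].sum()).to_numpy()
        mat = np.outer(totals, shares)
    else:
        ap_arr = ap.loc[years, cids].to_numpy()
        t0 = years.index(anchor_year)
        mat = np.empty_like(ap_arr)
        base_v = base.loc[cids].to_numpy(dtype=float)
        mat[t0] = base_v
        for t in range(t0 + 1, len(years)):
            growth = 1.0 + cpd * (ap_arr[t] - ap_arr[t - 1])
            if (growth <= 0).any():
                raise ValueError(
                    f"degenerate concentration jump between {years[t-1]} and {years[t]}"
                )
            mat[t] = mat[t - 1] * growth
        for t in range(t0 - 1, -1, -1):
            growth = 1.0 + cpd * (ap_arr[t + 1] - ap_arr[t])
            if (growth <= 0).any():
                raise ValueError(
                    f"degenerate concentration jump between {years[t]} and {years[t+1]}"
                )
            mat[t] = mat[t + 1] / growth
    if (mat < 0).any():
        warnings.warn("negative propagated death counts clipped to zero")
        mat = np.clip(mat, 0.0, None)
    rows = []
    for ti, yr in enumerate(years):
        rows.append(pd.DataFrame({"county_id": cids, "year": yr, "map_deaths": mat[ti]}))
    return MortalityPanel(pd.concat(rows, ignore_index=True))


def _propagate_series(ap: np.ndarray, t0: int, anchor_value: float, cpd: float) -> np.ndarray:
    out = np.empty(len(ap))
    out[t0] = anchor_value
    for t in range(t0 + 1, len(ap)):
        g = 1.0 + cpd * (ap[t] - ap[t - 1])
        if g <= 0:
            raise ValueError("degenerate concentration jump in national series")
        out[t] = out[t - 1] * g
    for t in range(t0 - 1, -1, -1):
        g = 1.0 + cpd * (ap[t + 1] - ap[t])
        if g <= 0:
            raise ValueError("degenerate concentration jump in national series")
        out[t] = out[t + 1] / g
    return out


@dataclass
class AttributionResult:
    """County-year and national attribution of deaths to on-road PM2.5."""

    county_year: pd.DataFrame  # county_id, year, map_deaths, mapor_deaths
    yearly: pd.DataFrame  # year, map_total, mapor_total, pta_pct
    pta_pooled_pct: float

    def summary(self) -> str:
        tab = self.yearly.copy()
        lines = [
            "PM2.5 premature-death attribution to on-road transportation",
            tab.to_string(
                index=False,
                formatters={
                    "map_total": lambda v: f"{v:,.0f}",
                    "mapor_total": lambda v: f"{v:,.0f}",
                    "pta_pct": lambda v: f"{v:.2f}",
                },
            ),
            f"pooled share over all years: {self.pta_pooled_pct:.2f}%",
        ]
        return "\n".join(lines)


def attributable_deaths(
    mortality: MortalityPanel, surface: ContributionSurface
) -> AttributionResult:
    """On-road attributable deaths ``MAPOR = MAP * C/100`` and PTA shares.

    The pooled percentage is the ratio of summed attributable to summed
    total deaths across all years — not the mean of the yearly percentages.
    """
    m = mortality.df.set_index(["county_id", "year"])["map_deaths"]
    c = surface.df.set_index(["county_id", "year"])["con_clamped"]
    common = m.index.intersection(c.index)
    if len(common) != len(m) or len(common) != len(c):
        raise ValueError(
            f"mortality ({len(m)}) and contribution ({len(c)}) tables are misaligned; "
            f"{len(common)} county-years in common"
        )
    if (c < 0).any() or (c > 100).any():
        raise ValueError("contribution shares must be clamped to [0, 100]")
    mapor = (m.loc[common] * c.loc[common] / 100.0).rename("mapor_deaths")
    cy = pd.concat([m.loc[common].rename("map_deaths"), mapor], axis=1).reset_index()
    yearly = (
        cy.groupby("year")
        .agg(map_total=("map_deaths", "sum"), mapor_total=("mapor_deaths", "sum"))
        .reset_index()
    )
    yearly["pta_pct"] = np.where(
        yearly["map_total"] > 0, yearly["mapor_total"] / yearly["map_total"] * 100.0, 0.0
    )
    tot_map = float(yearly["map_total"].sum())
    pooled = float(yearly["mapor_total"].sum()) / tot_map * 100.0 if tot_map > 0 else 0.0
    return AttributionResult(county_year=cy, yearly=yearly, pta_pooled_pct=pooled)
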