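"""Synthetic county panels with known spatial structure.

Two data-generating processes are provided, matching the two estimator
families downstream:

* **constant mode** — the combined spatial lag + spatial error panel model
  itself: ``y_t = (I - lam W)^{-1} (X_t beta + alpha + u_t)`` with
  ``u_t = (I - rho W)^{-1} nu_t``, Gaussian innovations and Gaussian county
  fixed effects held constant over time;
* **varying mode** — smooth space-time coefficient surfaces
  ``y_it = b0(x, y, t) + sum_k b_k(x, y, t) x_itk + eps`` for exercising the
  geographically and temporally weighted regression.

Covariates come in two styles: ``realistic`` (on-road CO2 per km2 on the
magnitude observed for U.S. counties, land-cover percentages, population
density, seasonal temperature and humidity) and ``standardized`` (iid
standard-normal columns) for clean parameter-recovery experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .lattice import LatticeGeometry
from .panel_data import CountyPanel, MortalityPanel
from .weights import SpatialWeights

__all__ = [
    "DGPParams",
    "simulate_panel",
    "simulate_baseline_mortality",
    "interpolate_missing_years",
    "make_smooth_surface",
]

#: realistic covariate columns generated for every panel
REALISTIC_COVARIATES = [
    "developed_open_pct",
    "developed_low_pct",
    "developed_medium_pct",
    "developed_high_pct",
    "forest_deciduous_pct",
    "grassland_pct",
    "shrubland_pct",
    "wetland_herbaceous_pct",
    "pop_density_1k_km2",
    "temp_summer_k",
    "temp_winter_k",
    "rh_summer_pct",
    "rh_winter_pct",
]


@dataclass
class DGPParams:
    """Parameters of the synthetic data-generating process.

    Attributes
    ----------
    beta : sequence of float
        True regression coefficients, aligned with ``regressors``.
    regressors : sequence of str
        Covariate columns entering the outcome equation. Names ending in
        ``_pct`` are percentages in [0, 100]; names starting with ``z``
        are generic standardized columns.
    intercept : float
        Baseline outcome level (absorbed into fixed effects in constant
        mode; the true local intercept in varying mode).
    lambda_lag : float
        Spatial lag parameter, in (-1, 1).
    rho_error : float
        Spatial error parameter, in (-1, 1).
    sigma_nu : float
        Idiosyncratic innovation s.d. (>= 0; 0 gives a noise-free panel).
    sigma_alpha : float
        County fixed-effect s.d.
    mode : {"constant", "varying"}
        Constant-coefficient spatial DGP vs smooth varying-coefficient DGP.
    coefficient_surface : callable, optional
        ``surface(x, y, t) -> (n, p+1)`` array of [intercept, betas] rows;
        required meaning only in varying mode (a default smooth surface is
        built when omitted).
    covariate_style : {"realistic", "standardized"}
    seed : int
    """

    beta: Sequence[float] = (0.646,)
    regressors: Sequence[str] = ("co2_per_km2",)
    intercept: float = 8.0
    lambda_lag: float = 0.0
    rho_error: float = 0.0
    sigma_nu: float = 1.0
    sigma_alpha: float = 0.5
    mode: str = "constant"
    coefficient_surface: Callable | None = None
    covariate_style: str = "realistic"
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.regressors):
            raise ValueError("beta and regressors must have equal length")
        if abs(self.lambda_lag) >= 1 or abs(self.rho_error) >= 1:
            raise ValueError("spatial parameters must lie strictly inside (-1, 1)")
        if self.sigma_nu < 0 or self.sigma_alpha < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.mode not in ("constant", "varying"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.covariate_style not in ("realistic", "standardized"):
            raise ValueError(f"unknown covariate_style {self.covariate_style!r}")


def _smooth_field(rng, xn, yn, scale=1.0, n_waves=3):
    """Random smooth surface on the unit square: a small sum of plane waves."""
    out = np.zeros_like(xn)
    for _ in range(n_waves):
        fx, fy = rng.uniform(0.5, 2.5, size=2)
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.3, 1.0)
        out += amp * np.sin(2 * np.pi * fx * xn + phx) * np.cos(2 * np.pi * fy * yn + phy)
    return scale * out / np.sqrt(n_waves)


def _realistic_covariates(rng, geometry: LatticeGeometry, years) -> pd.DataFrame:
    """Spatially smooth, temporally slowly-drifting covariate fields.

    CO2 per km2 is log-normal with county-mean around 4e-3 (units of
    10^6 t/km2, i.e. ~0.4 in the 10^4 t/km2 reporting unit); land covers are
    rescaled shares of positive smooth fields so the percentages sum to at
    most 100; climate variables sit in plausible CONUS ranges.
    """
    n = geometry.n
    cents = geometry.centroids
    ext_x = max(cents[:, 0].max() - cents[:, 0].min(), 1e-9)
    ext_y = max(cents[:, 1].max() - cents[:, 1].min(), 1e-9)
    xn = (cents[:, 0] - cents[:, 0].min()) / ext_x
    yn = (cents[:, 1] - cents[:, 1].min()) / ext_y

    log_co2_base = -5.6 + 1.1 * _smooth_field(rng, xn, yn)  # exp ~= 4e-3
    land_fields = {}
    names = [c for c in REALISTIC_COVARIATES if c.endswith("_pct") and "rh_" not in c]
    raw = []
    for _ in names:
        raw.append(np.exp(0.8 * _smooth_field(rng, xn, yn)))
    raw = np.array(raw)  # (n_classes, n)
    shares = raw / raw.sum(axis=0, keepdims=True) * rng.uniform(55, 85)
    for cname, row in zip(names, shares):
        land_fields[cname] = row
    log_pop = -2.5 + 1.3 * _smooth_field(rng, xn, yn)
    t_sum_base = 296.0 + 4.0 * _smooth_field(rng, xn, yn)
    t_win_base = 275.0 + 6.0 * _smooth_field(rng, xn, yn)
    rh_sum_base = 60.0 + 12.0 * _smooth_field(rng, xn, yn)
    rh_win_base = 65.0 + 10.0 * _smooth_field(rng, xn, yn)

    rows = []
    years = list(years)
    t_span = max(len(years) - 1, 1)
    for ti, year in enumerate(years):
        drift = ti / t_span
        rec = {
            "county_id": geometry.county_ids,
            "year": year,
            "x": cents[:, 0],
            "y": cents[:, 1],
            "co2_per_km2": np.exp(
                log_co2_base + 0.05 * np.sin(2 * np.pi * drift) + rng.normal(0, 0.08, n)
            ),
            "pop_density_1k_km2": np.exp(log_pop + 0.02 * ti + rng.normal(0, 0.05, n)),
            "temp_summer_k": t_sum_base + rng.normal(0, 0.6, n),
            "temp_winter_k": t_win_base + rng.normal(0, 1.0, n),
            "rh_summer_pct": np.clip(rh_sum_base + rng.normal(0, 2.0, n), 5, 95),
            "rh_winter_pct": np.clip(rh_win_base + rng.normal(0, 2.0, n), 5, 95),
        }
        for cname, base in land_fields.items():
            rec[cname] = np.clip(base + rng.normal(0, 0.25, n), 0.0, 100.0)
        rows.append(pd.DataFrame(rec))
    return pd.concat(rows, ignore_index=True)


def _standardized_columns(rng, df: pd.DataFrame, names) -> None:
    for c in names:
        if c not in df.columns:
            df[c] = rng.standard_normal(len(df))


def make_smooth_surface(
    geometry: LatticeGeometry,
    years,
    intercept: float,
    beta,
    rel_amplitude: float = 0.5,
) -> Callable:
    """Default smooth coefficient surface for varying-coefficient panels.

    Each slope oscillates around its base value with relative amplitude
    ``rel_amplitude`` over one spatial period across the lattice and one
    temporal period across the year range; the intercept carries a gentle
    east-west gradient.
    """
    beta = np.asarray(beta, dtype=float)
    years = list(years)
    cents = geometry.centroids
    x0, x1 = cents[:, 0].min(), cents[:, 0].max()
    y0, y1 = cents[:, 1].min(), cents[:, 1].max()
    t0, t1 = min(years), max(years)
    sx = max(x1 - x0, 1e-9)
    sy = max(y1 - y0, 1e-9)
    st = max(t1 - t0, 1)

    def surface(x, y, t):
        x = np.asarray(x, dtype=float)
        xn = (x - x0) / sx
        yn = (np.asarray(y, dtype=float) - y0) / sy
        tn = (np.asarray(t, dtype=float) - t0) / st
        out = np.empty((len(x), len(beta) + 1))
        out[:, 0] = intercept * (1 + 0.2 * rel_amplitude * (xn - 0.5))
        for k, b in enumerate(beta):
            wave = (
                np.sin(np.pi * xn + 0.5 * k) * np.cos(np.pi * yn + 0.3 * k)
                + 0.5 * np.sin(2 * np.pi * tn + 0.7 * k)
            )
            out[:, k + 1] = b * (1 + rel_amplitude * wave / 1.5)
        return out

    return surface


def simulate_panel(
    geometry: LatticeGeometry,
    years,
    params: DGPParams,
    weights: SpatialWeights,
) -> CountyPanel:
    """Draw a balanced panel from the configured data-generating process.

    Reproducible given ``params.seed``. In constant mode the outcome solves
    the simultaneous spatial system exactly (sparse LU); in varying mode the
    true local coefficients are attached as ``panel.true_coefficients``.
    """
    years = sorted(int(y) for y in years)
    if len(years) != len(set(years)):
        raise ValueError("duplicate years requested")
    if list(weights.ids) != [str(c) for c in geometry.county_ids]:
        raise ValueError("weights were not built on this geometry (id mismatch)")
    if (params.lambda_lag or params.rho_error) and not weights.standardized:
        raise ValueError(
            "spatial DGP parameters assume row-standardized weights "
            "(|lambda|, |rho| < 1 guarantees stationarity only then)"
        )
    rng = np.random.default_rng(params.seed)
    n = geometry.n
    T = len(years)

    df = _realistic_covariates(rng, geometry, years)
    if params.covariate_style == "standardized":
        _standardized_columns(rng, df, params.regressors)
    missing = [c for c in params.regressors if c not in df.columns]
    if missing:
        _standardized_columns(rng, df, missing)

    X = df[list(params.regressors)].to_numpy(dtype=float)
    p = X.shape[1]

    if params.mode == "constant":
        W = weights.sparse().tocsc()
        ident = sp.identity(n, format="csc")
        lu_a = splu((ident - params.lambda_lag * W).tocsc()) if params.lambda_lag else None
        lu_b = splu((ident - params.rho_error * W).tocsc()) if params.rho_error else None
        alpha = rng.normal(0, params.sigma_alpha, n) if params.sigma_alpha > 0 else np.zeros(n)
        y_all = np.empty(n * T)
        for ti in range(T):
            sl = slice(ti * n, (ti + 1) * n)
            nu = rng.normal(0, params.sigma_nu, n) if params.sigma_nu > 0 else np.zeros(n)
            u = lu_b.solve(nu) if lu_b is not None else nu
            rhs = params.intercept + X[sl] @ params.beta + alpha + u
            y_all[sl] = lu_a.solve(rhs) if lu_a is not None else rhs
        df["pm25"] = y_all
        panel = CountyPanel(df, validate=False)
        panel.validate(physical=False)
        return panel

    surface = params.coefficient_surface
    if surface is None:
        surface = make_smooth_surface(geometry, years, params.intercept, params.beta)
    coefs = surface(
        df["x"].to_numpy(), df["y"].to_numpy(), df["year"].to_numpy(dtype=float)
    )
    coefs = np.asarray(coefs, dtype=float)
    if coefs.shape != (len(df), p + 1):
        raise ValueError(
            f"coefficient_surface returned shape {coefs.shape}, expected {(len(df), p + 1)}"
        )
    eps = rng.normal(0, params.sigma_nu, len(df)) if params.sigma_nu > 0 else 0.0
    df["pm25"] = coefs[:, 0] + np.einsum("ij,ij->i", coefs[:, 1:], X) + eps
    panel = CountyPanel(df, validate=False)
    panel.validate(physical=False)
    tc = df[["county_id", "year"]].copy()
    tc["intercept"] = coefs[:, 0]
    for k, name in enumerate(params.regressors):
        tc[f"beta_{name}"] = coefs[:, k + 1]
    panel.true_coefficients = tc
    return panel


def simulate_baseline_mortality(
    panel: CountyPanel,
    anchor_year: int,
    rate_params,
    seed: int = 0,
) -> MortalityPanel:
    """Poisson draws of anchor-year PM2.5-attributable deaths per county.

    ``rate_params`` is either a scalar national total (split across counties
    proportionally to population density times concentration, mirroring how
    exposure-weighted burdens concentrate in dense, polluted counties) or a
    mapping/array of per-county expected deaths. Only the anchor year is
    populated; the concentration-change recursion fills the other years.
    """
    anchor_year = int(anchor_year)
    if anchor_year not in panel.years:
        raise ValueError(f"anchor year {anchor_year} not in panel years {panel.years}")
    rng = np.random.default_rng(seed)
    sub = panel.df[panel.df["year"] == anchor_year].sort_values("county_id")
    cids = sub["county_id"].tolist()
    if np.isscalar(rate_params):
        total = float(rate_params)
        if total < 0:
            raise ValueError("national total must be nonnegative")
        wcol = (
            sub["pop_density_1k_km2"].to_numpy()
            if "pop_density_1k_km2" in sub.columns
            else np.ones(len(sub))
        )
        load = wcol * np.clip(sub["pm25"].to_numpy(), 0, None)
        if load.sum() <= 0:
            load = np.ones(len(sub))
        mu = total * load / load.sum()
    else:
        if isinstance(rate_params, dict):
            mu = np.array([float(rate_params[c]) for c in cids])
        else:
            mu = np.asarray(rate_params, dtype=float)
            if len(mu) != len(cids):
                raise ValueError("per-county rates length mismatch")
    if (mu < 0).any():
        raise ValueError("expected deaths must be nonnegative")
    deaths = rng.poisson(mu).astype(float)
    return MortalityPanel(
        pd.DataFrame({"county_id": cids, "year": anchor_year, "map_deaths": deaths})
    )


def interpolate_missing_years(anchor_series, target_years) -> pd.Series:
    """Piecewise-linear interpolation of anchor-year values onto all years.

    Anchor years are reproduced exactly. Targets outside the anchor range
    get nearest-anchor constant extrapolation with a warning (keeps
    percentages from running negative). Fewer than two anchors with
    off-anchor targets is an error.
    """
    if isinstance(anchor_series, dict):
        items = sorted((int(k), float(v)) for k, v in anchor_series.items())
    else:
        items = sorted((int(k), float(v)) for k, v in anchor_series)
    if not items:
        raise ValueError("no anchor values supplied")
    ax = np.array([k for k, _ in items], dtype=float)
    av = np.array([v for _, v in items], dtype=float)
    if len(np.unique(ax)) != len(ax):
        raise ValueError("duplicate anchor years")
    targets = np.asarray(sorted(int(y) for y in target_years), dtype=float)
    outside = (targets < ax.min()) | (targets > ax.max())
    if len(ax) < 2 and outside.any():
        raise ValueError("at least two anchors required to fill off-anchor years")
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} target years outside anchor range "
            f"[{int(ax.min())}, {int(ax.max())}]; using nearest-anchor value"
        )
    vals = np.interp(targets, ax, av)  # np.interp clamps to end values
    return pd.Series(vals, index=targets.astype(int), name="value")
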