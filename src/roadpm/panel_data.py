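"""Balanced county-year panel containers and model specifications."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountyPanel", "MortalityPanel", "ModelSpec", "read_panel", "write_panel"]

#: columns every panel must carry besides the covariates
CORE_COLUMNS = ("county_id", "year", "pm25", "co2_per_km2", "x", "y")


@dataclass
class ModelSpec:
    """Which regression to run on a :class:`CountyPanel`.

    Parameters
    ----------
    dependent : str
        Outcome column, by default the annual mean PM2.5 concentration.
    regressors : list of str
        Ordered regressor columns (on-road CO2 per km2 plus controls).
    include_fixed_effects : bool
        Whether county fixed effects are removed (within transformation).
        No constant column is allowed when fixed effects are included.
    """

    dependent: str = "pm25"
    regressors: list[str] = field(default_factory=lambda: ["co2_per_km2"])
    include_fixed_effects: bool = True

    def validate(self, panel: "CountyPanel") -> None:
        missing = [c for c in [self.dependent, *self.regressors] if c not in panel.df.columns]
        if missing:
            raise ValueError(f"columns missing from panel: {missing}")
        if self.include_fixed_effects:
            for c in self.regressors:
                v = panel.df[c].to_numpy(dtype=float)
                if np.allclose(v, v[0]):
                    raise ValueError(
                        f"regressor {c!r} is constant; drop it when fixed effects are included"
                    )


class CountyPanel:
    """A balanced county x year long-format table.

    Wraps a :class:`pandas.DataFrame` with columns ``county_id, year, pm25,
    co2_per_km2, <covariates...>, x, y`` where (x, y) are planar centroid
    coordinates in km. Every county must appear in every year.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col in CORE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"panel is missing required column {col!r}")
        df["county_id"] = df["county_id"].astype(str)
        df["year"] = df["year"].astype(int)
        df = df.sort_values(["year", "county_id"], kind="mergesort").reset_index(drop=True)
        self.df = df
        self.true_coefficients: pd.DataFrame | None = None  # set by simulators
        if validate:
            self.validate()

    # -- structure --------------------------------------------------------
    @property
    def county_ids(self) -> list[str]:
        return sorted(self.df["county_id"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    @property
    def n_counties(self) -> int:
        return len(self.county_ids)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_obs(self) -> int:
        return len(self.df)

    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in CORE_COLUMNS]

    def validate(self, physical: bool = False) -> None:
        """Check balance (always) and physical ranges (optionally strict).

        Balance violations raise with the list of missing county-years.
        Physical-range violations (negative concentrations or emissions,
        percentages outside [0, 100]) raise when ``physical`` is true and
        warn otherwise.
        """
        counts = self.df.groupby("county_id")["year"].apply(set)
        all_years = set(self.years)
        gaps = {cid: sorted(all_years - yrs) for cid, yrs in counts.items() if yrs != all_years}
        if gaps:
            detail = "; ".join(f"{cid}: missing {g}" for cid, g in list(gaps.items())[:10])
            raise ValueError(f"unbalanced panel ({len(gaps)} counties with gaps): {detail}")
        dup = self.df.duplicated(["county_id", "year"])
        if dup.any():
            raise ValueError("duplicate county-year rows")
        problems = []
        if (self.df["pm25"] < 0).any():
            problems.append("negative pm25")
        if (self.df["co2_per_km2"] < 0).any():
            problems.append("negative co2_per_km2")
        for c in self.covariate_names:
            if c.endswith("_pct"):
                v = self.df[c]
                if (v < 0).any() or (v > 100).any():
                    problems.append(f"{c} outside [0, 100]")
        if problems:
            msg = "physical-range violations: " + ", ".join(problems)
            if physical:
                raise ValueError(msg)
            warnings.warn(msg)

    # -- views ------------------------------------------------------------
    def restrict_years(self, first: int | None = None, last: int | None = None) -> "CountyPanel":
        """Return the sub-panel with years in [first, last] (inclusive)."""
        df = self.df
        if first is not None:
            df = df[df["year"] >= first]
        if last is not None:
            df = df[df["year"] <= last]
        if df.empty:
            raise ValueError("year restriction removed every observation")
        out = CountyPanel(df)
        if self.true_coefficients is not None:
            tc = self.true_coefficients
            m = pd.Series(True, index=tc.index)
            if first is not None:
                m &= tc["year"] >= first
            if last is not None:
                m &= tc["year"] <= last
            out.true_coefficients = tc[m].reset_index(drop=True)
        return out

    def design(self, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        """(y, X) arrays in (year-major, county-minor) row order."""
        spec.validate(self)
        y = self.df[spec.dependent].to_numpy(dtype=float)
        X = self.df[list(spec.regressors)].to_numpy(dtype=float)
        return y, X

    def wide(self, column: str) -> pd.DataFrame:
        """Pivot one column to a (year x county_id) table."""
        return self.df.pivot(index="year", columns="county_id", values=column)

    # -- io ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountyPanel":
        return read_panel(path)


def read_panel(path) -> CountyPanel:
    """Read and validate a long-format panel CSV.

    Raises with an explicit message naming missing columns, non-numeric
    cells (with row numbers) or balance gaps.
    """
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file is missing required columns: {missing}")
    numeric_cols = [c for c in df.columns if c != "county_id"]
    for c in numeric_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[converted.isna() & df[c].notna()]
        if len(bad):
            rows = (bad + 2).tolist()[:10]  # 1-based + header line
            raise ValueError(f"non-numeric values in column {c!r} at file rows {rows}")
        if converted.isna().any():
            rows = (df.index[converted.isna()] + 2).tolist()[:10]
            raise ValueError(f"missing values in column {c!r} at file rows {rows}")
        df[c] = converted
    return CountyPanel(df)


def write_panel(panel: CountyPanel, path) -> None:
    panel.to_csv(path)


class MortalityPanel:
    """County-year PM2.5-attributable premature deaths (``map_deaths``).

    Only the anchor year need be populated initially; the recursive
    concentration-change propagation fills the remaining years.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        for col in ("county_id", "year", "map_deaths"):
            if col not in df.columns:
                raise ValueError(f"mortality table missing column {col!r}")
        df["county_id"] = df["county_id"].astype(str)
        df["year"] = df["year"].astype(int)
        if (df["map_deaths"] < 0).any():
            raise ValueError("map_deaths must be nonnegative")
        self.df = df.sort_values(["year", "county_id"]).reset_index(drop=True)

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique().tolist())

    def yearly_totals(self) -> pd.Series:
        return self.df.groupby("year")["map_deaths"].sum()

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MortalityPanel":
        return cls(pd.read_csv(path))
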