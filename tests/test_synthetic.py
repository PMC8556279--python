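import numpy as np
import pytest

from roadpm import (
    DGPParams,
    interpolate_missing_years,
    make_lattice,
    simulate_baseline_mortality,
    simulate_panel,
)
from roadpm.weights import lattice_queen


@pytest.fixture(scope="module")
def geom():
    return make_lattice(4, 4, 10.0)


@pytest.fixture(scope="module")
def w_std(geom):
    return lattice_queen(geom).row_standardize()


def test_noise_free_nonspatial_limit(geom, w_std):
    """With no spatial terms and no noise, y is exactly the linear predictor."""
    params = DGPParams(
        beta=(2.0, -1.0),
        regressors=("x1", "x2"),
        intercept=5.0,
        sigma_nu=0.0,
        sigma_alpha=0.0,
        covariate_style="standardized",
        seed=3,
    )
    panel = simulate_panel(geom, range(2001, 2005), params, w_std)
    expected = 5.0 + 2.0 * panel.df["x1"] - 1.0 * panel.df["x2"]
    assert panel.df["pm25"].to_numpy() == pytest.approx(expected.to_numpy(), abs=1e-10)


def test_row_standardized_lag_closed_form(geom, w_std):
    """lam=0.5 with constant unit input: y = 1/(1-lam) everywhere."""
    params = DGPParams(
        beta=(),
        regressors=(),
        intercept=1.0,
        lambda_lag=0.5,
        sigma_nu=0.0,
        sigma_alpha=0.0,
        seed=0,
    )
    panel = simulate_panel(geom, [2001], params, w_std)
    assert panel.df["pm25"].to_numpy() == pytest.approx(np.full(16, 2.0), abs=1e-10)


def test_seed_determinism(geom, w_std):
    params = DGPParams(lambda_lag=0.3, rho_error=0.2, seed=42)
    a = simulate_panel(geom, range(2003, 2008), params, w_std)
    b = simulate_panel(geom, range(2003, 2008), params, w_std)
    assert a.df.equals(b.df)


def test_stationarity_and_weights_errors(geom, w_std):
    with pytest.raises(ValueError, match="-1, 1"):
        DGPParams(lambda_lag=1.0)
    with pytest.raises(ValueError, match="row-standardized"):
        simulate_panel(geom, [2001], DGPParams(lambda_lag=0.4), lattice_queen(geom))


def test_solver_matches_truncated_power_series(geom, w_std):
    """(I - lam W)^{-1} x agrees with the 500-term Neumann series."""
    rng = np.random.default_rng(1)
    W = w_std.dense()
    x = rng.normal(size=16)
    for lam in (0.25, 0.8):
        direct = np.linalg.solve(np.eye(16) - lam * W, x)
        series = np.zeros(16)
        term = x.copy()
        for _ in range(501):
            series += term
            term = lam * (W @ term)
        assert np.linalg.norm(series - direct) / np.linalg.norm(direct) < 1e-8


def test_realistic_covariates_in_physical_ranges(geom, w_std):
    panel = simulate_panel(geom, range(2001, 2017), DGPParams(seed=9), w_std)
    df = panel.df
    assert (df["co2_per_km2"] >= 0).all()
    assert (df["pm25"] >= 0).all()
    pct_cols = [c for c in df.columns if c.endswith("_pct")]
    assert pct_cols
    for c in pct_cols:
        assert df[c].between(0, 100).all()
    assert df.groupby("county_id")["year"].count().eq(16).all()


def test_varying_mode_attaches_true_surfaces(geom, w_std):
    params = DGPParams(
        beta=(1.0,), regressors=("x1",), mode="varying", sigma_nu=0.0,
        covariate_style="standardized", seed=2,
    )
    panel = simulate_panel(geom, range(2003, 2007), params, w_std)
    tc = panel.true_coefficients
    assert tc is not None and len(tc) == panel.n_obs
    recon = tc["intercept"] + tc["beta_x1"] * panel.df["x1"]
    assert panel.df["pm25"].to_numpy() == pytest.approx(recon.to_numpy(), abs=1e-10)


class TestBaselineMortality:
    def test_zero_rate_gives_zero_deaths(self, geom, w_std):
        panel = simulate_panel(geom, range(2008, 2012), DGPParams(seed=1), w_std)
        m = simulate_baseline_mortality(panel, 2010, 0.0, seed=5)
        assert (m.df["map_deaths"] == 0).all()

    def test_national_total_within_poisson_error(self, geom, w_std):
        panel = simulate_panel(geom, range(2008, 2012), DGPParams(seed=1), w_std)
        m = simulate_baseline_mortality(panel, 2010, 54730.0, seed=5)
        total = m.df["map_deaths"].sum()
        assert abs(total - 54730) < 4 * np.sqrt(54730)

    def test_seed_determinism_and_anchor_error(self, geom, w_std):
        panel = simulate_panel(geom, range(2008, 2012), DGPParams(seed=1), w_std)
        a = simulate_baseline_mortality(panel, 2010, 1000.0, seed=7)
        b = simulate_baseline_mortality(panel, 2010, 1000.0, seed=7)
        assert a.df.equals(b.df)
        with pytest.raises(ValueError, match="anchor"):
            simulate_baseline_mortality(panel, 1999, 1000.0)


class TestInterpolation:
    def test_linear_between_anchors(self):
        out = interpolate_missing_years({2001: 10, 2004: 16}, [2001, 2002, 2003, 2004])
        assert out.loc[2002] == pytest.approx(12)
        assert out.loc[2003] == pytest.approx(14)

    def test_anchors_reproduced_exactly(self):
        anchors = {2001: 3.5, 2006: 9.0, 2011: 4.25}
        out = interpolate_missing_years(anchors, list(range(2001, 2012)))
        for yr, v in anchors.items():
            assert out.loc[yr] == v

    def test_constant_series(self):
        out = interpolate_missing_years({2013: 5, 2016: 5}, [2014])
        assert out.loc[2014] == 5

    def test_extrapolation_is_nearest_anchor_with_warning(self):
        with pytest.warns(UserWarning, match="outside anchor range"):
            out = interpolate_missing_years({2004: 10, 2006: 20}, [2001, 2008])
        assert out.loc[2001] == 10
        assert out.loc[2008] == 20

    def test_single_anchor_off_target_errors(self):
        with pytest.raises(ValueError, match="two anchors"):
            interpolate_missing_years({2004: 10}, [2005])
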