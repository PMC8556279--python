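import numpy as np
import pytest

from roadpm import (
    GTWR,
    Bandwidth,
    DGPParams,
    ModelSpec,
    STKernelParams,
    kernel_weights,
    make_lattice,
    simulate_panel,
    st_distances,
)
from roadpm.weights import lattice_queen

SPEC = ModelSpec(regressors=["x1"])


@pytest.fixture(scope="module")
def geom():
    return make_lattice(10, 10, 30.0)


@pytest.fixture(scope="module")
def w_std(geom):
    return lattice_queen(geom).row_standardize()


def _varying_panel(geom, w_std, seed, sigma=0.2, years=(2003, 2007)):
    params = DGPParams(
        beta=(1.0,), regressors=("x1",), mode="varying", sigma_nu=sigma,
        covariate_style="standardized", seed=seed,
    )
    return simulate_panel(geom, range(*years), params, w_std)


class TestDistanceAndKernel:
    def test_pythagorean_combination(self):
        d2 = st_distances((0, 0, 2000), [(3, 0, 2004)], STKernelParams(1.0, 1.0))
        assert d2[0] == pytest.approx(25.0)

    def test_zero_temporal_scale_is_purely_spatial(self):
        d2 = st_distances((0, 0, 2000), [(3, 4, 2050)], STKernelParams(1.0, 0.0))
        assert d2[0] == pytest.approx(25.0)

    def test_identity_of_indiscernibles(self):
        d2 = st_distances((1, 2, 2005), [(1, 2, 2005)], STKernelParams(2.0, 3.0))
        assert d2[0] == 0.0

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            STKernelParams(-1.0, 1.0)
        with pytest.raises(ValueError):
            STKernelParams(0.0, 0.0)

    def test_kernel_values(self):
        w = kernel_weights(np.array([0.0, 2.0, 5.0]), 2.0, [True, True, False])
        assert w[0] == 1.0
        assert w[1] == pytest.approx(np.exp(-1.0))
        assert w[2] == 0.0
        with pytest.raises(ValueError, match="positive"):
            kernel_weights(np.array([1.0]), 0.0)


def test_joint_rescaling_invariance(geom, w_std):
    """Scaling (phi_S, phi_T) jointly leaves the adaptive-bandwidth fit
    unchanged: only tau = phi_T/phi_S matters."""
    panel = _varying_panel(geom, w_std, seed=5)
    m = GTWR(panel, SPEC)
    f1 = m.fit(Bandwidth(k=40, params=STKernelParams(1.0, 3.0)))
    f2 = m.fit(Bandwidth(k=40, params=STKernelParams(10.0, 30.0)))
    assert np.allclose(
        f1.local_params["beta_x1"], f2.local_params["beta_x1"], atol=1e-10
    )


def test_flat_kernel_reduces_to_pooled_ols(geom, w_std):
    panel = _varying_panel(geom, w_std, seed=6)
    m = GTWR(panel, SPEC)
    fit = m.fit(Bandwidth(k=m.n_obs, radius=1e9))
    X = np.column_stack([np.ones(m.n_obs), panel.df["x1"].to_numpy()])
    b_ols, *_ = np.linalg.lstsq(X, panel.df["pm25"].to_numpy(), rcond=None)
    dev = np.abs(fit.local_params[["intercept", "beta_x1"]].to_numpy() - b_ols)
    assert dev.max() < 1e-6


def test_constant_coefficients_noise_free_exact(geom, w_std):
    params = DGPParams(
        beta=(0.7,), regressors=("x1",), intercept=3.0, sigma_nu=0.0,
        sigma_alpha=0.0, covariate_style="standardized", seed=7,
    )
    panel = simulate_panel(geom, range(2003, 2006), params, w_std)
    fit = GTWR(panel, SPEC).fit(k=25, tau=1.0)
    assert fit.local_params["beta_x1"].to_numpy() == pytest.approx(
        np.full(panel.n_obs, 0.7), abs=1e-8
    )
    assert fit.local_params["intercept"].to_numpy() == pytest.approx(
        np.full(panel.n_obs, 3.0), abs=1e-8
    )


def test_varying_surface_recovery(geom, w_std):
    """n = 400 observations; local slopes track the true smooth surface."""
    panel = _varying_panel(geom, w_std, seed=7)
    m = GTWR(panel, SPEC)
    bw = m.select_bandwidth([30, 60, 120], [1.0, 100.0, 900.0])
    fit = m.fit(bw)
    corr = np.corrcoef(
        panel.true_coefficients["beta_x1"], fit.local_params["beta_x1"]
    )[0, 1]
    assert corr > 0.8


def test_gtwr_r2_at_least_pooled_ols(geom, w_std):
    panel = _varying_panel(geom, w_std, seed=8)
    m = GTWR(panel, SPEC)
    fit = m.fit(k=40, tau=100.0)
    X = np.column_stack([np.ones(m.n_obs), panel.df["x1"].to_numpy()])
    y = panel.df["pm25"].to_numpy()
    b, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ b
    r2_ols = 1 - float(resid @ resid) / float(((y - y.mean()) ** 2).sum())
    assert fit.rsquared >= r2_ols


class TestBandwidthSelection:
    def test_single_candidate_returned_with_score(self, geom, w_std):
        panel = _varying_panel(geom, w_std, seed=9)
        m = GTWR(panel, SPEC)
        bw = m.select_bandwidth([50], [2.0])
        assert bw.k == 50 and bw.params.tau == 2.0
        assert bw.cv_score is not None and np.isfinite(bw.cv_score)

    def test_constant_dgp_selection_does_not_degrade_fit(self, geom, w_std):
        params = DGPParams(
            beta=(0.8,), regressors=("x1",), sigma_nu=0.3, sigma_alpha=0.0,
            covariate_style="standardized", seed=10,
        )
        panel = simulate_panel(geom, range(2003, 2007), params, w_std)
        m = GTWR(panel, SPEC)
        bw = m.select_bandwidth([50, 150, 399], [1.0])
        r2_sel = m.fit(bw).rsquared
        r2_max = m.fit(k=399, tau=1.0).rsquared
        assert r2_max - r2_sel < 0.02

    def test_varying_dgp_prefers_local_bandwidth(self, geom, w_std):
        chosen_below_max = 0
        n_rep = 20
        for s in range(n_rep):
            panel = _varying_panel(geom, w_std, seed=100 + s)
            m = GTWR(panel, SPEC)
            bw = m.select_bandwidth([40, 120, 399], [100.0])
            chosen_below_max += bw.k < 399
        assert chosen_below_max / n_rep >= 0.8

    def test_invalid_candidates_rejected(self, geom, w_std):
        panel = _varying_panel(geom, w_std, seed=11)
        m = GTWR(panel, SPEC)
        with pytest.raises(ValueError, match="outside valid range"):
            m.select_bandwidth([1], [1.0])
        with pytest.raises(ValueError, match="positive"):
            m.select_bandwidth([50], [-1.0])


def test_year_range_restriction_first_class(geom, w_std):
    panel = _varying_panel(geom, w_std, seed=12, years=(2001, 2017))
    trimmed = panel.restrict_years(2003, 2016)
    assert trimmed.years == list(range(2003, 2017))
    fit = GTWR(trimmed, SPEC).fit(k=60, tau=10.0)
    assert set(fit.local_params["year"]) == set(range(2003, 2017))
    assert len(trimmed.true_coefficients) == trimmed.n_obs


def test_serialization_round_trip(tmp_path, geom, w_std):
    panel = _varying_panel(geom, w_std, seed=13)
    fit = GTWR(panel, SPEC).fit(k=40, tau=10.0)
    out = tmp_path / "local.csv"
    fit.to_csv(out)
    import pandas as pd

    back = pd.read_csv(out)
    assert {"county_id", "year", "intercept", "beta_x1", "residual"} <= set(back.columns)
    meta = fit.metadata()
    assert meta["k"] == 40 and meta["rsquared"] == pytest.approx(fit.rsquared)
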