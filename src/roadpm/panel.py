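"""Global panel models: fixed effects, spatial lag/error/combined, impacts.

The modelling chain mirrors standard spatial-econometric practice for a
balanced county x year panel:

* ``FixedEffectsPanel`` — the within estimator removing time-invariant
  county effects;
* a diagnostics battery (F test for individual effects, Breusch-Pagan LM
  for random effects, Hausman, and the locally robust LM lag/error pair on
  the within-transformed data) that drives model selection;
* ``SpatialPanel`` — maximum likelihood for the spatial autoregressive
  panel (lag), the spatial error panel (error) and the combined model
  (sac) that carries both a spatially lagged outcome and a spatially
  autocorrelated error, estimated after the within transformation with
  exact log-determinants from the eigenvalues of the row-standardized W;
* spillover decomposition of lag-model coefficients into direct, indirect
  and total impacts via the truncated Neumann series of ``(I - lam W)^-1``
  (500 terms by default) or the exact dense inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import optimize, stats

from .panel_data import CountyPanel, ModelSpec
from .weights import SpatialWeights

__all__ = [
    "FixedEffectsPanel",
    "FixedEffectsResults",
    "SpatialPanel",
    "SpatialPanelResults",
    "ImpactEstimates",
    "TestResult",
    "DiagnosticsReport",
    "panel_diagnostics",
    "robust_lm_tests",
    "impacts",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _within_transform(values: np.ndarray, n: int, T: int) -> np.ndarray:
    """Demean within county. Rows must be year-major, county-minor."""
    v = values.reshape(T, n, -1)
    out = v - v.mean(axis=0, keepdims=True)
    return out.reshape(values.shape)


def _check_rank(X: np.ndarray, names) -> None:
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[i] for i in np.where(bad)[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {culprits}")


def _align(panel: CountyPanel, w: SpatialWeights) -> None:
    if panel.county_ids != list(w.ids) and sorted(w.ids) != panel.county_ids:
        raise ValueError("panel counties and weight-matrix units do not match")


def _w_matrix(panel: CountyPanel, w: SpatialWeights) -> sp.csr_matrix:
    """W reordered to the panel's sorted county order."""
    order = [list(w.ids).index(c) for c in panel.county_ids]
    return w.sparse()[order][:, order].tocsr()


def _apply_w(W: sp.csr_matrix, values: np.ndarray, n: int, T: int) -> np.ndarray:
    v = values.reshape(T, n, -1)
    out = np.empty_like(v)
    for t in range(T):
        out[t] = W @ v[t]
    return out.reshape(values.shape)


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: tuple


# ---------------------------------------------------------------------------
# fixed effects (within) estimator
# ---------------------------------------------------------------------------

class FixedEffectsPanel:
    """Within estimator for a balanced county panel.

    Parameters
    ----------
    panel : CountyPanel
    spec : ModelSpec
        Fixed effects must be enabled; no constant column is permitted
        (the county effects absorb it).
    """

    def __init__(self, panel: CountyPanel, spec: ModelSpec):
        if panel.n_years < 2:
            raise ValueError("within estimator needs at least two periods")
        spec.validate(panel)
        self.panel = panel
        self.spec = spec
        self.y, self.X = panel.design(spec)
        self.n = panel.n_counties
        self.T = panel.n_years

    def fit(self) -> "FixedEffectsResults":
        n, T = self.n, self.T
        yw = _within_transform(self.y[:, None], n, T).ravel()
        Xw = _within_transform(self.X, n, T)
        _check_rank(Xw, self.spec.regressors)
        beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid = yw - Xw @ beta
        ssr = float(resid @ resid)
        sst = float(yw @ yw)
        df_resid = n * T - n - len(beta)
        sigma2 = ssr / df_resid
        XtX_inv = np.linalg.inv(Xw.T @ Xw)
        bse = np.sqrt(sigma2 * np.diag(XtX_inv))
        # alpha_i = county mean of (y - X beta)
        part = (self.y - self.X @ beta).reshape(T, n)
        alpha = part.mean(axis=0)
        return FixedEffectsResults(
            model=self,
            params=pd.Series(beta, index=list(self.spec.regressors)),
            bse=pd.Series(bse, index=list(self.spec.regressors)),
            fixed_effects=pd.Series(alpha, index=self.panel.county_ids),
            resid=resid,
            rsquared_within=1.0 - ssr / sst if sst > 0 else 1.0,
            ssr=ssr,
            sigma2=sigma2,
            df_resid=df_resid,
            cov_params=sigma2 * XtX_inv,
            yw=yw,
            Xw=Xw,
        )


@dataclass
class FixedEffectsResults:
    """Within-estimator results with the usual inference accessories."""

    model: FixedEffectsPanel
    params: pd.Series
    bse: pd.Series
    fixed_effects: pd.Series
    resid: np.ndarray
    rsquared_within: float
    ssr: float
    sigma2: float
    df_resid: int
    cov_params: np.ndarray
    yw: np.ndarray = field(repr=False, default=None)
    Xw: np.ndarray = field(repr=False, default=None)

    @property
    def nobs(self) -> int:
        return self.model.panel.n_obs

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def summary(self) -> str:
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "t": self.tvalues,
                "P>|t|": self.pvalues,
                "[0.025": ci["lower"],
                "0.975]": ci["upper"],
            }
        )
        head = (
            "Fixed Effects (within) Panel Regression\n"
            f"Dep. variable: {self.model.spec.dependent}    "
            f"N counties: {self.model.n}  T: {self.model.T}  obs: {self.nobs}\n"
            f"Within R-squared: {self.rsquared_within:.4f}\n"
        )
        return head + tab.to_string(float_format=lambda v: f"{v: .4f}")

    def to_dict(self) -> dict:
        return {
            "model": "fem",
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "conf_int": {
                k: [float(lo), float(hi)]
                for k, (lo, hi) in self.conf_int().iterrows()
            },
            "rsquared_within": float(self.rsquared_within),
            "nobs": int(self.nobs),
        }


# ---------------------------------------------------------------------------
# diagnostics battery
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Model-selection test battery; fields are filled as tests are run."""

    f_individual: TestResult | None = None
    bp_lm: TestResult | None = None
    hausman: TestResult | None = None
    robust_lm_lag: TestResult | None = None
    robust_lm_error: TestResult | None = None
    lm_lag: TestResult | None = None
    lm_error: TestResult | None = None

    def merge(self, other: "DiagnosticsReport") -> "DiagnosticsReport":
        out = DiagnosticsReport()
        for f in out.__dataclass_fields__:
            setattr(out, f, getattr(other, f) or getattr(self, f))
        return out

    def recommended_model(self, alpha: float = 0.05) -> str:
        """Decision tree over the battery.

        OLS when neither individual effects nor random effects are
        supported; otherwise FEM vs REM by the Hausman test; then the
        locally robust LM pair upgrades the panel model to the spatial
        lag model, the spatial error model, or the combined model when
        both spatial correlations are significant.
        """

        def sig(t):
            return t is not None and t.pvalue < alpha

        if not sig(self.f_individual) and not sig(self.bp_lm):
            base = "OLS"
        elif sig(self.f_individual) and (not sig(self.bp_lm) or sig(self.hausman)):
            base = "FEM"
        else:
            base = "REM"
        lag_sig, err_sig = sig(self.robust_lm_lag), sig(self.robust_lm_error)
        if base in ("FEM", "REM"):
            if lag_sig and err_sig:
                return "SPDM"
            if lag_sig:
                return "SPAM"
            if err_sig:
                return "SPEM"
        return base

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in (
            "f_individual",
            "bp_lm",
            "hausman",
            "lm_lag",
            "lm_error",
            "robust_lm_lag",
            "robust_lm_error",
        ):
            t = getattr(self, name)
            if t is not None:
                rows.append({"test": name, "statistic": t.statistic, "pvalue": t.pvalue, "df": str(t.df)})
        return pd.DataFrame(rows)


def panel_diagnostics(panel: CountyPanel, spec: ModelSpec) -> DiagnosticsReport:
    """F test for individual effects, Breusch-Pagan LM, and Hausman test.

    The F test compares pooled OLS (with intercept) against the within
    estimator; the Breusch-Pagan LM statistic tests for a random county
    effect in the pooled residuals; the Hausman statistic contrasts the
    within and Swamy-Arora random-effects GLS slope estimates.
    """
    if panel.n_years < 2:
        raise ValueError("panel diagnostics need at least two periods")
    spec.validate(panel)
    y, X = panel.design(spec)
    n, T = panel.n_counties, panel.n_years
    p = X.shape[1]

    # pooled OLS with intercept
    Xc = np.column_stack([np.ones(len(y)), X])
    beta_p, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    e_p = y - Xc @ beta_p
    ssr_pool = float(e_p @ e_p)

    fem = FixedEffectsPanel(panel, spec).fit()
    ssr_fe = fem.ssr
    df1, df2 = n - 1, n * T - n - p
    f_stat = ((ssr_pool - ssr_fe) / df1) / (ssr_fe / df2)
    f_res = TestResult(f_stat, float(stats.f.sf(f_stat, df1, df2)), (df1, df2))

    # Breusch-Pagan LM for random effects (balanced panel)
    e_mat = e_p.reshape(T, n)
    num = float((e_mat.sum(axis=0) ** 2).sum())
    den = float(e_p @ e_p)
    lm = (n * T) / (2.0 * (T - 1)) * (num / den - 1.0) ** 2
    bp_res = TestResult(lm, float(stats.chi2.sf(lm, 1)), (1,))

    # Swamy-Arora random effects GLS, then Hausman
    sigma_nu2 = ssr_fe / (n * (T - 1) - p)
    ybar = y.reshape(T, n).mean(axis=0)
    Xbar = X.reshape(T, n, p).mean(axis=0)
    Xbc = np.column_stack([np.ones(n), Xbar])
    bb, *_ = np.linalg.lstsq(Xbc, ybar, rcond=None)
    eb = ybar - Xbc @ bb
    df_b = n - p - 1
    sigma1_2 = float(eb @ eb) / df_b if df_b > 0 else float(eb @ eb)
    sigma_alpha2 = max(sigma1_2 - sigma_nu2 / T, 0.0)
    theta = 1.0 - np.sqrt(sigma_nu2 / (T * sigma_alpha2 + sigma_nu2))
    y_q = y - theta * np.tile(ybar, T)
    X_q = np.column_stack(
        [np.full(len(y), 1.0 - theta), X - theta * np.tile(Xbar, (T, 1))]
    )
    beta_re, *_ = np.linalg.lstsq(X_q, y_q, rcond=None)
    e_re = y_q - X_q @ beta_re
    v_re = sigma_nu2 * np.linalg.inv(X_q.T @ X_q)
    q = fem.params.to_numpy() - beta_re[1:]
    V = fem.cov_params - v_re[1:, 1:]
    h_stat = float(q @ np.linalg.pinv(V) @ q)
    h_res = TestResult(abs(h_stat), float(stats.chi2.sf(abs(h_stat), p)), (p,))
    _ = e_re  # RE residuals unused beyond the contrast

    return DiagnosticsReport(f_individual=f_res, bp_lm=bp_res, hausman=h_res)


def robust_lm_tests(fem_fit: FixedEffectsResults, w: SpatialWeights) -> DiagnosticsReport:
    """Locally robust LM tests for spatial lag and spatial error correlation.

    Computed on the within-transformed panel, pooling over years with a
    common cross-sectional W: each statistic is asymptotically chi-square
    with one degree of freedom under its null, and each is robust to local
    misspecification of the other spatial correlation. The plain
    (non-robust) LM statistics are reported alongside.
    """
    panel = fem_fit.model.panel
    _align(panel, w)
    if not w.standardized:
        warnings.warn("weights are not row-standardized; standardizing for LM tests")
        w = w.row_standardize()
    W = _w_matrix(panel, w)
    n, T = fem_fit.model.n, fem_fit.model.T
    e = fem_fit.resid
    yw, Xw = fem_fit.yw, fem_fit.Xw
    beta = fem_fit.params.to_numpy()
    # the within transformation leaves T-1 free periods per county; using
    # N(T-1) for sigma^2 and (T-1) in the trace term restores nominal size
    sigma2 = float(e @ e) / (n * (T - 1))

    Wy = _apply_w(W, yw[:, None], n, T).ravel()
    We = _apply_w(W, e[:, None], n, T).ravel()
    WXb = _apply_w(W, (Xw @ beta)[:, None], n, T).ravel()

    d_y = float(e @ Wy) / sigma2
    d_e = float(e @ We) / sigma2
    trWW = float((W.multiply(W)).sum() + (W.multiply(W.T)).sum())
    T1 = (T - 1) * trWW
    # M-projection of W X beta off the regressors
    coef, *_ = np.linalg.lstsq(Xw, WXb, rcond=None)
    m_wxb = WXb - Xw @ coef
    G = float(m_wxb @ m_wxb) / sigma2 + T1

    lm_lag = d_y**2 / G
    lm_err = d_e**2 / T1
    r_lag = (d_y - d_e) ** 2 / (G - T1)
    r_err = (d_e - (T1 / G) * d_y) ** 2 / (T1 * (1.0 - T1 / G))

    def res(s):
        return TestResult(float(s), float(stats.chi2.sf(s, 1)), (1,))

    return DiagnosticsReport(
        lm_lag=res(lm_lag),
        lm_error=res(lm_err),
        robust_lm_lag=res(r_lag),
        robust_lm_error=res(r_err),
    )


# ---------------------------------------------------------------------------
# spatial panel maximum likelihood
# ---------------------------------------------------------------------------

class SpatialPanel:
    """Maximum-likelihood spatial panel model on within-transformed data.

    Parameters
    ----------
    panel : CountyPanel
    weights : SpatialWeights
        Must be row-standardized.
    spec : ModelSpec
    variant : {"lag", "error", "sac"}
        ``lag`` — spatially lagged outcome only; ``error`` — spatially
        autocorrelated disturbance only; ``sac`` — both, i.e. the combined
        model carrying parameters (lam, rho) simultaneously.

    Notes
    -----
    The log-likelihood is concentrated over (lam, rho): for fixed spatial
    parameters the slope vector is GLS and the innovation variance is the
    mean squared transformed residual, with the two Jacobian terms
    ``T sum_i ln(1 - lam w_i)`` and ``T sum_i ln(1 - rho w_i)`` evaluated
    from the (real) eigenvalues ``w_i`` of the row-standardized W.
    """

    _starts_1d = (0.0, 0.5, -0.5)
    _starts_2d = ((0.0, 0.0), (0.5, 0.5), (0.5, -0.5), (-0.5, 0.5), (-0.5, -0.5))

    def __init__(
        self,
        panel: CountyPanel,
        weights: SpatialWeights,
        spec: ModelSpec,
        variant: str = "sac",
    ):
        if variant not in ("lag", "error", "sac"):
            raise ValueError(f"unknown variant {variant!r}")
        _align(panel, weights)
        if not weights.standardized:
            raise ValueError("spatial panel ML requires row-standardized weights")
        spec.validate(panel)
        self.panel = panel
        self.weights = weights
        self.spec = spec
        self.variant = variant
        self.n, self.T = panel.n_counties, panel.n_years
        self.W = _w_matrix(panel, weights)
        y, X = panel.design(spec)
        self._y_raw, self._X_raw = y, X
        self.y = _within_transform(y[:, None], self.n, self.T).ravel()
        self.X = _within_transform(X, self.n, self.T)
        _check_rank(self.X, spec.regressors)
        # precompute spatial lags of the transformed data
        self._Wy = _apply_w(self.W, self.y[:, None], self.n, self.T).ravel()
        self._WWy = _apply_w(self.W, self._Wy[:, None], self.n, self.T).ravel()
        self._WX = _apply_w(self.W, self.X, self.n, self.T)
        self._eigs = weights.eigenvalues()

    # -- likelihood machinery --------------------------------------------
    def _bounds(self):
        lo = self._eigs.min()
        lb = 1.0 / lo + 1e-6 if lo < -1e-12 else -0.9999
        return max(lb, -0.9999), 0.9999

    def _transform(self, lam: float, rho: float):
        """y* = B A y,  X* = B X  (A = I - lam W, B = I - rho W)."""
        y_star = self.y - lam * self._Wy - rho * (self._Wy - lam * self._WWy)
        X_star = self.X - rho * self._WX
        return y_star, X_star

    def _profile(self, lam: float, rho: float):
        y_star, X_star = self._transform(lam, rho)
        beta, *_ = np.linalg.lstsq(X_star, y_star, rcond=None)
        resid = y_star - X_star @ beta
        sigma2 = float(resid @ resid) / len(resid)
        return beta, sigma2, resid, X_star

    def _logdet(self, val: float) -> float:
        return float(np.sum(np.log(1.0 - val * self._eigs)))

    def loglike(self, lam: float, rho: float) -> float:
        """Concentrated log-likelihood at (lam, rho)."""
        _, sigma2, _, _ = self._profile(lam, rho)
        NT = self.n * self.T
        ld = self._logdet(lam) if lam else 0.0
        ld += self._logdet(rho) if rho else 0.0
        return -0.5 * NT * (np.log(2 * np.pi * sigma2) + 1.0) + self.T * ld

    def _free_params(self, theta):
        if self.variant == "lag":
            return float(theta[0]), 0.0
        if self.variant == "error":
            return 0.0, float(theta[0])
        return float(theta[0]), float(theta[1])

    def fit(self, tol: float = 1e-8, maxiter: int = 500) -> "SpatialPanelResults":
        lb, ub = self._bounds()
        bounds = [(lb, ub)] * (2 if self.variant == "sac" else 1)
        starts = self._starts_2d if self.variant == "sac" else [(s,) for s in self._starts_1d]

        def nll(theta):
            lam, rho = self._free_params(theta)
            return -self.loglike(lam, rho)

        best = None
        for s in starts:
            res = optimize.minimize(
                nll,
                x0=np.asarray(s, dtype=float),
                method="L-BFGS-B",
                bounds=bounds,
                options={"ftol": tol, "maxiter": maxiter},
            )
            if not res.success and "ABNORMAL" in str(res.message).upper():
                continue
            cand = (res.fun, sum(abs(v) for v in res.x), res)
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is None:
            raise RuntimeError("spatial panel ML failed to converge from every start")
        res = best[2]
        lam, rho = self._free_params(res.x)
        boundary = any(
            min(abs(v - lb), abs(v - ub)) < 1e-3 for v in np.atleast_1d(res.x)
        )
        if boundary:
            warnings.warn(
                "spatial parameter estimate at the stationarity boundary; "
                "interpret with caution"
            )
        beta, sigma2, resid_star, X_star = self._profile(lam, rho)
        llf = self.loglike(lam, rho)

        cov_beta = sigma2 * np.linalg.inv(X_star.T @ X_star)
        bse = np.sqrt(np.diag(cov_beta))
        se_lam, se_rho = self._spatial_ses(lam, rho)

        # residual components on the within scale:
        # eps = A y - X beta (total spatial error), nu = B eps (innovation)
        eps = (self.y - lam * self._Wy) - self.X @ beta
        nu = eps - rho * _apply_w(self.W, eps[:, None], self.n, self.T).ravel()
        fitted = self._reduced_form_fit(lam, beta)
        obs = self.y
        r2 = float(np.corrcoef(fitted, obs)[0, 1] ** 2) if np.std(fitted) > 0 else 0.0

        # fixed effects from the untransformed data
        y_adj = self._y_raw - lam * _apply_w(
            self.W, self._y_raw[:, None], self.n, self.T
        ).ravel() - self._X_raw @ beta
        alpha = y_adj.reshape(self.T, self.n).mean(axis=0)

        return SpatialPanelResults(
            model=self,
            variant=self.variant,
            params=pd.Series(beta, index=list(self.spec.regressors)),
            bse=pd.Series(bse, index=list(self.spec.regressors)),
            lambda_lag=lam if self.variant in ("lag", "sac") else None,
            rho_error=rho if self.variant in ("error", "sac") else None,
            se_lambda=se_lam,
            se_rho=se_rho,
            sigma2=sigma2,
            llf=llf,
            fixed_effects=pd.Series(alpha, index=self.panel.county_ids),
            resid_spatial=eps,
            resid_idiosyncratic=nu,
            rsquared=r2,
            converged=bool(res.success),
            at_boundary=boundary,
        )

    def _reduced_form_fit(self, lam, beta):
        xb = self.X @ beta
        if lam == 0:
            return xb
        out = np.empty_like(xb)
        A = (sp.identity(self.n) - lam * self.W).tocsc()
        lu = sp.linalg.splu(A)
        for t in range(self.T):
            sl = slice(t * self.n, (t + 1) * self.n)
            out[sl] = lu.solve(xb[sl])
        return out

    def _spatial_ses(self, lam, rho, h=1e-4):
        """Numerical Hessian of the concentrated log-likelihood."""
        free = {"lag": [lam], "error": [rho], "sac": [lam, rho]}[self.variant]

        def f(theta):
            lam_, rho_ = self._free_params(theta)
            return self.loglike(lam_, rho_)

        k = len(free)
        H = np.zeros((k, k))
        x0 = np.asarray(free, dtype=float)
        f0 = f(x0)
        for i in range(k):
            for j in range(i, k):
                ei = np.zeros(k); ei[i] = h
                ej = np.zeros(k); ej[j] = h
                if i == j:
                    H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
                    ) / (4 * h**2)
        try:
            cov = np.linalg.inv(-H)
            ses = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            ses = np.full(k, np.nan)
        if self.variant == "lag":
            return float(ses[0]), None
        if self.variant == "error":
            return None, float(ses[0])
        return float(ses[0]), float(ses[1])


@dataclass
class SpatialPanelResults:
    """ML estimates for a spatial panel fit."""

    model: SpatialPanel
    variant: str
    params: pd.Series
    bse: pd.Series
    lambda_lag: float | None
    rho_error: float | None
    se_lambda: float | None
    se_rho: float | None
    sigma2: float
    llf: float
    fixed_effects: pd.Series
    resid_spatial: np.ndarray
    resid_idiosyncratic: np.ndarray
    rsquared: float
    converged: bool
    at_boundary: bool

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def impacts(self, n_terms: int = 500, method: str = "series") -> "ImpactEstimates":
        return impacts(self, self.model.weights, n_terms=n_terms, method=method)

    def summary(self) -> str:
        ci = self.conf_int()
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "std err": self.bse,
                "z": self.params / self.bse,
                "[0.025": ci["lower"],
                "0.975]": ci["upper"],
            }
        )
        lines = [
            f"Spatial Panel ML ({self.variant})   "
            f"N: {self.model.n}  T: {self.model.T}",
            f"Log-likelihood: {self.llf:.4f}   sigma2: {self.sigma2:.5f}   "
            f"R2 (corr^2): {self.rsquared:.4f}",
        ]
        if self.lambda_lag is not None:
            se = f" ({self.se_lambda:.4f})" if self.se_lambda else ""
            lines.append(f"lambda (spatial lag): {self.lambda_lag:.4f}{se}")
        if self.rho_error is not None:
            se = f" ({self.se_rho:.4f})" if self.se_rho else ""
            lines.append(f"rho (spatial error): {self.rho_error:.4f}{se}")
        return "\n".join(lines) + "\n" + tab.to_string(float_format=lambda v: f"{v: .4f}")

    def to_dict(self) -> dict:
        return {
            "model": self.variant,
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "conf_int": {
                k: [float(lo), float(hi)] for k, (lo, hi) in self.conf_int().iterrows()
            },
            "lambda": self.lambda_lag,
            "rho": self.rho_error,
            "log_likelihood": float(self.llf),
            "rsquared": float(self.rsquared),
        }


# ---------------------------------------------------------------------------
# impact decomposition
# ---------------------------------------------------------------------------

@dataclass
class ImpactEstimates:
    """Direct/indirect/total impacts of each regressor.

    ``direct`` is the average own-county effect (mean diagonal of the
    spatial multiplier), ``total`` the average cumulative effect over all
    counties (mean row sum), and ``indirect = total - direct`` the average
    spillover. ``total == direct + indirect`` holds exactly.
    """

    table: pd.DataFrame  # index regressors, columns direct/indirect/total
    n_terms: int
    method: str

    def __getitem__(self, reg):
        return self.table.loc[reg]


def impacts(
    fit: SpatialPanelResults,
    w: SpatialWeights,
    n_terms: int = 500,
    method: str = "series",
) -> ImpactEstimates:
    """Spillover decomposition via the multiplier ``sum_s lam^s W^s``.

    ``method="series"`` accumulates the truncated power series (default
    length 500); ``method="exact"`` uses the dense inverse
    ``(I - lam W)^{-1}`` and is the small-lattice oracle for the series.
    """
    if fit.lambda_lag is None:
        raise ValueError("impacts require a lag or sac fit (a lambda estimate)")
    lam = float(fit.lambda_lag)
    if abs(lam) >= 1:
        raise ValueError("lambda outside the stationary region")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    Wd = w.sparse().toarray()
    n = Wd.shape[0]
    if method == "series":
        P = np.eye(n)
        acc_tr = 0.0
        acc_sum = 0.0
        coef = 1.0
        for s in range(n_terms + 1):
            acc_tr += coef * np.trace(P)
            acc_sum += coef * P.sum()
            if s < n_terms:
                P = Wd @ P
                coef *= lam
        mean_diag = acc_tr / n
        mean_total = acc_sum / n
    elif method == "exact":
        S = np.linalg.inv(np.eye(n) - lam * Wd)
        mean_diag = float(np.trace(S)) / n
        mean_total = float(S.sum()) / n
    else:
        raise ValueError(f"unknown method {method!r}")
    rows = {}
    for reg, b in fit.params.items():
        direct = b * mean_diag
        total = b * mean_total
        rows[reg] = {"direct": direct, "indirect": total - direct, "total": total}
    return ImpactEstimates(
        table=pd.DataFrame(rows).T[["direct", "indirect", "total"]],
        n_terms=n_terms,
        method=method,
    )
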