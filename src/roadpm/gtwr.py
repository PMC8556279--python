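"""Geographically and temporally weighted regression (GTWR).

One weighted least-squares fit per county-year observation, with Gaussian
kernel weights decaying in a combined space-time distance

    d^2 = phi_S * dS^2 + phi_T * dT^2

where dS is planar Euclidean distance (km) and dT is the year difference.
The bandwidth is adaptive: each observation's kernel radius b_it is the
distance to its k-th nearest space-time neighbour, so every local fit uses
a subsample of the same size k. Only the ratio tau = phi_T / phi_S matters
under an adaptive bandwidth (jointly rescaling the two scale factors
rescales b^2 identically), so phi_S is fixed at 1 and (k, tau) are chosen
by leave-one-out cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel_data import CountyPanel, ModelSpec

__all__ = [
    "STKernelParams",
    "Bandwidth",
    "st_distances",
    "kernel_weights",
    "GTWR",
    "GTWRResults",
]


@dataclass
class STKernelParams:
    """Scale factors of the spatio-temporal distance."""

    phi_s: float = 1.0
    phi_t: float = 1.0

    def __post_init__(self) -> None:
        if self.phi_s < 0 or self.phi_t < 0:
            raise ValueError("scale factors must be nonnegative")
        if self.phi_s == 0 and self.phi_t == 0:
            raise ValueError("at least one scale factor must be positive")

    @property
    def tau(self) -> float:
        """Temporal-to-spatial scale ratio actually optimized."""
        if self.phi_s == 0:
            return np.inf
        return self.phi_t / self.phi_s


@dataclass
class Bandwidth:
    """Adaptive bandwidth: subsample size k plus kernel scale factors."""

    k: int
    params: STKernelParams = field(default_factory=STKernelParams)
    cv_score: float | None = None
    b_it: np.ndarray | None = None  # per-observation kernel radius (set at fit)
    radius: float | None = None  # fixed kernel radius overriding the adaptive rule

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("adaptive neighbour count k must exceed 1")
        if self.radius is not None and self.radius <= 0:
            raise ValueError("fixed kernel radius must be positive")


def st_distances(focal, others, params: STKernelParams) -> np.ndarray:
    """Squared combined distances from one (x, y, t) point to many others."""
    fx, fy, ft = (float(v) for v in focal)
    o = np.asarray(others, dtype=float)
    ds2 = (o[:, 0] - fx) ** 2 + (o[:, 1] - fy) ** 2
    dt2 = (o[:, 2] - ft) ** 2
    return params.phi_s * ds2 + params.phi_t * dt2


def kernel_weights(d, b, membership=None) -> np.ndarray:
    """Gaussian kernel ``exp(-d^2 / b^2)``; non-members get exactly zero.

    ``d`` holds plain (not squared) combined distances and ``b`` is the
    kernel radius, so the k-th neighbour at distance b receives weight
    ``exp(-1)``.
    """
    if b <= 0:
        raise ValueError("kernel radius b must be positive")
    d = np.asarray(d, dtype=float)
    w = np.exp(-(d**2) / b**2)
    if membership is not None:
        w = np.where(np.asarray(membership, dtype=bool), w, 0.0)
    return w


class GTWR:
    """Local weighted least squares over space-time neighbourhoods.

    Parameters
    ----------
    panel : CountyPanel
    spec : ModelSpec
        An intercept is always included in each local fit (the local
        intercept absorbs county effects).
    """

    def __init__(self, panel: CountyPanel, spec: ModelSpec):
        spec.validate(panel)
        self.panel = panel
        self.spec = spec
        df = panel.df
        self.y = df[spec.dependent].to_numpy(dtype=float)
        self.X = np.column_stack(
            [np.ones(len(df)), df[list(spec.regressors)].to_numpy(dtype=float)]
        )
        self.coords = df[["x", "y"]].to_numpy(dtype=float)
        self.years = df["year"].to_numpy(dtype=float)
        self.n_obs, self.p = len(self.y), self.X.shape[1]
        dx = self.coords[:, 0][:, None] - self.coords[:, 0][None, :]
        dy = self.coords[:, 1][:, None] - self.coords[:, 1][None, :]
        self._DS2 = dx**2 + dy**2
        dt = self.years[:, None] - self.years[None, :]
        self._DT2 = dt**2

    # -- local fitting core ----------------------------------------------
    def _d2_row(self, i: int, params: STKernelParams) -> np.ndarray:
        return params.phi_s * self._DS2[i] + params.phi_t * self._DT2[i]

    @staticmethod
    def _wls(Xs, ys, w):
        sw = np.sqrt(w)
        Xw = Xs * sw[:, None]
        yw = ys * sw
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        try:
            beta = np.linalg.solve(XtX, Xty)
            if not np.all(np.isfinite(beta)):
                raise np.linalg.LinAlgError
            return beta, False
        except np.linalg.LinAlgError:
            jitter = 1e-8 * np.trace(XtX) / XtX.shape[0]
            beta = np.linalg.solve(XtX + jitter * np.eye(XtX.shape[0]), Xty)
            return beta, True

    def _local_fit(self, i, params, k, exclude_self=False, radius=None):
        d2 = self._d2_row(i, params)
        if exclude_self:
            d2 = d2.copy()
            d2[i] = np.inf
        members = np.argpartition(d2, k - 1)[:k]
        b2 = float(radius**2) if radius is not None else float(d2[members].max())
        if b2 <= 0:  # all members coincide with the focal point
            w = np.ones(k)
        else:
            w = np.exp(-d2[members] / b2)
        beta, jittered = self._wls(self.X[members], self.y[members], w)
        return beta, b2, jittered

    # -- bandwidth selection ---------------------------------------------
    def select_bandwidth(self, k_candidates, tau_candidates) -> Bandwidth:
        """Leave-one-out CV over the (k, tau) grid.

        Each observation is predicted from a local fit that excludes it;
        the pair minimizing the summed squared prediction error wins, with
        ties broken toward smaller k, then smaller tau.
        """
        k_candidates = sorted(int(k) for k in k_candidates)
        tau_candidates = sorted(float(t) for t in tau_candidates)
        if not k_candidates or not tau_candidates:
            raise ValueError("empty candidate grid")
        for k in k_candidates:
            if k <= self.p or k > self.n_obs:
                raise ValueError(
                    f"k={k} outside valid range ({self.p}, {self.n_obs}]"
                )
        if any(t <= 0 for t in tau_candidates):
            raise ValueError("tau candidates must be positive")
        best = None
        for tau in tau_candidates:
            params = STKernelParams(1.0, tau)
            for k in k_candidates:
                kk = min(k, self.n_obs - 1)  # focal excluded
                sse = 0.0
                for i in range(self.n_obs):
                    beta, _, _ = self._local_fit(i, params, kk, exclude_self=True)
                    pred = float(self.X[i] @ beta)
                    sse += (self.y[i] - pred) ** 2
                if not np.isfinite(sse):
                    continue
                if best is None or sse < best[0] - 1e-12:
                    best = (sse, k, tau)
        if best is None:
            raise ValueError("every candidate bandwidth produced singular local fits")
        sse, k, tau = best
        return Bandwidth(k=k, params=STKernelParams(1.0, tau), cv_score=sse)

    # -- full fit ---------------------------------------------------------
    def fit(self, bandwidth: Bandwidth | None = None, k: int | None = None,
            tau: float | None = None) -> "GTWRResults":
        if bandwidth is None:
            if k is None:
                raise ValueError("provide a Bandwidth or an explicit k")
            bandwidth = Bandwidth(k=int(k), params=STKernelParams(1.0, 1.0 if tau is None else float(tau)))
        if bandwidth.k > self.n_obs:
            raise ValueError(f"k={bandwidth.k} exceeds the {self.n_obs} observations")
        if bandwidth.k <= self.p:
            raise ValueError(f"k={bandwidth.k} too small for {self.p} local parameters")
        betas = np.empty((self.n_obs, self.p))
        radii = np.empty(self.n_obs)
        n_jitter = 0
        for i in range(self.n_obs):
            beta, b2, jittered = self._local_fit(
                i, bandwidth.params, bandwidth.k, radius=bandwidth.radius
            )
            betas[i] = beta
            radii[i] = np.sqrt(b2)
            n_jitter += jittered
        if n_jitter:
            warnings.warn(f"{n_jitter} local fits required a ridge jitter")
        fitted = np.einsum("ij,ij->i", self.X, betas)
        resid = self.y - fitted
        sst = float(((self.y - self.y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / sst if sst > 0 else 1.0
        bandwidth = Bandwidth(
            k=bandwidth.k,
            params=bandwidth.params,
            cv_score=bandwidth.cv_score,
            b_it=radii,
            radius=bandwidth.radius,
        )
        local = self.panel.df[["county_id", "year"]].copy()
        local["intercept"] = betas[:, 0]
        for j, reg in enumerate(self.spec.regressors):
            local[f"beta_{reg}"] = betas[:, j + 1]
        return GTWRResults(
            model=self,
            local_params=local,
            fittedvalues=fitted,
            resid=resid,
            rsquared=r2,
            bandwidth=bandwidth,
            n_ridge_fallbacks=int(n_jitter),
        )


@dataclass
class GTWRResults:
    """Per-observation local coefficients and global goodness of fit."""

    model: GTWR
    local_params: pd.DataFrame
    fittedvalues: np.ndarray
    resid: np.ndarray
    rsquared: float
    bandwidth: Bandwidth
    n_ridge_fallbacks: int = 0

    def coefficients(self, regressor: str) -> pd.Series:
        """Local slope series for one regressor, indexed (county_id, year)."""
        col = f"beta_{regressor}"
        if col not in self.local_params.columns:
            raise KeyError(f"no local coefficients for {regressor!r}")
        return self.local_params.set_index(["county_id", "year"])[col]

    def summary(self) -> str:
        bw = self.bandwidth
        lines = [
            "Geographically and Temporally Weighted Regression",
            f"obs: {self.model.n_obs}   local parameters per fit: {self.model.p}",
            f"adaptive k: {bw.k}   tau (phi_T/phi_S): {bw.params.tau:.4g}",
            f"global R2: {self.rsquared:.4f}"
            + (f"   CV score: {bw.cv_score:.4f}" if bw.cv_score is not None else ""),
        ]
        desc = self.local_params.drop(columns=["county_id", "year"]).describe().T[
            ["mean", "std", "min", "max"]
        ]
        return "\n".join(lines) + "\nlocal coefficient summary:\n" + desc.to_string(
            float_format=lambda v: f"{v: .4f}"
        )

    def to_csv(self, path) -> None:
        out = self.local_params.copy()
        out["fitted"] = self.fittedvalues
        out["residual"] = self.resid
        out["kernel_radius"] = self.bandwidth.b_it
        out.to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "k": int(self.bandwidth.k),
            "tau": float(self.bandwidth.params.tau),
            "phi_s": float(self.bandwidth.params.phi_s),
            "phi_t": float(self.bandwidth.params.phi_t),
            "cv_score": None if self.bandwidth.cv_score is None else float(self.bandwidth.cv_score),
            "rsquared": float(self.rsquared),
            "n_ridge_fallbacks": int(self.n_ridge_fallbacks),
        }

    def plot_coefficient_surface(self, regressor: str, year: int, ax=None):
        """Scatter map of one regressor's local coefficients in one year."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.model.panel.df
        mask = df["year"] == year
        vals = self.coefficients(regressor).xs(year, level="year")
        pts = df.loc[mask].set_index("county_id").loc[vals.index]
        sc = ax.scatter(pts["x"], pts["y"], c=vals.to_numpy(), s=30, marker="s")
        ax.set_xlabel("x (km)")
        ax.set_ylabel("y (km)")
        ax.set_title(f"local beta[{regressor}], {year}")
        plt.colorbar(sc, ax=ax)
        return ax
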