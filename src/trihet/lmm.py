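"""REML fitting and Wald tests for the linear mixed ANCOVA model.

On balanced three-level data the per-cluster covariance
V_i = sigma_eps^2 I + sigma_u^2 I_{n_s} (x) J_m + sigma_gamma^2 J_{n_s m}
shares eigenvectors with the nested exchangeable structure, so writing
g = sigma_gamma^2 / sigma_eps^2 and h = sigma_u^2 / sigma_eps^2 gives
V_i = sigma_eps^2 M with M eigenvalues

    nu1 = 1,  nu2 = 1 + h m,  nu3 = 1 + h m + g n_s m,

acting on within-subcluster contrasts, between-subcluster contrasts, and
the cluster mean respectively.  M^{-1} v is therefore computable in O(N)
from subcluster and cluster means, which makes every restricted-likelihood
evaluation linear in the data size — no dense matrices, no generic mixed
model machinery.  The restricted likelihood is profiled over the fixed
effects and sigma_eps^2, leaving a two-parameter optimization over
(g, h) >= 0; boundary estimates are exact zeros.

Wald tests use the model-based GLS covariance at the REML estimates: the
interaction (HTE) test against a standard normal (or chi-square for joint
tests of several modifiers), and the treatment-effect (ATE) test against a
standard normal or a t with the between-within degrees of freedom n_c - 2,
the customary small-sample reference for cluster-level contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .variance import DesignSpec


@dataclass(frozen=True)
class FitResult:
    """REML fit of the linear mixed ANCOVA model."""

    beta: np.ndarray
    names: tuple[str, ...]
    cov_beta: np.ndarray
    sigma2_gamma: float
    sigma2_u: float
    sigma2_eps: float
    loglik: float
    converged: bool
    n_iter: int
    n_c: int
    n_s: int
    m: int
    p: int

    @property
    def sigma2_total(self) -> float:
        return self.sigma2_gamma + self.sigma2_u + self.sigma2_eps

    @property
    def alpha0(self) -> float:
        return (self.sigma2_gamma + self.sigma2_u) / self.sigma2_total

    @property
    def alpha1(self) -> float:
        return self.sigma2_gamma / self.sigma2_total

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.names, self.beta.tolist())),
            "cov_beta": self.cov_beta.tolist(),
            "sigma2_gamma": self.sigma2_gamma,
            "sigma2_u": self.sigma2_u,
            "sigma2_eps": self.sigma2_eps,
            "alpha0": self.alpha0,
            "alpha1": self.alpha1,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "dims": {"n_c": self.n_c, "n_s": self.n_s, "m": self.m, "p": self.p},
        }


@dataclass(frozen=True)
class WaldTest:
    """A Wald test of one or more fixed-effect coefficients."""

    statistic: float
    reference: str
    df: Optional[int]
    p_value: float
    coefficients: tuple[str, ...]
    estimate: np.ndarray


def _minv_apply(v: np.ndarray, nu2: float, nu3: float) -> np.ndarray:
    """Apply M^{-1} to v of shape (n_c, n_s, m, k) via the projections."""
    sub = v.mean(axis=2, keepdims=True)
    clus = sub.mean(axis=1, keepdims=True)
    return (v - sub) + (sub - clus) / nu2 + clus / nu3


def _infer_shape(data: pd.DataFrame) -> tuple[int, int, int]:
    n_c = data["cluster"].nunique()
    sizes = data.groupby(["cluster", "subcluster"], sort=False).size()
    n_s_counts = data.groupby("cluster", sort=False)["subcluster"].nunique()
    if n_s_counts.nunique() != 1 or sizes.nunique() != 1:
        raise ValueError("data must be balanced: equal n_s per cluster and m per subcluster")
    return n_c, int(n_s_counts.iloc[0]), int(sizes.iloc[0])


def _design_arrays(
    data: Optional[pd.DataFrame],
    y: Optional[np.ndarray],
    x: Optional[np.ndarray],
    w: Optional[np.ndarray],
    design: Optional[DesignSpec],
    x_cols: Optional[Sequence[str]],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, int, int]:
    if data is not None:
        data = data.sort_values(["cluster", "subcluster", "participant"], kind="stable")
        n_c, n_s, m = _infer_shape(data)
        y = data["Y"].to_numpy(dtype=float)
        w = data["W"].to_numpy(dtype=float)
        if x_cols is None:
            x_cols = [c for c in data.columns if c == "X" or c.startswith("X")]
        x = data[list(x_cols)].to_numpy(dtype=float)
    else:
        if y is None or x is None or w is None or design is None:
            raise ValueError("provide either a TrialDataset or (y, x, w, design)")
        n_c, n_s, m = design.n_c, design.n_s, design.m
        y = np.asarray(y, dtype=float)
        w = np.asarray(w, dtype=float)
        x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    n = n_c * n_s * m
    if y.shape != (n,) or w.shape != (n,) or x.shape[0] != n:
        raise ValueError("y, w, x must have length n_c * n_s * m")
    return y, x, w, n_c, n_s, m


def _profiled_reml_parts(
    z: np.ndarray,
    y: np.ndarray,
    shape: tuple[int, int, int],
    g: float,
    h: float,
) -> tuple[float, float, np.ndarray, np.ndarray, float]:
    """Return (rss, logdet_m, beta_hat, ztmz, logdet_ztmz) at (g, h)."""
    n_c, n_s, m = shape
    q = z.shape[1]
    nu2 = 1.0 + h * m
    nu3 = 1.0 + h * m + g * n_s * m
    zc = z.reshape(n_c, n_s, m, q)
    yc = y.reshape(n_c, n_s, m, 1)
    minv_z = _minv_apply(zc, nu2, nu3).reshape(-1, q)
    minv_y = _minv_apply(yc, nu2, nu3).ravel()
    ztmz = z.T @ minv_z
    ztmy = minv_z.T @ y
    ytmy = float(y @ minv_y)
    sign, logdet_ztmz = np.linalg.slogdet(ztmz)
    if sign <= 0:
        raise np.linalg.LinAlgError("Z'M^{-1}Z is rank deficient")
    beta = np.linalg.solve(ztmz, ztmy)
    rss = ytmy - float(ztmy @ beta)
    logdet_m = n_c * ((n_s - 1) * math.log(nu2) + math.log(nu3))
    return rss, logdet_m, beta, ztmz, logdet_ztmz


def restricted_loglik(
    y: np.ndarray,
    z: np.ndarray,
    shape: tuple[int, int, int],
    sigma2_gamma: float,
    sigma2_u: float,
    sigma2_eps: float,
) -> float:
    """Restricted log-likelihood at given variance components.

    Uses the convention l_R = -1/2 { (N-q) log 2*pi + log|V| +
    log|Z'V^{-1}Z| + r'V^{-1}r } with r the GLS residual; computed entirely
    through the eigenvalue algebra.
    """
    n_c, n_s, m = shape
    n = n_c * n_s * m
    q = z.shape[1]
    g = sigma2_gamma / sigma2_eps
    h = sigma2_u / sigma2_eps
    rss, logdet_m, _, _, logdet_ztmz = _profiled_reml_parts(z, y, shape, g, h)
    logdet_v = n * math.log(sigma2_eps) + logdet_m
    logdet_info = logdet_ztmz - q * math.log(sigma2_eps)
    quad = rss / sigma2_eps
    return -0.5 * ((n - q) * math.log(2 * math.pi) + logdet_v + logdet_info + quad)


def _anova_start(z: np.ndarray, y: np.ndarray, shape: tuple[int, int, int]) -> tuple[float, float]:
    """Moment-based starting values for (g, h) from OLS residual mean squares."""
    n_c, n_s, m = shape
    beta0, *_ = np.linalg.lstsq(z, y, rcond=None)
    r = (y - z @ beta0).reshape(n_c, n_s, m)
    sub = r.mean(axis=2)
    clus = sub.mean(axis=1)
    ms_within = ((r - sub[:, :, None]) ** 2).sum() / max(n_c * n_s * (m - 1), 1)
    ms_sub = m * ((sub - clus[:, None]) ** 2).sum() / max(n_c * (n_s - 1), 1)
    ms_clus = n_s * m * (clus**2).sum() / max(n_c - 1, 1)
    s_eps = max(ms_within, 1e-8)
    s_u = max((ms_sub - s_eps) / m, 0.0)
    s_gam = max((ms_clus - s_eps - m * s_u) / (n_s * m), 0.0)
    return s_gam / s_eps, s_u / s_eps


def fit_lm_ancova(
    data: Optional[pd.DataFrame] = None,
    *,
    y: Optional[np.ndarray] = None,
    x: Optional[np.ndarray] = None,
    w: Optional[np.ndarray] = None,
    design: Optional[DesignSpec] = None,
    x_cols: Optional[Sequence[str]] = None,
    center_w: bool = True,
    center_x: bool = False,
    start: Optional[tuple[float, float]] = None,
    max_iter: int = 200,
) -> FitResult:
    """Fit the linear mixed ANCOVA model by REML on balanced data.

    Accepts either a tidy TrialDataset (columns cluster, subcluster,
    participant, W, X..., Y) or raw arrays with a :class:`DesignSpec`.
    ``center_w`` centers the treatment indicator at its sample mean;
    ``center_x`` globally mean-centers the modifiers so the treatment
    coefficient is the covariate-adjusted ATE.  Mean-centering X does not
    change the interaction test.

    Non-convergence is flagged on the result, not raised.
    """
    y_a, x_a, w_a, n_c, n_s, m = _design_arrays(data, y, x, w, design, x_cols)
    shape = (n_c, n_s, m)
    p = x_a.shape[1]
    wc = w_a - w_a.mean() if center_w else w_a
    xc = x_a - x_a.mean(axis=0) if center_x else x_a
    n = n_c * n_s * m
    z = np.empty((n, 2 + 2 * p))
    z[:, 0] = 1.0
    z[:, 1] = wc
    z[:, 2 : 2 + p] = xc
    z[:, 2 + p :] = wc[:, None] * xc
    if p == 1:
        names = ("intercept", "W", "X", "W:X")
    else:
        names = (
            ("intercept", "W")
            + tuple(f"X{j + 1}" for j in range(p))
            + tuple(f"W:X{j + 1}" for j in range(p))
        )
    q = z.shape[1]

    def objective(params: np.ndarray) -> float:
        g, h = params
        try:
            rss, logdet_m, _, _, logdet_ztmz = _profiled_reml_parts(z, y_a, shape, g, h)
        except np.linalg.LinAlgError:
            return 1e12
        if rss <= 0:
            return 1e12
        return (n - q) * math.log(rss / (n - q)) + logdet_m + logdet_ztmz

    x0 = np.asarray(start if start is not None else _anova_start(z, y_a, shape))
    x0 = np.clip(x0, 0.0, 1e3)
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(0.0, 1e4), (0.0, 1e4)],
        options={"maxiter": max_iter},
    )
    if not res.success:
        # derivative-free polish; the profiled surface is smooth but can be
        # very flat near a variance-component boundary
        res2 = optimize.minimize(
            objective,
            np.clip(res.x, 0.0, 1e4),
            method="Nelder-Mead",
            bounds=[(0.0, 1e4), (0.0, 1e4)],
            options={"maxiter": 400, "xatol": 1e-10, "fatol": 1e-10},
        )
        if res2.fun <= res.fun:
            res2.nit += res.nit
            res = res2
    g_hat, h_hat = res.x
    rss, _, beta, ztmz, _ = _profiled_reml_parts(z, y_a, shape, g_hat, h_hat)
    sigma2_eps = rss / (n - q)
    cov_beta = sigma2_eps * np.linalg.inv(ztmz)
    loglik = restricted_loglik(
        y_a, z, shape, g_hat * sigma2_eps, h_hat * sigma2_eps, sigma2_eps
    )
    return FitResult(
        beta=beta,
        names=names,
        cov_beta=cov_beta,
        sigma2_gamma=g_hat * sigma2_eps,
        sigma2_u=h_hat * sigma2_eps,
        sigma2_eps=sigma2_eps,
        loglik=loglik,
        converged=bool(res.success),
        n_iter=int(res.nit),
        n_c=n_c,
        n_s=n_s,
        m=m,
        p=p,
    )


def wald_hte(fit: FitResult, joint: bool = False) -> WaldTest:
    """Wald test of no treatment-by-modifier interaction.

    Scalar case: z = beta4-hat / SE against a standard normal.  Joint case:
    quadratic form of all p interaction coefficients against chi-square(p).
    """
    idx = list(range(2 + fit.p, 2 + 2 * fit.p))
    est = fit.beta[idx]
    cov = fit.cov_beta[np.ix_(idx, idx)]
    coef_names = tuple(fit.names[i] for i in idx)
    if joint or fit.p > 1:
        sign, _ = np.linalg.slogdet(cov)
        if sign <= 0:
            raise np.linalg.LinAlgError("singular interaction covariance")
        stat = float(est @ np.linalg.solve(cov, est))
        pval = float(stats.chi2.sf(stat, fit.p))
        return WaldTest(stat, "chi2", fit.p, pval, coef_names, est)
    z = float(est[0] / math.sqrt(cov[0, 0]))
    pval = float(2 * stats.norm.sf(abs(z)))
    return WaldTest(z, "normal", None, pval, coef_names, est)


def wald_ate(fit: FitResult, reference: str = "normal") -> WaldTest:
    """Wald test of the covariate-adjusted ATE (treatment coefficient).

    With a globally mean-centered modifier, the treatment coefficient is the
    covariate-adjusted ATE.  ``reference`` is 'normal' or 't_betweenwithin'
    (t with n_c - 2 degrees of freedom, for cluster randomized designs).
    """
    est = fit.beta[1:2]
    se = math.sqrt(fit.cov_beta[1, 1])
    z = float(est[0] / se)
    if reference == "t_betweenwithin":
        df = fit.n_c - 2
        if df < 1:
            raise ValueError("t reference requires n_c > 2")
        pval = float(2 * stats.t.sf(abs(z), df))
        return WaldTest(z, "t", df, pval, (fit.names[1],), est)
    if reference != "normal":
        raise ValueError("reference must be 'normal' or 't_betweenwithin'")
    pval = float(2 * stats.norm.sf(abs(z)))
    return WaldTest(z, "normal", None, pval, (fit.names[1],), est)
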