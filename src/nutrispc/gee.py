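"""Generalized estimating equations with exchangeable working correlation.

A from-scratch GEE solver for the pre/post sensitivity analysis of the
chart suite: marginal regression of a repeated child outcome (binary
stunting with a logit link, or continuous LAZ with an identity link) on an
intercept plus a post-period indicator, clustering on the child, with a
robust (Liang-Zeger sandwich) covariance.

Estimating-equation conventions (these matter for cross-checks against
other software, which differ in small-sample corrections):

* Pearson dispersion  phi = sum(e_ij^2) / (N - p);
* exchangeable alpha  = [sum over within-cluster pairs e_ij e_ik / phi]
  / (sum_i n_i (n_i - 1)/2 - p);
* Fisher scoring on beta with working covariance
  V_i = A_i^(1/2) R(alpha) A_i^(1/2) (dispersion excluded, as it cancels
  from both the score equation and the sandwich);
* naive covariance B^(-1) * phi (phi fixed at 1 for the binomial family),
  robust covariance B^(-1) M B^(-1).

The exchangeable working inverse is applied in closed form (Woodbury), so
fits scale linearly in the number of observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "PanelData", "GEEFit",
    "build_panel", "fit_gee", "marginal_period_effect", "exclude_first_quarter",
]

_Z95 = 1.959963984540054  # standard-normal 97.5% quantile


@dataclass
class PanelData:
    """Stacked clustered data: outcome y, design matrix X (intercept +
    post-period indicator by default), child cluster ids, per-row quarter."""

    y: np.ndarray
    X: np.ndarray
    cluster: np.ndarray
    quarter: np.ndarray
    colnames: tuple[str, ...] = ("intercept", "post")

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.quarter = np.asarray(self.quarter)
        if len(np.unique(self.cluster)) < 2:
            raise ValueError("panel needs at least 2 clusters")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("design matrix is rank deficient")

    def subset(self, mask: np.ndarray) -> "PanelData":
        return PanelData(self.y[mask], self.X[mask], self.cluster[mask],
                         self.quarter[mask], self.colnames)


@dataclass
class GEEFit:
    """Fitted GEE: coefficients, exchangeable correlation, sandwich and
    model-based covariances, and convergence metadata."""

    beta: np.ndarray
    alpha: float
    robust_cov: np.ndarray
    naive_cov: np.ndarray
    scale: float
    n_iterations: int
    converged: bool
    family: str
    colnames: tuple[str, ...]

    @property
    def robust_se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.robust_cov))

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "beta": dict(zip(self.colnames, map(float, self.beta))),
            "robust_se": dict(zip(self.colnames, map(float, self.robust_se))),
            "alpha": float(self.alpha),
            "scale": float(self.scale),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
        }


def build_panel(dedup_records: pd.DataFrame, intervention_start: str,
                outcome: str = "stunted") -> PanelData:
    """Panel from per-child-per-quarter deduplicated observations.

    ``dedup_records`` needs columns child_id, quarter (string id), and the
    outcome ("stunted" or "laz"). The design is intercept + indicator of
    quarters at or after ``intervention_start``.
    """
    q_int = pd.Period(intervention_start, freq="Q")
    rows = dedup_records[dedup_records[outcome].notna()]
    quarters = np.array([str(q) for q in rows["quarter"]])
    post = np.array([pd.Period(q, freq="Q") >= q_int for q in quarters], dtype=float)
    X = np.column_stack([np.ones(len(rows)), post])
    return PanelData(rows[outcome].to_numpy(dtype=float), X,
                     rows["child_id"].to_numpy(), quarters)


def exclude_first_quarter(panel: PanelData) -> PanelData:
    """Drop all rows of the earliest quarter present (sensitivity variant).

    Not idempotent: applying twice removes the two earliest quarters.
    """
    periods = np.array([pd.Period(q, freq="Q").ordinal for q in panel.quarter])
    uniq = np.unique(periods)
    if len(uniq) < 2:
        raise ValueError("panel spans a single quarter; nothing would remain")
    return panel.subset(periods != uniq.min())


# --- the solver -----------------------------------------------------------

def _order_by_cluster(panel: PanelData):
    order = np.argsort(panel.cluster, kind="stable")
    cl = panel.cluster[order]
    starts = np.r_[0, 1 + np.flatnonzero(cl[1:] != cl[:-1])]
    sizes = np.diff(np.r_[starts, len(cl)])
    return order, starts, sizes


def _mu_and_deriv(eta: np.ndarray, family: str):
    if family == "gaussian":
        return eta, np.ones_like(eta), np.ones_like(eta)
    mu = expit(eta)
    var = mu * (1.0 - mu)
    return mu, var, var  # canonical logit: dmu/deta = mu(1-mu) = var


def fit_gee(panel: PanelData, family: str = "gaussian",
            max_iter: int = 100, tol: float = 1e-8,
            fixed_alpha: float | None = None) -> GEEFit:
    """Fit the GEE by alternating Fisher scoring on beta with moment
    updates of the exchangeable correlation.

    ``family`` is "gaussian" (identity link) or "binomial" (logit link).
    ``fixed_alpha`` freezes the working correlation (0 gives the
    independence-GLM fit). Convergence: max |delta beta| < tol.
    Non-convergence is reported via ``converged=False`` (with a warning),
    never an exception; quasi-complete separation in the binomial case is
    warned about.
    """
    if family not in ("gaussian", "binomial"):
        raise ValueError("family must be 'gaussian' or 'binomial'")
    order, starts, sizes = _order_by_cluster(panel)
    y = panel.y[order]
    X = panel.X[order]
    n_obs, p = X.shape
    seg = np.repeat(np.arange(len(sizes)), sizes)
    max_n = int(sizes.max())
    n_pairs = float(np.sum(sizes * (sizes - 1)) / 2.0)

    def segsum(a: np.ndarray) -> np.ndarray:
        """Per-cluster sums of rows (1-D or 2-D)."""
        return np.add.reduceat(a, starts, axis=0)

    beta = np.zeros(p)
    if family == "gaussian":
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
    alpha = 0.0
    scale = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu, var, dmu = _mu_and_deriv(eta, family)
        sdev = np.sqrt(var)
        resid = y - mu

        # moment updates of dispersion and alpha at the current beta
        e = resid / sdev
        scale = float(np.sum(e * e) / (n_obs - p))
        if fixed_alpha is not None:
            alpha = float(fixed_alpha)
        elif n_pairs > 0 and n_pairs - p > 0 and max_n > 1:
            cluster_e = segsum(e)
            cross = float(np.sum(cluster_e ** 2 - segsum(e * e)) / 2.0)
            alpha = cross / scale / (n_pairs - p)
            lo = -1.0 / (max_n - 1) + 1e-8
            alpha = float(np.clip(alpha, lo, 1.0 - 1e-8))
        else:
            alpha = 0.0

        # Fisher scoring step with exchangeable working inverse (Woodbury):
        # V^-1 x = A^-1/2 [ u/(1-a) - c_i * 1 * sum(u) ] with u = A^-1/2 x
        D = X * dmu[:, None]
        U = D / sdev[:, None]
        r_std = resid / sdev
        ci = (alpha / (1.0 - alpha)) / (1.0 + alpha * (sizes - 1.0))
        Usum = segsum(U)
        rsum = segsum(r_std)
        vinv_D = (U / (1.0 - alpha) - ci[seg, None] * Usum[seg]) / sdev[:, None]
        vinv_r = (r_std / (1.0 - alpha) - ci[seg] * rsum[seg]) / sdev

        bmat = D.T @ vinv_D
        score = D.T @ vinv_r
        try:
            step = np.linalg.solve(bmat, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(bmat, score, rcond=None)[0]
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break

    if not converged:
        warnings.warn(f"GEE did not converge in {max_iter} iterations", stacklevel=2)
    if family == "binomial" and np.max(np.abs(X @ beta)) > 30:
        warnings.warn("possible separation: fitted probabilities at 0/1", stacklevel=2)

    # covariances at the final beta
    eta = X @ beta
    mu, var, dmu = _mu_and_deriv(eta, family)
    sdev = np.sqrt(var)
    resid = y - mu
    e = resid / sdev
    scale = float(np.sum(e * e) / (n_obs - p))
    D = X * dmu[:, None]
    U = D / sdev[:, None]
    r_std = resid / sdev
    ci = (alpha / (1.0 - alpha)) / (1.0 + alpha * (sizes - 1.0))
    Usum = segsum(U)
    rsum = segsum(r_std)
    vinv_D = (U / (1.0 - alpha) - ci[seg, None] * Usum[seg]) / sdev[:, None]
    vinv_r = (r_std / (1.0 - alpha) - ci[seg] * rsum[seg]) / sdev
    bmat = D.T @ vinv_D
    t = segsum(D * vinv_r[:, None])           # per-cluster D_i' V_i^-1 r_i
    cmat = t.T @ t
    binv = np.linalg.inv(bmat)
    robust = binv @ cmat @ binv
    naive = binv * (1.0 if family == "binomial" else scale)

    return GEEFit(beta=beta, alpha=float(alpha), robust_cov=robust,
                  naive_cov=naive, scale=scale, n_iterations=it,
                  converged=converged, family=family, colnames=panel.colnames)


# --- marginal period effect ----------------------------------------------

def marginal_period_effect(fit: GEEFit, panel: PanelData,
                           term: str = "post") -> dict:
    """Marginal pre/post contrast with a 95% robust Wald CI.

    Gaussian family: the effect is the post-period coefficient itself
    (identity link), in Z units.

    Binomial family: g-computation — the average predicted stunting
    probability with the post indicator set to 1 versus 0 over all rows —
    reported both as an absolute risk difference and as a relative decline
    in percent, 100 * (p0 - p1)/p0, with a delta-method CI on the robust
    covariance. (A relative-decline reading of a "proportion declined x%"
    summary; the absolute difference is reported alongside.)
    """
    if not fit.converged:
        raise ValueError("marginal effect requires a converged fit")
    j = fit.colnames.index(term)
    if fit.family == "gaussian":
        est = float(fit.beta[j])
        se = float(fit.robust_se[j])
        return {
            "family": "gaussian", "kind": "mean_difference",
            "estimate": est, "se": se,
            "ci_low": est - _Z95 * se, "ci_high": est + _Z95 * se,
        }

    X1 = panel.X.copy()
    X0 = panel.X.copy()
    X1[:, j] = 1.0
    X0[:, j] = 0.0
    mu1 = expit(X1 @ fit.beta)
    mu0 = expit(X0 @ fit.beta)
    p1, p0 = float(mu1.mean()), float(mu0.mean())
    dp1 = (mu1 * (1 - mu1)) @ X1 / len(mu1)
    dp0 = (mu0 * (1 - mu0)) @ X0 / len(mu0)

    rd = p1 - p0
    g_rd = dp1 - dp0
    se_rd = float(np.sqrt(g_rd @ fit.robust_cov @ g_rd))

    decline = (p0 - p1) / p0              # relative decline, fraction
    g_dec = -dp1 / p0 + (p1 / p0 ** 2) * dp0
    se_dec = float(np.sqrt(g_dec @ fit.robust_cov @ g_dec))

    return {
        "family": "binomial", "kind": "stunting_decline",
        "p_pre": p0, "p_post": p1,
        "risk_difference": rd, "risk_difference_se": se_rd,
        "risk_difference_ci": [rd - _Z95 * se_rd, rd + _Z95 * se_rd],
        "estimate": 100.0 * decline, "se": 100.0 * se_dec,
        "ci_low": 100.0 * (decline - _Z95 * se_dec),
        "ci_high": 100.0 * (decline + _Z95 * se_dec),
    }
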