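"""Statistics for left-censored measurements.

Two estimators:

* :func:`ros_summary` — regression-on-order-statistics (Helsel / Hirsch-
  Stedinger) imputation on the natural-log scale, giving geometric and
  arithmetic means for multiply-censored concentration data.
* :func:`censored_linregress` — maximum-likelihood linear regression with a
  left-censored Gaussian likelihood (Tobit-type), the engine behind every
  trophic magnification factor.

Errors are Gaussian on the natural-log scale throughout (the lognormal
convention for environmental concentration data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import CensoringError, RegressionError

_SIGMA_FLOOR = 1e-8


@dataclass(frozen=True)
class CensoredMeasurement:
    """One measurement that may be below its quantification limit.

    ``value`` is the reported quantity, or the limit itself when censored;
    ``limit`` shares the units of ``value``.
    """

    value: float
    censored: bool = False
    limit: float = float("nan")

    def __post_init__(self):
        if not math.isfinite(self.value):
            raise ValueError("value must be finite")
        if self.censored:
            if not math.isfinite(self.limit):
                raise ValueError("censored measurement requires a finite limit")
            if self.value != self.limit:
                raise ValueError("censored measurement must carry value == limit")


@dataclass(frozen=True)
class CensoredFit:
    """Result of a left-censored Gaussian linear regression."""

    slope: float
    intercept: float
    slope_se: float
    sigma: float  # residual sd on the ln scale
    n_total: int
    n_censored: int
    log_likelihood: float
    p_value: float  # two-sided Wald test of slope == 0
    p_value_lr: float = float("nan")  # likelihood-ratio alternative

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0 <= self.n_censored <= self.n_total):
            raise ValueError("0 <= n_censored <= n_total violated")


# ---------------------------------------------------------------------------
# ROS summary statistics
# ---------------------------------------------------------------------------

def _hirsch_stedinger_ppoints(values, censored):
    """Cumulative plotting positions for multiply-censored data.

    Thresholds are the distinct censoring limits processed from the highest
    down (the Hirsch-Stedinger exceedance recursion); detects between
    thresholds and nondetects below each threshold get Weibull-type positions
    within their interval.  Returns (pp_detects, pp_censored) aligned with the
    detect/censored subsets in input order.
    """
    values = np.asarray(values, dtype=float)
    censored = np.asarray(censored, dtype=bool)
    det = values[~censored]
    cen = values[censored]

    limits = np.unique(cen)  # ascending
    # Interval edges: T_0 = 0 (below any detect), then the limits, then +inf.
    edges = np.concatenate(([-np.inf], limits, [np.inf]))
    k = len(limits)

    # Cohn numbers per threshold index j (0..k): A_j detects in (T_j, T_{j+1}],
    # B_j observations <= T_j, C_j nondetects censored exactly at T_j.
    A = np.array(
        [np.sum((det > edges[j]) & (det <= edges[j + 1])) for j in range(k + 1)]
    )
    B = np.array(
        [np.sum(det <= edges[j]) + np.sum(cen <= edges[j]) for j in range(k + 1)]
    )
    C = np.array([np.sum(cen == limits[j - 1]) if j >= 1 else 0 for j in range(k + 1)])

    # Exceedance probabilities P_j = P(X > T_j), recursion from the top.
    P = np.zeros(k + 2)  # P[k+1] = 0 above the highest interval
    for j in range(k, -1, -1):
        denom = A[j] + B[j]
        frac = A[j] / denom if denom > 0 else 0.0
        P[j] = P[j + 1] + frac * (1.0 - P[j + 1])

    pp_det = np.empty(len(det))
    for j in range(k + 1):
        idx = np.where((det > edges[j]) & (det <= edges[j + 1]))[0]
        if len(idx) == 0:
            continue
        order = np.argsort(det[idx], kind="stable")
        ranks = np.empty(len(idx))
        ranks[order] = np.arange(1, len(idx) + 1)
        pp_det[idx] = (1.0 - P[j]) + ranks / (A[j] + 1.0) * (P[j] - P[j + 1])

    pp_cen = np.empty(len(cen))
    for j in range(1, k + 1):
        idx = np.where(cen == limits[j - 1])[0]
        ranks = np.arange(1, len(idx) + 1)
        pp_cen[idx] = ranks / (C[j] + 1.0) * (1.0 - P[j])

    return pp_det, pp_cen


def ros_summary(measurements) -> dict:
    """Geometric and arithmetic mean of left-censored concentrations via ROS.

    Uncensored values are regressed (ln scale) on normal quantiles of their
    Hirsch-Stedinger plotting positions; censored observations are imputed
    from the fitted line at their own positions; means are taken over
    observed + imputed values.

    Returns ``{"geometric_mean", "arithmetic_mean", "n", "n_censored"}``.

    Raises
    ------
    CensoringError
        Fewer than 3 values, no uncensored value, or censoring >= 80 %
        (report "< limit" instead of a mean).
    """
    ms = list(measurements)
    n = len(ms)
    if n < 3:
        raise CensoringError(f"need >= 3 values, got {n}")
    values = np.array([m.value for m in ms], dtype=float)
    cens = np.array([m.censored for m in ms], dtype=bool)
    if np.any(values <= 0):
        raise CensoringError("ROS requires strictly positive values/limits")
    n_cen = int(cens.sum())
    if n_cen == n:
        raise CensoringError("all values censored; report '< limit' instead")
    if n_cen / n >= 0.8:
        raise CensoringError(
            f"censoring fraction {n_cen / n:.0%} >= 80%; report '< limit' instead"
        )

    if n_cen == 0:
        ln = np.log(values)
        return {
            "geometric_mean": float(np.exp(ln.mean())),
            "arithmetic_mean": float(values.mean()),
            "n": n,
            "n_censored": 0,
        }

    pp_det, pp_cen = _hirsch_stedinger_ppoints(values, cens)
    q_det = stats.norm.ppf(pp_det)
    ln_det = np.log(values[~cens])
    slope, intercept = np.polyfit(q_det, ln_det, 1)
    imputed = np.exp(intercept + slope * stats.norm.ppf(pp_cen))
    full = np.concatenate([values[~cens], imputed])
    return {
        "geometric_mean": float(np.exp(np.log(full).mean())),
        "arithmetic_mean": float(full.mean()),
        "n": n,
        "n_censored": n_cen,
    }


# ---------------------------------------------------------------------------
# Censored MLE regression
# ---------------------------------------------------------------------------

def censored_neg_loglik(params, x, y, cens):
    """Negative log-likelihood of the left-censored Gaussian line.

    ``params = (intercept, slope, ln_sigma)``.  Uncensored points contribute
    density terms; censored points contribute lower-tail Phi terms at their
    (ln) limits.
    """
    b0, b1, ln_s = params
    s = math.exp(ln_s)
    mu = b0 + b1 * x
    z = (y - mu) / s
    nll = 0.0
    unc = ~cens
    if np.any(unc):
        nll -= np.sum(stats.norm.logpdf(z[unc])) - unc.sum() * ln_s
    if np.any(cens):
        nll -= np.sum(stats.norm.logcdf(z[cens]))
    return nll


def _neg_loglik_and_grad(params, x, y, cens):
    """NLL and its analytic gradient wrt (intercept, slope, ln_sigma)."""
    b0, b1, ln_s = params
    s = math.exp(ln_s)
    z = (y - (b0 + b1 * x)) / s
    unc = ~cens
    zu, xu = z[unc], x[unc]
    zc, xc = z[cens], x[cens]
    nll = float(np.sum(0.5 * zu**2) + unc.sum() * (ln_s + 0.5 * math.log(2 * math.pi)))
    g0 = -np.sum(zu) / s
    g1 = -np.sum(xu * zu) / s
    gs = np.sum(1.0 - zu**2)
    if zc.size:
        nll -= float(np.sum(stats.norm.logcdf(zc)))
        r = np.exp(stats.norm.logpdf(zc) - stats.norm.logcdf(zc))  # inverse Mills
        g0 += np.sum(r) / s
        g1 += np.sum(xc * r) / s
        gs += np.sum(r * zc)
    return nll, np.array([g0, g1, gs])


def _numerical_hessian(f, p, steps):
    k = len(p)
    H = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            hi, hj = steps[i], steps[j]
            if i == j:
                H[i, i] = (f(_pert(p, i, hi)) - 2 * f(p) + f(_pert(p, i, -hi))) / hi**2
            else:
                fpp = f(_pert(_pert(p, i, hi), j, hj))
                fpm = f(_pert(_pert(p, i, hi), j, -hj))
                fmp = f(_pert(_pert(p, i, -hi), j, hj))
                fmm = f(_pert(_pert(p, i, -hi), j, -hj))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hi * hj)
    return H


def _pert(p, i, h):
    q = np.array(p, dtype=float)
    q[i] += h
    return q


def censored_linregress(y_measurements, x) -> CensoredFit:
    """MLE line through left-censored (ln-scale) responses.

    Parameters
    ----------
    y_measurements : sequence of CensoredMeasurement
        Responses on the natural-log scale (values may be negative); censored
        entries carry their ln quantification limit as both value and limit.
    x : array-like
        Covariate (trophic positions), same length.

    Returns
    -------
    CensoredFit
        Slope/intercept maximizing the censored Gaussian likelihood; slope SE
        from the observed information matrix; Wald and likelihood-ratio
        p-values for slope == 0.

    Raises
    ------
    RegressionError
        Constant covariate, fewer than 3 uncensored points, or optimizer
        failure (diagnostics attached to the message).
    """
    ms = list(y_measurements)
    x = np.asarray(x, dtype=float)
    if len(ms) != len(x):
        raise RegressionError(f"length mismatch: {len(ms)} responses vs {len(x)} covariates")
    y = np.array([m.value for m in ms], dtype=float)
    cens = np.array([m.censored for m in ms], dtype=bool)
    n = len(y)
    n_cen = int(cens.sum())
    if n - n_cen < 3:
        raise RegressionError(f"need >= 3 uncensored points, got {n - n_cen}")
    if np.ptp(x) == 0:
        raise RegressionError("covariate is constant (design degeneracy)")

    # Center both axes: conditioning, and it makes the fit exactly invariant
    # to per-sample-constant shifts of y (the scheme-equivalence identity).
    x_mean, y_mean = float(x.mean()), float(y.mean())
    x = x - x_mean
    y = y - y_mean

    # Start from OLS with censored responses substituted at their limits.
    b1_0, b0_0 = np.polyfit(x, y, 1)
    resid = y - (b0_0 + b1_0 * x)
    s0 = max(float(np.std(resid, ddof=min(2, n - 1))), _SIGMA_FLOOR)
    p0 = np.array([b0_0, b1_0, math.log(s0)])

    bounds = [(None, None), (None, None), (math.log(_SIGMA_FLOOR), None)]
    res = optimize.minimize(
        _neg_loglik_and_grad,
        p0,
        args=(x, y, cens),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-16, "gtol": 1e-12},
    )
    at_sigma_floor = res.x[2] <= math.log(_SIGMA_FLOOR) + 1e-6
    if not res.success and not at_sigma_floor:
        # Line-search hiccups can end L-BFGS-B prematurely; a near-zero
        # gradient means the optimum was reached anyway (Newton polish below
        # tightens it).  Otherwise try a Nelder-Mead restart before giving up.
        _, g = _neg_loglik_and_grad(res.x, x, y, cens)
        if np.max(np.abs(g)) > 1e-5:
            res2 = optimize.minimize(
                censored_neg_loglik,
                res.x,
                args=(x, y, cens),
                method="Nelder-Mead",
                options={"maxiter": 4000, "xatol": 1e-10, "fatol": 1e-10},
            )
            if res2.fun <= res.fun:
                res = res2
            at_sigma_floor = res.x[2] <= math.log(_SIGMA_FLOOR) + 1e-6
            _, g = _neg_loglik_and_grad(res.x, x, y, cens)
            if not res.success and not at_sigma_floor and np.max(np.abs(g)) > 1e-5:
                raise RegressionError(
                    f"censored regression did not converge: {res.message} "
                    f"(max |grad| {np.max(np.abs(g)):.2e})"
                )

    p_opt, f_opt = res.x, res.fun
    if not at_sigma_floor:
        p_opt, f_opt = _newton_polish(p_opt, f_opt, x, y, cens)

    b0, b1, ln_s = p_opt
    sigma = max(math.exp(ln_s), _SIGMA_FLOOR)
    ll = -f_opt
    intercept = b0 + y_mean - b1 * x_mean  # undo the centering

    slope_se = _slope_se(x, y, cens, b0, b1, sigma)

    if slope_se > 0 and math.isfinite(slope_se):
        wald_p = 2.0 * stats.norm.sf(abs(b1) / slope_se)
    else:
        wald_p = 0.0 if b1 != 0 else 1.0

    # Likelihood-ratio alternative: refit with slope pinned at 0.
    lr_p = float("nan")
    try:
        null = optimize.minimize(
            lambda q: censored_neg_loglik((q[0], 0.0, q[1]), x, y, cens),
            np.array([np.mean(y), math.log(max(np.std(y), _SIGMA_FLOOR))]),
            method="L-BFGS-B",
            bounds=[(None, None), (math.log(_SIGMA_FLOOR), None)],
        )
        if null.success:
            lr_stat = max(0.0, 2.0 * (ll - (-null.fun)))
            lr_p = float(stats.chi2.sf(lr_stat, df=1))
    except Exception:
        pass

    return CensoredFit(
        slope=float(b1),
        intercept=float(intercept),
        slope_se=float(slope_se),
        sigma=float(sigma),
        n_total=n,
        n_censored=n_cen,
        log_likelihood=float(ll),
        p_value=float(wald_p),
        p_value_lr=lr_p,
    )


def _newton_polish(p, f, x, y, cens, max_iter=20, gtol=1e-11):
    """Newton refinement of the L-BFGS-B optimum (analytic gradient,
    finite-difference Hessian of the gradient).  Tightens the solution to
    ~1e-12 so per-sample-constant transforms give bit-comparable slopes."""
    p = np.array(p, dtype=float)
    for _ in range(max_iter):
        _, g = _neg_loglik_and_grad(p, x, y, cens)
        if np.max(np.abs(g)) < gtol:
            break
        H = np.empty((3, 3))
        steps = np.maximum(1e-6 * np.abs(p), 1e-8)
        for i in range(3):
            _, g_plus = _neg_loglik_and_grad(_pert(p, i, steps[i]), x, y, cens)
            _, g_minus = _neg_loglik_and_grad(_pert(p, i, -steps[i]), x, y, cens)
            H[:, i] = (g_plus - g_minus) / (2 * steps[i])
        H = 0.5 * (H + H.T)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        trial = p - step
        f_trial, _ = _neg_loglik_and_grad(trial, x, y, cens)
        if not np.isfinite(f_trial) or f_trial > f + 1e-9:
            break
        p, f = trial, f_trial
    return p, f


def _slope_se(x, y, cens, b0, b1, sigma):
    """Slope SE from the observed information of (b0, b1, sigma).

    Falls back to the fixed-sigma two-parameter information when the full
    matrix is singular (e.g. sigma at its floor on noiseless data).
    """
    def nll_s(p):
        return censored_neg_loglik((p[0], p[1], math.log(max(p[2], _SIGMA_FLOOR))), x, y, cens)

    p = np.array([b0, b1, max(sigma, _SIGMA_FLOOR)])
    steps = np.maximum(1e-5 * np.abs(p), 1e-7)
    try:
        H = _numerical_hessian(nll_s, p, steps)
        cov = np.linalg.inv(H)
        se2 = cov[1, 1]
        if se2 > 0 and np.isfinite(se2):
            return math.sqrt(se2)
    except np.linalg.LinAlgError:
        pass
    # Fixed-sigma fallback: information of (b0, b1) only.
    try:
        H2 = _numerical_hessian(
            lambda q: censored_neg_loglik((q[0], q[1], math.log(sigma)), x, y, cens),
            np.array([b0, b1]),
            np.maximum(1e-5 * np.abs([b0, b1]), 1e-7),
        )
        cov2 = np.linalg.inv(H2)
        if cov2[1, 1] > 0:
            return math.sqrt(cov2[1, 1])
    except np.linalg.LinAlgError:
        pass
    # Last resort (noiseless fits): classical OLS-style formula.
    sxx = np.sum((x - x.mean()) ** 2)
    return sigma / math.sqrt(sxx)
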