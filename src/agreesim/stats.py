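"""Mixed-effects analyses for simulated agreement measures.

Probability responses (one-sample completion probabilities) are analyzed
with beta mixed-effects regression: ``y ~ Beta(mu*phi, (1-mu)*phi)`` with a
logit link for the mean ``mu`` (Ferrari & Cribari-Neto parameterization)
and Gaussian random intercepts/slopes integrated out by a Laplace
approximation (Fisher-scoring inner loop).  Surprisal responses are
analyzed with linear mixed-effects regression via the profiled marginal
likelihood (REML by default).  Significance of fixed effects is assessed
by Wald z (beta fits) or t statistics (linear fits; p-values use a normal
approximation, flagged in the output).  Equality of two fixed effects is
tested by a likelihood-ratio test against a model in which their design
columns are merged.

All factors are sum-to-zero coded (so with balanced two-level factors the
intercept is the grand mean on the link scale and each coefficient is half
the difference between level means); coefficient magnitudes depend on this
choice.  The convergence-driven pruning protocol starts from a maximal
random-effects structure and removes slope terms in a fixed, documented
order until the fit converges without singular variance estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy import stats as sps

__all__ = [
    "RegressionSpec",
    "FitResult",
    "fit_beta_mixed",
    "fit_linear_mixed",
    "prune_random_effects",
    "linear_hypothesis_test",
    "design_matrix",
    "squeeze_unit_interval",
]

logger = logging.getLogger(__name__)

_SD_LOG_BOUNDS = (-8.0, 4.0)
_SINGULAR_LOG_SD = -5.0


@dataclass(frozen=True)
class RegressionSpec:
    """Model specification: response, fixed terms, random-effect structure.

    ``fixed`` terms are factor names or ``a:b`` interactions; all terms are
    sum-to-zero coded.  ``random_slopes`` are (group, term) pairs; each
    random term contributes an independent variance component.
    """

    response: str
    kind: str                                  # "probability" | "gaussian"
    fixed: tuple[str, ...]
    random_intercepts: tuple[str, ...] = ("item", "instance")
    random_slopes: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.kind not in ("probability", "gaussian"):
            raise ValueError(f"unknown response kind {self.kind!r}")


@dataclass
class FitResult:
    """Coefficients, dispersion, random-effect variances and test statistics."""

    spec: RegressionSpec
    method: str                               # "beta_mixed" | "linear_mixed"
    params: pd.Series
    se: pd.Series
    stat: pd.Series                           # Wald z or t
    pvalues: pd.Series
    loglik: float
    phi: float | None = None                  # beta precision
    sigma2: float | None = None               # gaussian residual variance
    re_var: dict = field(default_factory=dict)
    converged: bool = True
    singular: bool = False
    reml: bool = False
    n_obs: int = 0
    notes: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        label = "|z|" if self.method == "beta_mixed" else "|t|"
        return pd.DataFrame({
            "term": self.params.index,
            "beta": self.params.values,
            "SE": self.se.values,
            label: np.abs(self.stat.values),
            "p": self.pvalues.values,
        })


# ---------------------------------------------------------------------------
# design matrices (sum-to-zero coding)
# ---------------------------------------------------------------------------

def _factor_columns(data: pd.DataFrame, factor: str):
    """Sum-coded columns for one factor (last level is the negative pole)."""
    col = data[factor]
    if pd.api.types.is_numeric_dtype(col):
        return [np.asarray(col, dtype=float)], [factor]
    levels = sorted(col.astype(str).unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    cols, names = [], []
    for lev in levels[:-1]:
        x = np.where(col.astype(str) == lev, 1.0, 0.0)
        x[col.astype(str) == levels[-1]] = -1.0
        cols.append(x)
        names.append(factor if len(levels) == 2 else f"{factor}[{lev}]")
    return cols, names


def design_matrix(data: pd.DataFrame, terms: Sequence[str]):
    """Fixed-effects design matrix with intercept, sum-to-zero coding, and
    product columns for ``a:b`` interaction terms.  Must be full rank."""
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for term in terms:
        parts = term.split(":")
        part_cols = [np.ones(len(data))]
        part_names = [""]
        for p_ in parts:
            pc, pn = _factor_columns(data, p_)
            part_cols = [a * b for a in part_cols for b in pc]
            part_names = [(a + ":" + b).strip(":") for a in part_names for b in pn]
        cols.extend(part_cols)
        names.extend(part_names)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X, names


def _random_design(data: pd.DataFrame, spec: RegressionSpec):
    """Random-effects design Z and per-component column slices.

    Components (one variance parameter each) appear in the fixed order:
    intercepts for each group (sorted), then slopes sorted by interaction
    order and name — the same order the pruning protocol relies on.
    """
    comps = []  # (name, Z_block)
    for g in spec.random_intercepts:
        codes, _ = pd.factorize(data[g], sort=True)
        Zg = np.zeros((len(data), codes.max() + 1))
        Zg[np.arange(len(data)), codes] = 1.0
        comps.append((f"intercept|{g}", Zg))
    for g, term in spec.random_slopes:
        codes, _ = pd.factorize(data[g], sort=True)
        Zg = np.zeros((len(data), codes.max() + 1))
        Zg[np.arange(len(data)), codes] = 1.0
        xcols, _ = design_matrix(data, [term])
        x = xcols[:, 1:]  # drop intercept column
        for j in range(x.shape[1]):
            comps.append((f"{term}|{g}" + (f"[{j}]" if x.shape[1] > 1 else ""),
                          Zg * x[:, j:j + 1]))
    if not comps:
        return np.zeros((len(data), 0)), []
    Z = np.concatenate([z for _, z in comps], axis=1)
    slices, start = [], 0
    for name, z in comps:
        slices.append((name, slice(start, start + z.shape[1])))
        start += z.shape[1]
    return Z, slices


def squeeze_unit_interval(y: np.ndarray) -> np.ndarray:
    """Smithson-Verkuilen squeeze ``(y*(N-1)+0.5)/N`` pulling 0/1 responses
    into the open interval; applied only when a boundary value occurs."""
    y = np.asarray(y, dtype=float)
    if y.min() > 0.0 and y.max() < 1.0:
        return y
    n = len(y)
    return (y * (n - 1) + 0.5) / n


# ---------------------------------------------------------------------------
# beta mixed-effects regression (Laplace)
# ---------------------------------------------------------------------------

def _beta_ll(y, eta, phi):
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
    a, b = mu * phi, (1.0 - mu) * phi
    return (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
            + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))


def _trigamma(x: np.ndarray) -> np.ndarray:
    """Vectorized trigamma via the shift recurrence plus the asymptotic
    series (scipy's polygamma routes through Hurwitz zeta, which is far too
    slow inside an optimization loop)."""
    x = np.asarray(x, dtype=np.float64)
    res = np.zeros_like(x)
    xx = x.copy()
    while True:
        small = xx < 6.0
        if not small.any():
            break
        res[small] += 1.0 / (xx[small] * xx[small])
        xx[small] += 1.0
    inv = 1.0 / xx
    inv2 = inv * inv
    res += inv * (1.0 + inv * (0.5 + inv * (1.0 / 6.0 + inv2 * (
        -1.0 / 30.0 + inv2 * (1.0 / 42.0 - inv2 / 30.0)))))
    return res


def _beta_g_w(y, eta, phi):
    """Gradient of the log-likelihood wrt eta and the expected information."""
    mu = special.expit(eta)
    mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
    a, b = mu * phi, (1.0 - mu) * phi
    v = mu * (1.0 - mu)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(a) - special.digamma(b)
    g = v * phi * (ystar - mustar)
    w = (v * phi) ** 2 * (_trigamma(a) + _trigamma(b))
    return g, w


def _penalized_mode(y, C, p, dvec, phi, th0):
    """Joint Fisher-scoring mode over (beta, u) of the penalized beta
    log-likelihood; ``C = [X Z]``, the first ``p`` columns unpenalized.

    Returns (th, H_uu, w) with H_uu the u-block of the penalized Hessian.
    """
    m = C.shape[1] - p
    pen = np.concatenate([np.zeros(p), 1.0 / dvec]) if m else np.zeros(p)
    th = th0.copy()

    def pen_ll(tt):
        return float(_beta_ll(y, C @ tt, phi).sum()) - 0.5 * float(np.sum(pen * tt * tt))

    f0 = pen_ll(th)
    for _ in range(60):
        eta = C @ th
        g, w = _beta_g_w(y, eta, phi)
        grad = C.T @ g - pen * th
        if np.max(np.abs(grad)) < 1e-9:
            break
        H = (C.T * w) @ C
        H[np.diag_indices(C.shape[1])] += pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(25):
            f1 = pen_ll(th + t * step)
            if f1 >= f0 - 1e-12:
                break
            t *= 0.5
        th = th + t * step
        if f1 < f0 + 1e-11:
            f0 = f1
            break
        f0 = f1
    eta = C @ th
    _, w = _beta_g_w(y, eta, phi)
    if m:
        Z = C[:, p:]
        H_uu = (Z.T * w) @ Z
        H_uu[np.diag_indices(m)] += 1.0 / dvec
    else:
        H_uu = np.zeros((0, 0))
    return th, H_uu, w


def _beta_laplace_profiled(vpar, y, C, p, slices, warm):
    """Negative Laplace log-likelihood as a function of the variance
    parameters ``vpar = [log phi, log sd_1, ...]``; beta is profiled at the
    joint penalized mode (the standard Laplace scheme for GLMMs)."""
    phi = np.exp(vpar[0])
    m = C.shape[1] - p
    dvec = np.empty(m)
    for (name, sl), ls in zip(slices, vpar[1:]):
        dvec[sl] = np.exp(2.0 * ls)
    th, H_uu, _ = _penalized_mode(y, C, p, dvec, phi, warm["th"])
    warm["th"] = th
    u = th[p:]
    ll = float(_beta_ll(y, C @ th, phi).sum())
    if m:
        ll -= 0.5 * float(np.sum(u * u / dvec))
        sign, logdet = np.linalg.slogdet(H_uu * dvec[:, None])
        if sign <= 0:
            return np.inf
        ll -= 0.5 * logdet
    return -ll


def fit_beta_mixed(data: pd.DataFrame, spec: RegressionSpec) -> FitResult:
    """Maximum-likelihood beta mixed-effects regression.

    Logit link for the mean, log link for the precision phi, Gaussian
    random effects integrated by a Laplace approximation; the fixed effects
    are profiled at the joint penalized mode.  Wald standard errors use the
    GLS covariance ``(X' V^-1 X)^-1`` with ``V = W^-1 + Z D Z'`` evaluated
    at the optimum.  Deterministic given the data and starting values.
    """
    if spec.kind != "probability":
        raise ValueError("fit_beta_mixed requires a probability response")
    y_raw = np.asarray(data[spec.response], dtype=float)
    if np.any(~np.isfinite(y_raw)):
        raise ValueError("non-finite responses")
    y = squeeze_unit_interval(y_raw)
    notes = [] if y is y_raw else ["boundary responses squeezed into (0,1)"]
    if np.ptp(y) == 0.0:
        raise ValueError(
            "degenerate input: all responses identical after squeeze; "
            "a beta regression cannot be identified"
        )
    X, names = design_matrix(data, spec.fixed)
    Z, slices = _random_design(data, spec)
    p, q = X.shape[1], len(slices)
    C = np.concatenate([X, Z], axis=1)

    # starting values: OLS on the empirical logit; moment-matched phi
    elogit = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, elogit, rcond=None)
    mu0 = special.expit(X @ beta0)
    resid_var = max(float(np.var(y - mu0)), 1e-6)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var) - 1.0, 2.0)
    v0 = np.concatenate([[np.log(phi0)], np.full(q, np.log(0.3))])

    warm = {"th": np.concatenate([beta0, np.zeros(Z.shape[1])])}
    bounds = [(-4.0, 12.0)] + [_SD_LOG_BOUNDS] * q
    res = optimize.minimize(
        _beta_laplace_profiled, v0, args=(y, C, p, slices, warm),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7},
    )
    vpar = res.x
    loglik = -float(_beta_laplace_profiled(vpar, y, C, p, slices, warm))
    converged = bool(res.success) and np.isfinite(loglik)
    phi = float(np.exp(vpar[0]))
    th = warm["th"]
    beta = th[:p]

    # Wald covariance: (X' V^-1 X)^-1, V = W^-1 + Z D Z' (Woodbury)
    _, w = _beta_g_w(y, C @ th, phi)
    se = np.full(p, np.nan)
    try:
        XtWX = (X.T * w) @ X
        if Z.shape[1]:
            dvec = np.empty(Z.shape[1])
            for (name, sl), ls in zip(slices, vpar[1:]):
                dvec[sl] = np.exp(2.0 * ls)
            XtWZ = (X.T * w) @ Z
            A = (Z.T * w) @ Z
            A[np.diag_indices(Z.shape[1])] += 1.0 / dvec
            info = XtWX - XtWZ @ np.linalg.solve(A, XtWZ.T)
        else:
            info = XtWX
        cov = np.linalg.inv(info)
        dvar = np.diag(cov)
        if np.all(dvar > 0):
            se = np.sqrt(dvar)
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False

    z = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    re_var = {name: float(np.exp(2.0 * vpar[1 + j]))
              for j, (name, _) in enumerate(slices)}
    singular = any(vpar[1 + j] < _SINGULAR_LOG_SD for j in range(q))
    return FitResult(
        spec=spec, method="beta_mixed",
        params=pd.Series(beta, index=names), se=pd.Series(se, index=names),
        stat=pd.Series(z, index=names), pvalues=pd.Series(pvals, index=names),
        loglik=loglik, phi=phi, re_var=re_var,
        converged=converged, singular=singular, n_obs=len(y), notes=notes,
    )


# ---------------------------------------------------------------------------
# linear mixed-effects regression (profiled marginal likelihood)
# ---------------------------------------------------------------------------

def _lmm_negll(vpar, y, X, Z, slices, reml):
    """Negative (RE)ML marginal log-likelihood with beta profiled out.

    vpar = [log sigma_res, log sd_1, ...]; V = s2 I + Z D Z'.
    """
    n, p = X.shape
    s2 = np.exp(2.0 * vpar[0])
    m = Z.shape[1]
    if m:
        dvec = np.empty(m)
        for (name, sl), ls in zip(slices, vpar[1:]):
            dvec[sl] = np.exp(2.0 * ls)
        # Woodbury: V^-1 = (I - Z A^-1 Z'/s2)/s2 with A = D^-1 + Z'Z/s2
        A = (Z.T @ Z) / s2
        A[np.diag_indices(m)] += 1.0 / dvec
        cA = np.linalg.cholesky(A)
        ZtX = Z.T @ X
        Zty = Z.T @ y

        def solve_a(M):
            return np.linalg.solve(cA.T, np.linalg.solve(cA, M))

        # V^-1 M = M/s2 - Z A^-1 (Z'M) / s2^2
        ViX = X / s2 - Z @ solve_a(ZtX) / (s2 * s2)
        Viy = y / s2 - Z @ solve_a(Zty) / (s2 * s2)
        # log|V| = n log s2 + log|A| + log|D|  (matrix determinant lemma)
        logdetV = n * np.log(s2) + 2.0 * np.sum(np.log(np.diag(cA))) + np.sum(np.log(dvec))
    else:
        ViX = X / s2
        Viy = y / s2
        logdetV = n * np.log(s2)
    XtViX = X.T @ ViX
    XtViy = X.T @ Viy
    beta = np.linalg.solve(XtViX, XtViy)
    # r' V^-1 r = y'V^-1 y - 2 beta'X'V^-1 y + beta'X'V^-1 X beta
    quad = float(y @ Viy - 2.0 * beta @ XtViy + beta @ XtViX @ beta)
    nll = 0.5 * (logdetV + quad + n * np.log(2.0 * np.pi))
    if reml:
        sign, ld = np.linalg.slogdet(XtViX)
        nll += 0.5 * (ld - p * np.log(2.0 * np.pi))
    return nll, beta, XtViX


def fit_linear_mixed(data: pd.DataFrame, spec: RegressionSpec,
                     reml: bool = True) -> FitResult:
    """Linear mixed-effects regression with independent variance components.

    The fixed effects are profiled out of the (restricted) marginal
    likelihood; t statistics use the GLS covariance and p-values a normal
    approximation (degrees-of-freedom method flagged in ``notes``).
    """
    y = np.asarray(data[spec.response], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite responses")
    X, names = design_matrix(data, spec.fixed)
    Z, slices = _random_design(data, spec)
    p, q = X.shape[1], len(slices)

    if np.ptp(y) == 0.0:
        beta = np.zeros(p)
        beta[0] = y[0]
        idx = pd.Index(names)
        return FitResult(
            spec=spec, method="linear_mixed",
            params=pd.Series(beta, index=idx),
            se=pd.Series(np.zeros(p), index=idx),
            stat=pd.Series(np.zeros(p), index=idx),
            pvalues=pd.Series(np.ones(p), index=idx),
            loglik=np.inf, sigma2=0.0,
            re_var={name: 0.0 for name, _ in slices},
            converged=True, singular=True, reml=reml, n_obs=len(y),
            notes=["constant response: residual variance 0 flagged"],
        )

    resid0 = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    s0 = max(float(np.std(resid0)), 1e-6)
    v0 = np.concatenate([[np.log(s0)], np.full(q, np.log(max(s0 * 0.5, 1e-3)))])
    bounds = [(np.log(1e-8), None)] + [_SD_LOG_BOUNDS] * q

    def obj(vpar):
        return _lmm_negll(vpar, y, X, Z, slices, reml)[0]

    res = optimize.minimize(obj, v0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    nll, beta, XtViX = _lmm_negll(res.x, y, X, Z, slices, reml)
    cov = np.linalg.inv(XtViX)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    pvals = 2.0 * sps.norm.sf(np.abs(t))
    re_var = {name: float(np.exp(2.0 * res.x[1 + j])) for j, (name, _) in enumerate(slices)}
    singular = any(res.x[1 + j] < _SINGULAR_LOG_SD for j in range(q))
    return FitResult(
        spec=spec, method="linear_mixed",
        params=pd.Series(beta, index=names), se=pd.Series(se, index=names),
        stat=pd.Series(t, index=names), pvalues=pd.Series(pvals, index=names),
        loglik=-float(nll), sigma2=float(np.exp(2.0 * res.x[0])), re_var=re_var,
        converged=bool(res.success), singular=singular, reml=reml, n_obs=len(y),
        notes=["p-values for t statistics use a normal approximation"],
    )


def _fit(data, spec, reml=True):
    if spec.kind == "probability":
        return fit_beta_mixed(data, spec)
    return fit_linear_mixed(data, spec, reml=reml)


# ---------------------------------------------------------------------------
# pruning protocol
# ---------------------------------------------------------------------------

def prune_random_effects(data: pd.DataFrame, maximal_spec: RegressionSpec,
                         reml: bool = True):
    """Incrementally prune the random-effects structure until convergence.

    Slope terms are removed one at a time in a fixed order (highest
    interaction order first, then by group name and term name,
    reverse-alphabetically) before any intercept; intercepts are removed
    (instance before item) only if no slope structure converges.  Returns
    ``(final_spec, fit, path)``; raises if nothing converges.
    """
    def slope_order(gs):
        g, term = gs
        return (-term.count(":"), g, term)

    spec = replace(maximal_spec,
                   random_slopes=tuple(sorted(maximal_spec.random_slopes, key=slope_order)))
    path = []
    candidates = [spec]
    s = spec
    while s.random_slopes:
        s = replace(s, random_slopes=s.random_slopes[1:])
        candidates.append(s)
    while s.random_intercepts:
        keep = tuple(g for g in s.random_intercepts if g != "instance") \
            if "instance" in s.random_intercepts else s.random_intercepts[:-1]
        s = replace(s, random_intercepts=keep)
        candidates.append(s)

    for cand in candidates:
        try:
            fit = _fit(data, cand, reml=reml)
            ok = fit.converged and not fit.singular
            reason = "converged" if ok else ("singular" if fit.singular else "no convergence")
        except (ValueError, np.linalg.LinAlgError) as e:
            fit, ok, reason = None, False, f"error: {e}"
        path.append({"spec": cand, "ok": ok, "reason": reason})
        if ok:
            logger.info("pruning stopped at %s", cand)
            return cand, fit, path
    raise RuntimeError(f"no random-effects structure converged; path: {path}")


# ---------------------------------------------------------------------------
# linear hypothesis test (equality of two fixed effects)
# ---------------------------------------------------------------------------

def _fit_merged(data, spec, term_a, term_b, kind):
    """ML fit with the design columns of term_a and term_b constrained equal."""
    y = np.asarray(data[spec.response], dtype=float)
    if kind == "probability":
        y = squeeze_unit_interval(y)
    X, names = design_matrix(data, spec.fixed)
    ia, ib = names.index(term_a), names.index(term_b)
    Xc = np.delete(X, ib, axis=1).copy()
    Xc[:, ia] = X[:, ia] + X[:, ib]
    Z, slices = _random_design(data, spec)
    p, q = Xc.shape[1], len(slices)
    if kind == "probability":
        elogit = np.log(y) - np.log1p(-y)
        beta0, *_ = np.linalg.lstsq(Xc, elogit, rcond=None)
        C = np.concatenate([Xc, Z], axis=1)
        v0 = np.concatenate([[np.log(10.0)], np.full(q, np.log(0.3))])
        warm = {"th": np.concatenate([beta0, np.zeros(Z.shape[1])])}
        bounds = [(-4.0, 12.0)] + [_SD_LOG_BOUNDS] * q
        res = optimize.minimize(
            _beta_laplace_profiled, v0, args=(y, C, p, slices, warm),
            method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 300, "ftol": 1e-11, "gtol": 1e-7})
        return -float(res.fun)
    v0 = np.concatenate([[0.0], np.full(q, np.log(0.3))])
    bounds = [(np.log(1e-8), None)] + [_SD_LOG_BOUNDS] * q

    def obj(vpar):
        return _lmm_negll(vpar, y, Xc, Z, slices, False)[0]

    res = optimize.minimize(obj, v0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12})
    return -float(res.fun)


def linear_hypothesis_test(fit_full: FitResult, data: pd.DataFrame,
                           constraint: str) -> tuple[float, float]:
    """Likelihood-ratio test of ``beta_a = beta_b`` against a model where
    the two design columns are merged; chi-square reference with 1 df."""
    parts = [s.strip() for s in constraint.split("=")]
    if len(parts) != 2:
        raise ValueError("constraint must have the form 'term_a = term_b'")
    term_a, term_b = parts
    for t in (term_a, term_b):
        if t not in fit_full.params.index:
            raise ValueError(f"coefficient {t!r} not in the model")
    if term_a == term_b:
        return 0.0, 1.0
    spec = fit_full.spec
    if fit_full.method == "linear_mixed" and fit_full.reml:
        # LRTs on fixed effects require ML fits
        fit_full = fit_linear_mixed(data, spec, reml=False)
    ll_full = fit_full.loglik
    ll_constr = _fit_merged(data, spec, term_a, term_b, spec.kind)
    stat = max(2.0 * (ll_full - ll_constr), 0.0)
    return float(stat), float(sps.chi2.sf(stat, df=1))
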