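"""Gaussian linear mixed models with crossed random effects.

Fits models of the form

    y = X beta + sum_k Z_k u_k + eps,   u_k ~ N(0, sigma2_k I),  eps ~ N(0, sigma2_e I)

by maximum likelihood (ML) or restricted maximum likelihood (REML), where
each random term k is either a random intercept for a grouping factor
(bird identity, year, ...) or an uncorrelated random slope of a covariate
within a grouping factor.

Estimation profiles out the fixed effects and the residual variance: with
variance ratios gamma_k = sigma2_k / sigma2_e the marginal correlation matrix
is V0 = I + sum_k gamma_k Z_k Z_k', and for given gamma the GLS estimate of
beta and the closed-form sigma2_e maximize the likelihood.  The profiled
(-2 log) likelihood is then optimized over theta_k = sqrt(gamma_k) >= 0 with
a bounded quasi-Newton search (two starts).  V0-quadratic forms are computed
through the Woodbury identity, so each evaluation costs O(q^3) in the total
number of random-effect levels q, not O(n^3).

The designs this package targets are small (n of order 100-1000); dense
cross-products are deliberate.  Scalability beyond ~5000 observations is a
non-goal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "RandomTerm",
    "ModelSpec",
    "MixedModelFit",
    "RepeatabilityResult",
    "fit_mixed_model",
    "repeatability",
    "lrt_pvalue",
    "akaike_ic",
    "r2_marginal_conditional",
    "wald_f_test",
]

_THETA_MAX = 1e3  # sqrt of the largest variance ratio entertained


@dataclass(frozen=True)
class RandomTerm:
    """One random term: intercept for ``factor``, or a slope of ``slope``.

    Slopes are uncorrelated with the corresponding intercept term (add both
    terms to the spec to get the uncorrelated intercept+slope model).
    """

    factor: str
    slope: str | None = None

    @property
    def label(self) -> str:
        return self.factor if self.slope is None else f"{self.slope}|{self.factor}"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model specification over columns of an observation table.

    ``fixed`` lists numeric covariate columns; an intercept is always
    included.  ``random`` lists the crossed random terms.
    """

    response: str
    fixed: tuple[str, ...] = ()
    random: tuple[RandomTerm, ...] = ()
    method: str = "REML"

    def __post_init__(self):
        if self.method not in ("REML", "ML"):
            raise ValueError("method must be 'REML' or 'ML'")
        if len(set(self.fixed)) != len(self.fixed):
            raise ValueError("duplicated fixed terms")
        if len(set(self.random)) != len(self.random):
            raise ValueError("duplicated random terms")


@dataclass
class MixedModelFit:
    """A fitted linear mixed model.

    ``varcomp`` maps each random-term label to its variance, plus
    ``"residual"`` for sigma2_e.  ``loglik`` is the REML or ML log-likelihood
    per ``spec.method``.  ``re_variance_total`` is the summed random-effect
    variance as it enters the conditional R2 (slope terms weighted by the
    mean squared covariate).
    """

    spec: ModelSpec
    beta: pd.Series
    beta_se: pd.Series
    varcomp: dict[str, float]
    loglik: float
    n_obs: int
    converged: bool
    singular: bool
    fixed_pred_var: float
    re_variance_total: float
    optimizer: dict = field(default_factory=dict, repr=False)

    @property
    def n_params(self) -> int:
        """Fixed effects + variance parameters (residual included)."""
        return len(self.beta) + len(self.varcomp)


@dataclass
class RepeatabilityResult:
    """Intraclass correlation R = sigma2_group / (sigma2_group + sigma2_resid)."""

    r: float
    se: float
    p_value: float
    varcomp: dict[str, float]
    n_boot: int
    seed: int | None


# ---------------------------------------------------------------------------
# design construction


def _design(data: pd.DataFrame, spec: ModelSpec):
    y = data[spec.response].to_numpy(dtype=float)
    n = len(y)
    X = np.column_stack([np.ones(n)] + [data[c].to_numpy(dtype=float) for c in spec.fixed])
    blocks = []
    for term in spec.random:
        codes, levels = pd.factorize(data[term.factor], sort=True)
        if len(levels) < 2:
            raise ValueError(f"grouping factor '{term.factor}' has < 2 levels")
        Z = np.zeros((n, len(levels)))
        w = np.ones(n) if term.slope is None else data[term.slope].to_numpy(dtype=float)
        Z[np.arange(n), codes] = w
        blocks.append(Z)
    return y, X, blocks


class _Profile:
    """Profiled -2 log-likelihood over theta = sqrt(variance ratios)."""

    def __init__(self, y, X, blocks, method):
        self.n, self.p = X.shape
        self.method = method
        self.block_sizes = [Z.shape[1] for Z in blocks]
        XY = np.column_stack([X, y])
        self.C = XY.T @ XY
        if blocks:
            Zc = np.hstack(blocks)
            self.ZtXY = Zc.T @ XY
            self.ZtZ = Zc.T @ Zc
        else:
            self.ZtXY = self.ZtZ = None

    def _expand(self, theta):
        return np.repeat(np.asarray(theta, dtype=float) ** 2, self.block_sizes)

    def components(self, theta):
        """Return (beta, rss, logdetV0, logdetXtVX, Ainv) at given theta."""
        n, p = self.n, self.p
        if self.ZtZ is not None and np.any(theta):
            d = self._expand(theta)
            s = np.sqrt(d)
            M = np.eye(len(d)) + (s[:, None] * self.ZtZ) * s[None, :]
            L = linalg.cholesky(M, lower=True)
            logdetV0 = 2.0 * float(np.sum(np.log(np.diag(L))))
            W = s[:, None] * self.ZtXY
            T = linalg.cho_solve((L, True), W)
            G = self.C - W.T @ T
        else:
            logdetV0 = 0.0
            G = self.C
        A = G[:p, :p]
        b = G[:p, p]
        c = G[p, p]
        La = linalg.cholesky(A, lower=True)
        beta = linalg.cho_solve((La, True), b)
        rss = max(float(c - b @ beta), 0.0)
        logdetA = 2.0 * float(np.sum(np.log(np.diag(La))))
        Ainv = linalg.cho_solve((La, True), np.eye(p))
        return beta, rss, logdetV0, logdetA, Ainv

    def neg2ll(self, theta):
        n, p = self.n, self.p
        try:
            _, rss, logdetV0, logdetA, _ = self.components(theta)
        except linalg.LinAlgError:
            return np.inf
        if rss <= 0:
            return -np.inf
        if self.method == "ML":
            s2 = rss / n
            return n * math.log(2 * math.pi * s2) + logdetV0 + n
        s2 = rss / (n - p)
        return (n - p) * math.log(2 * math.pi * s2) + logdetV0 + logdetA + (n - p)

    def sigma2(self, rss):
        return rss / (self.n if self.method == "ML" else self.n - self.p)


def _ols_fit(data: pd.DataFrame, spec: ModelSpec) -> "MixedModelFit":
    y, X, _ = _design(data, spec)
    n, p = X.shape
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n if spec.method == "ML" else n - p
    s2 = rss / dof
    if spec.method == "ML":
        ll = -0.5 * (n * math.log(2 * math.pi * s2) + n)
    else:
        XtX = X.T @ X
        sign, logdetA = np.linalg.slogdet(XtX)
        ll = -0.5 * ((n - p) * math.log(2 * math.pi * s2) + logdetA + (n - p))
    cov = s2 * np.linalg.inv(X.T @ X)
    names = ["(Intercept)", *spec.fixed]
    pred = X @ beta
    return MixedModelFit(
        spec=spec,
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        varcomp={"residual": s2},
        loglik=ll,
        n_obs=n,
        converged=True,
        singular=False,
        fixed_pred_var=float(np.var(pred)),
        re_variance_total=0.0,
        optimizer={"cov_beta": cov},
    )


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> MixedModelFit:
    """Fit ``spec`` to ``data`` by profiled REML/ML.

    Non-convergence is reported through ``converged=False`` with optimizer
    diagnostics attached — never a silent result.  Variance components
    estimated at the zero boundary set ``singular=True``.
    """
    y, X, blocks = _design(data, spec)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n_obs={n} must exceed number of fixed effects p={p}")

    if float(np.var(y)) < 1e-13:
        # degenerate: exactly constant response
        names = ["(Intercept)", *spec.fixed]
        beta = np.zeros(p)
        beta[0] = y[0]
        varcomp = {t.label: 0.0 for t in spec.random}
        varcomp["residual"] = 0.0
        return MixedModelFit(
            spec=spec,
            beta=pd.Series(beta, index=names),
            beta_se=pd.Series(np.zeros(p), index=names),
            varcomp=varcomp,
            loglik=math.inf,
            n_obs=n,
            converged=True,
            singular=True,
            fixed_pred_var=0.0,
            re_variance_total=0.0,
        )

    if not blocks:
        return _ols_fit(data, spec)

    prof = _Profile(y, X, blocks, spec.method)
    K = len(blocks)

    if K == 1:
        res = optimize.minimize_scalar(
            lambda t: prof.neg2ll([t]),
            bounds=(0.0, _THETA_MAX),
            method="bounded",
            options={"xatol": 1e-9},
        )
        cand = [(prof.neg2ll([0.0]), np.array([0.0]), True)]
        cand.append((res.fun, np.atleast_1d(res.x), bool(res.success)))
        f, theta, ok = min(cand, key=lambda c: c[0])
        info = {"nfev": int(getattr(res, "nfev", 0)), "fun": float(f)}
    else:
        results = []
        for start in (np.full(K, 1.0), np.full(K, 0.05)):
            results.append(
                optimize.minimize(
                    prof.neg2ll,
                    start,
                    method="L-BFGS-B",
                    bounds=[(0.0, _THETA_MAX)] * K,
                    options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
                )
            )
        best = min(results, key=lambda r: r.fun)
        scale = max(1.0, abs(best.fun))
        f, theta = float(best.fun), np.asarray(best.x)
        nfev = int(sum(r.nfev for r in results))
        # simplex polish: L-BFGS-B line searches can stall near the zero
        # boundary of a variance ratio; iterate until stationary
        improved = np.inf
        for _ in range(4):
            polish = optimize.minimize(
                lambda t: prof.neg2ll(np.abs(t)),
                theta,
                method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-11, "maxiter": 600},
            )
            nfev += int(polish.nfev)
            improved = f - float(polish.fun)
            if polish.fun <= f:
                f, theta = float(polish.fun), np.clip(np.abs(polish.x), 0.0, _THETA_MAX)
            if improved < 1e-6 * scale:
                break
        # converged when some start succeeded at this minimum or the polish
        # could not move the deviance further
        ok = (
            any(r.success and r.fun <= f + 1e-6 * scale for r in results)
            or improved < 1e-6 * scale
        )
        info = {"nfev": nfev, "fun": f}

    theta = np.where(theta < 1e-7, 0.0, theta)
    beta, rss, _, _, Ainv = prof.components(theta)
    s2e = prof.sigma2(rss)
    info["cov_beta"] = s2e * Ainv
    gammas = theta**2
    varcomp = {t.label: float(g * s2e) for t, g in zip(spec.random, gammas)}
    varcomp["residual"] = float(s2e)

    names = ["(Intercept)", *spec.fixed]
    pred = X @ beta
    # random-effect variance as it enters conditional R2: slope terms are
    # weighted by the mean squared covariate value
    re_total = 0.0
    for term, g in zip(spec.random, gammas):
        v = g * s2e
        if term.slope is not None:
            v *= float(np.mean(data[term.slope].to_numpy(dtype=float) ** 2))
        re_total += v

    return MixedModelFit(
        spec=spec,
        beta=pd.Series(beta, index=names),
        beta_se=pd.Series(np.sqrt(s2e * np.diag(Ainv)), index=names),
        varcomp=varcomp,
        loglik=-0.5 * f,
        n_obs=n,
        converged=ok and np.isfinite(f),
        singular=bool(np.any(gammas == 0.0)),
        fixed_pred_var=float(np.var(pred)),
        re_variance_total=float(re_total),
        optimizer=info,
    )


# ---------------------------------------------------------------------------
# inference helpers


def lrt_pvalue(
    loglik_full: float,
    loglik_reduced: float,
    df_diff: int = 1,
    boundary: bool = False,
    tol: float = 1e-6,
) -> float:
    """Likelihood-ratio p-value from two ML log-likelihoods.

    With ``boundary=True`` (testing one variance component pinned at zero
    under the null) the reference distribution is the equal mixture
    0.5 chi2_0 + 0.5 chi2_1.
    """
    lr = 2.0 * (loglik_full - loglik_reduced)
    if lr < -tol:
        raise ValueError(f"negative likelihood ratio {lr:.3g}: full model fit failed")
    lr = max(lr, 0.0)
    if boundary:
        if df_diff != 1:
            raise ValueError("boundary mixture implemented for df_diff=1 only")
        return 1.0 if lr == 0.0 else 0.5 * float(stats.chi2.sf(lr, 1))
    if df_diff < 1:
        raise ValueError("df_diff must be >= 1")
    return float(stats.chi2.sf(lr, df_diff))


def akaike_ic(fit: MixedModelFit) -> float:
    """AIC = -2 loglik + 2k, k = fixed effects + variance parameters.

    Only comparable across fits with the same method and, for REML, the same
    fixed-effect structure; model-comparison tables in this package use ML
    fits throughout.
    """
    if not fit.converged:
        raise ValueError("AIC requested for a non-converged fit")
    return -2.0 * fit.loglik + 2.0 * fit.n_params


def r2_marginal_conditional(fit: MixedModelFit) -> tuple[float, float]:
    """Variance-explained pair (Rm2, Rc2) for a mixed model.

    Rm2 = var(X beta) / (var(X beta) + sum random variances + sigma2_e);
    Rc2 adds the random-effect variance to the numerator.  var() is the
    population variance of the fixed-effect predictor over observations.
    """
    s2f = fit.fixed_pred_var
    s2r = fit.re_variance_total
    s2e = fit.varcomp["residual"]
    denom = s2f + s2r + s2e
    if denom <= 0:
        raise ValueError("zero total variance; R2 undefined")
    return s2f / denom, (s2f + s2r) / denom


def wald_f_test(fit: MixedModelFit, terms: list[str]) -> dict:
    """Approximate Wald F test for a set of fixed-effect terms.

    Denominator df uses residual containment (n - p); labelled approximate —
    likelihood-ratio tests are the primary inference path.
    """
    idx = [list(fit.beta.index).index(t) for t in terms]
    b = fit.beta.to_numpy()[idx]
    cov = np.asarray(fit.optimizer["cov_beta"])
    sub = cov[np.ix_(idx, idx)]
    F = float(b @ np.linalg.solve(sub, b) / len(idx))
    df1 = len(idx)
    df2 = fit.n_obs - len(fit.beta)
    return {
        "F": F,
        "df1": df1,
        "df2": df2,
        "p_approx": float(stats.f.sf(F, df1, df2)),
    }


# ---------------------------------------------------------------------------
# repeatability


def repeatability(
    data: pd.DataFrame,
    response: str,
    grouping: str,
    n_boot: int = 1000,
    seed: int | None = None,
    adjusted_for: tuple[str, ...] = (),
) -> RepeatabilityResult:
    """Among-group repeatability (intraclass correlation) by REML.

    R = sigma2_group / (sigma2_group + sigma2_resid) from the intercept-only
    model with ``grouping`` as the sole random factor (agreement
    repeatability; pass fixed covariates via ``adjusted_for`` for the
    adjusted variant).  The standard error is a parametric bootstrap over
    ``n_boot`` simulate-and-refit replicates; the p-value is a
    boundary-corrected likelihood-ratio test of sigma2_group = 0 using ML
    fits.
    """
    spec = ModelSpec(
        response=response,
        fixed=tuple(adjusted_for),
        random=(RandomTerm(grouping),),
        method="REML",
    )
    fit = fit_mixed_model(data, spec)
    s2g = fit.varcomp[grouping]
    s2e = fit.varcomp["residual"]
    total = s2g + s2e
    if total <= 0:
        raise ValueError("zero total variance: repeatability undefined")
    r = s2g / total

    # boundary LRT on ML fits
    full_ml = fit_mixed_model(data, ModelSpec(response, tuple(adjusted_for), spec.random, "ML"))
    null_ml = fit_mixed_model(data, ModelSpec(response, tuple(adjusted_for), (), "ML"))
    p = lrt_pvalue(full_ml.loglik, null_ml.loglik, df_diff=1, boundary=True)

    # parametric bootstrap for the SE
    rng = np.random.default_rng(seed)
    codes, levels = pd.factorize(data[grouping], sort=True)
    X = np.column_stack(
        [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in adjusted_for]
    )
    mean_part = X @ fit.beta.to_numpy()
    boot = np.empty(n_boot)
    sim = data[[grouping, *adjusted_for]].copy()
    for b in range(n_boot):
        u = rng.normal(0.0, math.sqrt(s2g), size=len(levels))
        ystar = mean_part + u[codes] + rng.normal(0.0, math.sqrt(s2e), size=len(data))
        sim[response] = ystar
        bf = fit_mixed_model(sim, spec)
        tot = bf.varcomp[grouping] + bf.varcomp["residual"]
        boot[b] = bf.varcomp[grouping] / tot if tot > 0 else 0.0
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else float("nan")

    return RepeatabilityResult(
        r=float(r),
        se=se,
        p_value=float(p),
        varcomp=dict(fit.varcomp),
        n_boot=n_boot,
        seed=seed,
    )
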