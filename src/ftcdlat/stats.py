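"""Twin-aware group-comparison statistics for laterality cohorts.

All group comparisons respect the non-independence of twin observations:

* continuous outcomes use a linear mixed model with a random intercept per
  twin pair, fit by profiled REML (closed form for this structure, exact at
  the zero-variance boundary) with Satterthwaite-approximate degrees of
  freedom for the fixed-effect t tests;
* binary outcomes use a random-intercept logistic model fit by adaptive
  Gauss-Hermite maximum likelihood, reporting the odds ratio with
  profile-likelihood 95% CIs;
* the three-level laterality category uses a baseline-category (left)
  multinomial logit with per-equation pair random intercepts, sampled by
  seeded random-walk Metropolis on the quadrature-marginalised likelihood,
  reporting posterior median odds ratios, 95% credible intervals and pMCMC;
* bounded, skewed handedness scores rescaled to [0, 1] use zero-one-inflated
  beta (ZOIB) regression fit by maximum likelihood, run separately in the
  twin-1 and twin-2 subsamples (an effect counts as significant only if
  p < .05 in both);
* correlational replication uses Spearman's rho with Holm-Bonferroni
  adjustment within each twin subsample, requiring adjusted significance in
  both.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats as sps
from scipy.special import expit, gammaln, logit, logsumexp
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import ProcessingError, ValidationError

logger = logging.getLogger("ftcdlat")

_SQRT2 = math.sqrt(2.0)


@dataclass
class ModelResult:
    """A fitted model's reportable quantities."""

    kind: str
    estimate: float | None = None          # focal fixed effect
    se: float | None = None
    stat: float | None = None
    df: float | None = None
    p: float | None = None
    ci: tuple | None = None
    params: dict = field(default_factory=dict)
    tests: dict = field(default_factory=dict)          # term -> {stat, df, p}
    marginal_means: dict = field(default_factory=dict)  # level -> (mean, lo, hi)
    variance_components: dict = field(default_factory=dict)
    odds_ratio: float | None = None
    or_ci: tuple | None = None
    flags: list = field(default_factory=list)
    seed: int | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Random-intercept REML machinery (closed form; used for Satterthwaite df)
# ---------------------------------------------------------------------------

class _RandomInterceptREML:
    """Profiled REML quantities for y = X b + u_group + e, vectorised over groups."""

    def __init__(self, X: np.ndarray, y: np.ndarray, groups: np.ndarray):
        self.X = X
        self.y = y
        self.n, self.p = X.shape
        codes, _ = pd.factorize(groups)
        order = np.argsort(codes, kind="stable")
        Xs, ys, cs = X[order], y[order], codes[order]
        starts = np.concatenate(([0], np.flatnonzero(np.diff(cs)) + 1))
        self.ng = np.diff(np.concatenate((starts, [len(cs)]))).astype(float)
        self.S = np.add.reduceat(Xs, starts, axis=0)          # per-group X' 1
        self.T = np.add.reduceat(ys, starts)                  # per-group y' 1
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _parts(self, gamma: float):
        c = gamma / (1.0 + self.ng * gamma)
        A = self.XtX - (self.S.T * c) @ self.S
        b = self.Xty - self.S.T @ (c * self.T)
        yvy = self.yty - float(c @ (self.T**2))
        return A, b, yvy, c

    def beta(self, gamma: float) -> np.ndarray:
        A, b, _, _ = self._parts(gamma)
        return np.linalg.solve(A, b)

    def beta_cov(self, sigma_u2: float, sigma_e2: float) -> np.ndarray:
        """(X' V^-1 X)^-1 at the given variance components."""
        gamma = sigma_u2 / sigma_e2
        A, _, _, _ = self._parts(gamma)
        return sigma_e2 * np.linalg.inv(A)

    def reml_loglik(self, sigma_u2: float, sigma_e2: float) -> float:
        if sigma_e2 <= 0 or sigma_u2 < 0:
            return -np.inf
        gamma = sigma_u2 / sigma_e2
        A, b, yvy, _ = self._parts(gamma)
        beta = np.linalg.solve(A, b)
        rvr = (yvy - float(b @ beta)) / sigma_e2
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf
        logdet_v = self.n * math.log(sigma_e2) + float(np.sum(np.log1p(self.ng * gamma)))
        logdet_xvx = logdet_a - self.p * math.log(sigma_e2)
        return -0.5 * (logdet_v + logdet_xvx + rvr)

    def concentrated_reml(self, gamma: float) -> float:
        """REML log-likelihood profiled over both beta and sigma_e^2."""
        if gamma < 0:
            return -np.inf
        A, b, yvy, _ = self._parts(gamma)
        beta = np.linalg.solve(A, b)
        rvr = yvy - float(b @ beta)
        if rvr <= 0:
            return -np.inf
        sign, logdet_a = np.linalg.slogdet(A)
        if sign <= 0:
            return -np.inf
        npp = self.n - self.p
        sigma_e2 = rvr / npp
        logdet_w = float(np.sum(np.log1p(self.ng * gamma)))
        return -0.5 * (npp * (math.log(sigma_e2) + 1.0) + logdet_w + logdet_a)

    def fit(self) -> tuple[np.ndarray, float, float]:
        """Maximise the REML criterion over gamma >= 0; return (beta, sigma_u2, sigma_e2)."""
        opt = optimize.minimize_scalar(
            lambda t: -self.concentrated_reml(math.exp(t)),
            bounds=(-12.0, 8.0), method="bounded",
            options={"xatol": 1e-10},
        )
        gamma = math.exp(opt.x)
        if self.concentrated_reml(0.0) >= -opt.fun:
            gamma = 0.0
        A, b, yvy, _ = self._parts(gamma)
        beta = np.linalg.solve(A, b)
        sigma_e2 = (yvy - float(b @ beta)) / (self.n - self.p)
        return beta, gamma * sigma_e2, sigma_e2

    def satterthwaite_df(self, c: np.ndarray, sigma_u2: float, sigma_e2: float) -> float:
        """Satterthwaite df for the contrast c' beta at the REML estimates."""
        if sigma_u2 <= 0:
            return float(self.n - self.p)
        theta = np.array([sigma_u2, sigma_e2])

        def g(th):
            return float(c @ self.beta_cov(th[0], th[1]) @ c)

        # gradient of g and Hessian of the REML log-likelihood, by finite
        # differences; steps kept strictly inside the positive orthant
        h = np.minimum(np.maximum(1e-7, 1e-4 * theta), theta / 2.0)
        grad = np.zeros(2)
        for i in range(2):
            up, dn = theta.copy(), theta.copy()
            up[i] += h[i]
            dn[i] -= h[i]
            grad[i] = (g(up) - g(dn)) / (up[i] - dn[i])

        def ll(th):
            return self.reml_loglik(th[0], th[1])

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        if not (np.all(np.isfinite(H)) and np.all(np.isfinite(grad))):
            return float(self.n - self.p)
        try:
            cov_theta = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            return float(self.n - self.p)
        denom = float(grad @ cov_theta @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.n - self.p)
        df = 2.0 * g(theta) ** 2 / denom
        return float(np.clip(df, 1.0, self.n - self.p))


def _drop_missing(data: pd.DataFrame, cols: list[str], context: str) -> pd.DataFrame:
    out = data.dropna(subset=[c for c in cols if c in data.columns])
    dropped = len(data) - len(out)
    if dropped:
        logger.info("%s: dropped %d row(s) with missing values", context, dropped)
    return out


def fit_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    pair: str = "pair_id",
    focus: str | None = None,
) -> ModelResult:
    """Linear mixed model with a random intercept per twin pair (REML).

    Fixed-effect t tests use Satterthwaite-approximate df. ``focus`` names the
    term whose coefficient is reported as the headline estimate (default: the
    first fixed term); for a categorical focus, marginal means per level with
    95% CIs are computed at the observed covariate distribution.
    """
    plain = [f.split("(")[-1].rstrip(")") for f in fixed]
    data = _drop_missing(data, [outcome, pair, *plain], f"lmm[{outcome}]").copy()
    if data[pair].nunique() < 2:
        raise ProcessingError("need at least 2 pairs")
    formula = f"{outcome} ~ " + " + ".join(fixed)
    y_dm, X_dm = patsy.dmatrices(formula, data, return_type="dataframe")
    X = np.asarray(X_dm, dtype=float)
    y = np.asarray(y_dm, dtype=float).ravel()
    reml = _RandomInterceptREML(X, y, data[pair].to_numpy())
    beta, sigma_u2, sigma_e2 = reml.fit()

    flags = []
    if sigma_u2 / max(sigma_e2, 1e-300) < 1e-6:
        # singular fit: the pair variance is floored at 0 and the model is then
        # exactly the ordinary fixed-effects regression
        flags.append("singular")
        sigma_u2 = 0.0
        A, b, yvy, _ = reml._parts(0.0)
        beta = np.linalg.solve(A, b)
        sigma_e2 = (yvy - float(b @ beta)) / (reml.n - reml.p)

    cov_beta = reml.beta_cov(sigma_u2, sigma_e2)
    names = list(X_dm.columns)

    focus = focus or fixed[0]
    focus_plain = focus.split("(")[-1].rstrip(")")
    tests: dict[str, dict] = {}
    focal_idx = None
    for j, name in enumerate(names):
        if name == "Intercept":
            continue
        cvec = np.zeros(reml.p)
        cvec[j] = 1.0
        se = math.sqrt(cov_beta[j, j])
        df = reml.satterthwaite_df(cvec, sigma_u2, sigma_e2)
        t = beta[j] / se
        pval = 2 * sps.t.sf(abs(t), df)
        tests[name] = {"estimate": float(beta[j]), "se": se, "stat": float(t), "df": df, "p": float(pval)}
        if focus_plain in name and focal_idx is None:
            focal_idx = j

    marginal_means: dict[str, tuple] = {}
    if focus_plain in data.columns and (data[focus_plain].dtype == object or str(data[focus_plain].dtype) == "category"):
        design_info = X_dm.design_info
        for level in sorted(data[focus_plain].unique()):
            ref = data.copy()
            ref[focus_plain] = level
            (Xl,) = patsy.build_design_matrices([design_info], ref)
            xrow = np.asarray(Xl, dtype=float).mean(axis=0)
            mm = float(xrow @ beta)
            se_mm = math.sqrt(float(xrow @ cov_beta @ xrow))
            df_mm = reml.satterthwaite_df(xrow, sigma_u2, sigma_e2)
            tcrit = sps.t.ppf(0.975, df_mm)
            marginal_means[str(level)] = (mm, mm - tcrit * se_mm, mm + tcrit * se_mm)

    result = ModelResult(
        kind="lmm",
        params={n: float(b) for n, b in zip(names, beta)},
        tests=tests,
        marginal_means=marginal_means,
        variance_components={"pair": sigma_u2, "resid": sigma_e2},
        flags=flags,
        extra={"outcome": outcome, "formula": formula, "n": int(reml.n),
               "n_pairs": int(data[pair].nunique())},
    )
    if focal_idx is not None:
        name = names[focal_idx]
        t = tests[name]
        tcrit = sps.t.ppf(0.975, t["df"])
        result.estimate = t["estimate"]
        result.se = t["se"]
        result.stat = t["stat"]
        result.df = t["df"]
        result.p = t["p"]
        result.ci = (t["estimate"] - tcrit * t["se"], t["estimate"] + tcrit * t["se"])
        result.extra["focus"] = name
    return result


def pseudo_r2(full: ModelResult, reduced: ModelResult) -> float:
    """Residual-variance pseudo R^2 of the full vs reduced mixed model, floored at 0.

    Both models must share the random-effect structure (same pairs and rows)
    and differ only in the fixed predictor.
    """
    for key in ("n", "n_pairs"):
        if full.extra.get(key) != reduced.extra.get(key):
            raise ValidationError("pseudo_r2: models fit to different data/structures")
    s_full = full.variance_components["resid"]
    s_red = reduced.variance_components["resid"]
    return max(0.0, (s_red - s_full) / s_red)


# ---------------------------------------------------------------------------
# Random-intercept logistic regression (adaptive Gauss-Hermite ML)
# ---------------------------------------------------------------------------

def _pair_segments(groups: np.ndarray) -> np.ndarray:
    codes, _ = pd.factorize(groups)
    order = np.argsort(codes, kind="stable")
    cs = codes[order]
    starts = np.concatenate(([0], np.flatnonzero(np.diff(cs)) + 1))
    return order, starts


def _binary_x(data: pd.DataFrame, col: str) -> tuple[np.ndarray, dict]:
    vals = data[col]
    if vals.dtype == bool:
        return vals.to_numpy().astype(float), {"coding": {False: 0, True: 1}}
    if np.issubdtype(vals.dtype, np.number):
        return vals.to_numpy().astype(float), {"coding": "numeric"}
    levels = sorted(vals.unique())
    if len(levels) != 2:
        raise ValidationError(f"{col}: expected 2 levels, got {levels}")
    return (vals == levels[1]).to_numpy().astype(float), {"coding": {levels[0]: 0, levels[1]: 1}}


def fit_multilevel_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    pair: str = "pair_id",
    n_quad: int = 21,
    profile_ci: bool = True,
) -> ModelResult:
    """Random-intercept logistic regression of a binary outcome on one predictor.

    The pair random intercept is integrated out by Gauss-Hermite quadrature and
    the marginal likelihood maximised over (b0, b1, sigma_u >= 0). Reports the
    odds ratio exp(b1) with profile-likelihood 95% CIs (Wald fallback with a
    logged note if profiling fails, or when ``profile_ci`` is off).
    """
    data = _drop_missing(data, [outcome, predictor, pair], f"logistic[{outcome}]")
    y = data[outcome]
    y = (y.astype(float) if y.dtype != object else (y == sorted(y.unique())[1])).to_numpy().astype(float)
    if len(np.unique(y)) < 2:
        raise ProcessingError(f"{outcome}: both outcome levels must be present")
    x, coding = _binary_x(data, predictor)
    order, starts = _pair_segments(data[pair].to_numpy())
    y, x = y[order], x[order]
    z, w = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(w) - 0.5 * math.log(math.pi)

    def negll(params: np.ndarray) -> float:
        b0, b1, sigma = params
        eta = b0 + b1 * x
        H = eta[:, None] + _SQRT2 * sigma * z[None, :]
        ll_obs = -(y[:, None] * np.logaddexp(0.0, -H) + (1 - y)[:, None] * np.logaddexp(0.0, H))
        S = np.add.reduceat(ll_obs, starts, axis=0)
        return -float(np.sum(logsumexp(S + logw[None, :], axis=1)))

    p_bar = y.mean()
    x0 = np.array([logit(min(max(p_bar, 1e-3), 1 - 1e-3)), 0.0, 0.5])
    bounds = [(-30, 30), (-30, 30), (0.0, 25.0)]
    opt = optimize.minimize(negll, x0, method="L-BFGS-B", bounds=bounds)
    b0, b1, sigma = opt.x
    llmax = -opt.fun

    flags = []
    # Wald SE from the numerical Hessian
    try:
        Hm = _num_hessian(negll, opt.x)
        cov = np.linalg.inv(Hm)
        se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se = float("nan")
    if not np.isfinite(se) or abs(b1) > 15:
        return ModelResult(
            kind="mixed_logistic", estimate=float(b1), flags=["separation"],
            params={"b0": float(b0), "b1": float(b1), "sigma_u": float(sigma)},
            extra={"outcome": outcome, "predictor": predictor, **coding,
                   "n": int(len(y)), "loglik": llmax},
        )
    zstat = b1 / se
    pval = 2 * sps.norm.sf(abs(zstat))

    # profile-likelihood CI for b1
    target = llmax - 0.5 * sps.chi2.ppf(0.95, 1)

    def profile(b1_fix: float) -> float:
        def inner(q):
            return negll(np.array([q[0], b1_fix, q[1]]))
        o = optimize.minimize(inner, np.array([b0, max(sigma, 0.05)]),
                              method="L-BFGS-B", bounds=[(-30, 30), (0.0, 25.0)])
        return -o.fun

    if profile_ci:
        try:
            lo = _profile_root(profile, b1, target, se, direction=-1)
            hi = _profile_root(profile, b1, target, se, direction=+1)
            ci = (lo, hi)
        except (RuntimeError, ValueError):
            logger.info("profile CI failed for %s ~ %s; Wald fallback", outcome, predictor)
            flags.append("wald_ci")
            ci = (b1 - 1.96 * se, b1 + 1.96 * se)
    else:
        flags.append("wald_ci")
        ci = (b1 - 1.96 * se, b1 + 1.96 * se)

    return ModelResult(
        kind="mixed_logistic",
        estimate=float(b1), se=float(se), stat=float(zstat), p=float(pval),
        ci=tuple(float(v) for v in ci),
        odds_ratio=float(np.exp(b1)),
        or_ci=(float(np.exp(ci[0])), float(np.exp(ci[1]))),
        params={"b0": float(b0), "b1": float(b1), "sigma_u": float(sigma)},
        variance_components={"pair": float(sigma**2)},
        flags=flags,
        extra={"outcome": outcome, "predictor": predictor, **coding,
               "n": int(len(y)), "loglik": float(llmax)},
    )


def _profile_root(profile, bhat: float, target: float, se: float, direction: int) -> float:
    """Find the profile-likelihood crossing on one side of the estimate."""
    step = max(se, 1e-3)
    a = bhat
    fa = 0.0  # profile(bhat) - target > 0 by construction
    for k in range(1, 60):
        b = bhat + direction * k * step
        fb = profile(b) - target
        if fb < 0:
            return optimize.brentq(lambda v: profile(v) - target, min(a, b), max(a, b), xtol=1e-5)
        a, fa = b, fb
    raise RuntimeError("profile bracket not found")


def _num_hessian(f, x: np.ndarray, rel: float = 1e-4) -> np.ndarray:
    k = len(x)
    h = np.maximum(np.abs(x) * rel, 1e-5)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h[i] * h[j])
    return H


# ---------------------------------------------------------------------------
# Multinomial multilevel model (Bayesian, random-walk Metropolis)
# ---------------------------------------------------------------------------

CATEGORY_ORDER = ("left", "bilateral", "right")


def fit_multinomial_mcmc(
    data: pd.DataFrame,
    category: str = "category",
    group: str = "group",
    pair: str = "pair_id",
    seed: int = 0,
    n_iter: int = 10000,
    burn_in: int = 2000,
    thin: int = 10,
    n_chains: int = 4,
    prior_sd_fixed: float = 10.0,
    prior_scale_re: float = 5.0,
    n_quad: int = 9,
    categories: tuple[str, str, str] = CATEGORY_ORDER,
) -> ModelResult:
    """Baseline-category multinomial logit with pair random intercepts, by MCMC.

    Two logit equations compare the baseline (first of ``categories``,
    normally 'left') with each atypical category; each equation has its own
    pair-level random intercept, integrated out by 2-D Gauss-Hermite
    quadrature so the sampler walks only over (4 fixed effects, 2 log
    random-effect SDs). Priors: N(0, prior_sd_fixed^2) on fixed effects,
    half-normal(prior_scale_re) on the random-effect SDs. Reports posterior
    median odds ratios, central 95% credible intervals, and
    pMCMC = 2 * min(P(beta>0), P(beta<0)); split-chain R-hat is logged and the
    result flagged if it exceeds 1.1.
    """
    base, cat1, cat2 = categories
    data = _drop_missing(data, [category, group, pair], "multinomial")
    observed = set(data[category].unique())
    if not {base, cat1, cat2} <= observed:
        raise ProcessingError(f"all three categories must be present, got {sorted(observed)}")
    x, coding = _binary_x(data, group)
    ycat = data[category].to_numpy()
    order, starts = _pair_segments(data[pair].to_numpy())
    x, ycat = x[order], ycat[order]
    is1 = (ycat == cat1).astype(float)
    is2 = (ycat == cat2).astype(float)

    z, w = np.polynomial.hermite.hermgauss(n_quad)
    Z1 = np.repeat(z, n_quad)
    Z2 = np.tile(z, n_quad)
    logW = (np.repeat(np.log(w), n_quad) + np.tile(np.log(w), n_quad)) - math.log(math.pi)

    def logpost(theta: np.ndarray) -> float:
        b01, b11, b02, b12, s1, s2 = theta
        sig1, sig2 = math.exp(s1), math.exp(s2)
        eta1 = (b01 + b11 * x)[:, None] + _SQRT2 * sig1 * Z1[None, :]
        eta2 = (b02 + b12 * x)[:, None] + _SQRT2 * sig2 * Z2[None, :]
        denom = np.logaddexp(0.0, np.logaddexp(eta1, eta2))
        ll_obs = is1[:, None] * eta1 + is2[:, None] * eta2 - denom
        S = np.add.reduceat(ll_obs, starts, axis=0)
        ll = float(np.sum(logsumexp(S + logW[None, :], axis=1)))
        lp = -0.5 * np.sum(theta[:4] ** 2) / prior_sd_fixed**2
        # half-normal prior on sigma, with the log-scale Jacobian
        lp += -0.5 * (sig1**2 + sig2**2) / prior_scale_re**2 + s1 + s2
        return ll + lp

    # initial values from the pooled contingency table (0.5 continuity correction)
    def _logodds(mask_cat, mask_x):
        a = float(np.sum(mask_cat & mask_x)) + 0.5
        b = float(np.sum((ycat == base) & mask_x)) + 0.5
        return math.log(a / b)

    x1 = x == 1
    init = np.array([
        _logodds(ycat == cat1, ~x1), _logodds(ycat == cat1, x1) - _logodds(ycat == cat1, ~x1),
        _logodds(ycat == cat2, ~x1), _logodds(ycat == cat2, x1) - _logodds(ycat == cat2, ~x1),
        math.log(0.5), math.log(0.5),
    ])

    ss = np.random.SeedSequence(seed)
    chain_draws = []
    for chain_seq in ss.spawn(n_chains):
        rng = np.random.default_rng(chain_seq)
        theta = init + 0.01 * rng.standard_normal(6)
        lp = logpost(theta)
        # adaptive Metropolis: diagonal proposals at first, then the empirical
        # posterior covariance (scaled 2.38^2/d) learned during burn-in
        log_step = 0.0
        chol = 0.1 * np.eye(6)
        history: list[np.ndarray] = []
        recent_acc: list[int] = []
        draws = []
        for it in range(n_iter):
            prop = theta + math.exp(log_step) * (chol @ rng.standard_normal(6))
            lp_prop = logpost(prop)
            acc = math.log(rng.random()) < lp_prop - lp
            if acc:
                theta, lp = prop, lp_prop
            if it < burn_in:
                history.append(theta.copy())
                recent_acc.append(int(acc))
                if (it + 1) % 50 == 0:
                    log_step += 0.7 * (np.mean(recent_acc[-50:]) - 0.25)
                if (it + 1) % 200 == 0 and len(history) >= 300:
                    cov = np.cov(np.array(history[-1000:]).T) + 1e-6 * np.eye(6)
                    try:
                        chol = np.linalg.cholesky(cov * (2.38**2 / 6.0))
                        log_step = 0.0
                    except np.linalg.LinAlgError:
                        pass
            elif (it - burn_in) % thin == 0:
                draws.append(theta.copy())
        chain_draws.append(np.array(draws))

    rhat = _split_rhat(chain_draws)
    flags = []
    if np.any(rhat > 1.1):
        flags.append("nonconverged")
        logger.warning("multinomial MCMC: max split R-hat %.3f", float(np.max(rhat)))

    samples = np.concatenate(chain_draws, axis=0)
    out_params = {}
    tests = {}
    for label, idx in ((cat1, 1), (cat2, 3)):
        beta = samples[:, idx]
        or_med = float(np.median(np.exp(beta)))
        lo, hi = np.quantile(np.exp(beta), [0.025, 0.975])
        pmcmc = 2.0 * min(float(np.mean(beta > 0)), float(np.mean(beta < 0)))
        pmcmc = max(pmcmc, 2.0 / len(beta))
        tests[f"{label}_vs_{base}"] = {
            "or": or_med, "or_ci": (float(lo), float(hi)), "pmcmc": pmcmc,
            "beta_median": float(np.median(beta)),
        }
        out_params[f"b_{label}"] = float(np.median(beta))

    return ModelResult(
        kind="multinomial_mcmc",
        params=out_params,
        tests=tests,
        variance_components={
            f"sigma_{cat1}": float(np.median(np.exp(samples[:, 4]))),
            f"sigma_{cat2}": float(np.median(np.exp(samples[:, 5]))),
        },
        flags=flags,
        seed=seed,
        extra={"n": int(len(x)), "n_draws": int(len(samples)),
               "rhat_max": float(np.max(rhat)), **coding,
               "chains": n_chains, "n_iter": n_iter, "burn_in": burn_in, "thin": thin},
    )


def _split_rhat(chain_draws: list[np.ndarray]) -> np.ndarray:
    """Split-chain potential scale reduction factor per parameter."""
    halves = []
    for d in chain_draws:
        half = len(d) // 2
        if half >= 2:
            halves.extend([d[:half], d[half:2 * half]])
    if len(halves) < 2:
        return np.ones(chain_draws[0].shape[1])
    arr = np.stack(halves)           # (m, n, k)
    m, n, _ = arr.shape
    means = arr.mean(axis=1)
    B = n * means.var(axis=0, ddof=1)
    W = arr.var(axis=1, ddof=1).mean(axis=0)
    W = np.where(W <= 0, 1e-12, W)
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / W)


# ---------------------------------------------------------------------------
# Zero-one-inflated beta regression
# ---------------------------------------------------------------------------

def fit_zoib(y: np.ndarray, x: np.ndarray) -> ModelResult:
    """Zero-one-inflated beta regression of y in [0, 1] on a single regressor.

    Mixture: P(y=0)=a0, P(y=1)=a1, and y in (0,1) ~ Beta(mu*phi, (1-mu)*phi)
    with logit(mu) = b0 + b1*x. The likelihood factorises, so (a0, a1) have
    the closed-form multinomial MLE (the sample proportions of exact 0s and
    1s) and the beta parameters are maximised numerically on the interior
    observations. Reports a Wald test for b1.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValidationError("ZOIB outcome must lie in [0, 1]")
    n = len(y)
    n0 = int(np.sum(y == 0))
    n1 = int(np.sum(y == 1))
    a0, a1 = n0 / n, n1 / n
    interior = (y > 0) & (y < 1)
    yi, xi = y[interior], x[interior]
    flags = []
    if len(yi) < 3:
        return ModelResult(
            kind="zoib", params={"alpha0": a0, "alpha1": a1},
            flags=["no_interior"], extra={"n": n, "n0": n0, "n1": n1},
        )

    ly, l1y = np.log(yi), np.log1p(-yi)

    def negll(params: np.ndarray) -> float:
        b0, b1, logphi = params
        phi = math.exp(logphi)
        mu = expit(b0 + b1 * xi)
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        ll = np.sum(
            gammaln(phi) - gammaln(mu * phi) - gammaln((1 - mu) * phi)
            + (mu * phi - 1) * ly + ((1 - mu) * phi - 1) * l1y
        )
        return -ll

    ybar = float(np.clip(yi.mean(), 1e-3, 1 - 1e-3))
    x0 = np.array([logit(ybar), 0.0, math.log(5.0)])
    opt = optimize.minimize(negll, x0, method="BFGS")
    if not opt.success:
        opt = optimize.minimize(negll, x0, method="Nelder-Mead",
                                options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    b0, b1, logphi = opt.x
    try:
        cov = np.linalg.inv(_num_hessian(negll, opt.x))
        se = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se = float("nan")
        flags.append("hessian_failed")
    zstat = b1 / se if se and np.isfinite(se) and se > 0 else float("nan")
    pval = 2 * sps.norm.sf(abs(zstat)) if np.isfinite(zstat) else float("nan")

    return ModelResult(
        kind="zoib",
        estimate=float(b1), se=float(se) if np.isfinite(se) else None,
        stat=float(zstat) if np.isfinite(zstat) else None,
        p=float(pval) if np.isfinite(pval) else None,
        ci=(b1 - 1.96 * se, b1 + 1.96 * se) if np.isfinite(se) else None,
        params={"alpha0": a0, "alpha1": a1, "b0": float(b0), "b1": float(b1),
                "phi": float(math.exp(logphi))},
        flags=flags,
        extra={"n": n, "n0": n0, "n1": n1, "n_interior": int(len(yi)),
               "loglik_beta": float(-opt.fun)},
    )


def zoib_twin_replication(
    data: pd.DataFrame,
    score: str,
    group: str = "group",
    twin: str = "twin_label",
    alpha: float = 0.05,
) -> dict:
    """Fit the ZOIB group model separately in the twin-1 and twin-2 subsamples.

    The split removes the non-independence of twin observations; the group
    effect counts as significant only if p < alpha in both subsamples.
    """
    results = {}
    for label in (1, 2):
        sub = data[data[twin] == label]
        sub = _drop_missing(sub, [score, group], f"zoib[{score}] twin {label}")
        x, _ = _binary_x(sub, group)
        results[f"twin{label}"] = fit_zoib(sub[score].to_numpy(), x)
    ps = [results["twin1"].p, results["twin2"].p]
    results["significant_in_both"] = bool(
        all(p is not None and np.isfinite(p) and p < alpha for p in ps)
    )
    return results


# ---------------------------------------------------------------------------
# QHP position model
# ---------------------------------------------------------------------------

def qhp_position_model(
    data: pd.DataFrame,
    group: str = "group",
    pair: str = "pair_id",
    child: str = "child_id",
) -> ModelResult:
    """Mixed model of per-position right-reach proportion.

    Expects columns qhp_pos1..qhp_pos7 per child; fits
    proportion ~ position * group with random intercepts for pair and for
    child nested in pair (each child contributes 7 rows). Position enters
    numerically (1-7, 4 = midline). Reports Wald tests for position, group and
    their interaction.
    """
    pos_cols = [f"qhp_pos{p}" for p in range(1, 8)]
    missing = [c for c in pos_cols if c not in data.columns]
    if missing:
        raise ValidationError(f"missing QHP position columns: {missing}")
    long = data.melt(
        id_vars=[child, pair, group], value_vars=pos_cols,
        var_name="position", value_name="prop_right",
    )
    long["position"] = long["position"].str.removeprefix("qhp_pos").astype(float)
    long = long.dropna(subset=["prop_right"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(
            f"prop_right ~ position * C({group})",
            data=long, groups=long[pair], re_formula="1",
            vc_formula={"child": f"0 + C({child})"},
        )
        res = md.fit(reml=True, method=["lbfgs", "bfgs", "cg"])
    tests = {}
    for name in res.fe_params.index:
        if name == "Intercept":
            continue
        key = ("interaction" if ":" in name
               else "position" if name == "position" else "group")
        tests[key] = {
            "estimate": float(res.fe_params[name]),
            "se": float(res.bse_fe[name]),
            "stat": float(res.tvalues[name]),
            "p": float(res.pvalues[name]),
            "term": name,
        }
    return ModelResult(
        kind="qhp_position",
        estimate=tests.get("position", {}).get("estimate"),
        tests=tests,
        variance_components={
            "pair": float(res.cov_re.iloc[0, 0]),
            "child": float(res.vcomp[0]) if len(res.vcomp) else 0.0,
            "resid": float(res.scale),
        },
        extra={"n_rows": int(len(long)), "n_children": int(long[child].nunique())},
    )


# ---------------------------------------------------------------------------
# Spearman replication, effect sizes, descriptives
# ---------------------------------------------------------------------------

def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def spearman_replication(
    data: pd.DataFrame,
    target: str,
    measures: list[str],
    twin: str = "twin_label",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlations of each measure with ``target`` in both twin subsamples.

    Within each subsample the p-values are Holm-adjusted over the measure
    family; a correlation is 'replicated' iff the adjusted p is below alpha in
    both subsamples. Measures with fewer than 3 complete observations in a
    subsample are omitted with a warning.
    """
    per_twin = {}
    for label in (1, 2):
        sub = data[data[twin] == label]
        rows = []
        for m in measures:
            ok = sub[[m, target]].dropna()
            if len(ok) < 3:
                logger.warning("spearman: measure %s omitted in twin %d subsample (<3 values)", m, label)
                continue
            rho, p = sps.spearmanr(ok[m], ok[target])
            rows.append({"measure": m, f"rho{label}": rho, f"p{label}": p, f"n{label}": len(ok)})
        df = pd.DataFrame(rows)
        if len(df):
            df[f"p{label}_adj"] = holm_adjust(df[f"p{label}"])
        per_twin[label] = df
    merged = per_twin[1].merge(per_twin[2], on="measure", how="inner")
    if len(merged):
        merged["replicated"] = (merged["p1_adj"] < alpha) & (merged["p2_adj"] < alpha)
    else:
        merged["replicated"] = pd.Series(dtype=bool)
    return merged


def cohens_d(mean1: float, sd1: float, mean2: float, sd2: float) -> float:
    """Cohen's d with the unweighted root-mean variance of the two groups, to 2 dp."""
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("cohens_d requires positive SDs")
    return round((mean1 - mean2) / math.sqrt((sd1**2 + sd2**2) / 2.0), 2)


def format_count(count: int, n: int) -> str:
    """Frequency cell: '134 (85.9%)' with the group n as denominator."""
    pct = 0.0 if n == 0 else 100.0 * count / n
    return f"{count} ({pct:.1f}%)"


def summarize_cohort(
    cohort: pd.DataFrame,
    group_col: str = "group",
    continuous: list[str] | None = None,
    flags: list[str] | None = None,
    category_col: str | None = "category",
) -> pd.DataFrame:
    """Descriptive table: mean (SD) for continuous variables, count (pct) for flags.

    Percentages use the group n as denominator, printed to 1 decimal.
    """
    if continuous is None:
        candidates = [
            "age", "performance_iq", "ehi_li", "qhp_score", "li",
            "pct_change_left", "pct_change_right", "mean_words_per_valid_trial",
        ]
        continuous = [c for c in candidates if c in cohort.columns]
    if flags is None:
        flags = [c for c in ("ehi_right", "qhp_right", "consistent_dominance", "male")
                 if c in cohort.columns]
    rows = []
    for grp, sub in cohort.groupby(group_col):
        n = len(sub)
        rows.append({"group": grp, "variable": "n", "value": str(n)})
        for c in continuous:
            vals = sub[c].dropna()
            rows.append({
                "group": grp, "variable": c,
                "value": f"{vals.mean():.1f} (±{vals.std(ddof=1):.1f})" if len(vals) > 1 else "NA",
            })
        for c in flags:
            count = int(sub[c].fillna(False).astype(bool).sum())
            rows.append({"group": grp, "variable": c, "value": format_count(count, n)})
        if category_col and category_col in cohort.columns:
            for level in ("left", "bilateral", "right"):
                count = int((sub[category_col] == level).sum())
                rows.append({
                    "group": grp, "variable": f"laterality_{level}",
                    "value": format_count(count, n),
                })
    return pd.DataFrame(rows)
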