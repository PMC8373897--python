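"""Mixed-effects models with crossed random effects.

Maximum-likelihood fitting for the model families the analysis ladder
needs, all with crossed random intercepts (participant and item) and
optional condition random slopes:

- gaussian (identity link): exact ML via the profiled deviance, one
  Cholesky factorization per variance-parameter evaluation;
- poisson (log link) and gamma (log link): Laplace-approximate ML, inner
  Newton over the joint fixed + random coefficient vector, outer
  Nelder-Mead over log standard deviations (and log shape for gamma);
- cumulative-logit (proportional odds) for ordinal responses, same
  Laplace machinery with threshold parameters; adaptive Gauss-Hermite
  quadrature is available for models with a single random intercept
  factor (``nagq > 1``); Laplace equals the one-node quadrature.

Random slopes are diagonal: the non-reference condition dummies share one
slope standard deviation per grouping factor, with no intercept-slope
correlation. This keeps the variance-parameter space small and the
singularity fallback deterministic; the synthetic generator draws its
slopes the same way.

Wald standard errors condition on the variance parameters (the usual
mixed-model convention). Log-likelihoods are ML (never REML), so nested
fits are directly comparable by likelihood ratio.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

#: a variance component below this fraction of the response variance is singular
SINGULAR_REL_VAR = 1e-6

_LOG_SD_MIN, _LOG_SD_MAX = -8.0, 4.0

GAUSSIAN = "gaussian"
POISSON = "poisson"
GAMMA_LOG = "gamma-log"
CUMLOGIT = "cumulative-logit"
FAMILIES = (GAUSSIAN, POISSON, GAMMA_LOG, CUMLOGIT)


@dataclass(frozen=True)
class RandomTerm:
    """One variance component: a random intercept or condition slope."""

    factor: str
    slope: bool = False  # condition slope (diagonal, shared SD over dummies)

    @property
    def name(self) -> str:
        return f"{self.factor}_slope" if self.slope else self.factor


@dataclass
class FitResult:
    """A fitted mixed model."""

    formula: str
    family: str
    response: str
    params: np.ndarray  # thresholds (ordinal) then fixed-effect coefficients
    param_names: list[str]
    se: np.ndarray
    cov: np.ndarray
    vc: dict[str, float]  # term name -> standard deviation
    loglik: float
    n: int
    n_params: int
    converged: bool
    singular: bool
    singular_terms: list[str]
    scale: float | None = None  # gaussian residual SD
    shape: float | None = None  # gamma shape
    n_thresholds: int = 0
    colspecs: list[list[tuple[str, str]]] = field(default_factory=list)
    factors: dict[str, list[str]] = field(default_factory=dict)
    random_terms: tuple[RandomTerm, ...] = ()

    @property
    def beta(self) -> np.ndarray:
        return self.params[self.n_thresholds :]

    @property
    def beta_names(self) -> list[str]:
        return self.param_names[self.n_thresholds :]

    def coef_table(self) -> pd.DataFrame:
        z = np.where(self.se > 0, self.params / self.se, np.nan)
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            },
            index=self.param_names,
        )


# ---------------------------------------------------------------------------
# design matrices


def _ordered_levels(series: pd.Series, preferred: list[str] | None = None) -> list[str]:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [str(c) for c in series.cat.categories if c in set(series.dropna())]
    levels = [str(v) for v in pd.unique(series.dropna())]
    if preferred:
        ordered = [l for l in preferred if l in levels]
        ordered += [l for l in levels if l not in ordered]
        return ordered
    return sorted(levels)


def build_fixed(
    table: pd.DataFrame,
    terms: tuple[str, ...],
    factors: dict[str, list[str]],
) -> tuple[np.ndarray, list[str], list[list[tuple[str, str]]]]:
    """Treatment-coded fixed design with an intercept.

    ``terms`` are factor names or ``a:b`` interactions; ``factors`` gives
    the level order (first level = reference). Returns the matrix, column
    names, and per-column (factor, level) requirement lists used later for
    marginal-mean predictions.
    """
    n = len(table)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["(Intercept)"]
    specs: list[list[tuple[str, str]]] = [[]]
    for term in terms:
        parts = term.split(":")
        dummy_sets = []
        for f in parts:
            lv = factors[f]
            dummy_sets.append([(f, l) for l in lv[1:]])
        combos: list[list[tuple[str, str]]] = [[]]
        for ds in dummy_sets:
            combos = [c + [d] for c in combos for d in ds]
        for combo in combos:
            col = np.ones(n)
            for f, l in combo:
                col = col * (table[f].astype(str).to_numpy() == l)
            cols.append(col)
            names.append(":".join(f"{f}[{l}]" for f, l in combo))
            specs.append(combo)
    return np.column_stack(cols), names, specs


def build_random(
    table: pd.DataFrame,
    rterms: tuple[RandomTerm, ...],
    condition_levels: list[str],
    condition_col: str = "condition",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Random-effects design: one-hot intercepts, condition-dummy slopes.

    Returns Z (n x q), the per-column term index, and the term names.
    """
    n = len(table)
    blocks: list[np.ndarray] = []
    col_term: list[int] = []
    names: list[str] = []
    for ti, rt in enumerate(rterms):
        fac = table[rt.factor].astype(str).to_numpy()
        levels = sorted(set(fac))
        onehot = (fac[:, None] == np.array(levels)[None, :]).astype(float)
        if rt.slope:
            cond = table[condition_col].astype(str).to_numpy()
            for dummy_level in condition_levels[1:]:
                d = (cond == dummy_level).astype(float)
                blocks.append(onehot * d[:, None])
                col_term.extend([ti] * len(levels))
        else:
            blocks.append(onehot)
            col_term.extend([ti] * len(levels))
        names.append(rt.name)
    if blocks:
        Z = np.concatenate(blocks, axis=1)
    else:
        Z = np.zeros((n, 0))
    return Z, np.asarray(col_term, dtype=int), names


# ---------------------------------------------------------------------------
# family log-likelihoods (eta-parameterized)


def _poisson_parts(y, eta, _shape):
    mu = np.exp(np.clip(eta, -30, 30))
    ll = y * eta - mu - special.gammaln(y + 1)
    return ll, y - mu, mu


def _gamma_parts(y, eta, shape):
    k = shape
    inv_mu_y = y * np.exp(np.clip(-eta, -30, 30))
    ll = k * np.log(k) - special.gammaln(k) + (k - 1) * np.log(y) - k * eta - k * inv_mu_y
    return ll, k * (inv_mu_y - 1), k * inv_mu_y


_FAMILY_PARTS = {POISSON: _poisson_parts, GAMMA_LOG: _gamma_parts}


def _logistic_cdf(x):
    return special.expit(x)


# ---------------------------------------------------------------------------
# gaussian: exact profiled ML


class _GaussianProfile:
    def __init__(self, y, X, Z, col_term, n_terms):
        self.y = y
        self.n = y.size
        self.q = Z.shape[1]
        self.p = X.shape[1]
        A = np.concatenate([Z, X], axis=1)
        self.AtA = A.T @ A
        self.Aty = A.T @ y
        self.yty = float(y @ y)
        self.col_term = col_term
        self.n_terms = n_terms

    def _solve(self, log_lambdas):
        lam = np.exp(np.clip(log_lambdas, _LOG_SD_MIN, _LOG_SD_MAX))
        d = np.zeros(self.q + self.p)
        if self.q:
            d[: self.q] = 1.0 / lam[self.col_term] ** 2
        K = self.AtA + np.diag(d)
        try:
            c, low = linalg.cho_factor(K, lower=True)
        except linalg.LinAlgError:
            return None
        gamma = linalg.cho_solve((c, low), self.Aty)
        r2 = max(self.yty - gamma @ self.Aty, 1e-12)
        logdet_zz = 2.0 * np.sum(np.log(np.diag(c)[: self.q]))
        logdet_d = float(np.sum(np.log(d[: self.q]))) if self.q else 0.0
        return c, low, gamma, r2, logdet_zz, logdet_d

    def neg2ll(self, log_lambdas):
        sol = self._solve(log_lambdas)
        if sol is None:
            return 1e12
        _, _, _, r2, logdet_zz, logdet_d = sol
        sigma2 = r2 / self.n
        return self.n * math.log(2 * math.pi * sigma2) + self.n + logdet_zz - logdet_d

    def details(self, log_lambdas):
        c, low, gamma, r2, logdet_zz, logdet_d = self._solve(log_lambdas)
        sigma2 = r2 / self.n
        beta = gamma[self.q :]
        # Cov(beta) = sigma^2 * S^{-1}, S the trailing Schur complement
        L = np.tril(c)
        Lxx = L[self.q :, self.q :]
        S = Lxx @ Lxx.T
        cov = sigma2 * linalg.inv(S)
        ll = -0.5 * (self.n * math.log(2 * math.pi * sigma2) + self.n + logdet_zz - logdet_d)
        lam = np.exp(np.clip(log_lambdas, _LOG_SD_MIN, _LOG_SD_MAX))
        sigmas = lam * math.sqrt(sigma2)
        return beta, cov, math.sqrt(sigma2), sigmas, ll


# ---------------------------------------------------------------------------
# Laplace machinery for non-gaussian families


class _LaplaceModel:
    def __init__(self, y, X, Z, col_term, n_terms, family, n_cats=0):
        self.y = y
        self.X = X
        self.Z = Z
        self.A = np.concatenate([X, Z], axis=1)
        self.col_term = col_term
        self.n_terms = n_terms
        self.family = family
        self.n = y.size
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.n_cuts = max(n_cats - 1, 0) if family == CUMLOGIT else 0
        self.dim = self.n_cuts + self.p + self.q
        self._u = None  # warm start
        if family == CUMLOGIT:
            K = self.n_cuts + 1
            c = y.astype(int)
            self.T = np.zeros((self.n, self.n_cuts))
            self.Tm = np.zeros((self.n, self.n_cuts))
            has_up = c < K - 1
            has_lo = c > 0
            self.T[np.flatnonzero(has_up), c[has_up]] = 1.0
            self.Tm[np.flatnonzero(has_lo), c[has_lo] - 1] = 1.0

    # ---- penalized joint log-likelihood, gradient, negative Hessian ----

    def _ll_parts(self, u, shape):
        cuts = u[: self.n_cuts]
        eta = self.A @ u[self.n_cuts :]
        if self.family == CUMLOGIT:
            if self.n_cuts > 1 and np.any(np.diff(cuts) <= 0):
                return None
            up = self.T @ cuts - eta
            lo = self.Tm @ cuts - eta
            Fu = np.where(self.T.sum(axis=1) > 0, _logistic_cdf(up), 1.0)
            Fl = np.where(self.Tm.sum(axis=1) > 0, _logistic_cdf(lo), 0.0)
            P = np.clip(Fu - Fl, 1e-12, None)
            return ("ord", eta, Fu, Fl, P)
        ll, d, w = _FAMILY_PARTS[self.family](self.y, eta, shape)
        return ("glm", eta, ll, d, w)

    def penalized(self, u, d_pen, shape):
        parts = self._ll_parts(u, shape)
        if parts is None:
            return -np.inf
        if parts[0] == "ord":
            ll = float(np.sum(np.log(parts[4])))
        else:
            ll = float(np.sum(parts[2]))
        b = u[self.n_cuts + self.p :]
        return ll - 0.5 * float(b @ (d_pen * b))

    def grad_hess(self, u, d_pen, shape):
        parts = self._ll_parts(u, shape)
        if parts is None:
            return None
        g = np.zeros(self.dim)
        H = np.zeros((self.dim, self.dim))
        nc = self.n_cuts
        if parts[0] == "ord":
            _, eta, Fu, Fl, P = parts
            has_up = self.T.sum(axis=1) > 0
            has_lo = self.Tm.sum(axis=1) > 0
            fu = np.where(has_up, Fu * (1 - Fu), 0.0)
            fl = np.where(has_lo, Fl * (1 - Fl), 0.0)
            fpu = np.where(has_up, fu * (1 - 2 * Fu), 0.0)
            fpl = np.where(has_lo, fl * (1 - 2 * Fl), 0.0)
            dU = fu / P
            dL = fl / P
            A_uu = fpu / P - dU**2
            A_ll = -fpl / P - dL**2
            A_ul = dU * dL
            g_eta = -(dU - dL)
            g[:nc] = self.T.T @ dU - self.Tm.T @ dL
            g[nc:] = self.A.T @ g_eta
            W = -(A_uu + A_ll + 2 * A_ul)  # = -d2ll/deta2, >= 0
            H_cc = (
                self.T.T @ (A_uu[:, None] * self.T)
                + self.Tm.T @ (A_ll[:, None] * self.Tm)
                + self.T.T @ (A_ul[:, None] * self.Tm)
                + self.Tm.T @ (A_ul[:, None] * self.T)
            )
            M = (-(A_uu + A_ul))[:, None] * self.T + (-(A_ll + A_ul))[:, None] * self.Tm
            H[:nc, :nc] = -H_cc
            H[:nc, nc:] = -(M.T @ self.A)
            H[nc:, :nc] = H[:nc, nc:].T
            H[nc:, nc:] = (self.A * W[:, None]).T @ self.A
        else:
            _, eta, ll, d, w = parts
            g[nc:] = self.A.T @ d
            H[nc:, nc:] = (self.A * w[:, None]).T @ self.A
        b = u[nc + self.p :]
        g[nc + self.p :] -= d_pen * b
        H[nc + self.p :, nc + self.p :] += np.diag(d_pen)
        return g, H

    def inner_newton(self, d_pen, shape, u0=None, max_iter=60, tol=1e-8):
        u = (
            u0
            if u0 is not None
            else (self._u.copy() if self._u is not None else self._default_start())
        )
        obj = self.penalized(u, d_pen, shape)
        if not np.isfinite(obj):
            u = self._default_start()
            obj = self.penalized(u, d_pen, shape)
        H = None
        for _ in range(max_iter):
            gh = self.grad_hess(u, d_pen, shape)
            if gh is None:
                break
            g, H = gh
            try:
                step = linalg.solve(H + 1e-10 * np.eye(self.dim), g, assume_a="pos")
            except linalg.LinAlgError:
                step = linalg.lstsq(H, g)[0]
            t = 1.0
            improved = False
            for _ in range(30):
                cand = u + t * step
                val = self.penalized(cand, d_pen, shape)
                if val > obj - 1e-12:
                    u, obj, improved = cand, val, True
                    break
                t *= 0.5
            if not improved or float(np.max(np.abs(t * step))) < tol:
                break
        self._u = u.copy()
        gh = self.grad_hess(u, d_pen, shape)
        if gh is not None:
            _, H = gh
        return u, obj, H

    def _default_start(self):
        u = np.zeros(self.dim)
        if self.family == CUMLOGIT:
            K = self.n_cuts + 1
            freq = np.bincount(self.y.astype(int), minlength=K) + 0.5
            cum = np.cumsum(freq)[:-1] / freq.sum()
            u[: self.n_cuts] = np.log(cum / (1 - cum))
        elif self.family in (POISSON, GAMMA_LOG):
            u[self.n_cuts] = math.log(max(float(np.mean(self.y)), 1e-3))
        return u

    def laplace_loglik(self, sigmas, shape):
        d_pen = np.zeros(self.q)
        if self.q:
            d_pen = 1.0 / np.asarray(sigmas)[self.col_term] ** 2
        u, obj, H = self.inner_newton(d_pen, shape)
        if H is None or not np.isfinite(obj):
            return -1e12, u, None
        if self.q:
            H_bb = H[self.n_cuts + self.p :, self.n_cuts + self.p :]
            try:
                cb = linalg.cholesky(H_bb, lower=True)
            except linalg.LinAlgError:
                return -1e12, u, None
            logdet_h = 2.0 * float(np.sum(np.log(np.diag(cb))))
            logdet_d = float(np.sum(np.log(d_pen)))
            ll = obj + 0.5 * logdet_d - 0.5 * logdet_h
        else:
            ll = obj
        return float(ll), u, H


# ---------------------------------------------------------------------------
# public fitting entry point


def fit_mixed(
    table: pd.DataFrame,
    response: str,
    family: str = GAUSSIAN,
    fixed: tuple[str, ...] = ("condition",),
    random: tuple[RandomTerm, ...] = (RandomTerm("participant"), RandomTerm("item")),
    factors: dict[str, list[str]] | None = None,
    condition_levels: list[str] | None = None,
    nagq: int = 1,
    theta0: "np.ndarray | None" = None,
) -> FitResult:
    """Fit one mixed model by ML and return the full result.

    ``fixed`` lists factor terms (``"condition"``, ``"modality"``,
    ``"condition:modality"``); an intercept is always included (ordinal
    models absorb it into the thresholds). ``random`` lists variance
    components. Rows with a missing response are dropped.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    data = table.dropna(subset=[response]).reset_index(drop=True)
    if len(data) == 0:
        raise ValueError(f"no observations with non-missing {response}")
    y = data[response].to_numpy(dtype=float)
    if family == POISSON and np.any(y < 0):
        raise ValueError("poisson family needs non-negative counts")
    if family == GAMMA_LOG and np.any(y <= 0):
        raise ValueError("gamma family needs a strictly positive response")

    fac = dict(factors or {})
    used = sorted({f for t in fixed for f in t.split(":")})
    for f in used:
        if f not in fac:
            pref = condition_levels if f == "condition" else None
            fac[f] = _ordered_levels(data[f], pref)
    cl = condition_levels or fac.get("condition") or _ordered_levels(
        data.get("condition", pd.Series(dtype=str))
    )

    X, names, specs = build_fixed(data, fixed, fac)
    Z, col_term, term_names = build_random(data, tuple(random), cl)
    n, p, q = len(data), X.shape[1], Z.shape[1]
    formula = f"{response} ~ {' + '.join(fixed) if fixed else '1'}" + "".join(
        f" + ({'0 + condition | ' if rt.slope else '1 | '}{rt.factor})" for rt in random
    )

    if family == CUMLOGIT:
        levels = np.sort(np.unique(y))
        if levels.size < 2:
            raise ValueError("ordinal response needs at least two observed levels")
        codes = np.searchsorted(levels, y)
        n_cats = levels.size
        X_ord = X[:, 1:]  # thresholds play the intercept's role
        names_ord = names[1:]
        specs_ord = specs[1:]
        result = _fit_laplace(
            codes, X_ord, Z, col_term, term_names, family, n_cats, nagq, data,
            tuple(random), theta0,
        )
        cut_names = [f"cut[{levels[k]:g}|{levels[k + 1]:g}]" for k in range(n_cats - 1)]
        param_names = cut_names + names_ord
        n_cuts = n_cats - 1
        fixed_specs = specs_ord
    elif family == GAUSSIAN:
        result = _fit_gaussian(y, X, Z, col_term, term_names)
        param_names, n_cuts, fixed_specs = names, 0, specs
    else:
        result = _fit_laplace(
            y, X, Z, col_term, term_names, family, 0, 1, data, tuple(random), theta0
        )
        param_names, n_cuts, fixed_specs = names, 0, specs

    params, cov, vc, ll, scale, shape, converged = result
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    scale_ref = _singular_scale(y, family)
    singular_terms = [
        t for t, sd in vc.items() if sd**2 < SINGULAR_REL_VAR * scale_ref
    ]
    n_params = (
        len(params)
        + len(vc)
        + (1 if family == GAUSSIAN else 0)
        + (1 if family == GAMMA_LOG else 0)
    )
    return FitResult(
        formula=formula,
        family=family,
        response=response,
        params=params,
        param_names=param_names,
        se=se,
        cov=cov,
        vc=vc,
        loglik=ll,
        n=n,
        n_params=n_params,
        converged=converged,
        singular=bool(singular_terms),
        singular_terms=singular_terms,
        scale=scale,
        shape=shape,
        n_thresholds=n_cuts,
        colspecs=fixed_specs,
        factors=fac,
        random_terms=tuple(random),
    )


def _singular_scale(y: np.ndarray, family: str) -> float:
    if family == GAUSSIAN:
        return float(np.var(y)) or 1.0
    if family in (POISSON, GAMMA_LOG):
        return float(np.var(np.log(y + 0.5))) or 1.0
    return 1.0  # logit scale


def _fit_gaussian(y, X, Z, col_term, term_names):
    prof = _GaussianProfile(y, X, Z, col_term, len(term_names))
    k = len(term_names)
    if k == 0:
        beta, cov, sigma, sigmas, ll = prof.details(np.zeros(0))
        return beta, cov, {}, ll, sigma, None, True
    best = optimize.minimize(
        prof.neg2ll, np.zeros(k), method="Nelder-Mead",
        options={"xatol": 5e-4, "fatol": 1e-7, "maxiter": 250 * k, "maxfev": 250 * k},
    )
    log_lam = np.clip(best.x, _LOG_SD_MIN, _LOG_SD_MAX)
    # boundary probe: a component whose removal leaves the deviance flat is
    # numerically at zero even if the optimizer stalled above the floor
    flat: list[str] = []
    for i, t in enumerate(term_names):
        probe = log_lam.copy()
        probe[i] = _LOG_SD_MIN
        if prof.neg2ll(probe) - best.fun < 2e-3:
            flat.append(t)
            log_lam[i] = _LOG_SD_MIN
    beta, cov, sigma, sigmas, ll = prof.details(log_lam)
    vc = {t: float(s) for t, s in zip(term_names, sigmas)}
    return beta, cov, vc, ll, sigma, None, bool(best.success or best.fun < 1e11)


def _fit_laplace(y, X, Z, col_term, term_names, family, n_cats, nagq, data, rterms, theta0=None):
    model = _LaplaceModel(y, X, Z, col_term, len(term_names), family, n_cats)
    k = len(term_names)
    has_shape = family == GAMMA_LOG
    dim = k + (1 if has_shape else 0)

    def unpack(theta):
        sigmas = np.exp(np.clip(theta[:k], _LOG_SD_MIN, _LOG_SD_MAX))
        shape = float(np.exp(np.clip(theta[k], -4, 8))) if has_shape else None
        return sigmas, shape

    if (
        family == CUMLOGIT
        and nagq > 1
        and k == 1
        and not rterms[0].slope
    ):
        return _fit_clmm_agq(model, data, rterms[0], nagq, term_names)

    def objective(theta):
        sigmas, shape = unpack(theta)
        ll, _, _ = model.laplace_loglik(sigmas, shape)
        return -ll

    if dim == 0:
        _, obj, H = model.inner_newton(np.zeros(0), None)
        u = model._u
        nf = model.n_cuts + model.p
        cov = linalg.inv(H[:nf, :nf] + 1e-10 * np.eye(nf))
        return u[:nf], cov, {}, obj, None, None, True

    x0 = np.full(dim, math.log(0.5))
    if has_shape:
        x0[k] = math.log(2.0)
    if theta0 is not None and len(theta0) == dim:
        x0 = np.asarray(theta0, dtype=float)
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 4e-3, "fatol": 3e-4, "maxiter": 200 * dim, "maxfev": 200 * dim},
    )
    theta = res.x.copy()
    # boundary probe, as in the gaussian path
    for i in range(k):
        probe = theta.copy()
        probe[i] = _LOG_SD_MIN
        if objective(probe) - res.fun < 1e-3:
            theta[i] = _LOG_SD_MIN
    sigmas, shape = unpack(theta)
    ll, u, H = model.laplace_loglik(sigmas, shape)
    nf = model.n_cuts + model.p
    # fixed-parameter covariance: profile the random effects out of the
    # joint negative Hessian (Schur complement), then invert
    if model.q:
        Hff = H[:nf, :nf]
        Hfb = H[:nf, nf:]
        Hbb = H[nf:, nf:]
        S = Hff - Hfb @ linalg.solve(Hbb, Hfb.T, assume_a="pos")
    else:
        S = H[:nf, :nf]
    cov = linalg.inv(S + 1e-10 * np.eye(nf))
    vc = {t: float(s) for t, s in zip(term_names, sigmas)}
    return u[:nf], cov, vc, ll, None, shape, bool(res.success or np.isfinite(ll))


def _fit_clmm_agq(model, data, rterm, nagq, term_names):
    """Adaptive Gauss-Hermite for a single random-intercept CLMM."""
    fac = data[rterm.factor].astype(str).to_numpy()
    levels = sorted(set(fac))
    groups = [np.flatnonzero(fac == l) for l in levels]
    nodes, weights = np.polynomial.hermite.hermgauss(nagq)
    nf = model.n_cuts + model.p
    T, Tm, Xo, y = model.T, model.Tm, model.X, model.y

    def group_ll(cuts, beta, sigma, idx):
        eta0 = Xo[idx] @ beta if model.p else np.zeros(idx.size)

        def ll_of_v(v):
            eta = eta0 + sigma * v
            up = T[idx] @ cuts - eta
            lo = Tm[idx] @ cuts - eta
            Fu = np.where(T[idx].sum(axis=1) > 0, _logistic_cdf(up), 1.0)
            Fl = np.where(Tm[idx].sum(axis=1) > 0, _logistic_cdf(lo), 0.0)
            return float(np.sum(np.log(np.clip(Fu - Fl, 1e-12, None))))

        # 1-D mode and curvature by a small Newton-on-grid refinement
        v = 0.0
        for _ in range(40):
            h = 1e-4
            g = (ll_of_v(v + h) - ll_of_v(v - h)) / (2 * h) - v
            hh = (ll_of_v(v + h) - 2 * ll_of_v(v) + ll_of_v(v - h)) / h**2 - 1.0
            if hh >= -1e-8:
                hh = -1.0
            step = -g / hh
            if abs(step) < 1e-8:
                break
            v += np.clip(step, -3, 3)
        curv = -( (ll_of_v(v + 1e-4) - 2 * ll_of_v(v) + ll_of_v(v - 1e-4)) / 1e-8 - 1.0)
        s = 1.0 / math.sqrt(max(curv, 1e-8))
        vals = np.array(
            [ll_of_v(v + s * math.sqrt(2.0) * x) - 0.5 * (v + s * math.sqrt(2.0) * x) ** 2
             for x in nodes]
        )
        m = np.max(vals + nodes**2)
        total = math.sqrt(2.0) * s * np.sum(weights * np.exp(vals + nodes**2 - m))
        return math.log(total) + m - 0.5 * math.log(2 * math.pi)

    def objective(theta):
        cuts = theta[: model.n_cuts]
        if model.n_cuts > 1 and np.any(np.diff(cuts) <= 0):
            return 1e10
        beta = theta[model.n_cuts : nf]
        sigma = math.exp(np.clip(theta[nf], _LOG_SD_MIN, _LOG_SD_MAX))
        return -sum(group_ll(cuts, beta, sigma, idx) for idx in groups)

    x0 = np.zeros(nf + 1)
    x0[: model.n_cuts] = model._default_start()[: model.n_cuts]
    x0[nf] = math.log(0.5)
    res = optimize.minimize(
        objective, x0, method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 600 * (nf + 1),
                 "maxfev": 600 * (nf + 1)},
    )
    ll = -res.fun
    sigma = math.exp(np.clip(res.x[nf], _LOG_SD_MIN, _LOG_SD_MAX))
    # covariance from a numerical Hessian over the fixed parameters
    hess = _num_hess(lambda th: -objective(np.concatenate([th, [res.x[nf]]])), res.x[:nf])
    try:
        cov = linalg.inv(-hess + 1e-8 * np.eye(nf))
    except linalg.LinAlgError:
        cov = np.full((nf, nf), np.nan)
    vc = {term_names[0]: sigma}
    return res.x[:nf], cov, vc, float(ll), None, None, bool(res.success)


def _num_hess(f, x, h=1e-4):
    n = x.size
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xi = x.copy(); xi[i] += h
            xj = x.copy(); xj[j] += h
            xij = x.copy(); xij[i] += h; xij[j] += h
            H[i, j] = H[j, i] = (f(xij) - f(xi) - f(xj) + f0) / h**2
    return H
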