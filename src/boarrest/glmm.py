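"""Generalized linear mixed models with nested random intercepts.

Three response families cover every model fitted downstream:

* ``binomial`` (logit link) — resource selection and relocation probability;
* ``zt_poisson`` (log link) — revisitation counts, which are >= 1 by
  construction, so the Poisson likelihood is conditioned on Y >= 1:
  P(Y = k | k >= 1) = lambda^k e^(-lambda) / (k! (1 - e^(-lambda)));
* ``gamma_log`` (log link) — positive continuous relocation distances.

Random structure: an intercept per study site and an intercept per animal
nested within site, each with its own variance.  The marginal likelihood is
integrated by a Laplace approximation over the joint random-effects vector:
the penalized log-likelihood is maximized over all intercepts by Newton
iterations that exploit the nested (arrowhead) sparsity of the Hessian, and
the Gaussian integral is corrected by the block determinant.  With no random
factors the likelihood is the exact GLM likelihood.  Standard errors are
Wald, from the numerically observed information of the marginal likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

log = logging.getLogger("boarrest")

FAMILIES = ("binomial", "zt_poisson", "gamma_log")
_ETA_CLIP = 30.0
_SD_LOG_BOUNDS = (-6.0, 3.0)


# ---------------------------------------------------------------------------
# Family log-likelihoods
# ---------------------------------------------------------------------------

def _ll_binomial(y, eta):
    return y * eta - np.logaddexp(0.0, eta)


def _ll_zt_poisson(y, eta):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    lam = np.exp(eta)
    # log(1 - e^{-lam}) via expm1 is stable down to tiny lam
    return y * eta - lam - special.gammaln(y + 1.0) - np.log(-np.expm1(-lam))


def _ll_gamma_log(y, eta, shape):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return (shape * np.log(shape) - special.gammaln(shape)
            + (shape - 1.0) * np.log(y) - shape * eta - shape * y * np.exp(-eta))


def zt_poisson_mean(lam):
    """Mean of the zero-truncated Poisson: lambda / (1 - e^(-lambda))."""
    lam = np.asarray(lam, dtype=float)
    return lam / -np.expm1(-lam)


def rvs_zt_poisson(lam, rng, size=None):
    """Draw zero-truncated Poisson variates by inverse CDF."""
    lam = np.broadcast_to(np.asarray(lam, dtype=float), np.shape(lam) if size is None else size)
    u = rng.uniform(size=lam.shape)
    p0 = np.exp(-lam)
    return stats.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(int)


# ---------------------------------------------------------------------------
# Fit container
# ---------------------------------------------------------------------------

@dataclass
class GlmmFit:
    family: str
    term_names: list
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray                      # fixed-effect covariance block
    var_components: dict                 # {"site": var, "animal": var}
    shape: float | None                  # gamma shape, else None
    loglik: float
    converged: bool
    n_obs: int
    penalized: bool = False
    eta_hat: np.ndarray = field(default=None, repr=False)
    X: np.ndarray = field(default=None, repr=False)   # kept-column design

    @property
    def z_values(self):
        return self.coef / self.se

    @property
    def p_values(self):
        return 2.0 * stats.norm.sf(np.abs(self.z_values))

    def summary_frame(self):
        import pandas as pd
        return pd.DataFrame({"term": self.term_names, "beta": self.coef,
                             "se": self.se, "z": self.z_values, "p": self.p_values})


# ---------------------------------------------------------------------------
# Marginal likelihood via Laplace approximation with nested sparsity
# ---------------------------------------------------------------------------

class _NestedData:
    """Integer group indices for (site, animal-within-site)."""

    def __init__(self, X, y, site, animal, offset):
        n = len(y)
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
        self.site = (np.zeros(n, dtype=int) if site is None
                     else np.unique(np.asarray(site), return_inverse=True)[1])
        if animal is None:
            self.animal = np.zeros(n, dtype=int)
        else:
            akey = np.array([f"{s}|{a}" for s, a in zip(self.site, np.asarray(animal))])
            self.animal = np.unique(akey, return_inverse=True)[1]
        self.n_sites = int(self.site.max()) + 1
        self.n_animals = int(self.animal.max()) + 1
        # site of each animal
        self.anim_site = np.full(self.n_animals, -1, dtype=int)
        self.anim_site[self.animal] = self.site


def _derivs(family, y, eta, shape):
    """(per-obs loglik, d loglik / d eta, -d2 loglik / d eta2)."""
    if family == "binomial":
        p = special.expit(eta)
        return _ll_binomial(y, eta), y - p, p * (1.0 - p)
    if family == "zt_poisson":
        lam = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        mu = lam / -np.expm1(-lam)
        # canonical link: curvature = Var(Y) of the truncated distribution
        w = np.maximum(mu * (1.0 + lam - mu), 1e-10)
        return _ll_zt_poisson(y, eta), y - mu, w
    r = y * np.exp(-np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
    return _ll_gamma_log(y, eta, shape), shape * (r - 1.0), np.maximum(shape * r, 1e-10)


def _make_nll(data: _NestedData, family, est_site, est_animal, est_shape):
    """Return the negative Laplace-approximate marginal log-likelihood.

    The inner Newton solve maximizes the penalized log-likelihood over the
    joint random-effects vector; each Newton step solves the arrowhead system
    (one site intercept bordered by its animals' diagonal block) exactly via
    a Schur complement.  Modes are warm-started across outer iterations.
    """
    p = data.X.shape[1]
    S, A = data.n_sites, data.n_animals
    state = {"u": np.zeros(S), "v": np.zeros(A)}

    def nll(theta):
        beta = theta[:p]
        k = p
        sd_s = np.exp(theta[k]) if est_site else 0.0
        k += est_site
        sd_a = np.exp(theta[k]) if est_animal else 0.0
        k += est_animal
        shape = np.exp(theta[k]) if est_shape else None

        eta0 = data.X @ beta + data.offset
        if not est_site and not est_animal:
            ll, _, _ = _derivs(family, data.y, eta0, shape)
            return -float(ll.sum())

        u, v = state["u"].copy(), state["v"].copy()

        def objective(u, v):
            eta = eta0 + sd_s * u[data.site] + sd_a * v[data.animal]
            ll, d1, w = _derivs(family, data.y, eta, shape)
            return float(ll.sum()) - 0.5 * float(u @ u) - 0.5 * float(v @ v), d1, w

        obj, d1, w = objective(u, v)
        for _ in range(60):
            g_u = sd_s * np.bincount(data.site, d1, S) - u
            g_v = sd_a * np.bincount(data.animal, d1, A) - v
            if max(np.abs(g_u).max(initial=0), np.abs(g_v).max(initial=0)) < 1e-8:
                break
            w_site = sd_s ** 2 * np.bincount(data.site, w, S) + 1.0
            w_anim = sd_a ** 2 * np.bincount(data.animal, w, A) + 1.0
            c = sd_s * sd_a * np.bincount(data.animal, w, A)   # cross term per animal
            if est_site and est_animal:
                schur = w_site - np.bincount(data.anim_site, c ** 2 / w_anim, S)
                rhs = g_u - np.bincount(data.anim_site, c * g_v / w_anim, S)
                du = rhs / schur
                dv = (g_v - c * du[data.anim_site]) / w_anim
            elif est_site:
                du, dv = g_u / w_site, np.zeros(A)
            else:
                du, dv = np.zeros(S), g_v / w_anim
            t = 1.0
            for _ in range(25):
                new_obj, nd1, nw = objective(u + t * du, v + t * dv)
                if new_obj >= obj - 1e-12:
                    break
                t *= 0.5
            u, v = u + t * du, v + t * dv
            obj, d1, w = new_obj, nd1, nw
        state["u"], state["v"] = u, v

        w_site = sd_s ** 2 * np.bincount(data.site, w, S) + 1.0
        w_anim = sd_a ** 2 * np.bincount(data.animal, w, A) + 1.0
        if est_site and est_animal:
            c = sd_s * sd_a * np.bincount(data.animal, w, A)
            schur = w_site - np.bincount(data.anim_site, c ** 2 / w_anim, S)
            logdet = float(np.log(schur).sum() + np.log(w_anim).sum())
        elif est_site:
            logdet = float(np.log(w_site).sum())
        else:
            logdet = float(np.log(w_anim).sum())
        return -(obj - 0.5 * logdet)

    return nll


def _init_beta(X, y, family, offset):
    import statsmodels.api as sm
    off = None if offset is None else np.asarray(offset, dtype=float)
    try:
        if family == "binomial":
            fam = sm.families.Binomial()
        elif family == "zt_poisson":
            fam = sm.families.Poisson()
        else:
            fam = sm.families.Gamma(link=sm.families.links.Log())
        res = sm.GLM(y, X, family=fam, offset=off).fit(maxiter=100)
        beta = np.asarray(res.params, dtype=float)
        if np.isfinite(beta).all():
            return np.clip(beta, -10, 10)
    except Exception:
        pass
    return np.zeros(X.shape[1])


def _num_hessian(f, x, step=1e-4):
    n = len(x)
    h = step * (1.0 + np.abs(x))
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = h[i]
            ej = np.zeros(n); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_glmm(X, y, family, site=None, animal=None, offset=None,
             term_names=None, ridge=0.0) -> GlmmFit:
    """Maximum (marginal) likelihood fit.

    ``site``/``animal``: group labels for the nested random intercepts.  A
    factor with fewer than 2 distinct levels has its variance pinned at 0
    (warning).  Complete separation in the binomial family (runaway
    coefficients) triggers a penalized refit with a small ridge on the
    slopes, flagged on the result.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if family == "zt_poisson" and (y < 1).any():
        raise ValueError("zero-truncated Poisson requires counts >= 1")
    if family == "gamma_log" and (y <= 0).any():
        raise ValueError("gamma response must be positive")

    # drop aliased columns
    q, r = np.linalg.qr(X)
    keep = np.abs(np.diag(r)) > 1e-9 * max(1.0, np.abs(np.diag(r)).max())
    if not keep.all():
        log.warning("design matrix rank deficient; dropping %d aliased columns",
                    int((~keep).sum()))
        X = X[:, keep]
        if term_names:
            term_names = [t for t, k in zip(term_names, keep) if k]
    term_names = term_names or [f"x{i}" for i in range(X.shape[1])]
    p = X.shape[1]

    def n_levels(g):
        return 0 if g is None else len(set(np.asarray(g).tolist()))

    est_site = n_levels(site) >= 2
    est_animal = n_levels(animal) >= 2
    if site is not None and not est_site:
        log.warning("fewer than 2 sites; site variance pinned at 0")
    if animal is not None and not est_animal:
        log.warning("fewer than 2 animals; animal variance pinned at 0")
    est_shape = family == "gamma_log"

    data = _NestedData(X, y, site if est_site else None,
                       animal if est_animal else None, offset)
    nll_raw = _make_nll(data, family, est_site, est_animal, est_shape)

    slope_mask = np.zeros(p)
    slope_mask[1:] = 1.0  # never penalize the leading column (intercept)

    best = {"f": np.inf, "x": None}

    def nll(theta):
        val = nll_raw(theta)
        if ridge > 0:
            val += ridge * float(np.sum((slope_mask * theta[:p]) ** 2))
        if np.isfinite(val) and val < best["f"]:
            best["f"], best["x"] = val, theta.copy()
        return val if np.isfinite(val) else 1e12

    x0 = list(_init_beta(X, y, family, offset))
    bounds = [(None, None)] * p
    for flag in (est_site, est_animal):
        if flag:
            x0.append(np.log(0.3))
            bounds.append(_SD_LOG_BOUNDS)
    if est_shape:
        x0.append(0.0)
        bounds.append((-4.0, 6.0))
    x0 = np.array(x0)

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 300, "ftol": 1e-10})
    xhat = best["x"] if best["x"] is not None else res.x
    converged = bool(res.success) or best["f"] < np.inf

    # separation guard
    if family == "binomial" and ridge == 0.0 and np.abs(xhat[:p]).max() > 10.0:
        log.warning("possible complete separation; refitting with ridge penalty")
        fit = fit_glmm(X, y, family, site=site if est_site else None,
                       animal=animal if est_animal else None, offset=offset,
                       term_names=term_names, ridge=1e-2)
        fit.penalized = True
        return fit

    H = _num_hessian(nll_raw, xhat)
    try:
        cov_all = np.linalg.inv(H)
        if not np.all(np.diag(cov_all)[:p] > 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
        converged = False
    se = np.sqrt(np.abs(np.diag(cov_all)[:p]))

    k = p
    var_c = {}
    if est_site:
        var_c["site"] = float(np.exp(2 * xhat[k])); k += 1
    else:
        var_c["site"] = 0.0
    if est_animal:
        var_c["animal"] = float(np.exp(2 * xhat[k])); k += 1
    else:
        var_c["animal"] = 0.0
    shape = float(np.exp(xhat[k])) if est_shape else None

    if not converged:
        log.warning("GLMM fit did not converge cleanly (family=%s)", family)
    return GlmmFit(family=family, term_names=list(term_names), coef=xhat[:p],
                   se=se, cov=cov_all[:p, :p], var_components=var_c, shape=shape,
                   loglik=-nll_raw(xhat), converged=converged, n_obs=len(y),
                   penalized=ridge > 0, eta_hat=X @ xhat[:p] + (
                       0.0 if offset is None else np.asarray(offset, dtype=float)),
                   X=X)


# ---------------------------------------------------------------------------
# Diagnostics and prediction
# ---------------------------------------------------------------------------

def marginal_r2(fit: GlmmFit, X=None, offset=None) -> float:
    """Nakagawa's marginal R^2: variance explained by fixed effects over
    fixed + random + family-specific residual variance (latent scale).

    Residual variance: pi^2/3 for binomial-logit; ln(1 + 1/mean(lambda)) for
    (zero-truncated) Poisson via the lognormal approximation; trigamma(shape)
    for gamma with log link.
    """
    X = np.asarray(fit.X if X is None else X, dtype=float)
    eta_f = X @ fit.coef
    var_f = float(np.var(eta_f))
    if var_f < 1e-12:
        return 0.0
    if fit.family == "binomial":
        resid = np.pi ** 2 / 3.0
    elif fit.family == "zt_poisson":
        full = eta_f + (0.0 if offset is None else np.asarray(offset, dtype=float))
        lam_bar = float(np.mean(np.exp(np.clip(full, -_ETA_CLIP, _ETA_CLIP))))
        resid = float(np.log1p(1.0 / lam_bar))
    else:
        resid = float(special.polygamma(1, fit.shape))
    total = var_f + sum(fit.var_components.values()) + resid
    return float(np.clip(var_f / total, 0.0, 1.0))


def predict_response(fit: GlmmFit, x_row, offset=0.0, alpha=0.05):
    """Response-scale prediction at random effects = 0, with a Wald CI
    computed on the link scale and back-transformed."""
    x = np.asarray(x_row, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != len(fit.coef):
        raise ValueError("covariate profile does not match the fitted design")
    eta = x @ fit.coef + offset
    se = np.sqrt(np.einsum("ij,jk,ik->i", x, fit.cov, x))
    zc = stats.norm.ppf(1 - alpha / 2)
    lo, hi = eta - zc * se, eta + zc * se
    inv = special.expit if fit.family == "binomial" else np.exp
    out = inv(eta), inv(lo), inv(hi)
    if np.shape(x_row) == (len(fit.coef),):
        return tuple(float(v[0]) for v in out)
    return out


# ---------------------------------------------------------------------------
# Simulation (used by tests and the synthetic study)
# ---------------------------------------------------------------------------

def simulate_glmm_response(X, beta, family, rng, site=None, animal=None,
                           sd_site=0.0, sd_animal=0.0, shape=2.0, offset=None):
    """Draw a response vector from the model, given true parameters."""
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    if offset is not None:
        eta = eta + np.asarray(offset, dtype=float)
    if site is not None and sd_site > 0:
        _, si = np.unique(site, return_inverse=True)
        eta = eta + rng.normal(0, sd_site, si.max() + 1)[si]
    if animal is not None and sd_animal > 0:
        _, ai = np.unique(animal, return_inverse=True)
        eta = eta + rng.normal(0, sd_animal, ai.max() + 1)[ai]
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    if family == "binomial":
        return (rng.uniform(size=len(eta)) < special.expit(eta)).astype(int)
    if family == "zt_poisson":
        return rvs_zt_poisson(np.exp(eta), rng)
    return rng.gamma(shape, np.exp(eta) / shape)


def build_design(df, terms):
    """Design matrix with intercept from a dataframe.

    ``terms`` are column names or ``a:b`` products; returns (X, names)."""
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for t in terms:
        parts = t.split(":")
        v = np.ones(len(df))
        for pt in parts:
            v = v * df[pt].to_numpy(dtype=float)
        cols.append(v)
        names.append(t)
    return np.column_stack(cols), names
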