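"""Binomial random-intercept occurrence models with a detectability offset.

The occurrence of the focal bird at a point count is modelled as a
Bernoulli outcome with a logit link,

.. math::

    \\mathrm{logit}\\, P(y_{ij} = 1)
        = \\mathrm{logit}(\\hat p_{ij}) + x_{ij}^\\top \\beta + u_i,
    \\qquad u_i \\sim N(0, \\sigma^2_{site}),

where the offset ``logit(p_hat)`` is the detection probability predicted
by the distance-sampling step (absorbing spatial heterogeneity in
detectability on the odds scale), ``x`` collects a survey-date term,
habitat terms (second-order orthogonal polynomials of four continuous
covers plus a river indicator), optional second-order terms in a
moderator (residence time or a climate variable) and optional
habitat-by-moderator interactions, and ``u_i`` is a site random
intercept accounting for the correlation of point counts within a site.

Fitting is by maximum likelihood with the site intercept integrated out
by adaptive Gauss-Hermite quadrature (default 25 nodes): for each site
the integrand is re-centred at its posterior mode and re-scaled by its
curvature before applying the Gauss-Hermite rule, which keeps the
quadrature accurate even for sites with many informative observations.
ML (not REML) is used throughout because the model set is compared by
AIC across different fixed-effect structures.

The competing biological hypotheses form a fixed set of ten models (a
null with date and offset only; habitat; habitat plus each of residence
time, cumulative water deficit, coldest-month temperature and a
precomputed climate-suitability score; and habitat crossed with each of
those four moderators).  Explanatory power of the fixed effects is
summarised by the latent-scale marginal R-squared,
``var(X beta) / (var(X beta) + sigma_site^2 + pi^2 / 3)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "HABITAT_CONTINUOUS",
    "MODERATORS",
    "DesignMatrices",
    "GLMMFit",
    "LRTResult",
    "OccurrenceModelSpec",
    "build_design",
    "build_hypothesis_set",
    "compare_models",
    "fit_glmm",
    "fit_occurrence_model",
    "likelihood_ratio_test",
    "marginal_r2",
    "predict_curves",
    "residual_spatial_check",
]

HABITAT_CONTINUOUS = ("emergent_veg", "trees_bushes", "forbs", "rough_grass")
MODERATORS = ("residence_time", "cwd", "mtcm", "climate_sdm")


# ---------------------------------------------------------------------------
# model specifications

@dataclass(frozen=True)
class OccurrenceModelSpec:
    """One hypothesis model: which terms enter the fixed effects.

    Every model contains the survey-date term and the logit-detectability
    offset; ``habitat`` switches the habitat block on, ``moderator``
    names an optional additive moderator, and ``interaction`` crosses
    the habitat terms (first and second order, and the river indicator)
    with the moderator's first- and second-order terms.
    """

    name: str
    habitat: bool = False
    moderator: Optional[str] = None
    interaction: bool = False

    def __post_init__(self):
        if self.moderator is not None and self.moderator not in MODERATORS:
            raise ValueError(f"unknown moderator {self.moderator!r}")
        if self.interaction and (not self.habitat or self.moderator is None):
            raise ValueError("interaction models need habitat and a moderator")

    @property
    def variables(self) -> tuple:
        out = ["date"]
        if self.habitat:
            out += list(HABITAT_CONTINUOUS) + ["river"]
        if self.moderator:
            out.append(self.moderator)
        return tuple(out)


def build_hypothesis_set(moderators=MODERATORS) -> list:
    """The fixed ten-model hypothesis set compared by AIC.

    Null (date + offset only); habitat only; habitat plus each moderator
    additively; habitat crossed with each moderator.
    """
    specs = [
        OccurrenceModelSpec("null (date only)"),
        OccurrenceModelSpec("habitat", habitat=True),
    ]
    for m in moderators:
        specs.append(OccurrenceModelSpec(f"habitat + {m}", habitat=True, moderator=m))
    for m in moderators:
        specs.append(
            OccurrenceModelSpec(f"habitat x {m}", habitat=True, moderator=m, interaction=True)
        )
    return specs


# ---------------------------------------------------------------------------
# design construction

class OrthoPoly:
    """Orthogonal polynomial basis of a continuous predictor.

    The predictor is standardised, then the raw power basis
    ``[1, z, z^2, ...]`` is orthonormalised by QR on the training data;
    the resulting linear map is stored so new data are projected onto
    exactly the same basis.  Predictions are invariant to the raw-vs-
    orthogonal choice; the orthogonal basis is used for numerical
    stability and so first- and second-order columns are uncorrelated.
    """

    def __init__(self, x: np.ndarray, degree: int = 2):
        x = np.asarray(x, dtype=float)
        self.degree = degree
        self.mean = float(x.mean())
        sd = float(x.std())
        if sd == 0.0:
            raise ValueError("constant predictor has no polynomial basis")
        self.sd = sd
        B = self._raw(x)
        Q, R = np.linalg.qr(B)
        self.map = np.linalg.inv(R)
        # fix signs so each column correlates positively with z**p
        Qs = B @ self.map
        for p in range(1, degree + 1):
            if np.dot(Qs[:, p], (x - self.mean) ** p) < 0:
                self.map[:, p] *= -1.0

    def _raw(self, x):
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        return np.column_stack([z**p for p in range(self.degree + 1)])

    def transform(self, x) -> np.ndarray:
        """Columns for powers 1..degree (the intercept column is dropped)."""
        return (self._raw(x) @ self.map)[:, 1:]


@dataclass
class DesignMatrices:
    """Design matrix, offset and grouping for one occurrence model."""

    X: np.ndarray
    colnames: list
    offset: np.ndarray
    group_codes: np.ndarray
    group_labels: np.ndarray
    spec: OccurrenceModelSpec
    transforms: dict
    data: pd.DataFrame = field(repr=False, default=None)

    def transform(self, new_data: pd.DataFrame) -> np.ndarray:
        """Design matrix for new raw data on the training basis."""
        cols, _ = _assemble_columns(new_data, self.spec, self.transforms)
        return cols


def _assemble_columns(data: pd.DataFrame, spec: OccurrenceModelSpec, transforms: dict):
    n = len(data)
    cols = [np.ones(n)]
    names = ["intercept"]

    t_date = transforms["date"]
    cols.append(((data["date"].to_numpy(float) - t_date[0]) / t_date[1])[:, None])
    names.append("date")

    hab_cols, hab_names = [], []
    if spec.habitat:
        for v in HABITAT_CONTINUOUS:
            P = transforms[v].transform(data[v].to_numpy(float))
            hab_cols.append(P)
            hab_names += [f"{v}^1", f"{v}^2"]
        hab_cols.append(data["river"].to_numpy(float)[:, None])
        hab_names.append("river")
        cols.extend(hab_cols)
        names.extend(hab_names)

    if spec.moderator:
        M = transforms[spec.moderator].transform(data[spec.moderator].to_numpy(float))
        cols.append(M)
        names += [f"{spec.moderator}^1", f"{spec.moderator}^2"]
        if spec.interaction:
            H = np.hstack(hab_cols)
            for q in range(M.shape[1]):
                cols.append(H * M[:, [q]])
                names += [f"{h}:{spec.moderator}^{q + 1}" for h in hab_names]

    X = np.hstack([np.atleast_2d(c.T).T if c.ndim == 1 else c for c in cols])
    return X, names


def build_design(data: pd.DataFrame, spec: OccurrenceModelSpec) -> DesignMatrices:
    """Build the fixed-effect design, offset and site grouping for a model.

    Continuous predictors are standardised and expanded to degree-2
    orthogonal polynomial columns; ``river`` enters as a 0/1 indicator;
    interactions are products of the habitat columns (orders 1 and 2,
    plus river) with the moderator columns (orders 1 and 2).  The offset
    is ``logit_p_detect`` and grouping is ``site_id``.  The matrix is
    checked for full column rank.
    """
    needed = set(spec.variables) | {"site_id", "logit_p_detect"}
    missing = sorted(needed - set(data.columns))
    if missing:
        raise ValueError(f"variables missing from data: {missing}")
    for v in spec.variables:
        vals = data[v].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in {v!r}")

    transforms = {"date": (float(data["date"].mean()), float(data["date"].std() or 1.0))}
    for v in spec.variables:
        if v in ("date", "river"):
            continue
        transforms[v] = OrthoPoly(data[v].to_numpy(float), degree=2)

    X, names = _assemble_columns(data, spec, transforms)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    labels, codes = np.unique(data["site_id"].to_numpy(), return_inverse=True)
    return DesignMatrices(
        X=X,
        colnames=names,
        offset=data["logit_p_detect"].to_numpy(float),
        group_codes=codes,
        group_labels=labels,
        spec=spec,
        transforms=transforms,
        data=data,
    )


# ---------------------------------------------------------------------------
# GLMM fitting: adaptive Gauss-Hermite quadrature, ML

def _log1pexp(x):
    # log(1 + e^x), stable
    return np.logaddexp(0.0, x)


class _AGQLoglik:
    """Marginal log-likelihood of the random-intercept logit model.

    Rows must be sorted by group; the per-site integral over the random
    intercept is evaluated by Gauss-Hermite quadrature after adapting
    (shifting/scaling) the rule to each site's posterior mode and
    curvature, found by Newton iterations on the concave integrand.
    """

    def __init__(self, X, y, codes, offset, n_quad=25):
        order = np.argsort(codes, kind="stable")
        self.X = X[order]
        self.y = y[order].astype(float)
        codes = codes[order]
        self.codes = codes
        self.n_groups = codes.max() + 1
        self.starts = np.searchsorted(codes, np.arange(self.n_groups))
        self.offset = np.zeros(len(y)) if offset is None else offset[order]
        z, wts = np.polynomial.hermite.hermgauss(n_quad)
        self.z = z
        self.logw = np.log(wts) + z**2

    def _group_sum(self, v):
        if v.ndim == 1:
            return np.add.reduceat(v, self.starts)
        return np.add.reduceat(v, self.starts, axis=0)

    def __call__(self, beta, sigma):
        eta0 = self.X @ beta + self.offset
        sig2 = max(sigma, 1e-8) ** 2
        b = getattr(self, "_b_warm", np.zeros(self.n_groups)).copy()
        for _ in range(100):
            eta = eta0 + b[self.codes]
            p = special.expit(eta)
            grad = self._group_sum(self.y - p) - b / sig2
            hess = -(self._group_sum(p * (1.0 - p)) + 1.0 / sig2)
            step = grad / hess
            step = np.clip(step, -4.0, 4.0)
            b = b - step
            if np.max(np.abs(step)) < 1e-10:
                break
        eta = eta0 + b[self.codes]
        p = special.expit(eta)
        hess = self._group_sum(p * (1.0 - p)) + 1.0 / sig2
        tau = 1.0 / np.sqrt(hess)
        self._b_warm = b

        nodes = b[:, None] + np.sqrt(2.0) * tau[:, None] * self.z[None, :]  # (G, K)
        eta_nk = eta0[:, None] + nodes[self.codes, :]
        ll_obs = self.y[:, None] * eta_nk - _log1pexp(eta_nk)
        ll_site = self._group_sum(ll_obs)  # (G, K)
        log_prior = -0.5 * nodes**2 / sig2 - 0.5 * np.log(2.0 * np.pi * sig2)
        integrand = self.logw[None, :] + ll_site + log_prior
        lse = special.logsumexp(integrand, axis=1)
        site_ll = lse + 0.5 * np.log(2.0) + np.log(tau)
        self._cache = (eta0, sig2, nodes, eta_nk, integrand - lse[:, None], b)
        return float(site_ll.sum()), b

    def loglik(self, beta, sigma):
        return self(beta, sigma)[0]

    def loglik_and_grad(self, beta, sigma):
        """Marginal loglik and its score in ``(beta, log sigma)``.

        The score uses Fisher's identity: the gradient of the marginal
        log-likelihood is the posterior expectation of the complete-data
        score, evaluated with the same adapted quadrature rule, so one
        call costs barely more than the objective alone.
        """
        value, _ = self(beta, sigma)
        eta0, sig2, nodes, eta_nk, log_wtilde, _ = self._cache
        wtilde = np.exp(log_wtilde)  # (G, K), rows sum to 1
        resid = self.y[:, None] - special.expit(eta_nk)
        w_obs = wtilde[self.codes, :]
        grad_beta = self.X.T @ (resid * w_obs).sum(axis=1)
        grad_log_sigma = float((wtilde * (nodes**2 / sig2 - 1.0)).sum())
        return value, np.append(grad_beta, grad_log_sigma)


@dataclass
class GLMMFit:
    """A fitted binomial random-intercept occurrence model."""

    spec: Optional[OccurrenceModelSpec]
    colnames: list
    beta: np.ndarray
    sigma_site: float
    loglik: float
    n_params: int          # fixed effects + 1 variance component
    aic: float
    marginal_r2: float
    converged: bool
    n_quad: int = 25
    design: Optional[DesignMatrices] = field(repr=False, default=None)
    ranef_modes: Optional[np.ndarray] = field(repr=False, default=None)
    _vcov: Optional[np.ndarray] = field(repr=False, default=None)
    _loglik_obj: object = field(repr=False, default=None)

    @property
    def coefficients(self) -> pd.Series:
        return pd.Series(self.beta, index=self.colnames)

    def vcov(self) -> np.ndarray:
        """Covariance of the fixed effects (inverse numerical Hessian)."""
        if self._vcov is None:
            theta = np.append(self.beta, np.log(max(self.sigma_site, 1e-6)))
            p = len(self.beta)

            def nll(t):
                return -self._loglik_obj.loglik(t[:p], np.exp(t[p]))

            H = _numerical_hessian(nll, theta, eps=1e-4)
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
            self._vcov = cov[:p, :p]
        return self._vcov


def _numerical_hessian(fun, x, eps=1e-4):
    n = x.size
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                fun(x + ei + ej) - fun(x + ei - ej) - fun(x - ei + ej) + fun(x - ei - ej)
            ) / (4.0 * eps * eps)
    return H


def _glm_start(X, y, offset):
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset).fit(maxiter=50)
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return np.clip(beta, -10.0, 10.0)
    except Exception:
        pass
    return np.zeros(X.shape[1])


def fit_glmm(
    X,
    y,
    groups,
    offset=None,
    n_quad: int = 25,
    colnames=None,
    spec: Optional[OccurrenceModelSpec] = None,
    design: Optional[DesignMatrices] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 3,
    sigma_bounds: tuple = (np.exp(-6.0), np.exp(3.0)),
) -> GLMMFit:
    """ML fit of a binomial logit GLMM with one random intercept.

    Parameters
    ----------
    X : (n, p) ndarray
        Fixed-effect design matrix (include the intercept column).
    y : (n,) array of {0, 1}
        Presence/absence response.
    groups : (n,) array
        Site identifiers (any hashable labels).
    offset : (n,) ndarray, optional
        Known term added to the linear predictor with coefficient 1
        (the logit detectability).
    n_quad : int
        Adaptive Gauss-Hermite nodes for the random-intercept integral.

    Returns
    -------
    GLMMFit
        ``n_params`` counts the fixed effects plus the one variance
        component; ``aic = 2 n_params - 2 loglik``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    if labels.size < 2:
        raise ValueError("need at least 2 sites for a random intercept")
    ll = _AGQLoglik(X, y, codes, None if offset is None else np.asarray(offset, float), n_quad)
    p = X.shape[1]

    def nll(t):
        val, grad = ll.loglik_and_grad(t[:p], np.exp(t[p]))
        if not np.isfinite(val):
            return 1e10, np.zeros_like(t)
        return -val, -grad

    lo, hi = (np.log(b) for b in sigma_bounds)
    bounds = [(None, None)] * p + [(lo, hi)]
    beta0 = _glm_start(X, y, None if offset is None else np.asarray(offset, float))
    t0 = np.append(beta0, np.clip(np.log(0.5), lo, hi))

    rng = np.random.default_rng(0)
    best, converged = None, False
    for attempt in range(1 + n_restarts):
        start = t0 if attempt == 0 else t0 + rng.normal(scale=0.2, size=t0.size)
        res = optimize.minimize(
            nll, start, method="L-BFGS-B", jac=True, bounds=bounds,
            options={"ftol": tol, "gtol": 1e-5, "maxiter": max_iter, "maxcor": 40},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if res.success:
            if res.fun <= best.fun + 1e-3:
                best = res
            converged = True
            break
    if not converged:
        warnings.warn("GLMM fit did not converge; fit retained for diagnostics")

    theta = best.x
    beta = theta[:p]
    sigma = float(np.exp(theta[p]))
    sigma_report = sigma
    loglik, modes = ll(beta, sigma)
    n_params = p + 1
    lp_fixed = X @ beta
    var_fixed = float(np.var(lp_fixed))
    r2m = var_fixed / (var_fixed + sigma_report**2 + np.pi**2 / 3.0)

    names = list(colnames) if colnames is not None else (
        design.colnames if design is not None else [f"x{i}" for i in range(p)]
    )
    return GLMMFit(
        spec=spec if spec is not None else (design.spec if design is not None else None),
        colnames=names,
        beta=beta,
        sigma_site=sigma_report,
        loglik=loglik,
        n_params=n_params,
        aic=2.0 * n_params - 2.0 * loglik,
        marginal_r2=r2m,
        converged=converged,
        n_quad=n_quad,
        design=design,
        ranef_modes=modes,
        _loglik_obj=ll,
    )


def fit_occurrence_model(
    data: pd.DataFrame, spec: OccurrenceModelSpec, n_quad: int = 25, **kw
) -> GLMMFit:
    """Build the design for ``spec`` and fit it (presence ~ spec terms)."""
    design = build_design(data, spec)
    return fit_glmm(
        design.X,
        data["presence"].to_numpy(float),
        design.group_codes,
        offset=design.offset,
        n_quad=n_quad,
        design=design,
        spec=spec,
        **kw,
    )


# ---------------------------------------------------------------------------
# inference on fitted models

def marginal_r2(fit: GLMMFit, design: Optional[DesignMatrices] = None) -> float:
    """Latent-scale marginal R-squared of the fixed effects.

    ``var(X beta) / (var(X beta) + sigma_site^2 + pi^2/3)`` — the
    logit-link variant for binary mixed models.  The offset is excluded
    from the fixed-effect variance; the date term is included.
    """
    X = design.X if design is not None else (fit.design.X if fit.design else None)
    if X is None:
        return fit.marginal_r2
    lp = X @ fit.beta
    v = float(np.var(lp))
    total = v + fit.sigma_site**2 + np.pi**2 / 3.0
    if total == 0.0:
        warnings.warn("zero total variance; marginal R2 set to 0")
        return 0.0
    return v / total


def compare_models(fits) -> pd.DataFrame:
    """AIC comparison table over fitted models, sorted by delta AIC.

    Non-converged fits are excluded with a warning.  Columns: model,
    loglik, n_params, aic, delta_aic, marginal_r2.
    """
    rows = []
    for fit in fits:
        if not fit.converged:
            warnings.warn(
                f"model {fit.spec.name if fit.spec else '?'} not converged; excluded"
            )
            continue
        rows.append(
            {
                "model": fit.spec.name if fit.spec else "(unnamed)",
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "aic": fit.aic,
                "marginal_r2": fit.marginal_r2,
            }
        )
    if len(rows) < 1:
        raise ValueError("no converged fits to compare")
    table = pd.DataFrame(rows).sort_values(["aic", "model"], kind="mergesort").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table[["model", "loglik", "n_params", "delta_aic", "aic", "marginal_r2"]]


class LRTResult:
    """Likelihood-ratio test result: statistic, df, p-value."""

    def __init__(self, statistic, df, pvalue):
        self.statistic = statistic
        self.df = df
        self.pvalue = pvalue

    def __iter__(self):
        return iter((self.statistic, self.df, self.pvalue))

    def __repr__(self):
        return f"LRT(chi2={self.statistic:.3g}, df={self.df}, p={self.pvalue:.3g})"


def likelihood_ratio_test(full: GLMMFit, reduced: GLMMFit) -> LRTResult:
    """Chi-square LR test of a reduced model nested in a full model."""
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    if not set(reduced.colnames) <= set(full.colnames):
        extra = sorted(set(reduced.colnames) - set(full.colnames))
        raise ValueError(f"models are not nested; reduced has extra terms {extra}")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise ValueError("full model has fewer parameters than reduced model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(stat, df, p)


def predict_curves(
    fit: GLMMFit,
    focal: str,
    moderator_values=None,
    n_grid: int = 50,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted occurrence probability along one focal variable.

    All other covariates are held at their observed means (the river
    indicator at its mean prevalence), the offset at the mean logit
    detectability, and the random intercept at zero.  Wald confidence
    intervals are formed on the link scale and back-transformed.  If
    ``moderator_values`` is given (e.g. residence times typifying the
    oldest and newest strata) one curve is returned per value.
    """
    if fit.design is None:
        raise ValueError("fit carries no design; refit via fit_occurrence_model")
    design = fit.design
    data = design.data
    model_vars = list(design.spec.variables)
    if focal not in model_vars:
        raise ValueError(f"{focal!r} is not a variable of this model")

    if focal == "river":
        grid = np.array([0.0, 1.0])
    else:
        x = data[focal].to_numpy(float)
        grid = np.linspace(x.min(), x.max(), n_grid)

    base = {v: [float(data[v].mean())] for v in model_vars}
    base["date"] = [float(data["date"].mean())]
    mod_vals = [None] if moderator_values is None else list(moderator_values)
    if moderator_values is not None and design.spec.moderator is None:
        raise ValueError("model has no moderator to condition on")

    z = stats.norm.ppf(0.5 + level / 2.0)
    off = float(np.mean(design.offset))
    V = fit.vcov()
    frames = []
    for mv in mod_vals:
        new = pd.DataFrame({k: v * len(grid) for k, v in base.items()})
        new[focal] = grid
        if mv is not None:
            new[design.spec.moderator] = mv
        Xg = design.transform(new)
        lp = Xg @ fit.beta + off
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, V, Xg), 0.0))
        frame = pd.DataFrame(
            {
                focal: grid,
                "probability": special.expit(lp),
                "ci_low": special.expit(lp - z * se),
                "ci_high": special.expit(lp + z * se),
            }
        )
        if mv is not None:
            frame.insert(1, design.spec.moderator, mv)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def residual_spatial_check(
    fit: GLMMFit,
    coords: np.ndarray,
    n_bins: int = 8,
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Binned residual spatial autocorrelation with a permutation envelope.

    Pearson residuals of the fitted model (population-level predictions)
    are cross-multiplied within distance bins — a binned Moran's-I
    correlogram — and compared against the 2.5/97.5 percentile envelope
    from randomly permuting residuals over locations (seeded).  Bins
    whose statistic escapes the envelope indicate residual spatial
    structure the site intercept has not absorbed.
    """
    if fit.design is None:
        raise ValueError("fit carries no design")
    coords = np.asarray(coords, dtype=float)
    X, off = fit.design.X, fit.design.offset
    y = fit.design.data["presence"].to_numpy(float)
    p = special.expit(X @ fit.beta + off)
    z = (y - p) / np.sqrt(p * (1.0 - p))
    z = (z - z.mean()) / z.std()

    n = len(z)
    iu, ju = np.triu_indices(n, k=1)
    d = np.hypot(coords[iu, 0] - coords[ju, 0], coords[iu, 1] - coords[ju, 1])
    edges = np.quantile(d, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    bin_idx = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, len(edges) - 2)
    counts = np.bincount(bin_idx, minlength=len(edges) - 1)
    populated = counts > 0
    if populated.sum() < 2:
        raise ValueError("fewer than 2 populated distance bins")

    def binned(zv):
        prod = zv[iu] * zv[ju]
        return np.bincount(bin_idx, weights=prod, minlength=len(counts)) / np.maximum(counts, 1)

    observed = binned(z)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, len(counts)))
    for k in range(n_perm):
        perms[k] = binned(z[rng.permutation(n)])
    lo = np.percentile(perms, 2.5, axis=0)
    hi = np.percentile(perms, 97.5, axis=0)

    out = pd.DataFrame(
        {
            "dist_low": edges[:-1],
            "dist_high": edges[1:],
            "n_pairs": counts,
            "moran": observed,
            "env_low": lo,
            "env_high": hi,
        }
    )
    out["outside"] = (out["moran"] < out["env_low"]) | (out["moran"] > out["env_high"])
    return out.loc[populated].reset_index(drop=True)
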