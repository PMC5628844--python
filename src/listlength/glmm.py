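"""Bernoulli/logit GLMM with a single scalar random intercept, by maximum likelihood.

The model for the reporting rate ``y`` of one species over sampling events
(lists) indexed by county ``i``::

    y ~ Bernoulli(p),   logit(p) = x'beta + b_i,   b_i ~ N(0, sd^2)

where ``x`` holds an intercept plus standardized continuous covariates
(year, log list length, record count, bioclim terms) and the county intercepts
``b_i`` are integrated out of the likelihood.  Because counties are
independent, the marginal likelihood factorises into one one-dimensional
integral per county; each integral is evaluated by adaptive Gauss–Hermite
quadrature centred at the county's conditional mode (1 node = the Laplace
approximation).

The entry point is the statsmodels-style pair :class:`LogisticGLMM` /
:class:`GLMMResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special

__all__ = [
    "standardize",
    "DesignMatrix",
    "LogisticGLMM",
    "GLMMResults",
    "aicc",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
#: below this the estimated random-effect SD is treated as the sd=0 boundary:
#: the marginal likelihood is flat to numerical precision over sd < 1e-3, so
#: the optimizer legitimately stops anywhere in that region
SD_BOUNDARY = 1e-3


def aicc(log_lik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion.

    AICc = -2 log L + 2k + 2k(k+1)/(n-k-1); undefined (raises) when n <= k+1.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * log_lik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def standardize(
    frame: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Center and scale columns to mean 0, SD 1 (SD with the n-1 denominator).

    Returns the transformed frame and ``{column: (mean, sd)}`` so estimates can
    be mapped back to natural units.  A zero-variance column is an error naming
    the column.
    """
    out = frame.copy()
    constants: dict[str, tuple[float, float]] = {}
    for col in columns if columns is not None else list(frame.columns):
        x = out[col].to_numpy(dtype=float)
        mu = float(x.mean())
        sd = float(x.std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"cannot standardize constant column {col!r} (SD = 0)")
        out[col] = (x - mu) / sd
        constants[col] = (mu, sd)
    return out, constants


@dataclass
class DesignMatrix:
    """A fitted-row design: 0/1 response, standardized predictors, group index.

    ``exog`` excludes the intercept (added by the model); ``constants`` maps
    each predictor name to the (mean, sd) used to standardize it.
    """

    endog: np.ndarray
    exog: np.ndarray
    groups: np.ndarray
    exog_names: list[str]
    constants: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.endog = np.asarray(self.endog, dtype=float)
        self.exog = np.asarray(self.exog, dtype=float)
        self.groups = np.asarray(self.groups)
        if self.exog.ndim != 2 or len(self.endog) != self.exog.shape[0]:
            raise ValueError("endog/exog shape mismatch")
        if len(self.groups) != len(self.endog):
            raise ValueError("groups length mismatch")
        if not set(np.unique(self.endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be 0/1")


def _bernoulli_loglike_terms(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    # y*eta - log(1 + exp(eta)), stable for large |eta|
    return y * eta - np.logaddexp(0.0, eta)


class LogisticGLMM:
    """Logistic mixed model with one random intercept per group.

    Parameters
    ----------
    endog : (n,) 0/1 response (species recorded on the list or not).
    exog : (n, p) predictor matrix *without* intercept; columns are expected
        to be standardized (the model does not re-standardize).
    groups : (n,) group labels (counties).
    exog_names : optional predictor names.
    """

    def __init__(self, endog, exog, groups, exog_names: list[str] | None = None):
        endog = np.asarray(endog, dtype=float)
        exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if exog.shape[0] != endog.shape[0]:
            raise ValueError("endog and exog must have the same number of rows")
        groups = np.asarray(groups)
        if groups.shape[0] != endog.shape[0]:
            raise ValueError("groups must align with endog")
        if not set(np.unique(endog)) <= {0.0, 1.0}:
            raise ValueError("endog must be binary 0/1")

        codes, uniques = pd.factorize(groups, sort=True)
        order = np.argsort(codes, kind="stable")
        self.endog = endog[order]
        self.exog = exog[order]
        self._codes = codes[order]
        self.group_labels = list(uniques)
        self.n_groups = len(uniques)
        # reduceat boundaries for per-group sums over the sorted rows
        self._starts = np.searchsorted(self._codes, np.arange(self.n_groups))
        self.nobs = len(self.endog)
        p = self.exog.shape[1]
        if exog_names is None:
            exog_names = [f"x{j}" for j in range(p)]
        if len(exog_names) != p:
            raise ValueError("exog_names length mismatch")
        self.exog_names = list(exog_names)
        self.param_names = ["intercept", *self.exog_names]
        self.k_fe = p + 1  # fixed-effect parameters incl. intercept

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "LogisticGLMM":
        return cls(design.endog, design.exog, design.groups, design.exog_names)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str, terms: list[str], group: str):
        """Build from a tidy per-row table; ``terms`` are predictor columns."""
        return cls(
            data[response].to_numpy(),
            data[list(terms)].to_numpy(dtype=float),
            data[group].to_numpy(),
            exog_names=list(terms),
        )

    # ---------------------------------------------------------------- likelihood

    def _linpred(self, fe_params: np.ndarray) -> np.ndarray:
        fe_params = np.asarray(fe_params, dtype=float)
        if fe_params.shape != (self.k_fe,):
            raise ValueError(f"expected {self.k_fe} fixed-effect parameters")
        return fe_params[0] + self.exog @ fe_params[1:]

    def _group_sum(self, values: np.ndarray) -> np.ndarray:
        return np.add.reduceat(values, self._starts)

    def _conditional_modes(
        self, eta0: np.ndarray, sd: float, tol: float = 1e-12, maxiter: int = 60
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-group mode and curvature of the conditional log joint density.

        Solves, for each group g, max_b sum_i [y eta - log(1+e^eta)] - b^2/(2 sd^2)
        by damped Newton (the objective is strictly concave in b).
        Returns (modes, negative second derivative at the modes).
        """
        inv_var = 1.0 / (sd * sd)
        b = np.zeros(self.n_groups)
        for _ in range(maxiter):
            eta = eta0 + b[self._codes]
            p = special.expit(eta)
            grad = self._group_sum(self.endog - p) - b * inv_var
            hess = -self._group_sum(p * (1.0 - p)) - inv_var
            step = grad / hess
            np.clip(step, -5.0, 5.0, out=step)
            b -= step
            if np.max(np.abs(step)) < tol:
                break
        eta = eta0 + b[self._codes]
        p = special.expit(eta)
        curv = self._group_sum(p * (1.0 - p)) + inv_var
        return b, curv

    def loglike(self, fe_params, re_sd: float, n_nodes: int = 15) -> float:
        """Marginal log-likelihood with the random intercepts integrated out.

        ``n_nodes`` Gauss–Hermite nodes per county, adaptively centred and
        scaled at the county's conditional mode; ``n_nodes=1`` is the Laplace
        approximation.  ``re_sd=0`` reduces exactly to the ordinary logistic
        log-likelihood.
        """
        if re_sd < 0:
            raise ValueError("re_sd must be nonnegative")
        eta0 = self._linpred(fe_params)
        if not np.all(np.isfinite(eta0)):
            raise ValueError("non-finite linear predictor")
        if re_sd == 0.0:
            return float(_bernoulli_loglike_terms(eta0, self.endog).sum())

        modes, curv = self._conditional_modes(eta0, re_sd)
        tau = 1.0 / np.sqrt(curv)  # adaptive scale per group
        z, w = hermgauss(n_nodes)
        # evaluation points: (n_groups, n_nodes)
        b_nodes = modes[:, None] + np.sqrt(2.0) * tau[:, None] * z[None, :]
        eta = eta0[:, None] + b_nodes[self._codes, :]
        row_terms = _bernoulli_loglike_terms(eta, self.endog[:, None])
        cond = np.add.reduceat(row_terms, self._starts, axis=0)  # (G, K)
        log_prior = -0.5 * (b_nodes / re_sd) ** 2 - np.log(re_sd) - _LOG_SQRT_2PI
        # integral_g = sum_k sqrt(2)*tau_g * w_k * exp(z_k^2) * f(b_gk); keep in logs
        log_terms = (
            cond
            + log_prior
            + np.log(w)[None, :]
            + z[None, :] ** 2
            + 0.5 * np.log(2.0)
            + np.log(tau)[:, None]
        )
        return float(special.logsumexp(log_terms, axis=1).sum())

    # ---------------------------------------------------------------- fitting

    def _fit_plain_logistic(self, start: np.ndarray | None = None) -> np.ndarray:
        """ML fit of the fixed effects with the random effect removed (sd=0),
        by full Newton iterations on the Bernoulli log-likelihood."""
        X = np.column_stack([np.ones(self.nobs), self.exog])
        beta = np.zeros(self.k_fe) if start is None else np.asarray(start, dtype=float).copy()
        for _ in range(100):
            eta = X @ beta
            p = special.expit(eta)
            grad = X.T @ (self.endog - p)
            W = p * (1.0 - p)
            hess = (X * W[:, None]).T @ X
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(hess, grad, rcond=None)[0]
            # step halving against overshoot on separable-ish data
            ll0 = _bernoulli_loglike_terms(eta, self.endog).sum()
            scale = 1.0
            for _ in range(30):
                trial = beta + scale * step
                ll1 = _bernoulli_loglike_terms(X @ trial, self.endog).sum()
                if ll1 >= ll0:
                    break
                scale *= 0.5
            beta = beta + scale * step
            if np.max(np.abs(scale * step)) < 1e-12:
                break
        return beta

    def fit(
        self,
        n_nodes: int = 15,
        start: np.ndarray | None = None,
        fix_re_sd: float | None = None,
        gtol: float = 1e-6,
        maxiter: int = 500,
    ) -> "GLMMResults":
        """Maximize the marginal likelihood over (beta, log sd).

        Parameters
        ----------
        n_nodes : adaptive Gauss–Hermite nodes per county (1 = Laplace).
        start : optional starting fixed-effect vector (intercept first).
        fix_re_sd : if given, the random-effect SD is held at this value
            (``0`` collapses the model to ordinary logistic regression).
        gtol : max-norm gradient tolerance for the convergence flag.
        """
        beta0 = self._fit_plain_logistic(start)

        if fix_re_sd is not None and fix_re_sd == 0.0:
            return self._results_fixed_sd0(beta0, gtol)

        if fix_re_sd is not None:
            log_sd0 = np.log(fix_re_sd)

            def negll(beta):
                return -self.loglike(beta, fix_re_sd, n_nodes=n_nodes)

            res = optimize.minimize(
                negll, beta0, method="L-BFGS-B",
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            theta = np.append(res.x, log_sd0)
            free = np.arange(self.k_fe)
        else:

            def negll_full(theta):
                return -self.loglike(theta[:-1], np.exp(theta[-1]), n_nodes=n_nodes)

            theta0 = np.append(beta0, np.log(0.5))
            res = optimize.minimize(
                negll_full, theta0, method="L-BFGS-B",
                bounds=[(None, None)] * self.k_fe + [(-18.0, 5.0)],
                options={"maxiter": maxiter, "ftol": 1e-13, "gtol": 1e-9},
            )
            theta = res.x
            free = np.arange(self.k_fe + 1)

        beta_hat = theta[: self.k_fe]
        sd_hat = float(np.exp(theta[-1]))
        at_boundary = sd_hat < SD_BOUNDARY
        llf = self.loglike(beta_hat, 0.0 if at_boundary else sd_hat, n_nodes=n_nodes)

        grad = self._numgrad(theta, n_nodes, free)
        gnorm = float(np.max(np.abs(grad))) if grad.size else 0.0
        converged = bool(res.success) and (gnorm < max(gtol, 1e-4 * max(1.0, abs(llf))))

        cov, se, hess_ok = self._covariance(theta, n_nodes, free, at_boundary)
        return GLMMResults(
            model=self,
            fe_params=beta_hat,
            re_sd=0.0 if at_boundary else sd_hat,
            bse=se,
            cov_params=cov,
            llf=float(llf),
            converged=converged,
            hessian_ok=hess_ok,
            gradient_norm=gnorm,
            n_iter=int(res.nit),
            n_nodes=n_nodes,
            sd_fixed=fix_re_sd is not None,
        )

    def _results_fixed_sd0(self, beta_hat: np.ndarray, gtol: float) -> "GLMMResults":
        X = np.column_stack([np.ones(self.nobs), self.exog])
        eta = X @ beta_hat
        p = special.expit(eta)
        llf = float(_bernoulli_loglike_terms(eta, self.endog).sum())
        grad = X.T @ (self.endog - p)
        hess = (X * (p * (1 - p))[:, None]).T @ X
        try:
            cov = np.linalg.inv(hess)
            se = np.sqrt(np.diag(cov))
            hess_ok = True
        except np.linalg.LinAlgError:
            cov = np.full((self.k_fe, self.k_fe), np.nan)
            se = np.full(self.k_fe, np.nan)
            hess_ok = False
        return GLMMResults(
            model=self,
            fe_params=beta_hat,
            re_sd=0.0,
            bse=se,
            cov_params=cov,
            llf=llf,
            converged=bool(np.max(np.abs(grad)) < max(gtol, 1e-6 * self.nobs)),
            hessian_ok=hess_ok,
            gradient_norm=float(np.max(np.abs(grad))),
            n_iter=0,
            n_nodes=0,
            sd_fixed=True,
        )

    def _negll_theta(self, theta: np.ndarray, n_nodes: int) -> float:
        return -self.loglike(theta[: self.k_fe], float(np.exp(theta[-1])), n_nodes=n_nodes)

    def _numgrad(self, theta: np.ndarray, n_nodes: int, free: np.ndarray) -> np.ndarray:
        g = np.zeros(free.size)
        for idx, j in enumerate(free):
            h = 1e-6 * max(1.0, abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            g[idx] = (self._negll_theta(tp, n_nodes) - self._negll_theta(tm, n_nodes)) / (2 * h)
        return g

    def _covariance(self, theta, n_nodes, free, at_boundary):
        """SEs from the inverse negative Hessian of the marginal log-likelihood
        (central finite differences over the free parameters)."""
        if at_boundary:
            # variance hit the boundary: condition on sd -> 0 for the SEs
            beta = theta[: self.k_fe]
            return self._results_fixed_sd0(beta, 1e-6).cov_params, \
                self._results_fixed_sd0(beta, 1e-6).bse, True
        m = free.size
        H = np.zeros((m, m))
        h = np.array([1e-4 * max(1.0, abs(theta[j])) for j in free])
        f0 = self._negll_theta(theta, n_nodes)
        for a in range(m):
            for b in range(a, m):
                ja, jb = free[a], free[b]
                if a == b:
                    tp, tm = theta.copy(), theta.copy()
                    tp[ja] += h[a]
                    tm[ja] -= h[a]
                    H[a, a] = (
                        self._negll_theta(tp, n_nodes)
                        - 2 * f0
                        + self._negll_theta(tm, n_nodes)
                    ) / h[a] ** 2
                else:
                    tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                    tpp[ja] += h[a]; tpp[jb] += h[b]
                    tpm[ja] += h[a]; tpm[jb] -= h[b]
                    tmp[ja] -= h[a]; tmp[jb] += h[b]
                    tmm[ja] -= h[a]; tmm[jb] -= h[b]
                    H[a, b] = H[b, a] = (
                        self._negll_theta(tpp, n_nodes)
                        - self._negll_theta(tpm, n_nodes)
                        - self._negll_theta(tmp, n_nodes)
                        + self._negll_theta(tmm, n_nodes)
                    ) / (4 * h[a] * h[b])
        try:
            np.linalg.cholesky(H)
            cov_free = np.linalg.inv(H)
            se = np.sqrt(np.diag(cov_free)[: self.k_fe])
            return cov_free, se, True
        except np.linalg.LinAlgError:
            warnings.warn("marginal-likelihood Hessian not positive definite; SEs unreliable")
            return np.full((m, m), np.nan), np.full(self.k_fe, np.nan), False


@dataclass
class GLMMResults:
    """Fit of :class:`LogisticGLMM`: estimates, SEs, likelihood, AICc."""

    model: LogisticGLMM
    fe_params: np.ndarray
    re_sd: float
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    converged: bool
    hessian_ok: bool
    gradient_norm: float
    n_iter: int
    n_nodes: int
    sd_fixed: bool = False

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k_params(self) -> int:
        """Fixed effects (incl. intercept) plus one random-effect variance."""
        return self.model.k_fe + (0 if self.sd_fixed else 1)

    @property
    def aicc(self) -> float:
        return aicc(self.llf, self.k_params, self.nobs)

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fe_params, index=self.model.param_names)

    @property
    def bse_series(self) -> pd.Series:
        return pd.Series(self.bse, index=self.model.param_names)

    def conf_int(self, z: float = 1.959963984540054) -> pd.DataFrame:
        lo = self.fe_params - z * self.bse
        hi = self.fe_params + z * self.bse
        return pd.DataFrame({"low": lo, "high": hi}, index=self.model.param_names)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Logistic GLMM (random intercept), maximum likelihood",
            f"n_obs = {self.nobs}   groups = {self.model.n_groups}   "
            f"k = {self.k_params}   logLik = {self.llf:.4f}   AICc = {self.aicc:.4f}",
            f"random-effect SD = {self.re_sd:.4f}   converged = {self.converged}",
            f"{'term':<12}{'estimate':>10}{'SE':>10}{'ci_low':>10}{'ci_high':>10}",
        ]
        for name, est, se in zip(self.model.param_names, self.fe_params, self.bse):
            lines.append(
                f"{name:<12}{est:>10.4f}{se:>10.4f}{ci.loc[name, 'low']:>10.4f}"
                f"{ci.loc[name, 'high']:>10.4f}"
            )
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """One row per term, plus model-level columns (for CSV export)."""
        ci = self.conf_int()
        df = pd.DataFrame(
            {
                "term": self.model.param_names,
                "estimate": self.fe_params,
                "se": self.bse,
                "ci_low": ci["low"].to_numpy(),
                "ci_high": ci["high"].to_numpy(),
            }
        )
        df["re_sd"] = self.re_sd
        df["n"] = self.nobs
        df["k"] = self.k_params
        df["logLik"] = self.llf
        df["aicc"] = self.aicc
        df["converged"] = self.converged
        return df
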