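"""Mate-choice and pup-survival regression models.

Statsmodels-style interface: :class:`LogisticModel` and
:class:`MixedLogisticModel` are built from data and their ``fit()`` returns a
:class:`LogisticResults` carrying estimates, standard errors, asymptotic Wald
p-values, log-likelihood and AIC, with a ``summary()`` table.  The mixed
model is a logistic regression with a Gaussian random intercept per group,
fitted by adaptive Gauss-Hermite quadrature.  Covariates are standardized
(z-transformation, n-1 denominator) so coefficients are comparable across
covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

__all__ = [
    "SeparationError",
    "LogisticResults",
    "LogisticModel",
    "MixedLogisticModel",
    "z_transform",
    "fit_logistic",
    "fit_mixed_logistic",
    "mate_choice_analysis",
    "pup_survival_analysis",
    "two_sample_t",
]


class SeparationError(RuntimeError):
    """Raised when a logistic fit is degenerate (constant or separable response)."""


def z_transform(X, names: list | None = None):
    """Standardize columns to mean 0, SD 1 (sample SD, n-1 denominator).

    Returns (standardized array or DataFrame, {name: (mean, sd)}).  A column
    with zero SD raises, since its coefficient would be unidentifiable.
    """
    is_frame = isinstance(X, pd.DataFrame)
    arr = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if names is None:
        names = list(X.columns) if is_frame else [f"x{i}" for i in range(arr.shape[1])]
    params = {}
    out = np.empty_like(arr)
    for j, name in enumerate(names):
        m, s = arr[:, j].mean(), arr[:, j].std(ddof=1)
        if s == 0 or not np.isfinite(s):
            raise ValueError(f"degenerate covariate {name!r}: zero standard deviation")
        out[:, j] = (arr[:, j] - m) / s
        params[name] = (float(m), float(s))
    if is_frame:
        out = pd.DataFrame(out, columns=names, index=X.index)
    return out, params


@dataclass
class LogisticResults:
    """Fit results shared by the fixed and mixed logistic models."""

    label: str
    names: list
    params: np.ndarray
    bse: np.ndarray
    llf: float
    nobs: int
    k_params: int
    re_sd: float | None = None
    re_group: str | None = None
    converged: bool = True
    diagnostics: dict = field(default_factory=dict)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues))

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame({
            "coef": self.params,
            "se": self.bse,
            "z": self.zvalues,
            "P>|z|": self.pvalues,
        }, index=self.names)
        return tab

    def __str__(self) -> str:
        head = (f"{self.label}: n={self.nobs}, llf={self.llf:.3f}, "
                f"AIC={self.aic:.2f}, params={self.k_params}")
        if self.re_sd is not None:
            head += f", RE({self.re_group}) SD={self.re_sd:.3f}"
        return head + "\n" + self.summary().to_string(float_format="%.4f")


def _design(X, names, add_intercept):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["intercept"] + names
    return X, names


class LogisticModel:
    """Binary-response logistic regression (maximum likelihood).

    ``y`` is 0/1; an intercept column is prepended unless ``add_intercept``
    is False.  Perfect separation and constant responses are rejected.
    """

    def __init__(self, y, X, names: list | None = None, add_intercept: bool = True,
                 label: str = "logit"):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X, self.names = _design(X, names, add_intercept)
        self.label = label
        if self.y.size <= self.X.shape[1]:
            raise ValueError("need more observations than parameters")
        if self.y.min() == self.y.max():
            raise SeparationError("response is constant")

    def fit(self) -> LogisticResults:
        import warnings

        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(self.y, self.X).fit(disp=0, method="newton", maxiter=200)
        except Exception as exc:  # statsmodels raises/warns on perfect separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc
        mu = res.predict()
        if np.all((mu < 1e-8) | (mu > 1 - 1e-8)) or np.abs(res.params).max() > 1e3:
            raise SeparationError("perfect separation detected")
        return LogisticResults(
            label=self.label, names=self.names,
            params=np.asarray(res.params), bse=np.asarray(res.bse),
            llf=float(res.llf), nobs=int(self.y.size),
            k_params=self.X.shape[1], converged=bool(res.mle_retvals["converged"]),
        )


def fit_logistic(y, X, names: list | None = None, add_intercept: bool = True,
                 label: str = "logit") -> LogisticResults:
    return LogisticModel(y, X, names, add_intercept, label).fit()


def _sigmoid(x):
    return special.expit(x)


class MixedLogisticModel:
    """Logistic regression with a Gaussian random intercept per group.

    The marginal likelihood integrates the random intercept out by adaptive
    Gauss-Hermite quadrature (default 21 nodes, centered and scaled at each
    group's conditional mode).  Parameters are (fixed coefficients, log SD of
    the random intercept), maximized with L-BFGS-B; standard errors come from
    the numerical Hessian at the optimum.
    """

    def __init__(self, y, X, groups, names: list | None = None,
                 add_intercept: bool = True, n_nodes: int = 21,
                 label: str = "mixed logit"):
        self.y = np.asarray(y, dtype=float).ravel()
        self.X, self.names = _design(X, names, add_intercept)
        codes, uniq = pd.factorize(np.asarray(groups))
        if len(uniq) < 2:
            raise ValueError("need >= 2 groups for a random intercept")
        self.group_idx = codes
        self.n_groups = len(uniq)
        self.n_nodes = int(n_nodes)
        self.gh_x, self.gh_w = np.polynomial.hermite.hermgauss(self.n_nodes)
        self.label = label
        if self.y.min() == self.y.max():
            raise SeparationError("response is constant")

    # ---- marginal log-likelihood by adaptive Gauss-Hermite quadrature ----
    def loglike(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma = np.exp(log_sigma)
        eta = self.X @ beta
        gi, nG = self.group_idx, self.n_groups

        # conditional mode of each group's random intercept (Newton)
        b = np.zeros(nG)
        for _ in range(50):
            mu = _sigmoid(eta + b[gi])
            g1 = np.bincount(gi, weights=self.y - mu, minlength=nG) - b / sigma**2
            g2 = -np.bincount(gi, weights=mu * (1 - mu), minlength=nG) - 1.0 / sigma**2
            step = g1 / g2
            b -= step
            if np.max(np.abs(step)) < 1e-10:
                break
        mu = _sigmoid(eta + b[gi])
        curv = np.bincount(gi, weights=mu * (1 - mu), minlength=nG) + 1.0 / sigma**2
        tau = 1.0 / np.sqrt(curv)

        # nodes b_jq = b_j + sqrt(2) tau_j x_q
        terms = np.empty((nG, self.n_nodes))
        for q in range(self.n_nodes):
            bq = b + np.sqrt(2.0) * tau * self.gh_x[q]
            etaq = eta + bq[gi]
            # Bernoulli log-likelihood summed within group, numerically safe
            ll_i = self.y * etaq - np.logaddexp(0.0, etaq)
            ll_g = np.bincount(gi, weights=ll_i, minlength=nG)
            log_phi = -0.5 * np.log(2 * np.pi) - log_sigma - 0.5 * (bq / sigma) ** 2
            terms[:, q] = np.log(self.gh_w[q]) + self.gh_x[q] ** 2 + ll_g + log_phi
        ll_groups = 0.5 * np.log(2.0) + np.log(tau) + special.logsumexp(terms, axis=1)
        return float(ll_groups.sum())

    def _neg_loglike(self, params):
        return -self.loglike(params)

    def fit(self, start_params: np.ndarray | None = None) -> LogisticResults:
        p = self.X.shape[1]
        if start_params is None:
            try:
                start_beta = fit_logistic(self.y, self.X, self.names,
                                          add_intercept=False).params
            except SeparationError:
                start_beta = np.zeros(p)
            start_params = np.append(start_beta, np.log(0.5))
        bounds = [(None, None)] * p + [(np.log(1e-6), np.log(1e3))]
        res = optimize.minimize(self._neg_loglike, start_params, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        params = res.x
        llf = -res.fun
        H = self._numerical_hessian(params)
        try:
            cov = np.linalg.pinv(H)
            bse_all = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            bse_all = np.full(p + 1, np.nan)
        sigma = float(np.exp(params[-1]))
        return LogisticResults(
            label=self.label, names=self.names,
            params=params[:p], bse=bse_all[:p], llf=llf,
            nobs=int(self.y.size), k_params=p + 1,
            re_sd=sigma, re_group="group", converged=bool(res.success),
            diagnostics={"message": str(res.message), "n_groups": self.n_groups,
                         "n_nodes": self.n_nodes},
        )

    def _numerical_hessian(self, params: np.ndarray, h: float = 1e-4) -> np.ndarray:
        n = len(params)
        H = np.empty((n, n))
        f = self._neg_loglike
        for i in range(n):
            for j in range(i, n):
                ei, ej = np.zeros(n), np.zeros(n)
                ei[i], ej[j] = h, h
                H[i, j] = H[j, i] = (
                    f(params + ei + ej) - f(params + ei - ej)
                    - f(params - ei + ej) + f(params - ei - ej)
                ) / (4 * h * h)
        return H


def fit_mixed_logistic(y, X, groups, names: list | None = None,
                       add_intercept: bool = True, n_nodes: int = 21,
                       label: str = "mixed logit") -> LogisticResults:
    return MixedLogisticModel(y, X, groups, names, add_intercept, n_nodes, label).fit()


def mate_choice_analysis(pair_table: pd.DataFrame, reference_mean: float,
                         female_col: str = "female_ho", male_col: str = "male_ho",
                         pair_col: str = "pair_id") -> dict:
    """Do low-diversity females pick high-diversity mates?

    The response is whether the male's observed heterozygosity exceeds the
    reference-pool mean; the predictor is the female's continuous H_o.  Fits
    the fixed logistic, a pair-random-intercept variant, and the
    intercept-only null; reports AIC differences (model minus null).
    """
    if len(pair_table) < 10:
        raise ValueError("need >= 10 pair-years for the mate-choice model")
    y = (pair_table[male_col].to_numpy(float) > reference_mean).astype(int)
    if y.min() == y.max():
        raise SeparationError("all males on one side of the reference mean")
    x = pair_table[female_col].to_numpy(float)
    if x.std(ddof=1) == 0:
        raise ValueError("degenerate covariate: constant female heterozygosity")
    fixed = fit_logistic(y, x, ["female_ho"], label="mate choice (fixed)")
    null = fit_logistic(y, np.empty((len(y), 0)), [], label="mate choice (null)")
    out = {"fixed": fixed, "null": null,
           "delta_aic_fixed_vs_null": fixed.aic - null.aic}
    groups = pair_table[pair_col].to_numpy()
    if len(pd.unique(groups)) >= 2:
        mixed = fit_mixed_logistic(y, x, groups, ["female_ho"],
                                   label="mate choice (mixed)")
        out["mixed"] = mixed
        out["delta_aic_mixed_vs_null"] = mixed.aic - null.aic
    return out


def pup_survival_analysis(table: pd.DataFrame, covariates: list | None = None,
                          response: str = "alive", pair_col: str = "pair_id") -> dict:
    """Fixed and pair-random-intercept logistic models of pup survival.

    Covariates are z-scored before fitting; returns both fits, the
    intercept-only null, and AIC comparisons (fixed vs null, mixed vs fixed).
    """
    if covariates is None:
        covariates = ["harvest_rate", "n_adults", "pair_ho", "density", "years_paired"]
    if len(table) < 30:
        raise ValueError("need >= 30 pup records")
    y = table[response].to_numpy(int)
    Z, zparams = z_transform(table[covariates])
    fixed = fit_logistic(y, Z.to_numpy(), covariates, label="pup survival (fixed)")
    mixed = fit_mixed_logistic(y, Z.to_numpy(), table[pair_col].to_numpy(),
                               covariates, label="pup survival (mixed)")
    null = fit_logistic(y, np.empty((len(y), 0)), [], label="pup survival (null)")
    return {
        "fixed": fixed, "mixed": mixed, "null": null, "z_params": zparams,
        "delta_aic_fixed_vs_null": fixed.aic - null.aic,
        "delta_aic_mixed_vs_null": mixed.aic - null.aic,
        "delta_aic_mixed_vs_fixed": mixed.aic - fixed.aic,
    }


def two_sample_t(x1, x2, variant: str = "welch") -> tuple[float, float, float]:
    """Two-sample t-test; Welch (default) or pooled variance.  Returns (t, df, p)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("need >= 2 observations per sample")
    v1, v2 = x1.var(ddof=1), x2.var(ddof=1)
    if v1 == 0 and v2 == 0:
        raise ValueError("t undefined: zero variance in both samples")
    n1, n2 = x1.size, x2.size
    diff = x1.mean() - x2.mean()
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        t = diff / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError("variant must be 'welch' or 'pooled'")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)
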