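"""Random-slope linear mixed-effects regression of aortic growth.

The cohort model is

    GR_im = beta0 + beta1 * x_im + b0_m + b1_m * x_im + eps_im

for region i of patient m, with independent patient-level random
intercepts b0_m ~ N(0, sd_b0^2) and slopes b1_m ~ N(0, sd_b1^2) and
residual eps_im ~ N(0, sd_eps^2).  The predictor x is region-averaged
maximum-principal stress (kPa) in the primary analysis and WSS,
pressure, or a thrombus indicator in the companion models; optional
fixed-effect terms (a quadratic in x, a follow-up-time covariate) extend
the mean model without changing the random-effects structure.

Estimation is direct maximum likelihood: the fixed effects are profiled
out by GLS and the marginal likelihood is optimized over the log
standard deviations, which enforces positivity and surfaces boundary
(SD -> 0) solutions explicitly.  Confidence intervals for the SDs are
profile-likelihood intervals (they are asymmetric, as variance-component
intervals should be); the fixed-slope test is a Wald-type F-test with
Satterthwaite denominator degrees of freedom by default (residual df is
available for compatibility with common commercial implementations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.linalg import cho_factor, cho_solve

__all__ = ["GrowthLME", "GrowthLMEResults", "ftest_fixed_slope"]

_LOG2PI = np.log(2.0 * np.pi)
_CHI2_95 = sps.chi2.ppf(0.95, 1)          # 3.841; profile-CI threshold /2


class GrowthLME:
    """Random intercept + random slope mixed model (diagonal covariance).

    Parameters
    ----------
    y : (n,) response (growth rate, %/year, or stress for the
        thrombus-stress model).
    X : (n, p) fixed-effects design; column 0 must be the intercept and
        column 1 the predictor that also carries the random slope.
    groups : (n,) patient labels.
    fe_names : fixed-effect column names.
    """

    def __init__(self, y, X, groups, fe_names=None):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        groups = np.asarray(groups)
        if self.X.ndim != 2 or len(self.X) != len(self.y) or len(groups) != len(self.y):
            raise ValueError("y, X and groups must align")
        self.fe_names = list(fe_names) if fe_names is not None else \
            [f"x{j}" for j in range(self.X.shape[1])]
        labels, inv = np.unique(groups, return_inverse=True)
        if len(labels) < 2:
            raise ValueError("need at least two patients")
        if len(np.unique(self.X[:, 1])) < 2:
            raise ValueError("predictor must take at least two distinct values")
        self.group_labels = labels
        self._idx = [np.where(inv == g)[0] for g in range(len(labels))]
        self._Z = [np.column_stack([np.ones(len(ix)), self.X[ix, 1]])
                   for ix in self._idx]

    # -- constructors -------------------------------------------------

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame,
                       predictor: str = "stress_kpa",
                       response: str = "growth_pct_per_year",
                       groups: str = "patient_id",
                       quadratic: bool = False,
                       extra_covariates: tuple[str, ...] = ()) -> "GrowthLME":
        """Build the model from a pooled region table.

        Rows with missing values in any used column are dropped
        (listwise deletion within the fit)."""
        cols = [response, predictor, groups, *extra_covariates]
        sub = table[cols].dropna()
        names = ["intercept", predictor]
        X = [np.ones(len(sub)), sub[predictor].to_numpy(dtype=float)]
        if quadratic:
            X.append(sub[predictor].to_numpy(dtype=float) ** 2)
            names.append(f"{predictor}^2")
        for c in extra_covariates:
            X.append(sub[c].to_numpy(dtype=float))
            names.append(c)
        return cls(sub[response].to_numpy(dtype=float), np.column_stack(X),
                   sub[groups].to_numpy(), fe_names=names)

    # -- likelihood ---------------------------------------------------

    def _scales(self) -> tuple[float, float]:
        sy = float(np.std(self.y)) or 1.0
        sx = float(np.std(self.X[:, 1])) or 1.0
        return sy, sx

    def _nll_parts(self, theta):
        """(nll, beta, cov_beta, cho factors) at theta = log SDs."""
        sd0, sd1, sde = np.exp(theta)
        p = self.X.shape[1]
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        chos = []
        for ix, Z in zip(self._idx, self._Z):
            V = (sd0 ** 2) * np.outer(Z[:, 0], Z[:, 0]) \
                + (sd1 ** 2) * np.outer(Z[:, 1], Z[:, 1]) \
                + (sde ** 2) * np.eye(len(ix))
            c = cho_factor(V, lower=True)
            chos.append(c)
            logdet += 2.0 * np.sum(np.log(np.diag(c[0])))
            Xg = self.X[ix]
            ViX = cho_solve(c, Xg)
            XtVX += Xg.T @ ViX
            XtVy += ViX.T @ self.y[ix]
        cov = np.linalg.inv(XtVX)
        beta = cov @ XtVy
        quad = 0.0
        for ix, c in zip(self._idx, chos):
            r = self.y[ix] - self.X[ix] @ beta
            quad += r @ cho_solve(c, r)
        nll = 0.5 * (logdet + quad + len(self.y) * _LOG2PI)
        return nll, beta, cov, chos

    def _nll(self, theta) -> float:
        try:
            return self._nll_parts(theta)[0]
        except np.linalg.LinAlgError:
            return 1e12

    def _bounds(self):
        sy, sx = self._scales()
        lo0, hi0 = np.log(sy * 1e-8), np.log(sy * 1e3)
        lo1, hi1 = np.log(sy / sx * 1e-8), np.log(sy / sx * 1e3)
        return [(lo0, hi0), (lo1, hi1), (lo0, hi0)]

    def _start(self):
        """Moment start: per-patient OLS intercept/slope spread."""
        sy, sx = self._scales()
        ints, slopes, resid = [], [], []
        for ix in self._idx:
            x, yy = self.X[ix, 1], self.y[ix]
            if len(ix) >= 3 and np.ptp(x) > 0:
                b, a = np.polyfit(x, yy, 1)
                ints.append(a)
                slopes.append(b)
                resid.extend(yy - (a + b * x))
        sd0 = np.std(ints) if len(ints) > 1 else 0.5 * sy
        sd1 = np.std(slopes) if len(slopes) > 1 else 0.5 * sy / sx
        sde = np.std(resid) if resid else 0.5 * sy
        floor0 = 1e-3 * sy
        floor1 = 1e-3 * sy / sx
        return np.log([max(sd0, floor0), max(sd1, floor1), max(sde, floor0)])

    def fit(self, method: str = "L-BFGS-B") -> "GrowthLMEResults":
        """Maximize the marginal likelihood over the log SDs."""
        bounds = self._bounds()
        res = optimize.minimize(self._nll, self._start(), method=method,
                                bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12})
        if not np.isfinite(res.fun):
            raise RuntimeError(f"mixed-model fit did not converge: {res.message}")
        theta = res.x
        nll, beta, cov, chos = self._nll_parts(theta)
        sd0, sd1, sde = np.exp(theta)
        sy, sx = self._scales()
        boundary = {
            "sd_b0": sd0 < 1e-6 * sy,
            "sd_b1": sd1 < 1e-6 * sy / sx,
            "sd_eps": sde < 1e-6 * sy,
        }
        # BLUPs: b_m = D Z' V^-1 r_m
        D = np.diag([sd0 ** 2, sd1 ** 2])
        blups = []
        for ix, Z, c in zip(self._idx, self._Z, chos):
            r = self.y[ix] - self.X[ix] @ beta
            blups.append(D @ Z.T @ cho_solve(c, r))
        blups = pd.DataFrame(np.array(blups), columns=["b0", "b1"],
                             index=self.group_labels)
        return GrowthLMEResults(
            model=self, fe_params=pd.Series(beta, index=self.fe_names),
            cov_fe=cov, sd_b0=sd0, sd_b1=sd1, sd_eps=sde,
            llf=-nll, theta=theta, blups=blups, boundary=boundary,
            converged=bool(res.success),
        )


@dataclass
class GrowthLMEResults:
    """Fitted mixed model: estimates, uncertainties, diagnostics."""

    model: GrowthLME
    fe_params: pd.Series
    cov_fe: np.ndarray
    sd_b0: float
    sd_b1: float
    sd_eps: float
    llf: float
    theta: np.ndarray
    blups: pd.DataFrame
    boundary: dict
    converged: bool
    _satt_cache: dict = field(default_factory=dict, repr=False)

    # -- information criteria -----------------------------------------

    @property
    def n_obs(self) -> int:
        return len(self.model.y)

    @property
    def k_params(self) -> int:
        return len(self.fe_params) + 3      # fixed effects + 3 SDs

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.n_obs)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_fe)), index=self.fe_params.index)

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.fe_params) - 2 * len(self.model.group_labels)

    # -- degrees of freedom -------------------------------------------

    def satterthwaite_df(self, param: int = 1) -> float:
        """Satterthwaite denominator df for one fixed effect.

        df = 2 c^2 / Var(c) with c = Var(beta_j) as a function of the
        variance parameters; Var(theta-hat) from the observed
        information.  Falls back to the residual df when the information
        matrix is unusable (boundary estimates)."""
        if param in self._satt_cache:
            return self._satt_cache[param]
        m = self.model
        h = 1e-4

        def cjj(th):
            return m._nll_parts(th)[2][param, param]

        try:
            g = optimize.approx_fprime(self.theta, cjj, h)
            H = np.zeros((3, 3))
            f0 = m._nll(self.theta)
            for i in range(3):
                for j in range(i, 3):
                    ei = np.eye(3)[i] * h
                    ej = np.eye(3)[j] * h
                    H[i, j] = H[j, i] = (
                        m._nll(self.theta + ei + ej) - m._nll(self.theta + ei)
                        - m._nll(self.theta + ej) + f0) / h ** 2
            cov_theta = np.linalg.inv(H)
            var_c = float(g @ cov_theta @ g)
            c = cjj(self.theta)
            df = 2.0 * c ** 2 / var_c if var_c > 0 else float(self.df_resid)
        except np.linalg.LinAlgError:
            df = float(self.df_resid)
        df = float(np.clip(df, 1.0, self.df_resid))
        self._satt_cache[param] = df
        return df

    # -- inference ----------------------------------------------------

    def conf_int(self, alpha: float = 0.05, ddf: str = "satterthwaite") -> pd.DataFrame:
        """Wald-type CIs for the fixed effects (t quantiles)."""
        if ddf == "satterthwaite":
            dfs = [self.satterthwaite_df(j) for j in range(len(self.fe_params))]
        elif ddf == "residual":
            dfs = [self.df_resid] * len(self.fe_params)
        elif ddf == "normal":
            dfs = None
        else:
            raise ValueError(f"unknown ddf {ddf!r}")
        se = self.bse.to_numpy()
        if dfs is None:
            q = sps.norm.ppf(1 - alpha / 2) * np.ones(len(se))
        else:
            q = np.array([sps.t.ppf(1 - alpha / 2, d) for d in dfs])
        lo = self.fe_params.to_numpy() - q * se
        hi = self.fe_params.to_numpy() + q * se
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.fe_params.index)

    def f_test_slope(self, param: int = 1, ddf: str = "satterthwaite") -> tuple[float, float]:
        """F-test of the fixed slope against zero: F = (beta/SE)^2.

        Denominator df from Satterthwaite (default) or the residual df
        (n - p - 2 * n_groups)."""
        se = float(self.bse.iloc[param])
        if se == 0:
            raise ValueError("zero standard error")
        F = float(self.fe_params.iloc[param] / se) ** 2
        df2 = self.satterthwaite_df(param) if ddf == "satterthwaite" else self.df_resid
        p = float(sps.f.sf(F, 1, df2))
        return F, p

    # -- profile CIs for the random-effect SDs ------------------------

    def sd_profile_ci(self, which: str, alpha: float = 0.05) -> tuple[float, float]:
        """Profile-likelihood CI for one SD ('b0', 'b1' or 'eps').

        The bound solves 2*(nll_profile(sd) - nll_min) = chi2_{1,1-a};
        a lower bound that runs into 0 is reported as 0 (boundary)."""
        k = {"b0": 0, "b1": 1, "eps": 2}[which]
        m = self.model
        nll_min = -self.llf
        target = nll_min + 0.5 * sps.chi2.ppf(1 - alpha, 1)
        bounds = m._bounds()
        others = [i for i in range(3) if i != k]

        def profile(log_sd: float) -> float:
            def obj(t2):
                th = np.empty(3)
                th[k] = log_sd
                th[others[0]], th[others[1]] = t2
                return m._nll(th)
            r = optimize.minimize(obj, self.theta[others], method="L-BFGS-B",
                                  bounds=[bounds[i] for i in others],
                                  options={"maxiter": 200})
            return r.fun

        th_hat = self.theta[k]

        def g(v):
            return profile(v) - target

        # upper bound
        step = 0.25
        hi = th_hat + step
        while g(hi) < 0 and hi < bounds[k][1]:
            hi += step
        upper = np.exp(optimize.brentq(g, th_hat, hi, xtol=1e-4)) \
            if g(hi) >= 0 else np.inf
        # lower bound
        lo = th_hat - step
        while g(lo) < 0 and lo > bounds[k][0] + 1e-9:
            lo -= step
        lower = np.exp(optimize.brentq(g, lo, th_hat, xtol=1e-4)) \
            if g(lo) >= 0 else 0.0
        return float(lower), float(upper)

    # -- companions ----------------------------------------------------

    def plot(self, ax=None, xlabel: str | None = None,
             ylabel: str = "growth rate (%/year)"):
        """Pooled scatter with per-patient regression lines.

        Points are colored by patient; thin lines show each patient's
        fixed + BLUP prediction, the heavy line the fixed effect alone.
        Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        m = self.model
        x = m.X[:, 1]
        beta = self.fe_params.to_numpy()
        cmap = plt.get_cmap("tab10")
        for k, (label, ix) in enumerate(zip(m.group_labels, m._idx)):
            color = cmap(k % 10)
            ax.scatter(x[ix], m.y[ix], s=12, alpha=0.6, color=color,
                       label=str(label))
            xs = np.linspace(x[ix].min(), x[ix].max(), 20)
            b0, b1 = self.blups.loc[label]
            ax.plot(xs, (beta[0] + b0) + (beta[1] + b1) * xs,
                    color=color, lw=0.8, alpha=0.8)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, beta[0] + beta[1] * xs, color="black", lw=2.2,
                label="fixed effect")
        ax.set_xlabel(xlabel or self.fe_params.index[1])
        ax.set_ylabel(ylabel)
        ax.legend(fontsize=7, ncol=2)
        return ax

    def ols_comparison(self):
        """Fixed-effects-only fit of the same mean model (statsmodels OLS)."""
        import statsmodels.api as sm

        return sm.OLS(self.model.y, self.model.X).fit()

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-slope linear mixed model (ML)",
            f"  groups: {len(self.model.group_labels)}   obs: {self.n_obs}"
            f"   logLik: {self.llf:.1f}   AIC: {self.aic:.1f}   BIC: {self.bic:.1f}",
            "  fixed effects                est        SE        95% CI",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"    {name:<22s} {self.fe_params[name]:>9.4g} "
                f"{self.bse[name]:>9.3g}  [{ci.loc[name, 'lower']:.4g}, "
                f"{ci.loc[name, 'upper']:.4g}]")
        F, p = self.f_test_slope()
        lines.append(f"  F-test (slope = 0): F = {F:.3f}, p = {p:.4g} "
                     f"(Satterthwaite df = {self.satterthwaite_df():.1f})")
        for nm, v in (("sd(b0)", self.sd_b0), ("sd(b1)", self.sd_b1),
                      ("sd(eps)", self.sd_eps)):
            flag = "  [boundary]" if self.boundary.get(
                nm.replace("sd(", "sd_").replace(")", "")) else ""
            lines.append(f"  {nm:<10s} {v:.4g}{flag}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        F, p = self.f_test_slope()
        return {
            "fe_params": self.fe_params.to_dict(),
            "fe_ci": {k: [float(ci.loc[k, "lower"]), float(ci.loc[k, "upper"])]
                      for k in self.fe_params.index},
            "sd_b0": self.sd_b0, "sd_b1": self.sd_b1, "sd_eps": self.sd_eps,
            "boundary": self.boundary,
            "llf": self.llf, "aic": self.aic, "bic": self.bic,
            "F": F, "p": p,
            "blups": self.blups.to_dict(),
        }


def ftest_fixed_slope(fit: GrowthLMEResults, ddf: str = "satterthwaite") -> tuple[float, float]:
    """Module-level convenience wrapper around ``f_test_slope``."""
    return fit.f_test_slope(ddf=ddf)
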