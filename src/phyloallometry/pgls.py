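"""Ordinary and phylogenetic least-squares allometric regression.

The workhorse model is log-log allometry, ``log(y) = beta * log(x) + alpha``,
fitted either by OLS (optionally with species fixed effects for
individual-level data) or by generalized least squares whose error
covariance derives from shared phylogenetic branch lengths under Brownian
motion, with Pagel's lambda scaling the off-diagonal covariance
(lambda = 0: star phylogeny, independent tips; lambda = 1: full Brownian
structure). Lambda can be fixed or estimated by (restricted) maximum
likelihood.

Both routes return a :class:`LinearFit` results object with coefficients,
standard errors, t statistics, p values, residuals and log-likelihood, plus
a ``summary()`` table. Nested fits are compared with :func:`anova_term`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

__all__ = ["LinearFit", "AnovaResult", "PGLS", "ols_fit", "pgls_fit",
           "residual_vector", "anova_term"]


@dataclass
class LinearFit:
    """Results of an OLS or (P)GLS linear model fit.

    ``params`` etc. are indexed by term name; ``const`` is the intercept.
    ``resid`` holds ordinary (response-scale) residuals keyed by
    observation id. For phylogenetic fits ``lam`` is Pagel's lambda and
    ``loglik`` the (restricted) log-likelihood at the estimate; both are
    None for non-phylogenetic fits.
    """

    response: str
    params: pd.Series
    bse: pd.Series
    df_resid: int
    resid: pd.Series
    rss: float           # V-whitened residual sum of squares
    sigma2: float
    method: str          # "ols" | "pgls"
    lam: float | None = None
    loglik: float | None = None
    log_base: float | None = None
    n_used: int = 0
    model: object = field(default=None, repr=False)

    @property
    def predictors(self) -> list:
        return [t for t in self.params.index if t != "const"]

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * scipy.stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = scipy.stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def coef(self, term: str) -> float:
        return float(self.params[term])

    def to_frame(self) -> pd.DataFrame:
        """Flat per-term table (estimate, SE, t, df, p)."""
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "se": self.bse.values,
            "t": self.tvalues.values,
            "df": self.df_resid,
            "p": self.pvalues.values,
        })

    def summary(self) -> str:
        lines = [
            f"{'PGLS' if self.method == 'pgls' else 'OLS'} fit: "
            f"{self.response} ~ {' + '.join(self.predictors) or '1'}",
            f"n = {self.n_used}, df_resid = {self.df_resid}, "
            f"sigma2 = {self.sigma2:.6g}"
            + (f", log base = {self.log_base:g}" if self.log_base else ""),
        ]
        if self.lam is not None:
            lines.append(f"Pagel's lambda = {self.lam:.4f}, "
                         f"loglik = {self.loglik:.4f}")
        lines.append(f"{'term':<20}{'estimate':>12}{'SE':>12}"
                     f"{'t':>10}{'p':>12}")
        for term in self.params.index:
            lines.append(
                f"{term:<20}{self.params[term]:>12.5f}{self.bse[term]:>12.5f}"
                f"{self.tvalues[term]:>10.3f}{self.pvalues[term]:>12.4g}")
        return "\n".join(lines)


@dataclass
class AnovaResult:
    term: str
    F: float
    df_num: int
    df_den: int
    p_value: float

    def summary(self) -> str:
        return (f"ANOVA [{self.term}]: F({self.df_num}, {self.df_den}) = "
                f"{self.F:.3f}, P = {self.p_value:.4g}")


def _design_matrix(table, response, predictors, species_fixed=False):
    """Build response vector and design DataFrame, dropping incomplete rows."""
    cols = [response] + list(predictors)
    sub = table.complete_rows(cols)
    y = sub.data[response].astype(float)
    X = sub.data[list(predictors)].astype(float)
    if species_fixed:
        species = sub.species.astype(str)
        levels = sorted(species.unique())
        # treatment coding, reference = alphabetically first species
        for level in levels[1:]:
            X[f"species[{level}]"] = (species == level).astype(float)
    X = sm.add_constant(X, has_constant="add")
    return y, X, sub


def _check_rank(X: pd.DataFrame):
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify pivoted-out columns via QR with column pivoting
        _, R, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad += [X.columns[p] for p in piv[len(diag):]]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}")


def ols_fit(table, response, predictors, species_fixed: bool = False) -> LinearFit:
    """Ordinary least squares of ``response`` on ``predictors``.

    With ``species_fixed=True`` the species label enters as treatment-coded
    dummies (reference level = alphabetically first species), the standard
    construction for individual-level data with species-specific intercepts.
    """
    y, X, sub = _design_matrix(table, response, predictors, species_fixed)
    p = X.shape[1]
    if len(y) < p + 1:
        raise ValueError(f"need at least {p + 1} usable rows, have {len(y)}")
    _check_rank(X)
    res = sm.OLS(y, X).fit()
    return LinearFit(
        response=response,
        params=res.params,
        bse=res.bse,
        df_resid=int(res.df_resid),
        resid=res.resid,
        rss=float(res.ssr),
        sigma2=float(res.ssr / res.df_resid),
        method="ols",
        log_base=sub.log_base,
        n_used=len(y),
        model=res,
    )


class PGLS:
    """Phylogenetic generalized least squares with Pagel's lambda.

    Parameters
    ----------
    endog : Series
        Response, indexed by species label (one observation per species).
    exog : DataFrame
        Predictors (a ``const`` column is added if absent), same index.
    cov : PhyloCovariance
        Brownian-motion covariance; it is subset and reordered to the
        observation index.
    """

    def __init__(self, endog: pd.Series, exog: pd.DataFrame, cov):
        species = list(endog.index)
        missing = set(species) - set(cov.taxa)
        if missing:
            raise KeyError(f"species not in phylogenetic covariance: "
                           f"{sorted(missing)}")
        if len(set(species)) != len(species):
            raise ValueError("phylogenetic fits need one row per species")
        self.cov = cov.subset(species)
        self.endog = endog.astype(float)
        self.exog = sm.add_constant(exog.astype(float), has_constant="add")
        _check_rank(self.exog)
        self.nobs, self.k = self.exog.shape
        if self.nobs < self.k + 1:
            raise ValueError("not enough species for the number of predictors")

    @classmethod
    def from_table(cls, table, response, predictors, cov) -> "PGLS":
        sub = table.complete_rows([response] + list(predictors))
        data = sub.data.set_index(sub.species_col)
        return cls(data[response], data[list(predictors)], cov)

    # -- likelihood ----------------------------------------------------

    def _gls(self, lam: float):
        V = self.cov.lambda_transform(lam)
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular phylogenetic covariance at lambda={lam}") from exc
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        Xw = scipy.linalg.solve_triangular(L, X, lower=True)
        yw = scipy.linalg.solve_triangular(L, y, lower=True)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        ew = yw - Xw @ beta
        rss = float(ew @ ew)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
        return beta, rss, logdetV, L, Xw

    def loglik(self, lam: float, reml: bool = True) -> float:
        """Profile (restricted) log-likelihood in lambda, sigma2 profiled out."""
        beta, rss, logdetV, _, Xw = self._gls(lam)
        n, k = self.nobs, self.k
        if reml:
            df = n - k
            sigma2 = rss / df
            _, logdetXX = np.linalg.slogdet(Xw.T @ Xw)
            return -0.5 * (df * math.log(2 * math.pi * sigma2) + logdetV
                           + logdetXX + df)
        sigma2 = rss / n
        return -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetV + n)

    # -- fitting -------------------------------------------------------

    def fit(self, lambda_mode="ml", reml: bool = True) -> LinearFit:
        """Fit the model.

        ``lambda_mode`` is either a fixed value in [0, 1] or ``"ml"``, in
        which case lambda maximizes the restricted (default) or full
        likelihood by bounded scalar optimization on [0, 1] (tolerance
        1e-6; boundary optima are reported as boundary estimates).
        """
        if lambda_mode == "ml":
            opt = scipy.optimize.minimize_scalar(
                lambda lam: -self.loglik(lam, reml=reml),
                bounds=(0.0, 1.0), method="bounded",
                options={"xatol": 1e-6})
            lam = float(opt.x)
            # the bounded optimizer never lands exactly on the boundary;
            # snap when the boundary is at least as good
            for edge in (0.0, 1.0):
                if self.loglik(edge, reml=reml) >= -opt.fun:
                    lam = edge
        else:
            lam = float(lambda_mode)
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        beta, rss, logdetV, L, Xw = self._gls(lam)
        df_resid = self.nobs - self.k
        sigma2 = rss / df_resid
        cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
        bse = np.sqrt(np.diag(cov_beta))
        terms = list(self.exog.columns)
        fitted = self.exog.to_numpy() @ beta
        resid = pd.Series(self.endog.to_numpy() - fitted,
                          index=self.endog.index)
        return LinearFit(
            response=self.endog.name or "y",
            params=pd.Series(beta, index=terms),
            bse=pd.Series(bse, index=terms),
            df_resid=df_resid,
            resid=resid,
            rss=rss,
            sigma2=sigma2,
            method="pgls",
            lam=lam,
            loglik=self.loglik(lam, reml=reml),
            n_used=self.nobs,
        )


    # -- optional MCMC -------------------------------------------------

    def sample_posterior(self, n_samples: int = 2000, seed: int = 0,
                         burn: int = 500, step_scale: float = 0.15):
        """Random-walk Metropolis over (beta, log sigma2, logit lambda).

        Methodological parity with MCMC-based phylogenetic regression:
        flat priors on beta and log sigma2, uniform on lambda. Returns a
        DataFrame of retained draws (one column per coefficient plus
        ``sigma2`` and ``lambda``). Deterministic given ``seed``. The ML
        fit remains the primary estimator; posterior means should agree
        with it closely on well-identified problems.
        """
        rng = np.random.default_rng(int(seed))
        X = self.exog.to_numpy()
        y = self.endog.to_numpy()
        n, k = X.shape

        def logpost(theta):
            beta, logs2, z = theta[:k], theta[k], theta[k + 1]
            lam = 1.0 / (1.0 + math.exp(-z))
            s2 = math.exp(logs2)
            V = self.cov.lambda_transform(lam)
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                return -np.inf
            e = scipy.linalg.solve_triangular(L, y - X @ beta, lower=True)
            logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
            ll = -0.5 * (n * math.log(2 * math.pi * s2) + logdetV
                         + (e @ e) / s2)
            # Jacobians of the log / logit transforms keep the priors
            # flat on (sigma2, lambda)
            return ll + logs2 + math.log(lam * (1 - lam))

        start_fit = self.fit(lambda_mode="ml", reml=False)
        lam0 = min(max(start_fit.lam, 1e-3), 1 - 1e-3)
        theta = np.concatenate([
            start_fit.params.to_numpy(),
            [math.log(start_fit.rss / n)],
            [math.log(lam0 / (1 - lam0))]])
        scales = np.concatenate([
            np.maximum(start_fit.bse.to_numpy(), 1e-6),
            [math.sqrt(2.0 / n)], [0.5]]) * step_scale / 0.15
        lp = logpost(theta)
        draws = []
        for it in range(burn + n_samples):
            prop = theta + rng.normal(0.0, scales)
            lp_prop = logpost(prop)
            if math.log(rng.uniform()) < lp_prop - lp:
                theta, lp = prop, lp_prop
            if it >= burn:
                lam = 1.0 / (1.0 + math.exp(-theta[k + 1]))
                draws.append(np.concatenate(
                    [theta[:k], [math.exp(theta[k]), lam]]))
        cols = list(self.exog.columns) + ["sigma2", "lambda"]
        return pd.DataFrame(draws, columns=cols)


def pgls_fit(table, response, predictors, cov, lambda_mode="ml",
             reml: bool = True) -> LinearFit:
    """Phylogenetic GLS of ``response`` on ``predictors``; see :class:`PGLS`."""
    return PGLS.from_table(table, response, predictors, cov).fit(
        lambda_mode=lambda_mode, reml=reml)


def residual_vector(fit: LinearFit) -> pd.Series:
    """Ordinary residuals ``y - X beta`` keyed by observation id."""
    return fit.resid.copy()


def anova_term(fit_full: LinearFit, fit_reduced: LinearFit,
               term: str | None = None) -> AnovaResult:
    """F test of the terms dropped from ``fit_full`` in ``fit_reduced``.

    Uses the extra-sum-of-squares F statistic
    ``F = [(RSS_r - RSS_f)/dp] / [RSS_f/df_f]`` on the (whitened, for GLS)
    residual sums of squares; both fits must use the same observations.
    """
    extra = set(fit_full.predictors) - set(fit_reduced.predictors)
    if set(fit_reduced.predictors) - set(fit_full.predictors):
        raise ValueError("reduced model terms must nest within the full model")
    if fit_full.n_used != fit_reduced.n_used or \
            not fit_full.resid.index.equals(fit_reduced.resid.index):
        raise ValueError("fits use different observations; refit on the "
                         "common row set before comparing")
    df_num = fit_reduced.df_resid - fit_full.df_resid
    df_den = fit_full.df_resid
    if df_num == 0:
        return AnovaResult(term or "<none>", 0.0, 0, df_den, 1.0)
    F = ((fit_reduced.rss - fit_full.rss) / df_num) / \
        (fit_full.rss / df_den)
    F = max(F, 0.0)
    p = float(scipy.stats.f.sf(F, df_num, df_den))
    label = term or " + ".join(sorted(extra))
    return AnovaResult(label, float(F), df_num, df_den, p)
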