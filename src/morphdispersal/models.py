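"""Morph-by-environment statistical models.

Two model families:

* a **linear mixed model** for natal dispersal distance with crossed random
  intercepts for year, brood and natal nest box, fixed effects for color
  morph, winter temperature anomaly, their interaction, prey abundance, sex,
  standardized fledging body mass and (in the all-ages analysis set) age at
  recruitment.  Estimation is REML with the variance ratios profiled out;
  per-term marginal (Type III) F tests use Satterthwaite denominator degrees
  of freedom computed from the gradient of the contrast variance with
  respect to the variance components and the asymptotic covariance of the
  variance-component estimates.

* a **binomial GLM** (logit link, weighted by yearly totals) of the yearly
  proportion of brown recruits on the winter anomaly, testing whether winter
  conditions shift morph composition among recruits at all.

The REML engine is implemented here with dense linear algebra: crossed
random intercepts do not factor into the nested block structure generic
mixed-model routines exploit, and the Satterthwaite machinery needs direct
access to the variance-component likelihood surface.  Sample sizes in this
kind of nest-box study (a few hundred recruits) make the dense approach
exact and fast.

Reference levels follow the field convention: gray morph, female sex,
one-year-old recruitment age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
import statsmodels.api as sm

__all__ = [
    "LmmFit",
    "GlmFit",
    "fit_crossed_lmm",
    "fit_dispersal_lmm",
    "fit_brown_proportion_glm",
    "satterthwaite_df",
    "marginal_effects",
    "ConvergenceWarning",
]


class ConvergenceWarning(UserWarning):
    pass


# --------------------------------------------------------------------------
# REML engine for crossed random intercepts
# --------------------------------------------------------------------------

def _labels_to_Z(labels: np.ndarray) -> np.ndarray:
    """Dense indicator matrix (n × n_levels) for a grouping factor."""
    codes, _ = pd.factorize(labels)
    Z = np.zeros((codes.size, codes.max() + 1))
    Z[np.arange(codes.size), codes] = 1.0
    return Z


class _REMLEngine:
    """Profiled REML for y = Xb + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I).

    The residual variance is profiled out; the optimizer works on the
    variance ratios gamma_k = s2_k / s2_e, constrained >= 0.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, Zs: Mapping[str, np.ndarray]):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        self.n, self.p = self.X.shape
        if self.n <= self.p:
            raise ValueError(f"need n > p (n={self.n}, p={self.p})")
        self.names = list(Zs)
        self.ZZt = [np.asarray(Z, float) @ np.asarray(Z, float).T for Z in Zs.values()]
        self.K = len(self.ZZt)

    def _gls(self, V: np.ndarray):
        cf = cho_factor(V, lower=True)
        ViX = cho_solve(cf, self.X)
        Viy = cho_solve(cf, self.y)
        XtViX = self.X.T @ ViX
        cf2 = cho_factor(XtViX, lower=True)
        beta = cho_solve(cf2, self.X.T @ Viy)
        r = self.y - self.X @ beta
        quad = float(r @ cho_solve(cf, r))
        logdet_V = 2.0 * np.log(np.diag(cf[0])).sum()
        logdet_XtViX = 2.0 * np.log(np.diag(cf2[0])).sum()
        return beta, XtViX, quad, logdet_V, logdet_XtViX

    def _V0(self, gamma: np.ndarray) -> np.ndarray:
        V0 = np.eye(self.n)
        for g, A in zip(gamma, self.ZZt):
            if g != 0.0:
                V0 += g * A
        return V0

    def profiled_nll(self, gamma: np.ndarray) -> float:
        try:
            _, _, quad, ld_V, ld_X = self._gls(self._V0(gamma))
        except np.linalg.LinAlgError:
            return np.inf
        if quad <= 0:
            return np.inf
        return 0.5 * ((self.n - self.p) * np.log(quad) + ld_V + ld_X)

    def full_nll(self, theta: np.ndarray, active: Sequence[int]) -> float:
        """-REML loglik (no constant) as a function of raw variances.

        ``theta`` = variances of the components listed in ``active`` followed
        by the residual variance; inactive components are held at zero.
        """
        s2e = theta[-1]
        if s2e <= 0 or (theta < 0).any():
            return np.inf
        V = s2e * np.eye(self.n)
        for t, k in zip(theta[:-1], active):
            V += t * self.ZZt[k]
        try:
            _, _, quad, ld_V, ld_X = self._gls(V)
        except np.linalg.LinAlgError:
            return np.inf
        return 0.5 * (ld_V + ld_X + quad)

    def fit(self, tol: float = 1e-10):
        if self.K == 0:
            gamma = np.empty(0)
            converged = True
        else:
            best = None
            for x0 in (np.full(self.K, 0.5), np.full(self.K, 0.05)):
                res = minimize(
                    self.profiled_nll,
                    x0,
                    method="L-BFGS-B",
                    bounds=[(0.0, None)] * self.K,
                    options={"ftol": tol, "gtol": 1e-9, "maxiter": 500},
                )
                if best is None or res.fun < best.fun - 1e-12:
                    best = res
            gamma = np.maximum(best.x, 0.0)
            # snap essentially-boundary ratios to 0 so variance components at
            # the boundary are reported as exact zeros
            gamma[gamma < 1e-10] = 0.0
            converged = bool(best.success)
        beta, XtViX, quad, ld_V, ld_X = self._gls(self._V0(gamma))
        s2e = quad / (self.n - self.p)
        cov_beta = s2e * np.linalg.inv(XtViX)
        theta = np.append(gamma * s2e, s2e)
        loglik = -0.5 * (
            (self.n - self.p) * np.log(2 * np.pi * s2e)
            + ld_V
            + ld_X
            + (self.n - self.p)
        )
        return beta, cov_beta, theta, loglik, converged

    # -- Satterthwaite ------------------------------------------------------
    def _contrast_var(self, theta: np.ndarray, active: Sequence[int], c: np.ndarray) -> float:
        s2e = theta[-1]
        V = s2e * np.eye(self.n)
        for t, k in zip(theta[:-1], active):
            V += t * self.ZZt[k]
        cf = cho_factor(V, lower=True)
        XtViX = self.X.T @ cho_solve(cf, self.X)
        return float(c @ np.linalg.solve(XtViX, c))

    def satterthwaite(self, theta_hat: np.ndarray, c: np.ndarray) -> float:
        """Denominator df for the contrast c'beta at the REML estimate.

        df = 2 f^2 / (g' A g) with f the contrast variance, g its gradient
        in the variance components and A the asymptotic covariance of the
        variance-component estimates (inverse observed REML information).
        Components estimated exactly at the zero boundary are excluded (the
        information matrix would be singular there); if the reduced
        information matrix is still not positive definite the residual
        df n - p is returned with a warning.
        """
        resid_df = float(self.n - self.p)
        active = [k for k in range(self.K) if theta_hat[k] > 0.0]
        th = np.append(theta_hat[active] if active else np.empty(0), theta_hat[-1])
        f0 = self._contrast_var(th, active, c)
        if len(th) == 1 and self.K == 0:
            return resid_df
        steps = np.array([1e-4 * max(t, 1e-3 * th[-1]) for t in th])
        steps = np.minimum(steps, th / 3.0)
        q = len(th)
        # gradient of the contrast variance
        g = np.empty(q)
        for i in range(q):
            e = np.zeros(q)
            e[i] = steps[i]
            g[i] = (
                self._contrast_var(th + e, active, c)
                - self._contrast_var(th - e, active, c)
            ) / (2 * steps[i])
        # observed information: Hessian of the negative REML loglik
        H = np.empty((q, q))
        f_c = self.full_nll(th, active)
        for i in range(q):
            ei = np.zeros(q)
            ei[i] = steps[i]
            for j in range(i, q):
                ej = np.zeros(q)
                ej[j] = steps[j]
                if i == j:
                    H[i, i] = (
                        self.full_nll(th + ei, active)
                        - 2 * f_c
                        + self.full_nll(th - ei, active)
                    ) / steps[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        self.full_nll(th + ei + ej, active)
                        - self.full_nll(th + ei - ej, active)
                        - self.full_nll(th - ei + ej, active)
                        + self.full_nll(th - ei - ej, active)
                    ) / (4 * steps[i] * steps[j])
        try:
            A = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn(
                "singular variance-component information; using residual df",
                ConvergenceWarning,
            )
            return resid_df
        denom = float(g @ A @ g)
        if denom <= 0 or not np.isfinite(denom):
            warnings.warn(
                "non-positive variance of the contrast variance; using residual df",
                ConvergenceWarning,
            )
            return resid_df
        return 2.0 * f0**2 / denom


@dataclass
class LmmFit:
    """A fitted crossed-random-intercepts linear mixed model."""

    beta: pd.Series
    cov_beta: pd.DataFrame
    variance_components: dict  # name -> {"variance": v, "sd": sqrt(v)}
    sigma2_resid: float
    loglik: float
    n_obs: int
    converged: bool
    terms: dict = field(default_factory=dict)  # term name -> list of columns
    _engine: "_REMLEngine | None" = field(default=None, repr=False)
    _theta: np.ndarray | None = field(default=None, repr=False)
    anomaly_range: tuple[float, float] | None = None
    column_means: pd.Series | None = None

    # -- inference ----------------------------------------------------------
    def contrast_df(self, c: np.ndarray) -> float:
        if self._engine is None or self._engine.K == 0:
            return float(self.n_obs - len(self.beta))
        return self._engine.satterthwaite(self._theta, np.asarray(c, float))

    def term_test(self, term: str) -> dict:
        """Marginal (Type III) F test of one fixed-effect term.

        Multi-column terms are tested jointly; the denominator df combines
        the Satterthwaite dfs of the eigen-contrasts of the term's covariance
        block (for a 1-df term this reduces to the plain Satterthwaite df).
        """
        cols = self.terms[term]
        idx = [self.beta.index.get_loc(c) for c in cols]
        qdim = len(idx)
        L = np.zeros((qdim, len(self.beta)))
        for r, i in enumerate(idx):
            L[r, i] = 1.0
        b = self.beta.to_numpy()
        Phi = self.cov_beta.to_numpy()
        VC = L @ Phi @ L.T
        Fstat = float(b[idx] @ np.linalg.solve(VC, b[idx])) / qdim
        evals, evecs = np.linalg.eigh(VC)
        nus = []
        for i in range(qdim):
            ci = L.T @ evecs[:, i]
            nus.append(self.contrast_df(ci))
        if qdim == 1:
            den_df = nus[0]
        else:
            usable = [nu for nu in nus if nu > 2.0]
            if len(usable) == qdim:
                E = sum(nu / (nu - 2.0) for nu in usable)
                den_df = 2.0 * E / (E - qdim) if E > qdim else min(nus)
            else:
                den_df = min(nus)
        p = float(stats.f.sf(Fstat, qdim, den_df))
        return {"term": term, "num_df": qdim, "den_df": den_df, "F": Fstat, "p": p}

    def fixed_table(self) -> pd.DataFrame:
        """Coefficient table: estimate, SE, Satterthwaite df, term F and p."""
        rows = []
        se = np.sqrt(np.diag(self.cov_beta.to_numpy()))
        for term, cols in self.terms.items():
            test = self.term_test(term) if term != "Intercept" else None
            for j, col in enumerate(cols):
                i = self.beta.index.get_loc(col)
                c = np.zeros(len(self.beta))
                c[i] = 1.0
                rows.append(
                    {
                        "term": term,
                        "coefficient": col,
                        "estimate": float(self.beta.iloc[i]),
                        "se": float(se[i]),
                        "df": self.contrast_df(c),
                        "F": test["F"] if test and j == 0 else np.nan,
                        "p": test["p"] if test and j == 0 else np.nan,
                    }
                )
        return pd.DataFrame(rows)

    def varcomp_table(self) -> pd.DataFrame:
        rows = [
            {"component": k, "variance": v["variance"], "sd": v["sd"]}
            for k, v in self.variance_components.items()
        ]
        rows.append(
            {
                "component": "Residual",
                "variance": self.sigma2_resid,
                "sd": float(np.sqrt(self.sigma2_resid)),
            }
        )
        return pd.DataFrame(rows)


def fit_crossed_lmm(
    y,
    X: pd.DataFrame,
    random_factors: Mapping[str, Sequence] | None = None,
    z_matrices: Mapping[str, np.ndarray] | None = None,
    terms: Mapping[str, Sequence[str]] | None = None,
    tol: float = 1e-10,
) -> LmmFit:
    """REML fit of a linear mixed model with crossed random intercepts.

    Parameters
    ----------
    y : array-like
        Response vector.
    X : DataFrame
        Fixed-effect design matrix (including the intercept column).
    random_factors : mapping name -> label vector
        Each entry adds a random intercept per level of the labels.
    z_matrices : mapping name -> (n, q) array
        Explicit random-effect design matrices, for non-factor structures.
    terms : mapping term -> columns of X
        Grouping of design columns into testable terms; defaults to one term
        per column.
    """
    X = pd.DataFrame(X)
    Zs: dict[str, np.ndarray] = {}
    for name, labels in (random_factors or {}).items():
        Zs[name] = _labels_to_Z(np.asarray(labels))
    for name, Z in (z_matrices or {}).items():
        Zs[name] = np.asarray(Z, float)
    engine = _REMLEngine(np.asarray(y, float), X.to_numpy(float), Zs)
    beta, cov_beta, theta, loglik, converged = engine.fit(tol=tol)
    if not converged:
        warnings.warn("REML optimizer did not report convergence", ConvergenceWarning)
    vc = {
        name: {"variance": float(theta[k]), "sd": float(np.sqrt(theta[k]))}
        for k, name in enumerate(engine.names)
    }
    if terms is None:
        terms = {c: [c] for c in X.columns}
    return LmmFit(
        beta=pd.Series(beta, index=X.columns),
        cov_beta=pd.DataFrame(cov_beta, index=X.columns, columns=X.columns),
        variance_components=vc,
        sigma2_resid=float(theta[-1]),
        loglik=float(loglik),
        n_obs=engine.n,
        converged=converged,
        terms=dict(terms),
        _engine=engine,
        _theta=theta,
        column_means=X.mean(),
    )


def satterthwaite_df(fit: LmmFit, contrast) -> float:
    """Satterthwaite denominator df for a fixed-effect contrast c'beta."""
    return fit.contrast_df(np.asarray(contrast, float))


# --------------------------------------------------------------------------
# The dispersal model
# --------------------------------------------------------------------------

_MORPH_LEVELS = ("gray", "brown")
_SEX_LEVELS = ("female", "male")
_AGE_LEVELS = ("1", "2", "3+")


def _check_levels(series: pd.Series, levels: tuple, what: str) -> None:
    bad = set(series.astype(str)) - set(levels)
    if bad:
        raise ValueError(f"unknown {what} level(s) {sorted(bad)}; expected {levels}")


def build_dispersal_design(
    recruits: pd.DataFrame, include_age: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Fixed-effect design matrix for the dispersal model.

    Treatment coding with reference levels gray / female / age 1; body mass
    is z-scored over the rows supplied (i.e. over the analysis sample).
    Returns the design and the term -> columns mapping in reporting order.
    """
    from .covariates import standardize

    df = recruits
    _check_levels(df["morph"], _MORPH_LEVELS, "morph")
    _check_levels(df["sex"], _SEX_LEVELS, "sex")
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    terms: dict[str, list[str]] = {"Intercept": ["Intercept"]}
    if include_age:
        age = df["age_at_recruitment"].astype(str)
        _check_levels(age, _AGE_LEVELS, "age_at_recruitment")
        X["age_2yo"] = (age == "2").astype(float)
        X["age_3plus"] = (age == "3+").astype(float)
        terms["age_at_recruitment"] = ["age_2yo", "age_3plus"]
    X["morph_brown"] = (df["morph"] == "brown").astype(float)
    terms["morph"] = ["morph_brown"]
    X["mass_z"] = standardize(df["body_mass_g"].to_numpy(float))
    terms["body_mass"] = ["mass_z"]
    X["sex_male"] = (df["sex"] == "male").astype(float)
    terms["sex"] = ["sex_male"]
    X["prey_index"] = df["prey_index"].astype(float)
    terms["prey_abundance"] = ["prey_index"]
    X["anomaly_c"] = df["anomaly_c"].astype(float)
    terms["winter_anomaly"] = ["anomaly_c"]
    X["anomaly_c:morph_brown"] = X["anomaly_c"] * X["morph_brown"]
    terms["winter_anomaly:morph"] = ["anomaly_c:morph_brown"]
    return X, terms


def fit_dispersal_lmm(
    recruits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    analysis_set: str = "all-ages",
    tol: float = 1e-10,
) -> LmmFit:
    """Fit the natal-dispersal mixed model for one analysis set.

    Parameters
    ----------
    recruits : DataFrame
        Per-recruit rows with columns dispersal_km, morph, sex, body_mass_g,
        age_at_recruitment, hatch_year, brood_id, natal_box_id, and (unless
        ``covariates`` is given) anomaly_c and prey_index.
    covariates : DataFrame, optional
        Per-year table with winter_year, anomaly_c, prey_index, merged onto
        hatch_year.
    analysis_set : {"all-ages", "one-year-olds"}
        "all-ages" keeps every recruit and includes the age term;
        "one-year-olds" restricts to age 1 and drops the age term.
    """
    df = recruits.copy()
    if covariates is not None:
        cov = covariates.rename(columns={"winter_year": "hatch_year", "year": "hatch_year"})
        keep = [c for c in ("hatch_year", "anomaly_c", "prey_index") if c in cov.columns]
        df = df.drop(columns=[c for c in ("anomaly_c", "prey_index") if c in df.columns])
        df = df.merge(cov[keep], on="hatch_year", how="left")
    if analysis_set == "one-year-olds":
        df = df[df["age_at_recruitment"].astype(str) == "1"]
        include_age = False
    elif analysis_set == "all-ages":
        include_age = True
    else:
        raise ValueError(f"unknown analysis set {analysis_set!r}")
    needed = [
        "dispersal_km", "morph", "sex", "body_mass_g", "age_at_recruitment",
        "hatch_year", "brood_id", "natal_box_id", "anomaly_c", "prey_index",
    ]
    df = df.dropna(subset=[c for c in needed if c in df.columns])
    if df.empty:
        raise ValueError("no complete cases for the dispersal model")
    X, terms = build_dispersal_design(df, include_age=include_age)
    fit = fit_crossed_lmm(
        df["dispersal_km"].to_numpy(float),
        X,
        random_factors={
            "Year": df["hatch_year"].to_numpy(),
            "Brood ID": df["brood_id"].to_numpy(),
            "Nest box ID": df["natal_box_id"].to_numpy(),
        },
        terms=terms,
        tol=tol,
    )
    a = df["anomaly_c"].to_numpy(float)
    fit.anomaly_range = (float(a.min()), float(a.max()))
    return fit


def marginal_effects(
    fit: LmmFit,
    anomaly_grid,
    morph_levels: Sequence[str] = _MORPH_LEVELS,
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Predicted dispersal distance per morph over a winter-anomaly grid.

    Non-focal design columns are held at their sample means; the confidence
    band comes from the fixed-effect covariance only (population-level
    prediction).  Grid points outside the fitted anomaly range are allowed
    and flagged ``extrapolated``.
    """
    if fit.column_means is None:
        raise ValueError("fit carries no design information")
    z = stats.norm.ppf(0.5 + ci_level / 2)
    cols = list(fit.beta.index)
    rows = []
    for morph in morph_levels:
        brown = 1.0 if morph == "brown" else 0.0
        for a in np.asarray(anomaly_grid, float):
            x = fit.column_means.copy()
            x["Intercept"] = 1.0
            x["morph_brown"] = brown
            x["anomaly_c"] = a
            x["anomaly_c:morph_brown"] = a * brown
            xv = x[cols].to_numpy(float)
            pred = float(xv @ fit.beta.to_numpy())
            se = float(np.sqrt(xv @ fit.cov_beta.to_numpy() @ xv))
            extrap = (
                fit.anomaly_range is not None
                and not (fit.anomaly_range[0] <= a <= fit.anomaly_range[1])
            )
            rows.append(
                {
                    "morph": morph,
                    "anomaly_c": a,
                    "predicted_km": pred,
                    "ci_low_km": pred - z * se,
                    "ci_high_km": pred + z * se,
                    "extrapolated": extrap,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Binomial GLM of yearly brown proportion
# --------------------------------------------------------------------------

@dataclass
class GlmFit:
    """Weighted logistic regression of yearly brown proportion on anomaly."""

    slope_estimate: float
    slope_se: float
    z_value: float
    p: float
    n_years: int
    intercept: float
    separation_flag: bool = False


def fit_brown_proportion_glm(yearly: pd.DataFrame) -> GlmFit:
    """Fit the binomial GLM of brown-recruit proportion on winter anomaly.

    ``yearly`` needs columns n_brown, n_total, anomaly_c, one row per hatch
    year with at least one recruit.  The logit-link fit is weighted by the
    yearly totals (successes/failures supplied as counts).
    """
    df = yearly[yearly["n_total"] > 0].copy()
    if len(df) < 2:
        raise ValueError("need >= 2 years with recruits for the proportion GLM")
    n_brown = df["n_brown"].to_numpy(float)
    n_total = df["n_total"].to_numpy(float)
    if (n_brown > n_total).any():
        raise ValueError("n_brown exceeds n_total in some year")
    if n_brown.sum() == 0 or (n_total - n_brown).sum() == 0:
        raise ValueError("all recruits are one morph; proportion model undefined")
    endog = np.column_stack([n_brown, n_total - n_brown])
    exog = sm.add_constant(df["anomaly_c"].to_numpy(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
    se = float(res.bse[1])
    separation = bool(not np.isfinite(se) or se > 50 or abs(res.params[1]) > 50)
    if separation:
        warnings.warn(
            "possible complete separation in proportion GLM; estimates unstable",
            ConvergenceWarning,
        )
    return GlmFit(
        slope_estimate=float(res.params[1]),
        slope_se=se,
        z_value=float(res.tvalues[1]),
        p=float(res.pvalues[1]),
        n_years=len(df),
        intercept=float(res.params[0]),
        separation_flag=separation,
    )
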