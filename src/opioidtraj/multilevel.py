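"""Nested random-effects logistic regression and provider-variation profiling.

The model for patient :math:`i` seen by prescriber :math:`d` in practice
:math:`p` in region :math:`r` is

.. math::

    \\operatorname{logit} P(y_i = 1) = x_i^T\\beta
        + u_r + u_p + u_d, \\qquad
    u_r \\sim N(0, \\sigma^2_{region}),\\;
    u_p \\sim N(0, \\sigma^2_{practice}),\\;
    u_d \\sim N(0, \\sigma^2_{prescriber}),

with prescribers nested within practices and practices within regions.
Estimation is Laplace-approximate maximum likelihood: for candidate standard
deviations the joint penalised log-likelihood is maximised over the fixed
effects and spherical random effects by Newton iteration, and the Laplace
log-marginal (joint optimum minus half the log-determinant of the
random-effects information) is optimised over the three standard deviations
under non-negativity bounds.

Explained variation follows the latent-variable decomposition for logistic
models (residual variance fixed at :math:`\\pi^2/3`): a level's share is its
variance component over the total latent variance.  Per-unit profiles come
from simulating the empirical-Bayes (conditional) distribution of each random
effect; units whose 95% interval lies entirely above the population average
(OR > 1) are flagged high-risk, entirely below low-risk.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

__all__ = [
    "NestedLogisticRegression",
    "NestingError",
    "variance_partition",
    "explained_variation",
    "simulate_random_effects",
    "summarize_and_flag",
    "effect_to_proportion",
    "marginal_effect_to_proportion",
    "annual_prescription_rate",
    "LATENT_RESIDUAL_VARIANCE",
    "LEVELS",
]

#: Latent-scale residual variance of the logistic link.
LATENT_RESIDUAL_VARIANCE = math.pi**2 / 3

LEVELS = ("region", "practice", "prescriber")


class NestingError(ValueError):
    """A grouping structure is not strictly nested."""


def _check_nested(child: np.ndarray, parent: np.ndarray, child_name: str, parent_name: str):
    df = pd.DataFrame({"c": child, "p": parent})
    bad = df.groupby("c")["p"].nunique()
    offenders = bad[bad > 1]
    if len(offenders):
        raise NestingError(
            f"{child_name} id(s) {list(offenders.index[:5])} appear under more than one {parent_name}"
        )


@dataclass
class _Encoded:
    Z: sp.csr_matrix  # n × q indicator matrix, columns ordered region|practice|prescriber
    level_of_col: np.ndarray  # 0/1/2 per column
    unit_ids: dict  # level name -> array of unit ids in column order
    n_units: dict


def _encode_groups(groups: pd.DataFrame) -> _Encoded:
    region = np.asarray(groups.iloc[:, 0])
    practice = np.asarray(groups.iloc[:, 1])
    prescriber = np.asarray(groups.iloc[:, 2])
    _check_nested(practice, region, "practice", "region")
    _check_nested(prescriber, practice, "prescriber", "practice")

    codes, uids, level_of_col = [], {}, []
    blocks = []
    n = len(region)
    offset = 0
    for li, (name, arr) in enumerate(zip(LEVELS, (region, practice, prescriber))):
        c, u = pd.factorize(arr, sort=True)
        uids[name] = np.asarray(u)
        q = len(u)
        blocks.append(sp.csr_matrix((np.ones(n), (np.arange(n), c)), shape=(n, q)))
        level_of_col.extend([li] * q)
        offset += q
    Z = sp.hstack(blocks, format="csr")
    return _Encoded(
        Z=Z,
        level_of_col=np.asarray(level_of_col),
        unit_ids=uids,
        n_units={name: len(uids[name]) for name in LEVELS},
    )


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{i}" for i in range(X.shape[1])]


class NestedLogisticRegression(BaseEstimator):
    """Three-level nested random-intercept logistic regression (Laplace ML).

    Parameters
    ----------
    fit_intercept : bool
        Add a fixed intercept column.
    sigma_bound : float
        Upper bound for each random-effect standard deviation during
        optimisation (log-odds scale).
    max_newton_iter, newton_tol : int, float
        Inner Newton solve of the joint penalised likelihood.
    outer_tol : float
        Convergence tolerance of the bounded variance-parameter search.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_, fe_se_ : fixed effects, their order matching
        ``feature_names_in_`` (``fe_se_`` includes the intercept last when
        fitted).
    sigma2_region_, sigma2_practice_, sigma2_prescriber_ : variance components.
    residual_latent_variance_ : π²/3, the latent logistic residual.
    random_effects_ : dict level → pandas Series of conditional modes.
    random_effect_sd_ : dict level → Series of conditional standard deviations.
    converged_, loglik_laplace_, n_units_, separation_warning_
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        sigma_bound: float = 5.0,
        max_newton_iter: int = 100,
        newton_tol: float = 1e-9,
        outer_tol: float = 1e-7,
    ):
        self.fit_intercept = fit_intercept
        self.sigma_bound = sigma_bound
        self.max_newton_iter = max_newton_iter
        self.newton_tol = newton_tol
        self.outer_tol = outer_tol

    # ---- internal machinery -------------------------------------------------

    def _joint_newton(self, sigmas, theta0):
        """Maximise the joint penalised log-likelihood over (beta, b).

        Random effects are spherical (u = sigma * b); returns the optimum,
        its value, the working weights, and the penalised objective pieces.
        """
        X, y, Z, level_of_col = self._X, self._y, self._Z, self._level_of_col
        n, p = X.shape
        q = Z.shape[1]
        s = np.asarray(sigmas)[level_of_col]
        theta = theta0.copy()
        obj_prev = -np.inf
        for _ in range(self.max_newton_iter):
            beta, b = theta[:p], theta[p:]
            eta = X @ beta + Z @ (s * b)
            eta = np.clip(eta, -30, 30)
            mu = expit(eta)
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            obj = ll - 0.5 * float(b @ b)
            w = mu * (1.0 - mu)
            r = y - mu
            g = np.concatenate([X.T @ r, s * (Z.T @ r) - b])
            Zs = Z.multiply(s)
            XtWX = X.T @ (X * w[:, None])
            XtWZ = (Zs.T @ (X * w[:, None])).T
            ZtWZ = (Zs.T @ Zs.multiply(w[:, None])).toarray()
            H = np.zeros((p + q, p + q))
            H[:p, :p] = XtWX
            H[:p, p:] = XtWZ
            H[p:, :p] = XtWZ.T
            H[p:, p:] = ZtWZ + np.eye(q)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.solve(H + 1e-8 * np.eye(p + q), g)
            # damped Newton: halve until the objective does not decrease
            t = 1.0
            for _halve in range(30):
                cand = theta + t * step
                beta_c, b_c = cand[:p], cand[p:]
                eta_c = np.clip(X @ beta_c + Z @ (s * b_c), -30, 30)
                ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
                obj_c = ll_c - 0.5 * float(b_c @ b_c)
                if obj_c >= obj - 1e-12:
                    break
                t *= 0.5
            theta = cand
            if abs(obj_c - obj_prev) < self.newton_tol * (1.0 + abs(obj_c)):
                obj_prev = obj_c
                break
            obj_prev = obj_c
        beta, b = theta[:p], theta[p:]
        eta = np.clip(X @ beta + Z @ (s * b), -30, 30)
        mu = expit(eta)
        w = mu * (1.0 - mu)
        return theta, obj_prev, w

    def _laplace_neg(self, sigmas, theta_cache):
        theta, obj, w = self._joint_newton(sigmas, theta_cache["theta"])
        theta_cache["theta"] = theta
        s = np.asarray(sigmas)[self._level_of_col]
        Zs = self._Z.multiply(s)
        A = (Zs.T @ Zs.multiply(w[:, None])).toarray() + np.eye(self._Z.shape[1])
        sign, logdet = np.linalg.slogdet(A)
        return -(obj - 0.5 * logdet)

    def _b_newton(self, sigmas, beta, b0):
        """Conditional mode of the spherical random effects at fixed (σ, β)."""
        X, y, Z, level_of_col = self._X, self._y, self._Z, self._level_of_col
        q = Z.shape[1]
        s = np.asarray(sigmas)[level_of_col]
        xb = X @ beta
        b = b0.copy()
        obj_prev = -np.inf
        for _ in range(self.max_newton_iter):
            eta = np.clip(xb + Z @ (s * b), -30, 30)
            mu = expit(eta)
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            obj = ll - 0.5 * float(b @ b)
            w = mu * (1.0 - mu)
            g = s * (Z.T @ (y - mu)) - b
            Zs = Z.multiply(s).tocsr()
            A = (Zs.T @ Zs.multiply(w[:, None])).toarray() + np.eye(q)
            step = np.linalg.solve(A, g)
            t = 1.0
            for _halve in range(30):
                cand = b + t * step
                eta_c = np.clip(xb + Z @ (s * cand), -30, 30)
                ll_c = float(y @ eta_c - np.logaddexp(0.0, eta_c).sum())
                obj_c = ll_c - 0.5 * float(cand @ cand)
                if obj_c >= obj - 1e-12:
                    break
                t *= 0.5
            b = cand
            if abs(obj_c - obj_prev) < self.newton_tol * (1.0 + abs(obj_c)):
                obj_prev = obj_c
                break
            obj_prev = obj_c
        eta = np.clip(xb + Z @ (s * b), -30, 30)
        mu = expit(eta)
        return b, obj_prev, mu * (1.0 - mu)

    def _laplace_neg_full(self, params, b_cache):
        """Negative Laplace log-marginal over (σ, β), integrating b only."""
        sigmas = np.maximum(params[:3], 0.0)
        beta = params[3:]
        b, obj, w = self._b_newton(sigmas, beta, b_cache["b"])
        b_cache["b"] = b
        s = sigmas[self._level_of_col]
        Zs = self._Z.multiply(s)
        A = (Zs.T @ Zs.multiply(w[:, None])).toarray() + np.eye(self._Z.shape[1])
        sign, logdet = np.linalg.slogdet(A)
        return -(obj - 0.5 * logdet)

    # ---- estimator API ------------------------------------------------------

    def fit(self, X, y, groups):
        """Fit the model.

        Parameters
        ----------
        X : array-like or DataFrame (n, p)
            Fixed-effect design (reference-coded categoricals upstream).
        y : array-like (n,)
            Binary outcome.
        groups : DataFrame or array (n, 3)
            Hierarchy ids in region, practice, prescriber column order;
            non-nested ids raise :class:`NestingError`.
        """
        Xm, names = _as_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != Xm.shape[0]:
            raise ValueError("X and y have different lengths")
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("y must be binary 0/1")
        groups = pd.DataFrame(groups)
        if groups.shape[1] != 3:
            raise ValueError("groups must have three columns: region, practice, prescriber")
        if groups.isna().any().any():
            raise ValueError("every observation needs complete hierarchy ids")
        enc = _encode_groups(groups)

        self.feature_names_in_ = names
        if self.fit_intercept:
            Xm = np.hstack([Xm, np.ones((Xm.shape[0], 1))])
        self._X, self._y, self._Z = Xm, y, enc.Z
        self._level_of_col = enc.level_of_col
        self._enc = enc

        p, q = Xm.shape[1], enc.Z.shape[1]
        theta_cache = {"theta": np.zeros(p + q)}
        x0 = np.array([0.3, 0.3, 0.3])
        res = scipy.optimize.minimize(
            self._laplace_neg,
            x0,
            args=(theta_cache,),
            method="L-BFGS-B",
            bounds=[(0.0, self.sigma_bound)] * 3,
            options={"ftol": self.outer_tol, "gtol": 1e-6, "eps": 1e-4},
        )
        sig0 = np.maximum(res.x, 0.0)
        theta0_full, _, _ = self._joint_newton(sig0, theta_cache["theta"])

        # stage 2 (proper Laplace ML): the log-determinant depends on the
        # fixed effects through the working weights, so β joins the outer
        # optimisation; the profiled stage-1 solution is the warm start
        b_cache = {"b": theta0_full[p:].copy()}
        params0 = np.concatenate([sig0, theta0_full[:p]])
        res2 = scipy.optimize.minimize(
            self._laplace_neg_full,
            params0,
            args=(b_cache,),
            method="L-BFGS-B",
            bounds=[(0.0, self.sigma_bound)] * 3 + [(None, None)] * p,
            options={"ftol": self.outer_tol, "gtol": 1e-7, "eps": 1e-5},
        )
        if res2.fun <= res.fun + 1e-9:
            best, best_x = res2, res2.x
        else:  # pragma: no cover - stage 2 starts at the stage-1 optimum
            best, best_x = res, np.concatenate([sig0, theta0_full[:p]])
        sig = np.maximum(best_x[:3], 0.0)
        beta_hat = best_x[3:]
        b_hat, _, w = self._b_newton(sig, beta_hat, b_cache["b"])
        theta = np.concatenate([beta_hat, b_hat])
        res = best

        s = sig[enc.level_of_col]
        Zs = enc.Z.multiply(s)
        XtWX = Xm.T @ (Xm * w[:, None])
        XtWZ = (Zs.T @ (Xm * w[:, None])).T
        A_bb = (Zs.T @ Zs.multiply(w[:, None])).toarray() + np.eye(q)
        H = np.zeros((p + q, p + q))
        H[:p, :p] = XtWX
        H[:p, p:] = XtWZ
        H[p:, :p] = XtWZ.T
        H[p:, p:] = A_bb
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.inv(H + 1e-8 * np.eye(p + q))
        fe_se = np.sqrt(np.maximum(np.diag(Hinv)[:p], 0.0))

        beta, b = theta[:p], theta[p:]
        if self.fit_intercept:
            self.coef_ = beta[:-1]
            self.intercept_ = float(beta[-1])
            self.fe_se_ = fe_se  # coef order then intercept last
        else:
            self.coef_ = beta
            self.intercept_ = 0.0
            self.fe_se_ = fe_se

        self.sigma_region_, self.sigma_practice_, self.sigma_prescriber_ = (float(v) for v in sig)
        self.sigma2_region_ = float(sig[0] ** 2)
        self.sigma2_practice_ = float(sig[1] ** 2)
        self.sigma2_prescriber_ = float(sig[2] ** 2)
        self.residual_latent_variance_ = LATENT_RESIDUAL_VARIANCE
        self.converged_ = bool(res.success)
        self.loglik_laplace_ = float(-res.fun)
        self.n_units_ = dict(enc.n_units)
        self.n_obs_ = len(y)

        # conditional modes and conditional sds of u = sigma * b
        V_b = np.linalg.inv(A_bb)
        cond_sd = s * np.sqrt(np.maximum(np.diag(V_b), 0.0))
        u_hat = s * b
        self.random_effects_ = {}
        self.random_effect_sd_ = {}
        start = 0
        for li, name in enumerate(LEVELS):
            k = enc.n_units[name]
            idx = pd.Index(enc.unit_ids[name], name="unit_id")
            self.random_effects_[name] = pd.Series(u_hat[start : start + k], index=idx)
            self.random_effect_sd_[name] = pd.Series(cond_sd[start : start + k], index=idx)
            start += k

        # separation diagnostic: runaway coefficients with huge SEs
        self.separation_warning_ = bool(np.any(np.abs(beta) > 15))
        if self.separation_warning_:
            warnings.warn("possible separation: a fixed-effect estimate exceeds 15 on the log-odds scale")
        self._groups = groups.reset_index(drop=True)
        return self

    def predict_proba(self, X, groups: pd.DataFrame | None = None) -> np.ndarray:
        """Probabilities; ``groups=None`` predicts at random effects = 0."""
        Xm, _ = _as_matrix(X)
        eta = Xm @ self.coef_ + self.intercept_
        if groups is not None:
            groups = pd.DataFrame(groups)
            for col, name in zip(range(3), LEVELS):
                u = self.random_effects_[name]
                eta = eta + groups.iloc[:, col].map(u).fillna(0.0).to_numpy()
        p1 = expit(eta)
        return np.column_stack([1.0 - p1, p1])

    def fixed_effects_frame(self) -> pd.DataFrame:
        names = list(self.feature_names_in_)
        est = list(self.coef_)
        if self.fit_intercept:
            names = names + ["intercept"]
            est = est + [self.intercept_]
        return pd.DataFrame({"term": names, "log_odds": est, "se": self.fe_se_})

    def explained_variation(self) -> dict:
        return variance_partition(self.sigma2_region_, self.sigma2_practice_, self.sigma2_prescriber_)


def variance_partition(sigma2_region: float, sigma2_practice: float, sigma2_prescriber: float) -> dict:
    """Percent of total latent variation at each level (latent residual π²/3).

    share_level = σ²_level / (σ²_region + σ²_practice + σ²_prescriber + π²/3) × 100;
    the residual share is defined as the complement so the four shares sum to
    100 exactly.
    """
    for name, v in (
        ("sigma2_region", sigma2_region),
        ("sigma2_practice", sigma2_practice),
        ("sigma2_prescriber", sigma2_prescriber),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative")
    total = sigma2_region + sigma2_practice + sigma2_prescriber + LATENT_RESIDUAL_VARIANCE
    shares = {
        "region": 100.0 * sigma2_region / total,
        "practice": 100.0 * sigma2_practice / total,
        "prescriber": 100.0 * sigma2_prescriber / total,
    }
    shares["residual"] = 100.0 - shares["region"] - shares["practice"] - shares["prescriber"]
    return shares


def explained_variation(fit: NestedLogisticRegression) -> dict:
    """Variance-partition shares of a fitted model (percent per level)."""
    return fit.explained_variation()


def simulate_random_effects(
    fit: NestedLogisticRegression, n_sims: int = 1000, seed: int | None = None
) -> dict:
    """Draw from each unit's empirical-Bayes (conditional) distribution.

    Returns ``{level: DataFrame(units × n_sims)}``.  A unit carrying no
    information keeps its prior: draws centred at 0 with its level's σ².
    """
    if n_sims < 1:
        raise ValueError("n_sims must be at least 1")
    if n_sims < 100:
        warnings.warn(f"n_sims={n_sims} is small; percentile intervals will be noisy")
    rng = np.random.default_rng(seed)
    out = {}
    for name in LEVELS:
        mean = fit.random_effects_[name]
        sd = fit.random_effect_sd_[name]
        draws = rng.normal(mean.to_numpy()[:, None], sd.to_numpy()[:, None], size=(len(mean), n_sims))
        out[name] = pd.DataFrame(draws, index=mean.index)
    return out


def effect_to_proportion(u, anchor: float):
    """Map a log-odds offset to a proportion of new users becoming long-term.

    The anchor is the population-average proportion; ``u = 0`` maps to it
    exactly and the transform ``expit(logit(anchor) + u)`` is strictly
    increasing in ``u``.
    """
    if not 0.0 < anchor < 1.0:
        raise ValueError("anchor proportion must lie strictly inside (0, 1)")
    return expit(logit(anchor) + np.asarray(u, dtype=float))


def marginal_effect_to_proportion(fit: NestedLogisticRegression, X, u) -> np.ndarray:
    """Marginal alternative to the anchored transform.

    Averages ``expit(x'β + intercept + u)`` over the observed covariate
    distribution instead of anchoring at the population proportion; selected
    with ``proportion_scale="marginal"`` in :func:`summarize_and_flag`.
    """
    Xm, _ = _as_matrix(X)
    eta = Xm @ fit.coef_ + fit.intercept_
    u = np.atleast_1d(np.asarray(u, dtype=float))
    return np.array([float(np.mean(expit(eta + ui))) for ui in u])


def summarize_and_flag(
    draws: dict,
    fit: NestedLogisticRegression,
    population_reference: float,
    ci: float = 95.0,
    proportion_scale: str = "anchored",
    X=None,
) -> pd.DataFrame:
    """Per-unit summaries: interval, OR, proportion, rank, and risk flag.

    Point estimates and 95% intervals are percentile summaries of the
    simulated conditional draws; OR scale by exponentiation; proportion
    scale via :func:`effect_to_proportion` anchored at the population
    reference.  Units are ranked within level by point estimate (1 =
    highest), ties broken by unit id; a unit is flagged ``high`` iff the
    whole OR interval is above 1 and ``low`` iff wholly below 1.
    """
    if proportion_scale == "anchored":
        def _prop(v):
            return effect_to_proportion(v, population_reference)
    elif proportion_scale == "marginal":
        if X is None:
            raise ValueError("proportion_scale='marginal' needs the covariate matrix X")
        def _prop(v):
            return marginal_effect_to_proportion(fit, X, v)
    else:
        raise ValueError(f"unknown proportion_scale {proportion_scale!r}")
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0
    frames = []
    for name in LEVELS:
        d = draws[name].to_numpy()
        est = np.median(d, axis=1)
        lo = np.percentile(d, lo_q, axis=1)
        hi = np.percentile(d, hi_q, axis=1)
        df = pd.DataFrame(
            {
                "unit_id": draws[name].index.to_numpy(),
                "level": name,
                "estimate": est,
                "lo": lo,
                "hi": hi,
            }
        )
        df["or_estimate"] = np.exp(df["estimate"])
        df["or_lo"] = np.exp(df["lo"])
        df["or_hi"] = np.exp(df["hi"])
        df["proportion"] = _prop(df["estimate"].to_numpy())
        df["proportion_lo"] = _prop(df["lo"].to_numpy())
        df["proportion_hi"] = _prop(df["hi"].to_numpy())
        df = df.sort_values(["estimate", "unit_id"], ascending=[False, True], kind="stable")
        df["rank"] = np.arange(1, len(df) + 1)
        df["flag"] = np.where(df["or_lo"] > 1.0, "high", np.where(df["or_hi"] < 1.0, "low", "average"))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def flag_interval(or_lo: float, or_hi: float) -> str:
    """Risk flag for one OR interval against the population average (1)."""
    if or_lo > 1.0:
        return "high"
    if or_hi < 1.0:
        return "low"
    return "average"


def annual_prescription_rate(
    prescriptions: pd.DataFrame,
    denominators: pd.DataFrame,
    per: float = 10000.0,
) -> pd.DataFrame:
    """Prescriptions per ``per`` registered patients, by ingredient and year.

    rate = count / denominator × per; the output grid is complete over
    ingredient × year with zero counts filled in.  A year with a
    non-positive denominator is an error.
    """
    den = denominators.set_index("year")["n_registered"]
    bad = den[den <= 0]
    if len(bad):
        raise ValueError(f"non-positive registration denominator for year(s) {list(bad.index)}")
    rx = prescriptions.copy()
    if "year" not in rx.columns:
        rx["year"] = pd.to_datetime(rx["issue_date"]).dt.year
    rx = rx[rx["year"].isin(den.index)]
    counts = rx.groupby(["ingredient", "year"]).size()
    ingredients = sorted(rx["ingredient"].unique())
    rows = []
    for ing in ingredients:
        for year in den.index:
            n = int(counts.get((ing, year), 0))
            rows.append(
                {
                    "ingredient": ing,
                    "year": int(year),
                    "n_prescriptions": n,
                    "n_registered": int(den[year]),
                    "rate_per_10000": per * n / den[year],
                }
            )
    return pd.DataFrame(rows, columns=["ingredient", "year", "n_prescriptions", "n_registered", "rate_per_10000"])
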