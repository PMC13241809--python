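"""Normative location-scale modeling of the lateralization index.

The response is modeled as LI ~ Normal(mu, sigma) with

    mu        = b0 + FP_mu(age) @ b + b_sex * [male] + u_mu[cohort]
    log sigma = g0 + FP_sig(age) @ g + g_sex * [male] + u_sig[cohort]

where FP_* are fractional-polynomial smooths of (age + age_offset).  The log
link keeps sigma positive and lets the population spread vary with age
(age-dependent heteroscedasticity).  Cohort offsets u absorb between-study
location and dispersion differences; by default they carry a Gaussian ridge
penalty whose variance (tau^2) is estimated by EM-type moment updates, with
an unpenalized fixed-effects fallback.

Fitting maximizes the (penalized) Gaussian log-likelihood by alternating
exact weighted least squares for the mu coefficients with Fisher-scoring
steps for the log-sigma coefficients; FP columns are standardized internally
for conditioning and coefficients are reported on the raw scale.

Model selection fits candidate FP specifications for mu and sigma and keeps
the converged candidate with the lowest BIC = −2 loglik + k log n, where k
counts every fitted regression coefficient (including sex terms and one
parameter per cohort offset).  Centile charts and rightward-prevalence
curves are derived from the fitted population predictors (cohort offsets set
to zero):  q_p(age) = mu + sigma * z_p  and  P(right) = Phi(mu / sigma).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fp import ALLOWED_POWERS, FPSpec, enumerate_fp_specs, fp_basis

__all__ = [
    "FitOptions",
    "NormativeModel",
    "CentileChart",
    "SelectionResult",
    "fit_location_scale",
    "select_model",
    "centile_curves",
    "prevalence_right",
    "DEFAULT_LEVELS",
]

DEFAULT_LEVELS: tuple[float, ...] = (2.5, 25.0, 50.0, 75.0, 97.5)

_CONTEXTS = ("female", "male", "average")


# ---------------------------------------------------------------------------
# options and results


@dataclass(frozen=True)
class FitOptions:
    """Controls for one location-scale fit.

    age_offset      years added to age before FP transforms (> 0 at age 0).
    sex_term        include the male indicator ("auto": only when both levels
                    are present).
    cohort_mode     "ridge" (penalized offsets, default), "fixed"
                    (reference-coded unpenalized), "none", or "auto"
                    ("none" when a single cohort is present, else "ridge").
    tau2_mu/sigma   ridge penalty variances for the cohort offsets; "auto"
                    selects them by a Laplace marginal-likelihood grid
                    search, a float fixes them.
    tol             absolute convergence tolerance on the penalized
                    log-likelihood (declared after two small steps).
    max_iter        outer iteration cap (alternations).
    n_restarts      multi-start fallback attempts on non-convergence.
    """

    age_offset: float = 1.0
    sex_term: bool | str = "auto"
    cohort_mode: str = "auto"
    tau2_mu: float | str = "auto"
    tau2_sigma: float | str = "auto"
    tol: float = 1e-10
    max_iter: int = 300
    n_restarts: int = 3
    min_log_sigma: float = -20.0
    max_log_sigma: float = 5.0
    seed: int = 0

    #: grid searched for "auto" penalty variances (LI-scale offsets)
    tau2_grid: tuple[float, ...] = tuple(np.geomspace(1e-6, 1e-1, 11))


@dataclass
class NormativeModel:
    """A fitted location-scale normative model for one tract–feature."""

    spec_mu: FPSpec
    spec_sigma: FPSpec
    age_offset: float
    mu_intercept: float
    mu_fp: np.ndarray
    mu_sex: float | None
    mu_cohorts: dict
    sigma_intercept: float
    sigma_fp: np.ndarray
    sigma_sex: float | None
    sigma_cohorts: dict
    tau2_mu: float | None
    tau2_sigma: float | None
    n: int
    k: int
    loglik: float
    bic: float
    converged: bool
    n_iter: int
    grad_norm: float
    age_range: tuple[float, float]
    cohort_mode: str
    cov_mu: np.ndarray | None = None  # population columns (intercept, FP, sex)
    tract: str | None = None
    feature: str | None = None

    # -- prediction ---------------------------------------------------------

    def _eta(self, ages, which: str, sex, cohort) -> np.ndarray:
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        if which == "mu":
            spec, icpt, fp, bsex, offsets = (
                self.spec_mu, self.mu_intercept, self.mu_fp, self.mu_sex, self.mu_cohorts)
        else:
            spec, icpt, fp, bsex, offsets = (
                self.spec_sigma, self.sigma_intercept, self.sigma_fp,
                self.sigma_sex, self.sigma_cohorts)
        eta = np.full(ages.shape, icpt)
        if spec.order:
            eta = eta + fp_basis(ages, spec, self.age_offset) @ fp
        if bsex is not None and sex is not None:
            male = np.atleast_1d(np.asarray(sex)) == "male"
            eta = eta + bsex * male
        if cohort is not None:
            if np.isscalar(cohort) or isinstance(cohort, str):
                eta = eta + offsets.get(cohort, 0.0)
            else:
                eta = eta + np.array(
                    [offsets.get(c, 0.0) for c in np.atleast_1d(np.asarray(cohort))]
                )
        return eta

    def predict(
        self, ages, sex: str | None = "female", cohort: str | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) at ``ages`` for one sex level; cohort offsets default
        to zero (population prediction)."""
        if sex == "average":
            mu_f, s_f = self.predict(ages, "female", cohort)
            mu_m, s_m = self.predict(ages, "male", cohort)
            return 0.5 * (mu_f + mu_m), 0.5 * (s_f + s_m)
        mu = self._eta(ages, "mu", sex, cohort)
        sigma = np.exp(self._eta(ages, "sigma", sex, cohort))
        return mu, sigma

    def predict_rows(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma) per observation row, including fitted cohort offsets."""
        ages = df["age_years"].to_numpy(dtype=float)
        sex = df["sex"].to_numpy()
        cohorts = df["cohort_id"].to_numpy()
        mu = self._eta(ages, "mu", sex, cohorts)
        sigma = np.exp(self._eta(ages, "sigma", sex, cohorts))
        return mu, sigma

    def median_se(self, ages, sex: str | None = "female") -> np.ndarray:
        """Model-based SE of the fitted population median curve."""
        if self.cov_mu is None:
            raise ValueError("model carries no covariance information")
        ages = np.atleast_1d(np.asarray(ages, dtype=float))
        cols = [np.ones(ages.shape[0])]
        if self.spec_mu.order:
            cols.append(fp_basis(ages, self.spec_mu, self.age_offset))
        if self.mu_sex is not None:
            frac = {"female": 0.0, "male": 1.0, "average": 0.5}[sex or "female"]
            cols.append(np.full((ages.shape[0], 1), frac))
        X = np.column_stack(cols)
        return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov_mu, X), 0.0))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "spec_mu": list(self.spec_mu.powers),
            "spec_sigma": list(self.spec_sigma.powers),
            "age_offset": self.age_offset,
            "mu": {
                "intercept": self.mu_intercept,
                "fp": np.asarray(self.mu_fp).tolist(),
                "sex": self.mu_sex,
                "cohorts": dict(self.mu_cohorts),
            },
            "sigma": {
                "intercept": self.sigma_intercept,
                "fp": np.asarray(self.sigma_fp).tolist(),
                "sex": self.sigma_sex,
                "cohorts": dict(self.sigma_cohorts),
            },
            "tau2_mu": self.tau2_mu,
            "tau2_sigma": self.tau2_sigma,
            "n": self.n,
            "k": self.k,
            "loglik": self.loglik,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "age_range": list(self.age_range),
            "cohort_mode": self.cohort_mode,
            "cov_mu": None if self.cov_mu is None else np.asarray(self.cov_mu).tolist(),
            "tract": self.tract,
            "feature": self.feature,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormativeModel":
        return cls(
            spec_mu=FPSpec(tuple(d["spec_mu"])),
            spec_sigma=FPSpec(tuple(d["spec_sigma"])),
            age_offset=d["age_offset"],
            mu_intercept=d["mu"]["intercept"],
            mu_fp=np.asarray(d["mu"]["fp"], dtype=float),
            mu_sex=d["mu"]["sex"],
            mu_cohorts=dict(d["mu"]["cohorts"]),
            sigma_intercept=d["sigma"]["intercept"],
            sigma_fp=np.asarray(d["sigma"]["fp"], dtype=float),
            sigma_sex=d["sigma"]["sex"],
            sigma_cohorts=dict(d["sigma"]["cohorts"]),
            tau2_mu=d["tau2_mu"],
            tau2_sigma=d["tau2_sigma"],
            n=d["n"],
            k=d["k"],
            loglik=d["loglik"],
            bic=d["bic"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            grad_norm=d["grad_norm"],
            age_range=tuple(d["age_range"]),
            cohort_mode=d["cohort_mode"],
            cov_mu=None if d.get("cov_mu") is None else np.asarray(d["cov_mu"], dtype=float),
            tract=d.get("tract"),
            feature=d.get("feature"),
        )


# ---------------------------------------------------------------------------
# design construction


class _Design:
    """One predictor's design matrix with internal FP-column standardization."""

    def __init__(self, df: pd.DataFrame, spec: FPSpec, options: FitOptions,
                 sex_term: bool, cohorts: list[str], mode: str):
        n = len(df)
        ages = df["age_years"].to_numpy(dtype=float)
        cols: list[np.ndarray] = [np.ones(n)]
        names = ["intercept"]
        if spec.order:
            B = fp_basis(ages, spec, options.age_offset)
            for j in range(spec.order):
                cols.append(B[:, j])
                names.append(f"fp{j}")
        self.n_fp = spec.order
        if sex_term:
            cols.append((df["sex"].to_numpy() == "male").astype(float))
            names.append("sex[male]")
        self.has_sex = sex_term
        self.cohorts = cohorts if mode == "ridge" else (cohorts[1:] if mode == "fixed" else [])
        self.mode = mode
        cohort_col = df["cohort_id"].to_numpy()
        for c in self.cohorts:
            cols.append((cohort_col == c).astype(float))
            names.append(f"cohort[{c}]")
        X = np.column_stack(cols)
        self.names = names
        self.p = X.shape[1]
        self.n_pop = 1 + self.n_fp + (1 if sex_term else 0)
        self.pen_mask = np.zeros(self.p, dtype=bool)
        if mode == "ridge":
            self.pen_mask[self.n_pop:] = True
        # standardize FP columns only
        self.shift = np.zeros(self.p)
        self.scale = np.ones(self.p)
        for j in range(1, 1 + self.n_fp):
            m, s = X[:, j].mean(), X[:, j].std()
            if s == 0 or not np.isfinite(s):
                s = 1.0
            self.shift[j], self.scale[j] = m, s
        self.Xs = (X - self.shift) / self.scale

    def raw_coefs(self, beta_s: np.ndarray) -> np.ndarray:
        beta = beta_s / self.scale
        beta[0] = beta_s[0] - np.sum(beta_s[1:] * self.shift[1:] / self.scale[1:])
        return beta

    def transform(self) -> np.ndarray:
        """Matrix T with beta_raw = T @ beta_scaled."""
        T = np.diag(1.0 / self.scale)
        T[0, 0] = 1.0
        T[0, 1:] = -self.shift[1:] / self.scale[1:]
        return T

    def split(self, beta_raw: np.ndarray):
        i = 1
        fp = beta_raw[i:i + self.n_fp]
        i += self.n_fp
        sex = float(beta_raw[i]) if self.has_sex else None
        i += int(self.has_sex)
        offs = dict(zip(self.cohorts, beta_raw[i:].tolist()))
        return float(beta_raw[0]), fp, sex, offs


def _resolve_modes(df: pd.DataFrame, options: FitOptions) -> tuple[bool, str, list[str]]:
    sexes = sorted(df["sex"].unique())
    if options.sex_term == "auto":
        sex_term = len(sexes) > 1
    else:
        sex_term = bool(options.sex_term)
        if sex_term and len(sexes) < 2:
            raise ValueError("sex term requested but a single sex level is present")
    cohorts = sorted(df["cohort_id"].unique())
    mode = options.cohort_mode
    if mode == "auto":
        mode = "none" if len(cohorts) == 1 else "ridge"
    if mode not in ("ridge", "fixed", "none"):
        raise ValueError(f"unknown cohort_mode {mode!r}")
    return sex_term, mode, cohorts


# ---------------------------------------------------------------------------
# fitting


def _penalized_loglik(y, Xm, beta, Xs_, gamma, lam_m, lam_s, lo, hi) -> tuple[float, float]:
    eta_s = np.clip(Xs_ @ gamma, lo, hi)
    r = y - Xm @ beta
    ll = float(np.sum(-0.5 * np.log(2 * np.pi) - eta_s - 0.5 * r**2 * np.exp(-2 * eta_s)))
    pen = 0.5 * float(np.sum(lam_m * beta**2) + np.sum(lam_s * gamma**2))
    return ll - pen, ll


@dataclass
class _FitState:
    beta: np.ndarray
    gamma: np.ndarray
    pll: float
    ll: float
    converged: bool
    n_iter: int
    grad_norm: float


def _fit_inner(
    y: np.ndarray,
    Xm: np.ndarray,
    Xsg: np.ndarray,
    lam_m: np.ndarray,
    lam_s: np.ndarray,
    options: FitOptions,
    gamma0_jitter: float = 0.0,
) -> _FitState:
    """Alternating WLS / Fisher-scoring ascent of the penalized loglik with
    fixed penalties.  Each sweep is a monotone ascent step (the sigma step
    uses halving), so the penalized loglik is non-decreasing."""
    lo, hi = options.min_log_sigma, options.max_log_sigma
    try:
        beta = np.linalg.lstsq(Xm, y, rcond=None)[0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular mu design") from exc
    r = y - Xm @ beta
    gamma = np.zeros(Xsg.shape[1])
    gamma[0] = 0.5 * np.log(max(float(np.mean(r**2)), 1e-12)) + gamma0_jitter

    H = 2.0 * (Xsg.T @ Xsg) + np.diag(lam_s)
    try:
        H_chol = np.linalg.cholesky(H)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular sigma design") from exc

    pll, _ = _penalized_loglik(y, Xm, beta, Xsg, gamma, lam_m, lam_s, lo, hi)
    converged = False
    n_small = 0
    it = 0
    for it in range(1, options.max_iter + 1):
        eta_s = np.clip(Xsg @ gamma, lo, hi)
        w = np.exp(-2.0 * eta_s)
        A_m = Xm.T @ (Xm * w[:, None]) + np.diag(lam_m)
        try:
            beta = np.linalg.solve(A_m, Xm.T @ (w * y))
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular mu design") from exc
        r = y - Xm @ beta
        # Fisher-scoring step for the log-sigma coefficients, with halving
        g = Xsg.T @ (r**2 * w - 1.0) - lam_s * gamma
        step = np.linalg.solve(H_chol.T, np.linalg.solve(H_chol, g))
        pll_mid, _ = _penalized_loglik(y, Xm, beta, Xsg, gamma, lam_m, lam_s, lo, hi)
        scale = 1.0
        pll_new = pll_mid
        for _ in range(30):
            cand = gamma + scale * step
            cand_pll, _ = _penalized_loglik(y, Xm, beta, Xsg, cand, lam_m, lam_s, lo, hi)
            if cand_pll >= pll_mid - 1e-12:
                gamma, pll_new = cand, cand_pll
                break
            scale *= 0.5
        if abs(pll_new - pll) < options.tol * max(1.0, abs(pll_new) * 1e-2):
            n_small += 1
            if n_small >= 2:
                converged = True
                pll = pll_new
                break
        else:
            n_small = 0
        pll = pll_new

    eta_s = np.clip(Xsg @ gamma, lo, hi)
    w = np.exp(-2.0 * eta_s)
    r = y - Xm @ beta
    g_beta = Xm.T @ (w * r) - lam_m * beta
    g_gamma = Xsg.T @ (r**2 * w - 1.0) - lam_s * gamma
    grad_norm = float(max(np.max(np.abs(g_beta)), np.max(np.abs(g_gamma))))
    _, ll = _penalized_loglik(y, Xm, beta, Xsg, gamma, lam_m, lam_s, lo, hi)
    return _FitState(beta, gamma, pll, ll, converged, it, grad_norm)


def _lambda_vectors(dm: "_Design", ds: "_Design", tau2_mu, tau2_sg):
    lam_m = (
        np.where(dm.pen_mask, 1.0 / tau2_mu, 0.0) if tau2_mu else np.zeros(dm.p)
    )
    lam_s = (
        np.where(ds.pen_mask, 1.0 / tau2_sg, 0.0) if tau2_sg else np.zeros(ds.p)
    )
    return lam_m, lam_s


def _laplace_score(
    y, dm: "_Design", ds: "_Design", state: _FitState, lam_m, lam_s,
    tau2_mu: float, tau2_sg: float, options: FitOptions,
) -> float:
    """Laplace approximation to the marginal log-likelihood of (tau2_mu,
    tau2_sigma) with the cohort offsets integrated out (up to constants)."""
    C = len(dm.cohorts)
    eta_s = np.clip(ds.Xs @ state.gamma, options.min_log_sigma, options.max_log_sigma)
    w = np.exp(-2.0 * eta_s)
    A_m = dm.Xs.T @ (dm.Xs * w[:, None]) + np.diag(lam_m)
    H_s = 2.0 * (ds.Xs.T @ ds.Xs) + np.diag(lam_s)
    sign_m, logdet_m = np.linalg.slogdet(A_m)
    sign_s, logdet_s = np.linalg.slogdet(H_s)
    if sign_m <= 0 or sign_s <= 0:  # pragma: no cover
        return -np.inf
    return (
        state.pll
        - 0.5 * C * (np.log(tau2_mu) + np.log(tau2_sg))
        - 0.5 * (logdet_m + logdet_s)
    )


def _search_tau2(
    y, dm: "_Design", ds: "_Design", options: FitOptions
) -> tuple[float, float]:
    """Two-pass grid search of the penalty variances maximizing the Laplace
    marginal likelihood: tau2_mu first (tau2_sigma anchored at 0.05^2), then
    tau2_sigma at the chosen tau2_mu."""
    grid = tuple(options.tau2_grid)
    fixed_mu = None if options.tau2_mu == "auto" else float(options.tau2_mu)
    fixed_sg = None if options.tau2_sigma == "auto" else float(options.tau2_sigma)

    def score(t_mu: float, t_sg: float) -> float:
        lam_m, lam_s = _lambda_vectors(dm, ds, t_mu, t_sg)
        state = _fit_inner(y, dm.Xs, ds.Xs, lam_m, lam_s, options)
        return _laplace_score(y, dm, ds, state, lam_m, lam_s, t_mu, t_sg, options)

    anchor_sg = fixed_sg if fixed_sg is not None else 0.05**2
    if fixed_mu is None:
        tau2_mu = max(grid, key=lambda t: score(t, anchor_sg))
    else:
        tau2_mu = fixed_mu
    if fixed_sg is None:
        tau2_sg = max(grid, key=lambda t: score(tau2_mu, t))
    else:
        tau2_sg = fixed_sg
    return tau2_mu, tau2_sg


def fit_location_scale(
    observations: pd.DataFrame,
    spec_mu: FPSpec,
    spec_sigma: FPSpec,
    options: FitOptions | None = None,
) -> NormativeModel:
    """Maximum-(penalized-)likelihood fit of the location-scale model.

    ``observations`` is a long table with columns age_years, sex, cohort_id
    and li.  In ridge cohort mode with "auto" penalty variances, tau^2 is
    first selected by the Laplace marginal-likelihood grid search and then
    held fixed for the final fit.  Raises on singular designs and flags
    (rather than hides) non-convergence.
    """
    options = options or FitOptions()
    df = observations
    y = df["li"].to_numpy(dtype=float)
    n = len(y)
    if n == 0:
        raise ValueError("no observations")
    sex_term, mode, cohorts = _resolve_modes(df, options)

    dm = _Design(df, spec_mu, options, sex_term, cohorts, mode)
    ds = _Design(df, spec_sigma, options, sex_term, cohorts, mode)
    k = dm.p + ds.p
    if n <= k:
        raise ValueError(f"n = {n} must exceed the parameter count k = {k}")

    if mode == "ridge":
        if options.tau2_mu == "auto" or options.tau2_sigma == "auto":
            tau2_mu, tau2_sg = _search_tau2(y, dm, ds, options)
        else:
            tau2_mu, tau2_sg = float(options.tau2_mu), float(options.tau2_sigma)
    else:
        tau2_mu = tau2_sg = None
    lam_m, lam_s = _lambda_vectors(dm, ds, tau2_mu, tau2_sg)

    rng = np.random.default_rng(options.seed)
    best: _FitState | None = None
    for attempt in range(1 + options.n_restarts):
        jitter = rng.normal(0.0, 0.5) if attempt else 0.0
        state = _fit_inner(y, dm.Xs, ds.Xs, lam_m, lam_s, options, gamma0_jitter=jitter)
        if best is None or state.pll > best.pll:
            best = state
        if state.converged:
            break

    beta, gamma = best.beta, best.gamma
    ll, converged, n_iter, grad_norm = best.ll, best.converged, best.n_iter, best.grad_norm
    lo, hi = options.min_log_sigma, options.max_log_sigma
    Xm, Xsg = dm.Xs, ds.Xs

    # covariance of the population mu coefficients, back on the raw scale
    eta_s = np.clip(Xsg @ gamma, lo, hi)
    w = np.exp(-2.0 * eta_s)
    A_m = Xm.T @ (Xm * w[:, None]) + np.diag(lam_m)
    try:
        cov_scaled = np.linalg.inv(A_m)
        T = dm.transform()
        cov_raw = T @ cov_scaled @ T.T
        cov_mu = cov_raw[: dm.n_pop, : dm.n_pop]
    except np.linalg.LinAlgError:  # pragma: no cover
        cov_mu = None

    b_raw = dm.raw_coefs(beta.copy())
    g_raw = ds.raw_coefs(gamma.copy())
    mu_icpt, mu_fp, mu_sex, mu_off = dm.split(b_raw)
    sg_icpt, sg_fp, sg_sex, sg_off = ds.split(g_raw)
    ages = df["age_years"].to_numpy(dtype=float)
    bic = -2.0 * ll + k * np.log(n)
    return NormativeModel(
        spec_mu=spec_mu,
        spec_sigma=spec_sigma,
        age_offset=options.age_offset,
        mu_intercept=mu_icpt,
        mu_fp=np.asarray(mu_fp, dtype=float),
        mu_sex=mu_sex,
        mu_cohorts=mu_off,
        sigma_intercept=sg_icpt,
        sigma_fp=np.asarray(sg_fp, dtype=float),
        sigma_sex=sg_sex,
        sigma_cohorts=sg_off,
        tau2_mu=tau2_mu,
        tau2_sigma=tau2_sg,
        n=n,
        k=k,
        loglik=ll,
        bic=float(bic),
        converged=bool(converged),
        n_iter=n_iter,
        grad_norm=grad_norm,
        age_range=(float(ages.min()), float(ages.max())),
        cohort_mode=mode,
        cov_mu=cov_mu,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class SelectionResult:
    """Best model plus the BIC report over every candidate tried."""

    model: NormativeModel
    report: pd.DataFrame


def _candidate_key(m: NormativeModel) -> tuple:
    return (m.bic, m.k, m.spec_mu.powers, m.spec_sigma.powers)


def select_model(
    observations: pd.DataFrame,
    power_set: Sequence[float] = ALLOWED_POWERS,
    max_order: int = 3,
    strategy: str = "staged",
    options: FitOptions | None = None,
    sigma_stage_spec: FPSpec = FPSpec((1.0,)),
) -> SelectionResult:
    """BIC selection over FP specifications for mu and sigma.

    "staged" (default) first selects the mu spec with the sigma spec held at
    ``sigma_stage_spec``, then selects the sigma spec with the chosen mu spec
    frozen.  "full_grid" fits every (mu, sigma) pair — exhaustive but
    quadratic in the candidate count.  Ties break toward fewer parameters,
    then lexicographic spec order.  Raises if no candidate converges.

    With "auto" penalty variances the tau^2 grid search runs once, on the
    ``sigma_stage_spec`` anchor model, and the selected values are held fixed
    across all candidates (tau^2 is a cohort-level nuisance that depends only
    weakly on the age smooth).
    """
    options = options or FitOptions()
    if (options.tau2_mu == "auto" or options.tau2_sigma == "auto"):
        sex_term, mode, cohorts = _resolve_modes(observations, options)
        if mode == "ridge":
            dm = _Design(observations, sigma_stage_spec, options, sex_term, cohorts, mode)
            ds = _Design(observations, sigma_stage_spec, options, sex_term, cohorts, mode)
            y = observations["li"].to_numpy(dtype=float)
            tau2_mu, tau2_sg = _search_tau2(y, dm, ds, options)
            options = replace(options, tau2_mu=tau2_mu, tau2_sigma=tau2_sg)
    specs = enumerate_fp_specs(tuple(power_set), max_order)
    if len(specs) < 2:
        raise ValueError("need at least 2 candidate specifications")
    rows: list[dict] = []

    def _try(sm: FPSpec, ss: FPSpec, stage: str) -> NormativeModel | None:
        try:
            m = fit_location_scale(observations, sm, ss, options)
        except (ValueError, np.linalg.LinAlgError) as exc:
            rows.append({"stage": stage, "spec_mu": str(sm), "spec_sigma": str(ss),
                         "k": np.nan, "loglik": np.nan, "bic": np.nan,
                         "converged": False, "error": str(exc)})
            return None
        rows.append({"stage": stage, "spec_mu": str(sm), "spec_sigma": str(ss),
                     "k": m.k, "loglik": m.loglik, "bic": m.bic,
                     "converged": m.converged, "error": ""})
        return m if m.converged else None

    candidates: list[NormativeModel] = []
    if strategy == "staged":
        stage1 = [m for sm in specs if (m := _try(sm, sigma_stage_spec, "mu")) is not None]
        if not stage1:
            raise RuntimeError("no mu-stage candidate converged")
        best_mu = min(stage1, key=_candidate_key).spec_mu
        stage2 = [m for ss in specs if (m := _try(best_mu, ss, "sigma")) is not None]
        candidates = stage2 or stage1
    elif strategy == "full_grid":
        for sm in specs:
            for ss in specs:
                if (m := _try(sm, ss, "grid")) is not None:
                    candidates.append(m)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if not candidates:
        raise RuntimeError("no candidate specification converged")
    best = min(candidates, key=_candidate_key)
    return SelectionResult(model=best, report=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# charts


@dataclass
class CentileChart:
    """Centile curves of one tract–feature on a dense age grid.

    ``values[i, j]`` is the LI at ``age_grid[i]`` and ``levels[j]`` (levels
    are percentages, strictly increasing).  ``context`` names the covariate
    convention: one sex level or the equal-weight "average"; cohort offsets
    are zero (population chart).
    """

    tract: str
    feature: str
    context: str
    age_grid: np.ndarray
    levels: tuple[float, ...]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.levels = tuple(float(p) for p in self.levels)
        if self.age_grid.ndim != 1 or np.any(np.diff(self.age_grid) <= 0):
            raise ValueError("age_grid must be strictly increasing")
        if list(self.levels) != sorted(self.levels) or not all(
            0 < p < 100 for p in self.levels
        ):
            raise ValueError("levels must be strictly increasing percentages in (0, 100)")
        if self.values.shape != (self.age_grid.size, len(self.levels)):
            raise ValueError("values shape mismatch with age_grid x levels")

    def level_index(self, level: float) -> int:
        diffs = np.abs(np.asarray(self.levels) - level)
        j = int(np.argmin(diffs))
        if diffs[j] > 1e-9:
            raise KeyError(f"chart has no {level} level (has {self.levels})")
        return j

    def median(self) -> np.ndarray:
        return self.values[:, self.level_index(50.0)]


def centile_curves(
    model: NormativeModel,
    age_grid: np.ndarray | None = None,
    levels: Sequence[float] = DEFAULT_LEVELS,
    context: str = "average",
    grid_size: int = 500,
    tract: str | None = None,
    feature: str | None = None,
) -> CentileChart:
    """Population centile chart q_p(age) = mu + sigma * z_p at ``context``.

    The default grid is ``grid_size`` equally spaced points over the fitted
    age range; a grid outside that support is flagged with a warning and in
    the chart metadata.  For the "average" context the two sex-specific
    quantile curves are averaged with equal weight.
    """
    if context not in _CONTEXTS:
        raise ValueError(f"context must be one of {_CONTEXTS}")
    if age_grid is None:
        age_grid = np.linspace(model.age_range[0], model.age_range[1], grid_size)
    age_grid = np.asarray(age_grid, dtype=float)
    if age_grid.size == 0:
        raise ValueError("empty age grid")
    extrapolated = bool(
        age_grid.min() < model.age_range[0] - 1e-9
        or age_grid.max() > model.age_range[1] + 1e-9
    )
    if extrapolated:
        warnings.warn("age grid extends beyond the fitted age support", stacklevel=2)
    z = stats.norm.ppf(np.asarray(levels, dtype=float) / 100.0)
    sexes = ("female", "male") if context == "average" else (context,)
    values = np.zeros((age_grid.size, len(z)))
    for sex in sexes:
        mu, sigma = model.predict(age_grid, sex)
        values += mu[:, None] + sigma[:, None] * z[None, :]
    values /= len(sexes)
    return CentileChart(
        tract=tract or model.tract or "unknown",
        feature=feature or model.feature or "unknown",
        context=context,
        age_grid=age_grid,
        levels=tuple(float(p) for p in levels),
        values=values,
        meta={
            "spec_mu": list(model.spec_mu.powers),
            "spec_sigma": list(model.spec_sigma.powers),
            "bic": model.bic,
            "n": model.n,
            "extrapolated": extrapolated,
        },
    )


def prevalence_right(model: NormativeModel, ages, context: str = "average") -> np.ndarray:
    """Percentage of the population with rightward asymmetry (LI > 0):
    100 * Phi(mu/sigma), sex-averaged for the "average" context."""
    if context not in _CONTEXTS:
        raise ValueError(f"context must be one of {_CONTEXTS}")
    ages = np.atleast_1d(np.asarray(ages, dtype=float))
    sexes = ("female", "male") if context == "average" else (context,)
    out = np.zeros(ages.shape)
    for sex in sexes:
        mu, sigma = model.predict(ages, sex)
        if np.any(sigma <= 0):
            raise ValueError("sigma must be positive")
        out += 100.0 * stats.norm.cdf(mu / sigma)
    return out / len(sexes)
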