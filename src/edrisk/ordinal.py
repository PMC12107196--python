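"""Proportional-odds (cumulative-logit) ordinal regression.

The association between ED presentation characteristics and risk-cluster
membership is quantified with the proportional-odds model

    logit P(Y <= j | x) = theta_j - beta' x,      j = 1..k-1,

with Y the ordinal cluster label (1 = lowest admission risk) and a common
coefficient vector across cut-points. Under this orientation a positive
coefficient — odds ratio exp(beta) above 1 — reads "higher odds of being in
a higher-risk cluster".

Fitting is by full Newton-Raphson on (theta, beta) with analytic gradient
and Hessian and step-halving, so the log-likelihood is non-decreasing across
iterations; Wald 95% intervals come from the observed information. A
simulator from the same model is provided for parameter-recovery and
CI-coverage checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._util import SeparationError, round_half_up

__all__ = [
    "Covariate",
    "DesignSpec",
    "DEFAULT_DESIGN",
    "OrdinalFitResult",
    "build_design",
    "fit_proportional_odds",
    "simulate_proportional_odds",
    "forest_table",
]


@dataclass(frozen=True)
class Covariate:
    """One model term: a continuous column or a categorical with a reference."""

    name: str
    kind: str = "continuous"            # "continuous" | "categorical"
    reference: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name!r} needs a reference level")


@dataclass(frozen=True)
class DesignSpec:
    """Ordered covariate list defining the design matrix columns."""

    covariates: tuple[Covariate, ...]
    outcome: str = "cluster"


#: The standard presentation-characteristics model: demographics, categorised
#: vitals and comorbidity, and prior-six-month encounter counts. Reference
#: levels: female sex, Chinese ethnicity (modal), normal vitals, no
#: comorbidity.
DEFAULT_DESIGN = DesignSpec(covariates=(
    Covariate("age"),
    Covariate("sex", "categorical", "female"),
    Covariate("ethnicity", "categorical", "Chinese"),
    Covariate("sbp_cat", "categorical", "normal"),
    Covariate("pulse_cat", "categorical", "normal"),
    Covariate("temp_cat", "categorical", "normal"),
    Covariate("cci_cat", "categorical", "none"),
    Covariate("prior_ed"),
    Covariate("prior_inpt"),
    Covariate("prior_surg"),
    Covariate("prior_icu"),
    Covariate("prior_hd"),
    Covariate("prior_ica"),
    Covariate("prior_infect"),
))

# Categorical level orderings for deterministic column order.
_LEVEL_ORDER = {
    "sbp_cat": ["hypotension", "normal", "hypertension"],
    "pulse_cat": ["bradycardia", "normal", "tachycardia"],
    "temp_cat": ["hypothermia", "normal", "hyperthermia"],
    "cci_cat": ["none", "mild", "moderate", "severe"],
}


def build_design(records: pd.DataFrame,
                 spec: DesignSpec = DEFAULT_DESIGN) -> tuple[pd.DataFrame, np.ndarray]:
    """Expand records into a design matrix and ordinal outcome vector.

    Categorical covariates become indicator columns ``name[level]`` against
    the configured reference (reference must be observed); continuous
    covariates pass through untransformed. Column order follows the spec,
    levels in their natural clinical order (otherwise alphabetical).
    """
    cols: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        if cov.name not in records.columns:
            raise KeyError(f"covariate {cov.name!r} not in records")
        if cov.kind == "continuous":
            col = records[cov.name].to_numpy(dtype=float)
            if np.all(col == col[0]):
                raise ValueError(f"covariate {cov.name!r} is constant")
            cols[cov.name] = col
        else:
            observed = set(records[cov.name].unique())
            if cov.reference not in observed:
                raise ValueError(
                    f"reference level {cov.reference!r} of {cov.name!r} absent from data"
                )
            order = _LEVEL_ORDER.get(cov.name)
            levels = [l for l in order if l in observed] if order else sorted(observed)
            for level in levels:
                if level == cov.reference:
                    continue
                cols[f"{cov.name}[{level}]"] = (
                    records[cov.name] == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=records.index)
    y = records[spec.outcome].to_numpy(dtype=int)
    return X, y


@dataclass
class OrdinalFitResult:
    """Maximum-likelihood proportional-odds fit."""

    thresholds: np.ndarray                 # theta_j, strictly increasing
    coef: pd.Series                        # beta by design column
    se: pd.Series
    odds_ratios: pd.Series                 # exp(beta)
    ci95: pd.DataFrame                     # columns low, high on the OR scale
    log_likelihood: float
    converged: bool
    n_used: int
    n_iter: int
    grad_norm: float

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds.tolist(),
            "coef": self.coef.to_dict(),
            "se": self.se.to_dict(),
            "odds_ratios": self.odds_ratios.to_dict(),
            "ci95_low": self.ci95["low"].to_dict(),
            "ci95_high": self.ci95["high"].to_dict(),
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "n_used": self.n_used,
            "n_iter": self.n_iter,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _loglik_parts(theta: np.ndarray, beta: np.ndarray, X: np.ndarray, y0: np.ndarray,
                  k: int):
    """Per-observation upper/lower cumulative logistic terms.

    Returns (loglik, p, upper, lower, has_u, has_l) where upper/lower are the
    cumulative probabilities bounding each observation's category.
    """
    eta = X @ beta
    has_u = y0 < k - 1          # category below the top -> theta_{y} defined
    has_l = y0 > 0              # category above the bottom
    upper = np.ones(len(y0))
    lower = np.zeros(len(y0))
    upper[has_u] = expit(theta[y0[has_u]] - eta[has_u])
    lower[has_l] = expit(theta[y0[has_l] - 1] - eta[has_l])
    p = upper - lower
    if np.any(p <= 0):
        return -np.inf, p, upper, lower, has_u, has_l
    return float(np.log(p).sum()), p, upper, lower, has_u, has_l


def _score_info(theta, beta, X, y0, k):
    """Log-likelihood, gradient and Hessian of the cumulative-logit model."""
    q = k - 1
    p_dim = X.shape[1]
    ll, p, upper, lower, has_u, has_l = _loglik_parts(theta, beta, X, y0, k)
    if not np.isfinite(ll):
        return ll, None, None

    g_u = np.where(has_u, upper * (1.0 - upper), 0.0)
    g_l = np.where(has_l, lower * (1.0 - lower), 0.0)
    gp_u = g_u * (1.0 - 2.0 * upper)
    gp_l = g_l * (1.0 - 2.0 * lower)

    du = g_u / p
    dl = g_l / p

    grad = np.zeros(q + p_dim)
    np.add.at(grad, y0[has_u], du[has_u])
    np.add.at(grad, y0[has_l] - 1, -dl[has_l])
    deta = -(du - dl)                       # dL/deta per observation
    grad[q:] = X.T @ deta

    # Hessian blocks in the z = theta - eta parametrisation
    H_uu = np.where(has_u, gp_u / p - du**2, 0.0)
    H_ll = np.where(has_l, -gp_l / p - dl**2, 0.0)
    H_ul = np.where(has_u & has_l, g_u * g_l / p**2, 0.0)

    H = np.zeros((q + p_dim, q + p_dim))
    np.add.at(H, (y0[has_u], y0[has_u]), H_uu[has_u])
    np.add.at(H, (y0[has_l] - 1, y0[has_l] - 1), H_ll[has_l])
    both = has_u & has_l
    np.add.at(H, (y0[both], y0[both] - 1), H_ul[both])
    np.add.at(H, (y0[both] - 1, y0[both]), H_ul[both])

    w_u = -(H_uu + H_ul)                    # d2L/dtheta_u dbeta weights
    w_l = -(H_ll + H_ul)
    cross = np.zeros((q, p_dim))
    for j in range(q):
        m_u = has_u & (y0 == j)
        m_l = has_l & (y0 - 1 == j)
        if m_u.any():
            cross[j] += w_u[m_u] @ X[m_u]
        if m_l.any():
            cross[j] += w_l[m_l] @ X[m_l]
    H[:q, q:] = cross
    H[q:, :q] = cross.T

    w_bb = H_uu + H_ll + 2.0 * H_ul
    H[q:, q:] = (X * w_bb[:, None]).T @ X
    return ll, grad, H


def fit_proportional_odds(X, y, tol: float = 1e-8,
                          max_iter: int = 100) -> OrdinalFitResult:
    """Maximum-likelihood fit of the proportional-odds model.

    Newton-Raphson with step-halving (halve until the log-likelihood does
    not decrease and the thresholds stay strictly increasing); convergence
    when the gradient's max-norm drops below ``tol * max(1, |loglik|)`` —
    the scaling keeps the criterion attainable at large n, where float
    accumulation noise in a likelihood of magnitude 1e5 exceeds an absolute
    1e-8. Diverging coefficients
    (|beta| or |theta| beyond 30) raise :class:`SeparationError`. Wald 95%
    CIs are exp(beta +/- 1.96 se).
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])]
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y)
    levels = np.unique(y)
    k = len(levels)
    if k < 2:
        raise ValueError("outcome needs at least 2 observed levels")
    y0 = np.searchsorted(levels, y)
    n, p_dim = Xa.shape
    q = k - 1

    cum = np.cumsum(np.bincount(y0, minlength=k))[:-1] / n
    theta = logit(cum)
    beta = np.zeros(p_dim)

    ll, grad, H = _score_info(theta, beta, Xa, y0, k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.max(np.abs(grad)))
        if gnorm < tol * max(1.0, abs(ll)):
            converged = True
            break
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, -grad, rcond=None)[0]
        # step-halving: keep the likelihood non-decreasing and theta ordered
        scale = 1.0
        for _ in range(40):
            theta_new = theta + scale * step[:q]
            beta_new = beta + scale * step[q:]
            if np.all(np.diff(theta_new) > 0) or q == 1:
                ll_new, grad_new, H_new = _score_info(theta_new, beta_new, Xa, y0, k)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
            scale /= 2.0
        else:
            break  # no acceptable step; report unconverged
        theta, beta, ll, grad, H = theta_new, beta_new, ll_new, grad_new, H_new
        if np.max(np.abs(beta)) > 30 or np.max(np.abs(theta)) > 30:
            raise SeparationError(
                "diverging coefficients; data appear separated by a covariate"
            )
    gnorm = float(np.max(np.abs(grad)))
    if gnorm < tol * max(1.0, abs(ll)):
        converged = True

    cov = np.linalg.inv(-H)
    se_all = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    se = pd.Series(se_all[q:], index=names)
    coef = pd.Series(beta, index=names)
    ors = np.exp(coef)
    ci = pd.DataFrame({
        "low": np.exp(coef - 1.96 * se),
        "high": np.exp(coef + 1.96 * se),
    }, index=names)
    return OrdinalFitResult(
        thresholds=theta, coef=coef, se=se, odds_ratios=ors, ci95=ci,
        log_likelihood=ll, converged=converged, n_used=n, n_iter=it,
        grad_norm=gnorm,
    )


def simulate_proportional_odds(X, beta, thresholds, seed=None) -> np.ndarray:
    """Draw ordinal outcomes 1..k from the proportional-odds model.

    Used for parameter-recovery and CI-coverage simulations: with design X,
    coefficients beta and strictly increasing cut-points theta (length k-1),
    categories are drawn from the cumulative probabilities
    P(Y <= j) = expit(theta_j - X beta).
    """
    rng = np.random.default_rng(seed)
    Xa = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    theta = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(theta) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    eta = Xa @ beta
    cum = expit(theta[None, :] - eta[:, None])          # (n, k-1)
    u = rng.random(len(eta))
    return (u[:, None] > cum).sum(axis=1) + 1


def forest_table(result: OrdinalFitResult) -> pd.DataFrame:
    """Odds-ratio report rows (covariate, OR, CI low, CI high), 2 decimals.

    Rows follow the design-column order; refuses an unconverged fit.
    """
    if not result.converged:
        raise ValueError("refusing to tabulate an unconverged fit")
    return pd.DataFrame({
        "covariate": result.coef.index,
        "or": [round_half_up(v, 2) for v in result.odds_ratios],
        "ci_low": [round_half_up(v, 2) for v in result.ci95["low"]],
        "ci_high": [round_half_up(v, 2) for v in result.ci95["high"]],
    })
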