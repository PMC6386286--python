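"""Collapse repeated measures to one age-adjusted score per individual.

Repeated phenotype measurements taken at varying ages are summarized by
a random-intercept linear mixed model

    y_ij = beta0 + beta1 * (age_ij - mean age) + b_i + e_ij,

with b_i ~ N(0, sigma_b^2) and e_ij ~ N(0, sigma_e^2).  The individual
score is beta0 + BLUP(b_i): an age-typical phenotype level that uses
every visit while regressing out the age trend.  Age is centred at the
sample mean so the intercept is not an extrapolation to age zero.

Variance components are estimated by REML, profiling the likelihood on
the variance ratio theta = sigma_b^2 / sigma_e^2; for a given theta the
GLS fixed effects and sigma_e^2 have closed forms via per-individual
sufficient statistics (Woodbury identity on the exchangeable
within-individual covariance), leaving a one-dimensional search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .simulate import LONGITUDINAL_COLUMNS

__all__ = ["AdjustedScores", "fit_random_intercept", "adjust_phenotypes", "derive_ldl"]


@dataclass
class AdjustedScores:
    """Per-individual age-adjusted scores and the mixed-model estimates."""

    phenotype: str
    scores: pd.Series            # indexed by individual_id
    intercept: float             # fixed intercept at the centring age
    age_slope: float
    intercept_variance: float    # sigma_b^2
    residual_variance: float     # sigma_e^2
    age_center: float
    n_individuals: int
    n_observations: int

    def __post_init__(self) -> None:
        if self.intercept_variance < 0 or self.residual_variance < 0:
            raise ValueError("variance estimates must be non-negative")


def _group_stats(ids: np.ndarray, x: np.ndarray, y: np.ndarray):
    """Per-individual counts and sums needed by the profiled REML."""
    order = np.argsort(ids, kind="stable")
    ids, x, y = ids[order], x[order], y[order]
    uniq, start = np.unique(ids, return_index=True)
    n_i = np.diff(np.append(start, ids.size))
    return uniq, start, n_i, x, y


def _profiled_reml(theta, n_i, starts, x, y):
    """REML criterion and GLS quantities at variance ratio theta.

    V_i = I + theta * J, so V_i^-1 = I - theta/(1 + n_i theta) * J.
    """
    shrink = theta / (1.0 + n_i * theta)          # per individual
    xtx = np.zeros((2, 2))
    xty = np.zeros(2)
    # design: [1, x]
    sum1 = n_i.astype(float)
    ends = np.append(starts[1:], x.size)
    sx = np.add.reduceat(x, starts)
    sy = np.add.reduceat(y, starts)
    sxx = np.add.reduceat(x * x, starts)
    sxy = np.add.reduceat(x * y, starts)
    syy = np.add.reduceat(y * y, starts)
    del ends
    xtx[0, 0] = np.sum(sum1 - shrink * sum1**2)
    xtx[0, 1] = xtx[1, 0] = np.sum(sx - shrink * sum1 * sx)
    xtx[1, 1] = np.sum(sxx - shrink * sx**2)
    xty[0] = np.sum(sy - shrink * sum1 * sy)
    xty[1] = np.sum(sxy - shrink * sx * sy)
    beta = np.linalg.solve(xtx, xty)
    # weighted residual sum of squares r' V^-1 r via the same group sums
    r_sq = (syy - 2.0 * beta[0] * sy - 2.0 * beta[1] * sxy
            + beta[0] ** 2 * sum1 + 2.0 * beta[0] * beta[1] * sx
            + beta[1] ** 2 * sxx)
    r_sum = sy - beta[0] * sum1 - beta[1] * sx
    rss = float(np.sum(r_sq - shrink * r_sum**2))
    n_total = x.size
    sigma_e2 = max(rss / max(n_total - 2, 1), 0.0)
    logdet_v = float(np.sum(np.log1p(n_i * theta)))
    sign, logdet_xtx = np.linalg.slogdet(xtx)
    crit = ((n_total - 2) * np.log(max(sigma_e2, 1e-300))
            + logdet_v + logdet_xtx)
    return crit, beta, sigma_e2, (sy, sum1, sx)


def fit_random_intercept(table: pd.DataFrame, phenotype_name: str) -> AdjustedScores:
    """Fit the random-intercept model and return per-individual scores.

    The score is beta0 + b_hat_i, with the empirical BLUP
    b_hat_i = (theta n_i / (1 + n_i theta)) * mean residual of
    individual i.  Individuals observed once are retained with shrunken
    scores.
    """
    missing = [c for c in LONGITUDINAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"longitudinal table lacks columns {missing}")
    sub = table[table["phenotype"] == phenotype_name].dropna(subset=["value"])
    if sub.empty:
        available = sorted(table["phenotype"].unique())
        raise ValueError(
            f"phenotype {phenotype_name!r} not present; available: {available}"
        )
    ages = sub["age"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    y_raw = sub["value"].to_numpy(dtype=float)
    if float(np.var(y_raw)) == 0.0:
        raise ValueError(
            f"phenotype {phenotype_name!r} has zero total variance; "
            "nothing to model"
        )
    ids = sub["individual_id"].to_numpy()
    if np.unique(ids).size < 2:
        raise ValueError("need at least two individuals")

    age_center = float(ages.mean())
    uniq, starts, n_i, x, y = _group_stats(ids, ages - age_center, y_raw)

    def crit(log_theta: float) -> float:
        return _profiled_reml(np.exp(log_theta), n_i, starts, x, y)[0]

    # profile over log(theta); also consider the theta -> 0 boundary
    res = optimize.minimize_scalar(crit, bounds=(-25.0, 25.0), method="bounded")
    candidates = [np.exp(res.x), 1e-12]
    best_theta = min(candidates,
                     key=lambda t: _profiled_reml(t, n_i, starts, x, y)[0])
    _, beta, sigma_e2, (sy, sum1, sx) = _profiled_reml(
        best_theta, n_i, starts, x, y)
    if best_theta <= 1e-12:
        best_theta = 0.0
    sigma_b2 = best_theta * sigma_e2

    mean_resid = (sy - beta[0] * sum1 - beta[1] * sx) / sum1
    blup = (best_theta * sum1 / (1.0 + sum1 * best_theta)) * mean_resid
    scores = pd.Series(beta[0] + blup, index=pd.Index(uniq, name="individual_id"),
                       name=phenotype_name)

    return AdjustedScores(
        phenotype=phenotype_name,
        scores=scores,
        intercept=float(beta[0]),
        age_slope=float(beta[1]),
        intercept_variance=float(sigma_b2),
        residual_variance=float(sigma_e2),
        age_center=age_center,
        n_individuals=int(uniq.size),
        n_observations=int(x.size),
    )


def adjust_phenotypes(table: pd.DataFrame,
                      phenotypes: list[str] | None = None) -> pd.DataFrame:
    """Wide per-individual score table, one column per phenotype."""
    if phenotypes is None:
        phenotypes = sorted(table["phenotype"].unique())
    cols = {ph: fit_random_intercept(table, ph).scores for ph in phenotypes}
    return pd.DataFrame(cols)


def derive_ldl(tc, hdl):
    """LDL cholesterol from total and HDL cholesterol (mmol/L).

    LDL-C = 3/4 (TC - HDL-C).  Negative results are returned as-is for
    the caller to filter.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    if not (np.all(np.isfinite(tc)) and np.all(np.isfinite(hdl))):
        raise ValueError("inputs must be finite")
    out = 0.75 * (tc - hdl)
    return float(out) if out.ndim == 0 else out
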