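"""Model fitting, standardization and likelihood-ratio comparison.

The FIML objective is minimized over the free parameters with a
quasi-Newton optimizer (L-BFGS-B, numerically estimated gradients) from
documented data-driven starts, with an optional multi-start safeguard.
Variance components are unbounded: a negative shared-environment
variance is a legitimate estimate in the classical twin model (it
signals a DZ correlation below half the MZ correlation) and is reported
rather than clipped.

Phenotypes are rescaled to approximate unit variance before
optimization and all estimates are mapped back to the original units;
the -2 log-likelihood is reported on the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ..dataset import TwinPairDataset, ZYGOSITIES
from .covariance import ModelStructureError, implied_moments, _reduced_form
from .likelihood import NotPositiveDefiniteError, _grouped, negloglik, negloglik_grouped
from .spec import SemSpec

__all__ = [
    "FitResult",
    "ModelComparison",
    "fit",
    "standardize",
    "variance_shares",
    "standardized_components",
    "lrt",
    "compare_table",
    "standard_errors",
]

_PENALTY = 1e12


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit."""

    spec: SemSpec
    minus2ll: float
    n_free: int
    df: int                       # non-missing data points minus free parameters
    converged: bool
    n_observed_values: int
    data_fingerprint: str
    diagnostics: dict = field(default_factory=dict)


@dataclass
class ModelComparison:
    """Likelihood-ratio comparison of a nested model against a fuller one."""

    diff_ll: float
    diff_df: int
    p: float


# ---------------------------------------------------------------------------
# rescaling between measurement units


def _anchor_rows(spec: SemSpec) -> list[int]:
    """Per factor, the indicator row that sets the latent scale.

    The anchor is the first phenotype with a non-free, nonzero loading
    (the unit-fixed loading in identified models).
    """
    free_loading_pos = {
        idx for par in spec.free if par.slot == "loadings" for idx in par.indices
    }
    anchors = []
    for f in range(spec.n_factors):
        fixed = [r for r in range(spec.n_phenotypes)
                 if spec.loadings[r, f] != 0.0 and (r, f) not in free_loading_pos]
        if not fixed:
            raise ValueError(
                f"factor {spec.factors[f]!r} has no fixed nonzero loading to "
                "anchor its scale"
            )
        anchors.append(fixed[0])
    return anchors


def rescale_spec(spec: SemSpec, s: np.ndarray) -> SemSpec:
    """Map a spec for data ``y'`` onto one for ``y = s * y'``.

    Latent factors are rescaled through their anchor indicators, so
    unit-fixed loadings stay at unity and the free-parameter structure
    is preserved exactly.
    """
    s = np.asarray(s, dtype=float)
    new = spec.copy()
    sf = s[_anchor_rows(spec)] if spec.n_factors else np.empty(0)
    new.loadings = spec.loadings * s[:, None] / sf[None, :]
    new.paths = spec.paths * sf[:, None] / sf[None, :]
    outer = np.outer(sf, sf)
    new.latent_a = spec.latent_a * outer
    new.latent_c = spec.latent_c * outer
    new.latent_e = spec.latent_e * outer
    new.specific_a = spec.specific_a * s**2
    new.specific_c = spec.specific_c * s**2
    new.specific_e = spec.specific_e * s**2
    new.means = spec.means * s
    return new


def _pooled_person_frame(data: TwinPairDataset) -> pd.DataFrame:
    """Stack twin-1 and twin-2 blocks into one person-level frame."""
    p = len(data.phenotypes)
    stacked = np.vstack([data.values[:, :p], data.values[:, p:]])
    return pd.DataFrame(stacked, columns=data.phenotypes)


def _auto_start(spec: SemSpec, data: TwinPairDataset) -> SemSpec:
    """Data-driven start values.

    Means start at sample means; free latent A/C/E entries split the
    sample (co)variance of the factors' anchor indicators equally across
    the three components (across six shares when specific variances are
    also estimated); specific variances take a sixth of the phenotype
    variance; loadings and causal paths keep their constructed starts
    (unity and zero respectively).
    """
    persons = _pooled_person_frame(data)
    sample_mean = persons.mean().to_numpy()
    sample_cov = persons.cov().to_numpy()
    sample_cov = np.where(np.isfinite(sample_cov), sample_cov, 0.0)
    anchors = _anchor_rows(spec) if spec.n_factors else []
    has_specific = any(par.slot.startswith("specific") for par in spec.free)
    latent_frac = 1.0 / 6.0 if has_specific else 1.0 / 3.0

    new = spec.copy()
    values = new.free_values()
    for j, par in enumerate(new.free):
        if par.slot == "means":
            values[j] = sample_mean[par.indices[0][0]]
        elif par.slot.startswith("latent"):
            i, l = par.indices[0]
            values[j] = latent_frac * sample_cov[anchors[i], anchors[l]]
        elif par.slot.startswith("specific"):
            r = par.indices[0][0]
            values[j] = sample_cov[r, r] / 6.0
    return new.with_free_values(values)


# ---------------------------------------------------------------------------
# fitting


def fit(
    spec: SemSpec,
    data: TwinPairDataset,
    *,
    start: str = "auto",
    rescale: bool = True,
    n_starts: int = 1,
    jitter: float = 0.1,
    seed: int = 0,
    maxiter: int = 5000,
    require_both_zygosities: bool = True,
) -> FitResult:
    """Minimize the FIML -2 log-likelihood over the free parameters.

    Parameters
    ----------
    start
        ``"auto"`` (data-driven starts, the default) or ``"spec"`` to
        start from the values already stored in ``spec``.
    n_starts
        Number of optimizer starts; starts beyond the first perturb the
        start vector with Gaussian jitter (SD ``jitter`` on the
        unit-variance working scale) and the best optimum is kept.
    """
    data = data.drop_empty()
    if data.n_pairs == 0:
        raise ValueError("no usable twin pairs")
    if require_both_zygosities:
        for zyg in ZYGOSITIES:
            if not np.any(data.zygosity == zyg):
                raise ValueError(f"no usable pairs in zygosity group {zyg}")

    p = len(data.phenotypes)
    if rescale:
        persons = _pooled_person_frame(data)
        s = persons.std(ddof=1).to_numpy()
        s = np.where(np.isfinite(s) & (s > 0), s, 1.0)
    else:
        s = np.ones(p)
    sdata = TwinPairDataset(data.phenotypes,
                            data.values / np.tile(s, 2),
                            data.zygosity)

    spec0 = rescale_spec(spec, 1.0 / s)
    if start == "auto":
        spec0 = _auto_start(spec0, sdata)
    elif start != "spec":
        raise ValueError("start must be 'auto' or 'spec'")

    work = spec0.copy()
    refs = [(getattr(work, par.slot), par.indices) for par in work.free]
    groups = _grouped(sdata)  # missingness patterns are data-only: group once

    def objective(x: np.ndarray) -> float:
        for v, (arr, idxs) in zip(x, refs):
            for idx in idxs:
                arr[idx] = v
        try:
            return negloglik_grouped(work, groups)
        except (NotPositiveDefiniteError, ModelStructureError):
            # smooth-ish penalty pointing back toward the feasible region
            return _PENALTY * (1.0 + float(np.sum(x**2)))

    x0 = spec0.free_values()
    rng = np.random.default_rng(seed)
    best = None
    for i in range(max(1, n_starts)):
        xi = x0 if i == 0 else x0 + rng.normal(0.0, jitter, x0.shape)
        res = optimize.minimize(
            objective, xi, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res

    converged = bool(best.success) and np.isfinite(best.fun) and best.fun < _PENALTY
    spec_scaled = spec0.with_free_values(best.x)

    # -2LL back on the original measurement scale: each observed value of
    # phenotype r contributes 2*log(s_r) through the change of variables.
    col_scales = np.tile(s, 2)
    n_obs_col = np.isfinite(data.values).sum(axis=0)
    minus2ll = float(best.fun + 2.0 * np.sum(n_obs_col * np.log(col_scales)))

    spec_est = rescale_spec(spec_scaled, s)
    n_obs = data.n_observed_values
    return FitResult(
        spec=spec_est,
        minus2ll=minus2ll,
        n_free=spec.n_free,
        df=n_obs - spec.n_free,
        converged=converged,
        n_observed_values=n_obs,
        data_fingerprint=data.fingerprint(),
        diagnostics={
            "message": str(best.message),
            "n_iterations": int(best.nit),
            "n_starts": max(1, n_starts),
            "objective_scaled": float(best.fun),
            "scales": s,
        },
    )


# ---------------------------------------------------------------------------
# standardization


def _as_spec(fit_or_spec) -> SemSpec:
    if isinstance(fit_or_spec, FitResult):
        if not fit_or_spec.converged:
            raise ValueError("refusing to standardize a non-converged fit")
        return fit_or_spec.spec
    return fit_or_spec


def standardize(fit_or_spec) -> SemSpec:
    """Rescale so every latent and observed variable has unit variance.

    Returns a spec with the same free-parameter structure whose implied
    correlation structure is identical to the input's.
    """
    spec = _as_spec(fit_or_spec)
    iib = _reduced_form(spec)
    lat_cov = iib @ (spec.latent_a + spec.latent_c + spec.latent_e) @ iib.T
    d_f = np.sqrt(np.diag(lat_cov)) if spec.n_factors else np.empty(0)
    total = spec.loadings @ lat_cov @ spec.loadings.T + np.diag(
        spec.specific_a + spec.specific_c + spec.specific_e
    )
    d_p = np.sqrt(np.diag(total))
    if np.any(~np.isfinite(d_p)) or np.any(d_p <= 0) or (
        spec.n_factors and (np.any(~np.isfinite(d_f)) or np.any(d_f <= 0))
    ):
        raise ValueError("cannot standardize: some implied variance is not positive")

    new = spec.copy()
    new.loadings = spec.loadings * d_f[None, :] / d_p[:, None]
    if spec.n_factors:
        new.paths = spec.paths / d_f[:, None] * d_f[None, :]
        inv_outer = np.outer(1.0 / d_f, 1.0 / d_f)
        new.latent_a = spec.latent_a * inv_outer
        new.latent_c = spec.latent_c * inv_outer
        new.latent_e = spec.latent_e * inv_outer
    new.specific_a = spec.specific_a / d_p**2
    new.specific_c = spec.specific_c / d_p**2
    new.specific_e = spec.specific_e / d_p**2
    new.means = spec.means / d_p
    return new


def _component_matrices(spec: SemSpec) -> dict[str, np.ndarray]:
    iib = _reduced_form(spec)
    lam = spec.loadings
    out = {}
    for comp, latent, specific in (
        ("A", spec.latent_a, spec.specific_a),
        ("C", spec.latent_c, spec.specific_c),
        ("E", spec.latent_e, spec.specific_e),
    ):
        out[comp] = lam @ iib @ latent @ iib.T @ lam.T + np.diag(specific)
    return out


def variance_shares(fit_or_spec) -> pd.DataFrame:
    """Per-phenotype A/C/E variance shares (sum to one by construction)."""
    spec = _as_spec(fit_or_spec)
    comps = _component_matrices(spec)
    total = np.diag(comps["A"] + comps["C"] + comps["E"])
    if np.any(total <= 0):
        raise ValueError("non-positive implied phenotypic variance")
    return pd.DataFrame(
        {"a2": np.diag(comps["A"]) / total,
         "c2": np.diag(comps["C"]) / total,
         "e2": np.diag(comps["E"]) / total},
        index=pd.Index(spec.phenotypes, name="phenotype"),
    )


def standardized_components(fit_or_spec) -> dict[str, pd.DataFrame]:
    """Phenotypically standardized A/C/E covariance matrices.

    Diagonals are variance shares; the three matrices sum to the implied
    phenotypic correlation matrix.
    """
    spec = _as_spec(fit_or_spec)
    comps = _component_matrices(spec)
    d = np.sqrt(np.diag(comps["A"] + comps["C"] + comps["E"]))
    scale = np.outer(d, d)
    idx = pd.Index(spec.phenotypes, name="phenotype")
    return {
        comp: pd.DataFrame(mat / scale, index=idx, columns=spec.phenotypes)
        for comp, mat in comps.items()
    }


# ---------------------------------------------------------------------------
# model comparison


def lrt(full: FitResult, nested: FitResult) -> ModelComparison:
    """Likelihood-ratio test of a nested model against the full model.

    The -2LL difference is floored at zero (optimizer noise can leave the
    nested optimum fractionally below the full one when a dropped
    parameter was already at its boundary).
    """
    if full.data_fingerprint != nested.data_fingerprint:
        raise ValueError("fits were obtained on different data")
    diff_df = full.n_free - nested.n_free
    if diff_df < 1:
        raise ValueError("nested model must have fewer free parameters")
    diff_ll = max(0.0, nested.minus2ll - full.minus2ll)
    return ModelComparison(diff_ll=diff_ll, diff_df=diff_df,
                           p=float(stats.chi2.sf(diff_ll, diff_df)))


def compare_table(full: FitResult, nested: dict[str, FitResult]) -> pd.DataFrame:
    """Model-comparison table: one row for the full model, one per drop."""
    rows = [{
        "test": "full model", "ep": full.n_free, "-2LL": full.minus2ll,
        "df": full.df, "diff LL": np.nan, "diff df": np.nan, "p": np.nan,
    }]
    for label, res in nested.items():
        cmp_ = lrt(full, res)
        rows.append({
            "test": label, "ep": res.n_free, "-2LL": res.minus2ll, "df": res.df,
            "diff LL": cmp_.diff_ll, "diff df": cmp_.diff_df, "p": cmp_.p,
        })
    return pd.DataFrame(rows)


def standard_errors(result: FitResult, data: TwinPairDataset,
                    step: float = 1e-4) -> pd.DataFrame:
    """Wald standard errors from the observed information matrix.

    Central-difference Hessian of the -2LL at the optimum; flags weak
    identification (near-singular information) instead of failing.
    """
    spec = result.spec
    x_hat = spec.free_values()
    h = step * np.maximum(1.0, np.abs(x_hat))

    def f(x: np.ndarray) -> float:
        return negloglik(spec.with_free_values(x), data)

    m = x_hat.size
    hess = np.empty((m, m))
    f0 = f(x_hat)
    fp = np.empty(m)
    fm = np.empty(m)
    for i in range(m):
        e = np.zeros(m); e[i] = h[i]
        fp[i] = f(x_hat + e)
        fm[i] = f(x_hat - e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(m):
        for j in range(i + 1, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = f(x_hat + ei + ej)
            fmm = f(x_hat - ei - ej)
            hess[i, j] = hess[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])

    info = 0.5 * hess  # observed information of the log-likelihood
    cond = np.linalg.cond(info)
    weak = not np.isfinite(cond) or cond > 1e10
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = np.where(se > 0, x_hat / se, np.nan)
    out = pd.DataFrame({
        "estimate": x_hat, "se": se, "z": z,
        "p": 2.0 * stats.norm.sf(np.abs(z)),
    }, index=pd.Index(spec.labels, name="parameter"))
    out.attrs["weak_identification"] = bool(weak)
    out.attrs["information_condition_number"] = float(cond)
    return out
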