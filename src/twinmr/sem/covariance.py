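"""Implied moment structure of the twin SEM.

The latent factors follow the nonrecursive structural system
``eta = B eta + zeta`` with innovation covariance split into A + C + E
components, so the reduced-form latent covariance involves
``(I - B)^-1``.  Cross-twin covariance uses the classical twin design:
additive-genetic latents correlate 1 across MZ co-twins and 0.5 across
DZ co-twins, shared-environment latents correlate 1, nonshared 0; the
same correlations apply to the phenotype-specific components.
"""

from __future__ import annotations

import numpy as np

from .spec import SemSpec

__all__ = ["GENETIC_CORRELATION", "implied_covariance", "implied_moments"]

#: additive-genetic cross-twin correlation by zygosity
GENETIC_CORRELATION = {"MZ": 1.0, "DZ": 0.5}


class ModelStructureError(ValueError):
    """The spec implies no valid covariance structure."""


def _check_zygosity(zygosity: str) -> float:
    try:
        return GENETIC_CORRELATION[zygosity]
    except KeyError:
        raise ModelStructureError(
            f"unknown zygosity {zygosity!r}; expected 'MZ' or 'DZ'"
        ) from None


def _reduced_form(spec: SemSpec) -> np.ndarray:
    """(I - B)^-1, rejecting non-invertible structural systems."""
    k = spec.n_factors
    b = spec.paths
    if k and np.max(np.abs(np.linalg.eigvals(b))) >= 1.0 - 1e-12:
        raise ModelStructureError(
            "causal-path matrix has spectral radius >= 1; the reciprocal "
            "system has no stable reduced form"
        )
    try:
        return np.linalg.inv(np.eye(k) - b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
        raise ModelStructureError("I - B is singular") from exc


def implied_moments(spec: SemSpec, zygosity: str) -> tuple[np.ndarray, np.ndarray]:
    """Implied 2p mean vector and 2p x 2p covariance for a twin pair.

    Phenotypes are ordered twin-1 block then twin-2 block.
    """
    r_a = _check_zygosity(zygosity)
    iib = _reduced_form(spec)
    lam = spec.loadings

    within_lat = iib @ (spec.latent_a + spec.latent_c + spec.latent_e) @ iib.T
    cross_lat = iib @ (r_a * spec.latent_a + spec.latent_c) @ iib.T

    within = lam @ within_lat @ lam.T + np.diag(
        spec.specific_a + spec.specific_c + spec.specific_e
    )
    cross = lam @ cross_lat @ lam.T + np.diag(
        r_a * spec.specific_a + spec.specific_c
    )

    cov = np.block([[within, cross], [cross.T, within.T]])
    cov = 0.5 * (cov + cov.T)
    mean = np.concatenate([spec.means, spec.means])
    return mean, cov


def implied_covariance(spec: SemSpec, zygosity: str) -> np.ndarray:
    """Implied 2p x 2p phenotypic covariance matrix for a twin pair."""
    return implied_moments(spec, zygosity)[1]
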