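"""Full-information maximum-likelihood (FIML) objective for twin pairs.

Each pair contributes the multivariate-normal log-density of its
*observed* entries only, with the implied mean and covariance subset to
the pair's missingness pattern — no listwise deletion.  Pairs are
grouped by (zygosity, pattern) so the per-pattern Cholesky factor is
reused across pairs, which keeps the objective fast enough for
numerical-gradient optimization.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import cholesky, solve_triangular, LinAlgError

from ..dataset import TwinPairDataset, ZYGOSITIES
from .covariance import implied_moments
from .spec import SemSpec

__all__ = ["negloglik", "NotPositiveDefiniteError"]

_LOG2PI = math.log(2.0 * math.pi)


class NotPositiveDefiniteError(ValueError):
    """Implied covariance (possibly pattern-subset) is not positive definite."""


def _pattern_groups(values: np.ndarray):
    """Yield (observed-column index array, data block) per missingness pattern."""
    mask = np.isfinite(values)
    if mask.all():  # fast path: complete data
        yield np.arange(values.shape[1]), values
        return
    keys, inverse = np.unique(mask, axis=0, return_inverse=True)
    for g, key in enumerate(keys):
        if not key.any():
            continue  # fully missing pair contributes nothing
        rows = values[inverse == g]
        cols = np.flatnonzero(key)
        yield cols, rows[:, cols]


def _grouped(data: TwinPairDataset):
    """Precomputed (zygosity, observed columns, data block) groups."""
    out = []
    for zyg in ZYGOSITIES:
        values = data.subset(zyg)
        if values.size == 0:
            continue
        for cols, block in _pattern_groups(values):
            out.append((zyg, cols, np.ascontiguousarray(block)))
    return out


def negloglik(spec: SemSpec, data: TwinPairDataset) -> float:
    """-2 log-likelihood of the raw pair data under the spec."""
    if list(data.phenotypes) != list(spec.phenotypes):
        raise ValueError(
            "dataset phenotypes do not match spec phenotypes: "
            f"{data.phenotypes} vs {spec.phenotypes}"
        )
    return negloglik_grouped(spec, _grouped(data))


def negloglik_grouped(spec: SemSpec, groups) -> float:
    """-2LL over pre-grouped missingness patterns (hot path for fitting)."""
    total = 0.0
    moments = {}
    for zyg, cols, block in groups:
        if zyg not in moments:
            moments[zyg] = implied_moments(spec, zyg)
        mean, cov = moments[zyg]
        sub = cov[np.ix_(cols, cols)]
        try:
            chol = cholesky(sub, lower=True, check_finite=False)
        except LinAlgError as exc:
            raise NotPositiveDefiniteError(
                f"implied covariance not positive definite for zygosity "
                f"{zyg}, observed positions {cols.tolist()}"
            ) from exc
        centred = block - mean[cols]
        z = solve_triangular(chol, centred.T, lower=True, check_finite=False)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        m = cols.size
        total += block.shape[0] * (m * _LOG2PI + logdet) + np.einsum(
            "ij,ij->", z, z
        )
    return float(total)
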