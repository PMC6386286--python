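"""Synthetic data generators.

Three generators stand in for the data sources this kind of analysis
draws on: MZ/DZ twin-pair phenotypes drawn from the moment structure of
any :class:`~twinmr.sem.spec.SemSpec`; longitudinal visit tables with a
linear age trend and individual random intercepts; and paired
exposure/outcome GWAS summary-statistic tables under a controlled causal
effect with optional (directional or balanced) pleiotropy.

All randomness flows through a single ``numpy.random.default_rng``
(PCG64) stream per call, fully determined by the config seed, so
identical configs reproduce identical data byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import TwinPairDataset
from .sem.covariance import implied_moments
from .sem.spec import SemSpec

__all__ = [
    "TwinSimConfig",
    "MRSimConfig",
    "simulate_twin_dataset",
    "simulate_longitudinal",
    "simulate_mr_summary",
    "GWAS_COLUMNS",
    "LONGITUDINAL_COLUMNS",
]

GWAS_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se",
                "pval", "samplesize"]
LONGITUDINAL_COLUMNS = ["individual_id", "pair_id", "zygosity", "age",
                        "phenotype", "value"]


@dataclass
class TwinSimConfig:
    """Twin-pair simulation settings.

    Defaults mirror a large adult twin registry: 1909 MZ and 1994 DZ
    pairs.
    """

    spec: SemSpec
    n_mz: int = 1909
    n_dz: int = 1994
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 0 or self.n_dz < 0:
            raise ValueError("pair counts must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        self.spec.validate()


@dataclass
class MRSimConfig:
    """Two-sample GWAS summary-statistic simulation settings.

    ``causal_effect`` is the true slope of the outcome on the exposure;
    SNPs in the ``invalid_fraction`` receive pleiotropic outcome effects
    drawn from Normal(pleiotropy_mean, pleiotropy_sd).  Default SE
    magnitudes (0.01) are typical of meta-GWAS with hundreds of
    thousands of samples.
    """

    n_snps: int = 50
    causal_effect: float = 0.0
    exposure_beta_loc: float = 0.3
    exposure_beta_scale: float = 0.1
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    exposure_se: float = 0.01
    outcome_se: float = 0.01
    invalid_fraction: float = 0.0
    samplesize: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("need at least one SNP")
        if self.exposure_se <= 0 or self.outcome_se <= 0:
            raise ValueError("SEs must be positive")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0, 1]")


def _safe_cholesky(cov: np.ndarray, zygosity: str) -> np.ndarray:
    eigmin = float(np.linalg.eigvalsh(cov).min())
    if eigmin < -1e-10 * max(1.0, float(np.abs(cov).max())):
        raise ValueError(
            f"implied covariance for zygosity {zygosity} is not positive "
            f"definite (min eigenvalue {eigmin:.3g})"
        )
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        # PSD up to rounding: nudge onto the cone
        return np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))


def simulate_twin_dataset(config: TwinSimConfig) -> TwinPairDataset:
    """Draw twin pairs from the model-implied MZ/DZ moment structure.

    Equivalent to simulating the latent A/C/E variables with their twin
    cross-correlations (1 for MZ genetics, 0.5 for DZ, 1 for shared and
    0 for nonshared environment) and pushing them through the structural
    system; drawing directly from the implied 2p-variate normal gives
    identical distributions.  Missingness is applied completely at
    random, element-wise.
    """
    rng = np.random.default_rng(config.seed)
    spec = config.spec
    p2 = 2 * spec.n_phenotypes
    blocks, zygs = [], []
    for zyg, n in (("MZ", config.n_mz), ("DZ", config.n_dz)):
        mean, cov = implied_moments(spec, zyg)
        chol = _safe_cholesky(cov, zyg)
        z = rng.standard_normal((n, p2))
        blocks.append(mean + z @ chol.T)
        zygs.extend([zyg] * n)
    values = np.vstack(blocks) if blocks else np.empty((0, p2))
    if config.missing_rate > 0.0:
        mask = rng.random(values.shape) < config.missing_rate
        values = np.where(mask, np.nan, values)
    return TwinPairDataset(list(spec.phenotypes), values, np.array(zygs, dtype=object))


def simulate_longitudinal(
    n_individuals: int,
    visits_per_individual: int,
    age_slope: float,
    intercept_sd: float,
    residual_sd: float,
    seed: int = 0,
    *,
    population_intercept: float = 0.0,
    phenotype_name: str = "phenotype",
    baseline_age_range: tuple[float, float] = (40.0, 60.0),
    followup_years: float = 17.0,
) -> pd.DataFrame:
    """Visit-level table with a linear age effect and random intercepts.

    value = population_intercept + individual_intercept + age_slope*age
    + residual noise.  Individuals are paired consecutively (pairs
    alternate MZ/DZ) so the table satisfies the twin-structure layout.
    """
    if visits_per_individual < 1:
        raise ValueError("need at least one visit per individual")
    if intercept_sd < 0 or residual_sd < 0:
        raise ValueError("SDs must be non-negative")
    rng = np.random.default_rng(seed)
    lo, hi = baseline_age_range
    rows = []
    intercepts = rng.normal(0.0, intercept_sd, n_individuals)
    for i in range(n_individuals):
        pair = i // 2
        zyg = "MZ" if pair % 2 == 0 else "DZ"
        base = rng.uniform(lo, hi)
        offsets = np.sort(rng.uniform(0.0, followup_years, visits_per_individual))
        offsets[0] = 0.0
        for off in offsets:
            age = base + off
            value = (population_intercept + intercepts[i] + age_slope * age
                     + rng.normal(0.0, residual_sd))
            rows.append((f"ind{i:05d}", f"pair{pair:05d}", zyg, age,
                         phenotype_name, value))
    return pd.DataFrame(rows, columns=LONGITUDINAL_COLUMNS)


_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def simulate_mr_summary(
    config: MRSimConfig, *, palindromic: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired exposure/outcome GWAS summary tables.

    Per SNP j: true outcome effect = causal_effect * true exposure
    effect + pleiotropy_j (nonzero only for the invalid fraction);
    observed betas add Normal noise with SD equal to the reported SE.
    Alleles are emitted identically in both tables (A/G, or A/T when
    ``palindromic`` is requested) so harmonization is the identity
    unless the caller scrambles them.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    snp = np.array([f"rs{j + 1:07d}" for j in range(n)])
    eaf = rng.uniform(0.05, 0.95, n)
    ea, oa = ("A", "T") if palindromic else ("A", "G")

    true_bx = rng.normal(config.exposure_beta_loc, config.exposure_beta_scale, n)
    n_invalid = int(round(config.invalid_fraction * n))
    invalid = rng.choice(n, size=n_invalid, replace=False)
    pleio = np.zeros(n)
    pleio[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd,
                                n_invalid)
    bx = true_bx + rng.normal(0.0, config.exposure_se, n)
    by = config.causal_effect * true_bx + pleio + rng.normal(
        0.0, config.outcome_se, n)

    def table(beta: np.ndarray, se: float) -> pd.DataFrame:
        se_arr = np.full(n, se)
        return pd.DataFrame({
            "SNP": snp, "effect_allele": ea, "other_allele": oa, "eaf": eaf,
            "beta": beta, "se": se_arr,
            "pval": 2.0 * stats.norm.sf(np.abs(beta) / se_arr),
            "samplesize": config.samplesize,
        })

    return table(bx, config.exposure_se), table(by, config.outcome_se)
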