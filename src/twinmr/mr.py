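"""Two-sample Mendelian randomization from GWAS summary statistics.

Implements the standard estimator suite: per-SNP Wald ratios,
inverse-variance-weighted (IVW) regression through the origin with
fixed or multiplicative-random-effect standard errors, MR-Egger
regression (slope and pleiotropy intercept), the weighted mode of the
ratio-estimate density, Cochran's Q heterogeneity statistic,
leave-one-out sensitivity estimates, and the per-SNP table behind
forest/funnel displays — together with summary-statistic harmonization
and greedy LD clumping.

Ratio variances use the first-order delta method throughout.  P-values
are two-sided: normal for Wald/IVW/mode, Student t with n_snps - 2
degrees of freedom for MR-Egger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MREstimate",
    "HarmonizedMRData",
    "harmonize",
    "clump",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_mode",
    "cochran_q",
    "leave_one_out",
    "single_snp_table",
    "validate_gwas_table",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
GWAS_COLUMNS = ["SNP", "effect_allele", "other_allele", "eaf", "beta", "se",
                "pval", "samplesize"]


def validate_gwas_table(df: pd.DataFrame, name: str = "table") -> None:
    missing = [c for c in GWAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{name} lacks columns {missing}")
    if df.empty:
        raise ValueError(f"{name} is empty")
    if df["SNP"].duplicated().any():
        dups = df.loc[df["SNP"].duplicated(), "SNP"].tolist()
        raise ValueError(f"{name} has duplicated SNP ids: {dups}")
    if (df["se"] <= 0).any():
        raise ValueError(f"{name} has non-positive standard errors")
    bad = ~df["effect_allele"].isin(_COMPLEMENT) | ~df["other_allele"].isin(_COMPLEMENT)
    if bad.any():
        raise ValueError(
            f"{name} has non-ACGT alleles for SNPs {df.loc[bad, 'SNP'].tolist()}"
        )


@dataclass
class MREstimate:
    """A single MR effect estimate."""

    method: str
    b: float
    se: float
    p: float
    n_snps: int


@dataclass
class HarmonizedMRData:
    """Per-SNP aligned exposure/outcome effects ready for estimation.

    ``data`` has one row per SNP surviving harmonization with columns
    SNP, effect_allele, other_allele, eaf_exposure, eaf_outcome,
    beta_exposure, se_exposure, beta_outcome, se_outcome.  ``log``
    records every flip and drop.
    """

    data: pd.DataFrame
    log: list[dict] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.data)

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Reconstruct aligned exposure and outcome summary tables."""
        d = self.data
        common = {"SNP": d["SNP"], "effect_allele": d["effect_allele"],
                  "other_allele": d["other_allele"]}
        exposure = pd.DataFrame({
            **common, "eaf": d["eaf_exposure"], "beta": d["beta_exposure"],
            "se": d["se_exposure"],
            "pval": 2.0 * stats.norm.sf(np.abs(d["beta_exposure"] / d["se_exposure"])),
            "samplesize": d.get("samplesize_exposure", np.nan),
        })
        outcome = pd.DataFrame({
            **common, "eaf": d["eaf_outcome"], "beta": d["beta_outcome"],
            "se": d["se_outcome"],
            "pval": 2.0 * stats.norm.sf(np.abs(d["beta_outcome"] / d["se_outcome"])),
            "samplesize": d.get("samplesize_outcome", np.nan),
        })
        return exposure.reset_index(drop=True), outcome.reset_index(drop=True)


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    palindromic_policy: str = "infer",
    ambiguous_eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedMRData:
    """Align outcome effects to the exposure's effect allele.

    SNPs present in both tables are matched; when the outcome's alleles
    are swapped relative to the exposure the outcome beta sign is
    flipped (and its frequency complemented); strand flips
    (complementary but non-palindromic coding) are resolved by
    complementing.  Palindromic SNPs (A/T, C/G) are handled per policy:

    - ``"infer"`` (default): use allele frequency — keep when both
      frequencies fall clearly on the same or on opposite sides of 0.5
      (flipping in the latter case), drop when either is inside the
      ambiguous window around 0.5;
    - ``"drop"``: drop all palindromic SNPs;
    - ``"keep"``: align by allele letters, trusting the strand.

    Irreconcilable allele pairs are dropped with a logged reason.
    """
    if palindromic_policy not in ("infer", "drop", "keep"):
        raise ValueError("palindromic_policy must be 'infer', 'drop' or 'keep'")
    validate_gwas_table(exposure, "exposure")
    validate_gwas_table(outcome, "outcome")
    lo, hi = ambiguous_eaf_window

    merged = exposure.merge(outcome, on="SNP", suffixes=("_exp", "_out"))
    log: list[dict] = []
    rows: list[dict] = []
    for rec in merged.itertuples(index=False):
        ea_x = rec.effect_allele_exp.upper()
        oa_x = rec.other_allele_exp.upper()
        ea_y = rec.effect_allele_out.upper()
        oa_y = rec.other_allele_out.upper()
        beta_y, eaf_y = float(rec.beta_out), float(rec.eaf_out)

        if _is_palindromic(ea_x, oa_x):
            if palindromic_policy == "drop":
                log.append({"SNP": rec.SNP, "action": "drop",
                            "reason": "palindromic"})
                continue
            if {ea_y, oa_y} != {ea_x, oa_x}:
                log.append({"SNP": rec.SNP, "action": "drop",
                            "reason": "irreconcilable alleles"})
                continue
            if palindromic_policy == "infer":
                eaf_x = float(rec.eaf_exp)
                if lo <= eaf_x <= hi or lo <= eaf_y <= hi:
                    log.append({"SNP": rec.SNP, "action": "drop",
                                "reason": "palindromic, frequency ambiguous"})
                    continue
                same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
                if not same_side:
                    beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                    log.append({"SNP": rec.SNP, "action": "flip",
                                "reason": "palindromic, frequency-inferred strand"})
            else:  # keep: align by letters
                if ea_y == oa_x and oa_y == ea_x:
                    beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                    log.append({"SNP": rec.SNP, "action": "flip",
                                "reason": "swapped alleles"})
        else:
            flipped_strand = False
            if {ea_y, oa_y} != {ea_x, oa_x}:
                ea_y2 = _COMPLEMENT[ea_y]
                oa_y2 = _COMPLEMENT[oa_y]
                if {ea_y2, oa_y2} == {ea_x, oa_x}:
                    ea_y, oa_y = ea_y2, oa_y2
                    flipped_strand = True
                else:
                    log.append({"SNP": rec.SNP, "action": "drop",
                                "reason": "irreconcilable alleles"})
                    continue
            if ea_y == ea_x and oa_y == oa_x:
                if flipped_strand:
                    log.append({"SNP": rec.SNP, "action": "strand",
                                "reason": "complementary coding"})
            else:  # swapped
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                log.append({"SNP": rec.SNP, "action": "flip",
                            "reason": "swapped alleles"})

        rows.append({
            "SNP": rec.SNP, "effect_allele": ea_x, "other_allele": oa_x,
            "eaf_exposure": float(rec.eaf_exp), "eaf_outcome": eaf_y,
            "beta_exposure": float(rec.beta_exp),
            "se_exposure": float(rec.se_exp),
            "beta_outcome": beta_y, "se_outcome": float(rec.se_out),
            "samplesize_exposure": rec.samplesize_exp,
            "samplesize_outcome": rec.samplesize_out,
        })
    return HarmonizedMRData(pd.DataFrame(rows), log)


def clump(table: pd.DataFrame, ld: pd.DataFrame,
          r2_threshold: float = 0.001) -> pd.DataFrame:
    """Greedy LD pruning: keep the smallest-p SNP, drop its LD partners.

    ``ld`` is a square r-squared matrix indexed by SNP id (symmetric,
    unit diagonal) covering every SNP in ``table``.
    """
    validate_gwas_table(table, "table")
    snps = table["SNP"].tolist()
    missing = [s for s in snps
               if s not in ld.index or s not in ld.columns]
    if missing:
        raise ValueError(f"LD matrix lacks entries for SNPs {missing}")
    sub = ld.loc[snps, snps].to_numpy(dtype=float)
    if not np.allclose(sub, sub.T) or not np.allclose(np.diag(sub), 1.0):
        raise ValueError("LD matrix must be symmetric with unit diagonal")

    order = table.sort_values(["pval", "SNP"], kind="stable")["SNP"].tolist()
    pos = {s: i for i, s in enumerate(snps)}
    retained: list[str] = []
    dropped: set[str] = set()
    for s in order:
        if s in dropped:
            continue
        retained.append(s)
        r2 = sub[pos[s]]
        for other in order:
            if other != s and other not in dropped and r2[pos[other]] >= r2_threshold:
                dropped.add(other)
    keep = set(retained)
    return table[table["SNP"].isin(keep)].reset_index(drop=True)


# ---------------------------------------------------------------------------
# estimators


def _ratios(data: HarmonizedMRData) -> tuple[np.ndarray, np.ndarray]:
    d = data.data
    bx = d["beta_exposure"].to_numpy(dtype=float)
    if np.any(bx == 0.0):
        raise ValueError("zero exposure beta: ratio undefined")
    ratio = d["beta_outcome"].to_numpy(dtype=float) / bx
    ratio_se = d["se_outcome"].to_numpy(dtype=float) / np.abs(bx)
    return ratio, ratio_se


def wald_ratio(beta_exposure: float, beta_outcome: float,
               se_outcome: float) -> MREstimate:
    """Single-instrument causal estimate b_out / b_exp.

    SE by the first-order delta method: se_out / |b_exp|.
    """
    if beta_exposure == 0.0:
        raise ValueError("exposure beta is zero: Wald ratio undefined")
    b = beta_outcome / beta_exposure
    se = se_outcome / abs(beta_exposure)
    z = b / se
    return MREstimate("wald", float(b), float(se),
                      float(2.0 * stats.norm.sf(abs(z))), 1)


def ivw(data: HarmonizedMRData, mode: str = "fixed") -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights 1/se_out^2.  ``mode="multiplicative_random"``
    inflates the SE by the residual scale (floored at 1);
    ``mode="fixed"`` uses unit scale.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError("mode must be 'fixed' or 'multiplicative_random'")
    d = data.data
    if len(d) < 2:
        raise ValueError("IVW needs at least 2 SNPs; use wald_ratio for one")
    bx = d["beta_exposure"].to_numpy(dtype=float)
    by = d["beta_outcome"].to_numpy(dtype=float)
    w = 1.0 / d["se_outcome"].to_numpy(dtype=float) ** 2
    sxx = np.sum(w * bx * bx)
    b = np.sum(w * bx * by) / sxx
    se = np.sqrt(1.0 / sxx)
    if mode == "multiplicative_random":
        sigma2 = np.sum(w * (by - b * bx) ** 2) / (len(d) - 1)
        se *= np.sqrt(max(1.0, sigma2))
    z = b / se
    label = "ivw_fe" if mode == "fixed" else "ivw_mre"
    return MREstimate(label, float(b), float(se),
                      float(2.0 * stats.norm.sf(abs(z))), len(d))


def egger(data: HarmonizedMRData) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression: (slope, intercept) estimates.

    Each SNP is oriented so its exposure beta is non-negative (the
    outcome beta flips with it), then outcome betas are regressed on
    exposure betas with a free intercept, weights 1/se_out^2.  A nonzero
    intercept indicates directional horizontal pleiotropy.  SEs carry
    multiplicative residual inflation floored at 1; p-values are from
    the t distribution with n_snps - 2 df.
    """
    d = data.data
    n = len(d)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    bx = d["beta_exposure"].to_numpy(dtype=float)
    by = d["beta_outcome"].to_numpy(dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sign, by * sign
    w = 1.0 / d["se_outcome"].to_numpy(dtype=float) ** 2

    x_mat = np.column_stack([np.ones(n), bx])
    xtwx = x_mat.T @ (w[:, None] * x_mat)
    coef = np.linalg.solve(xtwx, x_mat.T @ (w * by))
    resid = by - x_mat @ coef
    sigma2 = float(np.sum(w * resid**2) / (n - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    ses = np.sqrt(np.diag(cov))
    tvals = coef / ses
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - 2)
    slope = MREstimate("egger_slope", float(coef[1]), float(ses[1]),
                       float(pvals[1]), n)
    intercept = MREstimate("egger_intercept", float(coef[0]), float(ses[0]),
                           float(pvals[0]), n)
    return slope, intercept


def _mode_of_ratios(ratio: np.ndarray, weights: np.ndarray, h: float,
                    grid_size: int = 2048) -> float:
    """Argmax of the weighted normal-kernel density over the ratios."""
    lo = ratio.min() - 3.0 * h
    hi = ratio.max() + 3.0 * h
    grid = np.linspace(lo, hi, grid_size)
    dens = np.sum(
        weights[:, None] * np.exp(-0.5 * ((grid[None, :] - ratio[:, None]) / h) ** 2),
        axis=0,
    )
    return float(grid[np.argmax(dens)])


def _mode_bandwidth(ratio: np.ndarray, phi: float) -> float:
    """Modified-Silverman bandwidth: 0.9 phi min(sd, mad) n^(-1/5)."""
    sd = float(np.std(ratio, ddof=1))
    mad = float(stats.median_abs_deviation(ratio, scale="normal"))
    s = 0.9 * min(sd, mad) / len(ratio) ** 0.2
    return max(1e-8, phi * s)


def weighted_mode(data: HarmonizedMRData, phi: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-mode estimator: mode of the ratio-estimate density.

    Per-SNP Wald ratios are smoothed with a normal kernel (bandwidth =
    phi times the modified-Silverman scale of the ratios) under
    inverse-variance weights; the estimate is the density's argmax.
    Consistent as long as the largest weight-share of instruments is
    valid, even if most are not.  The SE is the standard deviation of
    the estimator over ``n_boot`` parametric-bootstrap resamples drawn
    from Normal(ratio_i, se_i), seeded deterministically.
    """
    if phi <= 0:
        raise ValueError("phi must be positive")
    if n_boot < 1:
        raise ValueError("n_boot must be at least 1")
    if data.n_snps < 3:
        raise ValueError("weighted mode needs at least 3 SNPs")
    ratio, ratio_se = _ratios(data)
    weights = ratio_se**-2
    weights = weights / weights.sum()

    if np.allclose(ratio, ratio[0]):
        b = float(ratio[0])
    else:
        b = _mode_of_ratios(ratio, weights, _mode_bandwidth(ratio, phi))

    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        r_star = rng.normal(ratio, ratio_se)
        if np.allclose(r_star, r_star[0]):
            boots[i] = r_star[0]
        else:
            boots[i] = _mode_of_ratios(r_star, weights,
                                       _mode_bandwidth(r_star, phi))
    se = float(np.std(boots, ddof=1)) if n_boot > 1 else float("nan")
    z = b / se if se > 0 else np.inf * np.sign(b)
    return MREstimate("weighted_mode", b, se,
                      float(2.0 * stats.norm.sf(abs(z))), data.n_snps)


def cochran_q(data: HarmonizedMRData) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity of the per-SNP ratio estimates."""
    if data.n_snps < 2:
        raise ValueError("Q needs at least 2 SNPs")
    ratio, ratio_se = _ratios(data)
    w = ratio_se**-2
    b_ivw = float(np.sum(w * ratio) / np.sum(w))
    q = float(np.sum(w * (ratio - b_ivw) ** 2))
    df = data.n_snps - 1
    return q, df, float(stats.chi2.sf(q, df))


def leave_one_out(data: HarmonizedMRData) -> pd.DataFrame:
    """Fixed-effect IVW estimate with each SNP omitted in turn.

    One row per omitted SNP (ordered by SNP id) plus an ``All`` row
    with the full-sample estimate.
    """
    if data.n_snps < 3:
        raise ValueError("leave-one-out needs at least 3 SNPs")
    rows = []
    order = data.data.sort_values("SNP")
    for snp in order["SNP"]:
        rest = HarmonizedMRData(data.data[data.data["SNP"] != snp], [])
        est = ivw(rest, mode="fixed")
        rows.append({"SNP": snp, "b": est.b, "se": est.se, "p": est.p,
                     "n_snps": est.n_snps})
    full = ivw(data, mode="fixed")
    rows.append({"SNP": "All", "b": full.b, "se": full.se, "p": full.p,
                 "n_snps": full.n_snps})
    return pd.DataFrame(rows)


def single_snp_table(data: HarmonizedMRData) -> pd.DataFrame:
    """Per-SNP Wald estimates with CI bounds and inverse SE.

    The underlying numbers of forest (b with 95% CI) and funnel (b
    against 1/se) displays, plus IVW and MR-Egger summary rows when
    enough SNPs are available.
    """
    if data.n_snps < 1:
        raise ValueError("no SNPs survived harmonization; nothing to tabulate")
    rows = []
    for rec in data.data.sort_values("SNP").itertuples(index=False):
        est = wald_ratio(rec.beta_exposure, rec.beta_outcome, rec.se_outcome)
        rows.append({"SNP": rec.SNP, "method": "wald", "b": est.b, "se": est.se,
                     "p": est.p})
    if data.n_snps >= 2:
        est = ivw(data, mode="fixed")
        rows.append({"SNP": "All", "method": est.method, "b": est.b,
                     "se": est.se, "p": est.p})
    if data.n_snps >= 3:
        slope, _ = egger(data)
        rows.append({"SNP": "All", "method": slope.method, "b": slope.b,
                     "se": slope.se, "p": slope.p})
    out = pd.DataFrame(rows)
    out["ci_low"] = out["b"] - 1.959963984540054 * out["se"]
    out["ci_high"] = out["b"] + 1.959963984540054 * out["se"]
    out["inv_se"] = 1.0 / out["se"]
    return out
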