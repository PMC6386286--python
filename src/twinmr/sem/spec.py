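"""Twin structural-equation model specification.

A :class:`SemSpec` fully parameterizes a latent-factor twin model:

* a p x k loading matrix mapping k latent factors onto p observed
  phenotypes (the measurement model),
* a k x k matrix ``paths`` of causal paths among the latent factors
  (zero diagonal; reciprocal pairs of paths are allowed, making the
  latent system nonrecursive),
* diagonal-free symmetric k x k additive-genetic (A), shared-environment
  (C) and nonshared-environment (E) covariance matrices for the latent
  factor innovations,
* per-phenotype specific A/C/E variances,
* phenotype means, equated across co-twins and zygosity groups.

Free parameters are tracked explicitly as labelled entries so models can
be nested by fixing single parameters to zero and compared by likelihood
ratio.  Two builders cover the analyses this package targets: a
direction-of-causation (DoC) model with one latent factor per trait
domain, and a saturated ACE model estimating full A/C/E covariance
matrices directly.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

__all__ = [
    "Parameter",
    "SemSpec",
    "build_doc_model",
    "build_saturated_ace",
    "drop_parameter",
    "bonferroni",
]

#: matrix slot names a free parameter may live in
_SLOTS = (
    "loadings",
    "paths",
    "latent_a",
    "latent_c",
    "latent_e",
    "specific_a",
    "specific_c",
    "specific_e",
    "means",
)

_SYMMETRIC_SLOTS = ("latent_a", "latent_c", "latent_e")


@dataclass(frozen=True)
class Parameter:
    """A single labelled free parameter.

    ``indices`` lists every matrix position tied to this parameter (a
    symmetric off-diagonal element occupies two positions).
    """

    label: str
    slot: str
    indices: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if self.slot not in _SLOTS:
            raise ValueError(f"unknown matrix slot {self.slot!r}")


@dataclass
class SemSpec:
    """Full parameterization of a latent-factor twin SEM."""

    phenotypes: list[str]
    factors: list[str]
    loadings: np.ndarray          # (p, k)
    paths: np.ndarray             # (k, k), zero diagonal
    latent_a: np.ndarray          # (k, k) symmetric
    latent_c: np.ndarray
    latent_e: np.ndarray
    specific_a: np.ndarray        # (p,)
    specific_c: np.ndarray
    specific_e: np.ndarray
    means: np.ndarray             # (p,)
    free: list[Parameter] = field(default_factory=list)

    # -- basic introspection -------------------------------------------------
    @property
    def n_phenotypes(self) -> int:
        return len(self.phenotypes)

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_free(self) -> int:
        return len(self.free)

    @property
    def labels(self) -> list[str]:
        return [par.label for par in self.free]

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.paths = np.asarray(self.paths, dtype=float)
        self.latent_a = np.asarray(self.latent_a, dtype=float)
        self.latent_c = np.asarray(self.latent_c, dtype=float)
        self.latent_e = np.asarray(self.latent_e, dtype=float)
        self.specific_a = np.asarray(self.specific_a, dtype=float)
        self.specific_c = np.asarray(self.specific_c, dtype=float)
        self.specific_e = np.asarray(self.specific_e, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.validate()

    def validate(self) -> None:
        p, k = self.n_phenotypes, self.n_factors
        if len(set(self.phenotypes)) != p:
            raise ValueError("phenotype names must be distinct")
        if len(set(self.factors)) != k:
            raise ValueError("factor names must be distinct")
        shapes = {
            "loadings": (p, k),
            "paths": (k, k),
            "latent_a": (k, k),
            "latent_c": (k, k),
            "latent_e": (k, k),
            "specific_a": (p,),
            "specific_c": (p,),
            "specific_e": (p,),
            "means": (p,),
        }
        for slot, shape in shapes.items():
            arr = getattr(self, slot)
            if arr.shape != shape:
                raise ValueError(f"{slot} has shape {arr.shape}, expected {shape}")
        if np.any(np.diag(self.paths) != 0.0):
            raise ValueError("causal-path matrix must have zero diagonal")
        for slot in _SYMMETRIC_SLOTS:
            arr = getattr(self, slot)
            if not np.allclose(arr, arr.T):
                raise ValueError(f"{slot} must be symmetric")
        seen_labels: set[str] = set()
        seen_pos: set[tuple] = set()
        for par in self.free:
            if par.label in seen_labels:
                raise ValueError(f"duplicate free-parameter label {par.label!r}")
            seen_labels.add(par.label)
            for idx in par.indices:
                key = (par.slot, idx)
                if key in seen_pos:
                    raise ValueError(
                        f"position {key} claimed by more than one free parameter"
                    )
                seen_pos.add(key)

    # -- free-parameter vector interface ------------------------------------
    def free_values(self) -> np.ndarray:
        """Current values of the free parameters, in ``free`` order."""
        out = np.empty(self.n_free)
        for j, par in enumerate(self.free):
            out[j] = getattr(self, par.slot)[par.indices[0]]
        return out

    def with_free_values(self, values: np.ndarray) -> "SemSpec":
        """Copy of the spec with the free parameters set to ``values``."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_free,):
            raise ValueError(f"expected {self.n_free} values, got {values.shape}")
        new = self.copy()
        for val, par in zip(values, new.free):
            arr = getattr(new, par.slot)
            for idx in par.indices:
                arr[idx] = val
        return new

    def copy(self) -> "SemSpec":
        return _copy.deepcopy(self)

    def parameter(self, label: str) -> Parameter:
        for par in self.free:
            if par.label == label:
                return par
        raise KeyError(
            f"no free parameter labelled {label!r}; available: {sorted(self.labels)}"
        )


def _sym_indices(i: int, j: int) -> tuple[tuple[int, int], ...]:
    return ((i, j),) if i == j else ((i, j), (j, i))


def build_doc_model(
    metabolite_names: list[str],
    lipid_names: list[str],
    bmd_names: list[str],
) -> SemSpec:
    """Full reciprocal-causation (direction-of-causation) model.

    One latent factor per trait domain: metabolites (3 indicators),
    lipids (2) and BMD (2).  The first loading of each factor is fixed to
    unity for identification, leaving 4 free loadings; all 6 directed
    paths among the 3 factors are free; the latent factors carry free
    diagonal A/C/E variances (9); each phenotype carries free specific
    A/C/E variances (21) and a free mean (7) — 47 free parameters.
    """
    if len(metabolite_names) != 3 or len(lipid_names) != 2 or len(bmd_names) != 2:
        raise ValueError("expected 3 metabolite, 2 lipid and 2 BMD phenotype names")
    phenotypes = list(metabolite_names) + list(lipid_names) + list(bmd_names)
    if len(set(phenotypes)) != 7:
        raise ValueError("phenotype names must be distinct")
    factors = ["metabolites", "lipids", "bmd"]
    p, k = 7, 3
    members = {0: [0, 1, 2], 1: [3, 4], 2: [5, 6]}

    loadings = np.zeros((p, k))
    free: list[Parameter] = []
    for f, rows in members.items():
        loadings[rows[0], f] = 1.0  # identification: first loading fixed at unity
        for r in rows[1:]:
            loadings[r, f] = 1.0
            free.append(
                Parameter(f"loading[{phenotypes[r]}~{factors[f]}]", "loadings", ((r, f),))
            )

    paths = np.zeros((k, k))
    for src in range(k):
        for dst in range(k):
            if src == dst:
                continue
            free.append(
                Parameter(f"path[{factors[src]}->{factors[dst]}]", "paths", ((dst, src),))
            )

    latent = {c: np.full(k, 1.0 / 3.0) for c in "ACE"}
    for comp in "ACE":
        for f in range(k):
            free.append(
                Parameter(f"latent_{comp}[{factors[f]}]", f"latent_{comp.lower()}",
                          ((f, f),))
            )

    for comp in "ACE":
        for r in range(p):
            free.append(
                Parameter(f"specific_{comp}[{phenotypes[r]}]",
                          f"specific_{comp.lower()}", ((r,),))
            )
    for r in range(p):
        free.append(Parameter(f"mean[{phenotypes[r]}]", "means", ((r,),)))

    return SemSpec(
        phenotypes=phenotypes,
        factors=factors,
        loadings=loadings,
        paths=paths,
        latent_a=np.diag(latent["A"]),
        latent_c=np.diag(latent["C"]),
        latent_e=np.diag(latent["E"]),
        specific_a=np.full(p, 1.0 / 6.0),
        specific_c=np.full(p, 1.0 / 6.0),
        specific_e=np.full(p, 1.0 / 6.0),
        means=np.zeros(p),
        free=free,
    )


def build_saturated_ace(phenotype_names: list[str]) -> SemSpec:
    """Saturated multivariate ACE model.

    Full symmetric A, C and E covariance matrices among the p phenotypes
    are estimated directly (3 * p(p+1)/2 covariance parameters) plus p
    means equated across co-twins and zygosity.  Represented as an
    identity measurement model (one "latent" per phenotype, no causal
    paths, specific variances fixed at zero).
    """
    phenotypes = list(phenotype_names)
    p = len(phenotypes)
    if p < 1:
        raise ValueError("need at least one phenotype")
    if len(set(phenotypes)) != p:
        raise ValueError("phenotype names must be distinct")
    free: list[Parameter] = []
    for comp in "ACE":
        for i in range(p):
            for j in range(i, p):
                lab = (f"{comp}[{phenotypes[i]}]" if i == j
                       else f"{comp}[{phenotypes[i]},{phenotypes[j]}]")
                free.append(Parameter(lab, f"latent_{comp.lower()}", _sym_indices(i, j)))
    for r in range(p):
        free.append(Parameter(f"mean[{phenotypes[r]}]", "means", ((r,),)))

    eye3 = np.eye(p) / 3.0
    return SemSpec(
        phenotypes=phenotypes,
        factors=phenotypes.copy(),
        loadings=np.eye(p),
        paths=np.zeros((p, p)),
        latent_a=eye3.copy(),
        latent_c=eye3.copy(),
        latent_e=eye3.copy(),
        specific_a=np.zeros(p),
        specific_c=np.zeros(p),
        specific_e=np.zeros(p),
        means=np.zeros(p),
        free=free,
    )


def drop_parameter(spec: SemSpec, label: str) -> SemSpec:
    """Fix the labelled free parameter to zero, producing a nested model."""
    par = spec.parameter(label)  # raises with the available labels
    new = spec.copy()
    new.free = [q for q in new.free if q.label != label]
    arr = getattr(new, par.slot)
    for idx in par.indices:
        arr[idx] = 0.0
    return new


def bonferroni(alpha: float, m: int, decimals: int | None = None) -> float:
    """Bonferroni-corrected per-test threshold alpha/m.

    With ``decimals`` the threshold is additionally rounded half-up to
    that many decimal places, matching how such thresholds are
    conventionally printed (e.g. 0.05/6 -> 0.008 at three decimals).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    exact = alpha / m
    if decimals is None:
        return exact
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(exact)).quantize(q, rounding=ROUND_HALF_UP))
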