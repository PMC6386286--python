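"""Pipeline orchestration with reproducible run manifests.

``run_pipeline`` executes the requested stages in dependency order —
simulate twin data, adjust longitudinal phenotypes, fit the saturated
ACE and direction-of-causation models, compare nested models, run the
MR suite — writing every artefact as tab-separated text under one run
directory and recording a manifest (library versions, seeds, config and
output digests).  Manifests contain no timestamps, so identical configs
yield identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .dataset import TwinPairDataset
from .longitudinal import adjust_phenotypes
from .mr import cochran_q, egger, harmonize, ivw, leave_one_out, single_snp_table, weighted_mode
from .sem import (
    build_doc_model,
    build_saturated_ace,
    compare_table,
    drop_parameter,
    fit,
    standardize,
    standardized_components,
    variance_shares,
)
from .simulate import MRSimConfig, TwinSimConfig, simulate_longitudinal, simulate_mr_summary, simulate_twin_dataset

__all__ = ["RunConfig", "run_pipeline", "demo_truth_spec", "DEMO_PHENOTYPES"]

STAGES = ("simulate", "adjust", "fit-ace", "fit-doc", "compare", "mr")

DEMO_PHENOTYPES = {
    "metabolites": ["ATS", "DHEAS", "D4dione"],
    "lipids": ["HDLC", "TG"],
    "bmd": ["spine_bmd", "hip_bmd"],
}


#: latent A/C/E innovation variances of the generating model.  The
#: profiles deliberately differ across factors (shared environment
#: matters for metabolites, BMD is the most heritable): the direction of
#: latent causation is identified through the MZ/DZ cross-trait
#: cross-twin contrast only when the factors' A/C/E profiles differ.
DEMO_LATENT_ACE = {
    "metabolites": (0.30, 0.40, 0.30),
    "lipids": (0.60, 0.05, 0.35),
    "bmd": (0.80, 0.02, 0.18),
}


def demo_truth_spec(causal_paths: dict[str, float] | None = None):
    """A plausible generating DoC spec for demonstrations and tests.

    Latent ACE profiles per :data:`DEMO_LATENT_ACE`, free loadings at
    0.8, specific variances splitting roughly half the phenotypic
    variance, and by default a single lipids -> BMD causal path of 0.3.
    """
    spec = build_doc_model(DEMO_PHENOTYPES["metabolites"],
                           DEMO_PHENOTYPES["lipids"],
                           DEMO_PHENOTYPES["bmd"])
    values = dict(zip(spec.labels, spec.free_values()))
    for lab in values:
        if lab.startswith("loading["):
            values[lab] = 0.8
        elif lab.startswith("specific_A"):
            values[lab] = 0.45
        elif lab.startswith("specific_C"):
            values[lab] = 0.10
        elif lab.startswith("specific_E"):
            values[lab] = 0.45
        elif lab.startswith("mean["):
            values[lab] = 0.0
    for factor, (a, c, e) in DEMO_LATENT_ACE.items():
        values[f"latent_A[{factor}]"] = a
        values[f"latent_C[{factor}]"] = c
        values[f"latent_E[{factor}]"] = e
    for path, val in (causal_paths or {"lipids->bmd": 0.3}).items():
        values[f"path[{path}]"] = val
    return spec.with_free_values(np.array([values[lab] for lab in spec.labels]))


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    stages: list[str]
    output_dir: Path
    seed: int = 0
    twin: dict = field(default_factory=dict)       # simulate settings
    longitudinal: dict = field(default_factory=dict)
    mr: dict = field(default_factory=dict)
    compare_drops: list[str] = field(default_factory=list)
    inputs: dict = field(default_factory=dict)     # stage -> existing path
    verbosity: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls(
            stages=list(raw.get("stages", STAGES)),
            output_dir=Path(raw.get("output_dir", "twinmr_run")),
            seed=int(raw.get("seed", 0)),
            twin=dict(raw.get("twin", {})),
            longitudinal=dict(raw.get("longitudinal", {})),
            mr=dict(raw.get("mr", {})),
            compare_drops=list(raw.get("compare_drops", [])),
            inputs={k: Path(v) for k, v in raw.get("inputs", {}).items()},
            verbosity=int(raw.get("verbosity", 1)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        for key, path in self.inputs.items():
            if not Path(path).exists():
                raise ValueError(f"input {key!r} refers to missing path {path}")
        if ("compare" in self.stages and "fit-doc" not in self.stages):
            raise ValueError("'compare' requires 'fit-doc' in the stage list")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are flagged in the message."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the manifest dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    log: list[str] = []

    def emit(name: str, df: pd.DataFrame) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = _sha256(path)
        return path

    def say(msg: str) -> None:
        log.append(msg)
        if config.verbosity:
            print(msg)

    ordered = [s for s in STAGES if s in config.stages]
    twin_data: TwinPairDataset | None = None
    doc_fit = None
    truth = demo_truth_spec(config.twin.get("causal_paths"))

    try:
        if "twin_data" in config.inputs:
            twin_data = TwinPairDataset.from_tsv(config.inputs["twin_data"])
        for stage in ordered:
            say(f"[{stage}] running")
            if stage == "simulate":
                sim = TwinSimConfig(
                    spec=truth,
                    n_mz=int(config.twin.get("n_mz", 500)),
                    n_dz=int(config.twin.get("n_dz", 500)),
                    missing_rate=float(config.twin.get("missing_rate", 0.0)),
                    seed=config.seed,
                )
                twin_data = simulate_twin_dataset(sim)
                path = out / "twin_data.tsv"
                twin_data.to_tsv(path)
                outputs["twin_data.tsv"] = _sha256(path)
            elif stage == "adjust":
                lcfg = config.longitudinal
                if "longitudinal" in config.inputs:
                    table = pd.read_csv(config.inputs["longitudinal"], sep="\t")
                else:
                    table = simulate_longitudinal(
                        n_individuals=int(lcfg.get("n_individuals", 200)),
                        visits_per_individual=int(lcfg.get("visits", 3)),
                        age_slope=float(lcfg.get("age_slope", 0.02)),
                        intercept_sd=float(lcfg.get("intercept_sd", 1.0)),
                        residual_sd=float(lcfg.get("residual_sd", 0.5)),
                        seed=config.seed + 1,
                    )
                    emit("longitudinal.tsv", table)
                scores = adjust_phenotypes(table)
                emit("adjusted_scores.tsv",
                     scores.reset_index().rename(columns={"index": "individual_id"}))
            elif stage == "fit-ace":
                if twin_data is None:
                    raise StageError("fit-ace needs twin data (simulate stage or input)")
                sat = build_saturated_ace(twin_data.phenotypes)
                ace_fit = fit(sat, twin_data)
                comps = standardized_components(ace_fit)
                rows = []
                for comp, mat in comps.items():
                    long = mat.reset_index().melt(
                        id_vars="phenotype", var_name="phenotype2", value_name="value")
                    long.insert(0, "component", comp)
                    rows.append(long)
                emit("ace_standardized_components.tsv", pd.concat(rows))
            elif stage == "fit-doc":
                if twin_data is None:
                    raise StageError("fit-doc needs twin data (simulate stage or input)")
                model = build_doc_model(DEMO_PHENOTYPES["metabolites"],
                                        DEMO_PHENOTYPES["lipids"],
                                        DEMO_PHENOTYPES["bmd"])
                doc_fit = fit(model, twin_data)
                std = standardize(doc_fit)
                est = pd.DataFrame({
                    "parameter": doc_fit.spec.labels,
                    "estimate": doc_fit.spec.free_values(),
                    "standardized": std.free_values(),
                })
                emit("doc_estimates.tsv", est)
                emit("doc_variance_shares.tsv",
                     variance_shares(doc_fit).reset_index())
            elif stage == "compare":
                if doc_fit is None:
                    raise StageError("compare needs the fit-doc stage")
                drops = config.compare_drops or [
                    lab for lab in doc_fit.spec.labels if lab.startswith("path[")
                ]
                nested = {}
                model = build_doc_model(DEMO_PHENOTYPES["metabolites"],
                                        DEMO_PHENOTYPES["lipids"],
                                        DEMO_PHENOTYPES["bmd"])
                for lab in drops:
                    sub = drop_parameter(model, lab)
                    nested[f"drop {lab}"] = fit(sub, twin_data)
                emit("model_comparisons.tsv", compare_table(doc_fit, nested))
            elif stage == "mr":
                if {"exposure", "outcome"} <= set(config.inputs):
                    exposure = pd.read_csv(config.inputs["exposure"], sep="\t")
                    outcome = pd.read_csv(config.inputs["outcome"], sep="\t")
                else:
                    mcfg = MRSimConfig(
                        n_snps=int(config.mr.get("n_snps", 30)),
                        causal_effect=float(config.mr.get("causal_effect", 0.2)),
                        invalid_fraction=float(config.mr.get("invalid_fraction", 0.0)),
                        pleiotropy_mean=float(config.mr.get("pleiotropy_mean", 0.0)),
                        pleiotropy_sd=float(config.mr.get("pleiotropy_sd", 0.0)),
                        seed=config.seed + 2,
                    )
                    exposure, outcome = simulate_mr_summary(mcfg)
                    emit("mr_exposure.tsv", exposure)
                    emit("mr_outcome.tsv", outcome)
                harm = harmonize(exposure, outcome)
                ests = [ivw(harm, "fixed"), ivw(harm, "multiplicative_random")]
                slope, intercept = egger(harm)
                ests += [slope, intercept,
                         weighted_mode(harm, n_boot=int(config.mr.get("n_boot", 200)),
                                       seed=config.seed + 3)]
                q, qdf, qp = cochran_q(harm)
                table = pd.DataFrame(
                    [{"method": e.method, "b": e.b, "se": e.se, "p": e.p,
                      "n_snps": e.n_snps} for e in ests]
                    + [{"method": "cochran_q", "b": q, "se": np.nan, "p": qp,
                        "n_snps": qdf + 1}])
                emit("mr_estimates.tsv", table)
                emit("mr_single_snp.tsv", single_snp_table(harm))
                emit("mr_leave_one_out.tsv", leave_one_out(harm))
            say(f"[{stage}] done")
    except Exception as exc:
        partial = sorted(outputs)
        raise StageError(
            f"stage {stage!r} failed: {exc}; partial outputs already "
            f"written: {partial}"
        ) from exc

    manifest = {
        "twinmr_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "stages": ordered,
        "config_digest": hashlib.sha256(
            json.dumps(
                {"stages": ordered, "seed": config.seed, "twin": config.twin,
                 "mr": config.mr, "longitudinal": config.longitudinal,
                 "compare_drops": config.compare_drops},
                sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {k: _sha256(Path(v)) for k, v in config.inputs.items()},
        "outputs": outputs,
        "log": log,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
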