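"""End-to-end orchestration from a single YAML config.

Stage order: simulate/load -> preprocess (collapse, censor, receptor
cutoffs) -> subtype assignment -> module scoring -> correlations ->
univariate scan -> covariate selection -> adjusted scans -> per-subtype
signature derivation -> median-split KM. Every output table carries a
provenance header with the config hash and seed, so a table can always be
traced to the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .datatypes import ClinicalTable, ExpressionStudy, ModsurvError
from .derive import SubtypeSignatureModel
from .preprocess import (
    censor_dmfs,
    collapse_duplicate_genes,
    dichotomize_receptor,
    fit_receptor_cutoff,
)
from .scoring import module_correlations, score_signatures
from .simulate import (
    ModuleSpec,
    SimulationConfig,
    make_signature,
    simulate_cohort,
    true_centroids,
)
from .subtype import assign_subtypes, assignments_frame
from .survival import ModuleDMFSModel, km_median_split, select_covariates

log = logging.getLogger("modsurv")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "ConfigError", "PipelineError"]


class ConfigError(ModsurvError):
    def __init__(self, errors: Sequence[str]):
        super().__init__("invalid config:\n  " + "\n  ".join(errors))
        self.errors = list(errors)


class PipelineError(ModsurvError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}/{code}] {message}")
        self.stage = stage
        self.code = code


_KNOWN_KEYS = {
    "simulate", "expression_dir", "clinical_path", "signatures_path",
    "centroids_path", "horizon_years", "receptor_genes", "analysis_subtypes",
    "covariate_candidates", "alpha", "fdr_threshold", "derive_signatures",
    "seed", "out_dir",
}

_SIM_KEYS = {
    "n_studies", "samples_per_study", "n_genes", "centroid_shift",
    "noise_sd", "baseline_hazard_per_study", "censoring_rate",
    "study_location_sd", "study_scale_sd", "modules",
}


@dataclass
class PipelineConfig:
    simulate: dict | None = None
    expression_dir: str | None = None
    clinical_path: str | None = None
    signatures_path: str | None = None
    centroids_path: str | None = None
    horizon_years: float = 10.0
    receptor_genes: dict = field(default_factory=dict)  # {"er": gene, "her2": gene}
    analysis_subtypes: list = field(default_factory=lambda: ["luminal_A", "luminal_B", "HER2", "basal"])
    covariate_candidates: list = field(default_factory=lambda: ["age_group", "nodal_status", "grade", "treatment"])
    alpha: float = 0.05
    fdr_threshold: float = 0.05
    derive_signatures: bool = False
    seed: int = 0
    out_dir: str = "modsurv_out"

    def canonical(self) -> str:
        # out_dir does not affect the analysis, so it stays out of the hash
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        return json.dumps(d, sort_keys=True, default=str)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Schema-check a YAML config; collects all per-field errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    sim = raw.get("simulate")
    if sim is not None:
        if not isinstance(sim, dict):
            errors.append("simulate: must be a mapping")
        else:
            bad = set(sim) - _SIM_KEYS
            if bad:
                errors.append(f"simulate: unknown keys {sorted(bad)}")
    else:
        for key in ("expression_dir", "clinical_path"):
            if not raw.get(key):
                errors.append(f"{key}: required when not simulating")
            elif not Path(raw[key]).exists():
                errors.append(f"{key}: path {raw[key]!r} does not exist")
    for key in ("signatures_path", "centroids_path"):
        if raw.get(key) and not Path(raw[key]).exists():
            errors.append(f"{key}: path {raw[key]!r} does not exist")
    alpha = raw.get("alpha", 0.05)
    if not (0 < float(alpha) < 1):
        errors.append(f"alpha: must be in (0,1), got {alpha}")
    fdr = raw.get("fdr_threshold", 0.05)
    if not (0 < float(fdr) < 1):
        errors.append(f"fdr_threshold: must be in (0,1), got {fdr}")
    horizon = raw.get("horizon_years", 10.0)
    if float(horizon) <= 0:
        errors.append(f"horizon_years: must be > 0, got {horizon}")
    subtypes = raw.get("analysis_subtypes", [])
    if len(subtypes) != len(set(subtypes)):
        errors.append("analysis_subtypes: duplicate entries")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")
    receptor = raw.get("receptor_genes", {})
    if receptor and (not isinstance(receptor, dict) or set(receptor) - {"er", "her2"}):
        errors.append("receptor_genes: must be a mapping with keys from {er, her2}")
    if errors:
        raise ConfigError(errors)
    kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS}
    return PipelineConfig(**kwargs)


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    sim = dict(config.simulate or {})
    modules = sim.pop("modules", [])
    specs = []
    for m in modules:
        sig = make_signature(m["name"], m["genes"], m.get("weights"))
        specs.append(ModuleSpec(signature=sig, log_hr=float(m.get("log_hr", 0.0))))
    if "baseline_hazard_per_study" in sim:
        sim["baseline_hazard_per_study"] = tuple(np.atleast_1d(sim["baseline_hazard_per_study"]))
    return SimulationConfig(seed=config.seed, module_specs=tuple(specs), **sim)


def _provenance(config: PipelineConfig) -> list[str]:
    return [f"modsurv config_sha256={config.config_hash} seed={config.seed}"]


def _write_df(df: pd.DataFrame, path: Path, config: PipelineConfig, index=False, index_label=None) -> None:
    with open(path, "w") as fh:
        for line in _provenance(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Deterministic: identical config (including seed) gives byte-identical
    tables. Any stage failure raises :class:`PipelineError` naming the
    stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # ---- stage: input -------------------------------------------------
    truth = None
    centroids = None
    if config.simulate is not None:
        sim_cfg = _sim_config(config)
        studies, clinical, truth = simulate_cohort(sim_cfg)
        centroids = true_centroids(sim_cfg)
        signatures = [spec.signature for spec in sim_cfg.module_specs]
        log.info("simulate: %d studies x %d samples, %d genes",
                 sim_cfg.n_studies, sim_cfg.samples_per_study, len(sim_cfg.gene_universe()))
        for st in studies:
            msio.write_expression(st, out / f"expression_{st.study_id}.tsv")
    else:
        expr_dir = Path(config.expression_dir)
        paths = sorted(expr_dir.glob("*.tsv")) + sorted(expr_dir.glob("*.gct"))
        if not paths:
            raise PipelineError("input", "no_expression", f"no expression files in {expr_dir}")
        studies = [msio.read_expression(p) for p in paths]
        clinical = msio.read_clinical(config.clinical_path)
        signatures = []
    if config.signatures_path:
        signatures = msio.read_signatures(config.signatures_path)
    if config.centroids_path:
        centroids = msio.read_centroids(config.centroids_path)
    if not signatures:
        raise PipelineError("input", "no_signatures",
                            "no signatures: give signatures_path or simulated modules")

    # ---- stage: preprocess --------------------------------------------
    try:
        studies = [collapse_duplicate_genes(st) for st in studies]
        clinical = censor_dmfs(clinical, config.horizon_years)
        for receptor, gene in (config.receptor_genes or {}).items():
            for st in studies:
                cut = fit_receptor_cutoff(st, gene, seed=config.seed)
                clinical = dichotomize_receptor(st, clinical, gene, cut, receptor=receptor)
    except ModsurvError as exc:
        raise PipelineError("preprocess", "failed", str(exc)) from exc
    msio.write_clinical(clinical, out / "clinical.tsv", header_lines=_provenance(config))
    log.info("preprocess: %d samples, %d events", len(clinical),
             int(clinical.df["dmfs_event"].sum()))

    # ---- stage: subtype ------------------------------------------------
    subtype_map = None
    if centroids is not None:
        try:
            frames = []
            for st in studies:
                frames.append(assignments_frame(assign_subtypes(st, centroids)))
            subtype_df = pd.concat(frames, ignore_index=True)
        except ModsurvError as exc:
            raise PipelineError("subtype", "failed", str(exc)) from exc
        _write_df(subtype_df, out / "subtypes.tsv", config)
        subtype_map = subtype_df.set_index("sample_id")["subtype"]
        counts = subtype_df["subtype"].value_counts().to_dict()
        log.info("subtype: %s", counts)

    # ---- stage: score + correlations ----------------------------------
    try:
        scores = score_signatures(studies, signatures)
    except ModsurvError as exc:
        raise PipelineError("score", "failed", str(exc)) from exc
    score_table = pd.DataFrame({
        "sample_id": scores.samples, "study_id": scores.study_ids.to_numpy(),
    })
    for name in scores.modules:
        score_table[f"{name}_raw"] = scores.raw[name].to_numpy()
        score_table[f"{name}_scaled"] = scores.scaled[name].to_numpy()
    _write_df(score_table, out / "scores.tsv", config)
    if len(scores.modules) >= 2:
        corr = module_correlations(scores)
        _write_df(corr, out / "module_correlations.tsv", config, index=True, index_label="module")

    # ---- stage: scans --------------------------------------------------
    cohorts: list[tuple[str, list[str] | None]] = [("all", None)]
    if subtype_map is not None:
        for label in config.analysis_subtypes:
            ids = subtype_map.index[subtype_map == label].tolist()
            if ids:
                cohorts.append((label, ids))
    selected_rows = []
    for label, ids in cohorts:
        try:
            uni = ModuleDMFSModel(scores, clinical, cohort=label, samples=ids,
                                  adjust=None, fdr_threshold=config.fdr_threshold).fit()
            _write_df(uni.summary(), out / f"scan_univariate_{label}.tsv", config)
            adj = ModuleDMFSModel(
                scores, clinical, cohort=label, samples=ids, adjust="auto",
                covariate_candidates=config.covariate_candidates,
                alpha=config.alpha, fdr_threshold=config.fdr_threshold,
            ).fit()
            _write_df(adj.summary(), out / f"scan_adjusted_{label}.tsv", config)
            selected_rows.append({"cohort": label,
                                  "covariates": ",".join(adj.covariates) or "none"})
            log.info("scan[%s]: n=%d events=%d adjusted_for=%s significant=%d",
                     label, uni.n, uni.n_events, adj.covariates or "none",
                     len(adj.significant()))
        except ModsurvError as exc:
            raise PipelineError("scan", label, str(exc)) from exc
    _write_df(pd.DataFrame(selected_rows), out / "selected_covariates.tsv", config)

    # ---- stage: derive + KM -------------------------------------------
    if config.derive_signatures:
        if subtype_map is None:
            raise PipelineError("derive", "no_subtypes",
                                "signature derivation needs subtype assignments")
        derived_sigs = []
        km_rows = []
        for label in config.analysis_subtypes:
            ids = subtype_map.index[subtype_map == label].tolist()
            if not ids:
                continue
            try:
                res = SubtypeSignatureModel(
                    studies, clinical, subtype=label, samples=ids, adjust="auto",
                    alpha=config.alpha,
                ).fit()
            except ModsurvError as exc:
                log.info("derive[%s]: skipped (%s)", label, exc)
                continue
            derived_sigs.append(res.signature)
            _write_df(res.summary(), out / f"sweep_{label}.tsv", config)
            ev = res.evaluate()
            km_rows.append({
                "subtype": label, "module_size": res.derived.selected.size,
                "uni_HR": ev.cox_univariate.hr, "adj_HR": ev.cox_adjusted.hr,
                "logrank_chi2": ev.km.chi_square, "logrank_p": ev.km.p,
                "in_sample": ev.in_sample,
            })
            log.info("derive[%s]: size=%d criterion=%.3f logrank_p=%.3g",
                     label, res.derived.selected.size,
                     res.derived.selected.criterion, ev.km.p)
        if derived_sigs:
            msio.write_signatures(derived_sigs, out / "derived_signatures.tsv")
            _write_df(pd.DataFrame(km_rows), out / "derived_km.tsv", config)

    if truth is not None:
        _write_df(truth, out / "truth.tsv", config)
    return out
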