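"""Synthetic multi-study cohort generator.

Emulates the statistical structure the downstream analysis assumes:

* several studies, each with its own baseline hazard and a study-level
  location (and optionally scale) shift of the expression matrix;
* a latent molecular subtype per sample driving a block-structured centroid
  pattern in expression;
* planted gene modules whose per-sample pathway activity enters the hazard
  multiplicatively with a configurable log hazard ratio per unit of raw
  module score;
* receptor genes (ESR1-like, ERBB2-like) drawn from a two-component normal
  mixture whose component is tied to the subtype, giving the bimodal
  marginal distribution receptor dichotomisation relies on;
* exponential event times with independent exponential censoring and a
  10-year administrative horizon.

Genes belonging to a planted module carry a per-sample standard-normal
pathway activity in their noise-free signal, so the true module score varies
continuously across samples and the planted log-HR is well defined;
measurement noise then attenuates, but does not redefine, the recoverable
effect.

Determinism: one global seed expands to per-study substreams via
``numpy.random.SeedSequence.spawn``, so adding a study leaves earlier
studies' draws untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    CentroidMatrix,
    ClinicalTable,
    ExpressionStudy,
    GeneSignature,
    ModsurvError,
)

__all__ = [
    "ReceptorSpec",
    "ModuleSpec",
    "SimulationConfig",
    "simulate_cohort",
    "planted_signature_truth",
    "true_centroids",
    "make_signature",
]

#: default subtype mix: luminal A/B, HER2+, basal-like, normal-like
#: proportions follow the 554/774/129/440/130 split of a 2027-patient
#: multi-study breast-cancer compendium
DEFAULT_SUBTYPES = ("luminal_A", "luminal_B", "HER2", "basal", "normal_like")
DEFAULT_PROPORTIONS = (554 / 2027, 774 / 2027, 129 / 2027, 440 / 2027, 130 / 2027)

#: marginal frequencies for simulated clinical covariates
_AGE_P = {"<50": 0.5, ">=50": 0.5}
_NODAL_P = {"negative": 0.6, "positive": 0.4}
_GRADE_P = {"1": 0.1, "2": 0.4, "3": 0.5}
_TREATMENT_P = {"chemo": 0.3, "endo": 0.3, "both": 0.2, "none": 0.2}


@dataclass(frozen=True)
class ReceptorSpec:
    """A receptor gene with subtype-tied bimodal expression.

    Samples of a ``positive_subtypes`` subtype draw from N(high_mean,
    high_sd), all others from N(low_mean, low_sd); the mixing weight is thus
    the total proportion of the positive subtypes.
    """

    gene: str
    low_mean: float
    high_mean: float
    low_sd: float = 1.0
    high_sd: float = 1.0
    positive_subtypes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModuleSpec:
    """A planted prognostic module: a signature plus its true log-HR per
    one-unit increase of the raw (noise-free) module score."""

    signature: GeneSignature
    log_hr: float


def make_signature(name: str, genes: Sequence[str], weights: Sequence[float] | None = None) -> GeneSignature:
    """Convenience constructor; default weights are all +1."""
    if weights is None:
        weights = [1.0] * len(genes)
    return GeneSignature(name=name, entries=list(zip(genes, [float(w) for w in weights])))


@dataclass
class SimulationConfig:
    n_studies: int = 4
    samples_per_study: int = 250
    n_genes: int = 200
    subtype_names: tuple[str, ...] = DEFAULT_SUBTYPES
    subtype_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    centroid_shift: float = 3.0
    module_specs: tuple[ModuleSpec, ...] = ()
    baseline_hazard_per_study: tuple[float, ...] | float = (0.05, 0.08, 0.11, 0.14)
    censoring_rate: float = 0.04
    admin_horizon_years: float = 10.0
    receptor_specs: tuple[ReceptorSpec, ...] = (
        ReceptorSpec("ESR1", low_mean=5.0, high_mean=10.0,
                     positive_subtypes=("luminal_A", "luminal_B", "normal_like")),
        ReceptorSpec("ERBB2", low_mean=5.0, high_mean=9.5,
                     positive_subtypes=("HER2",)),
    )
    study_location_sd: float = 0.5
    study_scale_sd: float = 0.0
    noise_sd: float = 1.0
    covariate_log_hr: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subtype_names) != len(self.subtype_proportions):
            raise ModsurvError("subtype_names and subtype_proportions lengths differ")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ModsurvError("subtype_proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ModsurvError("noise_sd must be > 0")
        if self.censoring_rate <= 0:
            raise ModsurvError("censoring_rate must be > 0")
        if self.admin_horizon_years <= 0:
            raise ModsurvError("admin_horizon_years must be > 0")
        for h in np.atleast_1d(self.baseline_hazard_per_study):
            if h <= 0:
                raise ModsurvError("baseline hazards must be > 0")
        universe = set(self.gene_universe())
        for spec in self.module_specs:
            unknown = set(spec.signature.genes) - universe
            if unknown:
                raise ModsurvError(
                    f"module {spec.signature.name!r} references genes outside "
                    f"the simulated universe: {sorted(unknown)}"
                )
        for key in self.covariate_log_hr:
            if "=" not in key:
                raise ModsurvError(
                    f"covariate_log_hr keys must look like 'field=level', got {key!r}"
                )

    def gene_universe(self) -> list[str]:
        genes = [f"G{i:04d}" for i in range(self.n_genes)]
        genes += [r.gene for r in self.receptor_specs]
        return genes

    def baseline_hazard(self, study_index: int) -> float:
        h = np.atleast_1d(np.asarray(self.baseline_hazard_per_study, dtype=float))
        return float(h[study_index % len(h)])


def true_centroids(config: SimulationConfig) -> CentroidMatrix:
    """Noise-free subtype centroids of the simulated gene universe.

    Block design: gene ``i`` is a marker of subtype ``i mod K`` and its
    centroid is elevated by ``centroid_shift`` in that subtype. Receptor
    genes use their component means.
    """
    genes = config.gene_universe()
    k = len(config.subtype_names)
    data = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"),
                        columns=list(config.subtype_names))
    for i in range(config.n_genes):
        data.iloc[i, i % k] = config.centroid_shift
    for spec in config.receptor_specs:
        for s in config.subtype_names:
            data.loc[spec.gene, s] = spec.high_mean if s in spec.positive_subtypes else spec.low_mean
    return CentroidMatrix(data)


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    levels = list(probs)
    p = np.array([probs[k] for k in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], ClinicalTable, pd.DataFrame]:
    """Generate expression studies, a clinical table and the ground truth.

    Returns ``(studies, clinical, truth)`` where ``truth`` has one row per
    sample with its latent subtype and the true (noise-free) raw score of
    every planted module. Identical config (including seed) gives
    bit-identical output.
    """
    centroids = true_centroids(config).data
    genes = list(centroids.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    subtype_names = list(config.subtype_names)
    props = np.asarray(config.subtype_proportions, dtype=float)
    receptor_rows = {spec.gene: spec for spec in config.receptor_specs}

    parent = np.random.SeedSequence(config.seed)
    streams = parent.spawn(config.n_studies)

    studies: list[ExpressionStudy] = []
    clin_rows = []
    truth_rows = []
    for k in range(config.n_studies):
        rng = np.random.default_rng(streams[k])
        sid = f"study{k + 1}"
        n = config.samples_per_study
        sample_ids = [f"{sid}-S{j:04d}" for j in range(n)]

        loc = rng.normal(0.0, config.study_location_sd) if config.study_location_sd > 0 else 0.0
        scale = float(np.exp(rng.normal(0.0, config.study_scale_sd))) if config.study_scale_sd > 0 else 1.0

        subtype_idx = rng.choice(len(subtype_names), size=n, p=props)
        subtypes = np.array(subtype_names, dtype=object)[subtype_idx]

        # noise-free signal: subtype centroid + per-module pathway activity
        signal = centroids.to_numpy()[:, subtype_idx].copy()  # genes x samples
        true_scores = {}
        for spec in config.module_specs:
            activity = rng.normal(0.0, 1.0, size=n)
            w = spec.signature.weights
            rows = [gene_pos[g] for g in spec.signature.genes]
            signal[rows, :] += np.outer(w, activity)
            true_scores[spec.signature.name] = (w @ signal[rows, :]) / np.abs(w).sum()

        noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
        expr = loc + scale * signal + noise
        # receptor genes: component sd replaces the global noise sd
        for g, spec in receptor_rows.items():
            i = gene_pos[g]
            comp_hi = np.isin(subtypes, spec.positive_subtypes)
            sd = np.where(comp_hi, spec.high_sd, spec.low_sd)
            expr[i, :] = loc + scale * signal[i, :] + rng.normal(0.0, 1.0, size=n) * sd

        # clinical covariates (independent of expression)
        age = _draw_categorical(rng, _AGE_P, n)
        nodal = _draw_categorical(rng, _NODAL_P, n)
        grade = _draw_categorical(rng, _GRADE_P, n)
        treatment = _draw_categorical(rng, _TREATMENT_P, n)
        covariate_values = {"age_group": age, "nodal_status": nodal,
                            "grade": grade, "treatment": treatment}

        log_hazard = np.full(n, np.log(config.baseline_hazard(k)))
        for spec in config.module_specs:
            log_hazard += spec.log_hr * true_scores[spec.signature.name]
        for key, beta in config.covariate_log_hr.items():
            fieldname, _, level = key.partition("=")
            if fieldname not in covariate_values:
                raise ModsurvError(f"unknown covariate {fieldname!r} in covariate_log_hr")
            log_hazard += beta * (covariate_values[fieldname] == level)

        t_event = rng.exponential(1.0 / np.exp(log_hazard))
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
        horizon = config.admin_horizon_years
        time = np.minimum(np.minimum(t_event, t_cens), horizon)
        event = (t_event <= t_cens) & (t_event < horizon)

        studies.append(ExpressionStudy(
            study_id=sid,
            data=pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=sample_ids),
        ))
        for j in range(n):
            clin_rows.append({
                "sample_id": sample_ids[j], "study_id": sid,
                "dmfs_time": float(time[j]), "dmfs_event": int(event[j]),
                "age_group": age[j], "nodal_status": nodal[j],
                "grade": grade[j], "treatment": treatment[j],
                "er_status": "unknown", "her2_status": "unknown",
            })
            row = {"sample_id": sample_ids[j], "study_id": sid, "subtype": subtypes[j]}
            for name, sc in true_scores.items():
                row[f"true_score_{name}"] = float(sc[j])
            truth_rows.append(row)

    clinical = ClinicalTable(pd.DataFrame(clin_rows))
    truth = pd.DataFrame(truth_rows)
    return studies, clinical, truth


def planted_signature_truth(config: SimulationConfig) -> list[tuple[str, int]]:
    """Genes carrying survival signal, with their hazard direction.

    A gene's direction is the sign of ``log_hr * weight`` summed over the
    planted modules containing it; genes with zero net effect are omitted.
    Returns an empty list when nothing is planted.
    """
    net: dict[str, float] = {}
    for spec in config.module_specs:
        if spec.log_hr == 0:
            continue
        for g, w in spec.signature.entries:
            net[g] = net.get(g, 0.0) + spec.log_hr * w
    return [(g, 1 if v > 0 else -1) for g, v in net.items() if v != 0]
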