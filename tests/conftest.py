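import numpy as np
import pandas as pd
import pytest

from modsurv import (
    ClinicalTable,
    ExpressionStudy,
    GeneSignature,
    ModuleSpec,
    SimulationConfig,
    make_signature,
    simulate_cohort,
)


def planted_signature(n_genes: int = 20) -> GeneSignature:
    """A 20-gene signature, half up- and half down-weighted."""
    genes = [f"G{i:04d}" for i in range(n_genes)]
    weights = [1.0] * (n_genes // 2) + [-1.0] * (n_genes - n_genes // 2)
    return make_signature("plant", genes, weights)


@pytest.fixture(scope="session")
def planted_sig() -> GeneSignature:
    return planted_signature()


@pytest.fixture(scope="session")
def planted_cohort(planted_sig):
    """4 studies x 250 samples with one planted module at log-HR 0.7."""
    cfg = SimulationConfig(
        n_studies=4, samples_per_study=250, n_genes=60,
        module_specs=(ModuleSpec(planted_sig, 0.7),), seed=11,
    )
    studies, clinical, truth = simulate_cohort(cfg)
    return cfg, studies, clinical, truth


@pytest.fixture()
def toy_study() -> ExpressionStudy:
    data = pd.DataFrame(
        [[2.0, 4.0], [1.0, 3.0], [5.0, 5.0]],
        index=pd.Index(["A", "B", "C"], name="gene"),
        columns=["s1", "s2"],
    )
    return ExpressionStudy("toy", data)


def make_clinical(times, events, study_ids=None, **overrides) -> ClinicalTable:
    n = len(times)
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "study_id": study_ids if study_ids is not None else ["st1"] * n,
        "dmfs_time": list(times),
        "dmfs_event": list(events),
        "age_group": ["<50"] * n,
        "nodal_status": ["negative"] * n,
        "grade": ["2"] * n,
        "treatment": ["both"] * n,
        "er_status": ["unknown"] * n,
        "her2_status": ["unknown"] * n,
    })
    for k, v in overrides.items():
        df[k] = v
    return ClinicalTable(df)
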