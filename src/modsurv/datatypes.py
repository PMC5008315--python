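"""Core in-memory containers shared across the analysis pipeline.

Expression data live in pandas DataFrames with genes as rows and samples as
columns (log2 scale), clinical data in a per-sample DataFrame with fixed
categorical vocabularies, and results in small dataclasses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

AGE_LEVELS = ("<50", ">=50", "unknown")
NODAL_LEVELS = ("negative", "positive", "unknown")
GRADE_LEVELS = ("1", "2", "3", "unknown")
TREATMENT_LEVELS = ("chemo", "endo", "both", "none", "unknown")
RECEPTOR_LEVELS = ("negative", "positive", "unknown")

#: required columns of a clinical table and their allowed categorical levels
CLINICAL_CATEGORICALS: Mapping[str, tuple[str, ...]] = {
    "age_group": AGE_LEVELS,
    "nodal_status": NODAL_LEVELS,
    "grade": GRADE_LEVELS,
    "treatment": TREATMENT_LEVELS,
    "er_status": RECEPTOR_LEVELS,
    "her2_status": RECEPTOR_LEVELS,
}

CLINICAL_COLUMNS = (
    "sample_id",
    "study_id",
    "dmfs_time",
    "dmfs_event",
) + tuple(CLINICAL_CATEGORICALS)


class ModsurvError(Exception):
    """Base class for package errors."""


class ParseError(ModsurvError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


@dataclass
class ExpressionStudy:
    """One study's log2 expression matrix, genes as rows, samples as columns.

    Duplicate gene rows (multiple probes mapping to one symbol) are allowed at
    load time and flagged via :attr:`has_duplicate_genes`; they must be
    collapsed before scoring (see :func:`modsurv.preprocess.collapse_duplicate_genes`).
    Duplicate sample IDs are never allowed.
    """

    study_id: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] == 0 or self.data.shape[0] == 0:
            raise ModsurvError(f"study {self.study_id!r}: empty expression matrix")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ModsurvError(
                f"study {self.study_id!r}: duplicate sample IDs {dups}"
            )

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def has_duplicate_genes(self) -> bool:
        return bool(self.data.index.duplicated().any())


@dataclass
class ClinicalTable:
    """Per-sample survival outcome (DMFS) and clinical covariates.

    One row per sample. ``dmfs_time`` is in years, ``dmfs_event`` in {0,1}.
    Categorical covariates use the fixed vocabularies in
    :data:`CLINICAL_CATEGORICALS`, with "unknown" explicit.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise ModsurvError(f"clinical table missing columns: {missing}")
        if self.df["sample_id"].duplicated().any():
            raise ModsurvError("clinical table has duplicate sample IDs")
        times = self.df["dmfs_time"].to_numpy(dtype=float)
        if np.any(times < 0) or np.any(~np.isfinite(times)):
            raise ModsurvError("dmfs_time must be finite and >= 0")
        events = self.df["dmfs_event"].to_numpy()
        if not np.isin(events, [0, 1]).all():
            raise ModsurvError("dmfs_event must be 0 or 1")
        for col, levels in CLINICAL_CATEGORICALS.items():
            bad = set(self.df[col].astype(str)) - set(levels)
            if bad:
                raise ModsurvError(f"invalid {col} levels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.df["sample_id"])

    def subset(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        keep = self.df["sample_id"].isin(set(sample_ids))
        return ClinicalTable(self.df.loc[keep].reset_index(drop=True))

    def replace(self, df: pd.DataFrame) -> "ClinicalTable":
        return ClinicalTable(df.reset_index(drop=True))


@dataclass
class GeneSignature:
    """A named gene module: (gene symbol, signed weight) pairs.

    Published modules use weights in {-1, +1} encoding the direction of
    association with outcome; arbitrary nonzero real weights are accepted.
    """

    name: str
    entries: list[tuple[str, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ModsurvError(f"signature {self.name!r} has no entries")
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            seen, dups = set(), set()
            for g in genes:
                (dups if g in seen else seen).add(g)
            raise ModsurvError(
                f"signature {self.name!r}: duplicate genes {sorted(dups)}"
            )
        for g, w in self.entries:
            if w == 0 or not np.isfinite(w):
                raise ModsurvError(
                    f"signature {self.name!r}: gene {g!r} has invalid weight {w}"
                )

    @property
    def genes(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CentroidMatrix:
    """Subtype centroids: genes as rows, subtype names as columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ModsurvError("centroid matrix has duplicate genes")
        if self.data.shape[1] < 2:
            raise ModsurvError("centroid matrix needs >= 2 subtypes")

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def subtypes(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class ModuleScoreMatrix:
    """Per-sample module scores, raw and robust-scaled, with study labels.

    ``raw`` and ``scaled`` are samples x modules DataFrames sharing the same
    index; ``study_ids`` maps each sample to its study.
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame
    study_ids: pd.Series

    @property
    def samples(self) -> pd.Index:
        return self.raw.index

    @property
    def modules(self) -> list[str]:
        return list(self.raw.columns)

    def subset(self, sample_ids: Sequence[str]) -> "ModuleScoreMatrix":
        idx = self.raw.index.intersection(pd.Index(sample_ids))
        return ModuleScoreMatrix(
            raw=self.raw.loc[idx], scaled=self.scaled.loc[idx],
            study_ids=self.study_ids.loc[idx],
        )


@dataclass
class CoxResult:
    """Hazard ratio for one predictor from a (stratified) Cox model.

    ``coef`` is the log hazard ratio for a one-unit predictor increase; the
    95% CI is normal-theory, ``exp(coef +/- 1.96 * se)``.
    """

    predictor: str
    cohort: str
    n: int
    n_events: int
    coef: float
    se: float
    p: float
    fdr: float | None = None

    @property
    def hr(self) -> float:
        return float(np.exp(self.coef))

    @property
    def ci_low(self) -> float:
        return float(np.exp(self.coef - 1.96 * self.se))

    @property
    def ci_high(self) -> float:
        return float(np.exp(self.coef + 1.96 * self.se))

    def as_dict(self) -> dict:
        return {
            "predictor": self.predictor, "cohort": self.cohort,
            "n": self.n, "n_events": self.n_events,
            "HR": self.hr, "CI_low": self.ci_low, "CI_high": self.ci_high,
            "p": self.p, "FDR": self.fdr,
        }


@dataclass
class KMResult:
    """Two-group Kaplan-Meier comparison with a log-rank test."""

    group_labels: tuple[str, str]
    survival_functions: dict[str, pd.DataFrame]
    group_sizes: dict[str, int]
    chi_square: float
    p: float


@dataclass
class MixtureCutoff:
    """Two-component normal mixture fit for one receptor gene in one study."""

    study_id: str
    gene: str
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    cutoff: float
    converged: bool


@dataclass
class SubtypeAssignment:
    """Nearest-centroid subtype call for one sample."""

    sample_id: str
    label: str
    similarities: dict[str, float]
    margin: float
    tie: bool = False


@dataclass
class GeneMetaResult:
    """Per-gene fixed-effect meta-analysis of study-level Cox fits."""

    gene: str
    study_coefs: dict[str, float]
    study_ses: dict[str, float]
    coef: float
    se: float
    p: float

    @property
    def direction(self) -> int:
        """+1 iff combined HR > 1, else -1."""
        return 1 if self.coef > 0 else -1


@dataclass
class CandidateModule:
    """One entry of the candidate-size sweep (sizes 10, 20, ..., 200)."""

    index: int
    size: int
    signature: GeneSignature
    uni_hr: float = float("nan")
    adj_hr: float = float("nan")

    @property
    def criterion(self) -> float:
        """Conservative selection criterion: min(univariate, adjusted) HR."""
        return min(self.uni_hr, self.adj_hr)


@dataclass
class DerivedSignature:
    """The selected subtype-specific prognostic module and its sweep audit."""

    subtype: str
    selected: CandidateModule
    sweep: pd.DataFrame

    @property
    def signature(self) -> GeneSignature:
        return self.selected.signature


@dataclass
class SignatureEvaluation:
    """Univariate/adjusted Cox plus median-split KM for a derived signature."""

    cox_univariate: CoxResult
    cox_adjusted: CoxResult
    km: KMResult
    in_sample: bool
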