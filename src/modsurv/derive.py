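"""Derivation of subtype-specific prognostic gene modules.

Three steps, run within one analysis cohort (typically one molecular
subtype across all studies):

1. **Per-gene meta-analytic Cox.** Each gene is dichotomised at its
   within-study median (high vs low) and a univariate Cox model is fitted
   per study; study-level log-HRs are combined by fixed-effect
   inverse-variance weighting: ``se = (sum 1/se_k^2)^{-1/2}``,
   ``coef = se^2 * sum(coef_k / se_k^2)``, Wald p from the normal.
   A study contributes only if it has at least ``min_events`` events in the
   cohort. A continuous variant (expression minus the within-study median)
   is available via ``method="median_centered"``.
2. **Candidate sweep.** Genes are ranked by combined p (ties broken by
   |combined log-HR| descending, then gene symbol) and nested candidate
   modules of sizes 10, 20, ..., 200 are built, each gene weighted +1 if
   its combined HR exceeds 1 and -1 otherwise.
3. **HR-maximising selection.** Every candidate is scored (signed module
   score + robust within-study scaling), assessed by stratified Cox with
   and without covariate adjustment, and the candidate maximising
   ``min(univariate HR, adjusted HR)`` is selected; ties go to the smaller
   module. The full sweep table is retained for audit.

Exposed statsmodels-style through :class:`SubtypeSignatureModel` /
:class:`SubtypeSignatureResults`; the step functions are public as well.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._fastcox import univariate_cox_batch
from .datatypes import (
    CandidateModule,
    ClinicalTable,
    CoxResult,
    DerivedSignature,
    ExpressionStudy,
    GeneMetaResult,
    GeneSignature,
    KMResult,
    ModsurvError,
    SignatureEvaluation,
)
from .scoring import robust_scale, score_module
from .survival import (
    complete_cases,
    cox_stratified,
    expand_covariates,
    km_median_split,
    select_covariates,
)

__all__ = [
    "combine_fixed_effect",
    "per_gene_meta_cox",
    "build_candidates",
    "select_best_module",
    "evaluate_signature",
    "SubtypeSignatureModel",
    "SubtypeSignatureResults",
]


def combine_fixed_effect(coefs: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Fixed-effect inverse-variance combination of per-study estimates."""
    coefs = np.asarray(coefs, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if coefs.shape != ses.shape or coefs.size == 0:
        raise ModsurvError("need matching, non-empty coef/se arrays")
    if np.any(ses <= 0):
        raise ModsurvError("standard errors must be positive")
    w = 1.0 / ses ** 2
    se = float(np.sqrt(1.0 / w.sum()))
    coef = float((w * coefs).sum() / w.sum())
    return coef, se


def _cohort_columns(
    study: ExpressionStudy, clinical_df: pd.DataFrame, samples: set[str] | None
) -> pd.DataFrame:
    df = clinical_df[clinical_df["study_id"] == study.study_id]
    keep = df["sample_id"].isin(set(study.samples))
    if samples is not None:
        keep &= df["sample_id"].isin(samples)
    return df.loc[keep]


def per_gene_meta_cox(
    studies: Iterable[ExpressionStudy],
    clinical: ClinicalTable,
    samples: Sequence[str] | None = None,
    min_events: int = 5,
    method: str = "median_split",
) -> list[GeneMetaResult]:
    """Per-gene Cox within each study, combined across studies.

    The gene universe is the intersection of gene sets across all given
    studies (sorted for determinism); genes that fail in every contributing
    study are dropped.
    """
    if method not in ("median_split", "median_centered"):
        raise ModsurvError(f"unknown method {method!r}")
    studies = list(studies)
    if not studies:
        raise ModsurvError("no studies given")
    universe: pd.Index | None = None
    for st in studies:
        if st.has_duplicate_genes:
            raise ModsurvError(f"study {st.study_id!r} has duplicate genes; collapse first")
        universe = st.genes if universe is None else universe.intersection(st.genes)
    universe = pd.Index(sorted(universe))
    if len(universe) == 0:
        raise ModsurvError("empty gene universe: studies share no genes")

    sample_set = None if samples is None else set(samples)
    per_study_coef: dict[str, np.ndarray] = {}
    per_study_se: dict[str, np.ndarray] = {}
    per_study_ok: dict[str, np.ndarray] = {}
    for st in studies:
        cdf = _cohort_columns(st, clinical.df, sample_set)
        if int(cdf["dmfs_event"].sum()) < min_events:
            continue
        expr = st.data.loc[universe, cdf["sample_id"]].to_numpy(dtype=float).T  # n x G
        med = np.median(expr, axis=0)
        if method == "median_split":
            X = (expr > med).astype(float)
        else:
            X = expr - med
        beta, se, ok = univariate_cox_batch(
            cdf["dmfs_time"].to_numpy(dtype=float),
            cdf["dmfs_event"].to_numpy(dtype=int),
            X,
        )
        per_study_coef[st.study_id] = beta
        per_study_se[st.study_id] = se
        per_study_ok[st.study_id] = ok

    if len(per_study_coef) < 2:
        raise ModsurvError(
            f"only {len(per_study_coef)} study(ies) contribute >= {min_events} "
            "events; need >= 2 for a meta-analysis"
        )

    results: list[GeneMetaResult] = []
    study_ids = list(per_study_coef)
    for g_idx, gene in enumerate(universe):
        coefs, ses, used = [], [], []
        for sid in study_ids:
            if per_study_ok[sid][g_idx]:
                coefs.append(per_study_coef[sid][g_idx])
                ses.append(per_study_se[sid][g_idx])
                used.append(sid)
        if not coefs:
            continue  # gene failed in every study
        coef, se = combine_fixed_effect(coefs, ses)
        p = float(2.0 * stats.norm.sf(abs(coef) / se))
        results.append(GeneMetaResult(
            gene=str(gene),
            study_coefs={s: float(b) for s, b in zip(used, coefs)},
            study_ses={s: float(e) for s, e in zip(used, ses)},
            coef=coef, se=se, p=p,
        ))
    return results


def build_candidates(
    meta_results: Sequence[GeneMetaResult], n_max: int = 20
) -> list[CandidateModule]:
    """Nested candidate modules of the top-ranked genes, sizes 10..10*n_max.

    Candidate n holds the ``10 + (n-1)*10`` most significant genes. Ranking
    is by combined p ascending, |combined log-HR| descending, gene symbol.
    If fewer than ``10 * n_max`` genes are available the sweep is truncated
    at the largest feasible size (with a warning); fewer than 10 genes is an
    error.
    """
    ranked = sorted(meta_results, key=lambda r: (r.p, -abs(r.coef), r.gene))
    if len(ranked) < 10:
        raise ModsurvError(f"only {len(ranked)} genes with valid meta-results; need >= 10")
    feasible = min(n_max, len(ranked) // 10)
    if feasible < n_max:
        warnings.warn(
            f"only {len(ranked)} genes available; candidate sweep truncated at "
            f"size {feasible * 10}", stacklevel=2,
        )
    candidates = []
    for n in range(1, feasible + 1):
        size = 10 + (n - 1) * 10
        entries = [(r.gene, float(r.direction)) for r in ranked[:size]]
        candidates.append(CandidateModule(
            index=n, size=size,
            signature=GeneSignature(name=f"top{size}", entries=entries),
        ))
    return candidates


def _score_cohort(
    signature: GeneSignature,
    studies: Sequence[ExpressionStudy],
    clinical_df: pd.DataFrame,
    samples: set[str] | None,
) -> pd.DataFrame:
    """Score + robust-scale a signature on the analysis cohort.

    Scaling quantiles are computed within study over the cohort samples
    (the analysis population), not the full study.
    """
    parts = []
    for st in studies:
        cdf = _cohort_columns(st, clinical_df, samples)
        if len(cdf) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc = score_module(st, signature)
        part = cdf[["sample_id", "study_id", "dmfs_time", "dmfs_event",
                    "age_group", "nodal_status", "grade", "treatment"]].copy()
        part["raw"] = sc.loc[part["sample_id"]].to_numpy()
        parts.append(part)
    if not parts:
        raise ModsurvError(
            f"signature {signature.name!r}: no cohort samples could be scored"
        )
    pooled = pd.concat(parts, axis=0, ignore_index=True)
    pooled["scaled"] = robust_scale(pooled["raw"].to_numpy(), pooled["study_id"].to_numpy())
    return pooled


def _fit_candidate(
    pooled: pd.DataFrame, adjust: Sequence[str], name: str, cohort: str
) -> tuple[CoxResult, CoxResult]:
    uni = cox_stratified(
        pooled["dmfs_time"], pooled["dmfs_event"], pooled["scaled"],
        pooled["study_id"], predictor_name=name, cohort=cohort,
    )
    if not adjust:
        return uni, uni
    cc = complete_cases(pooled, adjust)
    dummies = expand_covariates(cc, adjust)
    adj = cox_stratified(
        cc["dmfs_time"], cc["dmfs_event"], cc["scaled"], cc["study_id"],
        covariates=dummies, predictor_name=name, cohort=cohort,
    )
    return uni, adj


def select_best_module(
    candidates: Sequence[CandidateModule],
    studies: Sequence[ExpressionStudy],
    clinical: ClinicalTable,
    samples: Sequence[str] | None = None,
    adjust: Sequence[str] = (),
    cohort: str = "all",
) -> DerivedSignature:
    """Score every candidate and select the one maximising
    ``min(univariate HR, adjusted HR)``; ties go to the smaller module."""
    if not candidates:
        raise ModsurvError("no candidate modules given")
    sample_set = None if samples is None else set(samples)
    rows = []
    fitted: list[CandidateModule] = []
    for cand in candidates:
        try:
            pooled = _score_cohort(cand.signature, studies, clinical.df, sample_set)
            uni, adj = _fit_candidate(pooled, list(adjust), cand.signature.name, cohort)
        except ModsurvError as exc:
            rows.append({"n": cand.index, "alpha_n": cand.size,
                         "uni_HR": np.nan, "adj_HR": np.nan,
                         "criterion": np.nan, "selected": False,
                         "error": str(exc)})
            continue
        cand.uni_hr = uni.hr
        cand.adj_hr = adj.hr
        fitted.append(cand)
        rows.append({"n": cand.index, "alpha_n": cand.size,
                     "uni_HR": cand.uni_hr, "adj_HR": cand.adj_hr,
                     "criterion": cand.criterion, "selected": False,
                     "error": ""})
    if not fitted:
        raise ModsurvError("every candidate module failed Cox fitting")
    best = fitted[0]
    for cand in fitted[1:]:  # increasing size: strict '>' keeps the smaller on ties
        if cand.criterion > best.criterion:
            best = cand
    sweep = pd.DataFrame(rows)
    sweep.loc[sweep["alpha_n"] == best.size, "selected"] = True
    return DerivedSignature(subtype=cohort, selected=best, sweep=sweep)


def evaluate_signature(
    derived: DerivedSignature | GeneSignature,
    studies: Sequence[ExpressionStudy],
    clinical: ClinicalTable,
    samples: Sequence[str] | None = None,
    adjust: Sequence[str] = (),
    in_sample: bool = True,
    cohort: str = "all",
) -> SignatureEvaluation:
    """Assess a derived signature on a cohort: univariate and adjusted HRs
    plus the median-split Kaplan-Meier log-rank comparison.

    ``in_sample`` records whether the evaluation cohort is the training
    cohort; out-of-sample evaluation on an independent cohort is the honest
    estimate (in-sample HRs of a selected module are optimistic).
    """
    signature = derived.signature if isinstance(derived, DerivedSignature) else derived
    sample_set = None if samples is None else set(samples)
    pooled = _score_cohort(signature, studies, clinical.df, sample_set)
    uni, adj = _fit_candidate(pooled, list(adjust), signature.name, cohort)
    km = km_median_split(
        pooled["scaled"].to_numpy(),
        pooled["dmfs_time"].to_numpy(),
        pooled["dmfs_event"].to_numpy(),
    )
    return SignatureEvaluation(cox_univariate=uni, cox_adjusted=adj, km=km,
                               in_sample=in_sample)


class SubtypeSignatureModel:
    """End-to-end derivation of one subtype-specific prognostic module.

    Parameters
    ----------
    studies, clinical :
        The multi-study cohort (duplicate genes collapsed, DMFS censored).
    samples :
        Sample IDs of the analysis subtype (``None`` = all samples).
    subtype :
        Label recorded on the derived signature.
    adjust :
        ``()`` for univariate selection only, ``"auto"`` to select
        covariates at ``alpha``, or an explicit list.
    """

    def __init__(
        self,
        studies: Sequence[ExpressionStudy],
        clinical: ClinicalTable,
        subtype: str = "all",
        samples: Sequence[str] | None = None,
        adjust: str | Sequence[str] = (),
        alpha: float = 0.05,
        min_events: int = 5,
        method: str = "median_split",
        n_max: int = 20,
    ) -> None:
        self.studies = list(studies)
        self.clinical = clinical
        self.subtype = subtype
        self.samples = None if samples is None else list(samples)
        self.adjust = adjust
        self.alpha = alpha
        self.min_events = min_events
        self.method = method
        self.n_max = n_max

    def fit(self) -> "SubtypeSignatureResults":
        if self.adjust == "auto":
            adjust = select_covariates(
                self.clinical, list(COVARIATE_CANDIDATES), alpha=self.alpha,
                samples=self.samples,
            )
        else:
            adjust = list(self.adjust)
        meta = per_gene_meta_cox(
            self.studies, self.clinical, samples=self.samples,
            min_events=self.min_events, method=self.method,
        )
        candidates = build_candidates(meta, n_max=self.n_max)
        derived = select_best_module(
            candidates, self.studies, self.clinical, samples=self.samples,
            adjust=adjust, cohort=self.subtype,
        )
        return SubtypeSignatureResults(derived=derived, meta=meta,
                                       adjust=adjust, model=self)


COVARIATE_CANDIDATES = ("age_group", "nodal_status", "grade", "treatment")


class SubtypeSignatureResults:
    """Derived signature plus the per-gene meta table and sweep audit."""

    def __init__(self, derived, meta, adjust, model):
        self.derived: DerivedSignature = derived
        self.meta: list[GeneMetaResult] = meta
        self.adjust: list[str] = adjust
        self.model: SubtypeSignatureModel = model

    @property
    def signature(self) -> GeneSignature:
        return self.derived.signature

    def meta_table(self) -> pd.DataFrame:
        rows = [{"gene": r.gene, "coef": r.coef, "se": r.se, "p": r.p,
                 "direction": r.direction, "n_studies": len(r.study_coefs)}
                for r in self.meta]
        return pd.DataFrame(rows).sort_values(["p", "gene"]).reset_index(drop=True)

    def summary(self) -> pd.DataFrame:
        return self.derived.sweep

    def evaluate(self, studies=None, clinical=None, samples=None,
                 in_sample=None) -> SignatureEvaluation:
        """Evaluate on the training cohort by default, or on a held-out one."""
        own = studies is None and clinical is None and samples is None
        return evaluate_signature(
            self.derived,
            self.model.studies if studies is None else studies,
            self.model.clinical if clinical is None else clinical,
            samples=self.model.samples if samples is None else samples,
            adjust=self.adjust,
            in_sample=own if in_sample is None else in_sample,
            cohort=self.derived.subtype,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<SubtypeSignatureResults subtype={self.derived.subtype!r} "
                f"size={self.derived.selected.size} "
                f"criterion={self.derived.selected.criterion:.3f}>")
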