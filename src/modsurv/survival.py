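"""Stratified Cox association of module scores with DMFS.

The central model: for a module score Z,

    h_ks(t) = h_0k(t) * exp(beta * Z_s + gamma' C_s)

with a separate, unestimated baseline hazard h_0k per study k (dataset as
stratum), optional clinical covariates C, Efron handling of tied event
times, Wald tests and normal-theory confidence intervals. Scanning many
modules applies Benjamini-Hochberg FDR control across the scan.

The scan is exposed statsmodels-style: build a :class:`ModuleDMFSModel`
from a score matrix and a clinical table, call :meth:`~ModuleDMFSModel.fit`,
and read estimates off the returned :class:`ModuleDMFSResults` (or its
``summary()`` table). :func:`module_dmfs_scan` is the functional shorthand.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .datatypes import (
    CLINICAL_CATEGORICALS,
    ClinicalTable,
    CoxResult,
    KMResult,
    ModsurvError,
    ModuleScoreMatrix,
)

__all__ = [
    "bh_adjust",
    "cox_stratified",
    "select_covariates",
    "expand_covariates",
    "module_dmfs_scan",
    "km_median_split",
    "plot_km",
    "ModuleDMFSModel",
    "ModuleDMFSResults",
    "COVARIATE_REFERENCES",
    "NonIdentifiableError",
]

#: reference level of each clinical covariate in dummy expansion
COVARIATE_REFERENCES: Mapping[str, str] = {
    "age_group": "<50",
    "nodal_status": "negative",
    "grade": "1",
    "treatment": "both",
}


class NonIdentifiableError(ModsurvError):
    """The predictor carries no information given the stratification."""


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    return fdr


def cox_stratified(
    times,
    events,
    predictor,
    strata,
    covariates: pd.DataFrame | None = None,
    predictor_name: str = "score",
    cohort: str = "all",
) -> CoxResult:
    """Stratified Cox fit; returns the result for ``predictor``.

    ``covariates``, if given, is a numeric DataFrame (dummy-expanded) aligned
    row-wise with the other arrays and adjusted for but not reported.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    predictor = np.asarray(predictor, dtype=float)
    strata = np.asarray(strata)
    n = len(times)
    if not (len(events) == len(predictor) == len(strata) == n):
        raise ModsurvError("times/events/predictor/strata must align")
    if events.sum() < 2:
        raise ModsurvError(f"need >= 2 events, got {events.sum()}")
    varies = any(
        np.ptp(predictor[strata == s]) > 0 for s in pd.unique(strata)
    )
    if not varies:
        raise NonIdentifiableError(
            f"predictor {predictor_name!r} is constant within every stratum"
        )

    df = pd.DataFrame({"time": times, "event": events, "_strat": strata,
                       predictor_name: predictor})
    if covariates is not None:
        cov = covariates.reset_index(drop=True)
        if len(cov) != n:
            raise ModsurvError("covariates must align with the other arrays")
        for col in cov.columns:
            if np.ptp(cov[col].to_numpy(dtype=float)) == 0:
                cov = cov.drop(columns=[col])
        df = pd.concat([df, cov], axis=1)

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event", strata=["_strat"],
                    fit_options={"precision": 1e-9})
    except ConvergenceError as exc:
        raise ModsurvError(
            f"Cox fit for {predictor_name!r} did not converge: {exc}"
        ) from exc
    row = cph.summary.loc[predictor_name]
    return CoxResult(
        predictor=predictor_name, cohort=cohort, n=n, n_events=int(events.sum()),
        coef=float(row["coef"]), se=float(row["se(coef)"]), p=float(row["p"]),
    )


def expand_covariates(
    clinical_df: pd.DataFrame, names: Sequence[str]
) -> pd.DataFrame:
    """Dummy-expand categorical covariates against their reference levels.

    References: age <50, node-negative, grade 1, treatment both. Rows with
    "unknown" in any requested covariate must be removed beforehand
    (complete-case analysis).
    """
    cols = {}
    for name in names:
        if name not in COVARIATE_REFERENCES:
            raise ModsurvError(f"unknown covariate {name!r}")
        ref = COVARIATE_REFERENCES[name]
        values = clinical_df[name].astype(str)
        if (values == "unknown").any():
            raise ModsurvError(
                f"covariate {name!r} has 'unknown' values; take complete cases first"
            )
        for level in CLINICAL_CATEGORICALS[name]:
            if level in (ref, "unknown"):
                continue
            cols[f"{name}={level}"] = (values == level).astype(float).to_numpy()
    return pd.DataFrame(cols, index=clinical_df.index)


def complete_cases(clinical_df: pd.DataFrame, names: Sequence[str]) -> pd.DataFrame:
    mask = np.ones(len(clinical_df), dtype=bool)
    for name in names:
        mask &= clinical_df[name].astype(str).to_numpy() != "unknown"
    return clinical_df.loc[mask]


def select_covariates(
    clinical: ClinicalTable,
    candidates: Sequence[str],
    alpha: float = 0.05,
    samples: Sequence[str] | None = None,
) -> list[str]:
    """Select clinical covariates associated with DMFS at Wald p < alpha.

    Fits one multivariate stratified Cox on all candidates simultaneously
    (complete cases only; dataset as stratum) and keeps every covariate with
    at least one non-reference level below alpha.
    """
    candidates = list(candidates)
    if not candidates:
        return []
    bad = [c for c in candidates if c not in COVARIATE_REFERENCES]
    if bad:
        raise ModsurvError(f"unknown covariate candidates: {bad}")
    df = clinical.df
    if samples is not None:
        df = df[df["sample_id"].isin(set(samples))]
    df = complete_cases(df, candidates)
    if df["dmfs_event"].sum() < 10:
        raise ModsurvError(
            f"only {int(df['dmfs_event'].sum())} events in complete cases; need >= 10"
        )
    dummies = expand_covariates(df, candidates)
    fit_df = pd.DataFrame({
        "time": df["dmfs_time"].to_numpy(dtype=float),
        "event": df["dmfs_event"].to_numpy(dtype=int),
        "_strat": df["study_id"].to_numpy(),
    })
    fit_df = pd.concat([fit_df, dummies.reset_index(drop=True)], axis=1)
    dropped = [c for c in dummies.columns if np.ptp(fit_df[c].to_numpy()) == 0]
    fit_df = fit_df.drop(columns=dropped)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(fit_df, duration_col="time", event_col="event", strata=["_strat"])
    pvals = cph.summary["p"]
    selected = []
    for name in candidates:
        levels = [c for c in pvals.index if c.startswith(f"{name}=")]
        if levels and (pvals.loc[levels] < alpha).any():
            selected.append(name)
    return selected


class ModuleDMFSModel:
    """Stratified Cox scan of module scores against DMFS.

    Parameters
    ----------
    scores :
        Module score matrix (scaled scores are used: HRs are per one-unit
        scaled-score increase).
    clinical :
        Clinical table; merged with scores on sample_id.
    cohort :
        Label for the analysis population ("all" or a subtype name).
    samples :
        Optional subset of sample IDs defining the cohort.
    adjust :
        ``None`` for univariate, ``"auto"`` to select covariates at
        ``alpha`` first, or an explicit list of covariate names.
    """

    def __init__(
        self,
        scores: ModuleScoreMatrix,
        clinical: ClinicalTable,
        cohort: str = "all",
        samples: Sequence[str] | None = None,
        adjust: str | Sequence[str] | None = None,
        covariate_candidates: Sequence[str] = tuple(COVARIATE_REFERENCES),
        alpha: float = 0.05,
        fdr_threshold: float = 0.05,
    ) -> None:
        self.scores = scores
        self.clinical = clinical
        self.cohort = cohort
        self.samples = None if samples is None else list(samples)
        self.adjust = adjust
        self.covariate_candidates = list(covariate_candidates)
        self.alpha = alpha
        self.fdr_threshold = fdr_threshold

    def _cohort_frame(self) -> pd.DataFrame:
        df = self.clinical.df.set_index("sample_id")
        idx = self.scores.samples.intersection(df.index)
        if self.samples is not None:
            idx = idx.intersection(pd.Index(self.samples))
        if len(idx) == 0:
            raise ModsurvError("no samples in common between scores and clinical table")
        merged = df.loc[idx].copy()
        merged.index.name = "sample_id"
        merged["_study"] = self.scores.study_ids.loc[idx]
        return merged

    def fit(self) -> "ModuleDMFSResults":
        merged = self._cohort_frame()
        if self.adjust is None or self.adjust == "none":
            covariate_names: list[str] = []
        elif self.adjust == "auto":
            covariate_names = select_covariates(
                ClinicalTable(merged.reset_index()), self.covariate_candidates,
                alpha=self.alpha,
            )
        else:
            covariate_names = list(self.adjust)

        if covariate_names:
            merged = complete_cases(merged, covariate_names)
            dummies = expand_covariates(merged, covariate_names)
        else:
            dummies = None

        results: list[CoxResult] = []
        failed: dict[str, str] = {}
        scaled = self.scores.scaled.loc[merged.index]
        for module in self.scores.modules:
            try:
                res = cox_stratified(
                    merged["dmfs_time"], merged["dmfs_event"],
                    scaled[module], merged["_study"],
                    covariates=dummies, predictor_name=module, cohort=self.cohort,
                )
            except ModsurvError as exc:
                failed[module] = str(exc)
                continue
            results.append(res)
        if results:
            # BH step-up across the modules that produced a fit
            fdr = bh_adjust([r.p for r in results])
            for r, q in zip(results, fdr):
                r.fdr = float(q)
        return ModuleDMFSResults(
            results=results, failed=failed, cohort=self.cohort,
            covariates=covariate_names, fdr_threshold=self.fdr_threshold,
            n=len(merged), n_events=int(merged["dmfs_event"].sum()),
        )


class ModuleDMFSResults:
    """Results of a module scan: per-module CoxResult with BH-FDR."""

    def __init__(self, results, failed, cohort, covariates, fdr_threshold, n, n_events):
        self.results: list[CoxResult] = results
        self.failed: dict[str, str] = failed
        self.cohort = cohort
        self.covariates: list[str] = covariates
        self.fdr_threshold = fdr_threshold
        self.n = n
        self.n_events = n_events

    def significant(self) -> list[CoxResult]:
        return [r for r in self.results if r.fdr is not None and r.fdr < self.fdr_threshold]

    def summary(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            d = r.as_dict()
            d["significant"] = r.fdr is not None and r.fdr < self.fdr_threshold
            rows.append(d)
        for module, msg in self.failed.items():
            rows.append({"predictor": module, "cohort": self.cohort, "n": self.n,
                         "n_events": self.n_events, "HR": np.nan, "CI_low": np.nan,
                         "CI_high": np.nan, "p": np.nan, "FDR": np.nan,
                         "significant": False})
        return pd.DataFrame(rows)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        adj = ",".join(self.covariates) if self.covariates else "none"
        return (f"<ModuleDMFSResults cohort={self.cohort!r} modules={len(self.results)} "
                f"adjusted_for={adj} n={self.n} events={self.n_events}>")


def module_dmfs_scan(
    scores: ModuleScoreMatrix,
    clinical: ClinicalTable,
    cohort: str = "all",
    samples: Sequence[str] | None = None,
    adjust: str | Sequence[str] | None = None,
    **kwargs,
) -> ModuleDMFSResults:
    """One stratified Cox per module with BH-FDR across the scan."""
    model = ModuleDMFSModel(scores, clinical, cohort=cohort, samples=samples,
                            adjust=adjust, **kwargs)
    return model.fit()


def km_median_split(scores, times, events) -> KMResult:
    """Split at the score median into high (> median) / low (<= median) risk
    groups and compare their Kaplan-Meier curves with a log-rank test."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(scores) < 4:
        raise ModsurvError("need >= 4 samples for a median split")
    if np.ptp(scores) == 0:
        raise ModsurvError("score has zero variance; cannot median-split")
    med = np.median(scores)
    high = scores > med
    if high.all() or (~high).all():
        raise ModsurvError("median split produced an empty group (mass at the median)")
    surv = {}
    sizes = {}
    for label, mask in (("high", high), ("low", ~high)):
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=label)
        surv[label] = kmf.survival_function_
        sizes[label] = int(mask.sum())
    lr = logrank_test(times[high], times[~high], events[high], events[~high])
    return KMResult(
        group_labels=("high", "low"), survival_functions=surv,
        group_sizes=sizes, chi_square=float(lr.test_statistic), p=float(lr.p_value),
    )


def plot_km(km: KMResult, path) -> None:
    """Render the two KM curves to a file (format from the extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, sf in km.survival_functions.items():
        ax.step(sf.index, sf.iloc[:, 0], where="post",
                label=f"{label} (n={km.group_sizes[label]})")
    ax.set_xlabel("years")
    ax.set_ylabel("DMFS probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(f"log-rank p = {km.p:.2g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
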