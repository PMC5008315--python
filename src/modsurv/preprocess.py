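"""Preprocessing: probe collapsing, survival censoring, receptor cutoffs.

Receptor status (ER, HER2) is not taken from annotations but derived from
the expression of the receptor gene itself: a two-component normal mixture
is fitted per study and the cutoff placed where the posterior probability of
the high-expression component equals 0.5. This mirrors the common practice
of dichotomising bimodal receptor-gene expression study by study, so that
platform- and normalisation-specific shifts do not leak across studies.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

from .datatypes import ClinicalTable, ExpressionStudy, MixtureCutoff, ModsurvError

__all__ = [
    "collapse_duplicate_genes",
    "censor_dmfs",
    "fit_receptor_cutoff",
    "dichotomize_receptor",
]


def collapse_duplicate_genes(study: ExpressionStudy) -> ExpressionStudy:
    """Collapse duplicate gene rows to their per-sample arithmetic mean.

    Multiple probes mapping to one symbol are averaged; unique rows are
    untouched and first-occurrence row order is preserved. Idempotent.
    """
    if not study.has_duplicate_genes:
        return ExpressionStudy(study.study_id, study.data.copy())
    collapsed = study.data.groupby(level=0, sort=False).mean()
    order = study.data.index.drop_duplicates()
    collapsed = collapsed.loc[order]
    return ExpressionStudy(study.study_id, collapsed)


def censor_dmfs(clinical: ClinicalTable, horizon_years: float = 10.0) -> ClinicalTable:
    """Administratively censor DMFS at ``horizon_years``.

    Times beyond the horizon are truncated to it and their events zeroed;
    times at or below the horizon (including events exactly at it) are kept.
    """
    if horizon_years <= 0:
        raise ModsurvError("horizon_years must be positive")
    df = clinical.df.copy()
    times = df["dmfs_time"].to_numpy(dtype=float)
    if np.any(times < 0):
        raise ModsurvError("negative dmfs_time encountered")
    over = times > horizon_years
    df.loc[over, "dmfs_time"] = horizon_years
    df.loc[over, "dmfs_event"] = 0
    return clinical.replace(df)


def _posterior_half_point(means, sds, weights) -> float:
    """Expression value between the component means where the posterior of
    the upper component is 0.5, i.e. the weighted densities are equal."""
    (m_lo, m_hi), (s_lo, s_hi), (w_lo, w_hi) = means, sds, weights

    def logdiff(x):
        return (np.log(w_hi) + stats.norm.logpdf(x, m_hi, s_hi)
                - np.log(w_lo) - stats.norm.logpdf(x, m_lo, s_lo))

    a, b = m_lo, m_hi
    fa, fb = logdiff(a), logdiff(b)
    if fa == 0:
        return float(a)
    if fb == 0:
        return float(b)
    if fa * fb > 0:
        # equal-posterior point does not fall between the means (extreme
        # weight imbalance); use the midpoint as the closest sensible cut
        return float(0.5 * (m_lo + m_hi))
    return float(optimize.brentq(logdiff, a, b, xtol=1e-10))


def fit_receptor_cutoff(
    study: ExpressionStudy,
    gene: str,
    max_iter: int = 200,
    tol: float = 1e-6,
    restarts: int = 5,
    seed: int = 0,
) -> MixtureCutoff:
    """Fit a 2-component univariate Gaussian mixture to one gene's expression.

    EM with k-means initialisation and ``restarts`` random restarts, best
    log-likelihood kept. Degenerate fits (a component weight below 1e-3, or
    coincident means) fall back to the study median with ``converged=False``
    and a warning.
    """
    if gene not in study.data.index:
        raise ModsurvError(f"gene {gene!r} not in study {study.study_id!r}")
    x = study.data.loc[gene].to_numpy(dtype=float).reshape(-1, 1)
    if x.shape[0] < 20:
        raise ModsurvError(
            f"need >= 20 samples to fit a receptor mixture, got {x.shape[0]}"
        )

    def _fallback(reason: str) -> MixtureCutoff:
        med = float(np.median(x))
        warnings.warn(
            f"{study.study_id}/{gene}: degenerate mixture fit ({reason}); "
            "falling back to the study median cutoff", stacklevel=3,
        )
        sd = float(np.std(x))
        return MixtureCutoff(
            study_id=study.study_id, gene=gene,
            means=(med, med), sds=(sd, sd), weights=(0.5, 0.5),
            cutoff=med, converged=False,
        )

    if np.ptp(x) == 0:
        return _fallback("constant expression")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=restarts,
        init_params="kmeans", max_iter=max_iter, tol=tol, random_state=seed,
    )
    try:
        gm.fit(x)
    except ValueError as exc:
        return _fallback(str(exc))
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    if weights.min() < 1e-3 or (means[1] - means[0]) < 1e-8:
        return _fallback(f"weights={weights.round(4)}, means={means.round(4)}")
    cutoff = _posterior_half_point(tuple(means), tuple(sds), tuple(weights))
    return MixtureCutoff(
        study_id=study.study_id, gene=gene,
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        cutoff=cutoff, converged=bool(gm.converged_),
    )


def dichotomize_receptor(
    study: ExpressionStudy,
    clinical: ClinicalTable,
    gene: str,
    cutoff: float | MixtureCutoff,
    receptor: str = "er",
) -> ClinicalTable:
    """Fill er_status/her2_status from expression of ``gene`` vs ``cutoff``.

    Positive iff expression is strictly greater than the cutoff (a value
    exactly at the cutoff is negative), so a degenerate constant gene yields
    all-negative calls. Only samples of this study are updated.
    """
    if receptor not in ("er", "her2"):
        raise ModsurvError(f"receptor must be 'er' or 'her2', got {receptor!r}")
    if gene not in study.data.index:
        raise ModsurvError(f"gene {gene!r} not in study {study.study_id!r}")
    cut = cutoff.cutoff if isinstance(cutoff, MixtureCutoff) else float(cutoff)
    expr = study.data.loc[gene]
    col = f"{receptor}_status"
    df = clinical.df.copy()
    in_study = df["sample_id"].isin(study.samples)
    status = expr.loc[df.loc[in_study, "sample_id"]].to_numpy() > cut
    df.loc[in_study, col] = np.where(status, "positive", "negative")
    return clinical.replace(df)
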