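"""Signed gene-module scores and robust within-study rescaling.

The score of module M for sample s is

    score_s = sum_{i in M} w_i * x_is / sum_{i in M} |w_i|

with x_is the log2 expression of gene i and w_i its signed weight. Raw
scores are then rescaled within each study so that the 2.5%, 50% and 97.5%
percentiles equal -1, 0 and +1, which makes scores comparable across studies
profiled on different platforms. Because three quantile anchors cannot be
matched by one affine map, a two-piece linear map hinged at the median is
used:

    y = (x - q50) / (q50 - q2.5)    for x <  q50
    y = (x - q50) / (q97.5 - q50)   for x >= q50

The map is monotone, so ranks within a study are preserved. Quantiles are
taken as order statistics (numpy ``method="lower"``): because the map then
hinges at an actual data point, the empirical 2.5/50/97.5 percentiles of the
scaled scores hit the anchors exactly (to machine precision) for any sample
size, which an interpolated median cannot guarantee when its two straddling
order statistics fall on opposite sides of the hinge.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, GeneSignature, ModsurvError, ModuleScoreMatrix

__all__ = [
    "ANCHOR_PROBS",
    "anchor_quantiles",
    "score_module",
    "robust_scale",
    "score_signatures",
    "module_correlations",
    "DegenerateSpreadError",
]


class DegenerateSpreadError(ModsurvError):
    """Raised when a study's score distribution has no usable spread."""


#: percentile anchors pinned to -1 / 0 / +1 by the robust rescaling
ANCHOR_PROBS = (0.025, 0.5, 0.975)


def anchor_quantiles(x) -> np.ndarray:
    """The package's quantile convention: order statistics (method='lower')."""
    return np.quantile(np.asarray(x, dtype=float), ANCHOR_PROBS, method="lower")


def score_module(study: ExpressionStudy, signature: GeneSignature) -> pd.Series:
    """Raw signed module score per sample for one study.

    Signature genes absent from the study are dropped with a warning; both
    the numerator and the |w| denominator are restricted to the genes
    present, preserving the score's range. At least one signature gene must
    be present.
    """
    if study.has_duplicate_genes:
        raise ModsurvError(
            f"study {study.study_id!r} has duplicate gene rows; collapse first"
        )
    present = [(g, w) for g, w in signature.entries if g in study.data.index]
    if not present:
        raise ModsurvError(
            f"signature {signature.name!r}: no genes present in study {study.study_id!r}"
        )
    if len(present) < len(signature):
        missing = sorted(set(signature.genes) - {g for g, _ in present})
        warnings.warn(
            f"signature {signature.name!r}: {len(missing)} gene(s) missing from "
            f"study {study.study_id!r}: {missing[:5]}{'...' if len(missing) > 5 else ''}",
            stacklevel=2,
        )
    genes = [g for g, _ in present]
    w = np.array([wt for _, wt in present], dtype=float)
    x = study.data.loc[genes].to_numpy(dtype=float)
    scores = (w @ x) / np.abs(w).sum()
    return pd.Series(scores, index=study.samples, name=signature.name)


def _scale_one_study(x: np.ndarray, study_id: str) -> np.ndarray:
    if len(x) < 5:
        raise ModsurvError(
            f"study {study_id!r}: need >= 5 samples to robust-scale, got {len(x)}"
        )
    # order-statistic quantiles so the anchors are hit exactly (module doc)
    q_lo, q_med, q_hi = anchor_quantiles(x)
    if q_lo == q_med or q_med == q_hi:
        raise DegenerateSpreadError(
            f"study {study_id!r}: degenerate score spread "
            f"(q2.5={q_lo:g}, q50={q_med:g}, q97.5={q_hi:g})"
        )
    y = np.where(x < q_med, (x - q_med) / (q_med - q_lo), (x - q_med) / (q_hi - q_med))
    return y


def robust_scale(raw: Sequence[float] | pd.Series, study_ids: Sequence[str] | pd.Series) -> np.ndarray:
    """Rescale raw scores within each study to the -1/0/+1 quantile anchors."""
    raw = np.asarray(raw, dtype=float)
    study_ids = np.asarray(study_ids)
    if raw.shape != study_ids.shape:
        raise ModsurvError("raw scores and study ids must align")
    out = np.empty_like(raw)
    for sid in pd.unique(study_ids):
        mask = study_ids == sid
        out[mask] = _scale_one_study(raw[mask], str(sid))
    return out


def score_signatures(
    studies: Iterable[ExpressionStudy], signatures: Sequence[GeneSignature]
) -> ModuleScoreMatrix:
    """Score every signature on every study; return raw + scaled matrices."""
    studies = list(studies)
    if not studies:
        raise ModsurvError("no studies given")
    raw_parts = []
    for study in studies:
        cols = {sig.name: score_module(study, sig) for sig in signatures}
        part = pd.DataFrame(cols)
        part.insert(0, "_study", study.study_id)
        raw_parts.append(part)
    pooled = pd.concat(raw_parts, axis=0)
    if pooled.index.duplicated().any():
        raise ModsurvError("sample IDs collide across studies")
    study_ids = pooled.pop("_study")
    scaled = pooled.copy()
    for name in scaled.columns:
        scaled[name] = robust_scale(pooled[name].to_numpy(), study_ids.to_numpy())
    return ModuleScoreMatrix(raw=pooled, scaled=scaled, study_ids=study_ids)


def module_correlations(scores: ModuleScoreMatrix | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between module scores pooled across studies.

    Zero-variance modules get NA correlations; the diagonal is 1 for valid
    modules.
    """
    df = scores.scaled if isinstance(scores, ModuleScoreMatrix) else scores
    if df.shape[0] < 3:
        raise ModsurvError("need >= 3 samples for module correlations")
    if df.shape[1] < 2:
        raise ModsurvError("need >= 2 modules for module correlations")
    corr = df.corr(method="pearson")
    variances = df.var(axis=0).to_numpy()
    valid = variances > 0
    for j, name in enumerate(df.columns):
        if valid[j]:
            corr.loc[name, name] = 1.0
        else:
            corr.loc[name, :] = np.nan
            corr.loc[:, name] = np.nan
    return corr
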