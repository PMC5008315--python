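"""Nearest-centroid molecular subtyping.

Each sample is correlated (Spearman by default) against subtype centroids
over the genes shared between the study and the centroid matrix, after
per-gene median centering within the study; the best-correlated subtype is
assigned. This is a generic nearest-centroid classifier in the PAM50 style:
it recovers latent subtype structure when centroids are separated relative
to noise, but makes no claim of matching any specific published
implementation probe for probe.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CentroidMatrix, ExpressionStudy, ModsurvError, SubtypeAssignment

__all__ = ["assign_subtypes", "filter_analysis_subtypes", "assignments_frame"]

_SIMILARITIES = ("spearman", "pearson")


def assign_subtypes(
    study: ExpressionStudy,
    centroids: CentroidMatrix,
    similarity: str = "spearman",
) -> list[SubtypeAssignment]:
    """Assign every sample of a study to its nearest centroid.

    Requires at least 50% of centroid genes to be present in the study.
    Zero-variance sample vectors are unclassifiable and labelled ``"NA"``.
    Exact similarity ties are broken by centroid column order and flagged.
    """
    if similarity not in _SIMILARITIES:
        raise ModsurvError(f"similarity must be one of {_SIMILARITIES}")
    if study.has_duplicate_genes:
        raise ModsurvError(
            f"study {study.study_id!r} has duplicate gene rows; collapse first"
        )
    shared = centroids.genes.intersection(study.genes)
    if len(shared) < 0.5 * len(centroids.genes):
        missing = sorted(set(centroids.genes) - set(study.genes))
        raise ModsurvError(
            f"study {study.study_id!r}: only {len(shared)}/{len(centroids.genes)} "
            f"centroid genes present (<50%); missing: {missing}"
        )
    # keep centroid gene order for determinism
    shared = [g for g in centroids.genes if g in set(shared)]
    expr = study.data.loc[shared]
    expr = expr.sub(expr.median(axis=1), axis=0)  # per-gene median centering
    cent = centroids.data.loc[shared]
    subtypes = centroids.subtypes

    raw = study.data.loc[shared].to_numpy(dtype=float)
    x = expr.to_numpy(dtype=float)  # genes x samples
    c = cent.to_numpy(dtype=float)  # genes x subtypes
    if similarity == "spearman":
        x = stats.rankdata(x, axis=0)
        c = stats.rankdata(c, axis=0)

    xc = x - x.mean(axis=0)
    cc = c - c.mean(axis=0)
    xn = np.linalg.norm(xc, axis=0)
    cn = np.linalg.norm(cc, axis=0)
    # a flat raw expression vector carries no subtype information
    degenerate = (np.ptp(raw, axis=0) == 0) | (xn == 0)
    xn_safe = np.where(degenerate, 1.0, xn)
    sims = (xc.T @ cc) / np.outer(xn_safe, cn)  # samples x subtypes

    out: list[SubtypeAssignment] = []
    for j, sample in enumerate(study.samples):
        if degenerate[j]:
            out.append(SubtypeAssignment(
                sample_id=str(sample), label="NA",
                similarities={s: float("nan") for s in subtypes},
                margin=float("nan"),
            ))
            continue
        row = sims[j]
        best = int(np.argmax(row))
        order = np.sort(row)[::-1]
        margin = float(order[0] - order[1])
        tie = bool(np.sum(row == row[best]) > 1)
        out.append(SubtypeAssignment(
            sample_id=str(sample), label=subtypes[best],
            similarities={s: float(v) for s, v in zip(subtypes, row)},
            margin=margin, tie=tie,
        ))
    return out


def filter_analysis_subtypes(
    assignments: Iterable[SubtypeAssignment], keep: Sequence[str]
) -> tuple[list[SubtypeAssignment], dict[str, int]]:
    """Restrict to the subtypes under analysis (e.g. drop normal-like).

    Returns the retained assignments and the per-subtype counts of the
    input. Warns if nothing survives the filter.
    """
    keep = list(keep)
    if not keep:
        raise ModsurvError("keep must be a non-empty list of subtype labels")
    assignments = list(assignments)
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.label] = counts.get(a.label, 0) + 1
    kept = [a for a in assignments if a.label in set(keep)]
    if assignments and not kept:
        warnings.warn("no samples left after subtype filtering", stacklevel=2)
    return kept, counts


def assignments_frame(assignments: Iterable[SubtypeAssignment]) -> pd.DataFrame:
    """Tabulate assignments: one row per sample with label, margin, tie."""
    rows = [
        {"sample_id": a.sample_id, "subtype": a.label, "margin": a.margin, "tie": a.tie}
        for a in assignments
    ]
    return pd.DataFrame(rows, columns=["sample_id", "subtype", "margin", "tie"])
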