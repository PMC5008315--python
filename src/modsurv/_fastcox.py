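"""Vectorised single-covariate Cox partial-likelihood fits.

The per-gene derivation step needs thousands of univariate Cox fits (one
per gene per study). This module fits all genes of one study at once with a
damped Newton iteration on the Efron partial likelihood, vectorised over
genes. It is deliberately limited to one covariate per fit; the general
multivariate stratified model goes through lifelines.

Cross-checked against lifelines in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["univariate_cox_batch", "univariate_cox"]

_MAX_ABS_BETA = 10.0  # beyond this the MLE is effectively divergent


def _group_structure(time: np.ndarray, event: np.ndarray):
    """Sort descending by time; return sorted order and event-time groups.

    Each group is ``(risk_count, death_row_indices)`` in the sorted frame:
    the risk set of an event time t is the first ``risk_count`` rows
    (samples with time >= t); censored samples tied with an event time stay
    in its risk set.
    """
    order = np.argsort(-time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    groups = []
    for ut in np.unique(t_sorted[e_sorted == 1]):
        rows = np.nonzero((t_sorted == ut) & (e_sorted == 1))[0]
        risk_count = int(np.searchsorted(-t_sorted, -ut, side="right"))
        groups.append((risk_count, rows))
    # iterate from largest time to smallest (order irrelevant to the sums)
    return order, groups


def univariate_cox_batch(
    time: np.ndarray,
    event: np.ndarray,
    X: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit one univariate Cox model per column of ``X`` (Efron ties).

    Returns ``(beta, se, ok)`` arrays of length ``X.shape[1]``. ``ok`` is
    False for degenerate covariates (constant), non-convergence, or
    effectively infinite MLEs.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, G = X.shape
    if time.shape != (n,) or event.shape != (n,):
        raise ValueError("time/event must align with rows of X")
    if event.sum() < 2:
        raise ValueError("need >= 2 events")

    order, groups = _group_structure(time, event)
    Xs = X[order]
    Xs2 = Xs ** 2

    variable = np.ptp(Xs, axis=0) > 0
    beta = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    hess_final = np.full(G, -np.inf)

    for _ in range(max_iter):
        eta = Xs * beta  # n x G
        eta -= eta.max(axis=0)  # stabilise exp; cancels in ratios
        W = np.exp(eta)
        C0 = np.cumsum(W, axis=0)
        C1 = np.cumsum(Xs * W, axis=0)
        C2 = np.cumsum(Xs2 * W, axis=0)

        grad = np.zeros(G)
        hess = np.zeros(G)
        for risk_count, rows in groups:
            S0 = C0[risk_count - 1]
            S1 = C1[risk_count - 1]
            S2 = C2[risk_count - 1]
            d = len(rows)
            grad += Xs[rows].sum(axis=0)
            if d == 1:
                den = S0
                e1 = S1 / den
                grad -= e1
                hess -= S2 / den - e1 ** 2
            else:
                D0 = W[rows].sum(axis=0)
                D1 = (Xs[rows] * W[rows]).sum(axis=0)
                D2 = (Xs2[rows] * W[rows]).sum(axis=0)
                for j in range(d):
                    f = j / d
                    den = S0 - f * D0
                    e1 = (S1 - f * D1) / den
                    grad -= e1
                    hess -= (S2 - f * D2) / den - e1 ** 2

        hess_final = hess
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(hess < 0, -grad / hess, 0.0)
        step = np.clip(step, -1.0, 1.0)
        step = np.where(variable & ~converged, step, 0.0)
        beta = beta + step
        newly = np.abs(step) < tol
        converged |= newly
        if converged[variable].all() or np.all(np.abs(beta) > _MAX_ABS_BETA):
            if converged[variable].all():
                break
        beta = np.clip(beta, -_MAX_ABS_BETA, _MAX_ABS_BETA)

    ok = variable & converged & (hess_final < -1e-12) & (np.abs(beta) < _MAX_ABS_BETA)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(ok, np.sqrt(-1.0 / hess_final), np.inf)
    beta = np.where(ok, beta, np.nan)
    return beta, se, ok


def univariate_cox(time, event, x, **kwargs) -> tuple[float, float, bool]:
    """Single-covariate convenience wrapper around the batch fitter."""
    beta, se, ok = univariate_cox_batch(time, event, np.asarray(x, dtype=float)[:, None], **kwargs)
    return float(beta[0]), float(se[0]), bool(ok[0])
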