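"""Mahalanobis-distance scoring of beat-wise parameter vectors.

A reference window of beats (typically a quiet pre-intervention stretch)
defines a multivariate normal baseline — mean vector and sample covariance —
for a chosen parameter set, e.g. (σTn, σTp) for repolarisation spread or
(ST level, QT) for the conventional indices.  Each beat is then scored by

    MD(x) = sqrt((x − m)ᵀ S⁻¹ (x − m))

so MD² of in-reference beats is approximately χ²-distributed with one degree
of freedom per parameter.  Each intervention segment should be scored
against its own immediately-preceding quiet window, since the baseline
itself drifts across repeated interventions.

Highly correlated parameter pairs (σTn/σTp in particular) can make the
sample covariance near-singular; a small ridge is added to the diagonal when
the condition number exceeds 1e8.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = ["ReferenceModel", "fit_reference", "md_series"]


@dataclass
class ReferenceModel:
    """Baseline distribution of selected parameters over a reference window."""

    parameters: list[str]
    window: tuple[int, int]
    mean: np.ndarray
    covariance: np.ndarray
    regularization: float
    n_used: int
    n_missing: int


def fit_reference(series: np.ndarray, window: tuple[int, int],
                  parameters: list[str] | None = None,
                  cond_threshold: float = 1e8,
                  ridge_eps: float = 1e-6) -> ReferenceModel:
    """Estimate the baseline mean and covariance over ``window``.

    ``series`` is (n_beats, n_params); rows with any NaN inside the window
    are skipped (their count is reported).  At least ``max(10, 2·dim)``
    usable beats are required.  When the sample covariance has condition
    number above ``cond_threshold`` (or is singular), ``ridge_eps ·
    trace/dim`` is added to the diagonal — with an absolute floor for the
    all-constant case, where the trace itself vanishes.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    lo, hi = int(window[0]), int(window[1])
    W = X[lo:hi]
    ok = ~np.isnan(W).any(axis=1)
    Wu = W[ok]
    dim = X.shape[1]
    need = max(10, 2 * dim)
    if Wu.shape[0] < need:
        raise ValueError(
            f"reference window has {Wu.shape[0]} usable beats; "
            f"need at least {need} for {dim} parameters")
    mean = Wu.mean(axis=0)
    cov = np.cov(Wu, rowvar=False, ddof=1).reshape(dim, dim)
    reg = 0.0
    cond = np.linalg.cond(cov)
    if not np.isfinite(cond) or cond > cond_threshold:
        reg = ridge_eps * np.trace(cov) / dim
        if reg <= 0.0:
            reg = 1e-12  # constant reference: MD of the constant is still 0
        cov = cov + reg * np.eye(dim)
    if parameters is None:
        parameters = [f"p{i}" for i in range(dim)]
    return ReferenceModel(parameters=list(parameters), window=(lo, hi),
                          mean=mean, covariance=cov, regularization=reg,
                          n_used=int(Wu.shape[0]),
                          n_missing=int((~ok).sum()))


def md_series(series: np.ndarray, ref: ReferenceModel) -> np.ndarray:
    """Mahalanobis distance of every beat from the reference distribution.

    Missing beats (any NaN in the row) yield NaN.  The distance itself is
    reported, not its square.
    """
    X = np.asarray(series, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != ref.mean.size:
        raise ValueError(f"series has {X.shape[1]} parameters, reference "
                         f"has {ref.mean.size} ({ref.parameters})")
    out = np.full(X.shape[0], np.nan)
    ok = ~np.isnan(X).any(axis=1)
    if ok.any():
        d = X[ok] - ref.mean
        factor = cho_factor(ref.covariance)
        out[ok] = np.sqrt(np.einsum("ij,ij->i", d, cho_solve(factor, d.T).T))
    return out
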