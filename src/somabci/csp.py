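"""Common spatial patterns for two-class variance discrimination.

CSP solves the generalized eigenproblem ``C_hand w = lambda (C_hand +
C_foot) w`` on class-average covariances; eigenvalues lie in [0, 1] and the
filters at both ends of the spectrum maximize the variance of one class
while minimizing the other's.  Features are normalized log variances of the
top and bottom ``m_pairs`` filter outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .containers import FOOT, HAND, TrialSet

__all__ = ["CSPModel", "fit_csp", "transform_csp"]


@dataclass
class CSPModel:
    filters: np.ndarray      # (n_channels, n_channels), columns sorted by eigenvalue desc
    eigenvalues: np.ndarray  # descending, in [0, 1]
    m_pairs: int
    class_order: tuple[str, str] = (HAND, FOOT)

    @property
    def n_channels(self) -> int:
        return self.filters.shape[0]


def _class_covariance(data: np.ndarray, trace_normalize: bool = True) -> np.ndarray:
    """Average of per-trial covariances, each normalized by its trace."""
    covs = np.einsum("tcs,tds->tcd", data, data)
    if not trace_normalize:
        return covs.mean(axis=0)
    traces = np.einsum("tcc->t", covs)
    if np.any(traces <= 0):
        raise ValueError("trial with zero power cannot be trace-normalized")
    return (covs / traces[:, None, None]).mean(axis=0)


def fit_csp(trialset: TrialSet, m_pairs: int, shrinkage: float = 1e-6,
            trace_normalize: bool = True) -> CSPModel:
    """Fit CSP filters on a labeled two-class trial set.

    Each class covariance is shrunk toward a scaled identity,
    ``C <- (1 - delta) C + delta (trace(C)/n) I``, which keeps the composite
    covariance invertible for small channel counts and trial numbers.
    Per-trial trace normalization (the default) equalizes trial power before
    averaging; note it makes the eigenvalues invariant to channel mixing only
    approximately, whereas with ``trace_normalize=False`` and zero shrinkage
    the invariance is exact.
    """
    n_ch = trialset.n_channels
    if n_ch < 2:
        raise ValueError("CSP needs at least 2 channels")
    if not 1 <= m_pairs <= n_ch // 2:
        raise ValueError(f"m_pairs must lie in [1, {n_ch // 2}] for {n_ch} channels")
    covs = {}
    for label in (HAND, FOOT):
        mask = trialset.labels == label
        if mask.sum() < 2:
            raise ValueError(f"need at least 2 trials of class '{label}'")
        c = _class_covariance(trialset.data[mask], trace_normalize)
        covs[label] = (1.0 - shrinkage) * c + shrinkage * (np.trace(c) / n_ch) * np.eye(n_ch)
    composite = covs[HAND] + covs[FOOT]
    if np.linalg.matrix_rank(composite) < n_ch:
        raise ValueError("composite covariance is rank-deficient even after shrinkage")
    w, v = linalg.eigh(covs[HAND], composite)
    order = np.argsort(-w, kind="stable")
    eigenvalues = np.clip(w[order], 0.0, 1.0)
    return CSPModel(v[:, order], eigenvalues, m_pairs)


def transform_csp(model: CSPModel, trialset: TrialSet,
                  m_pairs: int | None = None) -> np.ndarray:
    """Normalized log-variance features, shape (n_trials, 2 * m_pairs).

    Each trial is projected onto the ``m_pairs`` top- and bottom-eigenvalue
    filters; each projected variance is divided by the sum over the 2 m
    retained filters before the log, so exp(features) sums to one per trial.
    """
    m = model.m_pairs if m_pairs is None else m_pairs
    if trialset.n_channels != model.n_channels:
        raise ValueError("channel count does not match the fitted model")
    if not 1 <= m <= model.n_channels // 2:
        raise ValueError(f"m_pairs={m} exceeds model capacity ({model.n_channels // 2})")
    sel = np.r_[np.arange(m), np.arange(model.n_channels - m, model.n_channels)]
    projected = np.einsum("cf,tcs->tfs", model.filters[:, sel], trialset.data)
    variances = projected.var(axis=2)
    normalized = variances / variances.sum(axis=1, keepdims=True)
    return np.log(np.maximum(normalized, 1e-300))
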