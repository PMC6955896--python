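"""sLORETA inverse solution.

The minimum-norm kernel ``T = L' (L L' + alpha * H)^+`` maps average-
referenced sensor data to source amplitudes (H is the centering operator of
the average reference, and the pseudoinverse absorbs the rank deficiency it
introduces).  sLORETA then standardizes each source estimate by the square
root of the corresponding diagonal entry of the resolution matrix
``R = T L``, assuming identity noise covariance.  With fixed radial
orientations the standardizer is a positive scalar per source, and the
standardized power of a single noiseless source peaks exactly at the true
location (the zero-localization-error property).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .headmodel import LeadField, SourceSpace

__all__ = ["InverseOperator", "SourceEstimate", "compute_inverse_operator",
           "apply_inverse", "localization_error"]

_RANK_CUTOFF = 1e-12  # relative eigenvalue cutoff for the average-reference subspace


@dataclass
class InverseOperator:
    kernel: np.ndarray        # (n_sources, n_electrodes) minimum-norm matrix T
    standardizer: np.ndarray  # (n_sources,) sqrt of diag(T L); 0 marks unreachable
    reg_param: float
    leadfield_ref: LeadField = field(repr=False, default=None)

    @property
    def unreachable(self) -> np.ndarray:
        """Boolean mask of sources the lead field cannot express."""
        return self.standardizer == 0.0

    @property
    def n_sources(self) -> int:
        return self.kernel.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.kernel.shape[1]


@dataclass
class SourceEstimate:
    amplitudes: np.ndarray  # (n_sources, n_samples), standardized
    space: str = "source"

    @property
    def power(self) -> np.ndarray:
        """Time-averaged standardized power per source."""
        return np.mean(self.amplitudes ** 2, axis=1)


def compute_inverse_operator(leadfield: LeadField, reg_param: float | None = None,
                             snr: float = 3.0) -> InverseOperator:
    """Build the sLORETA operator from an average-referenced lead field.

    ``reg_param`` is the Tikhonov alpha; when omitted it defaults to
    ``trace(L L') / (n_electrodes * snr**2)``, the standard minimum-norm
    scaling of the regularizer to an assumed sensor SNR.
    """
    L = leadfield.matrix
    n_e = L.shape[0]
    if reg_param is not None and reg_param < 0:
        raise ValueError("reg_param must be non-negative")
    gram = L @ L.T
    if reg_param is None:
        reg_param = float(np.trace(gram)) / (n_e * snr ** 2)
    centering = np.eye(n_e) - np.full((n_e, n_e), 1.0 / n_e)
    m = gram + reg_param * centering
    # eigendecomposition-based pseudoinverse: the average reference leaves a
    # null space along the constant vector
    w, u = linalg.eigh(m)
    cutoff = _RANK_CUTOFF * np.max(np.abs(w))
    inv_w = np.where(w > cutoff, 1.0 / np.where(w > cutoff, w, 1.0), 0.0)
    kernel = L.T @ ((u * inv_w) @ u.T)
    resolution_diag = np.einsum("ij,ji->i", kernel, L)
    reachable = np.linalg.norm(L, axis=0) > 0
    if np.any(resolution_diag[reachable] <= 0):
        raise RuntimeError("non-positive resolution diagonal for a reachable source")
    standardizer = np.where(reachable, np.sqrt(np.abs(resolution_diag)), 0.0)
    return InverseOperator(kernel, standardizer, float(reg_param), leadfield)


def apply_inverse(op: InverseOperator, sensor_trial: np.ndarray) -> SourceEstimate:
    """Standardized source time courses ``(T W)_j / s_j`` for one sensor epoch."""
    sensor_trial = np.asarray(sensor_trial, dtype=float)
    if sensor_trial.ndim != 2 or sensor_trial.shape[0] != op.n_electrodes:
        raise ValueError(
            f"sensor_trial must be (n_electrodes={op.n_electrodes}, n_samples), "
            f"got {sensor_trial.shape}")
    if op.unreachable.any():
        bad = np.flatnonzero(op.unreachable)
        raise ValueError(
            f"operator has unreachable sources (all-zero lead-field columns) at "
            f"indices {bad.tolist()}; standardization refuses division by zero")
    amplitudes = (op.kernel @ sensor_trial) / op.standardizer[:, None]
    return SourceEstimate(amplitudes)


def localization_error(source_estimate: SourceEstimate, true_index: int,
                       source_space: SourceSpace) -> float:
    """Euclidean distance (m) between the power arg-max and the true source."""
    if not 0 <= true_index < source_space.n_sources:
        raise ValueError(f"true_index {true_index} out of range")
    est_index = int(np.argmax(source_estimate.power))
    return float(np.linalg.norm(source_space.positions[est_index]
                                - source_space.positions[true_index]))
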