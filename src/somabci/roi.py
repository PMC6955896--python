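"""Collapse standardized source estimates to per-ROI time courses.

Each ROI contributes one time course: the sign-aligned mean of its member
sources.  Radially oriented dipoles on opposite flanks of a cap can project
with opposite polarity, so a plain mean can cancel genuine rhythm; members
are therefore flipped to agree in sign with the cap's first principal
temporal direction before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import TrialSet
from .headmodel import ROIAtlas, SourceSpace
from .inverse import InverseOperator, SourceEstimate, apply_inverse

__all__ = ["ROISubset", "extract_roi_timecourses", "build_roi_trialset"]


@dataclass(frozen=True)
class ROISubset:
    """Ordered, duplicate-free selection of atlas ROI ids."""

    roi_ids: tuple[str, ...]
    mode: str = "both"  # {left, right, both}

    def __post_init__(self) -> None:
        if not self.roi_ids:
            raise ValueError("ROI subset must be non-empty")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise ValueError("ROI subset contains duplicates")

    def validate(self, atlas: ROIAtlas) -> None:
        known = set(atlas.ids)
        missing = [r for r in self.roi_ids if r not in known]
        if missing:
            raise ValueError(f"ROI ids not in atlas: {missing}")

    def __len__(self) -> int:
        return len(self.roi_ids)


def _aggregate(member_tc: np.ndarray, method: str) -> np.ndarray:
    """Collapse (k, n_samples) member time courses to one row."""
    if member_tc.shape[0] == 1:
        return member_tc[0]
    if method == "mean":
        return member_tc.mean(axis=0)
    # principal temporal direction of the cap (first right singular vector)
    _, _, vt = np.linalg.svd(member_tc, full_matrices=False)
    v1 = vt[0]
    signs = np.sign(member_tc @ v1)
    signs[signs == 0] = 1.0
    # fix the global sign so the largest-norm member keeps its polarity
    ref = int(np.argmax(np.linalg.norm(member_tc, axis=1)))
    signs = signs * signs[ref]
    if method == "sign_aligned":
        return (signs[:, None] * member_tc).mean(axis=0)
    if method == "pca":
        u1 = member_tc @ v1
        scale = np.linalg.norm(u1) / max(np.linalg.norm(v1), 1e-300)
        return np.sign(u1[ref]) * v1 * scale / np.sqrt(member_tc.shape[0])
    raise ValueError(f"unknown aggregation method: {method}")


def extract_roi_timecourses(source_estimate: SourceEstimate, source_space: SourceSpace,
                            subset: ROISubset, method: str = "sign_aligned") -> np.ndarray:
    """One aggregated time course per ROI, shape (n_rois, n_samples)."""
    subset.validate(source_space.atlas)
    out = np.empty((len(subset), source_estimate.amplitudes.shape[1]))
    for i, roi_id in enumerate(subset.roi_ids):
        members = source_space.roi_members(roi_id)
        out[i] = _aggregate(source_estimate.amplitudes[members], method)
    return out


def build_roi_trialset(trialset_sensor: TrialSet, inverse_op: InverseOperator,
                       source_space: SourceSpace, subset: ROISubset,
                       method: str = "sign_aligned") -> TrialSet:
    """Apply the inverse and ROI aggregation to every trial (labels carried)."""
    if trialset_sensor.n_channels != inverse_op.n_electrodes:
        raise ValueError("sensor trial set does not match the operator's montage")
    n_samples = trialset_sensor.n_samples
    data = np.empty((trialset_sensor.n_trials, len(subset), n_samples))
    for t in range(trialset_sensor.n_trials):
        est = apply_inverse(inverse_op, trialset_sensor.data[t])
        data[t] = extract_roi_timecourses(est, source_space, subset, method)
    return TrialSet(data, trialset_sensor.labels.copy(), trialset_sensor.fs,
                    "roi", list(subset.roi_ids))
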