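"""Exhaustive ROI-subset search over the somatomotor atlas.

Five ROI search modes mirror the analysis design: all non-empty subsets of
one hemisphere's nine regions (``left_all`` / ``right_all``), all
three-region subsets of one hemisphere (``left_3`` / ``right_3``), and all
six-region subsets drawn from the full 18-region atlas (``both_6``, run
with six CSP filter pairs when the per-ROI multiplicity allows).  A
``sensor`` mode evaluates the raw montage without source localization.
Every (subset, m) configuration is evaluated through the identical chain:
band-pass -> inverse -> ROI aggregation -> CSP fit on train -> max-margin
classifier -> test-set metrics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .classify import (EvalResult, accuracy, confusion, predict, sensitivity,
                       specificity, train_classifier)
from .containers import TrialSet
from .csp import fit_csp, transform_csp
from .headmodel import ROIAtlas, SourceSpace
from .inverse import InverseOperator
from .preprocessing import BandSpec, bandpass
from .roi import ROISubset, build_roi_trialset

__all__ = ["SearchMode", "MODES", "SubsetReport", "PipelineBundle",
           "enumerate_subsets", "evaluate_subset", "evaluate_trialsets",
           "run_search", "tally_occurrences", "format_occurrence_chart"]


@dataclass(frozen=True)
class SearchMode:
    name: str
    lobe: str            # "L", "R" or "both"
    sizes: tuple[int, ...]


MODES = {
    "left_all": SearchMode("left_all", "L", tuple(range(1, 10))),
    "left_3": SearchMode("left_3", "L", (3,)),
    "right_all": SearchMode("right_all", "R", tuple(range(1, 10))),
    "right_3": SearchMode("right_3", "R", (3,)),
    "both_6": SearchMode("both_6", "both", (6,)),
}


def enumerate_subsets(atlas: ROIAtlas, mode: SearchMode | str) -> list[ROISubset]:
    """All ROI subsets of a mode, ordered by size then lexicographically by id."""
    if isinstance(mode, str):
        if mode not in MODES:
            raise ValueError(f"unknown search mode: {mode!r}")
        mode = MODES[mode]
    if mode.lobe == "both":
        pool = sorted(atlas.ids)
        tag = "both"
    else:
        pool = sorted(atlas.lobe_ids(mode.lobe))
        tag = "left" if mode.lobe == "L" else "right"
    subsets = []
    for size in mode.sizes:
        for combo in itertools.combinations(pool, size):
            subsets.append(ROISubset(combo, tag))
    return subsets


def evaluate_trialsets(train: TrialSet, test: TrialSet, m_pairs: int,
                       band_name: str = "custom",
                       subset: tuple[str, ...] | str = "sensor") -> EvalResult:
    """CSP + classifier on already-prepared train/test trial sets."""
    model = fit_csp(train, m_pairs)
    clf = train_classifier(transform_csp(model, train), train.labels)
    conf = confusion(test.labels, predict(clf, transform_csp(model, test)))
    return EvalResult(accuracy(conf), sensitivity(conf), specificity(conf),
                      conf, subset, m_pairs, band_name)


def evaluate_subset(subset: ROISubset, m_pairs: int, train_sensor: TrialSet,
                    test_sensor: TrialSet, inverse_op: InverseOperator,
                    source_space: SourceSpace, band: BandSpec | str) -> EvalResult:
    """Full chain for one ROI subset and one filter-pair count."""
    band_name = band if isinstance(band, str) else band.name
    train_roi = build_roi_trialset(bandpass(train_sensor, band), inverse_op,
                                   source_space, subset)
    test_roi = build_roi_trialset(bandpass(test_sensor, band), inverse_op,
                                  source_space, subset)
    return evaluate_trialsets(train_roi, test_roi, m_pairs, band_name, subset.roi_ids)


@dataclass
class PipelineBundle:
    """Everything a search needs: sensor splits plus the inverse machinery."""

    train_sensor: TrialSet
    test_sensor: TrialSet
    inverse_op: InverseOperator
    source_space: SourceSpace
    _roi_cache: dict = field(default_factory=dict, repr=False)

    @property
    def atlas(self) -> ROIAtlas:
        return self.source_space.atlas

    def roi_trialsets(self, band: BandSpec | str) -> tuple[TrialSet, TrialSet]:
        """Band-passed, source-localized trial sets over ALL atlas ROIs (cached)."""
        key = band if isinstance(band, str) else (band.low, band.high)
        if key not in self._roi_cache:
            all_rois = ROISubset(tuple(self.atlas.ids), "both")
            self._roi_cache[key] = tuple(
                build_roi_trialset(bandpass(ts, band), self.inverse_op,
                                   self.source_space, all_rois)
                for ts in (self.train_sensor, self.test_sensor))
        return self._roi_cache[key]


@dataclass
class SubsetReport:
    mode: str
    band: str
    results: list[EvalResult]
    skipped: list[dict]
    best_ties: list[EvalResult]

    @property
    def best(self) -> EvalResult:
        """Single winner after tie-breaking (smallest subset, then smallest m,
        then lexicographic subset order)."""
        return min(self.best_ties, key=_tie_key)

    def to_rows(self) -> list[dict]:
        return [r.row() for r in self.results]


def _tie_key(result: EvalResult):
    return (len(result.subset), result.m_pairs, tuple(result.subset))


def run_search(bundle: PipelineBundle, mode: SearchMode | str, band: BandSpec | str,
               m_grid: tuple[int, ...] = (1, 2, 3)) -> SubsetReport:
    """Evaluate every (subset, m) configuration of a mode and select the best.

    Filter-pair counts that exceed ``floor(|subset| / 2)`` (one time course
    per ROI) are recorded as skipped rather than evaluated.  The arg-max is
    taken over subsets and the m grid jointly; all accuracy ties are retained.
    """
    if isinstance(mode, str):
        if mode not in MODES and mode != "sensor":
            raise ValueError(f"unknown search mode: {mode!r}")
        if mode == "sensor":
            return _run_sensor(bundle, band, m_grid)
        mode = MODES[mode]
    if not m_grid:
        raise ValueError("m_grid must be non-empty")
    band_name = band if isinstance(band, str) else band.name
    train_all, test_all = bundle.roi_trialsets(band)
    results: list[EvalResult] = []
    skipped: list[dict] = []
    for subset in enumerate_subsets(bundle.atlas, mode):
        train = train_all.select_channels(list(subset.roi_ids))
        test = test_all.select_channels(list(subset.roi_ids))
        for m in m_grid:
            if m > len(subset) // 2:
                skipped.append({"subset": subset.roi_ids, "m_pairs": m,
                                "reason": f"m_pairs={m} exceeds floor({len(subset)}/2)"})
                continue
            try:
                results.append(evaluate_trialsets(train, test, m, band_name, subset.roi_ids))
            except ValueError as err:  # degenerate configuration; keep searching
                skipped.append({"subset": subset.roi_ids, "m_pairs": m, "reason": str(err)})
    if not results:
        raise ValueError(f"no evaluable configuration in mode {mode.name} with m_grid {m_grid}")
    best_acc = max(r.accuracy for r in results)
    ties = [r for r in results if r.accuracy == best_acc]
    return SubsetReport(mode.name, band_name, results, skipped, ties)


def _run_sensor(bundle: PipelineBundle, band: BandSpec | str,
                m_grid: tuple[int, ...]) -> SubsetReport:
    band_name = band if isinstance(band, str) else band.name
    train = bandpass(bundle.train_sensor, band)
    test = bandpass(bundle.test_sensor, band)
    cap = train.n_channels // 2
    results = [evaluate_trialsets(train, test, m, band_name, "sensor")
               for m in m_grid if m <= cap]
    skipped = [{"subset": "sensor", "m_pairs": m, "reason": f"m_pairs={m} exceeds floor(C/2)"}
               for m in m_grid if m > cap]
    best_acc = max(r.accuracy for r in results)
    return SubsetReport("sensor", band_name, results, skipped,
                        [r for r in results if r.accuracy == best_acc])


def tally_occurrences(reports: list[SubsetReport], fractional: bool = True,
                      allow_mixed: bool = False) -> dict[str, float]:
    """Count best-subset ROI memberships across runs (Figure-style tally).

    With ``fractional=True`` a k-way accuracy tie contributes 1/k per tied
    subset to each of its ROIs; otherwise only the tie-broken single winner
    counts.  Reports of different modes cannot be pooled unless
    ``allow_mixed`` is set.
    """
    if not reports:
        raise ValueError("need at least one report to tally")
    modes = {r.mode for r in reports}
    if len(modes) > 1 and not allow_mixed:
        raise ValueError(f"mixed search modes {sorted(modes)} require allow_mixed=True")
    tally: dict[str, float] = {}
    for report in reports:
        if fractional:
            subsets = sorted({tuple(r.subset) for r in report.best_ties})
            weight = 1.0 / len(subsets)
        else:
            subsets = [tuple(report.best.subset)]
            weight = 1.0
        for subset in subsets:
            for roi_id in subset:
                tally[roi_id] = tally.get(roi_id, 0.0) + weight
    return dict(sorted(tally.items()))


def format_occurrence_chart(tally: dict[str, float], width: int = 40) -> str:
    """Plain-text horizontal bar chart of ROI occurrence counts."""
    if not tally:
        return "(empty tally)"
    peak = max(tally.values()) or 1.0
    lines = []
    for roi_id, count in sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])):
        bar = "#" * max(1, int(round(width * count / peak))) if count > 0 else ""
        lines.append(f"{roi_id:8s} {bar} {count:g}")
    return "\n".join(lines)
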