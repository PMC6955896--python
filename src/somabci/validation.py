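"""End-to-end validation studies of the pipeline's core guarantees.

Each function rebuilds its inputs from scratch and measures one property the
method is supposed to have: exact single-source localization of the
standardized inverse, agreement of the operator and CSP solutions with
independent dense-algebra routes, the counting identities of the
performance metrics, exhaustiveness of the subset enumeration, recovery of
planted discriminative ROIs by the full search, and chance-level behavior
on effect-free data.  The studies use deliberately desk-scale problem sizes
(32 electrodes, a few hundred sources, 200/100 trial splits) so the whole
battery runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg as sla

from .classify import ConfusionCounts, accuracy
from .config import RunConfig
from .headmodel import (build_electrode_array, build_head_model, build_roi_atlas,
                        build_source_space, compute_lead_field)
from .inverse import apply_inverse, compute_inverse_operator, localization_error
from .roi import ROISubset
from .search import enumerate_subsets, evaluate_trialsets, run_search
from .simulate import GeneratorConfig, generate_trialset

__all__ = ["localization_study", "inverse_oracle_study", "csp_oracle_study",
           "metric_identity_study", "enumeration_study", "recovery_study",
           "null_calibration_study", "PLANTED_ROIS"]

PLANTED_ROIS = ("S1H_L", "M1H_L", "S1F_L", "M1F_L")


def localization_study(n_sources: int = 100, n_electrodes: int = 32,
                       seed: int = 0) -> dict:
    """Noiseless single-source localization over every grid position.

    For each source j, project a waveform through column j of the lead field
    and check that the standardized power arg-max lands exactly on j.
    """
    head = build_head_model()
    electrodes = build_electrode_array(n_electrodes, head)
    space = build_source_space(n_sources, head, None, seed=seed)
    lf = compute_lead_field(electrodes, space, head)
    op = compute_inverse_operator(lf)
    wave = np.sin(np.linspace(0.0, 12 * np.pi, 40))
    errors = []
    for j in range(n_sources):
        est = apply_inverse(op, np.outer(lf.matrix[:, j], wave))
        errors.append(localization_error(est, j, space))
    hits = sum(e == 0.0 for e in errors)
    return {"hits": int(hits), "n": n_sources, "median_error_m": float(np.median(errors))}


def inverse_oracle_study(seed: int = 0, n_instances: int = 5,
                         shape: tuple[int, int] = (10, 20), alpha: float = 0.1) -> dict:
    """Max deviation of T and R = T L from an independent SVD-pseudoinverse route."""
    rng = np.random.default_rng(seed)
    worst_t = worst_r = 0.0
    for _ in range(n_instances):
        m = rng.standard_normal(shape)
        m -= m.mean(axis=0, keepdims=True)
        from .headmodel import LeadField
        lf = LeadField.__new__(LeadField)
        lf.matrix, lf.electrode_ref, lf.source_ref = m, None, None
        op = compute_inverse_operator(lf, reg_param=alpha)
        h = np.eye(shape[0]) - np.ones((shape[0], shape[0])) / shape[0]
        t_oracle = m.T @ np.linalg.pinv(m @ m.T + alpha * h, rcond=1e-12)
        worst_t = max(worst_t, float(np.max(np.abs(op.kernel - t_oracle))))
        r_oracle = t_oracle @ m
        worst_r = max(worst_r, float(np.max(np.abs(
            op.standardizer - np.sqrt(np.diag(r_oracle))))))
    return {"max_kernel_dev": worst_t, "max_standardizer_dev": worst_r,
            "n": n_instances}


def csp_oracle_study(seed: int = 0, n_instances: int = 6) -> dict:
    """Two independent CSP solution routes on random covariance pairs.

    Compares scipy's generalized eigensolver (the implementation's route)
    against explicit whitening + ordinary eigendecomposition, and checks the
    lambda <-> 1 - lambda symmetry under class swap.
    """
    rng = np.random.default_rng(seed)
    worst_eig = worst_filt = worst_sym = 0.0
    for i in range(n_instances):
        n_ch = 4 + (i % 5)
        a = rng.standard_normal((n_ch, n_ch))
        b = rng.standard_normal((n_ch, n_ch))
        c_pos, c_neg = a @ a.T + n_ch * np.eye(n_ch), b @ b.T + n_ch * np.eye(n_ch)
        comp = c_pos + c_neg
        w, v = sla.eigh(c_pos, comp)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        # whitening route
        vals, vecs = np.linalg.eigh(comp)
        whitener = vecs @ np.diag(vals ** -0.5) @ vecs.T
        evals, evecs = np.linalg.eigh(whitener @ c_pos @ whitener)
        o2 = np.argsort(evals)[::-1]
        evals, filt = evals[o2], whitener @ evecs[:, o2]
        worst_eig = max(worst_eig, float(np.max(np.abs(w - evals))))
        for k in range(n_ch):
            x = v[:, k] / np.linalg.norm(v[:, k])
            y = filt[:, k] / np.linalg.norm(filt[:, k])
            worst_filt = max(worst_filt, float(min(np.linalg.norm(x - y),
                                                   np.linalg.norm(x + y))))
        w_swap = np.sort(sla.eigh(c_neg, comp, eigvals_only=True))[::-1]  # descending
        # descending spectrum of the swapped problem equals 1 - ascending spectrum
        worst_sym = max(worst_sym, float(np.max(np.abs((1.0 - w_swap) - w[::-1]))))
    return {"max_eigenvalue_dev": worst_eig, "max_filter_dev": worst_filt,
            "max_symmetry_dev": worst_sym, "n": n_instances}


def metric_identity_study(seed: int = 0, n_vectors: int = 200) -> dict:
    """Counting-oracle agreement on random confusion counts plus the 49/56 anchor."""
    from sklearn.metrics import confusion_matrix as sk_confusion
    from .classify import confusion, sensitivity, specificity
    from .containers import FOOT, HAND
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_vectors):
        n = rng.integers(2, 100)
        true = np.where(rng.random(n) < 0.5, HAND, FOOT).astype(object)
        pred = np.where(rng.random(n) < 0.5, HAND, FOOT).astype(object)
        conf = confusion(true, pred)
        m = sk_confusion(true.astype(str), pred.astype(str), labels=[HAND, FOOT])
        if (conf.tp, conf.fn, conf.fp, conf.tn) != (m[0, 0], m[0, 1], m[1, 0], m[1, 1]):
            mismatches += 1
        if conf.tp + conf.fn and conf.tn + conf.fp:
            s1, s2 = sensitivity(conf), specificity(conf)
            sw = conf.swapped()
            if abs(s1 - specificity(sw)) > 1e-12 or abs(s2 - sensitivity(sw)) > 1e-12:
                mismatches += 1
    anchor = accuracy(ConfusionCounts(tp=25, fn=3, tn=24, fp=4))  # 49 of 56
    return {"oracle_mismatches": int(mismatches), "n": n_vectors,
            "anchor_accuracy_49_of_56": float(anchor)}


def enumeration_study() -> dict:
    """Subset counts for the three exhaustive search modes."""
    atlas = build_roi_atlas()
    return {"left_all": len(enumerate_subsets(atlas, "left_all")),
            "left_3": len(enumerate_subsets(atlas, "left_3")),
            "both_6": len(enumerate_subsets(atlas, "both_6"))}


def _build_bundle(config: RunConfig):
    from .search import PipelineBundle
    head = build_head_model(config.radii, config.conductivities)
    atlas = build_roi_atlas(config.roi_radius_deg)
    electrodes = build_electrode_array(config.n_electrodes, head)
    space = build_source_space(config.n_sources, head, atlas, config.seed,
                               config.source_depth_fraction)
    lf = compute_lead_field(electrodes, space, head, config.n_terms)
    train, test = generate_trialset(config.generator, lf, space)
    op = compute_inverse_operator(lf, config.reg_param, config.inverse_snr)
    return PipelineBundle(train, test, op, space)


def recovery_study(seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
                   n_train: int = 200, n_test: int = 100) -> dict:
    """Parameter recovery on the default planted configuration, per seed.

    Measures (a) test accuracy on the planted four-ROI subset, (b) whether
    the exhaustive left-hemisphere 3-ROI search's winner intersects the
    planted set, and (c) whether the best mu-band accuracy is at least the
    best broad-band accuracy.
    """
    per_seed = []
    for seed in seeds:
        config = RunConfig(seed=seed,
                           generator=GeneratorConfig(n_train=n_train, n_test=n_test))
        bundle = _build_bundle(config)
        train_all, test_all = bundle.roi_trialsets("mu")
        planted = list(PLANTED_ROIS)
        planted_best = max(
            (evaluate_trialsets(train_all.select_channels(planted),
                                test_all.select_channels(planted),
                                m, "mu", tuple(planted))
             for m in (1, 2)), key=lambda r: r.accuracy)
        report_mu = run_search(bundle, "left_3", "mu", m_grid=(1,))
        report_bb = run_search(bundle, "left_3", "broadband", m_grid=(1,))
        per_seed.append({
            "seed": seed,
            "planted_accuracy": planted_best.accuracy,
            "best3_mu_accuracy": report_mu.best.accuracy,
            "best3_mu_subset": list(report_mu.best.subset),
            "best3_broadband_accuracy": report_bb.best.accuracy,
            "recovered": len(set(report_mu.best.subset) & set(PLANTED_ROIS)) >= 1,
            "mu_ge_broadband": report_mu.best.accuracy >= report_bb.best.accuracy,
        })
    return {
        "per_seed": per_seed,
        "min_planted_accuracy": min(s["planted_accuracy"] for s in per_seed),
        "mean_planted_accuracy": float(np.mean([s["planted_accuracy"] for s in per_seed])),
        "recovery_rate": float(np.mean([s["recovered"] for s in per_seed])),
        "mu_ge_broadband_rate": float(np.mean([s["mu_ge_broadband"] for s in per_seed])),
        "n": len(per_seed),
    }


def null_calibration_study(seeds: tuple[int, ...] = (1, 2, 3),
                           n_train: int = 120, n_test: int = 100) -> dict:
    """Chance-level check: no planted effects, accuracy on the would-be
    planted subset must stay within the binomial 99% interval around 50%."""
    accuracies = []
    for seed in seeds:
        gen = GeneratorConfig(n_train=n_train, n_test=n_test, planted_effects=[])
        config = RunConfig(seed=seed, generator=gen)
        bundle = _build_bundle(config)
        train_all, test_all = bundle.roi_trialsets("mu")
        planted = list(PLANTED_ROIS)
        res = evaluate_trialsets(train_all.select_channels(planted),
                                 test_all.select_channels(planted),
                                 2, "mu", tuple(planted))
        accuracies.append(res.accuracy)
    half_width = 100 * 2.576 * np.sqrt(0.25 / n_test)
    return {"accuracies": accuracies, "n_test": n_test,
            "interval_low": 50 - half_width, "interval_high": 50 + half_width,
            "all_within": bool(all(50 - half_width <= a <= 50 + half_width
                                   for a in accuracies))}
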