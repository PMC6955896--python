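"""Head geometry, ROI atlas, and analytic lead-field behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somabci import (ROI_BASE_IDS, build_electrode_array, build_head_model,
                     build_roi_atlas, build_source_space, compute_lead_field,
                     project_sources)
from somabci.headmodel import SourceSpace


class TestHeadModel:
    def test_default_conductivities_stored_verbatim(self):
        hm = build_head_model()
        assert hm.conductivities == (1.0, 0.0125, 1.0)
        assert hm.radii[0] > hm.radii[1] > hm.radii[2]

    @pytest.mark.parametrize("radii,conds", [
        ((0.08, 0.085, 0.09), (1.0, 0.0125, 1.0)),   # not decreasing
        ((0.09, 0.085, 0.08), (1.0, 0.0, 1.0)),      # zero skull conductivity
        ((0.09, 0.09, 0.08), (1.0, 0.0125, 1.0)),    # equal shells
    ])
    def test_invalid_geometry_rejected(self, radii, conds):
        with pytest.raises(ValueError):
            build_head_model(radii, conds)


class TestAtlas:
    def test_default_atlas_has_nine_regions_per_lobe(self, atlas):
        assert len(atlas.regions) == 18
        for lobe in ("L", "R"):
            ids = atlas.lobe_ids(lobe)
            assert len(ids) == 9
            assert {i.rsplit("_", 1)[0] for i in ids} == set(ROI_BASE_IDS)

    def test_left_right_mirror_symmetry(self, atlas):
        for base in ROI_BASE_IDS:
            left = np.asarray(atlas.region(f"{base}_L").center)
            right = np.asarray(atlas.region(f"{base}_R").center)
            assert np.allclose(left * [-1, 1, 1], right, atol=1e-12)

    def test_homuncular_ordering(self, atlas):
        # foot representations medial, hand representations lateral
        for base, lo, hi in [("S1F", 0, 15), ("M1F", 0, 15), ("S1H", 30, 45), ("M1H", 30, 45)]:
            c = np.asarray(atlas.region(f"{base}_L").center)
            lat = np.rad2deg(np.arcsin(abs(c[0])))
            assert lo <= lat <= hi, f"{base} at {lat:.1f} deg lateral"
        # premotor anterior to motor, somatosensory posterior
        assert atlas.region("PMd_L").center[1] > atlas.region("M1H_L").center[1]
        assert atlas.region("S1H_L").center[1] < atlas.region("M1H_L").center[1]

    def test_overlapping_caps_rejected(self, atlas):
        # find the closest same-lobe pair and double the radius until overlap
        centers = [np.asarray(r.center) for r in atlas.regions if r.lobe == "L"]
        gaps = [np.rad2deg(np.arccos(np.clip(np.dot(a, b), -1, 1)))
                for i, a in enumerate(centers) for b in centers[i + 1:]]
        with pytest.raises(ValueError, match="overlap"):
            build_roi_atlas(radius_deg=min(gaps) / 2 + 0.5)


class TestSourceSpace:
    def test_default_space_covers_every_roi(self, head_model, atlas):
        space = build_source_space(500, head_model, atlas, seed=0)
        for region in atlas.regions:
            assert np.sum(space.roi_labels == region.id) >= 1

    def test_insufficient_sources_error_names_empty_rois(self, head_model, atlas):
        with pytest.raises(ValueError, match="no member sources"):
            build_source_space(40, head_model, atlas, seed=0)

    def test_same_seed_reproduces_space(self, head_model, atlas):
        a = build_source_space(500, head_model, atlas, seed=3)
        b = build_source_space(500, head_model, atlas, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.roi_labels, b.roi_labels)

    def test_sources_strictly_inside_skull(self, source_space, head_model):
        radii = np.linalg.norm(source_space.positions, axis=1)
        assert np.all(radii < head_model.skull_radius)


class TestLeadField:
    def test_average_reference_closure(self, lead_field):
        col_norms = np.linalg.norm(lead_field.matrix, axis=0)
        assert np.max(np.abs(lead_field.matrix.sum(axis=0)) / col_norms) < 1e-10

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_forward_map_linearity(self, lead_field, a, b):
        rng = np.random.default_rng(0)
        s1 = rng.standard_normal((lead_field.matrix.shape[1], 8))
        s2 = rng.standard_normal((lead_field.matrix.shape[1], 8))
        lhs = project_sources(lead_field, a * s1 + b * s2)
        rhs = a * project_sources(lead_field, s1) + b * project_sources(lead_field, s2)
        assert np.allclose(lhs, rhs, rtol=1e-10, atol=1e-10 * np.abs(rhs).max())

    def test_projection_matches_dense_product(self, rng):
        hm = build_head_model()
        elec = build_electrode_array(32, hm)
        space = build_source_space(40, hm, None, seed=1)
        lf = compute_lead_field(elec, space, hm)
        s = rng.standard_normal((40, 6))
        assert np.allclose(project_sources(lf, s), lf.matrix @ s, atol=1e-12)
        assert np.all(project_sources(lf, np.zeros((40, 4))) == 0)
        # unit amplitude at one source reproduces that column over time
        e = np.zeros((40, 3))
        e[11] = 1.0
        assert np.allclose(project_sources(lf, e), lf.matrix[:, [11]] * np.ones(3), atol=1e-14)

    def test_projection_shape_mismatch(self, lead_field):
        with pytest.raises(ValueError):
            project_sources(lead_field, np.zeros((3, 10)))

    def test_series_self_convergence(self, electrodes, source_space, head_model):
        lf_a = compute_lead_field(electrodes, source_space, head_model, n_terms=200)
        lf_b = compute_lead_field(electrodes, source_space, head_model, n_terms=400)
        rel = np.linalg.norm(lf_a.matrix - lf_b.matrix, axis=0) / \
            np.linalg.norm(lf_b.matrix, axis=0)
        assert rel.max() < 1e-6

    def test_insufficient_truncation_raises_diagnostic(self, electrodes, source_space, head_model):
        with pytest.raises(RuntimeError, match="not converged"):
            compute_lead_field(electrodes, source_space, head_model, n_terms=20)

    def test_depth_attenuation_monotone(self, electrodes, head_model):
        # radial sweep at fixed angular positions under the montage: moving a
        # source deeper never increases its sensor-norm
        base = build_source_space(60, head_model, None, seed=2, depth_fraction=0.9)
        under_cap = base.positions[:, 2] > 0.2 * np.linalg.norm(base.positions[0])
        norms = []
        for frac in (0.9, 0.75, 0.6, 0.45, 0.3):
            space = build_source_space(60, head_model, None, seed=2, depth_fraction=frac)
            lf = compute_lead_field(electrodes, space, head_model)
            norms.append(np.linalg.norm(lf.matrix, axis=0)[under_cap])
        for shallow, deep in zip(norms, norms[1:]):
            assert np.all(shallow >= deep)

    def test_mirror_symmetry(self, electrodes, head_model):
        # a source and its midline reflection produce mirror-image sensor maps
        pos = np.array([[-0.03, 0.02, 0.055], [0.03, 0.02, 0.055]])
        ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        space = SourceSpace(pos, ori, np.array(["background"] * 2, dtype=object), None)
        lf = compute_lead_field(electrodes, space, head_model)
        mirrored = lf.matrix[electrodes.mirror_index, 0]
        assert np.allclose(mirrored, lf.matrix[:, 1], atol=1e-8 * np.abs(lf.matrix).max())

    def test_source_outside_brain_rejected(self, electrodes, head_model):
        pos = np.array([[0.0, 0.0, head_model.brain_radius]])
        space = SourceSpace(pos, np.array([[0.0, 0.0, 1.0]]),
                            np.array(["background"], dtype=object), None)
        with pytest.raises(ValueError, match="inside the brain"):
            compute_lead_field(electrodes, space, head_model)
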