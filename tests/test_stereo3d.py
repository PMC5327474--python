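import math

import numpy as np
import pandas as pd
import pytest

from vasodyn import stereo3d as st
from vasodyn.synthio import ImageStack


class TestVesselMask:
    def test_otsu_recovers_rasterized_lumen(self, stricture_stack):
        _, stack, truth = stricture_stack
        mask = st.vessel_mask(stack, min_component=27)
        ref = truth["vessel_mask"]
        dice = 2.0 * np.logical_and(mask, ref).sum() / (mask.sum() + ref.sum())
        assert dice > 0.95

    def test_fixed_threshold(self, stricture_stack):
        _, stack, _ = stricture_stack
        mask = st.vessel_mask(stack, method="fixed", threshold=100.0)
        assert mask.any()

    def test_min_component_removes_specks(self):
        img = np.zeros((6, 20, 20), np.float32)
        img[2, 5:15, 5:15] = 200.0   # 100-voxel slab
        img[0, 0, 0] = 200.0         # single speck
        stack = ImageStack({"vessel": img}, (2.0, 0.5, 0.5))
        mask = st.vessel_mask(stack, min_component=5)
        assert mask.sum() == 100 and not mask[0, 0, 0]

    def test_constant_channel_raises(self):
        stack = ImageStack({"vessel": np.zeros((4, 4, 4), np.float32)}, (1, 1, 1))
        with pytest.raises(ValueError):
            st.vessel_mask(stack)

    def test_missing_channel_raises(self):
        stack = ImageStack({"nuclei": np.ones((4, 4, 4))}, (1, 1, 1))
        with pytest.raises(KeyError):
            st.vessel_mask(stack)


def _brute_force(mask, voxel_size, pt):
    vox = np.argwhere(mask) * np.asarray(voxel_size)
    return np.sqrt(((vox - pt) ** 2).sum(axis=1)).min()


class TestSphereProbe:
    def test_hand_case_anisotropic(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        probe = st.SphereProbe(mask, (2.0, 0.5, 0.5), step=2.0)
        # point at (4, 1.5, 0): distance sqrt(16 + 2.25) = 4.272 -> quantized 6
        assert probe.euclidean([(4.0, 1.5, 0.0)])[0] == pytest.approx(
            math.sqrt(18.25))
        assert probe.quantized([(4.0, 1.5, 0.0)])[0] == 6.0

    def test_quantized_never_below_step(self):
        mask = np.ones((3, 3, 3), bool)
        probe = st.SphereProbe(mask, (1.0, 1.0, 1.0), step=2.0)
        assert probe.quantized([(1.0, 1.0, 1.0)])[0] == 2.0

    def test_multiples_of_step_only(self, stricture_stack):
        _, stack, truth = stricture_stack
        probe = st.SphereProbe(truth["vessel_mask"], stack.voxel_size, step=2.0)
        q = probe.quantized(truth["centroids_um"])
        np.testing.assert_allclose(q / 2.0, np.round(q / 2.0))
        assert np.all(q >= 2.0)

    def test_matches_brute_force_random(self, rng):
        for _ in range(25):
            shape = tuple(rng.integers(3, 7, 3))
            vs = tuple(rng.uniform(0.4, 2.5, 3))
            mask = rng.random(shape) < 0.2
            if not mask.any():
                continue
            probe = st.SphereProbe(mask, vs, step=2.0)
            hi = (np.asarray(shape) - 1) * np.asarray(vs)
            pts = rng.uniform(0, 1, (10, 3)) * hi
            d = probe.euclidean(pts)
            ref = [_brute_force(mask, vs, p) for p in pts]
            np.testing.assert_allclose(d, ref, rtol=1e-12)

    def test_outside_volume_rejected(self):
        mask = np.ones((3, 3, 3), bool)
        probe = st.SphereProbe(mask, (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            probe.euclidean([(5.0, 0.0, 0.0)])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            st.SphereProbe(np.zeros((3, 3, 3), bool), (1, 1, 1))


class TestDisectorFractionator:
    def test_frame_inclusion_exclusion_edges(self):
        design = st.SamplingDesign(section_thickness=24.0, guard=6.0)
        side = design.frame_side
        cells = pd.DataFrame({
            "x_um": [0.0, side, side - 1e-6, 10.0],
            "y_um": [0.0, 10.0, 10.0, side],
            "z_um": [12.0, 12.0, 12.0, 12.0],
        })
        # left/bottom edges included; right/top excluded
        assert st.disector_count(cells, design, (0.0, 0.0), (0.0, 24.0)) == 2

    def test_guard_slab_central(self):
        design = st.SamplingDesign(section_thickness=24.0, guard=6.0)
        cells = pd.DataFrame({"x_um": [1.0] * 3, "y_um": [1.0] * 3,
                              "z_um": [8.9, 12.0, 15.1]})
        # guard slab spans [9, 15): only the centre cell counts
        assert st.disector_count(cells, design, (0.0, 0.0), (0.0, 24.0)) == 1

    def test_thin_section_rejected(self):
        design = st.SamplingDesign(section_thickness=24.0, guard=6.0)
        cells = pd.DataFrame({"x_um": [1.0], "y_um": [1.0], "z_um": [1.0]})
        with pytest.raises(ValueError):
            st.disector_count(cells, design, (0.0, 0.0), (0.0, 5.0))

    def test_fractionator_worked_example(self):
        # 470 cells at 1/6 x 1/36 x (6/22.8) -> 385,776
        design = st.SamplingDesign()
        assert st.fractionator_total(470, design) == pytest.approx(385776, rel=1e-6)

    def test_subsample_cap(self, rng):
        design = st.SamplingDesign(max_per_disector=3)
        cells = pd.DataFrame({"x_um": rng.uniform(0, 900, 200),
                              "y_um": rng.uniform(0, 900, 200),
                              "z_um": rng.uniform(0, 20, 200)})
        sub = st.subsample_per_disector(st.assign_disectors(cells, design),
                                        design, seed=1)
        assert sub.groupby("disector_id").size().max() <= 3

    def test_subsample_needs_assignment(self):
        design = st.SamplingDesign()
        with pytest.raises(ValueError):
            st.subsample_per_disector(pd.DataFrame({"x_um": [1.0]}), design)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            st.SamplingDesign(ssf=0.0)
        with pytest.raises(ValueError):
            st.SamplingDesign(guard=30.0, section_thickness=20.0)


class TestDistanceDistributions:
    def test_bins_and_shift_hand_case(self):
        d = np.array([2.0, 2.0, 4.0, 6.0, 8.0, 8.0])
        pos = np.array([True, True, True, False, False, False])
        res = st.distance_distributions(d, pos)
        assert res.mean_pos == pytest.approx(8.0 / 3.0)
        assert res.mean_neg == pytest.approx(22.0 / 3.0)
        assert res.relative_shift == pytest.approx(100.0 * (22 - 8) / 22)
        assert res.counts_pos.tolist() == [2, 1, 0, 0]
        assert res.counts_neg.tolist() == [0, 0, 1, 2]

    def test_shift_invariant_to_rescaling(self, rng):
        d = 2.0 * rng.integers(1, 20, 200).astype(float)
        pos = rng.random(200) < 0.5
        pos[0], pos[1] = True, False
        a = st.distance_distributions(d, pos)
        b = st.distance_distributions(3.0 * d, pos, step=6.0)
        assert a.relative_shift == pytest.approx(b.relative_shift)

    def test_trend_detects_separation(self):
        d = np.concatenate([np.full(50, 2.0), np.full(50, 12.0)])
        pos = np.concatenate([np.ones(50, bool), np.zeros(50, bool)])
        res = st.distance_distributions(d, pos)
        assert res.trend.p < 1e-6

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            st.distance_distributions([2.0, 4.0], [True, True])

    def test_gaussian_fits_attached(self, rng):
        d = 2.0 * np.clip(np.round(rng.normal(8, 2, 400) / 2), 1, None)
        pos = np.arange(400) % 2 == 0
        res = st.distance_distributions(d, pos, fit_gaussians=True)
        assert res.gaussian_pos is not None and res.gaussian_pos.display_only


class TestDiameterProfile:
    def test_fwhm_of_rendered_tube(self):
        # 4-um-wide box profile in a 2D image (treated as 1-slice 3D)
        img = np.zeros((1, 41, 41))
        img[0, :, 16:24] = 100.0  # columns 16..23 at dx=0.5 -> 4.0 um wide
        fw = st.diameter_profile(img[0], (10.0, 0.0), (10.0, 20.0), (0.5, 0.5))
        assert fw == pytest.approx(4.0, abs=0.3)

    def test_no_peak_raises(self):
        img = np.zeros((21, 21))
        with pytest.raises(ValueError):
            st.diameter_profile(img, (5.0, 0.0), (5.0, 10.0), (0.5, 0.5))

    def test_unreturned_profile_raises(self):
        img = np.full((21, 21), 0.0)
        img[:, 10:] = 100.0  # never returns to background on the right
        with pytest.raises(ValueError):
            st.diameter_profile(img, (5.0, 0.0), (5.0, 10.0), (0.5, 0.5))


class TestStrictureAnalysis:
    def test_detects_seeded_stricture(self, stricture_stack):
        params, stack, truth = stricture_stack
        mask = st.vessel_mask(stack, min_component=27)
        mural = stack.channels["mural"] > 75.0
        recs = st.stricture_analysis(mask, stack.voxel_size, mural_mask=mural)
        assert recs, "the seeded stricture should be found"
        best = min(recs, key=lambda r: r.local_diameter_um)
        assert best.local_diameter_um == pytest.approx(1.0, abs=0.5)
        assert 2.0 * params.vessel_radius * 0.8 <= best.reference_diameter_um \
            <= 2.0 * params.vessel_radius * 1.2
        assert 60.0 <= best.constriction_percent <= 85.0
        assert best.mural_distance_um <= 4.0

    def test_no_stricture_on_uniform_tube(self):
        mask = np.zeros((9, 9, 60), bool)
        zz, yy = np.meshgrid(np.arange(9) - 4.0, np.arange(9) - 4.0,
                             indexing="ij")
        circle = zz**2 + yy**2 <= 3.0**2
        mask[:, :, :] = circle[:, :, None]  # constant cross-section, full span
        recs = st.stricture_analysis(mask, (1.0, 1.0, 1.0))
        assert recs == []

    def test_incongruent_mural_mask_rejected(self):
        mask = np.ones((4, 4, 12), bool)
        with pytest.raises(ValueError):
            st.stricture_analysis(mask, (1, 1, 1),
                                  mural_mask=np.ones((4, 4, 10), bool))


class TestColocalization:
    def test_per_animal_fractions(self):
        cells = pd.DataFrame({
            "animal_id": ["a"] * 4 + ["b"] * 4,
            "aif": [1, 1, 1, 0, 1, 1, 0, 0],
            "neun": [1, 1, 0, 1, 1, 0, 1, 0],
        })
        per, mean, sem = st.colocalization_fraction(cells, "aif", "neun")
        assert per["a"] == pytest.approx(200.0 / 3.0)
        assert per["b"] == pytest.approx(50.0)
        assert mean == pytest.approx((200.0 / 3.0 + 50.0) / 2.0)
        assert sem >= 0.0

    def test_no_positive_cells_raises(self):
        cells = pd.DataFrame({"animal_id": ["a"], "aif": [0], "neun": [1]})
        with pytest.raises(ValueError):
            st.colocalization_fraction(cells, "aif", "neun")


class TestFindNuclei:
    def test_recovers_rendered_centroids(self, stricture_stack):
        params, stack, truth = stricture_stack
        found = st.find_nuclei(stack)
        # rendered nuclei may merge when close; most centroids should appear
        assert len(found) >= 0.6 * params.n_cells
        pts = found[["z_um", "y_um", "x_um"]].to_numpy()
        ref = truth["centroids_um"]
        d = np.sqrt(((pts[:, None, :] - ref[None, :, :]) ** 2).sum(-1)).min(1)
        assert np.median(d) < 2.0
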