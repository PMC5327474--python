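import dataclasses

import numpy as np
import pytest

from vasodyn import synthio


class TestTraceGen:
    def test_seed_bit_identical(self):
        p = synthio.TraceGenParams(n_vessels=3, seed=5)
        t1, g1 = synthio.gen_vessel_traces(p)
        t2, g2 = synthio.gen_vessel_traces(p)
        for a, b in zip(t1, t2):
            np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        assert g1 == g2

    def test_time_grid_and_finiteness(self, trace_cohort):
        _, traces, _ = trace_cohort
        for tr in traces[:5]:
            dt = np.diff(tr.time)
            assert np.allclose(dt, dt[0])
            assert np.all(np.diff(tr.time) > 0)
            assert np.all(np.isfinite(tr.fluorescence))
            assert np.all(tr.fluorescence >= 0)

    def test_truth_trapezoid_geometry(self, trace_cohort):
        params, _, truth = trace_cohort
        for evs in truth.values():
            for a, b in zip(evs, evs[1:]):
                assert b.onset >= a.end  # non-overlap
            for e in evs:
                assert e.duration == pytest.approx(
                    params.onset_ramp + params.plateau + params.termination_ramp)
                assert 0.0 <= e.magnitude <= 100.0

    def test_noiseless_plateau_depth_exact(self):
        p = synthio.TraceGenParams(n_vessels=1, spasm_rate=3.0, noise_sd=0.0,
                                   magnitude=25.0, seed=2)
        traces, truth = synthio.gen_vessel_traces(p)
        tr, evs = traces[0], truth[traces[0].vessel_id]
        assert evs, "seeded generation should produce at least one event"
        for e in evs:
            m = (tr.time >= e.trough_start) & (tr.time <= e.trough_end)
            np.testing.assert_allclose(tr.fluorescence[m], 75.0)

    def test_event_count_matches_rate(self):
        p = synthio.TraceGenParams(n_vessels=200, spasm_rate=1.5, seed=9)
        _, truth = synthio.gen_vessel_traces(p)
        n = sum(len(v) for v in truth.values())
        # Poisson(300): 5 sigma band
        assert abs(n - 300) < 5 * np.sqrt(300)

    def test_overdense_raises(self):
        p = synthio.TraceGenParams(n_vessels=1, duration=600.0, spasm_rate=60.0,
                                   seed=0)
        with pytest.raises(ValueError):
            synthio.gen_vessel_traces(p)

    @pytest.mark.parametrize("kw", [
        {"duration": 0.0}, {"sample_interval": -1.0}, {"magnitude": 120.0},
        {"noise_sd": -0.1}, {"spasm_rate": -1.0}, {"onset_ramp": -1.0},
    ])
    def test_param_validation(self, kw):
        with pytest.raises(ValueError):
            synthio.TraceGenParams(**kw)


class TestTrainGen:
    def test_invariants(self, coupled_trains):
        params, trains, truth = coupled_trains
        assert len(trains) == params.n_animals
        for a in trains:
            for arr in (a.seizures, a.spasms):
                assert np.all(arr >= a.session_start)
                assert np.all(arr < a.session_end)
                assert np.all(np.diff(arr) > 0)  # sorted unique

    def test_coupled_lags_positive(self, coupled_trains):
        _, _, truth = coupled_trains
        saw_coupled = False
        for g in truth.values():
            coupled = g["spasms"][g["coupled"]]
            saw_coupled = saw_coupled or len(coupled) > 0
            for tt in coupled:  # every coupled spasm follows some seizure
                assert np.any(g["seizures"] <= tt)
        assert saw_coupled

    def test_coupling_fraction_zero_gives_no_coupled(self):
        p = synthio.TrainGenParams(coupling_fraction=0.0, seed=1)
        _, truth = synthio.gen_event_trains(p)
        assert not any(g["coupled"].any() for g in truth.values())

    def test_seed_reproducible(self):
        p = synthio.TrainGenParams(seed=12)
        a, _ = synthio.gen_event_trains(p)
        b, _ = synthio.gen_event_trains(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.seizures, y.seizures)
            np.testing.assert_array_equal(x.spasms, y.spasms)

    @pytest.mark.parametrize("kw", [
        {"coupling_fraction": 1.5}, {"seizure_rate": -1.0},
        {"lag_sd": -1.0}, {"session": 0.0},
    ])
    def test_param_validation(self, kw):
        with pytest.raises(ValueError):
            synthio.TrainGenParams(**kw)


class TestTubeGeometry:
    def test_capsule_distance_hand_case(self):
        tube = synthio.Tube((0.0, 0.0, 0.0), (0.0, 0.0, 10.0), 2.0)
        pts = np.array([
            [0.0, 5.0, 5.0],    # perpendicular: 5 - 2 = 3
            [0.0, 0.0, 5.0],    # on the axis: inside, 0
            [0.0, 0.0, 14.0],   # beyond the cap: 4 - 2 = 2
        ])
        d = synthio.tube_surface_distance(pts, [tube])
        np.testing.assert_allclose(d, [3.0, 0.0, 2.0])

    def test_local_radius_dips_at_stricture(self):
        tube = synthio.Tube((0.0, 0.0, 0.0), (0.0, 0.0, 100.0), 2.0,
                            strictures=((50.0, 0.5, 1.5),))
        s = np.array([0.0, 50.0, 100.0])
        r = tube.local_radius(s)
        assert r[0] == pytest.approx(2.0, abs=1e-6)
        assert r[1] == pytest.approx(0.5)
        assert r[2] == pytest.approx(2.0, abs=1e-6)


class TestStackGen:
    def test_channels_and_shapes(self, stricture_stack):
        params, stack, truth = stricture_stack
        assert set(stack.channels) == {"vessel", "nuclei", "marker", "mural"}
        for arr in stack.channels.values():
            assert arr.shape == params.shape
        assert stack.voxel_size == params.voxel_size

    def test_cells_outside_lumen(self, stricture_stack):
        _, _, truth = stricture_stack
        d = synthio.tube_surface_distance(truth["centroids_um"], truth["tubes"])
        assert np.all(d > 0)

    def test_exact_distances_match_geometry(self, stricture_stack):
        _, _, truth = stricture_stack
        d = synthio.tube_surface_distance(truth["centroids_um"], truth["tubes"])
        np.testing.assert_allclose(d, truth["exact_distance_um"])

    def test_every_cell_appears_once(self, stricture_stack):
        params, _, truth = stricture_stack
        assert len(truth["centroids_um"]) == params.n_cells == truth["total_cells"]
        assert truth["positive"].sum() == int(round(
            params.n_cells * params.positive_fraction))

    def test_shift_calibrated_within_one_point(self, stricture_stack):
        params, _, truth = stricture_stack
        d, pos = truth["exact_distance_um"], truth["positive"]
        mn, mp = d[~pos].mean(), d[pos].mean()
        shift = 100.0 * (mn - mp) / mn
        assert shift == pytest.approx(truth["realized_shift_percent"], abs=1e-9)
        assert abs(shift - params.target_shift) <= 1.0

    def test_seed_bit_identical(self):
        p = synthio.StackGenParams(shape=(8, 32, 32), n_vessels=2, n_cells=40,
                                   seed=4)
        s1, g1 = synthio.gen_stack(p)
        s2, g2 = synthio.gen_stack(p)
        for k in s1.channels:
            np.testing.assert_array_equal(s1.channels[k], s2.channels[k])
        np.testing.assert_array_equal(g1["centroids_um"], g2["centroids_um"])

    def test_zero_target_shift_classes_similar(self):
        p = synthio.StackGenParams(shape=(8, 64, 64), n_vessels=2, n_cells=400,
                                   target_shift=0.0, seed=6)
        _, truth = synthio.gen_stack(p)
        assert abs(truth["realized_shift_percent"]) < 10.0

    def test_unreachable_shift_raises(self):
        p = synthio.StackGenParams(shape=(8, 32, 32), n_vessels=2, n_cells=40,
                                   target_shift=150.0, seed=0)
        with pytest.raises(ValueError):
            synthio.gen_stack(p)

    @pytest.mark.parametrize("kw", [
        {"shape": (0, 8, 8)}, {"voxel_size": (1.0, 0.0, 1.0)},
        {"positive_fraction": 1.2}, {"vessel_radius": 0.0},
    ])
    def test_param_validation(self, kw):
        with pytest.raises(ValueError):
            synthio.StackGenParams(**kw)
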