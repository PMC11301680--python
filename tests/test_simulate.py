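"""Simulator unit and property tests: hidden-state Markov chain, confined
Brownian motion with motion blur, photophysics, and the observation model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import smtrack as st
from smtrack.config import ValidationError
from smtrack.simulate import (
    apply_photophysics,
    emitting_fraction_timeseries,
    observe,
    simulate_cell_population,
    simulate_motion,
    simulate_state_path,
    simulate_state_paths,
)

DT = 0.030475


class TestStatePath:
    def test_single_state_is_all_zero(self):
        model = st.DiffusionModel([0.5], [[1.0]], [1.0])
        assert np.all(simulate_state_path(model, 100, 0) == 0)

    def test_identity_matrix_freezes_initial_state(self):
        model = st.DiffusionModel([0.1, 1.0], np.eye(2), [0.0, 1.0])
        path = simulate_state_path(model, 200, 1)
        assert np.all(path == 1)

    def test_symmetric_chain_occupancy_is_half(self):
        model = st.DiffusionModel([0.1, 1.0], [[0.9, 0.1], [0.1, 0.9]], [0.5, 0.5])
        path = simulate_state_path(model, 100_000, 2)
        assert np.mean(path == 0) == pytest.approx(0.5, abs=0.01)

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ValidationError):
            st.DiffusionModel([0.1, 1.0], [[0.9, 0.2], [0.1, 0.9]], [0.5, 0.5])


class TestMotion:
    def test_zero_diffusion_stays_put(self, acq):
        geom = st.CellGeometry(length_um=3.0)
        res = simulate_motion(np.zeros(50, dtype=int), geom, [0.0], acq, 3)
        assert np.all(res.average_um == res.average_um[0])
        assert np.all(res.within_frame_travel_um == 0.0)

    def test_unconfined_msd_matches_4_d_dt(self):
        # no blur (single sub-step): consecutive frame positions are
        # separated by the full frame interval
        acq1 = st.AcquisitionConfig(n_frames=100_000, n_substeps=1)
        res = simulate_motion(np.zeros(acq1.n_frames, dtype=int), None, [0.5], acq1, 4)
        steps = np.diff(res.average_um, axis=0)
        msd = (steps ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(4 * 0.5 * DT, rel=0.01)

    def test_blur_reduces_msd_to_exact_discrete_factor(self):
        # independent oracle: the exposure-averaged position is a linear
        # combination of i.i.d. Gaussian sub-steps, so the variance of the
        # frame-to-frame displacement follows from the coefficients alone
        D, nsub = 0.5, 10
        acq10 = st.AcquisitionConfig(n_frames=200_000, n_substeps=nsub)
        dt_sub = acq10.exposure_s / nsub
        dt_dead = acq10.frame_interval_s - acq10.exposure_s
        # increments: n exposure steps, 1 dead step, n exposure steps
        variances = [2 * D * dt_sub] * nsub + [2 * D * dt_dead] + [2 * D * dt_sub] * nsub
        coef = np.zeros(2 * nsub + 1)
        for j in range(1, nsub + 1):          # -avg1: cumsum of steps 1..j
            coef[:j] -= 1.0 / nsub
        for j in range(1, nsub + 1):          # +avg2
            coef[: nsub + 1 + j] += 1.0 / nsub
        expected_var_per_axis = float(np.sum(coef ** 2 * np.array(variances)))
        res = simulate_motion(np.zeros(acq10.n_frames, dtype=int), None, [D], acq10, 5)
        steps = np.diff(res.average_um, axis=0)
        msd = (steps ** 2).sum(axis=1).mean()
        assert expected_var_per_axis * 2 < 4 * D * acq10.frame_interval_s  # blur reduces
        assert msd == pytest.approx(2 * expected_var_per_axis, rel=0.01)

    def test_increments_gaussian_with_variance_2_d_dt(self):
        acq1 = st.AcquisitionConfig(n_frames=100_000, n_substeps=1)
        res = simulate_motion(np.zeros(acq1.n_frames, dtype=int), None, [0.3], acq1, 6)
        inc = np.diff(res.average_um[:, 0])
        assert inc.var() == pytest.approx(2 * 0.3 * DT, rel=0.02)
        z = inc / np.sqrt(2 * 0.3 * DT)
        assert stats.kstest(z, "norm").pvalue > 0.01

    def test_reflection_keeps_positions_inside(self, acq):
        geom = st.CellGeometry(length_um=2.0, diameter_um=1.0, center=(3.0, -1.0),
                               orientation_rad=0.7)
        states = np.zeros(2000, dtype=int)
        res = simulate_motion(states, geom, [1.0], st.AcquisitionConfig(n_frames=2000), 7)
        local_avg = res.average_um  # local frame of the geometry
        geom0 = st.CellGeometry(length_um=2.0, diameter_um=1.0)
        assert geom0.contains(local_avg, tol_um=1e-9).all()

    def test_zero_area_geometry_rejected(self):
        with pytest.raises(ValidationError):
            st.CellGeometry(length_um=1.0, diameter_um=0.0)


class TestPhotophysics:
    def test_immortal_dye_always_on(self):
        model = st.PhotophysicsModel(0.0, 0.0, 0.0, 1.0)
        assert apply_photophysics(model, 500, 0).all()

    def test_photostable_mean_on_time_is_geometric(self):
        q = 0.02
        model = st.PhotophysicsModel(q, 0.0, 0.0, 1.0)
        emitting = apply_photophysics(model, 2000, 1, n_molecules=10_000)
        on_frames = emitting.sum(axis=1)
        assert on_frames.mean() == pytest.approx(1 / q, rel=0.05)

    def test_photostable_single_emitting_interval(self):
        model = st.jfx650_like_photophysics()
        emitting = apply_photophysics(model, 2000, 2, n_molecules=500)
        e = emitting.astype(int)
        n_runs = (np.diff(e, axis=1) == 1).sum(axis=1) + e[:, 0]
        assert np.all(n_runs <= 1)

    def test_photoswitching_reactivates(self):
        model = st.PhotophysicsModel(0.0, p_off_per_frame=0.1, p_on_per_frame=0.05,
                                     initial_on_fraction=1.0)
        emitting = apply_photophysics(model, 3000, 3, n_molecules=200)
        e = emitting.astype(int)
        n_runs = (np.diff(e, axis=1) == 1).sum(axis=1) + e[:, 0]
        assert (n_runs >= 2).any()


class TestObserve:
    def test_noise_free_stationary_exact(self):
        det = st.DetectionModel(localization_sigma_um=0.0, p_detect_base=1.0)
        pos = np.tile([1.0, 2.0], (100, 1))
        detected, reported = observe(pos, np.zeros(100), np.ones(100, bool), det, 0)
        assert detected.all()
        assert np.array_equal(reported, pos)

    def test_infinite_blur_scale_disables_dropout(self):
        det = st.DetectionModel(p_detect_base=0.8, blur_scale_um=np.inf)
        rng = np.random.default_rng(1)
        d = rng.uniform(0, 10, 50_000)
        detected, _ = observe(np.zeros((50_000, 2)), d, np.ones(50_000, bool), det, 1)
        assert detected.mean() == pytest.approx(0.8, abs=0.01)

    def test_pure_noise_displacement_variance(self):
        sigma = 0.035
        det = st.DetectionModel(localization_sigma_um=sigma, p_detect_base=1.0)
        pos = np.zeros((10_000, 2))
        _, reported = observe(pos, np.zeros(10_000), np.ones(10_000, bool), det, 2)
        msd = (np.diff(reported, axis=0) ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(4 * sigma ** 2, rel=0.02)

    def test_dropout_monotone_in_travel_distance(self):
        det = st.DetectionModel(p_detect_base=0.995, blur_scale_um=0.4)
        rng = np.random.default_rng(3)
        d = rng.uniform(0, 1.0, 10_000)
        detected, _ = observe(np.zeros((10_000, 2)), d, np.ones(10_000, bool), det, 3)
        bins = np.digitize(d, np.linspace(0, 1.0, 6)[1:-1])
        freqs = [detected[bins == b].mean() for b in range(5)]
        assert np.all(np.diff(freqs) <= 0)


class TestPopulation:
    def test_single_perfect_molecule_gives_all_frames(self):
        cfg = st.SimulationConfig(
            acquisition=st.AcquisitionConfig(n_frames=300),
            diffusion=st.three_state_model(),
            photophysics=st.PhotophysicsModel(0.0, 0.0, 0.0, 1.0),
            detection=st.DetectionModel(p_detect_base=1.0, blur_scale_um=np.inf),
            n_cells=1, molecules_per_cell=1,
        )
        sim = simulate_cell_population(cfg, 0)
        assert len(sim.localizations) == 300

    def test_seed_determinism_bit_identical(self):
        cfg = st.jfx650_like_config(n_cells=2, acquisition=st.AcquisitionConfig(n_frames=300))
        a = simulate_cell_population(cfg, 42)
        b = simulate_cell_population(cfg, 42)
        pd.testing.assert_frame_equal(a.localizations, b.localizations)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_zero_molecules_gives_empty_tables(self):
        cfg = st.jfx650_like_config(n_cells=2, molecules_per_cell=0)
        sim = simulate_cell_population(cfg, 0)
        assert sim.localizations.empty and sim.ground_truth.empty

    def test_detected_implies_emitting(self):
        cfg = st.jfx650_like_config(n_cells=3, acquisition=st.AcquisitionConfig(n_frames=500))
        sim = simulate_cell_population(cfg, 1)
        gt = sim.ground_truth
        assert not (gt["detected"] & ~gt["emitting"]).any()

    def test_true_positions_inside_cells(self):
        cfg = st.jfx650_like_config(n_cells=3, acquisition=st.AcquisitionConfig(n_frames=500))
        sim = simulate_cell_population(cfg, 2)
        for geom, (_, gt_cell) in zip(
            sim.cell_geometries, sim.ground_truth.groupby("cell_id")
        ):
            pts = gt_cell[["true_x_um", "true_y_um"]].to_numpy()
            assert geom.contains(pts, tol_um=1e-9).all()

    def test_photostable_molecules_yield_one_emitting_interval(self):
        cfg = st.jfx650_like_config(n_cells=3, acquisition=st.AcquisitionConfig(n_frames=800))
        sim = simulate_cell_population(cfg, 3)
        for _, mol in sim.ground_truth.groupby("molecule_id"):
            e = mol.sort_values("frame")["emitting"].to_numpy().astype(int)
            n_runs = (np.diff(e) == 1).sum() + e[0]
            assert n_runs <= 1

    def test_switching_preset_count_decays_to_sparse_plateau(self):
        cfg = st.tmr_like_config(n_cells=1, molecules_per_cell=100,
                                 acquisition=st.AcquisitionConfig(n_frames=1000))
        sim = simulate_cell_population(cfg, 4)
        ts = emitting_fraction_timeseries(sim.ground_truth, n_frames=1000)
        counts = ts.groupby("frame")["n_detected"].sum().to_numpy()
        early = counts[:50].mean()
        late = counts[-300:].mean()
        assert early > 5 * late
        assert late > 0  # sustained sparse blinking, not extinction


class TestEmittingTimeseries:
    def test_all_bleached_is_all_zero(self):
        gt = pd.DataFrame({
            "molecule_id": [0, 0], "frame": [0, 1], "state": [0, 0],
            "true_x_um": [0.0, 0.0], "true_y_um": [0.0, 0.0],
            "emitting": [False, False], "detected": [False, False], "cell_id": [0, 0],
        })
        ts = emitting_fraction_timeseries(gt, n_frames=4)
        assert (ts["n_emitting"] == 0).all() and (ts["n_detected"] == 0).all()
        assert len(ts) == 4

    def test_single_always_on_detected_molecule_is_all_ones(self):
        n = 6
        gt = pd.DataFrame({
            "molecule_id": 0, "frame": np.arange(n), "state": 0,
            "true_x_um": 0.0, "true_y_um": 0.0,
            "emitting": True, "detected": True, "cell_id": 0,
        })
        ts = emitting_fraction_timeseries(gt)
        assert (ts["n_emitting"] == 1).all() and (ts["n_detected"] == 1).all()

    def test_photostable_decay_monotone_in_expectation(self):
        model = st.jfx650_like_photophysics()
        mean_on = np.zeros(300)
        for seed in range(100):
            mean_on += apply_photophysics(model, 300, seed, n_molecules=10).sum(axis=0)
        assert np.all(np.diff(mean_on) <= 0)
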