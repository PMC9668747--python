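"""Synthetic behaviour and trace generators: invariants and oracles."""

import numpy as np
import pytest

import plateaulearn as pl
from plateaulearn.utils import circular_distance


class TestBehavior:
    def test_lap_structure_and_wrap(self):
        """Position wraps exactly at lap boundaries and lap_index counts wraps."""
        beh = pl.generate_behavior(50, "A", seed=1)
        assert beh.n_laps == 50
        assert beh.lap_index.max() == 49
        # brute-force wrap scan of the position trace
        wraps = np.flatnonzero(np.diff(beh.position) < 0)
        assert wraps.size == 49
        assert np.array_equal(np.diff(beh.lap_index)[wraps], np.ones(49))
        assert (np.diff(beh.lap_index)[np.setdiff1d(
            np.arange(beh.n_frames - 1), wraps)] == 0).all()
        assert beh.position.min() >= 0 and beh.position.max() < 180

    def test_velocity_is_position_derivative(self):
        beh = pl.generate_behavior(20, "A", seed=2)
        step = np.diff(beh.position) % 180
        np.testing.assert_allclose(step, beh.velocity[:-1] * beh.dt, atol=1e-9)

    def test_position_nondecreasing_within_lap(self):
        beh = pl.generate_behavior(20, "A", seed=3)
        for lap in (0, 7, 19):
            p = beh.position[beh.lap_mask(lap)]
            assert (np.diff(p) >= 0).all()

    def test_constant_speed_gives_uniform_dwell(self):
        """Uniform motion forces equal per-bin dwell (0.2 s/lap at 18 cm/s)."""
        beh = pl.generate_behavior(
            20, "A", speed_params=pl.SpeedParams(constant=True, lap_jitter_sigma=0.0),
            seed=1)
        dwell = beh.dwell_profile()
        np.testing.assert_allclose(dwell, 0.2, rtol=0.02)

    def test_reward_zone_dwell_doubling(self):
        """Default environment-A profile doubles dwell in the reward zone."""
        beh = pl.generate_behavior(40, "A", seed=1)
        dwell = beh.dwell_profile()
        zone = pl.zone_bins(beh.reward_position)
        off = np.setdiff1d(np.arange(50), zone)
        ratio = dwell[zone].mean() / dwell[off].mean()
        assert 1.8 <= ratio <= 2.2

    def test_dwell_time_conservation(self):
        """Per-lap bin dwell times sum to the lap duration."""
        beh = pl.generate_behavior(25, "A", seed=4)
        for lap in (0, 12, 24):
            sel = beh.lap_mask(lap)
            bins = np.minimum((beh.position[sel] / 3.6).astype(int), 49)
            total = np.bincount(bins, minlength=50).sum() * beh.dt
            assert abs(total - sel.sum() * beh.dt) < 1e-9

    def test_licks_concentrate_before_reward(self):
        beh = pl.generate_behavior(40, "A", seed=5)
        lick_pos = beh.position[beh.lick]
        near = circular_distance(lick_pos, beh.reward_position - 10) <= 20
        assert near.mean() > 0.5

    def test_reproducibility(self):
        a = pl.generate_behavior(15, "A", seed=9)
        b = pl.generate_behavior(15, "A", seed=9)
        c = pl.generate_behavior(15, "A", seed=10)
        np.testing.assert_array_equal(a.position, b.position)
        assert not np.array_equal(a.position, c.position)

    @pytest.mark.parametrize("kwargs", [
        dict(n_laps=0),
        dict(n_laps=10, speed_params=pl.SpeedParams(base_speed=-5.0)),
        dict(n_laps=10, environment="Z"),
    ])
    def test_rejects_bad_inputs(self, kwargs):
        with pytest.raises(ValueError):
            pl.generate_behavior(**{"environment": "A", **kwargs})


class TestCa1Generator:
    def test_frac_place_zero_has_no_place_cells(self, behavior_a):
        _, truth = pl.generate_ca1_traces(behavior_a, n_cells=30, frac_place=0.0,
                                          seed=3)
        assert truth.place_cell_indices().size == 0

    def test_zero_shift_scale_is_identity(self, behavior_a):
        """With no backward shift the field centre equals the induction peak."""
        traces, truth = pl.generate_ca1_traces(
            behavior_a, n_cells=20, frac_place=1.0,
            btsp_params=pl.BtspParams(backward_shift_cm=0.0), seed=4)
        # regenerate with a shift to confirm the bookkeeping moves with it
        _, shifted = pl.generate_ca1_traces(
            behavior_a, n_cells=20, frac_place=1.0,
            btsp_params=pl.BtspParams(backward_shift_cm=9.0), seed=4)
        d = circular_distance(truth.true_field_center, shifted.true_field_center)
        np.testing.assert_allclose(d, 9.0, atol=1e-9)

    def test_width_scales_with_induction_velocity(self):
        """Widths measured at 20% of peak on noiseless maps scale ~2x when the
        induction velocity doubles."""
        beh_slow = pl.generate_behavior(
            20, "A", speed_params=pl.SpeedParams(base_speed=10.0, slow_factor=1.0,
                                                 lap_jitter_sigma=0.0,
                                                 stop_probability=0.0), seed=5)
        beh_fast = pl.generate_behavior(
            20, "A", speed_params=pl.SpeedParams(base_speed=20.0, slow_factor=1.0,
                                                 lap_jitter_sigma=0.0,
                                                 stop_probability=0.0), seed=5)
        widths = []
        for beh in (beh_slow, beh_fast):
            traces, truth = pl.generate_ca1_traces(
                beh, n_cells=12, frac_place=1.0,
                noise_params=pl.NoiseParams(dff_sigma=1e-3), seed=6)
            traces = pl.compute_dff(traces)
            maps = pl.build_activity_map(traces, beh)
            per_cell = []
            for u in range(12):
                m = maps.mean_map(unit=u)
                # brute-force 20%-of-peak threshold scan
                per_cell.append(np.count_nonzero(m > 0.2 * m.max()) * 3.6)
            widths.append(np.mean(per_cell))
        ratio = widths[1] / widths[0]
        # one 3.6-cm bin of slack on the factor-2 prediction
        assert abs(widths[1] - 2 * widths[0]) <= 2 * 3.6 or 1.7 <= ratio <= 2.3

    def test_place_cells_silent_before_induction(self, ca1_session, behavior_a):
        traces, truth, maps = ca1_session
        sig = pl.detect_transients(traces)
        for u in truth.place_cell_indices()[:10]:
            lap0 = truth.true_induction_lap[u]
            before = behavior_a.lap_index < max(lap0 - 1, 0)
            # essentially no significant frames before the induction lap
            assert sig[u][before].mean() < 0.01

    def test_noise_free_recovery_of_all_place_cells(self, behavior_a):
        """The classification chain recovers every generated place cell with
        the peak within one bin of the true field centre."""
        traces, truth = pl.generate_ca1_traces(
            behavior_a, n_cells=40, frac_place=0.5,
            noise_params=pl.NoiseParams(dff_sigma=1e-3), seed=7)
        traces = pl.compute_dff(traces)
        maps = pl.build_activity_map(traces, behavior_a)
        records = pl.classify_place_cells(maps, traces, behavior_a, seed=8)
        found = records[records["is_place_cell"]]
        true_idx = truth.place_cell_indices()
        assert set(true_idx) <= set(found["unit"])
        for _, row in found.iterrows():
            u = int(row["unit"])
            if u in true_idx:
                d = circular_distance(row["peak_position"],
                                      truth.true_field_center[u])
                assert d <= 1.5 * 3.6

    def test_short_session_rejected(self):
        beh = pl.generate_behavior(5, "A", seed=1)
        with pytest.raises(ValueError, match="induction laps"):
            pl.generate_ca1_traces(beh, n_cells=10)


class TestEc3Generator:
    def test_one_roi_per_axon_matches_chain_count(self, small_population,
                                                  behavior_a):
        rois, truth = pl.generate_ec3_rois(small_population, behavior_a,
                                           rois_per_axon=1, seed=9)
        assert rois.n_rois == small_population.config.n_chains
        assert np.array_equal(truth.axon_id, np.arange(rois.n_rois))

    def test_zero_noise_rois_correlate_perfectly(self, small_population,
                                                 behavior_a):
        rois, truth = pl.generate_ec3_rois(
            small_population, behavior_a, rois_per_axon=2,
            noise_params=pl.NoiseParams(dff_sigma=0.0), seed=10)
        f = rois.F
        # same axon, unit correlation; F0 differs so compare shapes
        for a in range(3):
            i, j = np.flatnonzero(truth.axon_id == a)
            r = np.corrcoef(f[i], f[j])[0, 1]
            assert r > 0.999999

    def test_within_axon_beats_between_axon_correlation(self, behavior_a):
        """Exhaustive all-pairs correlation separates shared-axon pairs."""
        cfg = pl.build_config("uniform", overrides={"n_chains": 40})
        pop = pl.simulate_chains(cfg, seed=23)
        rois, truth = pl.generate_ec3_rois(pop, behavior_a, rois_per_axon=2,
                                           seed=24)
        rois = pl.compute_dff(rois)
        corr = np.corrcoef(rois.dff)
        same = truth.axon_id[:, None] == truth.axon_id[None, :]
        iu = np.triu_indices(rois.n_rois, k=1)
        within = corr[iu][same[iu]]
        between = corr[iu][~same[iu]]
        assert np.median(within) > np.median(between)
        assert np.median(within) > 0.5

    def test_empty_population_rejected(self, behavior_a):
        cfg = pl.build_config("uniform", overrides={"n_chains": 1})
        pop = pl.simulate_chains(cfg, seed=1)
        pop.states = pop.states[:0]
        pop.config.n_chains = 0
        with pytest.raises(ValueError, match="empty"):
            pl.generate_ec3_rois(pop, behavior_a)
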