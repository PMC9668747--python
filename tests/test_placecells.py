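"""Place-cell identification: field geometry, induction rule, spatial
information, shuffle test, classification and population summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plateaulearn as pl
from plateaulearn.placecells import (detect_induction_lap, find_eventual_field,
                                     si_shuffle_test, spatial_information)


class TestEventualField:
    def test_single_active_bin(self):
        m = np.zeros(50)
        m[10] = 1.0
        field, peak = find_eventual_field(m)
        assert peak == 10 and set(field) == {10}
        assert field.size * 3.6 == pytest.approx(3.6)

    def test_triangular_bump_width(self):
        """Five bins above 20% of peak -> 18 cm width (threshold-scan oracle)."""
        m = np.zeros(50)
        m[18:23] = [0.5, 0.8, 1.0, 0.8, 0.5]
        m[17] = 0.1
        m[23] = 0.1
        field, peak = find_eventual_field(m)
        assert peak == 20
        assert field.size * 3.6 == pytest.approx(18.0)

    def test_field_contiguous_across_wrap(self):
        m = np.zeros(50)
        m[[48, 49, 0, 1]] = [0.6, 1.0, 0.9, 0.5]
        field, peak = find_eventual_field(m)
        assert peak == 49
        assert set(field) == {48, 49, 0, 1}

    def test_all_zero_map_has_no_field(self):
        field, peak = find_eventual_field(np.zeros(50))
        assert field is None and peak == -1


class TestInductionLap:
    @staticmethod
    def _sig(active_laps, n_laps=60, bins=(5,)):
        s = np.zeros((n_laps, 50), dtype=bool)
        for lap in active_laps:
            s[lap, list(bins)] = True
        return s

    def test_simple_confirmed_onset(self):
        sig = self._sig([5, 6, 7])
        assert detect_induction_lap(sig, np.array([5])) == 5

    def test_two_of_five_rule_rejects_isolated_lap(self):
        """Activity in lap 3 alone fails confirmation; the streak at lap 30
        is the induction (exhaustive-scan oracle)."""
        sig = self._sig([3, 30, 31, 32])
        assert detect_induction_lap(sig, np.array([5])) == 30

    def test_never_confirmed_is_absent(self):
        sig = self._sig([3, 20, 40])
        assert detect_induction_lap(sig, np.array([5])) == -1

    def test_gap_rule_resumes_after_disappearance(self):
        """A weak field vanishing for >20 laps restarts the search."""
        sig = self._sig([2, 3, 4] + list(range(30, 45)))
        assert detect_induction_lap(sig, np.array([5])) == 30

    def test_outside_field_activity_ignored(self):
        sig = self._sig([5, 6, 7], bins=(40,))
        assert detect_induction_lap(sig, np.array([5])) == -1


class TestSpatialInformation:
    def test_uniform_map_is_zero(self):
        p = np.full(50, 0.02)
        assert spatial_information(np.full(50, 3.3), p) == pytest.approx(0.0)

    def test_two_bin_worked_example(self):
        """P=(0.5,0.5), lambda=(2,0): mean rate 1, SI = 0.5*2*log2(2) = 1 bit."""
        assert spatial_information(np.array([2.0, 0.0]),
                                   np.array([0.5, 0.5])) == pytest.approx(1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 10.0), min_size=2, max_size=50),
           st.integers(0, 2 ** 31 - 1))
    def test_nonnegative_for_any_map(self, lam, occ_seed):
        """Occupancy-weighted SI is a Jensen divergence, hence >= 0."""
        rng = np.random.default_rng(occ_seed)
        p = rng.random(len(lam)) + 1e-9
        p /= p.sum()
        assert spatial_information(np.array(lam), p) >= -1e-12

    def test_joint_permutation_invariance(self, rng):
        lam = rng.random(50)
        p = rng.random(50)
        p /= p.sum()
        perm = rng.permutation(50)
        assert spatial_information(lam[perm], p[perm]) == pytest.approx(
            spatial_information(lam, p))

    def test_silent_unit_flagged_zero(self):
        assert spatial_information(np.zeros(10), np.full(10, 0.1)) == 0.0


class TestShuffleTest:
    def test_perfect_place_cell_passes(self, behavior_a):
        from plateaulearn.utils import circular_distance
        running = behavior_a.running_mask()
        act = np.exp(-circular_distance(behavior_a.position, 90.0) ** 2 / 50.0)
        bins = np.minimum((behavior_a.position / 3.6).astype(int), 49)
        p = np.bincount(bins[running], minlength=50).astype(float)
        p /= p.sum()
        obs, shuffles, passes = si_shuffle_test(act[running], bins[running], p,
                                                seed=5)
        assert passes
        assert obs > shuffles.max()

    def test_seed_determinism(self, behavior_a, rng):
        running = behavior_a.running_mask()
        d = rng.normal(0, 0.1, behavior_a.n_frames)
        bins = np.minimum((behavior_a.position / 3.6).astype(int), 49)
        p = np.bincount(bins[running], minlength=50).astype(float)
        p /= p.sum()
        _, s1, _ = si_shuffle_test(d[running], bins[running], p, seed=3)
        _, s2, _ = si_shuffle_test(d[running], bins[running], p, seed=3)
        np.testing.assert_array_equal(s1, s2)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="short"):
            si_shuffle_test(np.zeros(900), np.zeros(900, int), np.ones(50) / 50)


class TestClassification:
    def test_recovers_ground_truth_cells(self, ca1_records):
        records, truth = ca1_records
        found = set(records[records["is_place_cell"]]["unit"])
        true_set = set(truth.place_cell_indices())
        recall = len(found & true_set) / len(true_set)
        assert recall >= 0.9
        noise_idx = set(np.flatnonzero(truth.cell_class == "noise_only"))
        fpr = len(found & noise_idx) / max(len(noise_idx), 1)
        assert fpr <= 0.05

    def test_one_record_per_unit(self, ca1_records, ca1_session):
        records, _ = ca1_records
        traces, _, _ = ca1_session
        assert len(records) == traces.n_rois
        assert records["unit"].is_unique

    def test_all_silent_population_yields_no_place_cells(self, behavior_a):
        traces, _ = pl.generate_ca1_traces(behavior_a, n_cells=10,
                                           frac_place=0.0, seed=41)
        traces = pl.compute_dff(traces)
        maps = pl.build_activity_map(traces, behavior_a)
        records = pl.classify_place_cells(maps, traces, behavior_a, seed=42)
        silent = np.flatnonzero(~maps.significant.any(axis=(1, 2)))
        assert not records.loc[records["unit"].isin(silent), "is_place_cell"].any()

    def test_classification_monotone_in_reliability(self, ca1_session,
                                                    behavior_a):
        """Raising the reliability threshold never adds place cells."""
        traces, _, maps = ca1_session
        lo = pl.classify_place_cells(maps, traces, behavior_a, seed=13,
                                     reliability_threshold=0.30)
        hi = pl.classify_place_cells(maps, traces, behavior_a, seed=13,
                                     reliability_threshold=0.60)
        assert set(hi[hi["is_place_cell"]]["unit"]) <= \
            set(lo[lo["is_place_cell"]]["unit"])

    def test_peak_shift_sign_convention(self):
        """Backward displacements are negative and wrap-aware."""
        from plateaulearn.utils import circular_signed_difference as csd
        assert csd(88.0, 90.0) == pytest.approx(-2.0)
        assert csd(178.0, 2.0) == pytest.approx(-4.0)
        assert csd(90.0, 90.0) == pytest.approx(0.0)

    def test_btsp_cells_shift_backward(self, ca1_records):
        records, _ = ca1_records
        pc = records[records["is_place_cell"]]
        assert pc["peak_shift"].median() < 0


class TestWidthVelocity:
    def test_exact_linear_data_recovered(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(5, 30, 60)
        records = pd.DataFrame({
            "is_place_cell": True, "induction_velocity": v, "width": 1.8 * v})
        fit = pl.width_velocity_relation(records)
        assert fit["slope"] == pytest.approx(1.8, rel=1e-6)
        assert fit["r"] == pytest.approx(1.0, abs=1e-9)

    def test_single_velocity_bin_refused(self):
        records = pd.DataFrame({
            "is_place_cell": True,
            "induction_velocity": [12.0, 12.5, 13.0],
            "width": [20.0, 21.0, 22.0]})
        with pytest.raises(ValueError, match="one velocity bin"):
            pl.width_velocity_relation(records)

    def test_empty_records_refused(self):
        records = pd.DataFrame({"is_place_cell": [], "induction_velocity": [],
                                "width": []})
        with pytest.raises(ValueError):
            pl.width_velocity_relation(records)


class TestPopulationAnalyses:
    def test_step_appearance_when_all_inductions_on_lap_one(self, ca1_session,
                                                            behavior_a):
        _, _, maps = ca1_session
        records = pd.DataFrame({
            "is_place_cell": [True] * 5, "induction_lap": [1] * 5,
            "peak_position": [10.0, 50.0, 90.0, 130.0, 170.0]})
        bm = pl.behavior_maps(behavior_a)
        out = pl.population_summaries(records, maps, bm)
        assert out["appearance"][0] == 0.0
        assert out["appearance"][1] == 1.0
        assert (out["appearance"][1:] == 1.0).all()

    def test_uniform_field_centres_spread_over_density_bins(self, behavior_a,
                                                            ca1_session):
        """Uniformly placed peaks land ~0.1 per 18-cm bin (binomial oracle)."""
        _, _, maps = ca1_session
        rng = np.random.default_rng(8)
        n = 400
        records = pd.DataFrame({
            "is_place_cell": True, "induction_lap": 5,
            "peak_position": rng.uniform(0, 180, n)})
        bm = pl.behavior_maps(behavior_a)
        out = pl.population_summaries(records, maps, bm)
        se = np.sqrt(0.1 * 0.9 / n)
        assert np.all(np.abs(out["density"] - 0.1) < 4 * se)

    def test_population_vector_identical_maps(self, ca1_session):
        _, _, maps = ca1_session
        out = pl.population_vector_correlation(maps, maps)
        np.testing.assert_allclose(out["per_bin"][np.isfinite(out["per_bin"])],
                                   1.0, atol=1e-9)

    def test_population_vector_unit_permutation_invariance(self, ca1_session):
        """Permuting units identically in both maps leaves correlations
        unchanged."""
        _, _, maps = ca1_session
        rng = np.random.default_rng(5)
        perm = rng.permutation(maps.n_units)
        a = pl.population_vector_correlation(maps, maps, units=perm)
        b = pl.population_vector_correlation(maps, maps)
        assert a["mean"] == pytest.approx(b["mean"])

    def test_population_vector_needs_three_units(self, ca1_session):
        _, _, maps = ca1_session
        with pytest.raises(ValueError, match="3"):
            pl.population_vector_correlation(maps, maps, units=np.array([0, 1]))

    def test_independent_noise_maps_decorrelate(self):
        import dataclasses
        rng = np.random.default_rng(9)
        beh = pl.generate_behavior(12, "A", seed=10)
        base = pl.build_activity_map(
            pl.compute_dff(pl.RoiTraceSet(
                F=100 * (1 + np.abs(rng.normal(0, 0.05, (3, beh.n_frames)))),
                roi_size=np.full(3, 50))), beh,
            significant=np.zeros((3, beh.n_frames), bool))
        m1 = dataclasses.replace(base, mean_dff=rng.normal(size=(200, 12, 50)))
        m2 = dataclasses.replace(base, mean_dff=rng.normal(size=(200, 12, 50)))
        out = pl.population_vector_correlation(m1, m2)
        assert abs(out["mean"]) < 0.1


class TestSessionSections:
    def test_identical_ec3_and_ca1_profiles_correlate_fully(self, ca1_session):
        _, _, maps = ca1_session
        records = pd.DataFrame({"is_place_cell": [True], "induction_lap": [2]})
        out = pl.session_section_profiles(maps, records, maps, section_laps=10)
        np.testing.assert_allclose(out["ec3_ca1_correlation"], 1.0, atol=1e-9)

    def test_formation_fraction_concentrates_in_first_section(self, ca1_session):
        _, _, maps = ca1_session
        records = pd.DataFrame({"is_place_cell": [True] * 4,
                                "induction_lap": [1, 3, 5, 9]})
        out = pl.session_section_profiles(maps, records, maps, section_laps=10)
        assert out["formation_fraction"][0] == pytest.approx(1.0)
        assert np.allclose(out["formation_fraction"][1:], 0.0)

    def test_too_many_sections_refused(self, ca1_session):
        _, _, maps = ca1_session
        records = pd.DataFrame({"is_place_cell": [True], "induction_lap": [2]})
        with pytest.raises(ValueError, match="sections"):
            pl.session_section_profiles(maps, records, maps, section_laps=10,
                                        n_sections=20)
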