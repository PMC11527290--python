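"""Grid, cost and window-fitting tests, including the tie-break cascade."""

import numpy as np
import pandas as pd
import pytest

from sleepswitch.metrics import N_BINS, SleepProbabilityProfile
from sleepswitch.fitting import (GridLibrary, GridSpec, NoFeasibleEntry,
                                 PARAM_NAMES, build_grid, fit_trajectory,
                                 fit_window, loess_smooth, precompute_library,
                                 record_profile, total_cost, window_cost,
                                 constrained_scan)
from sleepswitch.synth import NoiseConfig, ParameterTrajectory, generate_record


def flat_profile(value, coverage=1.0, center=0.0):
    return SleepProbabilityProfile(probs=np.full(N_BINS, value),
                                   coverage=np.full(N_BINS, coverage),
                                   window_center_day=center)


def toy_library(rows):
    """Hand-built library; rows = (mu, chi, nu_vc, b, bpd, tau, probs)."""
    data = []
    for mu, chi, nu_vc, b, bpd, tau, probs in rows:
        row = {"mu": mu, "chi": chi, "nu_vc": nu_vc, "b": b,
               "sim_ok": True, "bpd": bpd, "tau_obs": tau}
        row.update({f"prob_{i:02d}": p for i, p in enumerate(probs)})
        data.append(row)
    return GridLibrary(table=pd.DataFrame(data))


class TestGrid:
    def test_published_value_counts(self):
        spec = GridSpec()
        assert len(spec.mu_values) == 47          # (15.9-2.1)/0.3 + 1
        assert len(spec.nu_vc_values) == 20       # 15 + 11 - 6 duplicates
        assert len(spec.b_values) == 9            # 4 + 5
        # chi: 31 linear + 24 log-spaced, no coincidences
        assert len(spec.chi_values) == 55
        assert spec.size == 47 * 55 * 20 * 9

    def test_value_sets_sorted_and_unique(self):
        spec = GridSpec()
        for name in PARAM_NAMES:
            v = np.array(spec.values(name))
            assert np.all(np.diff(v) > 0)

    def test_nu_vc_enumeration_oracle(self):
        coarse = {round(-7.0 + 0.5 * i, 6) for i in range(15)}
        fine = {round(-3.5 + 0.25 * i, 6) for i in range(11)}
        assert set(GridSpec().nu_vc_values) == coarse | fine

    def test_grid_is_lexicographic_product(self):
        spec = GridSpec(mu_values=(1.0, 2.0), chi_values=(5.0, 6.0),
                        nu_vc_values=(-1.0,), b_values=(0.4, 0.5))
        grid = build_grid(spec)
        assert len(grid) == 8
        assert grid == sorted(grid)

    def test_empty_value_set_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(mu_values=())


class TestCost:
    def test_identical_profiles(self):
        assert window_cost(flat_profile(0.3), flat_profile(0.3)) == 0.0

    def test_single_bin_difference(self):
        a = flat_profile(0.5)
        b = flat_profile(0.5)
        b.probs = b.probs.copy()
        b.probs[10] = 1.0
        assert window_cost(a, b) == pytest.approx(0.25)

    def test_zero_coverage_bins_excluded(self):
        a = flat_profile(0.0)
        a.coverage = a.coverage.copy()
        a.coverage[:24] = 0.0
        b = flat_profile(0.0)
        b.probs = b.probs.copy()
        b.probs[:24] = 1.0   # disagreement only where data are missing
        assert window_cost(a, b) == 0.0

    def test_no_covered_bins_rejected(self):
        a = flat_profile(0.0, coverage=0.0)
        with pytest.raises(ValueError):
            window_cost(a, flat_profile(0.0))

    def test_random_profiles_match_summation_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            pa, pb = rng.random(N_BINS), rng.random(N_BINS)
            cov = (rng.random(N_BINS) < 0.8).astype(float)
            a = SleepProbabilityProfile(probs=pa, coverage=cov)
            b = SleepProbabilityProfile(probs=pb, coverage=np.ones(N_BINS))
            expect = sum((x - y) ** 2 for x, y, c in zip(pa, pb, cov) if c > 0)
            assert window_cost(a, b) == pytest.approx(expect)

    def test_total_cost(self):
        assert total_cost([0.0, 0.0]) == 0.0
        assert total_cost([1.0, 2.0, 3.0], 3) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            total_cost([1.0, 2.0], 3)


class TestFitWindow:
    def base_rows(self):
        probs_a = np.linspace(0, 1, N_BINS)
        probs_b = 1.0 - np.linspace(0, 1, N_BINS)
        return [
            (4.0, 10.0, -2.0, 0.8, 3.0, 24.001, probs_a),
            (5.0, 10.0, -2.0, 0.8, 3.0, 24.000, probs_b),
        ]

    def test_self_fit_returns_generating_entry(self):
        lib = toy_library(self.base_rows())
        profile = lib.profile_of((4.0, 10.0, -2.0, 0.8))
        fit = fit_window(profile, lib)
        assert fit.best_combo == (4.0, 10.0, -2.0, 0.8)
        assert fit.cost == 0.0

    def test_bpd_and_period_filters(self):
        rows = self.base_rows()
        rows[0] = rows[0][:4] + (1.0, 24.001, rows[0][6])       # bpd too low
        rows[1] = rows[1][:4] + (3.0, 24.010, rows[1][6])       # period outside
        lib = toy_library(rows)
        with pytest.raises(NoFeasibleEntry):
            fit_window(flat_profile(0.5), lib)

    def test_fixed_constraint_excludes_other_values(self):
        lib = toy_library(self.base_rows())
        fit = fit_window(flat_profile(0.5), lib, fixed={"mu": 5.0})
        assert fit.best_combo[0] == 5.0
        assert fit.feasible_count == 1

    def test_fixed_value_off_grid_rejected(self):
        lib = toy_library(self.base_rows())
        with pytest.raises(ValueError):
            fit_window(flat_profile(0.5), lib, fixed={"mu": 4.5})

    def test_tie_cascade_period_then_grid_order(self):
        probs = np.full(N_BINS, 0.5)
        rows = [
            # equal cost, |tau-24| = 0.004 for both: grid order decides
            (4.0, 10.0, -2.0, 0.8, 3.0, 23.996, probs),
            (5.0, 10.0, -2.0, 0.8, 3.0, 24.004, probs),
            # worse period distance loses even at equal cost
            (6.0, 10.0, -2.0, 0.8, 3.0, 24.005, probs),
        ]
        fit = fit_window(flat_profile(0.5), toy_library(rows))
        assert fit.cost == 0.0
        assert fit.n_ties == 3
        assert fit.best_combo == (4.0, 10.0, -2.0, 0.8)

    def test_period_tiebreak_prefers_closest_to_24h(self):
        probs = np.full(N_BINS, 0.5)
        rows = [
            (4.0, 10.0, -2.0, 0.8, 3.0, 24.004, probs),
            (5.0, 10.0, -2.0, 0.8, 3.0, 24.001, probs),
        ]
        fit = fit_window(flat_profile(0.5), toy_library(rows))
        assert fit.best_combo[0] == 5.0

    def test_constraint_never_decreases_cost(self, reduced_library):
        rng = np.random.default_rng(4)
        for _ in range(10):
            profile = SleepProbabilityProfile(probs=rng.random(N_BINS),
                                              coverage=np.ones(N_BINS))
            free = fit_window(profile, reduced_library)
            for name, value in zip(PARAM_NAMES, free.best_combo):
                pinned = fit_window(profile, reduced_library,
                                    fixed={name: value})
                assert pinned.cost >= free.cost or np.isclose(pinned.cost, free.cost)
            other = fit_window(profile, reduced_library, fixed={"b": 0.85})
            assert other.cost >= free.cost - 1e-12

    def test_widening_period_band_never_increases_cost(self, reduced_library):
        rng = np.random.default_rng(9)
        profile = SleepProbabilityProfile(probs=rng.random(N_BINS),
                                          coverage=np.ones(N_BINS))
        narrow = fit_window(profile, reduced_library)
        wide = fit_window(profile, reduced_library, period_band=(23.5, 24.5))
        assert wide.cost <= narrow.cost


class TestLibraryCache:
    def test_cache_hit_skips_simulation(self, tmp_path, monkeypatch):
        spec = GridSpec(mu_values=(8.1,), chi_values=(12.0,),
                        nu_vc_values=(-3.0,), b_values=(0.85, 1.0))
        grid = build_grid(spec)
        cache = str(tmp_path / "lib.csv")
        first = precompute_library(grid, cache_path=cache)

        calls = {"n": 0}
        import sleepswitch.fitting as fitting_mod

        def counting_entry(*args, **kwargs):
            calls["n"] += 1
            raise AssertionError("cache miss")

        monkeypatch.setattr(fitting_mod, "simulate_combo_entry", counting_entry)
        second = precompute_library(grid, cache_path=cache)
        assert calls["n"] == 0
        pd.testing.assert_frame_equal(first.table, second.table)

    def test_manifest_mismatch_rejected(self, tmp_path):
        spec = GridSpec(mu_values=(8.1,), chi_values=(12.0,),
                        nu_vc_values=(-3.0,), b_values=(1.0,))
        cache = str(tmp_path / "lib.csv")
        precompute_library(build_grid(spec), cache_path=cache)
        with pytest.raises(ValueError):
            precompute_library(build_grid(spec), cache_path=cache, run_days=14)

    def test_library_row_per_combo_in_grid_order(self, reduced_library):
        assert len(reduced_library) == 72
        combos = reduced_library.combos
        order = sorted(map(tuple, combos))
        assert [tuple(c) for c in combos] == order


class TestTrajectory:
    def test_noiseless_record_recovers_generating_combo(self, reduced_library):
        combo = (8.1, 12.0, -3.0, 1.0)
        record, _ = generate_record(ParameterTrajectory.constant(combo),
                                    NoiseConfig(), n_days=14)
        traj = fit_trajectory(record, reduced_library)
        assert len(traj.results) == 8           # 14 days, 7-day window, step 1
        for r in traj.results:
            assert r.best_combo == combo

    def test_window_count_for_minimal_record(self, reduced_library):
        record, _ = generate_record(
            ParameterTrajectory.constant((8.1, 12.0, -3.0, 1.0)),
            NoiseConfig(), n_days=7)
        traj = fit_trajectory(record, reduced_library)
        assert len(traj.results) == 1
        assert traj.results[0].window_center_day == 3.0

    def test_parameter_switch_located(self, reduced_library):
        traj_spec = ParameterTrajectory(
            breakpoints=(0.0, 14.0),
            values=((10.5, 7.0, -1.5, 1.0), (8.1, 12.0, -3.0, 1.0)))
        record, _ = generate_record(traj_spec, NoiseConfig(), n_days=28,
                                    block_days=7)
        fitted = fit_trajectory(record, reduced_library).to_frame()
        mu = fitted.set_index("window_center_day")["mu"]
        # windows fully before/after the switch recover the two plateaus
        assert np.all(mu[mu.index <= 10] == 10.5)
        assert np.all(mu[mu.index >= 18] == 8.1)
        change_days = mu.index[np.flatnonzero(np.diff(mu.to_numpy()) != 0)]
        assert np.all(np.abs(change_days - 14.0) <= 4.0)

    def test_gap_days_skip_windows_and_log(self):
        # 21-day record with days 7-13 absent entirely: windows falling
        # wholly inside the gap are skipped and logged, the rest fitted
        from sleepswitch.records import SleepRecord, WAKE, SLEEP
        probs = np.zeros(N_BINS)
        probs[:16] = 1.0
        lib = toy_library([(4.0, 10.0, -2.0, 0.8, 3.0, 24.001, probs)])
        days = np.array([d for d in range(21) if not 7 <= d <= 13])
        states = np.full((days.size, 1440), WAKE, dtype=np.int8)
        states[:, :480] = SLEEP
        record = SleepRecord(days=days, states=states, meta={})
        traj = fit_trajectory(record, lib)
        skipped_starts = [s for s, _ in traj.skipped]
        assert skipped_starts == [7]          # the only all-missing window
        assert len(traj.results) == 14
        assert all(r.cost == 0.0 for r in traj.results)

    def test_record_shorter_than_window_rejected(self, reduced_library):
        record, _ = generate_record(
            ParameterTrajectory.constant((8.1, 12.0, -3.0, 1.0)),
            NoiseConfig(), n_days=7)
        short = type(record)(days=record.days[:5], states=record.states[:5],
                             meta=record.meta)
        with pytest.raises(ValueError):
            fit_trajectory(short, reduced_library)

    def test_constrained_scan_contracts(self, reduced_library):
        combo = (9.3, 12.0, -1.5, 1.0)
        record, _ = generate_record(ParameterTrajectory.constant(combo),
                                    NoiseConfig(onset_jitter_sd=20.0, seed=3),
                                    n_days=10)
        subsets = [{}, {"b": 1.0}, dict(zip(PARAM_NAMES, combo))]
        scan = constrained_scan(record, reduced_library, subsets,
                                day_ranges=[(0, 9)])
        free, fixed_b, fixed_all = scan.iloc[0], scan.iloc[1], scan.iloc[2]
        unconstrained = fit_trajectory(record, reduced_library)
        assert np.allclose(free["costs"], unconstrained.costs)
        assert fixed_b["mean_cost"] >= free["mean_cost"] - 1e-12
        assert fixed_all["mean_cost"] >= fixed_b["mean_cost"] - 1e-12

    def test_fully_fixed_subset_is_constant(self, reduced_library):
        combo = (9.3, 12.0, -1.5, 1.0)
        record, _ = generate_record(ParameterTrajectory.constant(combo),
                                    NoiseConfig(onset_jitter_sd=20.0, seed=3),
                                    n_days=10)
        traj = fit_trajectory(record, reduced_library,
                              fixed=dict(zip(PARAM_NAMES, combo)))
        assert all(r.best_combo == combo for r in traj.results)


class TestLoess:
    def test_constant_series(self):
        x = np.arange(30.0)
        assert np.allclose(loess_smooth(x, np.full(30, 5.0)), 5.0)

    def test_linear_series_recovered(self):
        x = np.arange(50.0)
        y = 2.0 * x + 1.0
        assert np.allclose(loess_smooth(x, y, alpha=0.4), y, atol=1e-8)

    def test_noisy_sinusoid_variance_reduced(self):
        rng = np.random.default_rng(6)
        x = np.arange(200.0)
        signal = np.sin(2 * np.pi * x / 100.0)
        y = signal + rng.normal(0, 0.3, size=x.size)
        smooth = loess_smooth(x, y, alpha=0.2)
        assert np.var(smooth - signal) < np.var(y - signal)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth(np.zeros(5), np.arange(5.0))
        with pytest.raises(ValueError):
            loess_smooth(np.arange(2.0), np.arange(2.0))
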