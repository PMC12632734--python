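"""Data model and per-unit statistics: binning, selectivity, preferred
location, laminar bands, population rate, delay-elevation test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import wmstates as w
from wmstates.core import epoch_mean_rates, laminar_selectivity, n_bins_for

from conftest import make_dataset


class TestBinRates:
    def test_counts_divided_by_width(self):
        ds = make_dataset({(0, 0): [0.01, 0.02, 0.54]}, n_trials=1)
        b = w.bin_rates(ds, width=0.5, step=0.5, span=(0.0, 1.0))
        assert b.n_bins == 2
        np.testing.assert_allclose(b.rates[0, 0], [4.0, 2.0])

    def test_empty_bins_are_zero(self):
        ds = make_dataset({(0, 0): [0.01]}, n_trials=1)
        b = w.bin_rates(ds, width=0.1, step=0.1, span=(1.0, 2.0))
        assert (b.rates == 0).all()

    def test_overlapping_bins_count_spikes_twice(self):
        ds = make_dataset({(0, 0): [0.26]}, n_trials=1)
        b = w.bin_rates(ds, width=0.1, step=0.05, span=(0.0, 0.5))
        hit = b.rates[0, 0] > 0
        assert hit.sum() == 2  # spike lies in two overlapping 100 ms windows

    def test_total_count_conserved_with_abutting_bins(self, tuned_session):
        b = w.bin_rates(tuned_session, width=0.05, step=0.05, span=(-1.0, 4.1))
        assert int(round(b.rates.sum() * 0.05)) == len(tuned_session.spikes)

    def test_poisson_rate_recovered(self):
        rng = np.random.default_rng(0)
        spikes = {
            (0, t): rng.uniform(-1.0, 4.1, size=rng.poisson(10 * 5.1)) for t in range(200)
        }
        ds = make_dataset(spikes, n_trials=200)
        b = w.bin_rates(ds, width=0.05, step=0.05, span=(-1.0, 4.1))
        mean = b.rates.mean()
        se = 10.0 / np.sqrt(0.05 * b.n_bins * 200 * 10)
        assert abs(mean - 10.0) < 3 * se

    def test_errors(self):
        ds = make_dataset({(0, 0): [0.1]}, n_trials=1)
        with pytest.raises(ValueError):
            w.bin_rates(ds, width=-0.1)
        with pytest.raises(ValueError):
            w.bin_rates(ds, width=0.1, span=(-5.0, 0.0))
        empty = w.SpikeDataset(
            ds.spikes.iloc[:0], ds.trials.iloc[:0], ds.units.iloc[:0]
        )
        with pytest.raises(ValueError):
            w.bin_rates(empty)

    @given(
        width=st.floats(0.02, 0.5),
        ratio=st.integers(1, 4),
    )
    @settings(max_examples=20, deadline=None)
    def test_bin_count_formula(self, width, ratio):
        step = width / ratio
        span = (0.0, 3.0)
        assert n_bins_for(span, width, step) == int(np.floor((3.0 - width) / step + 1e-9)) + 1


class TestSelectivity:
    def _session(self, rates_by_loc, n_per_loc=10, seed=0):
        rng = np.random.default_rng(seed)
        locs = np.repeat(np.arange(0.0, 360.0, 45.0), n_per_loc)
        spikes = {}
        for t, ang in enumerate(locs):
            lam = rates_by_loc(ang) * 3.0
            spikes[(0, t)] = 0.5 + np.sort(rng.uniform(0, 3.0, size=rng.poisson(lam)))
        return make_dataset(spikes, n_trials=len(locs), locations=locs)

    def test_tuned_unit_flagged(self):
        ds = self._session(lambda a: 20.0 if a == 0.0 else 1.0)
        out = w.classify_selectivity(ds, epoch=(0.5, 3.5))
        assert bool(out["selective"][0])

    def test_rate_gate_blocks_weak_unit(self):
        ds = self._session(lambda a: 1.0 if a == 0.0 else 0.05)
        out = w.classify_selectivity(ds, epoch=(0.5, 3.5))
        assert out["p_anova"][0] < 0.05 and not bool(out["selective"][0])

    def test_null_type_one_rate(self, untuned_session):
        out = w.classify_selectivity(untuned_session, alpha=0.05, min_best_rate_hz=0.0)
        frac = (out["p_anova"] < 0.05).mean()
        n = len(out)
        assert frac < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)

    def test_anova_pvalues_uniform_under_null(self):
        # 200 independent Poisson units, no tuning: p ~ U(0,1)
        rng = np.random.default_rng(3)
        locs = np.repeat(np.arange(0.0, 360.0, 45.0), 5)
        spikes = {}
        for u in range(200):
            for t in range(len(locs)):
                spikes[(u, t)] = 0.5 + np.sort(rng.uniform(0, 3.0, size=rng.poisson(24)))
        ds = make_dataset(spikes, n_trials=len(locs), locations=locs)
        out = w.classify_selectivity(ds)
        assert stats.kstest(out["p_anova"], "uniform").pvalue > 0.01

    def test_missing_location_errors(self):
        ds = make_dataset({(0, 0): [1.0], (0, 1): [1.0]}, n_trials=2, locations=[0.0, 45.0])
        with pytest.raises(ValueError, match="fewer than 2 trials"):
            w.classify_selectivity(ds)


class TestPreferredLocation:
    def test_single_mass(self):
        p = w.preferred_location([0, 0, 1, 0, 0, 0, 0, 0])
        assert p.theta_pref_deg == pytest.approx(90.0)
        assert p.modulus == pytest.approx(1.0)

    def test_symmetry_undefined(self):
        p = w.preferred_location([3.0] * 8)
        assert not p.defined and p.modulus == 0.0

    def test_two_mass_bisector(self):
        n = np.zeros(8)
        n[0] = 5
        n[2] = 5  # 0 and 90 degrees
        p = w.preferred_location(n)
        assert p.theta_pref_deg == pytest.approx(45.0)
        assert p.modulus == pytest.approx(np.cos(np.deg2rad(45.0)), abs=1e-12)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            w.preferred_location(np.zeros(8))

    @given(
        counts=st.lists(st.floats(0.0, 50.0, allow_subnormal=False), min_size=8, max_size=8),
        shift=st.integers(0, 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_rotation_equivariance(self, counts, shift):
        counts = np.asarray(counts)
        if counts.sum() == 0:
            return
        p0 = w.preferred_location(counts)
        p1 = w.preferred_location(np.roll(counts, shift))
        if p0.defined and p1.defined:
            delta = (p1.theta_pref_deg - p0.theta_pref_deg - 45.0 * shift + 180.0) % 360.0 - 180.0
            assert delta == pytest.approx(0.0, abs=1e-6)
            assert p1.modulus == pytest.approx(p0.modulus, abs=1e-9)


class TestLaminar:
    @pytest.mark.parametrize(
        "depth,layer",
        [(0.0, "superficial"), (0.79, "superficial"), (0.8, "middle"), (1.19, "middle"),
         (1.2, "deep"), (2.0, "deep")],
    )
    def test_band_assignment(self, depth, layer):
        assert w.laminar_class(depth) == layer

    def test_negative_depth_errors(self):
        with pytest.raises(ValueError):
            w.laminar_class(-0.1)

    def test_selective_proportion(self, untuned_session):
        sel = w.classify_selectivity(untuned_session)
        table = laminar_selectivity(untuned_session, sel)
        assert set(table.columns) >= {"layer", "n_selective", "n_units", "proportion"}
        assert (table["proportion"] <= 1).all()


class TestPopulationRate:
    def test_constant_unit_gives_flat_trace(self):
        rng = np.random.default_rng(1)
        spikes = {(0, t): np.sort(rng.uniform(-1, 4.1, size=rng.poisson(51))) for t in range(50)}
        ds = make_dataset(spikes, n_trials=50)
        out = w.population_rate_preferred(ds, width=0.5, step=0.5)
        assert np.allclose(out["mean"], 10.0, atol=1.5)

    def test_without_states_equals_all_trial_mean(self, tuned_session):
        prefs = w.preferred_locations_table(tuned_session)
        out = w.population_rate_preferred(tuned_session, prefs=prefs)
        assert "mean_on" not in out
        assert out["n_pairs"] > 0

    def test_gated_on_exceeds_off(self):
        ds, truth = w.state_detection_session(seed=9, n_units_per_area=10, n_trials_per_location=6)
        # use ground-truth gating as the state masks
        centers = np.arange(0.55, 3.5, 0.05)
        tids = ds.trial_ids
        off = np.zeros((len(tids), len(centers)), dtype=bool)
        for i, tid in enumerate(tids):
            for a, b in truth["PFC"][int(tid)]:
                off[i] |= (centers >= a) & (centers < b)
        out = w.population_rate_preferred(
            ds, width=0.1, step=0.05, span=(0.5, 3.5),
            state_masks={"on": ~off, "off": off},
            state_trial_ids=tids, state_centers=centers,
        )
        sel = ~np.isnan(out["mean_on"]) & ~np.isnan(out["mean_off"])
        assert out["mean_on"][sel].mean() > out["mean_off"][sel].mean()


class TestDelayElevation:
    def _session(self, delay_gain, n_trials=50, seed=0):
        rng = np.random.default_rng(seed)
        spikes = {}
        for u in range(5):
            for t in range(n_trials):
                fix = -1.0 + np.sort(rng.uniform(0, 1.0, size=rng.poisson(10)))
                delay = 0.5 + np.sort(rng.uniform(0, 3.0, size=rng.poisson(30 * delay_gain)))
                spikes[(u, t)] = np.concatenate([fix, delay])
        return make_dataset(spikes, n_trials=n_trials)

    def test_null_few_significant(self):
        out = w.delay_elevation_test(self._session(1.0), cue_location_deg=0.0)
        assert len(out) == 60
        assert out["significant"].mean() <= 0.05

    def test_doubled_delay_all_significant(self):
        out = w.delay_elevation_test(self._session(2.0), cue_location_deg=0.0)
        assert out["significant"].all()

    def test_fdr_flags_monotone_in_q(self):
        ds = self._session(1.3, n_trials=20, seed=5)
        flags = {}
        for q in (0.01, 0.05, 0.2):
            flags[q] = w.delay_elevation_test(ds, 0.0, q=q)["significant"].to_numpy()
        assert set(np.where(flags[0.01])[0]) <= set(np.where(flags[0.05])[0])
        assert set(np.where(flags[0.05])[0]) <= set(np.where(flags[0.2])[0])

    def test_single_trial_errors(self):
        ds = make_dataset({(0, 0): [1.0]}, n_trials=1)
        with pytest.raises(ValueError):
            w.delay_elevation_test(ds, 0.0)


class TestValidation:
    def test_orphan_unit_rejected(self):
        ds = make_dataset({(0, 0): [1.0]}, n_trials=1)
        bad = w.SpikeDataset(
            pd.concat([ds.spikes, pd.DataFrame([{"unit_id": 99, "trial_id": 0, "time_s": 1.0}])]),
            ds.trials,
            ds.units,
        )
        with pytest.raises(ValueError, match="unit_id"):
            bad.validate()

    def test_out_of_range_time_rejected(self):
        ds = make_dataset({(0, 0): [1.0]}, n_trials=1)
        bad = w.SpikeDataset(
            pd.DataFrame([{"unit_id": 0, "trial_id": 0, "time_s": 9.0}]), ds.trials, ds.units
        )
        with pytest.raises(ValueError, match="bounds"):
            bad.validate()

    def test_group_to_canonical_120_variant(self):
        fine = np.arange(0.0, 360.0, 3.0)
        grouped = w.group_to_canonical(fine)
        assert set(grouped) == set(np.arange(0.0, 360.0, 45.0))
        assert w.group_to_canonical(np.array([23.0]))[0] == 45.0  # nearest canonical

    def test_epoch_mean_rates_counts(self):
        ds = make_dataset({(0, 0): [0.6, 1.0, 3.2], (0, 1): []}, n_trials=2)
        r = epoch_mean_rates(ds, (0.5, 3.5))
        np.testing.assert_allclose(r.to_numpy()[0], [1.0, 0.0])
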