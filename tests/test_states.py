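"""On/off-state labeling, debiased state tuning, cross-areal transfer, and
state counts by trial outcome."""

import numpy as np
import pandas as pd
import pytest

import wmstates as w
from wmstates.decoding import ConfidenceSeries
from wmstates.states import (
    _max_cluster_mass,
    _runs,
    label_states,
    state_count_table,
    state_counts_anova,
)


def series_from_z(z, centers=None, n_shuffles=50, null_sd=1.0, seed=0):
    """Confidence series whose z-scores equal ``z`` under its own null."""
    rng = np.random.default_rng(seed)
    n_trials, n_bins = z.shape
    if centers is None:
        centers = 0.55 + 0.05 * np.arange(n_bins)
    null = rng.normal(0.5, null_sd, size=(n_shuffles, n_trials, n_bins))
    s = ConfidenceSeries(
        conf=np.zeros_like(z, dtype=float),
        trial_ids=np.arange(n_trials),
        centers=centers,
        y=np.zeros(n_trials),
        pair=(0.0, 180.0),
        null_conf=null,
    )
    s.null_mean = null.mean(axis=0)
    s.null_sd = null.std(axis=0, ddof=0)
    s.conf = s.null_mean + z * s.null_sd
    return s


class TestClusterLabeling:
    def test_runs_helper(self):
        assert _runs(np.array([0, 1, 1, 0, 1], dtype=bool)) == [(1, 3), (4, 5)]
        assert _max_cluster_mass(np.array([0.0, 2.0, 2.0, 0.0]), 1.64) == 4.0

    def test_flat_zero_trace_is_all_off(self):
        z = np.zeros((3, 20))
        lab = label_states(series_from_z(z))
        assert all(len(iv) == 0 for iv in lab.on)
        assert all(iv == [(0, 20)] for iv in lab.off)

    def test_strong_run_labeled_on(self):
        z = np.zeros((1, 30))
        z[0, 10:20] = 3.0
        lab = label_states(series_from_z(z))
        on_bins = lab.on_mask[0]
        assert on_bins[10:20].all()
        assert not on_bins[:10].any()

    def test_short_sub_threshold_run_not_off(self):
        z = np.full((1, 10), 1.0)  # between thresholds: neither on nor off
        z[0, 4:6] = 0.0  # only 2 consecutive below 0.3
        lab = label_states(series_from_z(z))
        assert lab.off[0] == []

    def test_three_bin_run_is_off(self):
        z = np.full((1, 10), 1.0)
        z[0, 4:7] = 0.0
        lab = label_states(series_from_z(z))
        assert lab.off[0] == [(4, 7)]

    def test_cluster_mass_criterion_blocks_weak_clusters(self):
        # a run barely above threshold has small mass; against a null with
        # occasional large clusters it must not be labeled on
        rng = np.random.default_rng(1)
        z = np.full((1, 30), 0.5)
        z[0, 5:7] = 1.7  # mass ~3.4
        s = series_from_z(z, seed=2)
        # inject null traces containing strong clusters
        s.null_conf = s.null_mean[None] + rng.normal(0, 1, (50, 1, 30)) * s.null_sd[None] * 2.0
        lab = label_states(s)
        assert lab.on[0] == []

    def test_monotone_rescaling_invariance(self):
        # scaling conf and null by the same affine map leaves labels unchanged
        z = np.zeros((2, 25))
        z[0, 3:12] = 2.5
        z[1, 5:8] = -0.5
        s1 = series_from_z(z, seed=3)
        s2 = ConfidenceSeries(
            conf=2.0 * s1.conf + 1.0,
            trial_ids=s1.trial_ids,
            centers=s1.centers,
            y=s1.y,
            pair=s1.pair,
            null_conf=2.0 * s1.null_conf + 1.0,
        )
        s2.null_mean = s2.null_conf.mean(axis=0)
        s2.null_sd = s2.null_conf.std(axis=0, ddof=0)
        l1, l2 = label_states(s1), label_states(s2)
        assert l1.on == l2.on and l1.off == l2.off

    def test_pooled_sigma_fallback(self):
        z = np.zeros((1, 10))
        s = series_from_z(z)
        s.null_conf[:, 0, 3] = 0.5  # zero variance at one bin
        s.null_mean = s.null_conf.mean(axis=0)
        s.null_sd = s.null_conf.std(axis=0, ddof=0)
        lab = label_states(s)  # must not divide by zero
        assert np.isfinite(lab.z).all()

    def test_null_requirement(self):
        s = series_from_z(np.zeros((1, 5)))
        s.null_conf = None
        with pytest.raises(ValueError, match="null"):
            label_states(s)


@pytest.fixture(scope="module")
def gated_session_with_labels():
    """Shared-gating two-area session with PFC-derived state labels."""
    ds, truth = w.state_detection_session(seed=42, n_units_per_area=12,
                                          n_trials_per_location=25)
    pfc = ds.units.loc[ds.units.area == "PFC", "unit_id"].to_numpy()
    labels, series = w.label_states_all_pairs(
        ds, n_shuffles=50, rng=1, span=ds.epochs.delay, unit_ids=pfc
    )
    return ds, truth, labels, series


class TestStateRecovery:
    def test_on_labels_track_ground_truth(self, gated_session_with_labels):
        ds, truth, labels, _ = gated_session_with_labels
        centers = labels.centers
        tm = np.zeros_like(labels.on_mask)
        for i, tid in enumerate(labels.trial_ids):
            for a, b in truth["PFC"][int(tid)]:
                tm[i] |= (centers >= a) & (centers < b)
        on = labels.on_mask
        jac = (on & ~tm).sum() / (on | ~tm).sum()
        assert jac > 0.6

    def test_off_labels_fall_inside_truth(self, gated_session_with_labels):
        ds, truth, labels, _ = gated_session_with_labels
        centers = labels.centers
        tm = np.zeros_like(labels.on_mask)
        for i, tid in enumerate(labels.trial_ids):
            for a, b in truth["PFC"][int(tid)]:
                tm[i] |= (centers >= a) & (centers < b)
        off = labels.off_mask
        if off.any():
            precision = (off & tm).sum() / off.sum()
            assert precision > 0.7

    def test_tuning_depth_collapses_in_off_states(self, gated_session_with_labels):
        ds, truth, labels, _ = gated_session_with_labels
        pfc = ds.units.loc[ds.units.area == "PFC", "unit_id"].to_numpy()
        tun = w.state_tuning(ds, labels, n_shuffles=300, rng=2, unit_ids=pfc)
        assert tun.mean_depth_on > 0
        assert tun.depth_reduction_pct >= 50.0

    def test_cross_areal_transfer_detects_shared_gating(self, gated_session_with_labels):
        ds, truth, labels, _ = gated_session_with_labels
        ct = w.cross_areal_transfer(
            ds, labels, "PPC", n_shuffles=300, rng=3,
            min_source_units=12, n_source_units=12,
        )
        res = w.depth_reduction_test(ct)
        assert res["p"] < 0.05
        assert ct.rate_tests["on_vs_off"]["p"] < 0.05

    def test_source_unit_gate_enforced(self, gated_session_with_labels):
        ds, _, labels, _ = gated_session_with_labels
        with pytest.raises(ValueError, match="80"):
            w.cross_areal_transfer(ds, labels, "PPC", n_source_units=12)


class TestStateTuningProperties:
    def test_random_labels_debias_to_zero(self, tuned_session):
        rng = np.random.default_rng(4)
        n_trials = len(tuned_session.trials)
        centers = 0.55 + 0.05 * np.arange(59)
        on = rng.random((n_trials, 59)) < 0.3
        off = ~on & (rng.random((n_trials, 59)) < 0.3)
        labels = w.StateLabels(
            trial_ids=tuned_session.trial_ids,
            centers=centers,
            z=np.zeros((n_trials, 59)),
            on=[_mask_to_ivs(r) for r in on],
            off=[_mask_to_ivs(r) for r in off],
            crit_mass=np.zeros(n_trials),
        )
        tun = w.state_tuning(tuned_session, labels, n_shuffles=400, rng=5)
        # with labels independent of the rates, both debiased tuning
        # functions are flat at zero
        np.testing.assert_allclose(tun.on_curve, 0.0, atol=0.25)
        np.testing.assert_allclose(tun.off_curve, 0.0, atol=0.25)
        assert abs(tun.mean_depth_on) < 0.25
        assert abs(tun.mean_depth_off) < 0.25

    def test_identical_on_off_labels_give_identical_curves(self, tuned_session):
        rng = np.random.default_rng(6)
        n_trials = len(tuned_session.trials)
        mask = rng.random((n_trials, 59)) < 0.4
        ivs = [_mask_to_ivs(r) for r in mask]
        labels = w.StateLabels(
            trial_ids=tuned_session.trial_ids,
            centers=0.55 + 0.05 * np.arange(59),
            z=np.zeros((n_trials, 59)),
            on=ivs,
            off=[list(v) for v in ivs],
            crit_mass=np.zeros(n_trials),
        )
        tun = w.state_tuning(tuned_session, labels, n_shuffles=50, rng=7)
        np.testing.assert_allclose(tun.on_curve, tun.off_curve, atol=1e-10)
        assert tun.depth_reduction_pct == pytest.approx(0.0, abs=1e-8)


def _mask_to_ivs(row):
    out = []
    i = 0
    n = len(row)
    while i < n:
        if row[i]:
            j = i
            while j < n and row[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestSitePreference:
    def test_max_and_min_mean_confidence_picked(self):
        from wmstates.states import site_preference_from_confidence

        centers = 0.55 + 0.05 * np.arange(10)
        series = {}
        means = {0.0: 0.9, 180.0: 0.4, 90.0: 0.6, 270.0: 0.7}
        for pair in ((0.0, 180.0), (90.0, 270.0)):
            y = np.array([pair[0]] * 3 + [pair[1]] * 3)
            conf = np.stack([np.full(10, means[v]) for v in y])
            series[pair] = ConfidenceSeries(
                conf=conf, trial_ids=np.arange(6), centers=centers, y=y, pair=pair
            )
        pref, least = site_preference_from_confidence(series, delay=(0.5, 3.5))
        assert pref == 0.0 and least == 180.0

    def test_state_series_extraction(self):
        from wmstates.mixture import state_series_from_labels

        labels = w.StateLabels(
            trial_ids=np.arange(2),
            centers=0.55 + 0.05 * np.arange(6),
            z=np.zeros((2, 6)),
            on=[[(0, 2)], []],
            off=[[], [(3, 6)]],
            crit_mass=np.zeros(2),
        )
        on_series = state_series_from_labels(labels, "on")
        off_series = state_series_from_labels(labels, "off")
        np.testing.assert_array_equal(on_series[0], [1, 1, 0, 0, 0, 0])
        np.testing.assert_array_equal(off_series[1], [0, 0, 0, 1, 1, 1])


class TestStateCounts:
    def _labels(self, trial_ids, per_trial_states):
        n = len(trial_ids)
        return w.StateLabels(
            trial_ids=np.asarray(trial_ids),
            centers=0.55 + 0.05 * np.arange(59),
            z=np.zeros((n, 59)),
            on=[s.get("on", []) for s in per_trial_states],
            off=[s.get("off", []) for s in per_trial_states],
            crit_mass=np.zeros(n),
        )

    def test_any_overlap_counting(self, tuned_session):
        tids = tuned_session.trial_ids
        states = [{} for _ in tids]
        # bin 50 ends at 3.15 s (< 3.0 s window start); bin 55 straddles it
        states[0] = {"on": [(48, 52), (54, 59)], "off": [(0, 10)]}
        labels = self._labels(tids, states)
        locs = tuned_session.trials["cue_location_deg"].to_numpy()
        tab = state_count_table(
            tuned_session, labels, pref_cue=locs[0], least_cue=(locs[0] + 45) % 360
        )
        on_row = tab[(tab.preference == "preferred") & (tab.state == "on")]
        # only the straddling + final clusters overlap the last 0.5 s
        assert on_row["n_states"].iloc[0] * (locs == locs[0]).sum() == pytest.approx(2.0)

    def test_anova_detects_injected_interaction(self):
        rng = np.random.default_rng(8)
        tables = []
        for _ in range(6):
            rows = []
            for corr in (True, False):
                for pref in ("preferred", "least"):
                    for st in ("on", "off"):
                        base = 1.0
                        if st == "on" and ((corr and pref == "preferred") or
                                           (not corr and pref == "least")):
                            base = 2.5
                        if st == "off" and ((corr and pref == "least") or
                                            (not corr and pref == "preferred")):
                            base = 2.5
                        rows.append((corr, pref, st, base + rng.normal(0, 0.1)))
            tables.append(pd.DataFrame(rows, columns=["correct", "preference", "state", "n_states"]))
        anova = state_counts_anova(tables)
        p3 = anova.loc["C(correct):C(preference):C(state)", "PR(>F)"]
        assert p3 < 0.01

    def test_anova_null_interaction_not_significant(self):
        rng = np.random.default_rng(9)
        tables = []
        for _ in range(6):
            rows = [
                (corr, pref, st, 1.0 + rng.normal(0, 0.2))
                for corr in (True, False)
                for pref in ("preferred", "least")
                for st in ("on", "off")
            ]
            tables.append(pd.DataFrame(rows, columns=["correct", "preference", "state", "n_states"]))
        anova = state_counts_anova(tables)
        assert anova.loc["C(correct):C(preference):C(state)", "PR(>F)"] > 0.05

    def test_missing_outcome_level_skips_anova(self):
        df = pd.DataFrame(
            [(True, "preferred", "on", 1.0), (True, "least", "off", 1.0)],
            columns=["correct", "preference", "state", "n_states"],
        )
        assert state_counts_anova([df]) is None
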