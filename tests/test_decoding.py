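"""Decoding: z-scoring, engine agreement, LOO calibration and leakage,
softmax posteriors, pseudo-population construction."""

import numpy as np
import pytest

import wmstates as w
from wmstates._lasso import append_intercept, lasso_logistic_batch, loo_margins
from wmstates.decoding import (
    DecoderConfig,
    OneVsAllLasso,
    _confidence_sets,
    _make_clf,
    decode_from_features,
    softmax_posterior,
)


class TestZscore:
    def test_columns_standardized(self):
        rng = np.random.default_rng(0)
        r = rng.gamma(2.0, 2.0, size=(4, 30, 5))
        z, mu, sd = w.zscore_rates(r)
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=1), 1.0, atol=1e-12)

    def test_constant_feature_zeroed(self):
        r = np.ones((2, 10, 3))
        z, _, _ = w.zscore_rates(r)
        assert (z == 0).all()

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        r = rng.normal(10, 2, size=(3, 20, 4))
        z, mu, sd = w.zscore_rates(r)
        np.testing.assert_allclose(z * sd + mu, r, atol=1e-10)

    def test_single_trial_errors(self):
        with pytest.raises(ValueError):
            w.zscore_rates(np.ones((2, 1, 3)))


class TestSolverEngines:
    def test_batch_matches_liblinear_margins(self):
        rng = np.random.default_rng(2)
        n, f = 24, 30
        cfg = DecoderConfig()
        C = 1.0 / ((n - 1) * cfg.lam)
        for k in range(5):
            X = rng.normal(size=(n, f))
            y = np.where(rng.random(n) < 0.5, -1, 1)
            y[:2], y[-2:] = -1, 1
            if k % 2:
                X[:, :4] += y[:, None]  # separable-ish signal
            Xi = append_intercept(X[None])
            Wb = lasso_logistic_batch(Xi, y[None, :, None].astype(float), C)
            m_batch = Xi[0] @ Wb[0, :, 0]
            clf = _make_clf(cfg, n)
            clf.C = C
            clf.tol = 1e-8
            clf.fit(X, y)
            np.testing.assert_allclose(m_batch, clf.decision_function(X), atol=2e-3)

    def test_engines_agree_on_decoded_labels(self, tuned_session):
        sub = tuned_session.subset_trials(tuned_session.trial_ids[:40]).subset_units(
            tuned_session.unit_ids[:12]
        )
        locs = w.group_to_canonical(sub.trials["cue_location_deg"].to_numpy())
        keep = sub.trial_ids[np.isin(locs, [0.0, 180.0])]
        sub = sub.subset_trials(keep)
        res_b = w.binary_diametric_decode(sub, DecoderConfig(engine="batch"), span=(1.0, 1.6))
        res_l = w.binary_diametric_decode(sub, DecoderConfig(engine="liblinear"), span=(1.0, 1.6))
        np.testing.assert_allclose(res_b.conf, res_l.conf, atol=2e-3)

    def test_cross_temporal_diagonal_consistency(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 6, 5))
        y = np.tile([0.0, 180.0], 8)
        X[:, :3, :] += np.where(y == 0.0, 1.0, -1.0)[:, None, None]
        cfg = DecoderConfig()
        c_diag, p_diag = decode_from_features(X, y, cfg, diagonal_only=True)
        c_full, p_full = decode_from_features(X, y, cfg, diagonal_only=False)
        np.testing.assert_array_equal(c_diag, np.einsum("ibb->ib", c_full.astype(int)) > 0)

    def test_loo_is_deterministic_and_leak_free(self):
        # recomputing a fold from scratch reproduces the cached result exactly
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 5, 3))
        y = np.tile([0.0, 180.0], 6)
        cfg = DecoderConfig()
        c1, _ = decode_from_features(X, y, cfg, diagonal_only=True)
        c2, _ = decode_from_features(X, y, cfg, diagonal_only=True)
        np.testing.assert_array_equal(c1, c2)


class TestSoftmax:
    def test_symmetric_scores(self):
        np.testing.assert_allclose(softmax_posterior([1.3, 1.3]), [0.5, 0.5])

    def test_closed_form(self):
        np.testing.assert_allclose(
            softmax_posterior([np.log(3.0), 0.0]), [0.75, 0.25], atol=1e-12
        )


class TestChanceCalibration:
    def test_eight_way_diagonal_at_chance(self, untuned_session):
        res = w.crosstemporal_decode(
            untuned_session, DecoderConfig(step=0.25), span=(0.5, 3.5), diagonal_only=True
        )
        # trials are the independent units (each is tested at every bin);
        # leave-one-out is slightly pessimistic, never optimistic
        n_trials = len(untuned_session.trials)
        se = np.sqrt(0.125 * 0.875 / n_trials)
        assert abs(res.accuracy.mean() - 0.125) < 3 * se

    def test_binary_confidence_at_chance(self, untuned_session):
        s = w.binary_diametric_decode(untuned_session, span=(0.5, 3.5))
        trial_means = s.conf.mean(axis=1)  # trials are the independent units
        se = trial_means.std(ddof=1) / np.sqrt(len(trial_means))
        assert abs(trial_means.mean() - 0.5) < 3 * se

    def test_fold_safe_zscoring_unbiased_at_small_n(self):
        # full-matrix z-scoring constrains features to sum to zero across
        # trials, which leaks the held-out label at small n; the fold-safe
        # option removes that bias
        ds = w.simulate_tuned_session(
            w.SimConfig(n_neurons=20, n_trials_per_location=8,
                        tuning=w.TuningSpec(gain=1.0), seed=55)
        )
        cfg = DecoderConfig(zscore_full=False, engine="liblinear")
        s = w.binary_diametric_decode(ds, cfg, span=(1.0, 2.0))
        tm = s.conf.mean(axis=1)
        assert abs(tm.mean() - 0.5) < max(3 * tm.std(ddof=1) / np.sqrt(len(tm)), 0.03)

    def test_label_permutation_calibration_binary(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(20, 8, 4))
        y = np.tile([0.0, 180.0], 10)
        conf = _confidence_sets(
            X, np.stack([y[rng.permutation(20)] for _ in range(10)]), y, DecoderConfig()
        )
        assert abs(conf.mean() - 0.5) < 0.05


class TestSeparableAndGeneralization:
    def test_separable_diagonal_accuracy_one(self):
        rng = np.random.default_rng(6)
        y = np.repeat(np.arange(0.0, 360.0, 45.0), 3)
        X = rng.normal(scale=0.05, size=(24, 16, 3))
        for i, ang in enumerate(np.arange(0.0, 360.0, 45.0)):
            X[y == ang, 2 * i : 2 * i + 2, :] += 3.0
        correct, _ = decode_from_features(X, y, DecoderConfig(), diagonal_only=True)
        assert correct.mean() == 1.0

    def test_cue_to_delay_generalization(self, tuned_session):
        # stable tuning across epochs: training on cue bins decodes delay bins
        res = w.crosstemporal_decode(
            tuned_session, DecoderConfig(step=0.5), span=(0.0, 3.5)
        )
        cue_train = res.centers < 0.5
        delay_test = res.centers >= 0.5
        gen = res.accuracy[np.ix_(cue_train, delay_test)].mean()
        assert gen > 0.125 + 0.1


class TestPseudoPopulations:
    def test_marginals_exactly_preserved(self, tuned_session):
        binned = w.bin_rates(tuned_session, width=0.1, step=0.5, span=(0.5, 3.5))
        locs = tuned_session.trials["cue_location_deg"].to_numpy()
        ps = w.build_pseudopopulations(binned, locs, n=5, rng=0)
        for k in range(5):
            r = ps.rates(k)
            for ang in np.unique(locs):
                m = locs == ang
                np.testing.assert_allclose(
                    np.sort(r[:, m, :], axis=1),
                    np.sort(binned.rates[:, m, :], axis=1),
                    atol=1e-12,
                )

    def test_single_neuron_accuracy_distribution_unchanged(self):
        rng = np.random.default_rng(8)
        ds = w.simulate_tuned_session(
            w.SimConfig(n_neurons=1, n_trials_per_location=4, seed=13,
                        tuning=w.TuningSpec(gain=4.0))
        )
        comp = w.pseudo_population_decode(
            ds, DecoderConfig(step=1.0), n_pseudo=8, span=(1.0, 3.0), rng=rng
        )
        # permuting a single neuron's trials within location relabels identical
        # data: every pseudo accuracy equals the simultaneous accuracy
        assert np.allclose(comp.pseudo_accuracy.mean(axis=0), comp.simul_accuracy, atol=0.1)

    def test_identical_series_gives_zero_epoch_diff(self):
        acc = np.full(10, 0.5)
        pseudo = np.tile(acc, (20, 1))
        comp = w.compare_simul_vs_pseudo(
            acc, pseudo, np.linspace(0.6, 3.4, 10), w.EpochSpec()
        )
        assert comp.epoch_diff["delay"] == 0.0
        assert comp.wilcoxon_p == 1.0
        assert not comp.significant_bonferroni.any()
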