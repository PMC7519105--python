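import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from tactsurf.friction import trial_friction
from tactsurf.observer import (
    FRICTION_INTERCEPT,
    FRICTION_SLOPE,
    DecisionSet,
    ObserverConfig,
    TripletDecision,
    enumerate_triplets,
    friction_line,
    planted_dissimilarity,
    preset_config,
    simulate_decision,
    simulate_experiment,
    simulate_force_trace,
    simulate_friction,
    simulate_sliding_with_friction,
)
from tactsurf.metric import dissimilarity_table, pair_vector


class TestEnumerateTriplets:
    def test_nine_samples_give_252(self):
        trips = enumerate_triplets([f"s{i}" for i in range(9)])
        assert len(trips) == 252

    def test_three_samples_give_three(self):
        trips = enumerate_triplets(["a", "b", "c"])
        assert len(trips) == 3
        assert len(set(trips)) == 3

    def test_pairs_are_unordered(self):
        trips = enumerate_triplets(["a", "b", "c", "d"])
        assert len(set(trips)) == len(trips)  # frozenset pairs deduplicate

    def test_too_few_ids_rejected(self):
        with pytest.raises(ValueError):
            enumerate_triplets(["a", "b"])


@pytest.fixture()
def simple_D():
    ids = ["a", "b", "c"]
    D = pd.DataFrame(0.0, index=ids, columns=ids)
    D.loc["b", "a"] = D.loc["a", "b"] = 1.0
    D.loc["c", "a"] = D.loc["a", "c"] = 3.0
    D.loc["b", "c"] = D.loc["c", "b"] = 2.0
    return D


class TestSimulateDecision:
    def test_zero_noise_is_argmin(self, simple_D):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = simulate_decision(("a", "b", "c"), simple_D, 0.0, 0.0, rng)
            assert d.choice == "left"  # D(b,a)=1 < D(c,a)=3

    def test_equal_distances_are_fair_coin(self):
        ids = ["a", "b", "c"]
        D = pd.DataFrame(1.0, index=ids, columns=ids)
        np.fill_diagonal(D.values, 0.0)
        rng = np.random.default_rng(1)
        lefts = sum(
            simulate_decision(("a", "b", "c"), D, 1.0, 0.0, rng).choice == "left"
            for _ in range(4000)
        )
        assert abs(lefts / 4000 - 0.5) < 0.03

    def test_logistic_choice_probability(self, simple_D):
        # Delta D = D(c,a) - D(b,a) = 2, sigma = 2 -> P(left) = logistic(1)
        rng = np.random.default_rng(2)
        n = 10000
        lefts = sum(
            simulate_decision(("a", "b", "c"), simple_D, 2.0, 0.0, rng).choice == "left"
            for _ in range(n)
        )
        assert lefts / n == pytest.approx(expit(1.0), abs=0.015)

    def test_full_lapse_is_uniform_even_when_obvious(self, simple_D):
        rng = np.random.default_rng(3)
        lefts = sum(
            simulate_decision(("a", "b", "c"), simple_D, 0.0, 1.0, rng).choice == "left"
            for _ in range(4000)
        )
        assert abs(lefts / 4000 - 0.5) < 0.03


class TestSimulateExperiment:
    def test_preset_sizes(self, summary_small):
        for modality, n_expected in [("visual", 750), ("tapping", 280), ("sliding", 364)]:
            cfg = preset_config(modality, seed=0)
            dec = simulate_experiment(cfg, summary_small)
            assert len(dec) == n_expected

    def test_determinism(self, summary_small):
        cfg = preset_config("tapping", seed=7)
        a = simulate_experiment(cfg, summary_small)
        b = simulate_experiment(cfg, summary_small)
        assert a.to_frame().equals(b.to_frame())

    def test_oversubscription_rejected(self, summary_small):
        cfg = preset_config("tapping", seed=0, triplets_per_participant=300)
        with pytest.raises(ValueError):
            simulate_experiment(cfg, summary_small)

    def test_planted_table_matches_metric_module(self, summary_small):
        cfg = preset_config("sliding", seed=0)
        D = planted_dissimilarity(cfg, summary_small)
        expected = dissimilarity_table(summary_small, alpha=cfg.alpha_true)
        pd.testing.assert_frame_equal(D, expected)

    def test_participants_exchangeable(self, summary_small):
        cfg = preset_config("visual", seed=11, noise_scale=1.0)
        dec = simulate_experiment(cfg, summary_small)
        frame = dec.to_frame()
        counts = frame.groupby("participant")["choice"].apply(lambda c: (c == "left").sum())
        n = frame.groupby("participant").size()
        # no participant's left-rate is implausible under a shared binomial
        rates = counts / n
        assert rates.std() < 0.2

    def test_agreement_with_planted_metric_monotone_in_noise(self, summary_small):
        fracs = []
        for noise in (1e-6, 1.0, 50.0):
            cfg = preset_config("visual", seed=5, noise_scale=noise)
            dec = simulate_experiment(cfg, summary_small)
            D = planted_dissimilarity(cfg, summary_small)
            agree = n_scored = 0
            for d in dec:
                dl, dr = D.loc[d.left_id, d.ref_id], D.loc[d.right_id, d.ref_id]
                if abs(dl - dr) < 1e-9:  # (near-)ties are coin flips at any noise level
                    continue
                n_scored += 1
                agree += d.choice == ("left" if dl < dr else "right")
            fracs.append(agree / n_scored)
        assert fracs[0] > 0.99
        assert fracs[0] > fracs[1] > fracs[2]
        assert abs(fracs[2] - 0.5) < 0.1


class TestSimulateFriction:
    def test_planted_line_anchors(self):
        assert friction_line(1.0) == pytest.approx(0.35)
        assert friction_line(3.5) == pytest.approx(0.45)
        assert FRICTION_INTERCEPT + FRICTION_SLOPE * 2.25 == pytest.approx(0.40)

    def test_zero_noise_reproduces_line(self, summary_small):
        cfg = preset_config("sliding", seed=0, friction_participant_sd=0.0,
                            friction_trial_sd=0.0)
        rec = simulate_friction(cfg, summary_small, n_trials_per_participant=2)
        merged = rec.groupby("sample")["mu"].mean()
        for sid, mu in merged.items():
            assert mu == pytest.approx(friction_line(summary_small.loc[sid, "kappa"]))

    def test_noisy_mean_converges_to_line(self, summary_small):
        cfg = preset_config("sliding", seed=1, n_participants=100)
        rec = simulate_friction(cfg, summary_small, n_trials_per_participant=10)
        sid = summary_small.index[0]
        mu_bar = rec[rec["sample"] == sid]["mu"].mean()
        expected = friction_line(summary_small.loc[sid, "kappa"])
        assert mu_bar == pytest.approx(expected, abs=0.02)

    def test_sliding_with_friction_returns_aligned_records(self, summary_small):
        cfg = preset_config("sliding", seed=2)
        dec, rec = simulate_sliding_with_friction(cfg, summary_small)
        assert len(dec) == 13 * 28
        assert len(rec) == 3 * len(dec)
        # every decision's three samples have a record at that trial
        first = next(iter(dec))
        sub = rec[(rec.participant == 0) & (rec.trial == 0)]
        assert set(sub["sample"]) == {first.ref_id, first.left_id, first.right_id}


class TestForceTrace:
    def test_zero_friction_gives_zero_lateral(self):
        tr = simulate_force_trace(0.0, 2.0)
        assert np.all(tr.fx == 0.0) and np.all(tr.fy == 0.0)

    def test_noise_free_trace_recovers_mu(self):
        tr = simulate_force_trace(0.42, 1.5, motion_period=1.3)
        assert trial_friction(tr) == pytest.approx(0.42, rel=1e-12)

    def test_noisy_traces_recover_mu_on_average(self):
        rng = np.random.default_rng(0)
        mus = [
            trial_friction(simulate_force_trace(0.42, 1.5, noise=0.01, rng=rng))
            for _ in range(200)
        ]
        assert np.mean(mus) == pytest.approx(0.42, rel=0.01)

    def test_nonpositive_load_rejected(self):
        with pytest.raises(ValueError):
            simulate_force_trace(0.3, 0.0)


class TestDecisionSetRoundTrip:
    def test_frame_round_trip(self, summary_small):
        cfg = preset_config("tapping", seed=3)
        dec = simulate_experiment(cfg, summary_small)
        again = DecisionSet.from_frame(dec.to_frame())
        assert again.decisions == dec.decisions
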