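"""Generative cohort: random effects, factorial balance, forward model."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_config, noise_free_config
from hypoalgesia.performance_sdt import score_stream
from hypoalgesia.synthetic_cohort import (
    GenerativeConfig,
    default_psi,
    generate_choice_set,
    generate_participants,
    generate_response_stream,
    generate_thermal_table,
    generate_trials,
)


class TestGenerateParticipants:
    def test_cohort_size_and_ids(self):
        profs = generate_participants(make_config(n_participants=57))
        assert len(profs) == 57
        assert [p.participant_id for p in profs] == list(range(1, 58))

    def test_zero_covariance_gives_exactly_zero_effects(self):
        profs = generate_participants(make_config(psi=np.zeros((5, 5))))
        for p in profs:
            assert np.all(p.random_effects == 0.0)

    def test_sample_covariance_approaches_psi(self):
        psi = default_psi(sd_a=0.3, sd_b=0.3, cov_ab=0.05)
        cfg = make_config(n_participants=10_000, psi=psi, seed=42)
        re = np.array([p.random_effects for p in generate_participants(cfg)])
        cov_ab = np.cov(re[:, 0], re[:, 1])[0, 1]
        assert abs(cov_ab - 0.05) < 0.005

    def test_non_psd_psi_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = bad[1, 0] = 2.0  # |cov| > sd_a*sd_b
        with pytest.raises(ValueError, match="semi-definite"):
            make_config(psi=bad)

    def test_profile_ranges(self):
        for p in generate_participants(make_config(n_participants=50)):
            assert p.low_temp < p.high_temp
            assert 0.5 <= p.reward_amount <= 3.0


class TestGenerateTrials:
    def test_noise_free_degenerate_model(self):
        cfg = noise_free_config(
            alpha_M=0.3, a=0, a_rew=0, rew_M=0, gamma1_M=0, gamma2_M=0,
            alpha_Y=0.4, b=0, b_rew=0, cprime=0, cprime_rew=0, rew_Y=0,
            gamma1_Y=0, gamma2_Y=0,
        )
        trials = generate_trials(generate_participants(cfg), cfg)
        assert np.allclose(trials["performance"], 0.3)
        high = trials[trials["temperature"] == "HIGH"]
        assert np.allclose(high["rating"], 40.0)

    def test_task_effect_is_exact_without_noise(self):
        cfg = noise_free_config(
            alpha_M=0.5, a=-0.13, a_rew=0, rew_M=0, gamma1_M=0, gamma2_M=0,
        )
        trials = generate_trials(generate_participants(cfg), cfg)
        m2 = trials.loc[trials["task"] == "2back", "performance"].mean()
        m1 = trials.loc[trials["task"] == "LR", "performance"].mean()
        assert m2 - m1 == pytest.approx(-0.13, abs=1e-12)

    def test_balanced_factorial_cells(self):
        cfg = make_config(n_participants=5, n_trials=64)
        trials = generate_trials(generate_participants(cfg), cfg)
        counts = trials.groupby(
            ["participant_id", "task", "reward", "temperature"]
        ).size()
        assert (counts == 8).all()
        for col in ["task", "reward", "temperature"]:
            assert trials[col].value_counts(normalize=True).max() == 0.5

    def test_temperature_runs_bounded(self):
        cfg = make_config(n_participants=8, n_trials=64)
        trials = generate_trials(generate_participants(cfg), cfg)
        for _, grp in trials.groupby("participant_id"):
            temps = grp.sort_values("trial")["temperature"].to_numpy()
            run = 1
            for i in range(1, len(temps)):
                run = run + 1 if temps[i] == temps[i - 1] else 1
                assert run <= 3

    def test_unbalanced_trial_count_rejected(self):
        cfg = make_config(n_trials=20)
        with pytest.raises(ValueError, match="divisible by 8"):
            generate_trials(generate_participants(cfg), cfg)

    def test_seeded_determinism_bytes(self):
        cfg = make_config(n_participants=4)
        t1 = generate_trials(generate_participants(cfg), cfg)
        t2 = generate_trials(generate_participants(cfg), cfg)
        assert t1.to_csv(index=False) == t2.to_csv(index=False)


class TestResponseStream:
    def test_stimulus_count_follows_timeline(self, rng):
        # 250 fixation + 500 letter + 1250 ISI = 2000 ms -> 10 in 20 s
        s = generate_response_stream(2.0, 1250.0, 20.0, rng=rng)
        assert len(s) == 10

    def test_isi_bounds_enforced(self, rng):
        for isi in (10.0, 3000.0):
            with pytest.raises(ValueError):
                generate_response_stream(2.0, isi, rng=rng)

    def test_infinite_sensitivity_observer_is_perfect(self, rng):
        s = generate_response_stream(np.inf, 500.0, rng=rng)
        sc = score_stream(s)
        assert sc.hits == sc.n_targets and sc.false_alarms == 0

    def test_zero_sensitivity_observer_guesses(self, rng):
        hits = targets = fas = nontargets = 0
        for _ in range(300):
            sc = score_stream(generate_response_stream(0.0, 500.0, rng=rng))
            hits, targets = hits + sc.hits, targets + sc.n_targets
            fas, nontargets = fas + sc.false_alarms, nontargets + sc.n_nontargets
        assert abs(hits / targets - fas / nontargets) < 0.05

    def test_first_two_positions_never_targets(self, rng):
        for _ in range(20):
            s = generate_response_stream(1.0, 300.0, rng=rng)
            assert not s.is_target[:2].any()


class TestChoiceAndThermalTables:
    def test_choice_set_has_26_offers(self, rng):
        prof = generate_participants(make_config())[0]
        tab = generate_choice_set(prof, rng=rng)
        assert len(tab) == 26
        assert tab["offer"].min() == 0.0 and tab["offer"].max() == 3.0

    def test_steep_value_function_is_step(self, rng):
        prof = generate_participants(make_config())[0]
        prof.money_logit_slope = 1e8
        prof.money_logit_intercept = -1.5e8  # threshold at $1.50
        tab = generate_choice_set(prof, rng=rng)
        assert (tab.loc[tab["offer"] > 1.51, "accept"] == 1).all()
        assert (tab.loc[tab["offer"] < 1.49, "accept"] == 0).all()

    def test_choices_reproducible_under_seed(self):
        prof = generate_participants(make_config())[0]
        a = generate_choice_set(prof, rng=np.random.default_rng(5))
        b = generate_choice_set(prof, rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_offers_outside_range_rejected(self, rng):
        prof = generate_participants(make_config())[0]
        with pytest.raises(ValueError):
            generate_choice_set(prof, offers=[1.0, 3.5], rng=rng)

    def test_thermal_table_shape(self, rng):
        prof = generate_participants(make_config())[0]
        tab = generate_thermal_table(prof, rng=rng)
        assert len(tab) == 28  # 7 temperatures x 4 sites
        assert tab["rating"].between(0, 100).all()


def test_config_yaml_round_trip():
    cfg = make_config(a=-0.2, sigma_Y=0.25)
    back = GenerativeConfig.from_yaml(cfg.to_yaml())
    assert back.a == cfg.a and back.sigma_Y == cfg.sigma_Y
    assert np.array_equal(back.psi, cfg.psi)
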