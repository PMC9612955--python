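"""Stacked mediation model: design construction, fitting, indirect effects."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_config, noise_free_config
from hypoalgesia._lmm import LMMFit
from hypoalgesia.ml_mediation import (
    IndirectEstimate,
    MediationFit,
    bootstrap_ci,
    fit_mediation,
    fit_total_effect,
    indirect_effects,
    stack_rows,
    unstack_rows,
)
from hypoalgesia.preprocess import filter_and_derive, select_analysis_set
from hypoalgesia.synthetic_cohort import generate_participants, generate_trials


def _pain_table(cfg):
    trials = generate_trials(generate_participants(cfg), cfg)
    clean, _ = filter_and_derive(trials)
    return select_analysis_set(clean, "PAIN")


class TestStacking:
    def test_two_rows_per_trial(self, small_pain_table):
        sd = stack_rows(small_pain_table)
        assert sd.n_rows == 2 * len(small_pain_table)
        assert sd.n_rows == 2 * sd.n_trials

    def test_selector_sparsity(self, small_pain_table):
        sd = stack_rows(small_pain_table)
        med = sd.frame[sd.frame["row_type"] == 0]
        out = sd.frame[sd.frame["row_type"] == 1]
        for col in ["int_Y", "b", "rew_Y", "b_rew", "cprime", "cprime_rew", "trial_Y", "logtrial_Y"]:
            assert (med[col] == 0).all()
        for col in ["int_M", "a", "rew_M", "a_rew", "trial_M", "logtrial_M"]:
            assert (out[col] == 0).all()

    def test_constant_task_zeroes_task_columns(self, small_pain_table):
        tab = small_pain_table.copy()
        tab["task"] = "LR"
        sd = stack_rows(tab)
        assert (sd.frame["a"] == 0).all()
        assert (sd.frame["cprime"] == 0).all()

    def test_round_trip_unstack(self, small_pain_table):
        sd = stack_rows(small_pain_table)
        back = unstack_rows(sd)
        orig = (
            small_pain_table[["participant_id", "task", "reward", "performance", "rating01", "t"]]
            .sort_values(["participant_id", "t"])
            .reset_index(drop=True)
        )
        back = back.sort_values(["participant_id", "t"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(
            back[orig.columns.tolist()].astype({"reward": int}),
            orig.astype({"reward": int}),
            check_dtype=False,
        )

    def test_missing_mediator_rows_dropped(self, small_pain_table):
        tab = small_pain_table.copy()
        tab.iloc[0, tab.columns.get_loc("performance")] = np.nan
        with pytest.warns(UserWarning, match="dropping 1 trial"):
            sd = stack_rows(tab)
        assert sd.n_dropped == 1
        assert sd.n_rows == 2 * (len(tab) - 1)


def _stub_fit(coefs, sigma_ab=None):
    names = list(coefs)
    u_names = ["a", "b"] if sigma_ab is not None else ["cprime"]
    psi = np.zeros((len(u_names), len(u_names)))
    if sigma_ab is not None:
        psi[0, 1] = psi[1, 0] = sigma_ab
    lmm = LMMFit(
        beta=np.array(list(coefs.values())), se=np.ones(len(names)),
        tvals=np.zeros(len(names)), pvals=np.ones(len(names)), df_resid=10,
        psi=psi, sigma2=np.array([0.1, 0.1]), lam=psi, theta=np.zeros(1),
        reml_neg2=0.0, converged=True, grad_inf=0.0, n_iter=1,
        x_names=names, u_names=u_names,
    )
    return MediationFit(lmm=lmm, random_set=tuple(u_names), psi_structure="unstructured")


class TestIndirectEffects:
    def test_product_plus_covariance(self):
        fit = _stub_fit({"a": -0.13, "b": -0.16}, sigma_ab=0.0)
        ind = IndirectEstimate.from_fit(fit)
        assert ind.ab == pytest.approx(0.0208, abs=1e-12)

    def test_pure_covariance_case(self):
        fit = _stub_fit({"a": 0.0, "b": 0.0}, sigma_ab=0.05)
        assert IndirectEstimate.from_fit(fit).ab == pytest.approx(0.05)

    def test_no_moderation_means_equal_conditional_effects(self):
        fit = _stub_fit({"a": -0.1, "b": -0.2}, sigma_ab=0.01)
        ind = IndirectEstimate.from_fit(fit)
        assert ind.ie0 == ind.ie1 and ind.ie_diff == 0.0

    def test_moderated_conditional_effects(self):
        fit = _stub_fit({"a": -0.13, "b": -0.16, "a_rew": 0.04, "b_rew": 0.09}, sigma_ab=0.0)
        ind = IndirectEstimate.from_fit(fit)
        assert ind.ie0 == pytest.approx((-0.13) * (-0.16))
        assert ind.ie1 == pytest.approx((-0.09) * (-0.07))
        assert ind.ie_diff == pytest.approx(ind.ie1 - ind.ie0)

    def test_sigma_ab_zero_when_a_or_b_not_random(self):
        fit = _stub_fit({"a": 0.5, "b": 0.5})
        assert fit.sigma_ab == 0.0


class TestFitMediation:
    def test_ols_oracle_without_random_effects(self):
        # with Psi pinned at zero the stacked GLS must reduce to the
        # two-equation OLS closed form (predictors are disjoint by block)
        cfg = make_config(
            n_participants=12, n_trials=32, psi=np.zeros((5, 5)),
            sigma_M=0.05, sigma_Y=0.05, clip=False, p_painful_high=1.0,
            fast_guess_rate=0.0, seed=31,
        )
        pain = _pain_table(cfg)
        sd = stack_rows(pain)
        fit = fit_mediation(sd, psi_structure="zero")
        frame = sd.frame
        for row_type, terms in ((0, ["int_M", "a", "rew_M", "a_rew", "trial_M", "logtrial_M"]),
                                (1, ["int_Y", "b", "rew_Y", "b_rew", "cprime", "cprime_rew",
                                     "trial_Y", "logtrial_Y"])):
            sub = frame[frame["row_type"] == row_type]
            Xo = sub[terms].to_numpy(float)
            beta_ols, *_ = np.linalg.lstsq(Xo, sub["z"].to_numpy(float), rcond=None)
            mine = np.array([fit.coef(t) for t in terms])
            assert np.max(np.abs(mine - beta_ols)) < 1e-4

    def test_diagonal_psi_reduces_ab_to_product(self, small_pain_table):
        sd = stack_rows(small_pain_table)
        fit = fit_mediation(sd, random_set=("a", "b", "cprime"), psi_structure="diagonal")
        ind = indirect_effects(fit)
        assert fit.sigma_ab == 0.0
        assert ind.ab == pytest.approx(fit.coef("a") * fit.coef("b"), abs=1e-15)

    def test_participant_relabelling_invariance(self, small_pain_table):
        f1 = fit_mediation(stack_rows(small_pain_table), random_set=("a", "b"))
        relab = small_pain_table.copy()
        relab["participant_id"] = 1000 - relab["participant_id"]
        f2 = fit_mediation(stack_rows(relab), random_set=("a", "b"))
        assert np.allclose(f1.lmm.beta, f2.lmm.beta, atol=1e-6)

    def test_requires_enough_participants(self):
        cfg = make_config(n_participants=5)
        with pytest.raises(ValueError, match="participants"):
            fit_mediation(stack_rows(_pain_table(cfg)))

    def test_empty_random_set_rejected(self, small_pain_table):
        with pytest.raises(ValueError, match="non-empty"):
            fit_mediation(stack_rows(small_pain_table), random_set=())

    def test_out_of_range_response_warns(self, small_pain_table):
        tab = small_pain_table.copy()
        tab["rating01"] = tab["rating01"] + 2.0
        with pytest.warns(UserWarning, match="outside"):
            fit_mediation(stack_rows(tab), random_set=("a",))


class TestBootstrap:
    def test_seed_determinism(self, small_pain_table):
        sd = stack_rows(small_pain_table)
        r1 = bootstrap_ci(sd, B=100, seed=9, random_set=("a", "b"))
        r2 = bootstrap_ci(sd, B=100, seed=9, random_set=("a", "b"))
        assert r1.ci == r2.ci

    def test_tiny_noise_gives_tight_intervals(self):
        cfg = noise_free_config(
            n_participants=10, n_trials=16, sigma_M=0.01, sigma_Y=0.01, seed=17
        )
        sd = stack_rows(_pain_table(cfg))
        res = bootstrap_ci(sd, B=100, seed=1, random_set=("a",))
        lo, hi = res.ci["a"]
        assert hi - lo < 0.05

    def test_small_b_rejected(self, small_pain_table):
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_ci(stack_rows(small_pain_table), B=10, seed=0)


class TestTotalEffect:
    def test_null_task_effect_recovered(self):
        cfg = make_config(
            n_participants=20, n_trials=32, a=0.0, a_rew=0.0, cprime=0.0,
            cprime_rew=0.0, b=0.0, b_rew=0.0, clip=False, p_painful_high=1.0,
            fast_guess_rate=0.0, seed=5,
        )
        tot = fit_total_effect(_pain_table(cfg))
        i = tot.lmm.x_names.index("c")
        assert abs(tot.c) < 2.5 * tot.lmm.se[i]

    def test_constant_task_is_inestimable(self, small_pain_table):
        tab = small_pain_table.copy()
        tab["task"] = "2back"
        with pytest.raises(ValueError, match="task is constant"):
            fit_total_effect(tab)
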