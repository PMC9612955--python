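"""Generative model for a synthetic motivated-distraction cohort.

The study this package analyses collected, per participant: a thermal
calibration (28 rated heat stimulations), a 15-trial ISI staircase on the
2-back task, 26 pain-for-money choices, and 64 main trials in a 2 (task: easy
left-right arrows vs demanding 2-back) x 2 (reward: $0 vs a calibrated
amount) x 2 (temperature: warm vs painful) within-subjects factorial.  No raw
data are distributed with the study, so this module generates all of those
inputs with the statistical structure the downstream analyses assume.

Trial-level performance M (the A statistic, 0-1) and pain V (rating/100) are
produced by running the moderated 1-1-1 mediation model forward, with X the
task contrast (LR=0, 2-back=1), W the reward contrast (0/1), t the trial
number, and participant-level random effects (a_j, b_j, c'_j, intercepts):

    M = alpha_M + (a + a_rew*W + a_j)*X + rew_M*W + g1M*t + g2M*log t
        + int_Mj + e_M,            e_M ~ N(0, sigma_M^2)
    V = alpha_Y + int_Yj + (b + b_rew*W + b_j)*M + (c' + c'_rew*W + c'_j)*X
        + rew_Y*W + g1Y*t + g2Y*log t + e_Y,   e_Y ~ N(0, sigma_Y^2)

and the emitted rating is 100*clip(V, 0, 1) (clipping optional: it mimics the
bounded visual-analogue scale but censors the linear model near its bounds).
Default coefficient values are the study's reported estimates, so that the
generator's conditions are the study's conditions.

Random effects are drawn from N(0, Psi) with Psi ordered
``(a, b, c', int_M, int_Y)``; the a-b covariance is what makes the indirect
effect exceed the product of fixed effects downstream.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from hypoalgesia._rng import substream
from hypoalgesia.performance_sdt import ResponseStream

__all__ = [
    "RANDOM_EFFECT_ORDER",
    "GenerativeConfig",
    "ParticipantProfile",
    "generate_participants",
    "generate_trials",
    "generate_response_stream",
    "generate_choice_set",
    "generate_thermal_table",
    "write_trials_csv",
    "TRIAL_CSV_COLUMNS",
]

RANDOM_EFFECT_ORDER = ("a", "b", "cprime", "int_M", "int_Y")

TRIAL_CSV_COLUMNS = [
    "participant_id",
    "trial",
    "task",
    "reward",
    "temperature",
    "performance",
    "pain_binary",
    "rating",
    "rating_rt_ms",
    "reward_amount_shown",
]

#: timing of one 2-back stimulus: fixation 250 ms + letter 500 ms (+ ISI)
FIXATION_MS = 250.0
LETTER_MS = 500.0
ISI_MIN_MS = 19.0
ISI_MAX_MS = 2583.0


def default_psi(
    sd_a: float = 0.06,
    sd_b: float = 0.12,
    sd_cprime: float = 0.05,
    sd_int_m: float = 0.04,
    sd_int_y: float = 0.12,
    cov_ab: float = 0.005,
) -> np.ndarray:
    """Random-effect covariance with an a-b covariance and diagonal elsewhere."""
    psi = np.diag(np.array([sd_a, sd_b, sd_cprime, sd_int_m, sd_int_y]) ** 2)
    psi[0, 1] = psi[1, 0] = cov_ab
    return psi


@dataclass
class GenerativeConfig:
    """Parameters of the forward model; defaults follow the study estimates."""

    n_participants: int = 57
    n_trials: int = 64
    # mediator (performance) equation
    alpha_M: float = 0.96
    a: float = -0.13
    rew_M: float = 0.0
    a_rew: float = 0.04
    gamma1_M: float = 0.0
    gamma2_M: float = 0.01
    # outcome (pain rating) equation
    alpha_Y: float = 0.64
    b: float = -0.16
    rew_Y: float = -0.13
    b_rew: float = 0.09
    cprime: float = -0.04
    cprime_rew: float = -0.04
    gamma1_Y: float = 0.0
    gamma2_Y: float = 0.03
    # random-effect covariance over (a, b, c', int_M, int_Y) and residual SDs
    psi: np.ndarray = field(default_factory=default_psi)
    sigma_M: float = 0.06
    sigma_Y: float = 0.18
    # realism switches
    clip: bool = True
    p_painful_high: float = 0.9
    p_painful_low: float = 0.0
    fast_guess_rate: float = 0.011
    seed: int = 0

    def __post_init__(self) -> None:
        self.psi = np.asarray(self.psi, dtype=float)
        if self.psi.shape != (5, 5):
            raise ValueError("psi must be a 5x5 covariance over " + str(RANDOM_EFFECT_ORDER))
        if not np.allclose(self.psi, self.psi.T, atol=1e-10):
            raise ValueError("psi must be symmetric")
        if np.min(np.linalg.eigvalsh(self.psi)) < -1e-10:
            raise ValueError("psi must be positive semi-definite")
        if self.sigma_M < 0 or self.sigma_Y < 0:
            raise ValueError("residual SDs must be non-negative")

    # -- YAML round-trip -------------------------------------------------
    def to_yaml(self) -> str:
        d = self.__dict__.copy()
        d["psi"] = self.psi.tolist()
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GenerativeConfig":
        d = yaml.safe_load(io.StringIO(text))
        return cls(**d)

    def replace(self, **kw) -> "GenerativeConfig":
        return replace(self, **kw)


@dataclass
class ParticipantProfile:
    """Generative truth for one simulated participant."""

    participant_id: int
    random_effects: np.ndarray  # (a_j, b_j, c'_j, int_Mj, int_Yj)
    low_temp: float
    high_temp: float
    true_isi: float
    money_logit_intercept: float
    money_logit_slope: float
    reward_amount: float
    warmth_slope: float = 10.0
    pain_slope: float = 20.0
    nback_dmax: float = 3.0
    nback_tau: float = 1000.0

    def nback_dprime(self, isi_ms: float) -> float:
        """True 2-back sensitivity at a given ISI (saturating, monotone)."""
        return self.nback_dmax * isi_ms / (isi_ms + self.nback_tau)


def generate_participants(config: GenerativeConfig) -> list[ParticipantProfile]:
    """Draw ``config.n_participants`` profiles; ids run 1..n.

    Random mediation effects come from N(0, Psi) (SVD sampling, so a
    semi-definite or zero Psi is valid and Psi = 0 yields exactly zero
    effects).  Thermal, ISI, and monetary parameters are drawn around the
    study's reported cohort means.
    """
    rng = substream(config.seed, "participants")
    n = int(config.n_participants)
    re = rng.multivariate_normal(np.zeros(5), config.psi, size=n, method="svd")

    low = np.clip(rng.normal(45.3, 1.9, size=n), 40.0, 48.0)
    high = np.clip(rng.normal(48.4, 0.6, size=n), 46.0, 49.0)
    high = np.maximum(high, low + 0.5)

    isi = np.clip(np.exp(rng.normal(np.log(800.0), 0.45, size=n)), 303.0, ISI_MAX_MS)

    amount_true = np.clip(rng.normal(2.02, 1.04, size=n), 0.2, 3.5)
    slope = np.clip(rng.normal(3.0, 0.8, size=n), 0.5, None)
    intercept = math.log(19.0) - slope * amount_true  # logit(0.95) = log 19
    reward = np.clip(amount_true, 0.5, 3.0)

    wslope = np.clip(rng.normal(10.0, 1.5, size=n), 4.0, None)
    pslope = np.clip(rng.normal(20.0, 3.0, size=n), 8.0, None)
    dmax = np.clip(rng.normal(3.0, 0.4, size=n), 1.5, None)
    tau = np.clip(rng.normal(1000.0, 250.0, size=n), 300.0, None)

    return [
        ParticipantProfile(
            participant_id=i + 1,
            random_effects=re[i],
            low_temp=float(low[i]),
            high_temp=float(high[i]),
            true_isi=float(isi[i]),
            money_logit_intercept=float(intercept[i]),
            money_logit_slope=float(slope[i]),
            reward_amount=float(reward[i]),
            warmth_slope=float(wslope[i]),
            pain_slope=float(pslope[i]),
            nback_dmax=float(dmax[i]),
            nback_tau=float(tau[i]),
        )
        for i in range(n)
    ]


def _condition_sequence(n_trials: int, rng: np.random.Generator) -> np.ndarray:
    """Pseudo-random balanced 2x2x2 order: permuted blocks of 8 (one trial
    per cell each), re-drawn until no more than 3 consecutive trials share a
    temperature level."""
    cells = np.array(
        [(x, w, h) for x in (0, 1) for w in (0, 1) for h in (0, 1)], dtype=int
    )
    n_blocks = n_trials // 8
    for _ in range(1000):
        order = np.concatenate([rng.permutation(8) for _ in range(n_blocks)])
        seq = cells[order]
        temp = seq[:, 2]
        # longest run of equal temperature
        run, longest = 1, 1
        for i in range(1, len(temp)):
            run = run + 1 if temp[i] == temp[i - 1] else 1
            longest = max(longest, run)
        if longest <= 3:
            return seq
    return seq  # pragma: no cover - astronomically unlikely


def generate_trials(
    profiles: list[ParticipantProfile], config: GenerativeConfig
) -> pd.DataFrame:
    """Run the mediation model forward into a long-format trial table.

    Each participant contributes exactly ``config.n_trials`` trials, balanced
    over the 2x2x2 factorial (``n_trials`` must be divisible by 8).  Output
    columns follow :data:`TRIAL_CSV_COLUMNS`.
    """
    if config.n_trials % 8:
        raise ValueError("n_trials must be divisible by 8 for a balanced 2x2x2 design")
    rows = []
    for prof in profiles:
        rng = substream(config.seed, f"trials:{prof.participant_id}")
        a_j, b_j, c_j, im_j, iy_j = prof.random_effects
        seq = _condition_sequence(config.n_trials, rng)
        t = np.arange(1, config.n_trials + 1, dtype=float)
        logt = np.log(t)
        X = seq[:, 0].astype(float)
        W = seq[:, 1].astype(float)
        hot = seq[:, 2].astype(bool)

        e_m = rng.normal(0.0, config.sigma_M, size=config.n_trials)
        M = (
            config.alpha_M
            + (config.a + config.a_rew * W + a_j) * X
            + config.rew_M * W
            + config.gamma1_M * t
            + config.gamma2_M * logt
            + im_j
            + e_m
        )
        if config.clip:
            M = np.clip(M, 0.0, 1.0)

        e_y = rng.normal(0.0, config.sigma_Y, size=config.n_trials)
        V = (
            config.alpha_Y
            + iy_j
            + (config.b + config.b_rew * W + b_j) * M
            + (config.cprime + config.cprime_rew * W + c_j) * X
            + config.rew_Y * W
            + config.gamma1_Y * t
            + config.gamma2_Y * logt
            + e_y
        )
        if config.clip:
            V = np.clip(V, 0.0, 1.0)

        painful = np.where(
            hot,
            rng.random(config.n_trials) < config.p_painful_high,
            rng.random(config.n_trials) < config.p_painful_low,
        )
        warmth_low = 100.0 * np.clip(rng.normal(0.8, 0.1, size=config.n_trials), 0, 1)
        rating = np.where(hot, 100.0 * V, warmth_low)
        if config.clip:
            rating = np.clip(rating, 0.0, 100.0)

        rt = np.exp(rng.normal(np.log(1100.0), 0.35, size=config.n_trials))
        rt = np.maximum(rt, 160.0)
        fast = rng.random(config.n_trials) < config.fast_guess_rate
        rt = np.where(fast, rng.uniform(50.0, 149.0, size=config.n_trials), rt)

        rows.append(
            pd.DataFrame(
                {
                    "participant_id": prof.participant_id,
                    "trial": t.astype(int),
                    "task": np.where(X > 0, "2back", "LR"),
                    "reward": W.astype(int),
                    "temperature": np.where(hot, "HIGH", "LOW"),
                    "performance": M,
                    "pain_binary": np.where(painful, "painful", "not_painful"),
                    "rating": rating,
                    "rating_rt_ms": rt,
                    "reward_amount_shown": np.where(W > 0, prof.reward_amount, 0.0),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def generate_response_stream(
    sensitivity,
    isi_ms: float,
    duration_s: float = 20.0,
    *,
    rng: np.random.Generator,
    p_target: float = 0.3,
    criterion: float = 0.0,
    task: str = "TWO_BACK",
) -> ResponseStream:
    """Simulate one 20-second letter (or arrow) stream and its responses.

    The number of stimuli is ``floor(duration / (250 + 500 + isi) ms)``.  The
    observer is an equal-variance Gaussian detector with sensitivity
    ``d' = sensitivity(isi_ms)`` (or a constant, if ``sensitivity`` is a
    number; ``inf`` yields a perfect observer, 0 a guesser): it answers
    "signal" with probability ``Phi(d'/2 - criterion)`` on targets and
    ``Phi(-d'/2 - criterion)`` on non-targets.  For the 2-back stream the
    first two positions can never be targets.
    """
    if not (ISI_MIN_MS <= isi_ms <= ISI_MAX_MS):
        raise ValueError(f"isi_ms must lie in [{ISI_MIN_MS}, {ISI_MAX_MS}] ms")
    period = FIXATION_MS + LETTER_MS + isi_ms
    n = int(math.floor(duration_s * 1000.0 / period))
    d = float(sensitivity(isi_ms)) if callable(sensitivity) else float(sensitivity)
    from scipy.stats import norm

    if math.isinf(d):
        H, F = (1.0, 0.0) if d > 0 else (0.0, 1.0)
    else:
        H = float(norm.cdf(d / 2.0 - criterion))
        F = float(norm.cdf(-d / 2.0 - criterion))

    is_target = np.zeros(n, dtype=bool)
    if task == "TWO_BACK":
        if n > 2:
            is_target[2:] = rng.random(n - 2) < p_target
    else:  # LR arrows: left arrow is the signal category
        is_target = rng.random(n) < 0.5
    u = rng.random(n)
    said = np.where(is_target, u < H, u < F)
    onsets = np.arange(n) * period
    return ResponseStream(
        is_target=is_target,
        response_signal=np.array([bool(x) for x in said], dtype=object),
        isi_ms=isi_ms,
        task=task,
        onsets_ms=onsets,
    )


def generate_choice_set(
    profile: ParticipantProfile,
    offers=None,
    *,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bernoulli pain-for-money choices over a 26-offer ($0-$3) ladder.

    P(accept) = logistic(intercept + slope * offer) with the participant's
    monetary-value parameters.
    """
    if offers is None:
        offers = np.round(np.linspace(0.0, 3.0, 26), 2)
    offers = np.asarray(offers, dtype=float)
    if offers.min() < 0.0 or offers.max() > 3.0:
        raise ValueError("offers must lie within [$0, $3]")
    p = expit(profile.money_logit_intercept + profile.money_logit_slope * offers)
    accept = rng.random(len(offers)) < p
    return pd.DataFrame({"offer": offers, "accept": accept.astype(int)})


def generate_thermal_table(
    profile: ParticipantProfile,
    *,
    rng: np.random.Generator,
    temperatures=(40.0, 44.0, 45.0, 46.0, 47.0, 48.0, 49.0),
    n_sites: int = 4,
    noise_sd: float = 4.0,
) -> pd.DataFrame:
    """Per-stimulus heat ratings: 7 temperatures x 4 forearm sites.

    Each stimulation is classified painful with probability rising steeply
    between the participant's warm and painful temperatures; warmth ratings
    follow ``80 + warmth_slope*(T - low_temp)`` and pain-intensity ratings
    ``60 + pain_slope*(T - high_temp)``, both with Gaussian noise, clipped to
    the 0-100 scale.
    """
    temps = np.repeat(np.asarray(temperatures, dtype=float), n_sites)
    mid = 0.5 * (profile.low_temp + profile.high_temp)
    p_pain = expit((temps - mid) / 0.6)
    painful = rng.random(len(temps)) < p_pain
    warmth = 80.0 + profile.warmth_slope * (temps - profile.low_temp)
    pain = 60.0 + profile.pain_slope * (temps - profile.high_temp)
    rating = np.where(painful, pain, warmth) + rng.normal(0, noise_sd, len(temps))
    rating = np.clip(rating, 0.0, 100.0)
    return pd.DataFrame(
        {
            "temperature": temps,
            "painful": painful.astype(int),
            "rating": rating,
        }
    )


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write the long-format trial table with the canonical column order."""
    trials.loc[:, TRIAL_CSV_COLUMNS].to_csv(path, index=False)
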