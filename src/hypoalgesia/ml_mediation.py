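"""Multilevel 1-1-1 moderated mediation via a row-stacked mixed model.

The mediation engine follows the stacked ("selector-variable") formulation:
each analysed trial contributes two rows, a mediator row (response = task
performance M) and an outcome row (response = pain rating on the 0-1 scale),
with selector indicators S_M and S_Y switching the relevant predictors on.
One mixed model fitted to the stacked rows then estimates both equations

    M = int_M + (a + a_rew*W)*X + rew_M*W + g1*t + g2*log t + (a_j X + ...)
    Y = int_Y + (b + b_rew*W)*M + (c' + c'_rew*W)*X + rew_Y*W + g1*t + g2*log t + ...

jointly, with participant-level random effects for any subset of
{int_M, int_Y, a, b, c'} sharing an unstructured covariance Psi, and
separate residual variances for mediator and outcome rows.

Because a_j and b_j may covary across participants, the population-average
indirect effect is *more* than the product of fixed effects:

    ab = a*b + cov(a_j, b_j)

and with reward moderation the conditional indirect effects are
``IE(w) = (a + a_rew*w)(b + b_rew*w) + cov(a_j, b_j)`` for w in {0, 1}.
Interval estimates come from a participant-level nonparametric bootstrap
(resample participants with replacement, refit, percentile CIs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hypoalgesia._lmm import GroupStats, LMMFit, fit_lmm
from hypoalgesia._rng import substream

__all__ = [
    "StackedDesign",
    "MediationFit",
    "IndirectEstimate",
    "TotalEffectFit",
    "BootstrapResult",
    "stack_rows",
    "unstack_rows",
    "fit_mediation",
    "indirect_effects",
    "bootstrap_ci",
    "fit_total_effect",
    "mediation_table",
    "path_summary",
]

#: canonical fixed-effect order: mediator block then outcome block
MEDIATOR_TERMS = ["int_M", "a", "rew_M", "a_rew", "trial_M", "logtrial_M"]
OUTCOME_TERMS = [
    "int_Y",
    "b",
    "rew_Y",
    "b_rew",
    "cprime",
    "cprime_rew",
    "trial_Y",
    "logtrial_Y",
]
REWARD_TERMS = {"rew_M", "a_rew", "rew_Y", "b_rew", "cprime_rew"}
TRIAL_TERMS = {"trial_M", "logtrial_M", "trial_Y", "logtrial_Y"}
RANDOM_TERMS = ["int_M", "int_Y", "a", "b", "cprime"]

#: M-side vs Y-side random effects, used for the block-diagonal Psi structure
_M_SIDE = {"int_M", "a"}


@dataclass
class StackedDesign:
    """Two-rows-per-trial design for the stacked mediation model."""

    frame: pd.DataFrame  # long rows with selector/predictor columns
    x_names: list[str]
    n_trials: int
    n_dropped: int
    include_reward: bool
    include_trial: bool

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def participants(self) -> np.ndarray:
        return self.frame["participant_id"].unique()

    def to_group_stats(self, random_set: tuple[str, ...]) -> GroupStats:
        bad = [r for r in random_set if r not in RANDOM_TERMS]
        if bad:
            raise ValueError(f"unknown random terms {bad}; choose from {RANDOM_TERMS}")
        u_names = [r for r in RANDOM_TERMS if r in random_set]
        X = self.frame[self.x_names].to_numpy(float)
        U = self.frame[u_names].to_numpy(float)
        return GroupStats.from_arrays(
            groups=self.frame["participant_id"].to_numpy(),
            row_type=self.frame["row_type"].to_numpy(int),
            X=X,
            U=U,
            z=self.frame["z"].to_numpy(float),
            x_names=self.x_names,
            u_names=u_names,
            n_types=2,
        )


def stack_rows(
    table: pd.DataFrame,
    *,
    include_reward: bool = True,
    include_trial: bool = True,
) -> StackedDesign:
    """Stack high-temperature trials into mediator + outcome rows.

    ``table`` is a cleaned trial table (one row per trial) with columns
    ``participant_id``, ``task``, ``reward``, ``performance``, ``rating01``,
    ``t``, ``log_t``.  Trials missing the mediator or the outcome are
    dropped (and counted).  ``include_reward=False`` drops every
    reward-bearing term; ``include_trial=False`` drops the time covariates —
    both for reduced simulation designs.
    """
    needed = ["participant_id", "task", "reward", "performance", "rating01", "t", "log_t"]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ValueError(f"stack_rows: missing columns {missing}")
    ok = table["performance"].notna() & table["rating01"].notna()
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} trial(s) with missing M or rating", stacklevel=2)
    tab = table.loc[ok]
    nt = len(tab)

    pid = tab["participant_id"].to_numpy()
    X = (tab["task"].astype(str).str.lower() != "lr").to_numpy(float)
    W = tab["reward"].to_numpy(float)
    M = tab["performance"].to_numpy(float)
    Y = tab["rating01"].to_numpy(float)
    t = tab["t"].to_numpy(float)
    logt = tab["log_t"].to_numpy(float)
    trial = tab["t"].to_numpy(float)

    x_names = [
        n
        for n in MEDIATOR_TERMS + OUTCOME_TERMS
        if (include_reward or n not in REWARD_TERMS)
        and (include_trial or n not in TRIAL_TERMS)
    ]
    zero = np.zeros(nt)
    one = np.ones(nt)
    med = {
        "int_M": one, "a": X, "rew_M": W, "a_rew": X * W,
        "trial_M": t, "logtrial_M": logt,
        "int_Y": zero, "b": zero, "rew_Y": zero, "b_rew": zero,
        "cprime": zero, "cprime_rew": zero, "trial_Y": zero, "logtrial_Y": zero,
    }
    out = {
        "int_M": zero, "a": zero, "rew_M": zero, "a_rew": zero,
        "trial_M": zero, "logtrial_M": zero,
        "int_Y": one, "b": M, "rew_Y": W, "b_rew": M * W,
        "cprime": X, "cprime_rew": X * W, "trial_Y": t, "logtrial_Y": logt,
    }
    frames = []
    for row_type, cols, z in ((0, med, M), (1, out, Y)):
        f = pd.DataFrame({n: cols[n] for n in x_names})
        f.insert(0, "participant_id", pid)
        f.insert(1, "trial", trial)
        f.insert(2, "row_type", row_type)
        f["z"] = z
        # carried along for round-trip and bootstrap bookkeeping
        f["X"] = X
        f["W"] = W
        f["M"] = M
        f["Y"] = Y
        frames.append(f)
    long = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["participant_id", "trial", "row_type"], kind="stable")
        .reset_index(drop=True)
    )
    return StackedDesign(
        frame=long,
        x_names=x_names,
        n_trials=nt,
        n_dropped=n_dropped,
        include_reward=include_reward,
        include_trial=include_trial,
    )


def unstack_rows(design: StackedDesign) -> pd.DataFrame:
    """Recover the one-row-per-trial table from a stacked design."""
    med = design.frame[design.frame["row_type"] == 0]
    out = pd.DataFrame(
        {
            "participant_id": med["participant_id"].to_numpy(),
            "task": np.where(med["X"].to_numpy() > 0, "2back", "LR"),
            "reward": med["W"].to_numpy(int),
            "performance": med["M"].to_numpy(),
            "rating01": med["Y"].to_numpy(),
            "t": med["trial"].to_numpy(float),
        }
    )
    out["log_t"] = np.log(out["t"])
    return out.reset_index(drop=True)


@dataclass
class MediationFit:
    """Stacked REML fit plus mediation-specific bookkeeping."""

    lmm: LMMFit
    random_set: tuple[str, ...]
    psi_structure: str
    design: StackedDesign | None = None

    # -- convenience views ------------------------------------------------
    @property
    def converged(self) -> bool:
        return self.lmm.converged

    @property
    def psi(self) -> np.ndarray:
        return self.lmm.psi

    @property
    def sigma2_M(self) -> float:
        return float(self.lmm.sigma2[0])

    @property
    def sigma2_Y(self) -> float:
        return float(self.lmm.sigma2[1])

    @property
    def sigma_ab(self) -> float:
        """cov(a_j, b_j); 0 unless both a and b are random."""
        if "a" in self.lmm.u_names and "b" in self.lmm.u_names:
            return self.lmm.psi_entry("a", "b")
        return 0.0

    def coef(self, name: str, default: float = 0.0) -> float:
        if name in self.lmm.x_names:
            return float(self.lmm.beta[self.lmm.x_names.index(name)])
        return default


@dataclass
class IndirectEstimate:
    """Covariance-inclusive indirect effects and their moderation."""

    ab: float
    ie0: float
    ie1: float
    ie_diff: float
    sigma_ab: float

    @classmethod
    def from_fit(cls, fit: MediationFit) -> "IndirectEstimate":
        a = fit.coef("a")
        b = fit.coef("b")
        a_rew = fit.coef("a_rew")
        b_rew = fit.coef("b_rew")
        s = fit.sigma_ab
        ie0 = a * b + s
        ie1 = (a + a_rew) * (b + b_rew) + s
        return cls(ab=a * b + s, ie0=ie0, ie1=ie1, ie_diff=ie1 - ie0, sigma_ab=s)

    def as_dict(self) -> dict[str, float]:
        return {
            "ab": self.ab,
            "ie0": self.ie0,
            "ie1": self.ie1,
            "ie_diff": self.ie_diff,
            "sigma_ab": self.sigma_ab,
        }


def _psi_mask(u_names: list[str], structure: str) -> np.ndarray | None:
    q = len(u_names)
    if structure == "unstructured":
        return None
    if structure == "diagonal":
        return np.eye(q, dtype=bool)
    if structure == "blockdiag":
        # no covariance between mediator-equation and outcome-equation effects
        side = np.array([u in _M_SIDE for u in u_names])
        mask = np.tril(side[:, None] == side[None, :])
        np.fill_diagonal(mask, True)
        return mask
    raise ValueError(f"unknown psi structure {structure!r}")


def fit_mediation(
    stacked: StackedDesign,
    random_set: tuple[str, ...] = ("int_M", "int_Y", "a", "b", "cprime"),
    *,
    psi_structure: str = "unstructured",
    theta0: np.ndarray | None = None,
    track_objective: bool = False,
    keep_design: bool = True,
) -> MediationFit:
    """REML fit of the stacked mediation model.

    ``random_set`` chooses which paths get participant-level random effects;
    the default adds random intercepts to the random a/b/c' paths, and the
    "paper" preset ``("a", "b", "cprime")`` is one argument away.
    ``psi_structure`` is ``"unstructured"`` (default), ``"diagonal"``,
    ``"blockdiag"`` (no mediator-outcome covariance), or ``"zero"`` (Psi
    pinned at 0, in which case the stacked GLS reduces algebraically to
    per-equation ordinary least squares).
    """
    if len(random_set) == 0:
        raise ValueError("random_set must be non-empty")
    n_part = len(stacked.participants)
    if n_part < 10:
        raise ValueError(f"need >=10 participants, got {n_part}")
    z = stacked.frame["z"].to_numpy(float)
    if z.min() < -1e-8 or z.max() > 1.0 + 1e-8:
        warnings.warn(
            "stacked responses fall outside [0, 1]; expected rescaled ratings "
            "and A-scores",
            stacklevel=2,
        )
    stats = stacked.to_group_stats(tuple(random_set))
    zero = psi_structure == "zero"
    mask = None if zero else _psi_mask(stats.u_names, psi_structure)
    lmm = fit_lmm(
        stats, psi_mask=mask, theta0=theta0, zero_psi=zero,
        track_objective=track_objective,
    )
    return MediationFit(
        lmm=lmm,
        random_set=tuple(stats.u_names),
        psi_structure=psi_structure,
        design=stacked if keep_design else None,
    )


def indirect_effects(fit: MediationFit) -> IndirectEstimate:
    """Covariance-inclusive indirect effect and its conditional values.

    ``ab = a*b + cov(a_j, b_j)``; conditional effects at w = 0 and w = 1 use
    the moderated paths where present (absent moderators contribute 0).
    """
    if not fit.converged:
        warnings.warn("indirect effects from a non-converged fit", stacklevel=2)
    return IndirectEstimate.from_fit(fit)


@dataclass
class BootstrapResult:
    """Percentile CIs from participant-level resampling."""

    ci: dict[str, tuple[float, float]]
    B: int
    n_failed: int
    seed: int
    level: float = 0.95
    draws: pd.DataFrame | None = None


def bootstrap_ci(
    stacked: StackedDesign,
    B: int = 10_000,
    seed: int = 0,
    *,
    random_set: tuple[str, ...] = ("int_M", "int_Y", "a", "b", "cprime"),
    psi_structure: str = "unstructured",
    level: float = 0.95,
    max_fail_frac: float = 0.10,
    keep_draws: bool = False,
) -> BootstrapResult:
    """Participant-level bootstrap percentile CIs.

    Each replicate resamples participants with replacement (a sampled
    participant's full set of rows enters once per draw, re-indexed), refits
    the stacked model warm-started at the full-data variance parameters, and
    records all fixed effects plus the indirect quantities.  Replicates
    whose optimizer fails to converge are dropped and counted; more than
    ``max_fail_frac`` failures raise.
    """
    if B < 100:
        raise ValueError("B must be at least 100 (use B=0 upstream to skip CIs)")
    stats = stacked.to_group_stats(tuple(random_set))
    mask = _psi_mask(stats.u_names, psi_structure)
    full = fit_lmm(stats, psi_mask=mask)
    theta_hat = full.theta
    rng = substream(seed, "bootstrap")
    J = stats.J

    names = list(stats.x_names) + ["ab", "ie0", "ie1", "ie_diff", "sigma_ab"]
    draws = np.full((B, len(names)), np.nan)
    n_failed = 0
    for bidx in range(B):
        idx = rng.integers(0, J, size=J)
        rep = fit_lmm(
            stats.take(idx), psi_mask=mask, theta0=theta_hat, max_restarts=0
        )
        if not rep.converged:
            n_failed += 1
            continue
        mfit = MediationFit(lmm=rep, random_set=tuple(stats.u_names), psi_structure=psi_structure)
        ind = IndirectEstimate.from_fit(mfit)
        draws[bidx, : stats.p] = rep.beta
        draws[bidx, stats.p :] = [ind.ab, ind.ie0, ind.ie1, ind.ie_diff, ind.sigma_ab]
    if n_failed > max_fail_frac * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to converge "
            f"(> {max_fail_frac:.0%} ceiling)"
        )
    good = draws[~np.isnan(draws[:, 0])]
    alpha = 100.0 * (1.0 - level) / 2.0
    lo = np.percentile(good, alpha, axis=0)
    hi = np.percentile(good, 100.0 - alpha, axis=0)
    ci = {n: (float(lo[i]), float(hi[i])) for i, n in enumerate(names)}
    return BootstrapResult(
        ci=ci,
        B=B,
        n_failed=n_failed,
        seed=seed,
        level=level,
        draws=pd.DataFrame(good, columns=names) if keep_draws else None,
    )


@dataclass
class TotalEffectFit:
    """Mixed model for the total effect of task demands (no mediator)."""

    lmm: LMMFit

    @property
    def c(self) -> float:
        return float(self.lmm.beta[self.lmm.x_names.index("c")])

    @property
    def c_rew(self) -> float:
        if "c_rew" in self.lmm.x_names:
            return float(self.lmm.beta[self.lmm.x_names.index("c_rew")])
        return 0.0


def fit_total_effect(
    table: pd.DataFrame,
    *,
    include_reward: bool = True,
    include_trial: bool = True,
) -> TotalEffectFit:
    """Total effect c of task demands on pain, not adjusting for performance.

    Mixed model of ``rating01`` on task, reward, task x reward, and the time
    covariates, with a random intercept and a random task slope per
    participant.
    """
    X_task = (table["task"].astype(str).str.lower() != "lr").to_numpy(float)
    if np.all(X_task == X_task[0]):
        raise ValueError("task is constant; the total effect c is inestimable")
    W = table["reward"].to_numpy(float)
    t = table["t"].to_numpy(float)
    logt = table["log_t"].to_numpy(float)
    z = table["rating01"].to_numpy(float)
    cols = [("int", np.ones(len(table))), ("c", X_task)]
    if include_reward:
        cols += [("rew", W), ("c_rew", X_task * W)]
    if include_trial:
        cols += [("trial", t), ("logtrial", logt)]
    x_names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])
    U = X[:, :2]  # random intercept + random task slope
    stats = GroupStats.from_arrays(
        groups=table["participant_id"].to_numpy(),
        row_type=np.zeros(len(table), dtype=int),
        X=X,
        U=U,
        z=z,
        x_names=x_names,
        u_names=["int", "c"],
        n_types=1,
    )
    return TotalEffectFit(lmm=fit_lmm(stats))


# --------------------------------------------------------------------------
# reporting helpers
# --------------------------------------------------------------------------

_PRETTY = {
    "int_M": ("performance", "(Intercept)"),
    "a": ("performance", "Task demands"),
    "rew_M": ("performance", "Reward"),
    "a_rew": ("performance", "Task demands x reward"),
    "trial_M": ("performance", "Trial number"),
    "logtrial_M": ("performance", "log(trial number)"),
    "int_Y": ("ratings", "(Intercept)"),
    "b": ("ratings", "Performance"),
    "rew_Y": ("ratings", "Reward"),
    "b_rew": ("ratings", "Performance x reward"),
    "cprime": ("ratings", "Task demands"),
    "cprime_rew": ("ratings", "Task demands x reward"),
    "trial_Y": ("ratings", "Trial number"),
    "logtrial_Y": ("ratings", "log(trial number)"),
}


def mediation_table(
    fit: MediationFit,
    indirect: IndirectEstimate,
    boot: BootstrapResult | None = None,
) -> pd.DataFrame:
    """Coefficient table in the two-block layout plus indirect-effect rows."""
    lmm = fit.lmm
    rows = []
    for i, name in enumerate(lmm.x_names):
        block, label = _PRETTY.get(name, ("", name))
        lo, hi = (boot.ci[name] if boot and name in boot.ci else (np.nan, np.nan))
        rows.append(
            {
                "outcome": block,
                "predictor": label,
                "term": name,
                "estimate": float(lmm.beta[i]),
                "ci_lower": lo,
                "ci_upper": hi,
                "se": float(lmm.se[i]),
                "df": lmm.df_resid,
                "t": float(lmm.tvals[i]),
                "p": float(lmm.pvals[i]),
            }
        )
    for term, label in [
        ("ab", "Indirect effect"),
        ("ie_diff", "Difference of indirect effects"),
    ]:
        lo, hi = (boot.ci[term] if boot and term in boot.ci else (np.nan, np.nan))
        rows.append(
            {
                "outcome": "indirect",
                "predictor": label,
                "term": term,
                "estimate": getattr(indirect, term if term != "ab" else "ab"),
                "ci_lower": lo,
                "ci_upper": hi,
                "se": np.nan,
                "df": np.nan,
                "t": np.nan,
                "p": np.nan,
            }
        )
    return pd.DataFrame(rows)


def path_summary(
    fit: MediationFit,
    indirect: IndirectEstimate,
    total: TotalEffectFit | None = None,
) -> str:
    """Human-readable path-diagram summary of the fitted mediation."""
    lines = [
        "Mediation paths (task demands -> performance -> pain):",
        f"  a      (task -> performance)        = {fit.coef('a'):+.4f}",
        f"  a*rew  (reward moderation of a)     = {fit.coef('a_rew'):+.4f}",
        f"  b      (performance -> pain)        = {fit.coef('b'):+.4f}",
        f"  c'     (direct task -> pain)        = {fit.coef('cprime'):+.4f}",
        f"  cov(a_j, b_j)                       = {indirect.sigma_ab:+.5f}",
        f"  ab     (indirect, incl. covariance) = {indirect.ab:+.4f}",
        f"  IE(w=0) = {indirect.ie0:+.4f}   IE(w=1) = {indirect.ie1:+.4f}   "
        f"difference = {indirect.ie_diff:+.4f}",
    ]
    if total is not None:
        lines.append(
            f"  c      (total task -> pain)         = {total.c:+.4f}   "
            f"c*rew = {total.c_rew:+.4f}"
        )
    lines.append(
        f"  residual SD: mediator {np.sqrt(fit.sigma2_M):.4f}, "
        f"outcome {np.sqrt(fit.sigma2_Y):.4f}; converged={fit.converged}"
    )
    return "\n".join(lines)
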