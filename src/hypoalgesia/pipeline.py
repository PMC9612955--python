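"""Reproducible simulate -> calibrate -> preprocess -> analyze -> report runs.

One :class:`RunConfig` (a single seed plus the generative and analysis
settings) drives every stage; each stage draws from its own named random
substream of the top-level seed, so changing the bootstrap replicate count
never perturbs the simulated cohort.  Identical config + seed produces
byte-identical output files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hypoalgesia import __version__
from hypoalgesia._rng import substream
from hypoalgesia.calibrators import (
    CalibrationError,
    fit_money_acceptance,
    fit_thermal_curve,
    run_isi_staircase,
)
from hypoalgesia.ml_mediation import (
    bootstrap_ci,
    fit_mediation,
    fit_total_effect,
    indirect_effects,
    mediation_table,
    path_summary,
    stack_rows,
)
from hypoalgesia.preprocess import cell_means, filter_and_derive, select_analysis_set
from hypoalgesia.rm_anova import (
    anova_to_frame,
    contrasts_to_frame,
    planned_contrasts,
    rm_anova_2x2,
    within_subject_se,
)
from hypoalgesia.synthetic_cohort import (
    GenerativeConfig,
    generate_choice_set,
    generate_participants,
    generate_response_stream,
    generate_thermal_table,
    generate_trials,
    write_trials_csv,
)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "simulate_stage", "calibrate_stage", "analyze_stage"]

log = logging.getLogger("hypoalgesia.pipeline")

#: analysis presets: random-effect set and bootstrap size
PRESETS = {
    "default": {"random_set": ("int_M", "int_Y", "a", "b", "cprime"), "bootstrap_B": 200},
    "paper": {"random_set": ("a", "b", "cprime"), "bootstrap_B": 10_000},
}


@dataclass
class RunConfig:
    """Everything needed to reproduce one full pipeline run."""

    seed: int = 0
    cohort: GenerativeConfig = field(default_factory=GenerativeConfig)
    preset: str = "default"
    bootstrap_B: int | None = None  # None -> preset default; 0 disables CIs
    random_set: tuple[str, ...] | None = None

    def resolved_random_set(self) -> tuple[str, ...]:
        return tuple(self.random_set or PRESETS[self.preset]["random_set"])

    def resolved_B(self) -> int:
        return self.bootstrap_B if self.bootstrap_B is not None else PRESETS[self.preset]["bootstrap_B"]

    def to_yaml(self) -> str:
        d = {
            "seed": self.seed,
            "preset": self.preset,
            "bootstrap_B": self.bootstrap_B,
            "random_set": list(self.random_set) if self.random_set else None,
            "cohort": yaml.safe_load(self.cohort.to_yaml()),
        }
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        cohort = GenerativeConfig(**d.pop("cohort", {}))
        rs = d.pop("random_set", None)
        return cls(cohort=cohort, random_set=tuple(rs) if rs else None, **d)


@dataclass
class ReportBundle:
    outdir: Path
    manifest: dict
    files: list[str]


def _stage(name):
    """Label stage failures and leave a marker file for partial outputs."""

    def deco(fn):
        def wrapped(outdir: Path, *a, **kw):
            try:
                log.info("stage %s: start", name)
                out = fn(outdir, *a, **kw)
                log.info("stage %s: done", name)
                return out
            except Exception as exc:
                (outdir / f"FAILED_{name}").write_text(str(exc))
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("simulate")
def simulate_stage(outdir: Path, config: RunConfig):
    cohort_cfg = config.cohort.replace(seed=config.seed)
    profiles = generate_participants(cohort_cfg)
    return cohort_cfg, profiles


@_stage("calibrate")
def calibrate_stage(outdir: Path, config: RunConfig, profiles):
    """Run all three simulated calibration tasks for every participant."""
    rows = []
    for prof in profiles:
        rng = substream(config.seed, f"calibrate:{prof.participant_id}")
        row = {"participant_id": prof.participant_id}
        try:
            therm = fit_thermal_curve(generate_thermal_table(prof, rng=rng))
            row.update(low_temp=therm.low_temp, high_temp=therm.high_temp, thermal_note="")
        except CalibrationError as exc:
            row.update(low_temp=np.nan, high_temp=np.nan, thermal_note=str(exc))

        def observer(isi, _prof=prof, _rng=rng):
            return generate_response_stream(_prof.nback_dprime, isi, rng=_rng)

        isi = run_isi_staircase(observer)
        row.update(
            final_isi=isi.final_isi,
            staircase_trials=len(isi.trajectory),
            staircase_monotone_suspect=isi.monotone_suspect,
        )
        money = fit_money_acceptance(generate_choice_set(prof, rng=rng))
        row.update(
            reward_amount=money.amount_95,
            money_intercept=money.intercept,
            money_slope=money.slope,
            money_note="; ".join(money.notes) if money.notes else "",
        )
        rows.append(row)
        # the main task displays the calibrated amount on reward trials
        prof.reward_amount = money.amount_95
    calib = pd.DataFrame(rows)
    calib.to_csv(outdir / "calibrations.csv", index=False)
    return calib


@_stage("analyze")
def analyze_stage(outdir: Path, config: RunConfig, cohort_cfg: GenerativeConfig, profiles):
    trials = generate_trials(profiles, cohort_cfg)
    write_trials_csv(trials, outdir / "cohort.csv")

    clean, report = filter_and_derive(trials)
    (outdir / "filter_report.json").write_text(json.dumps(report.to_dict(), indent=2))

    # pain analyses: high-temperature trials, task x reward
    pain = select_analysis_set(clean, "PAIN")
    pain_cells = cell_means(pain, factors=("task", "reward"), value="pain0")
    anova_to_frame(rm_anova_2x2(pain_cells)).to_csv(outdir / "anova_pain.csv", index=False)
    contrasts_to_frame(planned_contrasts(pain_cells)).to_csv(
        outdir / "contrasts_pain.csv", index=False
    )
    se = within_subject_se(pain_cells)
    fig = pd.DataFrame(
        {"mean": pain_cells.mean(axis=0), "within_subject_se": se}
    ).reset_index()
    fig.to_csv(outdir / "cellmeans_pain.csv", index=False)

    # performance analysis: 2-back trials, temperature x reward
    perf = select_analysis_set(clean, "PERFORMANCE")
    perf_cells = cell_means(perf, factors=("temperature", "reward"), value="performance")
    anova_to_frame(rm_anova_2x2(perf_cells)).to_csv(outdir / "anova_performance.csv", index=False)
    contrasts_to_frame(planned_contrasts(perf_cells)).to_csv(
        outdir / "contrasts_performance.csv", index=False
    )

    # multilevel mediation on high-temperature trials
    stacked = stack_rows(pain)
    fit = fit_mediation(stacked, random_set=config.resolved_random_set())
    ind = indirect_effects(fit)
    B = config.resolved_B()
    boot = None
    if B > 0:
        boot = bootstrap_ci(
            stacked,
            B=B,
            seed=config.seed,
            random_set=config.resolved_random_set(),
        )
    total = fit_total_effect(pain)
    mediation_table(fit, ind, boot).to_csv(outdir / "mediation_coefficients.csv", index=False)
    (outdir / "path_summary.txt").write_text(path_summary(fit, ind, total) + "\n")
    bundle = {
        "random_set": list(fit.random_set),
        "psi": fit.psi.tolist(),
        "sigma2_mediator": fit.sigma2_M,
        "sigma2_outcome": fit.sigma2_Y,
        "converged": bool(fit.converged),
        "grad_inf": fit.lmm.grad_inf,
        "reml_neg2": fit.lmm.reml_neg2,
        "indirect": ind.as_dict(),
        "total_effect": {"c": total.c, "c_rew": total.c_rew},
        "bootstrap": {
            "B": B,
            "n_failed": boot.n_failed if boot else None,
            "seed": config.seed,
        },
    }
    (outdir / "mediation_fit.json").write_text(json.dumps(bundle, indent=2))
    return fit, ind, boot, total


def run_pipeline(config: RunConfig, outdir) -> ReportBundle:
    """Run every stage and write a manifest sufficient to reproduce the run."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    log.addHandler(handler)
    try:
        cohort_cfg, profiles = simulate_stage(outdir, config)
        calibrate_stage(outdir, config, profiles)
        analyze_stage(outdir, config, cohort_cfg, profiles)
    finally:
        log.removeHandler(handler)
        handler.close()

    cfg_yaml = config.to_yaml()
    (outdir / "config.yaml").write_text(cfg_yaml)
    files = sorted(
        p.name for p in outdir.iterdir() if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "preset": config.preset,
        "bootstrap_B": config.resolved_B(),
        "random_set": list(config.resolved_random_set()),
        "package_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "files": files,
        "file_sha256": {
            f: hashlib.sha256((outdir / f).read_bytes()).hexdigest()
            for f in files
            if f != "run.log"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ReportBundle(outdir=outdir, manifest=manifest, files=files)
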