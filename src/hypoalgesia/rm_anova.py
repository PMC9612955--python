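"""2x2 repeated-measures ANOVA, planned contrasts, within-subject error bars.

The omnibus test is a standard two-factor within-subjects ANOVA on
per-participant condition-cell means (all effects have 1 numerator df in a
2x2 design, so each F is the square of the corresponding paired t).  Effect
sizes are partial eta squared.  Planned simple-effect contrasts are paired t
tests over cell means with Holm-Bonferroni step-down adjustment across the
4-member family.  Error bars for condition means use the Cousineau-O'Brien
within-subject method: participant means are removed before computing
per-cell SDs, and the SD is inflated by sqrt(C/(C-1)) to correct the bias
introduced by the centering (C = number of cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "rm_anova_2x2",
    "planned_contrasts",
    "default_simple_effects",
    "within_subject_se",
    "anova_to_frame",
    "contrasts_to_frame",
]


@dataclass
class AnovaResult:
    """One omnibus effect: F, degrees of freedom, p, partial eta squared."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float
    note: str = ""


@dataclass
class ContrastResult:
    """One planned paired contrast with raw and Holm-adjusted p."""

    label: str
    estimate: float
    t: float
    df: int
    p_raw: float
    p_holm: float = float("nan")


def _check_cells(cells: pd.DataFrame) -> pd.DataFrame:
    if cells.isna().any().any():
        raise ValueError("incomplete cells; drop participants with empty cells first")
    if cells.shape[1] != 4 or not isinstance(cells.columns, pd.MultiIndex):
        raise ValueError(
            "expected a participants x 4 cell-mean matrix with a 2-level "
            "MultiIndex of factor levels (see preprocess.cell_means)"
        )
    return cells


def rm_anova_2x2(cells: pd.DataFrame) -> list[AnovaResult]:
    """Two-factor within-subjects ANOVA on a participants x 4 cell matrix.

    ``cells`` comes from :func:`hypoalgesia.preprocess.cell_means`: the
    column MultiIndex names the two factors and their levels.  Returns the
    two main effects and the interaction; the error df for every effect is
    n_participants - 1.  A fully degenerate effect (zero effect *and* zero
    error variation) is reported as F = 0 with a note rather than NaN.
    """
    cells = _check_cells(cells)
    if len(cells) < 3:
        raise ValueError("need at least 3 participants")
    f1, f2 = cells.columns.names
    n = cells.shape[0]

    # per-effect difference scores; a 2x2 within effect is degenerate (0/0)
    # exactly when its difference score is identically zero
    a0, a1 = sorted({c[0] for c in cells.columns})
    b0, b1 = sorted({c[1] for c in cells.columns})
    d1 = cells[a1].mean(axis=1) - cells[a0].mean(axis=1)
    d2 = cells.xs(b1, axis=1, level=1).mean(axis=1) - cells.xs(b0, axis=1, level=1).mean(axis=1)
    dd = cells[(a1, b1)] - cells[(a1, b0)] - cells[(a0, b1)] + cells[(a0, b0)]
    diffs = {f1: d1.to_numpy(), f2: d2.to_numpy(), f"{f1}:{f2}": dd.to_numpy()}
    degenerate = {k: bool(np.allclose(v, 0.0, atol=1e-12)) for k, v in diffs.items()}

    tab = None
    if not all(degenerate.values()):
        long = cells.stack([0, 1], future_stack=True).rename("y").reset_index()
        long.columns = ["participant_id", f1, f2, "y"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tab = AnovaRM(
                long, depvar="y", subject="participant_id", within=[f1, f2]
            ).fit().anova_table

    results: list[AnovaResult] = []
    for effect in [f1, f2, f"{f1}:{f2}"]:
        if degenerate[effect] or tab is None:
            results.append(
                AnovaResult(effect, 0.0, 1, n - 1, 1.0, 0.0,
                            "degenerate 0/0 effect reported as 0")
            )
            continue
        F = float(tab.loc[effect, "F Value"])
        dfn = int(tab.loc[effect, "Num DF"])
        dfd = int(tab.loc[effect, "Den DF"])
        p = float(tab.loc[effect, "Pr > F"])
        note = ""
        if not np.isfinite(F):
            F, p, note = 0.0, 1.0, "degenerate 0/0 effect reported as 0"
        eta = F * dfn / (F * dfn + dfd)
        results.append(AnovaResult(effect, F, dfn, dfd, p, eta, note))
    return results


def _paired_t(diff: np.ndarray) -> tuple[float, float, int]:
    n = len(diff)
    df = n - 1
    sd = diff.std(ddof=1)
    m = diff.mean()
    if sd == 0.0:
        if m == 0.0:
            return 0.0, 1.0, df
        return float(np.sign(m) * np.inf), 0.0, df
    t = m / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def default_simple_effects(cells: pd.DataFrame) -> list[tuple[str, tuple, tuple]]:
    """The 4 planned simple effects of a 2x2 design.

    Each entry is ``(label, cell_hi, cell_lo)`` giving the difference
    ``mean(cell_hi) - mean(cell_lo)``: factor-1 effect within each level of
    factor 2, and factor-2 effect within each level of factor 1.
    """
    f1, f2 = cells.columns.names
    (a0, a1) = sorted({c[0] for c in cells.columns})
    (b0, b1) = sorted({c[1] for c in cells.columns})
    return [
        (f"{f1}[{a1}-{a0}] | {f2}={b1}", (a1, b1), (a0, b1)),
        (f"{f1}[{a1}-{a0}] | {f2}={b0}", (a1, b0), (a0, b0)),
        (f"{f2}[{b1}-{b0}] | {f1}={a1}", (a1, b1), (a1, b0)),
        (f"{f2}[{b1}-{b0}] | {f1}={a0}", (a0, b1), (a0, b0)),
    ]


def planned_contrasts(
    cells: pd.DataFrame,
    family: list[tuple[str, tuple, tuple]] | None = None,
) -> list[ContrastResult]:
    """Paired-t planned contrasts with Holm step-down adjustment.

    ``family`` defaults to the 4 simple effects of the 2x2 design; the Holm
    family is exactly the set of contrasts passed in one call.  Contrast SEs
    come from each contrast's own paired-difference variance, which is robust
    to sphericity violations.
    """
    cells = _check_cells(cells)
    if family is None:
        family = default_simple_effects(cells)
    if len(family) == 0:
        raise ValueError("contrast family is empty")
    out: list[ContrastResult] = []
    for label, hi, lo in family:
        diff = cells[hi].to_numpy(float) - cells[lo].to_numpy(float)
        t, p, df = _paired_t(diff)
        out.append(ContrastResult(label, float(diff.mean()), t, df, p))
    p_holm = multipletests([c.p_raw for c in out], method="holm")[1]
    for c, ph in zip(out, p_holm):
        c.p_holm = float(ph)
    return out


def within_subject_se(cells: pd.DataFrame) -> pd.Series:
    """Cousineau-O'Brien within-subject SE for each condition cell.

    Each participant's cell values are centered on their own mean and
    re-centered on the grand mean (removing between-participant offsets);
    the per-cell SD of the centered values is multiplied by sqrt(C/(C-1))
    and divided by sqrt(n).
    """
    cells = _check_cells(cells)
    n, C = cells.shape
    if n < 2:
        raise ValueError("within-subject SE needs at least 2 participants")
    centered = cells.sub(cells.mean(axis=1), axis=0) + cells.to_numpy().mean()
    return centered.std(ddof=1) * np.sqrt(C / (C - 1)) / np.sqrt(n)


def anova_to_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
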