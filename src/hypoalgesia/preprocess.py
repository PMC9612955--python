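"""Trial filtering, rescaling, and per-participant condition-cell means.

Rules applied before any inferential analysis:

- ratings answered faster than 150 ms are removed (the boundary value
  150 ms itself is kept — the criterion is strictly "faster than");
- on high-temperature trials classified "not painful", the pain rating is
  converted to 0;
- ratings are rescaled from the 0-100 visual-analogue scale to 0-1
  (``rating01``), which is the scale the mediation model is fitted on;
- trial number ``t`` and ``log t`` are carried as time covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "FilterReport",
    "filter_and_derive",
    "select_analysis_set",
    "cell_means",
]

RT_CUTOFF_MS = 150.0

REQUIRED_COLUMNS = [
    "participant_id",
    "trial",
    "task",
    "reward",
    "temperature",
    "performance",
    "pain_binary",
    "rating",
    "rating_rt_ms",
]


class SchemaError(ValueError):
    """Input table lacks required columns."""


@dataclass
class FilterReport:
    """Counts and removal fractions from the fast-response filter.

    Removal is reported against two denominators — all trials, and
    high-temperature trials only — since either could be the base of a
    quoted removal percentage.
    """

    n_input: int
    n_removed: int
    n_high_input: int
    n_high_removed: int

    @property
    def frac_removed(self) -> float:
        return self.n_removed / self.n_input if self.n_input else 0.0

    @property
    def frac_removed_of_high(self) -> float:
        return self.n_high_removed / self.n_high_input if self.n_high_input else 0.0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "frac_removed": self.frac_removed,
            "n_high_input": self.n_high_input,
            "n_high_removed": self.n_high_removed,
            "frac_removed_of_high": self.frac_removed_of_high,
        }


def filter_and_derive(table: pd.DataFrame) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the fast-response filter and derive analysis columns.

    Returns the cleaned table (new copy) plus a :class:`FilterReport`.
    Derived columns: ``t`` (trial number), ``log_t``, ``pain0`` (rating with
    non-painful classifications set to 0), and ``rating01`` (``pain0``/100 on
    high-temperature rows, ``rating``/100 on low-temperature rows).  The
    operation is idempotent.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    high = table["temperature"].astype(str).str.upper() == "HIGH"
    fast = table["rating_rt_ms"].to_numpy(float) < RT_CUTOFF_MS
    report = FilterReport(
        n_input=len(table),
        n_removed=int(fast.sum()),
        n_high_input=int(high.sum()),
        n_high_removed=int((fast & high.to_numpy()).sum()),
    )
    out = table.loc[~fast].copy()
    out["t"] = out["trial"].astype(float)
    out["log_t"] = np.log(out["t"]) if len(out) else pd.Series(dtype=float)
    painful = out["pain_binary"].astype(str).str.lower().str.startswith("painful")
    out["pain0"] = np.where(painful, out["rating"].to_numpy(float), 0.0)
    high_kept = out["temperature"].astype(str).str.upper() == "HIGH"
    out["rating01"] = np.where(
        high_kept, out["pain0"].to_numpy(float), out["rating"].to_numpy(float)
    ) / 100.0
    return out, report


def select_analysis_set(table: pd.DataFrame, analysis: str) -> pd.DataFrame:
    """Restrict to the rows an analysis uses.

    ``"PAIN"`` keeps high-temperature trials only (pain analyses);
    ``"PERFORMANCE"`` keeps 2-back trials only (the easy arrow task is at
    ceiling and carries no performance signal).
    """
    key = analysis.upper()
    if key == "PAIN":
        out = table[table["temperature"].astype(str).str.upper() == "HIGH"]
    elif key == "PERFORMANCE":
        out = table[table["task"].astype(str).str.lower().isin(["2back", "two_back", "twoback"])]
    else:
        raise ValueError(f"unknown analysis {analysis!r}; expected 'PAIN' or 'PERFORMANCE'")
    if len(out) == 0 and len(table) > 0:
        warnings.warn(f"analysis set {key} is empty", stacklevel=2)
    return out.copy()


def cell_means(
    table: pd.DataFrame,
    factors: tuple[str, str] = ("task", "reward"),
    value: str = "pain0",
) -> pd.DataFrame:
    """Participants x condition-cells matrix of means.

    Columns are a MultiIndex over the two factors' levels.  Participants
    missing any cell are dropped listwise (with a warning), mirroring the
    complete-cells requirement of a repeated-measures ANOVA.
    """
    wide = table.pivot_table(
        index="participant_id", columns=list(factors), values=value, aggfunc="mean"
    )
    incomplete = wide.index[wide.isna().any(axis=1)]
    if len(incomplete):
        warnings.warn(
            f"dropping {len(incomplete)} participant(s) with empty cells: "
            f"{list(incomplete)}",
            stacklevel=2,
        )
        wide = wide.drop(index=incomplete)
    return wide
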