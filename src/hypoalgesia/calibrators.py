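"""Per-participant calibration procedures.

Three calibrations precede the main task:

1. **Thermal** — a method-of-constant-stimuli series (7 temperatures x 4
   sites, 28 stimulations) rated on 0-100 warmth or pain scales.  A
   temperature-response line is fitted per branch and inverted to find the
   low (warmth 80/100) and high (pain 60/100) stimulus temperatures.
2. **ISI staircase** — 15 trials of the 2-back task with the interstimulus
   interval updated after each trial to bring the A sensitivity into the
   0.75-0.85 band.
3. **Monetary** — 26 pain-for-money choices fitted with a logistic
   regression; the calibrated reward is the offer accepted 95% of the time,
   clamped to [$0.50, $3.00].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import spearmanr

from hypoalgesia.performance_sdt import ResponseStream, score_stream
from hypoalgesia.synthetic_cohort import ISI_MAX_MS, ISI_MIN_MS

__all__ = [
    "CalibrationError",
    "ThermalCalibration",
    "ISICalibration",
    "MoneyCalibration",
    "fit_thermal_curve",
    "run_isi_staircase",
    "fit_money_acceptance",
]

LOGIT_95 = math.log(19.0)  # logit(0.95)
AMOUNT_MIN, AMOUNT_MAX = 0.50, 3.00
TEMP_MIN, TEMP_MAX = 40.0, 49.0


class CalibrationError(RuntimeError):
    """A calibration procedure could not produce a usable setting."""


# --------------------------------------------------------------------------
# thermal
# --------------------------------------------------------------------------


@dataclass
class ThermalCalibration:
    """Fitted temperature-response lines and the two inverted thresholds."""

    warmth_intercept: float
    warmth_slope: float
    pain_intercept: float
    pain_slope: float
    low_temp: float  # warmth(T) = 80
    high_temp: float  # pain(T) = 60
    n_rows: int
    used_isotonic_warmth: bool = False
    used_isotonic_pain: bool = False

    def warmth(self, temp: float) -> float:
        return self.warmth_intercept + self.warmth_slope * temp

    def pain(self, temp: float) -> float:
        return self.pain_intercept + self.pain_slope * temp


def _invert_branch(
    temps: np.ndarray, ratings: np.ndarray, target: float, label: str
) -> tuple[float, float, float, bool]:
    """Fit rating ~ temperature and solve rating(T) = target.

    Ordinary least squares first; if the fitted slope is not positive the
    branch falls back to isotonic regression inverted by interpolation.
    Returns (intercept, slope, solution, used_isotonic).
    """
    if len(np.unique(temps)) < 2:
        raise CalibrationError(
            f"{label} branch needs >=2 distinct temperatures, got {len(np.unique(temps))}"
        )
    slope, intercept = np.polyfit(temps, ratings, 1)
    if slope > 1e-9:
        return float(intercept), float(slope), float((target - intercept) / slope), False
    # non-increasing line: try a monotone (isotonic) fit and invert it
    from scipy.optimize import isotonic_regression

    order = np.argsort(temps)
    iso = isotonic_regression(ratings[order]).x
    t_sorted = temps[order]
    if iso.max() <= iso.min() or not (iso.min() <= target <= iso.max()):
        raise CalibrationError(
            f"{label} temperature-response curve is flat or never reaches "
            f"{target}/100; inversion undefined"
        )
    sol = float(np.interp(target, iso, t_sorted))
    return float(intercept), float(slope), sol, True


def fit_thermal_curve(ratings: pd.DataFrame) -> ThermalCalibration:
    """Calibrate the low (warmth 80) and high (pain 60) temperatures.

    ``ratings`` has one row per stimulation with columns ``temperature``,
    ``painful`` (0/1), and ``rating`` (0-100).  Warmth ratings (non-painful
    rows) and pain-intensity ratings (painful rows) are fitted separately;
    solutions are clipped to the stimulated range [40, 49] C.
    """
    required = {"temperature", "painful", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise CalibrationError(f"thermal table missing columns: {sorted(missing)}")
    warm = ratings[ratings["painful"] == 0]
    pain = ratings[ratings["painful"] == 1]
    if len(pain) == 0:
        raise CalibrationError(
            "no stimulation was rated painful at any temperature; "
            "the painful threshold cannot be calibrated"
        )
    if len(warm) == 0:
        raise CalibrationError("no non-painful stimulation; warmth branch empty")

    wi, ws, low, iso_w = _invert_branch(
        warm["temperature"].to_numpy(float), warm["rating"].to_numpy(float), 80.0, "warmth"
    )
    pi, ps, high, iso_p = _invert_branch(
        pain["temperature"].to_numpy(float), pain["rating"].to_numpy(float), 60.0, "pain"
    )
    low = float(np.clip(low, TEMP_MIN, TEMP_MAX))
    high = float(np.clip(high, TEMP_MIN, TEMP_MAX))
    if not low < high:
        warnings.warn(
            f"calibrated low temperature ({low:.2f} C) is not below the high "
            f"temperature ({high:.2f} C); check the rating table",
            stacklevel=2,
        )
    return ThermalCalibration(
        warmth_intercept=wi,
        warmth_slope=ws,
        pain_intercept=pi,
        pain_slope=ps,
        low_temp=low,
        high_temp=high,
        n_rows=len(ratings),
        used_isotonic_warmth=iso_w,
        used_isotonic_pain=iso_p,
    )


# --------------------------------------------------------------------------
# ISI staircase
# --------------------------------------------------------------------------


@dataclass
class ISICalibration:
    """Staircase trajectory and the calibrated interstimulus interval."""

    trajectory: list[tuple[float, float]]  # (isi_ms tested, A observed)
    final_isi: float
    monotone_suspect: bool = False


def run_isi_staircase(
    observer,
    n_trials: int = 15,
    band: tuple[float, float] = (0.75, 0.85),
    *,
    start_isi: float = 1250.0,
    initial_factor: float = 1.5,
    min_factor: float = 1.02,
) -> ISICalibration:
    """Titrate the 2-back ISI toward the target performance band.

    ``observer`` is called with the current ISI (ms) and must return either a
    scalar A for that trial or a :class:`ResponseStream` to be scored.  After
    each trial: A above the band shortens the ISI (harder), A below lengthens
    it (easier), A inside holds.  Steps are multiplicative (x / / 1.5 at the
    start) and the step factor's excess over 1 is halved after every
    direction reversal, so the procedure brackets its target within the
    15-trial budget.  The returned ISI is the geometric mean of the last few
    reversal points (the usual variance-reducing staircase estimate); runs
    with fewer than two reversals return the terminal ISI.  All values are
    clamped to the displayable [19, 2583] ms.

    An observer whose measured A correlates *negatively* with ISI over the
    run contradicts the assumed monotone difficulty curve; the result is
    still returned but flagged ``monotone_suspect``.
    """
    isi = float(np.clip(start_isi, ISI_MIN_MS, ISI_MAX_MS))
    factor = float(initial_factor)
    last_direction = 0
    trajectory: list[tuple[float, float]] = []
    reversals: list[float] = []
    for _ in range(int(n_trials)):
        out = observer(isi)
        if isinstance(out, ResponseStream):
            out = score_stream(out).A
        A = float(out)
        trajectory.append((isi, A))
        if A > band[1]:
            direction = -1
        elif A < band[0]:
            direction = +1
        else:
            direction = 0
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                factor = max(1.0 + (factor - 1.0) / 2.0, min_factor)
                reversals.append(isi)
            isi = isi * factor if direction > 0 else isi / factor
            isi = float(np.clip(isi, ISI_MIN_MS, ISI_MAX_MS))
            last_direction = direction
    # the calibrated ISI: geometric mean of the last few reversal points
    # (steps are multiplicative), falling back to the terminal value when
    # the run produced fewer than two reversals
    if len(reversals) >= 2:
        tail = np.log(reversals[-4:] + [isi])
        isi = float(np.clip(np.exp(tail.mean()), ISI_MIN_MS, ISI_MAX_MS))
    suspect = False
    isis = np.array([p[0] for p in trajectory])
    scores = np.array([p[1] for p in trajectory])
    if len(np.unique(isis)) >= 4 and np.std(scores) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearmanr(isis, scores).statistic
        if np.isfinite(rho) and rho < -0.5:
            suspect = True
    return ISICalibration(trajectory=trajectory, final_isi=isi, monotone_suspect=suspect)


# --------------------------------------------------------------------------
# monetary
# --------------------------------------------------------------------------


@dataclass
class MoneyCalibration:
    """Logistic pain-for-money value function and the 95%-acceptance offer."""

    intercept: float
    slope: float
    amount_95_unclamped: float
    amount_95: float
    separation: bool = False
    notes: list[str] = field(default_factory=list)

    def p_accept(self, offer) -> np.ndarray:
        return expit(self.intercept + self.slope * np.asarray(offer, dtype=float))


def fit_money_acceptance(choices: pd.DataFrame) -> MoneyCalibration:
    """Maximum-likelihood logistic fit of accept ~ offer.

    The calibrated amount is the offer with fitted acceptance probability
    0.95, i.e. ``(logit(0.95) - intercept) / slope``, clamped to
    [$0.50, $3.00].  Completely separated choice data (including all-accept
    and all-reject) have no finite MLE; those fall back to the midpoint
    between the highest rejected and lowest accepted offers (or the relevant
    extreme), with a note.  A non-positive fitted slope — money not making
    acceptance more likely — clamps the amount to $3.00.
    """
    offer = choices["offer"].to_numpy(float)
    accept = choices["accept"].to_numpy(int)
    acc, rej = offer[accept == 1], offer[accept == 0]

    def _fallback(note: str) -> MoneyCalibration:
        if len(acc) and len(rej):
            amt = 0.5 * (rej.max() + acc.min())
        elif len(acc):
            amt = float(acc.min())
        else:
            amt = float(AMOUNT_MAX)
        warnings.warn(f"monetary calibration: {note}", stacklevel=3)
        return MoneyCalibration(
            intercept=float("nan"),
            slope=float("nan"),
            amount_95_unclamped=float(amt),
            amount_95=float(np.clip(amt, AMOUNT_MIN, AMOUNT_MAX)),
            separation=True,
            notes=[note],
        )

    separated = len(acc) == 0 or len(rej) == 0 or rej.max() < acc.min()
    if separated:
        return _fallback("complete separation; using midpoint-between-extremes rule")

    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(accept, sm.add_constant(offer)).fit(disp=0)
        b0, b1 = map(float, fit.params)
    except Exception as exc:  # quasi-separation or non-convergence
        return _fallback(f"logistic fit failed ({exc}); using midpoint rule")

    notes: list[str] = []
    if b1 <= 0:
        notes.append("non-positive slope; amount clamped to $3.00")
        warnings.warn("monetary calibration: " + notes[-1], stacklevel=2)
        unclamped = float("inf")
        amount = AMOUNT_MAX
    else:
        unclamped = (LOGIT_95 - b0) / b1
        amount = float(np.clip(unclamped, AMOUNT_MIN, AMOUNT_MAX))
    return MoneyCalibration(
        intercept=b0,
        slope=b1,
        amount_95_unclamped=float(unclamped),
        amount_95=amount,
        notes=notes,
    )
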