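"""Nonparametric signal-detection sensitivity A and response-stream scoring.

Task performance on each trial is summarised by the nonparametric sensitivity
statistic A, computed from the hit rate H (proportion of targets answered
"same" / "left") and the false-alarm rate F (proportion of non-targets
answered "same" / "left").  A ranges over [0, 1]: 1 is perfect discrimination,
0.5 is chance, 0 means every response is incorrect.  Unlike d', A remains
defined when H or F sit at 0 or 1, which matters for near-ceiling easy-task
performance.

The statistic is the three-case rectified-area measure of Zhang & Mueller:

    F <= 0.5 <= H :  A = 3/4 + (H - F)/4 - F(1 - H)
    F <= H < 0.5  :  A = 3/4 + (H - F)/4 - F/(4H)
    0.5 < F <= H  :  A = 3/4 + (H - F)/4 - (1 - H)/(4(1 - F))

with A(H, F) = 1 - A(F, H) when F > H.  Exact chance performance H == F
(including the corners (0,0) and (1,1)) returns 0.5, preserving both the
chance anchor and the complement symmetry A(H,F) + A(F,H) = 1 everywhere.
For F = 0 < H < 0.5 the ratio F/(4H) is taken as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["a_sensitivity", "score_stream", "ResponseStream", "TrialScore"]


@dataclass
class ResponseStream:
    """A sequence of stimuli and the observer's binary responses.

    ``is_target`` flags signal stimuli (2-back match, or left arrow for the
    LR task); ``response_signal`` is True where the observer answered
    "same" (2-back) / "left" (LR).  ``None`` responses are omissions.
    """

    is_target: np.ndarray  # bool, shape (n,)
    response_signal: np.ndarray  # object array of {True, False, None}
    isi_ms: float = float("nan")
    task: str = "TWO_BACK"
    onsets_ms: np.ndarray | None = None

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.is_target)


@dataclass
class TrialScore:
    """Hit/false-alarm counts and the A sensitivity for one trial."""

    n_targets: int
    n_nontargets: int
    hits: int
    false_alarms: int
    degenerate: bool = False
    H: float = field(init=False)
    F: float = field(init=False)
    A: float = field(init=False)

    def __post_init__(self) -> None:
        self.H = self.hits / self.n_targets if self.n_targets else float("nan")
        self.F = (
            self.false_alarms / self.n_nontargets
            if self.n_nontargets
            else float("nan")
        )
        self.A = (
            a_sensitivity(self.H, self.F) if not self.degenerate else float("nan")
        )


def _a_upper(H: float, F: float) -> float:
    # upper triangle F <= H; exact H == F handled by the caller
    if F <= 0.5 <= H:
        return 0.75 + (H - F) / 4.0 - F * (1.0 - H)
    if H < 0.5:  # F <= H < 0.5
        ratio = 0.0 if F == 0.0 else F / (4.0 * H)
        return 0.75 + (H - F) / 4.0 - ratio
    # 0.5 < F <= H
    return 0.75 + (H - F) / 4.0 - (1.0 - H) / (4.0 * (1.0 - F))


def a_sensitivity(H: float, F: float) -> float:
    """Nonparametric sensitivity A from hit rate ``H`` and false-alarm rate ``F``.

    Parameters
    ----------
    H, F
        Rates in [0, 1].

    Returns
    -------
    float
        A in [0, 1]; 1 = perfect, 0.5 = chance (returned exactly whenever
        H == F), 0 = fully inverted responding.
    """
    H = float(H)
    F = float(F)
    if not (0.0 <= H <= 1.0 and 0.0 <= F <= 1.0):
        raise ValueError(f"H and F must lie in [0, 1]; got H={H}, F={F}")
    if H == F:
        return 0.5
    if F < H:
        return _a_upper(H, F)
    return 1.0 - _a_upper(F, H)


def score_stream(stream: ResponseStream, task: str | None = None) -> TrialScore:
    """Score one response stream into hits, false alarms, and A.

    For the 2-back task a "same" response on a 2-back match is a hit and a
    "same" response on a non-match is a false alarm.  For the LR arrow task
    the left arrow is (arbitrarily) the signal: "left" on a left arrow is a
    hit, "left" on a right arrow a false alarm.  A's complement symmetry
    makes the score invariant to which arrow is called the signal.

    Omitted responses count as incorrect for their stimulus category (a miss
    on targets, a correct rejection is *not* credited on non-targets — i.e.
    omissions never add hits or false alarms, so a non-target omission is
    effectively a correct rejection while a target omission is a miss; both
    are the conservative reading of "no response").

    Streams with no target or no non-target are flagged ``degenerate`` and
    carry A = NaN.
    """
    del task  # scoring rule is identical once the signal category is fixed
    if len(stream.is_target) == 0:
        raise ValueError("cannot score an empty response stream")
    tgt = np.asarray(stream.is_target, dtype=bool)
    resp = np.asarray(stream.response_signal, dtype=object)
    said_signal = np.array([r is not None and bool(r) for r in resp])
    n_targets = int(tgt.sum())
    n_nontargets = int((~tgt).sum())
    hits = int((said_signal & tgt).sum())
    fas = int((said_signal & ~tgt).sum())
    degenerate = n_targets < 1 or n_nontargets < 1
    return TrialScore(
        n_targets=n_targets,
        n_nontargets=n_nontargets,
        hits=hits,
        false_alarms=fas,
        degenerate=degenerate,
    )
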