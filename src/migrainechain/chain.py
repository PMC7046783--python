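"""Day-to-state mapping and transition tallies for the (n+2)-state chain.

The chain has a well/at-risk state ``S_W``, attack-day states ``S_1 .. S_n``
(``S_i`` means the previous day was the i-th consecutive migraine day), and —
when the Fill48 pipeline is used — a quarantine state ``S_Q`` occupied on the
day after an attack's first migraine-free day, from which the chain exits
deterministically back to ``S_W``.

Convention: a day's state is the chain state at the *start* of that day,
i.e. it is determined by the record up to and including the previous day;
the day's own record then determines which transition event the day
realises.  Concretely, for day ``d``:

* first diary day, or previous day free (and not a quarantine entry) → ``W``;
  a migraine on ``d`` is an *onset*, otherwise the day *stays* in ``W``;
* previous day was the k-th consecutive migraine day → state ``k``; a
  migraine on ``d`` is a *continuation* (the attack reaches day k+1),
  otherwise the attack *terminates*;
* quarantine enabled and the previous day was the first migraine-free day
  after a migraine day → ``Q``; the exit back to ``W`` is deterministic.

With quarantine disabled the post-attack day maps directly to ``W``.  The
onset probability μ is estimated as onsets / days-in-W and each continuation
probability δ_i as continuations-from-``S_i`` / days-in-``S_i``.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diary import Cohort, Diary
from .fill48 import find_locked_days, impute

__all__ = [
    "W_STATE",
    "Q_STATE",
    "StateSequence",
    "TransitionCounts",
    "ChainError",
    "map_states",
    "tally_transitions",
    "pool_counts",
    "diary_counts",
    "pooled_cohort_counts",
    "at_risk_day_table",
]

W_STATE = 0
Q_STATE = -1

EVENT_STAY_W = "stay_W"
EVENT_ONSET = "onset"
EVENT_CONTINUE = "continue"
EVENT_TERMINATE = "terminate"
EVENT_QUARANTINE_EXIT = "quarantine_exit"

_MODES = ("raw", "fill48")


class ChainError(ValueError):
    """The requested mapping is ill-defined for the given diary."""


def state_label(state: int) -> str:
    if state == W_STATE:
        return "W"
    if state == Q_STATE:
        return "Q"
    return str(state)


@dataclass(frozen=True)
class StateSequence:
    """Per-day chain states and transition events for one diary."""

    diary_id: str
    first_day: int
    migraine: np.ndarray  # the record the mapping was computed from
    states: np.ndarray  # int: 0=W, -1=Q, i>=1 = attack-day index
    events: tuple[str, ...]
    quarantine_enabled: bool

    @property
    def n_days(self) -> int:
        return int(self.states.size)

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.first_day, self.first_day + self.n_days)

    def state_labels(self) -> tuple[str, ...]:
        return tuple(state_label(int(s)) for s in self.states)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.diary_id,
                "day": self.days,
                "state": self.state_labels(),
                "event": list(self.events),
            }
        )


@dataclass(frozen=True)
class TransitionCounts:
    """Numerators and denominators for μ and the δ_i.

    ``cont_num[i-1] / cont_den[i-1]`` estimate δ_i; the tuples run from
    ``S_1`` up to the largest attack-day state observed (the empirical
    truncation bound n).  Every diary day contributes to exactly one tally:
    W days to the onset denominator, ``S_i`` days to ``cont_den[i-1]``, Q
    days to ``quarantine_days``.
    """

    onset_num: int
    onset_den: int
    cont_num: tuple[int, ...]
    cont_den: tuple[int, ...]
    quarantine_days: int = 0

    def __post_init__(self) -> None:
        if len(self.cont_num) != len(self.cont_den):
            raise ValueError("cont_num and cont_den must have equal length")
        if self.onset_num > self.onset_den or any(
            x > n for x, n in zip(self.cont_num, self.cont_den)
        ):
            raise ValueError("numerator exceeds denominator")
        if min((self.onset_num, self.onset_den, self.quarantine_days,
                *self.cont_num, *self.cont_den), default=0) < 0:
            raise ValueError("negative count")

    @property
    def n_max(self) -> int:
        """Empirical truncation bound: largest attack-day state observed."""
        return len(self.cont_den)

    @property
    def total_days(self) -> int:
        return self.onset_den + sum(self.cont_den) + self.quarantine_days


def map_states(diary: Diary, quarantine_enabled: bool = True) -> StateSequence:
    """Map each diary day to its start-of-day chain state and event.

    Raises
    ------
    ChainError
        If ``quarantine_enabled`` and the diary still contains a
        migraine-locked day (the quarantine semantics are ill-defined then);
        apply Fill48 imputation first.
    """
    if quarantine_enabled:
        locked = find_locked_days(diary)
        if locked.days:
            raise ChainError(
                f"diary {diary.patient_id!r} contains migraine-locked day(s) "
                f"{sorted(locked.days)}; apply Fill48 imputation before "
                "mapping with the quarantine state enabled"
            )
    m = diary.migraine
    n = m.size
    idx = np.arange(n)
    # k[d] = length of the consecutive migraine run ending at day d (0 if free)
    last_free = np.maximum.accumulate(np.where(~m, idx, -1))
    k = np.where(m, idx - last_free, 0)

    states = np.zeros(n, dtype=int)  # W by default (covers day 0)
    if n > 1:
        prev_mig = m[:-1]
        states[1:][prev_mig] = k[:-1][prev_mig]
        if quarantine_enabled and n > 2:
            # previous day free, day before that a migraine day -> quarantine
            q = ~m[1:-1] & m[:-2]
            states[2:][q] = Q_STATE

    events = np.empty(n, dtype=object)
    w = states == W_STATE
    events[w & m] = EVENT_ONSET
    events[w & ~m] = EVENT_STAY_W
    att = states >= 1
    events[att & m] = EVENT_CONTINUE
    events[att & ~m] = EVENT_TERMINATE
    events[states == Q_STATE] = EVENT_QUARANTINE_EXIT

    return StateSequence(
        diary_id=diary.patient_id,
        first_day=diary.first_day,
        migraine=m,
        states=states,
        events=tuple(events),
        quarantine_enabled=quarantine_enabled,
    )


def tally_transitions(
    seq: StateSequence, censor_edges: bool = False
) -> TransitionCounts:
    """Tally onset and continuation numerators/denominators from a mapping.

    With ``censor_edges=True`` a migraine run starting on the diary's first
    day — whose true onset is unobserved — is dropped from the tallies: the
    day-1 onset event, the run's continuation days and its terminating day
    contribute to neither numerators nor denominators.
    """
    states = seq.states
    m = seq.migraine
    keep = np.ones(states.size, dtype=bool)
    if censor_edges and m.size and m[0]:
        r = int(np.argmin(m)) if not m.all() else m.size  # leading run length
        keep[: min(r + 1, m.size)] = False  # onset day, run days, terminate day

    s = states[keep]
    mk = m[keep]
    onset_den = int((s == W_STATE).sum())
    onset_num = int(((s == W_STATE) & mk).sum())
    quarantine_days = int((s == Q_STATE).sum())
    n_max = int(s.max(initial=0))
    if n_max > 0:
        att = s >= 1
        cont_den = np.bincount(s[att], minlength=n_max + 1)[1:]
        cont_num = np.bincount(s[att & mk], minlength=n_max + 1)[1:]
    else:
        cont_den = cont_num = np.zeros(0, dtype=int)
    return TransitionCounts(
        onset_num=onset_num,
        onset_den=onset_den,
        cont_num=tuple(int(x) for x in cont_num),
        cont_den=tuple(int(x) for x in cont_den),
        quarantine_days=quarantine_days,
    )


def pool_counts(counts: Iterable[TransitionCounts]) -> TransitionCounts:
    """Element-wise sum over diaries; n is the largest i observed anywhere."""
    counts = list(counts)
    if not counts:
        raise ValueError("pool_counts needs at least one TransitionCounts")
    n_max = max(c.n_max for c in counts)

    def padded(tup: tuple[int, ...]) -> np.ndarray:
        out = np.zeros(n_max, dtype=int)
        out[: len(tup)] = tup
        return out

    return TransitionCounts(
        onset_num=sum(c.onset_num for c in counts),
        onset_den=sum(c.onset_den for c in counts),
        cont_num=tuple(int(x) for x in sum(padded(c.cont_num) for c in counts)),
        cont_den=tuple(int(x) for x in sum(padded(c.cont_den) for c in counts)),
        quarantine_days=sum(c.quarantine_days for c in counts),
    )


def _prepare(diary: Diary, mode: str, quarantine: bool | None) -> tuple[Diary, bool]:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    if mode == "fill48":
        return impute(diary), True if quarantine is None else quarantine
    return diary, False if quarantine is None else quarantine


def diary_counts(
    diary: Diary,
    mode: str = "fill48",
    censor_edges: bool = False,
    quarantine: bool | None = None,
) -> TransitionCounts:
    """Map and tally one diary under an analysis mode.

    ``fill48`` imputes locked days first and enables the quarantine state;
    ``raw`` analyses the record as-is with quarantine off.  ``quarantine``
    overrides the mode's default when not None.
    """
    d, q = _prepare(diary, mode, quarantine)
    return tally_transitions(map_states(d, quarantine_enabled=q), censor_edges)


def pooled_cohort_counts(
    cohort: Cohort,
    mode: str = "fill48",
    censor_edges: bool = False,
    quarantine: bool | None = None,
) -> TransitionCounts:
    """Pool the per-diary tallies of a whole cohort."""
    return pool_counts(
        diary_counts(d, mode=mode, censor_edges=censor_edges, quarantine=quarantine)
        for d in cohort
    )


def at_risk_day_table(
    cohort: Cohort,
    mode: str = "fill48",
    quarantine: bool | None = None,
) -> pd.DataFrame:
    """Day-level table of days at risk of continuing an attack.

    One row per diary day whose start-of-day state is some ``S_k`` (k ≥ 1):
    columns ``patient_id``, ``day``, ``k`` (number of immediately preceding
    consecutive migraine days) and ``migraine`` (1 if the attack continued
    on that day).  This is the design table for the logistic trend test.
    """
    frames = []
    for diary in cohort:
        d, q = _prepare(diary, mode, quarantine)
        seq = map_states(d, quarantine_enabled=q)
        at_risk = seq.states >= 1
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": d.patient_id,
                    "day": seq.days[at_risk],
                    "k": seq.states[at_risk],
                    "migraine": d.migraine[at_risk].astype(int),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["patient_id", "day", "k", "migraine"])
    return pd.concat(frames, ignore_index=True)
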