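"""Migraine-locked days and the Fill48 imputation.

A *migraine-locked day* is a migraine-free diary day whose immediately
preceding and immediately succeeding days are both migraine days.  Clinical
guidance regards headache returning within roughly 48 hours of relief as a
relapse of the same attack, so a single recorded free day wedged between two
migraine days is best read as a treated (or remitting) day *inside* one
attack rather than as an inter-attack day.  Fill48 therefore imputes every
locked day as a migraine day before attacks are counted: the migraine-day
count rises by the number of locked days and the attack count falls by the
same number, because each locked day merges exactly two runs.

Detection and imputation are simultaneous, on the input record: imputing a
locked day can never create a new locked day (its neighbours are already
migraine days), so a single pass is exact and the operation is idempotent.
Boundary days are never locked — one of their neighbours is unobserved.
"""

from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np

from .diary import Cohort, Diary

__all__ = ["LockedDaySet", "find_locked_days", "impute", "impute_cohort",
           "locked_days_per30"]


@dataclass(frozen=True)
class LockedDaySet:
    """The migraine-locked day numbers of one diary."""

    diary_id: str
    days: frozenset[int]

    def __len__(self) -> int:
        return len(self.days)

    def __iter__(self) -> Iterator[int]:
        return iter(sorted(self.days))

    def __contains__(self, day: int) -> bool:
        return day in self.days


def find_locked_days(diary: Diary) -> LockedDaySet:
    """Exactly the free days whose both neighbours are recorded migraine days."""
    m = diary.migraine
    if m.size < 3:
        return LockedDaySet(diary.patient_id, frozenset())
    interior = m[:-2] & ~m[1:-1] & m[2:]
    days = diary.first_day + 1 + np.flatnonzero(interior)
    return LockedDaySet(diary.patient_id, frozenset(int(d) for d in days))


def impute(diary: Diary) -> Diary:
    """Return a copy of ``diary`` with every locked day imputed as migraine.

    Imputed days get ``migraine=True`` and ``imputed=True``; all other
    records are untouched.  Idempotent: the result has no locked days.
    """
    locked = find_locked_days(diary)
    if not locked.days:
        return diary.replace()
    idx = np.fromiter(locked.days, dtype=int) - diary.first_day
    m = diary.migraine.copy()
    imp = diary.imputed.copy()
    m[idx] = True
    imp[idx] = True
    return diary.replace(migraine=m, imputed=imp)


def impute_cohort(cohort: Cohort) -> Cohort:
    return Cohort(impute(d) for d in cohort)


def locked_days_per30(diary: Diary) -> float:
    """Locked-day frequency per 30 observed days."""
    return 30.0 * len(find_locked_days(diary)) / diary.n_days
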