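"""Attack segmentation and descriptive statistics for diary cohorts.

A migraine *attack* is a maximal run of consecutive migraine days; the first
migraine-free day defines its end.  A run touching a diary boundary is
censored there (its true duration is only partially observed); censored
attacks are kept in all counts at their observed duration by default, with an
exclusion option for sensitivity analyses.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterator
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diary import Cohort, Diary
from .fill48 import find_locked_days, impute

__all__ = [
    "Attack",
    "AttackTable",
    "DiarySummary",
    "segment_attacks",
    "summarise_diary",
    "cohort_summary",
    "duration_histogram",
    "per_diary_table",
]

_MODES = ("raw", "fill48")


def _cohort_in_mode(cohort: Cohort, mode: str) -> Cohort:
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}, got {mode!r}")
    return Cohort(impute(d) for d in cohort) if mode == "fill48" else cohort


@dataclass(frozen=True)
class Attack:
    start_day: int
    duration_days: int
    left_censored: bool = False
    right_censored: bool = False

    @property
    def end_day(self) -> int:
        return self.start_day + self.duration_days - 1


@dataclass(frozen=True)
class AttackTable:
    diary_id: str
    attacks: tuple[Attack, ...]

    def __len__(self) -> int:
        return len(self.attacks)

    def __iter__(self) -> Iterator[Attack]:
        return iter(self.attacks)

    def durations(self) -> tuple[int, ...]:
        return tuple(a.duration_days for a in self.attacks)


@dataclass(frozen=True)
class DiarySummary:
    diary_id: str
    observed_days: int
    migraine_days: int
    attack_count: int
    locked_days: int
    migraine_days_per30: float
    locked_days_per30: float
    durations: tuple[int, ...]


def segment_attacks(diary: Diary) -> AttackTable:
    """One :class:`Attack` per maximal run of consecutive migraine days."""
    m = diary.migraine.astype(np.int8)
    edges = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # one past the run
    attacks = tuple(
        Attack(
            start_day=diary.first_day + int(s),
            duration_days=int(e - s),
            left_censored=s == 0,
            right_censored=e == diary.n_days,
        )
        for s, e in zip(starts, ends)
    )
    return AttackTable(diary.patient_id, attacks)


def summarise_diary(diary: Diary) -> DiarySummary:
    """Per-diary counts and per-30-day rates; locked days from the record as given."""
    table = segment_attacks(diary)
    locked = len(find_locked_days(diary))
    n = diary.n_days
    return DiarySummary(
        diary_id=diary.patient_id,
        observed_days=n,
        migraine_days=diary.n_migraine_days,
        attack_count=len(table),
        locked_days=locked,
        migraine_days_per30=30.0 * diary.n_migraine_days / n,
        locked_days_per30=30.0 * locked / n,
        durations=table.durations(),
    )


def per_diary_table(cohort: Cohort, mode: str = "raw") -> pd.DataFrame:
    """One row per diary with the :class:`DiarySummary` count fields.

    In ``fill48`` mode the counts are computed on the imputed diaries, while
    ``locked_days`` always refers to the raw record.
    """
    prepared = _cohort_in_mode(cohort, mode)
    rows = []
    for raw, d in zip(cohort, prepared):
        s = summarise_diary(d)
        locked = len(find_locked_days(raw))
        rows.append(
            {
                "patient_id": s.diary_id,
                "observed_days": s.observed_days,
                "migraine_days": s.migraine_days,
                "attacks": s.attack_count,
                "locked_days": locked,
                "migraine_days_per30": s.migraine_days_per30,
                "locked_days_per30": 30.0 * locked / s.observed_days,
            }
        )
    return pd.DataFrame(rows)


def _spread(values: np.ndarray) -> dict[str, float]:
    # linear-interpolation quantiles for the IQR endpoints
    return {
        "median": float(np.median(values)),
        "iqr_low": float(np.percentile(values, 25)),
        "iqr_high": float(np.percentile(values, 75)),
        "mean": float(np.mean(values)),
    }


def cohort_summary(
    cohort: Cohort, mode: str = "raw", include_censored: bool = True
) -> pd.DataFrame:
    """Cohort-level descriptive table: median, IQR and mean per statistic.

    Per-diary statistics (observed days, migraine days, attacks, rates,
    locked days per 30) are aggregated over diaries.  Attack durations are
    pooled over all attacks of all diaries, so that with censored attacks
    included the pooled mean duration equals total migraine days divided by
    total attacks.

    Parameters
    ----------
    mode : {"raw", "fill48"}
        ``fill48`` applies the imputation first (locked-day rows still refer
        to the raw records).
    include_censored : bool
        If False, attacks touching a diary boundary are dropped from attack
        counts and duration statistics (sensitivity analysis).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    prepared = _cohort_in_mode(cohort, mode)

    per_diary: dict[str, list[float]] = {
        "observed_days": [],
        "locked_days_per30": [],
        "migraine_days": [],
        "attacks": [],
        "migraine_days_per30": [],
    }
    pooled_durations: list[int] = []
    for raw, d in zip(cohort, prepared):
        table = segment_attacks(d)
        attacks = [
            a
            for a in table
            if include_censored or not (a.left_censored or a.right_censored)
        ]
        per_diary["observed_days"].append(d.n_days)
        per_diary["locked_days_per30"].append(locked_per30 := 30.0 * len(find_locked_days(raw)) / raw.n_days)
        per_diary["migraine_days"].append(d.n_migraine_days)
        per_diary["attacks"].append(len(attacks))
        per_diary["migraine_days_per30"].append(30.0 * d.n_migraine_days / d.n_days)
        pooled_durations.extend(a.duration_days for a in attacks)

    rows = {stat: _spread(np.asarray(vals)) for stat, vals in per_diary.items()}
    if pooled_durations:
        rows["attack_duration"] = _spread(np.asarray(pooled_durations, dtype=float))
    else:
        rows["attack_duration"] = dict.fromkeys(
            ("median", "iqr_low", "iqr_high", "mean"), float("nan")
        )
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["median", "iqr_low", "iqr_high", "mean"]
    ]


def duration_histogram(
    cohort: Cohort, mode: str = "raw", include_censored: bool = True
) -> dict[int, int]:
    """Counts of attacks by duration (days), pooled over the cohort."""
    prepared = _cohort_in_mode(cohort, mode)
    counts: Counter[int] = Counter()
    for d in prepared:
        for a in segment_attacks(d):
            if include_censored or not (a.left_censored or a.right_censored):
                counts[a.duration_days] += 1
    return dict(sorted(counts.items()))
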