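"""Data model, validation and I/O for daily headache diaries.

A headache diary is an ordered run of *consecutive* calendar days on which a
patient recorded, for each day, whether a migraine headache occurred.  Days
are numbered by integers (1-based by convention, but a diary may start at any
day number — excerpts are common).  Each day additionally carries an
``imputed`` provenance flag, set only by the Fill48 imputation step, so that
raw records and imputed records remain distinguishable downstream.

Two plain-text serialisations are supported:

``long``
    Delimited table with header ``patient_id,day,migraine[,imputed]`` and one
    row per patient-day.  The optional ``imputed`` column preserves
    provenance across a write/read round trip.

``symbol``
    One line per patient, ``<patient_id>: <string>``, where the string is a
    character per day: ``M`` a recorded migraine day, ``-`` a migraine-free
    day, and ``m`` an imputed migraine day.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Iterator, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DayRecord",
    "Diary",
    "Cohort",
    "DiaryError",
    "DiaryParseError",
    "DiaryValidationError",
    "read_diaries",
    "write_diaries",
    "worked_example",
]

LONG_COLUMNS = ("patient_id", "day", "migraine")

_SYMBOLS = {"M": (True, False), "m": (True, True), "-": (False, False)}


class DiaryError(ValueError):
    """Base class for diary parsing and validation problems."""


class DiaryParseError(DiaryError):
    """A file could not be parsed as a diary serialisation."""


class DiaryValidationError(DiaryError):
    """A parsed diary violates a structural invariant."""


@dataclass(frozen=True)
class DayRecord:
    """A single patient-day: day number, migraine flag, imputation provenance."""

    day: int
    migraine: bool
    imputed: bool = False

    def __post_init__(self) -> None:
        if self.imputed and not self.migraine:
            raise DiaryValidationError(
                f"day {self.day}: an imputed day must be a migraine day"
            )


class Diary:
    """One patient's diary: contiguous days with binary migraine flags.

    Parameters
    ----------
    patient_id : str
        Opaque identifier, unique within a :class:`Cohort`.
    migraine : array-like of bool or 0/1
        Migraine flag per day, in day order; at least one day.
    first_day : int, default 1
        Day number of the first record; days are then contiguous.
    imputed : array-like of bool, optional
        Provenance flags (set by Fill48); an imputed day must be a migraine
        day.  Defaults to all-False.
    age_years, sex : optional metadata, never used by any computation.
    """

    __slots__ = ("patient_id", "first_day", "migraine", "imputed", "age_years", "sex")

    def __init__(
        self,
        patient_id: str,
        migraine: Sequence[int] | np.ndarray,
        first_day: int = 1,
        imputed: Sequence[int] | np.ndarray | None = None,
        age_years: float | None = None,
        sex: str | None = None,
    ) -> None:
        m = np.asarray(migraine)
        if m.ndim != 1 or m.size == 0:
            raise DiaryValidationError(
                f"diary {patient_id!r}: needs at least one day of records"
            )
        if m.dtype != np.bool_:
            if not np.isin(m, (0, 1)).all():
                raise DiaryValidationError(
                    f"diary {patient_id!r}: migraine flags must be binary"
                )
            m = m.astype(bool)
        if imputed is None:
            imp = np.zeros(m.size, dtype=bool)
        else:
            imp = np.asarray(imputed)
            if imp.shape != m.shape:
                raise DiaryValidationError(
                    f"diary {patient_id!r}: imputed flags must match day count"
                )
            if imp.dtype != np.bool_:
                if not np.isin(imp, (0, 1)).all():
                    raise DiaryValidationError(
                        f"diary {patient_id!r}: imputed flags must be binary"
                    )
                imp = imp.astype(bool)
            if (imp & ~m).any():
                bad = int(np.flatnonzero(imp & ~m)[0]) + int(first_day)
                raise DiaryValidationError(
                    f"diary {patient_id!r}: day {bad} marked imputed but migraine-free"
                )
        if age_years is not None and age_years < 0:
            raise DiaryValidationError(f"diary {patient_id!r}: negative age")
        self.patient_id = str(patient_id)
        self.first_day = int(first_day)
        m.setflags(write=False)
        imp.setflags(write=False)
        self.migraine = m
        self.imputed = imp
        self.age_years = age_years
        self.sex = sex

    # -- basic protocol ----------------------------------------------------
    @property
    def n_days(self) -> int:
        return int(self.migraine.size)

    def __len__(self) -> int:
        return self.n_days

    @property
    def last_day(self) -> int:
        return self.first_day + self.n_days - 1

    @property
    def days(self) -> np.ndarray:
        """Day numbers, ``first_day .. last_day`` inclusive."""
        return np.arange(self.first_day, self.last_day + 1)

    @property
    def n_migraine_days(self) -> int:
        return int(self.migraine.sum())

    @property
    def n_imputed_days(self) -> int:
        return int(self.imputed.sum())

    @property
    def migraine_day_numbers(self) -> tuple[int, ...]:
        return tuple(int(d) for d in self.days[self.migraine])

    def records(self) -> Iterator[DayRecord]:
        for d, m, i in zip(self.days, self.migraine, self.imputed):
            yield DayRecord(int(d), bool(m), bool(i))

    def replace(self, **kwargs) -> "Diary":
        """Copy with selected fields replaced (arrays are re-validated)."""
        init = dict(
            patient_id=self.patient_id,
            migraine=self.migraine,
            first_day=self.first_day,
            imputed=self.imputed,
            age_years=self.age_years,
            sex=self.sex,
        )
        init.update(kwargs)
        return Diary(**init)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diary):
            return NotImplemented
        return (
            self.patient_id == other.patient_id
            and self.first_day == other.first_day
            and np.array_equal(self.migraine, other.migraine)
            and np.array_equal(self.imputed, other.imputed)
            and self.age_years == other.age_years
            and self.sex == other.sex
        )

    def __hash__(self) -> int:
        return hash((self.patient_id, self.first_day, self.migraine.tobytes()))

    def __repr__(self) -> str:
        return (
            f"Diary({self.patient_id!r}, days {self.first_day}-{self.last_day}, "
            f"{self.n_migraine_days}/{self.n_days} migraine days)"
        )

    # -- symbol strings ----------------------------------------------------
    def to_symbols(self) -> str:
        out = []
        for m, i in zip(self.migraine, self.imputed):
            out.append("m" if i else ("M" if m else "-"))
        return "".join(out)

    @classmethod
    def from_symbols(
        cls, patient_id: str, symbols: str, first_day: int = 1, **meta
    ) -> "Diary":
        bad = set(symbols) - set(_SYMBOLS)
        if bad:
            raise DiaryParseError(
                f"diary {patient_id!r}: invalid symbol(s) {sorted(bad)!r}; "
                "expected characters from 'M', 'm', '-'"
            )
        mig = np.array([_SYMBOLS[c][0] for c in symbols], dtype=bool)
        imp = np.array([_SYMBOLS[c][1] for c in symbols], dtype=bool)
        return cls(patient_id, mig, first_day=first_day, imputed=imp, **meta)


class Cohort:
    """An ordered collection of diaries with unique patient ids."""

    __slots__ = ("diaries",)

    def __init__(self, diaries: Iterable[Diary]) -> None:
        ds = tuple(diaries)
        ids = [d.patient_id for d in ds]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DiaryValidationError(f"duplicate patient ids: {dupes}")
        self.diaries = ds

    def __iter__(self) -> Iterator[Diary]:
        return iter(self.diaries)

    def __len__(self) -> int:
        return len(self.diaries)

    def __getitem__(self, key: int | str) -> Diary:
        if isinstance(key, str):
            for d in self.diaries:
                if d.patient_id == key:
                    return d
            raise KeyError(key)
        return self.diaries[key]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.diaries == other.diaries

    def __repr__(self) -> str:
        return f"Cohort({len(self)} diaries)"


def worked_example() -> Diary:
    """The nine-day illustrative diary (days 29-37).

    Migraine is recorded on days 30, 32, 35 and 36.  Day 31 is the single
    migraine-locked day (free, flanked by migraine days 30 and 32); the raw
    record holds 4 migraine days in 3 attacks, and Fill48 imputation turns it
    into 5 migraine days in 2 attacks.
    """
    return Diary.from_symbols("table1", "-M-M--MM-", first_day=29)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _split_contiguous(days: np.ndarray) -> list[np.ndarray]:
    """Index blocks of ``days`` (sorted, unique) that are contiguous runs."""
    breaks = np.flatnonzero(np.diff(days) != 1) + 1
    return np.split(np.arange(days.size), breaks)


def _read_long(path: Path, split_at_gaps: bool) -> Cohort:
    try:
        df = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.ParserError as exc:  # malformed CSV structure
        raise DiaryParseError(f"{path}: {exc}") from exc
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise DiaryParseError(f"{path}: missing column(s) {missing}")
    for col in ("day", "migraine") + (("imputed",) if "imputed" in df.columns else ()):
        num = pd.to_numeric(df[col], errors="coerce")
        bad = num.isna() | (num != num.round())
        if bad.any():
            line = int(bad[bad].index[0]) + 2  # +1 header, +1 one-based
            raise DiaryParseError(
                f"{path}: line {line}: non-integer value in column {col!r}"
            )
        as_int = num.astype(int)
        if col != "day" and not as_int.isin((0, 1)).all():
            line = int(as_int[~as_int.isin((0, 1))].index[0]) + 2
            raise DiaryParseError(f"{path}: line {line}: column {col!r} must be 0 or 1")
        df[col] = as_int

    diaries: list[Diary] = []
    for pid, grp in df.groupby("patient_id", sort=False):
        dup = grp["day"].duplicated()
        if dup.any():
            d = int(grp["day"][dup].iloc[0])
            raise DiaryValidationError(f"patient {pid!r}: duplicate day {d}")
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        mig = grp["migraine"].to_numpy()
        imp = grp["imputed"].to_numpy() if "imputed" in grp else None
        blocks = _split_contiguous(days)
        if len(blocks) > 1 and not split_at_gaps:
            gap_after = int(days[blocks[0][-1]])
            raise DiaryValidationError(
                f"patient {pid!r}: day {gap_after + 1} missing (non-contiguous "
                "diary; pass split_at_gaps=True to split into sub-diaries)"
            )
        for k, idx in enumerate(blocks):
            sub_id = pid if len(blocks) == 1 else f"{pid}.{k + 1}"
            diaries.append(
                Diary(
                    sub_id,
                    mig[idx],
                    first_day=int(days[idx[0]]),
                    imputed=None if imp is None else imp[idx],
                )
            )
    return Cohort(diaries)


def _read_symbol(path: Path, first_day: int) -> Cohort:
    diaries: list[Diary] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            pid, sep, body = line.partition(":")
            if not sep or not pid.strip():
                raise DiaryParseError(
                    f"{path}: line {lineno}: expected '<patient_id>: <symbols>'"
                )
            try:
                diaries.append(
                    Diary.from_symbols(pid.strip(), body.strip(), first_day=first_day)
                )
            except DiaryError as exc:
                raise DiaryParseError(f"{path}: line {lineno}: {exc}") from exc
    return Cohort(diaries)


def read_diaries(
    path: str | Path,
    fmt: str = "long",
    split_at_gaps: bool = False,
    first_day: int = 1,
) -> Cohort:
    """Read a cohort of diaries from ``path``.

    Parameters
    ----------
    fmt : {"long", "symbol"}
        Serialisation format (see module docstring).
    split_at_gaps : bool
        In ``long`` format, split a patient's records at missing days into
        suffixed sub-diaries (``pid.1``, ``pid.2`` …) instead of raising.
    first_day : int
        Day number of the first symbol in ``symbol`` format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "long":
        return _read_long(path, split_at_gaps)
    if fmt == "symbol":
        return _read_symbol(path, first_day)
    raise ValueError(f"unknown diary format {fmt!r}")


def write_diaries(cohort: Cohort, path: str | Path, fmt: str = "long") -> None:
    """Write ``cohort`` to ``path``; output re-reads to an equal cohort."""
    path = Path(path)
    if fmt == "long":
        frames = []
        for d in cohort:
            frames.append(
                pd.DataFrame(
                    {
                        "patient_id": d.patient_id,
                        "day": d.days,
                        "migraine": d.migraine.astype(int),
                        "imputed": d.imputed.astype(int),
                    }
                )
            )
        if frames:
            out = pd.concat(frames, ignore_index=True)
        else:
            out = pd.DataFrame(columns=list(LONG_COLUMNS) + ["imputed"])
        out.to_csv(path, index=False)
    elif fmt == "symbol":
        with open(path, "w") as fh:
            for d in cohort:
                fh.write(f"{d.patient_id}: {d.to_symbols()}\n")
    else:
        raise ValueError(f"unknown diary format {fmt!r}")
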