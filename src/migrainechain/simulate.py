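"""Generative simulator for the migraine-attack Markov chain.

Generates synthetic headache diaries from the (n+2)-state chain: on a well
day an attack begins with probability μ; on the i-th attack day the attack
continues with probability δ_i (a scalar δ applies to every i — the
collapsed, omnibus chain); when the quarantine state is enabled the day
after an attack's first free day is a forced free day before the chain
returns to the well state.  A truncation bound is implied by a vector δ:
states beyond its length reuse the last entry (the self-loop at S_n).

Cohort generation supports per-patient parameter heterogeneity (pass a
callable drawing :class:`ChainParams` per patient) and a treatment-masking
noise mode that flips interior attack days to migraine-free, manufacturing
migraine-locked days whose ground truth is exactly recoverable by Fill48.

All randomness flows through a named, seedable :class:`numpy.random.Generator`;
no global state is used.
"""

from __future__ import annotations

from collections.abc import Callable
from dataclasses import dataclass

import numpy as np

from .attacks import segment_attacks
from .diary import Cohort, Diary

__all__ = [
    "ChainParams",
    "CohortSpec",
    "simulate_diary",
    "apply_masking",
    "simulate_cohort",
    "expected_migraine_fraction",
]

_W, _Q = 0, -1


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class ChainParams:
    """Generative parameters of the chain.

    Parameters
    ----------
    mu : float
        Daily attack-onset probability from the well state.
    delta : float or sequence of float
        Continuation probability; a scalar is the duration-unconditional
        δ_Omni, a vector gives (δ_1, …, δ_n) with a self-loop at S_n.
    quarantine_enabled : bool
        Insert the forced quarantine free day after each attack.
    """

    mu: float
    delta: float | tuple[float, ...]
    quarantine_enabled: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.mu <= 1:
            raise ValueError(f"mu must be in [0,1], got {self.mu}")
        d = self.delta
        if np.isscalar(d):
            if not 0 <= d <= 1:
                raise ValueError(f"delta must be in [0,1], got {d}")
        else:
            d = tuple(float(x) for x in d)
            if not d:
                raise ValueError("vector delta must be non-empty")
            if any(not 0 <= x <= 1 for x in d):
                raise ValueError(f"delta entries must be in [0,1], got {d}")
            object.__setattr__(self, "delta", d)

    @property
    def is_scalar_delta(self) -> bool:
        return np.isscalar(self.delta)

    def delta_for_state(self, i: int) -> float:
        """δ_i, with the self-loop at the truncation bound for i beyond it."""
        if i < 1:
            raise ValueError("attack-day state index starts at 1")
        if self.is_scalar_delta:
            return float(self.delta)
        d = self.delta
        return d[min(i, len(d)) - 1]


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort.

    ``n_days`` is either a fixed diary length or an inclusive ``(low, high)``
    range sampled uniformly per patient.  ``params`` is either one
    :class:`ChainParams` shared by all patients or a callable drawing one per
    patient from the supplied generator (parameter heterogeneity).
    ``masking_prob`` is the per-interior-attack-day probability of flipping
    the record to migraine-free (see :func:`apply_masking`).
    """

    n_patients: int
    n_days: int | tuple[int, int]
    params: ChainParams | Callable[[np.random.Generator], ChainParams]
    masking_prob: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.masking_prob <= 1:
            raise ValueError("masking_prob must be in [0,1]")
        nd = self.n_days
        if not np.isscalar(nd):
            lo, hi = nd
            if not 1 <= lo <= hi:
                raise ValueError(f"invalid diary-length range {nd}")
        elif nd < 1:
            raise ValueError("n_days must be >= 1")


def simulate_diary(
    params: ChainParams,
    n_days: int,
    rng: np.random.Generator | int | None = None,
    patient_id: str = "sim",
    first_day: int = 1,
) -> Diary:
    """Simulate one diary of ``n_days`` days, starting in the well state."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = _as_rng(rng)
    m = np.zeros(n_days, dtype=bool)
    state = _W
    for d in range(n_days):
        if state == _Q:
            state = _W  # forced free day, deterministic exit
        elif state == _W:
            if rng.random() < params.mu:
                m[d] = True
                state = 1
        else:  # i-th attack day was yesterday
            if rng.random() < params.delta_for_state(state):
                m[d] = True
                state += 1
            else:
                state = _Q if params.quarantine_enabled else _W
    return Diary(patient_id, m, first_day=first_day)


def apply_masking(
    diary: Diary, rho: float, rng: np.random.Generator | int | None = None
) -> Diary:
    """Flip interior attack days to migraine-free, never two adjacent.

    Emulates single effectively-treated days inside ongoing attacks.  Each
    *interior* attack day (both neighbours are attack days) is masked with
    probability ``rho``, scanning left to right and skipping a day whose
    left neighbour was just masked — so masked days are never adjacent and
    never touch an attack boundary.  Every masked day is therefore a
    migraine-locked day of the output, and Fill48 imputation reconstructs
    the input exactly.
    """
    if not 0 <= rho <= 1:
        raise ValueError(f"rho must be in [0,1], got {rho}")
    rng = _as_rng(rng)
    if rho == 0:
        return diary.replace()
    m = diary.migraine.copy()
    imp = diary.imputed.copy()
    for attack in segment_attacks(diary):
        if attack.duration_days < 3:
            continue
        start = attack.start_day - diary.first_day
        prev_masked = False
        for pos in range(start + 1, start + attack.duration_days - 1):
            if not prev_masked and rng.random() < rho:
                m[pos] = False
                imp[pos] = False
                prev_masked = True
            else:
                prev_masked = False
    return diary.replace(migraine=m, imputed=imp)


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a cohort per ``spec``; fully reproducible given its seed."""
    rng = np.random.default_rng(spec.seed)
    width = max(3, len(str(spec.n_patients)))
    diaries = []
    for j in range(spec.n_patients):
        if np.isscalar(spec.n_days):
            n_days = int(spec.n_days)
        else:
            lo, hi = spec.n_days
            n_days = int(rng.integers(lo, hi + 1))
        params = spec.params(rng) if callable(spec.params) else spec.params
        d = simulate_diary(params, n_days, rng, patient_id=f"p{j + 1:0{width}d}")
        if spec.masking_prob > 0:
            d = apply_masking(d, spec.masking_prob, rng)
        diaries.append(d)
    return Cohort(diaries)


def expected_migraine_fraction(params: ChainParams) -> float:
    """Stationary fraction of migraine days under a scalar δ.

    A renewal cycle consists of a Geometric(μ) number of well-state days
    (mean 1/μ, the last of which is the attack's first migraine day), the
    attack's remaining days (total attack length is Geometric(1−δ), mean
    L = 1/(1−δ)), the terminating free day, and — if quarantine is enabled —
    one extra forced free day.  The mean cycle length is therefore
    (1/μ − 1) + L + 1 + c = 1/μ + L + c and the long-run migraine-day
    fraction is L / (1/μ + L + c), with c = 1 if quarantine is enabled,
    else 0.
    """
    if not params.is_scalar_delta:
        raise ValueError("closed form requires a scalar (omnibus) delta")
    mu, delta = params.mu, float(params.delta)
    if mu <= 0 or delta >= 1:
        raise ValueError("undefined for mu = 0 or delta = 1")
    L = 1.0 / (1.0 - delta)
    c = 1.0 if params.quarantine_enabled else 0.0
    return L / (1.0 / mu + L + c)
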