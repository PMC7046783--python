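"""Independent brute-force oracles for the test suite.

Everything here scans plain Python lists day by day, directly transcribing
the verbal definitions (maximal runs, locked days, start-of-day states), and
deliberately shares no code with the package implementation.
"""

from __future__ import annotations

from itertools import product


def enumerate_flag_strings(max_len: int, min_len: int = 1):
    """Every binary diary of length min_len..max_len, as tuples of bool."""
    for length in range(min_len, max_len + 1):
        yield from product((False, True), repeat=length)


def runs_naive(flags) -> list[tuple[int, int]]:
    """Maximal migraine runs as (start_index, length), 0-based."""
    out = []
    i, n = 0, len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j < n and flags[j]:
                j += 1
            out.append((i, j - i))
            i = j
        else:
            i += 1
    return out


def locked_days_naive(flags) -> list[int]:
    """0-based indices of free days flanked by migraine days on both sides."""
    return [
        i
        for i in range(1, len(flags) - 1)
        if not flags[i] and flags[i - 1] and flags[i + 1]
    ]


def impute_naive(flags) -> list[bool]:
    locked = set(locked_days_naive(flags))
    return [bool(f) or (i in locked) for i, f in enumerate(flags)]


def map_states_naive(flags, quarantine: bool) -> list[object]:
    """Start-of-day states: 'W', 'Q', or int k >= 1 (k prior migraine days)."""
    states: list[object] = []
    for d in range(len(flags)):
        if d == 0:
            states.append("W")
        elif flags[d - 1]:
            k = 0
            j = d - 1
            while j >= 0 and flags[j]:
                k += 1
                j -= 1
            states.append(k)
        elif quarantine and d >= 2 and flags[d - 2] and not flags[d - 1]:
            states.append("Q")
        else:
            states.append("W")
    return states


def events_naive(states, flags) -> list[str]:
    out = []
    for s, m in zip(states, flags):
        if s == "W":
            out.append("onset" if m else "stay_W")
        elif s == "Q":
            out.append("quarantine_exit")
        else:
            out.append("continue" if m else "terminate")
    return out


def tally_naive(states, flags) -> dict[str, object]:
    """Frequency tallies straight off the naive state list."""
    onset_den = sum(1 for s in states if s == "W")
    onset_num = sum(1 for s, m in zip(states, flags) if s == "W" and m)
    q_days = sum(1 for s in states if s == "Q")
    ks = [s for s in states if isinstance(s, int)]
    n_max = max(ks, default=0)
    cont_den = [sum(1 for s in ks if s == i) for i in range(1, n_max + 1)]
    cont_num = [
        sum(1 for s, m in zip(states, flags) if s == i and m)
        for i in range(1, n_max + 1)
    ]
    return {
        "onset_num": onset_num,
        "onset_den": onset_den,
        "cont_num": tuple(cont_num),
        "cont_den": tuple(cont_den),
        "quarantine_days": q_days,
    }


def omnibus_naive(flags) -> tuple[int, int]:
    """Collapsed two-state continuation tally: days preceded by a migraine day."""
    x = n = 0
    for d in range(1, len(flags)):
        if flags[d - 1]:
            n += 1
            x += bool(flags[d])
    return x, n
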