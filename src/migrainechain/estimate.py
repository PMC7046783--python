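"""Transition-probability estimation, trend tests and the diary bootstrap.

Point estimates are Bernoulli frequencies (onsets / at-risk days for μ,
continuations / days-in-state for each δ_i) with 95% continuity-corrected
Wilson score intervals.  The omnibus continuation probability δ_Omni pools
all attack-day states: the probability that an attack continues once begun,
without conditioning on how long it has lasted.  Trend in the δ_i is tested
two ways — an N-weighted least-squares regression of the δ̂_i on i, and a
day-level logistic regression of the continuation indicator on the number of
preceding consecutive migraine days.  Uncertainty of the pooled estimates is
assessed with a patient-level bootstrap: whole diaries are resampled with
replacement and the pooled μ̂ and δ̂_Omni recomputed per replicate.
"""

from __future__ import annotations

import logging
import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .chain import TransitionCounts, diary_counts
from .diary import Cohort

__all__ = [
    "ProportionEstimate",
    "TrendTestResult",
    "IndividualTPs",
    "BootstrapResult",
    "UndefinedEstimateError",
    "wilson_cc_interval",
    "estimate_tps",
    "estimate_omnibus",
    "trend_test_wls",
    "trend_test_logistic",
    "individual_tps",
    "bootstrap_tps",
]

logger = logging.getLogger(__name__)


class UndefinedEstimateError(ValueError):
    """An estimate was requested from an empty denominator."""


@dataclass(frozen=True)
class ProportionEstimate:
    """A Bernoulli probability estimate x/n with a confidence interval."""

    label: str
    x: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    def __str__(self) -> str:
        return (
            f"{self.label}: {self.p_hat:.3f} "
            f"({self.ci_low:.3f}, {self.ci_high:.3f}) [N={self.n}]"
        )


def wilson_cc_interval(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Continuity-corrected Wilson score interval for a binomial proportion.

    With p̂ = x/n and z the standard-normal quantile at (1+conf)/2::

        low  = max(0, (2np̂ + z² − 1 − z·sqrt(z² − 2 − 1/n + 4p̂(n(1−p̂)+1)))
                      / (2(n+z²)))
        high = min(1, (2np̂ + z² + 1 + z·sqrt(z² + 2 − 1/n + 4p̂(n(1−p̂)−1)))
                      / (2(n+z²)))

    with ``low = 0`` when x = 0 and ``high = 1`` when x = n.  The z quantile
    is computed exactly, not rounded to 1.96.
    """
    if n < 1:
        raise UndefinedEstimateError("interval undefined for n = 0")
    if not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n, got x={x}, n={n}")
    if not 0 < conf < 1:
        raise ValueError(f"confidence level must be in (0,1), got {conf}")
    z = stats.norm.ppf((1 + conf) / 2)
    p = x / n
    denom = 2 * (n + z * z)
    if x == 0:
        low = 0.0
    else:
        low = (2 * n * p + z * z - 1
               - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))) / denom
        low = max(0.0, low)
    if x == n:
        high = 1.0
    else:
        high = (2 * n * p + z * z + 1
                + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))) / denom
        high = min(1.0, high)
    return low, high


def _proportion(label: str, x: int, n: int, conf: float) -> ProportionEstimate:
    low, high = wilson_cc_interval(x, n, conf)
    return ProportionEstimate(label, x, n, x / n, low, high, conf)


def estimate_tps(
    counts: TransitionCounts, conf: float = 0.95
) -> list[ProportionEstimate]:
    """Point estimates with CIs for μ and every δ_i with a nonzero denominator.

    Parameters with empty denominators are skipped with a logged notice.
    """
    out: list[ProportionEstimate] = []
    if counts.onset_den > 0:
        out.append(_proportion("mu", counts.onset_num, counts.onset_den, conf))
    else:
        logger.info("mu skipped: no at-risk (S_W) days observed")
    for i, (x, n) in enumerate(zip(counts.cont_num, counts.cont_den), start=1):
        if n > 0:
            out.append(_proportion(f"delta_{i}", x, n, conf))
        else:
            logger.info("delta_%d skipped: zero denominator", i)
    return out


def estimate_omnibus(counts: TransitionCounts, conf: float = 0.95) -> ProportionEstimate:
    """Pooled, duration-unconditional continuation probability δ_Omni."""
    n = sum(counts.cont_den)
    if n < 1:
        raise UndefinedEstimateError(
            "delta_Omni undefined: no attack-day observations"
        )
    x = sum(counts.cont_num)
    return _proportion("delta_omni", x, n, conf)


@dataclass(frozen=True)
class TrendTestResult:
    """Outcome of a trend test of the δ_i against attack duration i."""

    method: str  # "weighted_ls" or "logistic"
    slope: float  # WLS slope, or logistic coefficient on k (nan if categorical)
    p_value: float
    detail: str = ""


def trend_test_wls(estimates: Sequence[ProportionEstimate]) -> TrendTestResult:
    """N-weighted least-squares regression of the δ̂_i on i.

    Takes the output of :func:`estimate_tps` (the ``delta_i`` entries are
    extracted; ``mu``/``delta_omni`` entries are ignored).  Weights are the
    denominators N_i, so the slope is invariant to rescaling all N_i.  A
    perfect fit (zero residual variance) is reported with p = 1 when the
    slope is zero and p = 0 otherwise.
    """
    pts = [
        (int(e.label.split("_")[1]), e.p_hat, e.n)
        for e in estimates
        if e.label.startswith("delta_") and e.label != "delta_omni"
    ]
    if len({i for i, _, _ in pts}) < 3:
        raise UndefinedEstimateError(
            "trend test needs at least 3 distinct attack-day states"
        )
    i = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts])
    w = np.array([p[2] for p in pts], dtype=float)
    res = sm.WLS(y, sm.add_constant(i), weights=w).fit()
    slope = float(res.params[1])
    p_value = float(res.pvalues[1])
    if not math.isfinite(p_value) or res.ssr < 1e-12:
        p_value = 1.0 if abs(slope) < 1e-9 else 0.0
    return TrendTestResult(
        "weighted_ls", slope, p_value, detail=f"{len(pts)} points, N-weighted"
    )


def trend_test_logistic(
    day_table: pd.DataFrame, coding: str = "linear"
) -> TrendTestResult:
    """Logistic regression of day-level continuation on attack duration so far.

    ``day_table`` is the output of :func:`migrainechain.chain.at_risk_day_table`:
    one row per day at risk of continuing, with ``migraine`` the day's
    outcome and ``k`` the number of immediately preceding consecutive
    migraine days.

    With ``coding="linear"`` the model is ``migraine ~ k`` and the Wald
    p-value of the ``k`` coefficient is reported.  With
    ``coding="categorical"`` each k gets its own dummy and a likelihood-ratio
    test against the constant-probability model is reported (slope is nan).
    Perfect separation is caught and flagged in ``detail`` with p-value nan.
    """
    if coding not in ("linear", "categorical"):
        raise ValueError(f"unknown coding {coding!r}")
    y = day_table["migraine"].to_numpy(dtype=float)
    k = day_table["k"].to_numpy(dtype=float)
    if y.size == 0:
        raise UndefinedEstimateError("no at-risk days")
    if np.unique(k).size < 2:
        raise UndefinedEstimateError(
            "all at-risk days share one duration k: no contrast to test"
        )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if coding == "linear":
                X = sm.add_constant(k)
                res = sm.Logit(y, X).fit(disp=0)
                return TrendTestResult(
                    "logistic", float(res.params[1]), float(res.pvalues[1]),
                    detail="linear in k",
                )
            dummies = pd.get_dummies(k.astype(int), drop_first=True, dtype=float)
            X = sm.add_constant(dummies.to_numpy())
            res = sm.Logit(y, X).fit(disp=0)
            null = sm.Logit(y, np.ones_like(y)).fit(disp=0)
            lr = 2 * (res.llf - null.llf)
            df = X.shape[1] - 1
            p = float(stats.chi2.sf(lr, df))
            return TrendTestResult(
                "logistic", float("nan"), p, detail=f"categorical k, LR df={df}"
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        return TrendTestResult(
            "logistic", float("nan"), float("nan"), detail=f"separation: {exc}"
        )


# ---------------------------------------------------------------------------
# per-patient estimates and the bootstrap
# ---------------------------------------------------------------------------

def _per_diary_mu_domni(
    cohort: Cohort, mode: str, censor_edges: bool = False
) -> np.ndarray:
    """(P, 4) array: onset_num, onset_den, Σ cont_num, Σ cont_den per diary."""
    rows = np.zeros((len(cohort), 4), dtype=float)
    for j, d in enumerate(cohort):
        c = diary_counts(d, mode=mode, censor_edges=censor_edges)
        rows[j] = (c.onset_num, c.onset_den, sum(c.cont_num), sum(c.cont_den))
    return rows


@dataclass(frozen=True)
class IndividualTPs:
    """Per-patient μ̂_j and δ̂_Omni,j with cohort percentile summaries.

    ``table`` has one row per diary (``mu_hat`` / ``delta_omni_hat`` are NaN
    when the diary has no corresponding observations); ``summary`` has rows
    ``mu`` and ``delta_omni`` with the median and the central-95% range
    (2.5th-97.5th percentiles) of the defined point estimates.
    """

    table: pd.DataFrame
    summary: pd.DataFrame


def individual_tps(cohort: Cohort, mode: str = "fill48") -> IndividualTPs:
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    arr = _per_diary_mu_domni(cohort, mode)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(arr[:, 1] > 0, arr[:, 0] / arr[:, 1], np.nan)
        domni = np.where(arr[:, 3] > 0, arr[:, 2] / arr[:, 3], np.nan)
    table = pd.DataFrame(
        {
            "patient_id": [d.patient_id for d in cohort],
            "mu_x": arr[:, 0].astype(int),
            "mu_n": arr[:, 1].astype(int),
            "mu_hat": mu,
            "delta_omni_x": arr[:, 2].astype(int),
            "delta_omni_n": arr[:, 3].astype(int),
            "delta_omni_hat": domni,
        }
    )
    rows = {}
    for name, vals in (("mu", mu), ("delta_omni", domni)):
        defined = vals[~np.isnan(vals)]
        n_missing = int(np.isnan(vals).sum())
        if n_missing:
            logger.info("%s undefined for %d diaries (zero denominator)",
                        name, n_missing)
        if defined.size:
            rows[name] = {
                "median": float(np.median(defined)),
                "p2.5": float(np.percentile(defined, 2.5)),
                "p97.5": float(np.percentile(defined, 97.5)),
                "n_defined": defined.size,
                "n_missing": n_missing,
            }
        else:
            rows[name] = {
                "median": float("nan"), "p2.5": float("nan"),
                "p97.5": float("nan"), "n_defined": 0, "n_missing": n_missing,
            }
    return IndividualTPs(table=table, summary=pd.DataFrame.from_dict(rows, "index"))


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile intervals from resampling whole diaries with replacement."""

    B: int
    seed: int
    mode: str
    intervals: dict[str, tuple[float, float]]
    replicate_mean: dict[str, float]
    replicate_sd: dict[str, float]
    n_excluded: dict[str, int] = field(default_factory=dict)


def bootstrap_tps(
    cohort: Cohort,
    B: int = 100_000,
    seed: int = 0,
    mode: str = "fill48",
    alpha: float = 0.05,
) -> BootstrapResult:
    """Patient-level bootstrap of the pooled μ̂ and δ̂_Omni.

    Each of the ``B`` replicates draws ``len(cohort)`` diaries with
    replacement, re-pools the transition counts and re-estimates both
    parameters; the (α/2, 1−α/2) percentile interval of the replicate
    estimates is returned.  Replicates with an empty denominator are
    recorded and excluded.  Fully reproducible given ``seed``.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if B < 1:
        raise ValueError("B must be >= 1")
    arr = _per_diary_mu_domni(cohort, mode)
    rng = np.random.default_rng(seed)
    P = arr.shape[0]
    mu_reps = np.empty(B)
    domni_reps = np.empty(B)
    chunk = 10_000
    for lo in range(0, B, chunk):
        hi = min(lo + chunk, B)
        idx = rng.integers(0, P, size=(hi - lo, P))
        sums = arr[idx].sum(axis=1)  # (chunk, 4)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu_reps[lo:hi] = np.where(sums[:, 1] > 0, sums[:, 0] / sums[:, 1], np.nan)
            domni_reps[lo:hi] = np.where(
                sums[:, 3] > 0, sums[:, 2] / sums[:, 3], np.nan
            )
    intervals: dict[str, tuple[float, float]] = {}
    rep_mean: dict[str, float] = {}
    rep_sd: dict[str, float] = {}
    n_excluded: dict[str, int] = {}
    for name, reps in (("mu", mu_reps), ("delta_omni", domni_reps)):
        ok = reps[~np.isnan(reps)]
        n_excluded[name] = int(reps.size - ok.size)
        if n_excluded[name]:
            logger.info("bootstrap: %d/%d replicates excluded for %s "
                        "(empty denominator)", n_excluded[name], B, name)
        if ok.size == 0:
            raise UndefinedEstimateError(
                f"every bootstrap replicate had an empty denominator for {name}"
            )
        lo_q, hi_q = np.percentile(ok, (100 * alpha / 2, 100 * (1 - alpha / 2)))
        intervals[name] = (float(lo_q), float(hi_q))
        rep_mean[name] = float(ok.mean())
        rep_sd[name] = float(ok.std(ddof=1)) if ok.size > 1 else 0.0
    return BootstrapResult(
        B=B, seed=seed, mode=mode, intervals=intervals,
        replicate_mean=rep_mean, replicate_sd=rep_sd, n_excluded=n_excluded,
    )
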