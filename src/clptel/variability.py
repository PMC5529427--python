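"""Cohort variability analysis on time-to-criteria outcomes.

Builds the hourly capture table (mice meeting criteria within +/-30 min of
each whole hour post-CLP), selects the best single capture window, converts
the capture proportion into sample-size implications for a fixed-time-point
design, and provides the exact small-sample tests used to compare windows
and seasonal sub-cohorts: exact binomial McNemar for paired windows, an
exact conditional 2xk Fisher test by complete enumeration, Kruskal-Wallis
across seasons, and Spearman correlation against ambient temperature.

Window convention: hour ``h`` covers ``[60h - tol, 60h + tol)`` minutes,
half-open so that with the default 30-min tolerance the windows partition
the axis and every uncensored time is captured by exactly one hour.
Proportions are computed over uncensored ("analyzable") mice at full
precision; whole-percent roundings (half-up) are provided for reporting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import AnalysisError, CapabilityError, ParameterError
from .outcomes import MouseOutcome

__all__ = [
    "CaptureTable",
    "WindowComparison",
    "SampleSizePlan",
    "SeasonalSummary",
    "round_half_up",
    "capture_table",
    "best_window",
    "compare_windows",
    "sample_size_plan",
    "binomial_ci",
    "mcnemar_exact",
    "fisher_exact_2xk",
    "seasonal_analysis",
]

DEFAULT_HOURS = range(4, 25)
DEFAULT_TOLERANCE = 30.0

_CI_METHODS = {"wald": "normal", "wilson": "wilson", "clopper-pearson": "beta"}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (reporting convention)."""
    scale = 10.0 ** ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CaptureTable:
    """Per-hour capture-window summary over the analyzable (uncensored) cohort.

    ``data`` is indexed by whole hour and carries, at full precision,
    ``window_count``, ``window_prop`` (in-window fraction),
    ``cumulative_prop`` (time <= hour + tolerance), ``past_prop``
    (time < hour - tolerance) and ``not_yet_prop`` (time >= hour +
    tolerance); the three state fractions sum to 1 at every hour.
    """

    data: pd.DataFrame
    n_analyzed: int
    tolerance: float

    def to_percent(self) -> pd.DataFrame:
        """Whole-percent (half-up) view for reporting."""
        cols = ["window_prop", "cumulative_prop", "past_prop", "not_yet_prop"]
        out = self.data[["window_count"]].copy()
        for c in cols:
            out[c.replace("_prop", "_pct")] = [
                int(round_half_up(100.0 * v)) for v in self.data[c]
            ]
        return out


@dataclass(frozen=True)
class WindowComparison:
    """Exact McNemar comparison of two disjoint capture windows."""

    hour_a: int
    hour_b: int
    count_a: int
    count_b: int
    p_value: float


@dataclass(frozen=True)
class SampleSizePlan:
    """Fixed-time-point sample-size implications of a capture proportion."""

    p_hat: float
    fold_increase: float
    q_target: int
    required_total: int
    ci_low: int | None = None   # percent
    ci_high: int | None = None  # percent


@dataclass(frozen=True)
class SeasonalSummary:
    """Season-stratified view of the cohort (the Table-2 analog)."""

    per_season: pd.DataFrame
    kruskal_p: float
    capture_fisher_p: float | None
    spearman_r: float | None
    spearman_p: float | None


def _uncensored_times(outcomes: list[MouseOutcome]) -> np.ndarray:
    return np.array(
        [o.time_to_criteria for o in outcomes if not o.censored], dtype=float
    )


def capture_table(
    outcomes: list[MouseOutcome],
    tolerance: float = DEFAULT_TOLERANCE,
    hours: range = DEFAULT_HOURS,
) -> CaptureTable:
    """Tabulate hourly capture windows over the uncensored cohort."""
    if not outcomes:
        raise AnalysisError("empty cohort")
    if tolerance <= 0:
        raise ParameterError("tolerance must be > 0")
    times = _uncensored_times(outcomes)
    n = times.size
    if n == 0:
        raise AnalysisError("all mice censored; no analyzable cohort")

    rows = []
    for h in hours:
        m = 60.0 * h
        in_window = int(np.sum((times >= m - tolerance) & (times < m + tolerance)))
        past = int(np.sum(times < m - tolerance))
        cumulative = int(np.sum(times < m + tolerance))
        rows.append(
            {
                "hour": h,
                "window_count": in_window,
                "window_prop": in_window / n,
                "cumulative_prop": cumulative / n,
                "past_prop": past / n,
                "not_yet_prop": (n - cumulative) / n,
            }
        )
    data = pd.DataFrame(rows).set_index("hour")
    return CaptureTable(data=data, n_analyzed=n, tolerance=tolerance)


def best_window(table: CaptureTable) -> int:
    """Hour whose window captures the most mice; ties go to the earliest hour."""
    counts = table.data["window_count"]
    return int(counts.index[np.argmax(counts.to_numpy())])


def mcnemar_exact(b: int, c: int, *, method: str = "exact") -> float:
    """Two-sided McNemar test on discordant-pair counts ``(b, c)``.

    ``"exact"`` (default) is the exact binomial form
    ``min(1, 2 * P(X <= min(b, c)))`` with ``X ~ Binomial(b + c, 1/2)``;
    ``"chi2cc"`` is the continuity-corrected chi-square approximation.
    ``b = c = 0`` returns 1 by convention (no discordance, no evidence).
    """
    if b < 0 or c < 0:
        raise ParameterError("discordant counts must be >= 0")
    n = b + c
    if n == 0:
        return 1.0
    if method == "exact":
        return float(min(1.0, 2.0 * stats.binom.cdf(min(b, c), n, 0.5)))
    if method == "chi2cc":
        statistic = (abs(b - c) - 1.0) ** 2 / n
        return float(stats.chi2.sf(statistic, df=1))
    raise ParameterError(f"unknown method {method!r}")


def compare_windows(table: CaptureTable, hour_a: int, hour_b: int) -> WindowComparison:
    """Exact McNemar comparison of two capture windows.

    With half-open hourly windows the windows are disjoint, so the
    discordant pairs (captured at one hour but not the other) are exactly
    the two window counts themselves.
    """
    a = int(table.data.loc[hour_a, "window_count"])
    b = int(table.data.loc[hour_b, "window_count"])
    return WindowComparison(hour_a, hour_b, a, b, mcnemar_exact(a, b))


def binomial_ci(
    successes: int,
    n: int,
    level: float = 0.95,
    method: str = "wald",
    *,
    as_percent: bool = True,
) -> tuple:
    """Binomial confidence interval on a capture proportion.

    ``method`` is one of ``"wald"`` (default), ``"wilson"`` or
    ``"clopper-pearson"``.  By default the bounds are reported in whole
    percent (half-up); pass ``as_percent=False`` for full-precision
    fractions.
    """
    if n < 1 or not (0 <= successes <= n):
        raise ParameterError("need 0 <= successes <= n, n >= 1")
    if method not in _CI_METHODS:
        raise ParameterError(f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}")
    lo, hi = proportion_confint(successes, n, alpha=1.0 - level, method=_CI_METHODS[method])
    lo, hi = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
    if as_percent:
        return int(round_half_up(100 * lo)), int(round_half_up(100 * hi))
    return lo, hi


def sample_size_plan(
    q_target: int,
    p_hat: float | None = None,
    *,
    successes: int | None = None,
    n: int | None = None,
    ci_method: str = "wald",
) -> SampleSizePlan:
    """Sample size a fixed-time-point design needs to match ``q_target`` captured mice.

    Supply either the capture proportion ``p_hat`` directly or the
    ``successes``/``n`` counts it came from (which also yields a 95% CI).
    ``fold_increase`` is ``1 / p_hat`` to 2 decimals; ``required_total``
    is ``q_target / p_hat`` rounded up to the next whole mouse.
    """
    if q_target < 1:
        raise ParameterError("q_target must be >= 1")
    ci_low = ci_high = None
    if p_hat is None:
        if successes is None or n is None:
            raise ParameterError("supply p_hat or successes and n")
        p_hat = successes / n
        ci_low, ci_high = binomial_ci(successes, n, method=ci_method)
    if not (0.0 < p_hat <= 1.0):
        raise ParameterError("p_hat must be in (0, 1]")
    return SampleSizePlan(
        p_hat=p_hat,
        fold_increase=round_half_up(1.0 / p_hat, 2),
        q_target=q_target,
        required_total=math.ceil(q_target / p_hat),
        ci_low=ci_low,
        ci_high=ci_high,
    )


def fisher_exact_2xk(table, *, max_tables: int = 2_000_000) -> float:
    """Exact conditional test of homogeneity for a 2 x k count table.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one under
    the multivariate hypergeometric null (the standard Fisher-Freeman-
    Halton construction).  Intended for the small tables arising here
    (k <= 4, modest counts); enumeration beyond ``max_tables`` candidate
    tables raises :class:`CapabilityError`.
    """
    a = np.asarray(table, dtype=int)
    if a.ndim != 2 or a.shape[0] != 2:
        raise ParameterError("table must be 2 x k")
    if a.shape[1] > 4:
        raise ParameterError("k <= 4 supported")
    if np.any(a < 0):
        raise ParameterError("counts must be non-negative")
    col_totals = a.sum(axis=0)
    r = int(a[0].sum())
    n_tables = int(np.prod(col_totals + 1))
    if n_tables > max_tables:
        raise CapabilityError(
            f"margins admit ~{n_tables} candidate tables (> {max_tables}); "
            "exact enumeration refused"
        )

    # log P(x | margins) = sum_j log C(n_j, x_j) - log C(N, r)
    log_c = [
        np.array([math.lgamma(nj + 1) - math.lgamma(x + 1) - math.lgamma(nj - x + 1)
                  for x in range(nj + 1)])
        for nj in col_totals
    ]
    obs_logp = sum(lc[int(x)] for lc, x in zip(log_c, a[0]))

    total = 0.0
    extreme = 0.0
    for xs in itertools.product(*(range(nj + 1) for nj in col_totals)):
        if sum(xs) != r:
            continue
        lp = sum(lc[x] for lc, x in zip(log_c, xs))
        p = math.exp(lp - obs_logp)  # relative to observed; rescaled below
        total += p
        if lp <= obs_logp + 1e-9:
            extreme += p
    return float(min(1.0, extreme / total))


def seasonal_analysis(
    outcomes: list[MouseOutcome],
    tolerance: float = DEFAULT_TOLERANCE,
    at_hour: int = 8,
    *,
    exact_capture_test: bool = True,
) -> SeasonalSummary:
    """Season-stratified summary of the uncensored cohort.

    Per season: n, median and IQR of time-to-criteria, and the capture
    proportion at ``at_hour``.  Across seasons: Kruskal-Wallis on the time
    distributions and an exact 2xk test on the capture counts.  If ambient
    temperatures are recorded, Spearman rank correlation of ambient
    temperature against time-to-criteria is included.
    """
    recs = [
        o for o in outcomes
        if not o.censored and o.season is not None
    ]
    by_season: dict[str, list[MouseOutcome]] = {}
    for o in recs:
        by_season.setdefault(o.season, []).append(o)
    usable = {s: v for s, v in by_season.items() if len(v) >= 2}
    if len(usable) < 2:
        raise AnalysisError("need >= 2 seasons with >= 2 uncensored mice each")

    lo, hi = 60.0 * at_hour - tolerance, 60.0 * at_hour + tolerance
    rows = []
    groups = []
    captured = []
    missed = []
    for season in sorted(usable):
        t = np.array([o.time_to_criteria for o in usable[season]])
        groups.append(t)
        cap = int(np.sum((t >= lo) & (t < hi)))
        captured.append(cap)
        missed.append(t.size - cap)
        q1, med, q3 = np.percentile(t, [25, 50, 75])
        rows.append(
            {
                "season": season,
                "n": t.size,
                "median_min": med,
                "iqr_low_min": q1,
                "iqr_high_min": q3,
                "captured_at_hour": cap,
                "capture_prop": cap / t.size,
            }
        )
    kw_p = float(stats.kruskal(*groups).pvalue)
    fisher_p = None
    if exact_capture_test:
        try:
            fisher_p = fisher_exact_2xk(np.array([captured, missed]))
        except CapabilityError:
            pass

    amb = [(o.ambient_temp, o.time_to_criteria) for o in recs if o.ambient_temp is not None]
    r = p = None
    if len(amb) >= 3:
        temps, times = zip(*amb)
        res = stats.spearmanr(temps, times)
        r, p = float(res.statistic), float(res.pvalue)

    return SeasonalSummary(
        per_season=pd.DataFrame(rows).set_index("season"),
        kruskal_p=kw_p,
        capture_fisher_p=fisher_p,
        spearman_r=r,
        spearman_p=p,
    )
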