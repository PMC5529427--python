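"""Synthetic biotelemetry cohorts.

Two generators live here:

* a stochastic trace-level simulator (:func:`simulate_mouse`,
  :func:`simulate_cohort`) producing ramp--plateau--decline physiologic
  traces whose latent deterioration onsets follow a truncated log-normal
  calibrated to the observed cohort (median 465 min, IQR roughly 422--536),
  with ~7% of mice never deteriorating within 24 h; and
* a deterministic 115-mouse fixture (:func:`fixture_cohort_table1`) that
  reconstructs the published hourly capture distribution from its
  whole-percent frequency column, for exact downstream regression tests.

The trace waveform is intentionally simple — linear rise to a plateau peak,
then linear decline from the latent onset — so that threshold-crossing
times have a closed form against which the detector can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ParameterError
from .outcomes import MouseOutcome
from .trace import TEMP_MAX_C, TEMP_MIN_C, TelemetryTrace

__all__ = [
    "SimulationParams",
    "MouseDraw",
    "draw_latent",
    "simulate_mouse",
    "simulate_cohort",
    "fixture_cohort_table1",
    "TABLE1_WINDOW_COUNTS",
]


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level simulation settings.

    Defaults reproduce the study conditions: 115 mice, ~7% never reaching
    criteria within the 1440-min horizon, latent onsets log-normal with
    median 465 min and log-scale 0.16 (truncated to [240, 1440] min),
    sampled every minute.
    """

    n_mice: int = 115
    onset_log_mu: float = math.log(465.0)
    onset_log_sigma: float = 0.16
    onset_bounds: tuple[float, float] = (240.0, 1440.0)
    non_deteriorator_fraction: float = 0.07
    hr_peak_range: tuple[float, float] = (650.0, 750.0)
    temp_peak_range: tuple[float, float] = (37.0, 38.5)
    hr_decline_slope: float = 2.0       # bpm per min after onset
    temp_decline_slope: float = 0.04    # deg C per min after onset
    noise_sd_hr: float = 15.0           # bpm
    noise_sd_temp: float = 0.15         # deg C
    sampling_interval: float = 1.0      # minutes
    horizon: float = 1440.0             # minutes
    seed: int = 0
    # waveform shape (not varied in the study-condition defaults)
    ramp_minutes: float = 120.0
    hr_baseline_fraction: float = 0.85
    temp_baseline_drop: float = 1.0     # deg C below peak at t = 0
    hr_floor: float = 30.0              # moribund plateau, bpm
    temp_floor: float = 23.0            # moribund plateau, deg C
    include_activity: bool = True

    def __post_init__(self) -> None:
        if self.n_mice < 0:
            raise ParameterError("n_mice must be >= 0")
        if not (0.0 <= self.non_deteriorator_fraction <= 1.0):
            raise ParameterError("non_deteriorator_fraction must be in [0, 1]")
        if self.hr_decline_slope <= 0 or self.temp_decline_slope <= 0:
            raise ParameterError("decline slopes must be > 0")
        if self.horizon <= 0 or self.sampling_interval <= 0:
            raise ParameterError("horizon and sampling_interval must be > 0")
        if self.onset_log_sigma < 0:
            raise ParameterError("onset_log_sigma must be >= 0")
        if self.onset_bounds[0] >= self.onset_bounds[1]:
            raise ParameterError("onset_bounds must be an increasing pair")
        if self.noise_sd_hr < 0 or self.noise_sd_temp < 0:
            raise ParameterError("noise SDs must be >= 0")

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MouseDraw:
    """Latent per-mouse quantities drawn before trace construction."""

    mouse_id: str
    censored: bool
    onset: float | None
    hr_peak: float
    temp_peak: float


def _mouse_rng(params: SimulationParams, index: int) -> np.random.Generator:
    # (seed, index) keyed generator: bit-identical traces for equal keys,
    # statistically independent streams across mice.
    return np.random.default_rng([params.seed, index])


def _draw_from(rng: np.random.Generator, params: SimulationParams, index: int) -> MouseDraw:
    censored = bool(rng.random() < params.non_deteriorator_fraction)
    lo, hi = params.onset_bounds
    if params.onset_log_sigma == 0.0:
        onset = float(np.clip(math.exp(params.onset_log_mu), lo, hi))
    else:
        # rejection sampling from the truncated log-normal
        onset = float(rng.lognormal(params.onset_log_mu, params.onset_log_sigma))
        while not (lo <= onset <= hi):
            onset = float(rng.lognormal(params.onset_log_mu, params.onset_log_sigma))
    hr_peak = float(rng.uniform(*params.hr_peak_range))
    temp_peak = float(rng.uniform(*params.temp_peak_range))
    return MouseDraw(
        mouse_id=f"sim{index:04d}",
        censored=censored,
        onset=None if censored else onset,
        hr_peak=hr_peak,
        temp_peak=temp_peak,
    )


def draw_latent(params: SimulationParams, index: int) -> MouseDraw:
    """Draw the latent state of mouse ``index`` without building its trace.

    Deterministic given ``(params.seed, index)`` and consistent with
    :func:`simulate_mouse`, which consumes the same draws in the same order.
    """
    if index < 0 or index >= params.n_mice:
        raise ParameterError(f"index {index} outside cohort of {params.n_mice}")
    return _draw_from(_mouse_rng(params, index), params, index)


def simulate_mouse(params: SimulationParams, index: int) -> TelemetryTrace:
    """Simulate one mouse's post-CLP telemetry trace.

    The waveform rises linearly from a post-anaesthesia baseline to its
    peak over ``ramp_minutes``, plateaus, and — unless the mouse is a
    sampled non-deteriorator — declines linearly from the latent onset at
    the configured slopes, flattening at a moribund floor.  Gaussian
    measurement noise is added per channel.
    """
    if index < 0 or index >= params.n_mice:
        raise ParameterError(f"index {index} outside cohort of {params.n_mice}")
    rng = _mouse_rng(params, index)
    draw = _draw_from(rng, params, index)  # noise draws below continue the stream

    n = int(math.floor(params.horizon / params.sampling_interval)) + 1
    t = np.arange(n) * params.sampling_interval

    hr = np.full(n, draw.hr_peak)
    temp = np.full(n, draw.temp_peak)
    if params.ramp_minutes > 0:
        ramp = t < params.ramp_minutes
        frac = t[ramp] / params.ramp_minutes
        hr[ramp] = draw.hr_peak * (params.hr_baseline_fraction + (1 - params.hr_baseline_fraction) * frac)
        temp[ramp] = draw.temp_peak - params.temp_baseline_drop * (1 - frac)
    if draw.onset is not None:
        post = t > draw.onset
        hr[post] = draw.hr_peak - params.hr_decline_slope * (t[post] - draw.onset)
        temp[post] = draw.temp_peak - params.temp_decline_slope * (t[post] - draw.onset)
    hr = np.maximum(hr, params.hr_floor)
    temp = np.maximum(temp, params.temp_floor)

    if params.noise_sd_hr > 0:
        hr = hr + rng.normal(0.0, params.noise_sd_hr, n)
    if params.noise_sd_temp > 0:
        temp = temp + rng.normal(0.0, params.noise_sd_temp, n)
    hr = np.clip(hr, 1.0, None)
    temp = np.clip(temp, TEMP_MIN_C, TEMP_MAX_C)

    activity = None
    if params.include_activity:
        # crude circadian-free activity: bursts that die off after onset
        level = np.ones(n)
        if draw.onset is not None:
            level[t > draw.onset] = 0.2
        activity = rng.poisson(3.0 * level, n).astype(float)

    return TelemetryTrace(
        mouse_id=draw.mouse_id,
        times=t,
        heart_rate=hr,
        core_temp=temp,
        activity=activity,
    )


def simulate_cohort(params: SimulationParams) -> list[TelemetryTrace]:
    """Simulate the full cohort; deterministic given ``params.seed``."""
    return [simulate_mouse(params, i) for i in range(params.n_mice)]


# ---------------------------------------------------------------------------
# Deterministic fixture reconstructing the published hourly distribution
# ---------------------------------------------------------------------------

#: Uncensored mice per hourly capture window (hour -> count out of 107).
#: Each count, divided by 107 and rounded to whole percent, reproduces the
#: published "% meeting criteria (+/-30 min)" column for hours 4-23.
TABLE1_WINDOW_COUNTS: dict[int, int] = {
    5: 2, 6: 13, 7: 26, 8: 30, 9: 11, 10: 5, 11: 4, 12: 2,
    13: 3, 14: 3, 15: 1, 16: 1, 17: 1, 22: 1, 23: 2,
}

_FIXTURE_N_TOTAL = 115
_FIXTURE_N_CENSORED = 8
_FIXTURE_TAIL_WINDOW = (1410.0, 1440.0)  # residual mice: beyond 23.5 h, within 24 h


def _evenly_spaced(lo: float, hi: float, k: int) -> list[float]:
    # k interior points of [lo, hi): lo + i*(hi-lo)/(k+1), i = 1..k
    w = hi - lo
    return [lo + (i + 1) * w / (k + 1) for i in range(k)]


def fixture_cohort_table1() -> list[MouseOutcome]:
    """Deterministic 115-mouse cohort matching the published hourly table.

    Returns 8 censored mice and 107 uncensored mice whose times are evenly
    spaced inside their hourly +/-30-min windows.  The per-window counts
    reproduce the published whole-percent frequency column; 2 residual mice
    (unplaceable from the printed column, which sums to 99%) sit in the
    final half-hour before the 24-h horizon.  The overall median falls near,
    though not exactly at, the published 465 min — the raw times are not
    recoverable from whole-percent rounding.
    """
    times: list[float] = []
    for hour in sorted(TABLE1_WINDOW_COUNTS):
        lo, hi = hour * 60.0 - 30.0, hour * 60.0 + 30.0
        times.extend(_evenly_spaced(lo, hi, TABLE1_WINDOW_COUNTS[hour]))
    times.extend(_evenly_spaced(*_FIXTURE_TAIL_WINDOW, 2))
    assert len(times) == _FIXTURE_N_TOTAL - _FIXTURE_N_CENSORED

    outcomes = [
        MouseOutcome(mouse_id=f"fix{i:03d}", time_to_criteria=t, censored=False)
        for i, t in enumerate(sorted(times))
    ]
    outcomes.extend(
        MouseOutcome(mouse_id=f"fix{len(times) + j:03d}", time_to_criteria=None, censored=True)
        for j in range(_FIXTURE_N_CENSORED)
    )
    return outcomes
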