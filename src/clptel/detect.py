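"""Acute physiologic deterioration detection.

A mouse meets criteria at the first sample where, simultaneously,

1. heart rate has fallen by at least ``hr_drop_fraction`` (default 10%)
   from its peak value so far, and
2. core temperature has fallen from its peak so far by at least
   ``temp_drop_fraction`` (default 10%) of the difference between that
   peak and a 25 deg C floor.

"Peak" defaults to the running maximum up to the current sample, making
the criterion causal — evaluable in real time on a live animal.  A
retrospective variant using the whole-trace maximum is available for
sensitivity analyses via ``peak_mode="global"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DetectionError, ParameterError, TraceError
from .outcomes import MouseOutcome
from .trace import TelemetryTrace

__all__ = ["DeteriorationCriteria", "DetectionResult", "detect", "detect_cohort"]


@dataclass(frozen=True)
class DeteriorationCriteria:
    """Thresholds defining acute physiologic deterioration."""

    hr_drop_fraction: float = 0.10
    temp_drop_fraction: float = 0.10
    temp_floor: float = 25.0        # deg C
    horizon: float = 1440.0         # minutes

    def __post_init__(self) -> None:
        if not (0.0 < self.hr_drop_fraction < 1.0):
            raise ParameterError("hr_drop_fraction must be in (0, 1)")
        if not (0.0 < self.temp_drop_fraction < 1.0):
            raise ParameterError("temp_drop_fraction must be in (0, 1)")
        if self.horizon <= 0:
            raise ParameterError("horizon must be > 0")


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of applying the criteria to one trace."""

    mouse_id: str
    detected: bool
    time_to_criteria: float | None
    hr_peak: float | None
    temp_peak: float | None

    def to_outcome(self, horizon: float, **covariates) -> MouseOutcome:
        return MouseOutcome(
            mouse_id=self.mouse_id,
            time_to_criteria=self.time_to_criteria,
            censored=not self.detected,
            horizon=horizon,
            **covariates,
        )


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    # trailing moving average; the first window-1 samples average what is
    # available so the series stays causal and full length
    c = np.cumsum(np.insert(x, 0, 0.0))
    n = x.size
    idx = np.arange(1, n + 1)
    lo = np.maximum(idx - window, 0)
    return (c[idx] - c[lo]) / (idx - lo)


def detect(
    trace: TelemetryTrace,
    criteria: DeteriorationCriteria = DeteriorationCriteria(),
    *,
    peak_mode: str = "running",
    smooth_window: int | None = None,
) -> DetectionResult:
    """Return the earliest time at which both deterioration criteria hold.

    Parameters
    ----------
    trace
        Validated telemetry trace.
    criteria
        Threshold definition; samples beyond ``criteria.horizon`` are
        never reported as detections.
    peak_mode
        ``"running"`` (causal, default) compares each sample against the
        channel maxima observed so far; ``"global"`` against the
        whole-trace maxima.
    smooth_window
        Optional trailing moving-average width (samples) applied to both
        channels before thresholding.  Off by default.

    Raises
    ------
    DetectionError
        If the peak core temperature does not exceed ``temp_floor`` (the
        temperature criterion is then undefined).
    """
    trace.validate()
    if peak_mode not in ("running", "global"):
        raise ParameterError(f"unknown peak_mode {peak_mode!r}")

    hr = trace.heart_rate
    temp = trace.core_temp
    if smooth_window is not None:
        if smooth_window < 1:
            raise ParameterError("smooth_window must be >= 1")
        hr = _smooth(hr, smooth_window)
        temp = _smooth(temp, smooth_window)

    in_horizon = trace.times <= criteria.horizon
    if not in_horizon.any():
        raise TraceError(f"{trace.mouse_id}: no samples within horizon")
    t = trace.times[in_horizon]
    hr = hr[in_horizon]
    temp = temp[in_horizon]

    if temp.max() <= criteria.temp_floor:
        raise DetectionError(
            f"{trace.mouse_id}: peak core temperature {temp.max():.2f} deg C does not "
            f"exceed the {criteria.temp_floor} deg C floor; criterion undefined"
        )

    if peak_mode == "running":
        hr_peak = np.maximum.accumulate(hr)
        temp_peak = np.maximum.accumulate(temp)
    else:
        hr_peak = np.full_like(hr, hr.max())
        temp_peak = np.full_like(temp, temp.max())

    hr_met = hr <= (1.0 - criteria.hr_drop_fraction) * hr_peak
    temp_met = temp <= temp_peak - criteria.temp_drop_fraction * (temp_peak - criteria.temp_floor)
    # temperature criterion is only meaningful once the peak clears the floor
    temp_met &= temp_peak > criteria.temp_floor

    both = hr_met & temp_met
    hits = np.flatnonzero(both)
    if hits.size == 0:
        return DetectionResult(trace.mouse_id, False, None, None, None)
    i = int(hits[0])
    return DetectionResult(
        mouse_id=trace.mouse_id,
        detected=True,
        time_to_criteria=float(t[i]),
        hr_peak=float(hr_peak[i]),
        temp_peak=float(temp_peak[i]),
    )


def detect_cohort(
    traces: list[TelemetryTrace],
    criteria: DeteriorationCriteria = DeteriorationCriteria(),
    **detect_kwargs,
) -> list[MouseOutcome]:
    """Apply :func:`detect` to every trace, yielding analysis-ready outcomes.

    Mice not meeting criteria within the horizon are censored.  Per-trace
    failures are re-raised with the offending mouse identified.
    """
    outcomes: list[MouseOutcome] = []
    for trace in traces:
        try:
            result = detect(trace, criteria, **detect_kwargs)
        except Exception as exc:  # annotate with mouse context and re-raise
            raise type(exc)(f"mouse {trace.mouse_id}: {exc}") from exc
        outcomes.append(result.to_outcome(horizon=criteria.horizon))
    return outcomes
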