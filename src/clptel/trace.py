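"""Telemetry trace container.

A :class:`TelemetryTrace` holds one mouse's post-CLP physiologic record:
heart rate (bpm), core temperature (deg C) and, optionally, gross activity,
sampled on a uniform grid of minutes starting at the moment of CLP.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import TraceError

TEMP_MIN_C = 20.0
TEMP_MAX_C = 42.0


@dataclass(frozen=True)
class TelemetryTrace:
    """One mouse's sampled heart-rate / core-temperature / activity series.

    Parameters
    ----------
    mouse_id
        Opaque identifier carried through all downstream outputs.
    times
        Minutes post-CLP; strictly increasing, starting at 0, uniformly
        sampled.
    heart_rate
        Beats per minute at each sample; strictly positive.
    core_temp
        Core temperature in deg C at each sample; physiologically bounded
        to [20, 42].
    activity
        Arbitrary-unit gross activity; optional channel.
    """

    mouse_id: str
    times: np.ndarray
    heart_rate: np.ndarray
    core_temp: np.ndarray
    activity: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("times", "heart_rate", "core_temp"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.activity is not None:
            object.__setattr__(self, "activity", np.asarray(self.activity, dtype=float))
        self.validate()

    def validate(self) -> None:
        """Raise :class:`TraceError` if any structural invariant is violated."""
        t, hr, tc = self.times, self.heart_rate, self.core_temp
        if t.size == 0:
            raise TraceError(f"{self.mouse_id}: empty trace")
        lengths = {t.size, hr.size, tc.size}
        if self.activity is not None:
            lengths.add(self.activity.size)
        if len(lengths) != 1:
            raise TraceError(f"{self.mouse_id}: channel lengths differ: {sorted(lengths)}")
        if t[0] != 0.0:
            raise TraceError(f"{self.mouse_id}: times must start at 0, got {t[0]}")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise TraceError(f"{self.mouse_id}: times not strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise TraceError(f"{self.mouse_id}: sampling interval is not constant")
        if np.any(hr <= 0):
            raise TraceError(f"{self.mouse_id}: heart rate must be > 0")
        if np.any(tc < TEMP_MIN_C) or np.any(tc > TEMP_MAX_C):
            raise TraceError(
                f"{self.mouse_id}: core temperature outside "
                f"[{TEMP_MIN_C}, {TEMP_MAX_C}] deg C"
            )

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def sampling_interval(self) -> float:
        """Sampling step in minutes (0 for a single-sample trace)."""
        return float(self.times[1] - self.times[0]) if self.times.size > 1 else 0.0
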