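"""Per-mouse time-to-criteria outcome record."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

SEASONS = ("winter", "spring", "summer", "fall")


@dataclass(frozen=True)
class MouseOutcome:
    """Time from CLP to acute physiologic deterioration for one mouse.

    A mouse either met both deterioration criteria at ``time_to_criteria``
    minutes post-CLP, or is ``censored`` (no deterioration within the study
    horizon, 24 h by default).  Season of experimentation and ambient room
    temperature are optional covariates for the seasonal stratification.
    """

    mouse_id: str
    time_to_criteria: float | None
    censored: bool
    season: str | None = None
    ambient_temp: float | None = None
    horizon: float = 1440.0

    def __post_init__(self) -> None:
        if self.censored:
            if self.time_to_criteria is not None:
                raise ParameterError(
                    f"{self.mouse_id}: censored outcome must not carry a time"
                )
        else:
            t = self.time_to_criteria
            if t is None or not (0.0 < t <= self.horizon):
                raise ParameterError(
                    f"{self.mouse_id}: uncensored time must lie in (0, {self.horizon}], "
                    f"got {t}"
                )
        if self.season is not None and self.season not in SEASONS:
            raise ParameterError(
                f"{self.mouse_id}: season must be one of {SEASONS}, got {self.season!r}"
            )
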