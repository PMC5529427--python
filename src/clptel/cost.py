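"""Cost-equivalency decision model: biotelemetry vs fixed-time-point CLP.

The biotelemetry arm pays a stepped equipment cost — monitoring system plus
a set of four implantable devices up front, then a battery-replacement set
after each block of ``mice_per_cycle`` (default 120 = 4 devices x 30
one-day experiments) — plus the per-mouse cost ``c`` for exactly the ``Q``
quality mice it needs.  The fixed-time-point arm buys no equipment but must
enrol ``Q / p`` mice to capture ``Q`` at the point of deterioration, where
``p`` is the capture proportion of its chosen window (0.28 at 8 h).

All cost algebra uses the *fractional* standard-arm size ``Q / p``;
integers (ceilings / nearest-mouse roundings) appear only in reported
animal counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ParameterError
from .variability import round_half_up

__all__ = [
    "CostParameters",
    "EquivalencyResult",
    "SensitivityGrid",
    "setup_cost",
    "standard_mice_needed",
    "incremental_cost_per_quality_mouse",
    "equivalency_cost",
    "equivalency_quality_mice",
    "incremental_cost_difference_curve",
    "two_way_sensitivity",
]


@dataclass(frozen=True)
class CostParameters:
    """Equipment prices and model constants (defaults: published list prices)."""

    system_cost: float = 24336.50       # monitoring system, initial purchase (USD)
    device_set_cost: float = 11610.0    # four implantable devices (USD)
    battery_set_cost: float = 2405.0    # battery replacement, set of four (USD)
    mice_per_cycle: int = 120           # experiments per battery life (4 x 30)
    cost_per_mouse: float = 25.0        # default per-mouse cost c (USD)
    capture_proportion: float = 0.28    # p-hat of the 8-h window

    def __post_init__(self) -> None:
        if min(self.system_cost, self.device_set_cost, self.battery_set_cost) < 0:
            raise ParameterError("costs must be >= 0")
        if self.mice_per_cycle < 1:
            raise ParameterError("mice_per_cycle must be >= 1")
        if not (0.0 < self.capture_proportion <= 1.0):
            raise ParameterError("capture_proportion must be in (0, 1]")
        if self.cost_per_mouse < 0:
            raise ParameterError("cost_per_mouse must be >= 0")

    def with_(self, **kwargs) -> "CostParameters":
        return replace(self, **kwargs)


DEFAULT_COST_PARAMS = CostParameters()


@dataclass(frozen=True)
class EquivalencyResult:
    """Solved cost-equivalency point for a given per-mouse cost."""

    quality_mice: int
    cost_per_mouse: float
    standard_mice: int
    mice_spared: int
    battery_replacements: int


@dataclass(frozen=True)
class SensitivityGrid:
    """Two-way sensitivity surface over (quality mice, cost per mouse)."""

    c_values: np.ndarray                 # USD per mouse axis
    q_values: np.ndarray                 # quality-mice axis
    difference: np.ndarray               # biotelemetry minus standard, shape (len c, len q)
    favors_biotelemetry: np.ndarray      # difference < 0
    boundary: pd.DataFrame               # per Q: equivalency cost-per-mouse


def _battery_replacements(q: float, params: CostParameters) -> int:
    return int(math.ceil(q / params.mice_per_cycle)) - 1


def setup_cost(quality_mice: float, params: CostParameters = DEFAULT_COST_PARAMS) -> float:
    """Equipment cost to monitor ``quality_mice`` experiments.

    System + first device set, plus one battery set per additional block of
    ``mice_per_cycle`` experiments (the first block is covered by the
    initial device purchase).
    """
    if quality_mice < 1:
        raise ParameterError("quality_mice must be >= 1")
    k = _battery_replacements(quality_mice, params)
    return params.system_cost + params.device_set_cost + params.battery_set_cost * k


def standard_mice_needed(
    quality_mice: float,
    p: float | None = None,
    params: CostParameters = DEFAULT_COST_PARAMS,
) -> tuple[float, int]:
    """Fixed-time-point enrolment needed for ``quality_mice`` captured mice.

    Returns ``(Q / p, ceil(Q / p))`` — the fractional value feeds the cost
    algebra, the ceiling is the reported animal count.
    """
    p = params.capture_proportion if p is None else p
    if not (0.0 < p <= 1.0):
        raise ParameterError("capture proportion must be in (0, 1]")
    frac = quality_mice / p
    return frac, int(math.ceil(frac - 1e-9))


def incremental_cost_per_quality_mouse(
    quality_mice: float,
    cost_per_mouse: float | None = None,
    p: float | None = None,
    params: CostParameters = DEFAULT_COST_PARAMS,
) -> float:
    """Extra cost per quality mouse of the biotelemetry arm over the standard arm."""
    c = params.cost_per_mouse if cost_per_mouse is None else cost_per_mouse
    frac, _ = standard_mice_needed(quality_mice, p, params)
    biotel = setup_cost(quality_mice, params) + quality_mice * c
    standard = frac * c
    return (biotel - standard) / quality_mice


def equivalency_cost(
    quality_mice: float,
    p: float | None = None,
    params: CostParameters = DEFAULT_COST_PARAMS,
) -> float:
    """Per-mouse cost at which the two arms cost the same for ``quality_mice``."""
    p = params.capture_proportion if p is None else p
    if p >= 1.0:
        raise ParameterError("capture proportion of 1 spares no mice; equivalency undefined")
    frac, _ = standard_mice_needed(quality_mice, p, params)
    return setup_cost(quality_mice, params) / (frac - quality_mice)


def equivalency_quality_mice(
    cost_per_mouse: float,
    p: float | None = None,
    params: CostParameters = DEFAULT_COST_PARAMS,
    *,
    max_tiers: int = 200,
) -> EquivalencyResult:
    """Solve for the cohort size at which the two arms cost the same.

    Under the stepped battery schedule the equipment cost is piecewise
    constant in Q, so the solve runs per battery tier ``k``: candidate
    ``Q_k = (system + devices + k * battery) / (c * (1/p - 1))`` is accepted
    when it is self-consistent with its tier, i.e. falls in
    ``(k * cycle, (k+1) * cycle]``.  The accepted Q is rounded to the
    nearest mouse; the standard-arm count is ``round(Q / p)``.
    """
    p = params.capture_proportion if p is None else p
    if cost_per_mouse <= 0:
        raise ParameterError("cost_per_mouse must be > 0")
    if not (0.0 < p < 1.0):
        raise ParameterError("capture proportion must be in (0, 1) for equivalency")
    denom = cost_per_mouse * (1.0 / p - 1.0)
    base = params.system_cost + params.device_set_cost
    for k in range(max_tiers):
        q_k = (base + k * params.battery_set_cost) / denom
        lo, hi = k * params.mice_per_cycle, (k + 1) * params.mice_per_cycle
        if lo < q_k <= hi:
            q = int(round_half_up(q_k))
            standard = int(round_half_up(q / p))
            return EquivalencyResult(
                quality_mice=q,
                cost_per_mouse=cost_per_mouse,
                standard_mice=standard,
                mice_spared=standard - q,
                battery_replacements=k,
            )
    raise ParameterError(
        f"no self-consistent battery tier within {max_tiers} tiers; equivalency unreachable"
    )


def incremental_cost_difference_curve(
    c_values,
    quality_mice: float,
    p: float | None = None,
    params: CostParameters = DEFAULT_COST_PARAMS,
) -> pd.DataFrame:
    """Total-cost difference (biotelemetry minus standard) across per-mouse costs.

    Exactly linear in ``c`` with slope ``Q - Q/p`` (negative whenever
    ``p < 1``); its zero crossing is :func:`equivalency_cost`.
    """
    c = np.asarray(c_values, dtype=float)
    frac, _ = standard_mice_needed(quality_mice, p, params)
    diff = setup_cost(quality_mice, params) + quality_mice * c - frac * c
    return pd.DataFrame({"cost_per_mouse": c, "difference": diff})


def two_way_sensitivity(
    c_grid,
    q_grid,
    p: float | None = None,
    params: CostParameters = DEFAULT_COST_PARAMS,
) -> SensitivityGrid:
    """Cost-preference surface over per-mouse cost and planned quality mice.

    Cells where the biotelemetry arm is cheaper sit above the equivalency
    boundary ``c = equivalency_cost(Q)``; below it the fixed-time-point
    arm wins on cost alone.
    """
    c = np.asarray(c_grid, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if c.size == 0 or q.size == 0:
        raise ParameterError("grids must be non-empty")
    pp = params.capture_proportion if p is None else p
    setup = np.array([setup_cost(qi, params) for qi in q])
    frac = q / pp
    diff = setup[None, :] + q[None, :] * c[:, None] - frac[None, :] * c[:, None]
    boundary = pd.DataFrame(
        {
            "quality_mice": q,
            "equivalency_cost": [equivalency_cost(qi, pp, params) for qi in q],
        }
    )
    return SensitivityGrid(
        c_values=c,
        q_values=q,
        difference=diff,
        favors_biotelemetry=diff < 0,
        boundary=boundary,
    )
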