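"""Discounted cost and QALY accrual over cohort traces, and incremental results.

Costs accrue as ``occupancy(t, k) * annual_cost(k) * factor(t)`` summed
over cycles and states; QALYs analogously with per-state utility weights.
The discount factor is ``(1 + rate) ** -(t - origin)`` (floored at 1), so
``origin = 0`` discounts the first model year once and ``origin = 1``
leaves it undiscounted — the literature uses both conventions and the
choice is a config switch, not a constant.

Accrual timing is a second switch: ``"end"`` charges cycle *t* with the
occupancy *after* t transitions (rows 1..n of the trace), ``"start"``
with the occupancy before (rows 0..n-1); ``"half"`` averages the two
(half-cycle correction, off by default everywhere in this package).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import CohortTrace, StateSpace, StructuralError

__all__ = [
    "CostSchedule",
    "UtilitySchedule",
    "DiscountSchedule",
    "EconomicResult",
    "IncrementalResult",
    "accrue",
    "compute_icer",
    "occupancy_difference",
]


def _check_states(kind: str, values: dict[str, float], space: StateSpace) -> dict[str, float]:
    missing = set(space.states) - set(values)
    extra = set(values) - set(space.states)
    if missing or extra:
        raise StructuralError(
            f"{kind} states do not match the state space "
            f"(missing {sorted(missing)}, unknown {sorted(extra)})"
        )
    return {s: float(values[s]) for s in space.states}


@dataclass
class CostSchedule:
    """Annual per-person cost of occupying each state (currency / person-year).

    ``annotations`` carries non-arithmetic metadata (e.g. the yen figures a
    USD cost was converted from); it never enters computation.
    """

    space: StateSpace
    annual_cost: dict[str, float]
    currency: str = "USD"
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.annual_cost = _check_states("cost", self.annual_cost, self.space)
        for s, c in self.annual_cost.items():
            if c < 0:
                raise ValueError(f"negative annual cost for {s!r}: {c}")
        for s in self.space.absorbing:
            if s == "death" and self.annual_cost[s] != 0:
                raise ValueError("death state must have zero cost")

    def vector(self) -> np.ndarray:
        return np.array([self.annual_cost[s] for s in self.space.states])

    def with_overrides(self, overrides: dict[str, float]) -> "CostSchedule":
        merged = {**self.annual_cost, **overrides}
        return CostSchedule(self.space, merged, self.currency, dict(self.annotations))


@dataclass
class UtilitySchedule:
    """Annual QALY weight of each state, in [0, 1]; death is 0."""

    space: StateSpace
    annual_utility: dict[str, float]

    def __post_init__(self) -> None:
        self.annual_utility = _check_states("utility", self.annual_utility, self.space)
        for s, u in self.annual_utility.items():
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility for {s!r} must lie in [0, 1], got {u}")
        if "death" in self.space.states and self.annual_utility["death"] != 0:
            raise ValueError("death utility must be 0")

    def vector(self) -> np.ndarray:
        return np.array([self.annual_utility[s] for s in self.space.states])

    def with_overrides(self, overrides: dict[str, float]) -> "UtilitySchedule":
        return UtilitySchedule(self.space, {**self.annual_utility, **overrides})


@dataclass(frozen=True)
class DiscountSchedule:
    """Exponential discounting: factor(t) = (1 + rate) ** -(max(t - origin, 0))."""

    rate: float = 0.04
    origin: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"discount rate must be >= 0, got {self.rate}")
        if self.origin not in (0, 1):
            raise ValueError("discount origin must be 0 (discount year 1 once) or 1")

    def factor(self, t: int) -> float:
        return (1.0 + self.rate) ** -(max(t - self.origin, 0))

    def factors(self, cycles: np.ndarray) -> np.ndarray:
        return (1.0 + self.rate) ** -(np.maximum(cycles - self.origin, 0))


@dataclass
class EconomicResult:
    """Discounted totals for one scenario, with a per-state decomposition.

    ``per_state_person_years`` is undiscounted occupancy time (persons x
    years) under the same accrual timing, useful for reporting; the cost
    decomposition is discounted and sums to ``total_cost``.
    """

    space: StateSpace
    total_cost: float
    total_qaly: float
    per_state_cost: dict[str, float]
    per_state_person_years: dict[str, float]
    horizon: int

    def __post_init__(self) -> None:
        recomposed = sum(self.per_state_cost.values())
        if not math.isclose(recomposed, self.total_cost, rel_tol=1e-6, abs_tol=1e-6):
            raise ValueError("per-state costs do not sum to the total")

    def scaled(self, factor: float) -> "EconomicResult":
        return EconomicResult(
            self.space,
            self.total_cost * factor,
            self.total_qaly * factor,
            {s: c * factor for s, c in self.per_state_cost.items()},
            {s: p * factor for s, p in self.per_state_person_years.items()},
            self.horizon,
        )

    def __add__(self, other: "EconomicResult") -> "EconomicResult":
        if self.space != other.space or self.horizon != other.horizon:
            raise StructuralError("cannot add results over different spaces/horizons")
        return EconomicResult(
            self.space,
            self.total_cost + other.total_cost,
            self.total_qaly + other.total_qaly,
            {s: self.per_state_cost[s] + other.per_state_cost[s] for s in self.space.states},
            {
                s: self.per_state_person_years[s] + other.per_state_person_years[s]
                for s in self.space.states
            },
            self.horizon,
        )


#: marker stored in IncrementalResult.icer when delta_effect == 0
UNDEFINED_ICER = "undefined"


@dataclass
class IncrementalResult:
    """Incremental comparison of scenario b against scenario a.

    ``icer = delta_cost / delta_effect`` with signs preserved; when
    ``delta_effect == 0`` the ratio is undefined and ``icer`` is ``None``
    with ``status == "undefined"`` (dominance must be judged from the
    signs, never from an absolute value).
    """

    delta_cost: float
    delta_effect: float
    icer: float | None
    status: str  # "defined" | "undefined"
    occupancy_diff: pd.DataFrame | None = None


#: slack (relative to cohort size) below which a trace entry counts as negative
CONSERVATION_SLACK = 1e-9


def _cycle_weights(horizon: int, timing: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (cycle indices, row-weight matrix rows) for an accrual timing.

    Yields pairs such that accrual sums w * occupancy[row] at discount
    cycle t for each (t, row, w).
    """
    if timing == "end":
        return np.arange(1, horizon + 1), [((t, 1.0),) for t in range(1, horizon + 1)]
    if timing == "start":
        return np.arange(1, horizon + 1), [((t - 1, 1.0),) for t in range(1, horizon + 1)]
    if timing == "half":
        return (
            np.arange(1, horizon + 1),
            [((t - 1, 0.5), (t, 0.5)) for t in range(1, horizon + 1)],
        )
    raise ValueError(f"unknown accrual timing {timing!r}")


def accrue(
    trace: CohortTrace,
    costs: CostSchedule,
    utilities: UtilitySchedule,
    discount: DiscountSchedule,
    *,
    utility_discount: DiscountSchedule | None = None,
    timing: str = "end",
) -> EconomicResult:
    """Accrue discounted costs and QALYs over a cohort trace.

    ``utility_discount`` defaults to the cost discount; passing a
    different schedule lets costs and QALYs be discounted at different
    rates (including 0).
    """
    for sched in (costs, utilities):
        if sched.space != trace.space:
            raise StructuralError("schedule states do not match the trace")
    if (trace.occupancy < -CONSERVATION_SLACK * max(trace.initial_size, 1.0)).any():
        raise ValueError("negative occupancy in trace")
    udisc = utility_discount if utility_discount is not None else discount
    cvec = costs.vector()
    uvec = utilities.vector()
    n = trace.horizon
    cycles, rows = _cycle_weights(n, timing)
    per_state_cost = np.zeros(len(trace.space))
    per_state_py = np.zeros(len(trace.space))
    total_qaly = 0.0
    for t, parts in zip(cycles, rows):
        occ = sum(w * trace.occupancy[r] for r, w in parts)
        fc = discount.factor(int(t))
        fu = udisc.factor(int(t))
        per_state_cost += occ * cvec * fc
        per_state_py += occ
        total_qaly += float(occ @ uvec) * fu
    states = trace.space.states
    return EconomicResult(
        trace.space,
        total_cost=float(per_state_cost.sum()),
        total_qaly=total_qaly,
        per_state_cost=dict(zip(states, per_state_cost.tolist())),
        per_state_person_years=dict(zip(states, per_state_py.tolist())),
        horizon=n,
    )


def compute_icer(a: EconomicResult, b: EconomicResult) -> IncrementalResult:
    """Incremental cost-effectiveness of b over a: (cost_b - cost_a) / (qaly_b - qaly_a)."""
    if a.space != b.space:
        raise StructuralError("results come from different state spaces")
    if a.horizon != b.horizon:
        raise StructuralError(f"horizon mismatch: {a.horizon} vs {b.horizon}")
    delta_cost = b.total_cost - a.total_cost
    delta_effect = b.total_qaly - a.total_qaly
    if delta_effect == 0.0:
        return IncrementalResult(delta_cost, delta_effect, None, UNDEFINED_ICER)
    return IncrementalResult(delta_cost, delta_effect, delta_cost / delta_effect, "defined")


def occupancy_difference(a: CohortTrace, b: CohortTrace) -> pd.DataFrame:
    """Signed per-state occupancy differences (b - a).

    Reported under both conventions because the field uses both: the
    difference at the final cycle (``final_cycle``) and the cumulative
    person-year difference over cycles 1..n (``person_years``).
    """
    if a.space != b.space:
        raise StructuralError("traces over different state spaces")
    if a.horizon != b.horizon:
        raise StructuralError(f"horizon mismatch: {a.horizon} vs {b.horizon}")
    diff = b.occupancy - a.occupancy
    return pd.DataFrame(
        {
            "final_cycle": diff[-1],
            "person_years": diff[1:].sum(axis=0),
        },
        index=pd.Index(a.space.states, name="state"),
    )
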