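"""Random model generation and brute-force oracles.

The generator emits structurally valid cost-effectiveness models — a
row-stochastic transition matrix over 2-8 states with an absorbing death
state, nonnegative costs (death 0), utilities in [0, 1] (death 0) — so
that the engine and economics layers can be exercised without any real
data.  The fixtures are structural, not clinical: they make no attempt to
look like diabetes epidemiology.

The oracles recompute traces and accruals with explicit nested Python
loops, sharing no code with :mod:`markovcea.engine` or
:mod:`markovcea.econ`; agreement between the two routes is the package's
core correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .econ import CostSchedule, DiscountSchedule, UtilitySchedule
from .engine import MarkovModel, StateSpace, TransitionMatrix

__all__ = ["GeneratorConfig", "SyntheticModel", "random_model", "oracle_trace", "oracle_accrue"]


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int
    n_states: int = 4
    horizon: int = 10
    max_cost: float = 50_000.0
    discount_rate: float = 0.04
    max_initial: float = 10_000.0

    def __post_init__(self) -> None:
        if not (2 <= self.n_states <= 8):
            raise ValueError(f"n_states must be in 2..8, got {self.n_states}")
        if not (1 <= self.horizon <= 30):
            raise ValueError(f"horizon must be in 1..30, got {self.horizon}")
        if self.max_cost < 0 or self.discount_rate < 0:
            raise ValueError("max_cost and discount_rate must be nonnegative")


@dataclass
class SyntheticModel:
    model: MarkovModel
    costs: CostSchedule
    utilities: UtilitySchedule
    discount: DiscountSchedule
    initial: np.ndarray


def random_model(config: GeneratorConfig) -> SyntheticModel:
    """Draw one valid model; identical config -> bit-identical output.

    Transient rows are normalised positive draws (hence exactly
    row-stochastic); the death row is absorbing; death cost and utility
    are zero.  A single seeded generator is threaded through all draws —
    no global numpy state is touched.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_states
    labels = tuple(f"s{i}" for i in range(n - 1)) + ("death",)
    space = StateSpace(labels, absorbing=frozenset({"death"}))
    probs = np.zeros((n, n))
    for i in range(n - 1):
        row = rng.uniform(0.05, 1.0, size=n)
        probs[i] = row / row.sum()
    probs[n - 1, n - 1] = 1.0
    matrix = TransitionMatrix(space, probs)
    model = MarkovModel(space, matrix, horizon=config.horizon)
    costs = {s: float(rng.uniform(0.0, config.max_cost)) for s in labels}
    costs["death"] = 0.0
    utilities = {s: float(rng.uniform(0.0, 1.0)) for s in labels}
    utilities["death"] = 0.0
    initial = rng.uniform(0.0, config.max_initial, size=n)
    initial[n - 1] = 0.0
    return SyntheticModel(
        model=model,
        costs=CostSchedule(space, costs),
        utilities=UtilitySchedule(space, utilities),
        discount=DiscountSchedule(config.discount_rate, origin=0),
        initial=initial,
    )


def oracle_trace(probs, initial, horizon: int):
    """Trace by explicit element-wise loops (no vectorised products)."""
    probs = [[float(p) for p in row] for row in np.asarray(probs)]
    n = len(probs)
    occ = [[0.0] * n for _ in range(horizon + 1)]
    for j in range(n):
        occ[0][j] = float(initial[j])
    for t in range(1, horizon + 1):
        for j in range(n):
            total = 0.0
            for i in range(n):
                total += occ[t - 1][i] * probs[i][j]
            occ[t][j] = total
    return occ


def oracle_accrue(
    synthetic: SyntheticModel,
    initial=None,
    *,
    timing: str = "end",
    utility_rate: float | None = None,
    origin: int = 0,
) -> tuple[float, float]:
    """(total cost, total QALYs) by explicit nested loops.

    Independent of :func:`markovcea.econ.accrue`: its own trace loop, its
    own discount arithmetic.
    """
    model = synthetic.model
    if initial is None:
        initial = synthetic.initial
    occ = oracle_trace(model.matrix.probs, initial, model.horizon)
    labels = model.space.states
    rate = synthetic.discount.rate
    urate = rate if utility_rate is None else utility_rate
    total_cost = 0.0
    total_qaly = 0.0
    for t in range(1, model.horizon + 1):
        row = occ[t] if timing == "end" else occ[t - 1]
        exponent = t - origin if t - origin > 0 else 0
        fc = 1.0 / (1.0 + rate) ** exponent
        fu = 1.0 / (1.0 + urate) ** exponent
        for j, label in enumerate(labels):
            total_cost += row[j] * synthetic.costs.annual_cost[label] * fc
            total_qaly += row[j] * synthetic.utilities.annual_utility[label] * fu
    return total_cost, total_qaly
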