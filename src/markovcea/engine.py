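"""Cohort state-transition core.

A Markov cohort model tracks the expected number of patients in each of a
small set of mutually exclusive health states.  Each cycle (one year here)
the occupancy row vector is propagated through a row-stochastic transition
matrix; absorbing states (at minimum death) are never left.  The engine is
deterministic: occupancies are expected values, real-valued, and conserved
across cycles.

The classes in this module are deliberately thin wrappers around numpy
arrays so that the economics layer (:mod:`markovcea.econ`) can consume
traces directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StateSpace",
    "TransitionMatrix",
    "MarkovModel",
    "CohortTrace",
    "ValidationReport",
    "StructuralError",
    "validate_matrix",
    "matrix_from_edges",
    "step_cohort",
    "simulate_cohort",
]

#: tolerance on row sums of a transition matrix
ROW_SUM_TOL = 1e-9
#: relative tolerance on cohort-size conservation in a trace
CONSERVATION_RTOL = 1e-6


class StructuralError(ValueError):
    """A model is malformed (unknown state, shape mismatch, bad horizon).

    Distinct from a numeric validation failure, which is reported through
    :class:`ValidationReport` rather than raised.
    """


@dataclass(frozen=True)
class StateSpace:
    """Ordered set of health-state labels with an absorbing subset."""

    states: tuple[str, ...]
    absorbing: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        if not states:
            raise StructuralError("state space needs at least one state")
        if any(not isinstance(s, str) or not s for s in states):
            raise StructuralError("state labels must be nonempty strings")
        if len(set(states)) != len(states):
            raise StructuralError(f"duplicate state labels in {states}")
        unknown = self.absorbing - set(states)
        if unknown:
            raise StructuralError(f"absorbing labels not in state space: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self):
        return iter(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise StructuralError(f"unknown state label {label!r}") from None

    @property
    def absorbing_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s in self.absorbing]


@dataclass
class TransitionMatrix:
    """Annual transition probabilities over a :class:`StateSpace`.

    ``probs[i, j]`` is the probability of moving from ``space.states[i]``
    to ``space.states[j]`` in one cycle.
    """

    space: StateSpace
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        n = len(self.space)
        if self.probs.shape != (n, n):
            raise StructuralError(
                f"matrix shape {self.probs.shape} does not match {n} states"
            )

    def __getitem__(self, key: tuple[str, str]) -> float:
        frm, to = key
        return float(self.probs[self.space.index(frm), self.space.index(to)])

    def permuted(self, order: tuple[str, ...]) -> "TransitionMatrix":
        """Return the same matrix over a relabelled (permuted) state order."""
        if set(order) != set(self.space.states) or len(order) != len(self.space):
            raise StructuralError("permutation must cover exactly the same labels")
        idx = [self.space.index(s) for s in order]
        space = StateSpace(tuple(order), self.space.absorbing)
        return TransitionMatrix(space, self.probs[np.ix_(idx, idx)])


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of :func:`validate_matrix`: pass/fail plus per-row residuals."""

    ok: bool
    row_residuals: dict[str, float]
    messages: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.ok


@dataclass
class MarkovModel:
    """A validated transition structure plus the simulation horizon.

    half_cycle
        Off by default.  When on, downstream accrual averages the
        start-of-cycle and end-of-cycle occupancies instead of using a
        single convention.
    """

    space: StateSpace
    matrix: TransitionMatrix
    horizon: int
    half_cycle: bool = False

    def __post_init__(self) -> None:
        if self.matrix.space is not self.space and self.matrix.space != self.space:
            raise StructuralError("matrix defined over a different state space")
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise StructuralError(f"horizon must be a positive integer, got {self.horizon}")
        self.horizon = int(self.horizon)
        report = validate_matrix(self.matrix, self.space)
        if not report:
            raise StructuralError("invalid transition matrix: " + "; ".join(report.messages))


@dataclass
class CohortTrace:
    """Per-cycle expected state occupancy, cycles t = 0..horizon inclusive."""

    space: StateSpace
    occupancy: np.ndarray  # shape (horizon + 1, n_states), persons
    initial_size: float

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.occupancy.ndim != 2 or self.occupancy.shape[1] != len(self.space):
            raise StructuralError("occupancy must be (cycles, n_states)")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def column(self, label: str) -> np.ndarray:
        return self.occupancy[:, self.space.index(label)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.occupancy, columns=list(self.space.states))
        df.index.name = "cycle"
        return df


def validate_matrix(matrix: TransitionMatrix, space: StateSpace | None = None) -> ValidationReport:
    """Check row-stochasticity, probability bounds and absorbing rows.

    Returns a report rather than raising: a numerically bad matrix is a
    *validation failure*; a matrix over the wrong labels is a
    :class:`StructuralError`.
    """
    if space is None:
        space = matrix.space
    if matrix.space != space:
        raise StructuralError(
            f"matrix states {matrix.space.states} do not match expected {space.states}"
        )
    msgs: list[str] = []
    residuals: dict[str, float] = {}
    P = matrix.probs
    for i, label in enumerate(space.states):
        residual = float(P[i].sum() - 1.0)
        residuals[label] = residual
        if abs(residual) > ROW_SUM_TOL:
            msgs.append(f"row {label!r} sums to {P[i].sum():.12g} (residual {residual:.3g})")
    bad = (P < 0.0) | (P > 1.0)
    if bad.any():
        for i, j in zip(*np.nonzero(bad)):
            msgs.append(
                f"entry {space.states[i]!r}->{space.states[j]!r} = {P[i, j]:.12g} outside [0, 1]"
            )
    for i in space.absorbing_indices:
        if P[i, i] != 1.0:
            msgs.append(
                f"absorbing state {space.states[i]!r} has self-transition {P[i, i]:.12g} != 1"
            )
    return ValidationReport(ok=not msgs, row_residuals=residuals, messages=tuple(msgs))


def matrix_from_edges(
    space: StateSpace,
    edges: dict[tuple[str, str], float],
    *,
    log: list[str] | None = None,
) -> TransitionMatrix:
    """Build a transition matrix from a sparse edge list.

    Rows that do not sum to 1 are completed by assigning the remainder to
    the self-transition; every such completion is appended to ``log`` so
    the repair is never silent.  A row whose explicit probabilities exceed
    1 (beyond tolerance) is a :class:`StructuralError` naming the row.
    Absorbing states reject outgoing edges and get self-probability 1.
    """
    n = len(space)
    P = np.zeros((n, n))
    for (frm, to), p in edges.items():
        i, j = space.index(frm), space.index(to)
        if frm in space.absorbing and frm != to:
            raise StructuralError(f"absorbing state {frm!r} cannot have an outgoing edge to {to!r}")
        if not (0.0 <= p <= 1.0):
            raise StructuralError(f"edge {frm!r}->{to!r} probability {p} outside [0, 1]")
        P[i, j] += p
    for i in space.absorbing_indices:
        P[i, :] = 0.0
        P[i, i] = 1.0
    for i, label in enumerate(space.states):
        if label in space.absorbing:
            continue
        total = P[i].sum()
        if total > 1.0 + ROW_SUM_TOL:
            raise StructuralError(
                f"row {label!r}: explicit probabilities sum to {total:.12g} > 1"
            )
        remainder = 1.0 - total
        if abs(remainder) > ROW_SUM_TOL:
            P[i, i] += remainder
            if log is not None:
                log.append(
                    f"row {label!r}: assigned remainder {remainder:.6g} to self-transition"
                )
    return TransitionMatrix(space, P)


def step_cohort(occupancy: np.ndarray, matrix: TransitionMatrix) -> np.ndarray:
    """Advance the cohort one cycle: occupancy @ P.

    Persons are conserved because the matrix is row-stochastic.
    """
    occ = np.asarray(occupancy, dtype=float)
    if occ.shape != (len(matrix.space),):
        raise StructuralError(
            f"occupancy length {occ.shape} does not match {len(matrix.space)} states"
        )
    if (occ < 0).any():
        raise ValueError(f"negative occupancy rejected: {occ}")
    return occ @ matrix.probs


def simulate_cohort(model: MarkovModel, initial: np.ndarray | dict[str, float]) -> CohortTrace:
    """Run the full horizon and return the trace, t = 0 included.

    ``initial`` may be a vector in state order or a ``{label: persons}``
    mapping (unlisted states start empty).
    """
    if isinstance(initial, dict):
        vec = np.zeros(len(model.space))
        for label, count in initial.items():
            vec[model.space.index(label)] = count
        initial = vec
    initial = np.asarray(initial, dtype=float)
    if (initial < 0).any():
        raise ValueError("negative initial occupancy rejected")
    occ = np.empty((model.horizon + 1, len(model.space)))
    occ[0] = initial
    for t in range(1, model.horizon + 1):
        occ[t] = step_cohort(occ[t - 1], model.matrix)
    return CohortTrace(model.space, occ, initial_size=float(initial.sum()))
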