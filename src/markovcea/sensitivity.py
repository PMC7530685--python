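"""One-way (tornado) sensitivity analysis.

Each scenario perturbs exactly one parameter — a transition edge, a
per-state utility, a per-state cost, or the annual app cost — reruns the
two-scenario study, and records the resulting ICERs.  Scenarios are
ranked by the width of the ICER range they induce, the tornado ordering.

Parameter paths
---------------
``edge:FROM>TO``    a transition probability
``cost:STATE``      a per-state annual cost (base value, before any
                    structural composition)
``utility:STATE``   a per-state utility weight
``app_cost``        the annual app cost (app arm by construction)

Default grids follow the study's published protocol: transition
probabilities x0.5 / x2.0 (literature standard deviations being
unavailable), utilities and costs -10 % / +10 %; the one published
exception (insulin-therapy utility +/-5 %) is an extra manifest entry,
not a changed default.

By default a perturbation is applied to the app arm only — the published
analysis describes varying "the CGM app use model parameters" — with
``arms="both"`` available per scenario.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .econ import UNDEFINED_ICER
from .engine import StructuralError
from .study import (
    ANNUAL_COSTS_USD,
    STATES,
    UTILITIES,
    INSULIN_UTILITY,
    DEFAULT_SETTINGS,
    StudyPopulation,
    StudySettings,
    build_arm,
    run_study,
)

__all__ = [
    "SensitivityScenario",
    "ScenarioOutcome",
    "perturb",
    "run_tornado",
    "default_manifest",
]


@dataclass(frozen=True)
class SensitivityScenario:
    """One perturbed parameter with its low/high variation.

    ``kind`` is "multiplicative" (low/high are multipliers on the base
    value) or "relative" (low/high are fractional offsets, e.g. -0.10 for
    a 10 % reduction).  ``arms`` selects which arm receives the
    perturbation: "app" (default) or "both".
    """

    path: str
    kind: str
    low: float
    high: float
    arms: str = "app"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative", "relative"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.arms not in ("app", "both"):
            raise ValueError(f"arms must be 'app' or 'both', got {self.arms!r}")
        _parse_path(self.path)  # fail fast on malformed paths

    def value(self, base: float, which: str) -> float:
        delta = {"low": self.low, "high": self.high}[which]
        if self.kind == "multiplicative":
            return base * delta
        return base * (1.0 + delta)


@dataclass
class ScenarioOutcome:
    scenario: SensitivityScenario
    base_value: float
    icer_low: float | None
    icer_high: float | None
    icer_base: float

    @property
    def width(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return float("inf")
        return abs(self.icer_high - self.icer_low)


def _parse_path(path: str) -> tuple[str, tuple[str, ...]]:
    if path == "app_cost":
        return "app_cost", ()
    if ":" not in path:
        raise StructuralError(f"malformed parameter path {path!r}")
    kind, _, rest = path.partition(":")
    if kind == "edge":
        frm, sep, to = rest.partition(">")
        if not sep or frm not in STATES or to not in STATES:
            raise StructuralError(f"unknown edge path {path!r}")
        return "edge", (frm, to)
    if kind in ("cost", "utility"):
        if rest not in STATES:
            raise StructuralError(f"unknown state in path {path!r}")
        return kind, (rest,)
    raise StructuralError(f"unknown parameter kind in path {path!r}")


def _base_value(path: str, settings: StudySettings, arm: str) -> float:
    kind, parts = _parse_path(path)
    if kind == "app_cost":
        return build_arm("app_use", settings).app_annual_cost
    if kind == "edge":
        arm_params = build_arm(arm, settings)
        return arm_params.model.matrix[parts]
    if kind == "cost":
        return ANNUAL_COSTS_USD[parts[0]]
    if kind == "utility":
        if parts[0] == "insulin_therapy":
            return INSULIN_UTILITY[arm]
        return UTILITIES[parts[0]]
    raise AssertionError(kind)


def perturb(
    scenario: SensitivityScenario,
    which: str,
    settings: StudySettings = DEFAULT_SETTINGS,
) -> dict[str, dict]:
    """Resolve one scenario side into per-arm build overrides.

    Returns ``{"app_use": {...}, "non_use": {...}}`` keyword overrides for
    :func:`markovcea.study.build_arm`.  Exactly one parameter changes; a
    perturbed probability outside [0, 1] or a perturbed utility outside
    its bounds is an error, never clipped, and the death state's fixed
    cost/utility of zero may not be perturbed.
    """
    kind, parts = _parse_path(scenario.path)
    targets = ("app_use",) if scenario.arms == "app" else ("app_use", "non_use")
    overrides: dict[str, dict] = {"app_use": {}, "non_use": {}}
    for arm in targets:
        base = _base_value(scenario.path, settings, arm)
        new = scenario.value(base, which)
        if kind == "edge":
            if not (0.0 <= new <= 1.0):
                raise StructuralError(
                    f"{scenario.path}: perturbed probability {new:.6g} outside [0, 1]"
                )
            overrides[arm].setdefault("edge_overrides", {})[parts] = new
        elif kind == "cost":
            if parts[0] == "death":
                raise StructuralError("death state cost is fixed at 0")
            if new < 0:
                raise StructuralError(f"{scenario.path}: negative cost {new:.6g}")
            overrides[arm].setdefault("cost_overrides", {})[parts[0]] = new
        elif kind == "utility":
            if parts[0] == "death":
                raise StructuralError("death state utility is fixed at 0")
            if not (0.0 <= new <= 1.0):
                raise StructuralError(
                    f"{scenario.path}: perturbed utility {new:.6g} outside [0, 1]"
                )
            overrides[arm].setdefault("utility_overrides", {})[parts[0]] = new
        elif kind == "app_cost":
            if new < 0:
                raise StructuralError("negative app cost")
            overrides["app_use"]["app_annual_cost"] = new
    return overrides


def _run_with_overrides(
    overrides: dict[str, dict],
    population: StudyPopulation,
    settings: StudySettings,
) -> float | None:
    arms = {}
    for arm in ("non_use", "app_use"):
        kw = dict(overrides.get(arm, {}))
        app_cost = kw.pop("app_annual_cost", None)
        params = build_arm(arm, settings, **kw)
        if app_cost is not None:
            params.app_annual_cost = app_cost
        arms[arm] = params
    result = run_study(population, settings, non_use=arms["non_use"], app_use=arms["app_use"])
    return result.incremental.icer


def run_tornado(
    manifest: list[SensitivityScenario],
    population: StudyPopulation = StudyPopulation(),
    settings: StudySettings = DEFAULT_SETTINGS,
) -> pd.DataFrame:
    """Run every scenario and return the tornado table, widest range first.

    The base case is computed once and shared; any scenario failure aborts
    the whole run with the scenario named (no silent partial tables).
    Ties in range width break by manifest path so that two manifests with
    the same entries in different orders produce identical tables.
    """
    if not manifest:
        raise StructuralError("empty sensitivity manifest")
    base = run_study(population, settings)
    icer_base = base.incremental.icer
    if icer_base is None:
        raise StructuralError("base-case ICER undefined; tornado is meaningless")
    outcomes: list[ScenarioOutcome] = []
    for sc in manifest:
        try:
            icers = {}
            for which in ("low", "high"):
                icers[which] = _run_with_overrides(
                    perturb(sc, which, settings), population, settings
                )
            outcomes.append(
                ScenarioOutcome(
                    sc,
                    base_value=_base_value(sc.path, settings, "app_use"),
                    icer_low=icers["low"],
                    icer_high=icers["high"],
                    icer_base=icer_base,
                )
            )
        except Exception as exc:
            raise StructuralError(f"sensitivity scenario {sc.path!r} failed: {exc}") from exc
    outcomes.sort(key=lambda o: (-o.width, o.scenario.path, o.scenario.label))
    rows = []
    for o in outcomes:
        rows.append(
            {
                "parameter": o.scenario.label or o.scenario.path,
                "path": o.scenario.path,
                "kind": o.scenario.kind,
                "arms": o.scenario.arms,
                "base_value": o.base_value,
                "icer_base": o.icer_base,
                "icer_low": o.icer_low if o.icer_low is not None else UNDEFINED_ICER,
                "icer_high": o.icer_high if o.icer_high is not None else UNDEFINED_ICER,
                "range_width": o.width,
            }
        )
    return pd.DataFrame(rows)


def default_manifest() -> list[SensitivityScenario]:
    """The packaged tornado: x0.5/x2 on every transition edge, +/-10 % on
    every cost and utility, +/-10 % on the app cost, plus the published
    one-off +/-5 % insulin-therapy utility entry."""
    manifest: list[SensitivityScenario] = []
    edges = [
        ("insulin_therapy", "microalbuminuria"),
        ("insulin_therapy", "macroalbuminuria"),
        ("microalbuminuria", "macroalbuminuria"),
        ("macroalbuminuria", "esrd"),
        ("esrd", "dialysis"),
        ("microalbuminuria", "cvd"),
        ("macroalbuminuria", "cvd"),
        ("esrd", "cvd"),
        ("dialysis", "death"),
        ("cvd", "death"),
    ]
    for frm, to in edges:
        manifest.append(
            SensitivityScenario(f"edge:{frm}>{to}", "multiplicative", 0.5, 2.0)
        )
    for state in STATES:
        if state == "death":
            continue
        manifest.append(SensitivityScenario(f"cost:{state}", "relative", -0.10, +0.10))
        manifest.append(SensitivityScenario(f"utility:{state}", "relative", -0.10, +0.10))
    manifest.append(SensitivityScenario("app_cost", "relative", -0.10, +0.10))
    manifest.append(
        SensitivityScenario(
            "utility:insulin_therapy", "relative", -0.05, +0.05,
            label="utility:insulin_therapy (+/-5%)",
        )
    )
    return manifest
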