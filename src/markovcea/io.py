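"""Config parsing, tabular writers and run manifests.

Model definitions travel as YAML with a strict schema: unknown keys are
rejected with the key named, probability and row-sum failures delegate to
:func:`markovcea.engine.validate_matrix`, and loading a written config
reproduces the model exactly.  All CSV output uses '.' decimals, no
thousands separators, UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

import numpy as np
import yaml

from .econ import CostSchedule, DiscountSchedule, UtilitySchedule
from .engine import (
    CohortTrace,
    MarkovModel,
    StateSpace,
    StructuralError,
    matrix_from_edges,
)
from .study import StudyPopulation, StudySettings

__all__ = [
    "ModelConfig",
    "RunManifest",
    "load_model_config",
    "write_model_config",
    "load_study_config",
    "load_manifest_config",
    "packaged_config_path",
    "write_trace_csv",
    "write_economic_csv",
    "write_incremental_csv",
]

_MODEL_KEYS = {
    "states",
    "absorbing",
    "horizon",
    "discount",
    "utility_discount",
    "accrual_timing",
    "edges",
    "costs",
    "utilities",
    "app_annual_cost",
    "currency",
    "notes",
}
_DISCOUNT_KEYS = {"rate", "origin"}
_EDGE_KEYS = {"from", "to", "p"}


@dataclass
class ModelConfig:
    """A fully resolved single-arm model: structure plus economics."""

    model: MarkovModel
    costs: CostSchedule
    utilities: UtilitySchedule
    discount: DiscountSchedule
    utility_discount: DiscountSchedule
    accrual_timing: str = "end"
    app_annual_cost: float = 0.0
    notes: str = ""
    resolution_log: tuple[str, ...] = ()


def _reject_unknown(mapping: dict, allowed: set[str], context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise StructuralError(f"unknown key(s) {sorted(unknown)} in {context}")


def _parse_discount(raw, context: str, default_rate: float = 0.04) -> DiscountSchedule:
    if raw is None:
        return DiscountSchedule(default_rate, origin=0)
    if not isinstance(raw, dict):
        raise StructuralError(f"{context} must be a mapping with keys rate/origin")
    _reject_unknown(raw, _DISCOUNT_KEYS, context)
    return DiscountSchedule(float(raw.get("rate", default_rate)), int(raw.get("origin", 0)))


def load_model_config(path: str | Path) -> ModelConfig:
    """Load and validate a single-arm model definition."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise StructuralError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _MODEL_KEYS, str(path))
    for key in ("states", "horizon", "edges", "costs", "utilities"):
        if key not in raw:
            raise StructuralError(f"{path}: missing required key {key!r}")
    space = StateSpace(tuple(raw["states"]), absorbing=frozenset(raw.get("absorbing", ())))
    edges: dict[tuple[str, str], float] = {}
    for i, edge in enumerate(raw["edges"]):
        if not isinstance(edge, dict):
            raise StructuralError(f"{path}: edge #{i} must be a mapping")
        _reject_unknown(edge, _EDGE_KEYS, f"{path} edge #{i}")
        try:
            edges[(edge["from"], edge["to"])] = float(edge["p"])
        except KeyError as exc:
            raise StructuralError(f"{path}: edge #{i} missing key {exc}") from None
    log: list[str] = []
    matrix = matrix_from_edges(space, edges, log=log)
    model = MarkovModel(space, matrix, horizon=int(raw["horizon"]))
    costs = CostSchedule(
        space,
        {str(k): float(v) for k, v in raw["costs"].items()},
        currency=str(raw.get("currency", "USD")),
    )
    utilities = UtilitySchedule(space, {str(k): float(v) for k, v in raw["utilities"].items()})
    discount = _parse_discount(raw.get("discount"), f"{path}:discount")
    utility_discount = (
        _parse_discount(raw["utility_discount"], f"{path}:utility_discount")
        if "utility_discount" in raw
        else discount
    )
    timing = str(raw.get("accrual_timing", "end"))
    if timing not in ("end", "start", "half"):
        raise StructuralError(f"{path}: unknown accrual_timing {timing!r}")
    return ModelConfig(
        model=model,
        costs=costs,
        utilities=utilities,
        discount=discount,
        utility_discount=utility_discount,
        accrual_timing=timing,
        app_annual_cost=float(raw.get("app_annual_cost", 0.0)),
        notes=str(raw.get("notes", "")),
        resolution_log=tuple(log),
    )


def write_model_config(config: ModelConfig, path: str | Path) -> None:
    """Serialise a model so that :func:`load_model_config` reproduces it."""
    space = config.model.space
    edges = []
    P = config.model.matrix.probs
    for i, frm in enumerate(space.states):
        for j, to in enumerate(space.states):
            if frm in space.absorbing:
                continue
            # self-transitions are the loader's row remainder; only
            # explicit off-diagonal mass is serialised
            if i != j and P[i, j] != 0.0:
                edges.append({"from": frm, "to": to, "p": float(P[i, j])})
    payload = {
        "states": list(space.states),
        "absorbing": sorted(space.absorbing),
        "horizon": config.model.horizon,
        "discount": {"rate": config.discount.rate, "origin": config.discount.origin},
        "utility_discount": {
            "rate": config.utility_discount.rate,
            "origin": config.utility_discount.origin,
        },
        "accrual_timing": config.accrual_timing,
        "edges": edges,
        "costs": {s: config.costs.annual_cost[s] for s in space.states},
        "utilities": {s: config.utilities.annual_utility[s] for s in space.states},
        "currency": config.costs.currency,
    }
    if config.app_annual_cost:
        payload["app_annual_cost"] = config.app_annual_cost
    if config.notes:
        payload["notes"] = config.notes
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


_STUDY_KEYS = {
    "population",
    "horizon",
    "discount",
    "utility_discount",
    "accrual_timing",
    "combine_insulin_cost",
    "app_cost_states",
    "insulin_to_macro",
    "invert_table1_labels",
    "uptake_mode",
    "currency",
    "wtp_thresholds",
    "notes",
}
_POPULATION_KEYS = {
    "claims_population",
    "eligible",
    "app_users",
    "uptake_fraction",
    "annual_uptake_probability",
}


def load_study_config(path: str | Path) -> tuple[StudyPopulation, StudySettings]:
    """Load the two-scenario study definition (population + switches)."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise StructuralError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _STUDY_KEYS, str(path))
    pop_raw = raw.get("population", {})
    _reject_unknown(pop_raw, _POPULATION_KEYS, f"{path}:population")
    population = StudyPopulation(**{k: v for k, v in pop_raw.items()})
    kwargs: dict = {}
    if "horizon" in raw:
        kwargs["horizon"] = int(raw["horizon"])
    if "discount" in raw:
        kwargs["discount"] = _parse_discount(raw["discount"], f"{path}:discount")
    if "utility_discount" in raw:
        kwargs["utility_discount"] = _parse_discount(
            raw["utility_discount"], f"{path}:utility_discount", default_rate=0.0
        )
    for key in (
        "accrual_timing",
        "combine_insulin_cost",
        "insulin_to_macro",
        "invert_table1_labels",
        "uptake_mode",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "app_cost_states" in raw:
        kwargs["app_cost_states"] = tuple(raw["app_cost_states"])
    return population, StudySettings(**kwargs)


_MANIFEST_KEYS = {"scenarios"}
_SCENARIO_KEYS = {"path", "kind", "low", "high", "arms", "label"}


def load_manifest_config(path: str | Path):
    """Load a tornado manifest: a list of one-parameter scenarios."""
    from .sensitivity import SensitivityScenario

    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise StructuralError(f"{path}: top level must be a mapping")
    _reject_unknown(raw, _MANIFEST_KEYS, str(path))
    scenarios = raw.get("scenarios") or []
    if not scenarios:
        raise StructuralError(f"{path}: manifest lists no scenarios")
    out = []
    for i, sc in enumerate(scenarios):
        _reject_unknown(sc, _SCENARIO_KEYS, f"{path} scenario #{i}")
        out.append(
            SensitivityScenario(
                path=sc["path"],
                kind=sc["kind"],
                low=float(sc["low"]),
                high=float(sc["high"]),
                arms=sc.get("arms", "app"),
                label=sc.get("label", ""),
            )
        )
    return out


def packaged_config_path(name: str) -> Path:
    """Path of a config shipped with the package (e.g. ``study.yaml``)."""
    ref = resources.files("markovcea") / "data" / name
    path = Path(str(ref))
    if not path.exists():
        raise FileNotFoundError(f"no packaged config named {name!r}")
    return path


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------


def write_trace_csv(trace: CohortTrace, path: str | Path) -> None:
    """One row per cycle, one column per state, header row of state labels."""
    trace.to_frame().to_csv(path, encoding="utf-8")


def write_economic_csv(results: dict[str, "EconomicResult"], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for label, res in results.items():
        row = {"scenario": label, "total_cost": res.total_cost, "total_qaly": res.total_qaly}
        for s in res.space.states:
            row[f"cost:{s}"] = res.per_state_cost[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_incremental_csv(inc, path: str | Path) -> None:
    import pandas as pd

    row = {
        "delta_cost": inc.delta_cost,
        "delta_effect": inc.delta_effect,
        "icer": inc.icer if inc.icer is not None else "undefined",
        "status": inc.status,
    }
    if inc.occupancy_diff is not None:
        for state, rec in inc.occupancy_diff.iterrows():
            row[f"final_cycle_diff:{state}"] = rec["final_cycle"]
            row[f"person_years_diff:{state}"] = rec["person_years"]
    pd.DataFrame([row]).to_csv(path, index=False, encoding="utf-8")


@dataclass
class RunManifest:
    """Reproducibility record paired with every set of result files."""

    command: str
    config_paths: dict[str, str]
    output_dir: str
    resolved_parameters: dict[str, object] = field(default_factory=dict)
    resolution_log: tuple[str, ...] = ()
    seed: int | None = None
    version: str = field(default_factory=lambda: _package_version())

    def to_json(self) -> str:
        payload = {
            "command": self.command,
            "config_paths": self.config_paths,
            "output_dir": self.output_dir,
            "resolved_parameters": self.resolved_parameters,
            "resolution_log": list(self.resolution_log),
            "seed": self.seed,
            "version": self.version,
        }
        return json.dumps(payload, indent=2, default=_json_default)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n", encoding="utf-8")


def _package_version() -> str:
    try:
        return metadata.version("markovcea")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")
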