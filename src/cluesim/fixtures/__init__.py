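"""Packaged reference parameterisation of the mining-area study.

Loads the published calibration tables shipped with the package — the
per-class logistic coefficients on standardized drivers, the
multicollinearity diagnostics, the three policy scenarios' 2025 demand
endpoints with their change summary, and the conversion elasticities —
so calibration-parameterised runs need no refitting.

The three scenarios are named ``natural`` (trend extrapolation),
``ecological`` (wetland/water/garden-land conversions restricted) and
``farmland`` (conversions out of farmland restricted).
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

from ..allocation import ScenarioConfig
from ..demand import DemandTable
from ..rasterkit import CLASS_CODES, N_CLASSES
from ..suitability import ClassModel, StandardizationParams, SuitabilityModel

__all__ = [
    "SCENARIOS",
    "reference_coefficients",
    "reference_suitability_model",
    "reference_collinearity",
    "scenario_endpoints_2025",
    "scenario_change_table",
    "scenario_start_areas",
    "scenario_elasticities",
    "scenario_allowed_matrix",
    "scenario_demand_table",
    "scenario_config",
]

SCENARIOS = ("natural", "ecological", "farmland")

#: Simulation horizon of the packaged scenarios.
START_YEAR = 2016
END_YEAR = 2025

#: Printed per-scenario 2025 totals agree within 0.02 ha; the common total.
TOTAL_AREA_HA = 117_681.84


def _read_text(name: str) -> str:
    return resources.files(__package__).joinpath("data", name).read_text()


def _read_csv(name: str) -> pd.DataFrame:
    import io

    return pd.read_csv(io.StringIO(_read_text(name)), comment="#")


def reference_coefficients() -> dict:
    """Raw published coefficient table (per-class intercept + included drivers)."""
    return json.loads(_read_text("table_coefficients.json"))


def reference_suitability_model(
    standardization: StandardizationParams | None = None,
) -> SuitabilityModel:
    """The published coefficients wrapped as a :class:`SuitabilityModel`.

    The published fit's standardization constants are unavailable, so the
    caller supplies the (mean, sd) parameters of the drivers the model
    will be applied to; identity parameters are used if omitted (drivers
    already standardized).
    """
    doc = reference_coefficients()
    classes = {
        int(c): ClassModel(
            class_code=int(c),
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
        )
        for c, d in doc["classes"].items()
    }
    if standardization is None:
        standardization = {name: (0.0, 1.0) for name in doc["driver_order"]}
    return SuitabilityModel(classes, standardization)


def reference_collinearity() -> pd.DataFrame:
    """Published tolerance/VIF diagnostics as a DataFrame indexed by driver."""
    doc = json.loads(_read_text("table_collinearity.json"))
    return pd.DataFrame({"tolerance": doc["tolerance"], "vif": doc["vif"]})


def _scenario_rows(scenario: str) -> pd.DataFrame:
    df = _read_csv("scenario_tables.csv")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return df[df["scenario"] == scenario].set_index("class_code").sort_index()


def scenario_endpoints_2025(scenario: str) -> dict[int, float]:
    """Projected 2025 class areas (ha) for one scenario."""
    rows = _scenario_rows(scenario)
    return {int(c): float(v) for c, v in rows["area_2025_ha"].items()}


def scenario_change_table(scenario: str) -> pd.DataFrame:
    """Published change summary: signed area change and dynamics (%/yr)."""
    return _scenario_rows(scenario)[["class_name", "area_change_ha", "single_dynamics_pct"]]


def scenario_start_areas(scenario: str) -> dict[int, float]:
    """Start-of-horizon areas implied by endpoint − change, renormalised.

    The printed start areas sum 4 ha off the common scenario total
    (rounding drift in the source tables); they are rescaled to close on
    :data:`TOTAL_AREA_HA` exactly.
    """
    rows = _scenario_rows(scenario)
    start = rows["area_2025_ha"] - rows["area_change_ha"]
    start = start * (TOTAL_AREA_HA / start.sum())
    return {int(c): float(v) for c, v in start.items()}


def scenario_elasticities(scenario: str) -> dict[int, float]:
    df = _read_csv("elasticities.csv")
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    rows = df[df["scenario"] == scenario].set_index("class_code").sort_index()
    return {int(c): float(v) for c, v in rows["elas"].items()}


def scenario_allowed_matrix(scenario: str) -> np.ndarray:
    """Allowed-conversion matrix per scenario narrative.

    Natural development permits every conversion. Ecological protection
    forbids water and tidal wetland turning into construction land;
    farmland protection forbids farmland turning into construction land.
    (Blanket bans on flows out of the protected classes would contradict
    the published endpoints, which still shrink those classes; the
    protective pressure is otherwise carried by elasticities and demand.)
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    allowed = np.ones((N_CLASSES, N_CLASSES), dtype=bool)
    if scenario == "ecological":
        allowed[4, 2] = False  # water -> construction
        allowed[5, 2] = False  # tidal wetland -> construction
    elif scenario == "farmland":
        allowed[0, 2] = False  # farmland -> construction
    return allowed


def scenario_demand_table(
    scenario: str, total_area_ha: float | None = None
) -> DemandTable:
    """Yearly demand trajectory from the start areas to the 2025 endpoints.

    Linear interpolation over the 2016–2025 horizon, each year's row
    renormalised to the common total so the table closes exactly.
    ``total_area_ha`` rescales the whole trajectory (preserving class
    shares) onto a different landscape, e.g. a synthetic one.
    """
    start = np.array([scenario_start_areas(scenario)[c] for c in CLASS_CODES])
    end = np.array([scenario_endpoints_2025(scenario)[c] for c in CLASS_CODES])
    end = end * (TOTAL_AREA_HA / end.sum())
    years = list(range(START_YEAR, END_YEAR + 1))
    frac = np.linspace(0.0, 1.0, len(years))
    rows = start[None, :] + frac[:, None] * (end - start)[None, :]
    rows *= TOTAL_AREA_HA / rows.sum(axis=1, keepdims=True)
    if total_area_ha is not None:
        rows *= total_area_ha / TOTAL_AREA_HA
    df = pd.DataFrame(rows, index=years, columns=list(CLASS_CODES))
    return DemandTable(df)


def scenario_config(
    scenario: str,
    total_area_ha: float | None = None,
    **overrides,
) -> ScenarioConfig:
    """Assemble the full packaged :class:`ScenarioConfig` for one scenario."""
    cfg = dict(
        name=scenario,
        elas=scenario_elasticities(scenario),
        demand=scenario_demand_table(scenario, total_area_ha),
        allowed=scenario_allowed_matrix(scenario),
    )
    cfg.update(overrides)
    return ScenarioConfig(**cfg)
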