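"""Robustness analyses under alternative portal-user definitions.

Two scenarios re-derive the cohort and re-run the full pipeline:

* ``min_two_logins`` -- users require at least two portal logins (the
  activation plus one subsequent login); adopters below the threshold are
  reclassified as non-users.
* ``include_consistent_users`` -- patients whose portal activation predates
  the study window join the user group with the adoption quarter set to the
  window start (t = 0); their baseline is floored at t = 0.

Scenario runs never mutate the input tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .prep import STATUS_CONSISTENT, STATUS_NONUSER, STATUS_USER

SCENARIOS = ("baseline", "min_two_logins", "include_consistent_users")


@dataclass(frozen=True)
class SensitivityScenario:
    name: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.name!r}; choose from {SCENARIOS}")


def redefine_users_by_login(patients: pd.DataFrame, min_logins: int = 2) -> pd.DataFrame:
    """Reclassify users with fewer than ``min_logins`` logins as non-users."""
    out = patients.copy()
    low = (out["status"] == STATUS_USER) & (out["login_count"] < min_logins)
    out.loc[low, "status"] = STATUS_NONUSER
    out.loc[low, "adopt_index"] = math.nan
    return out


def include_consistent_users(patients: pd.DataFrame) -> pd.DataFrame:
    """Move consistent-users into the user group with adoption at t = 0."""
    out = patients.copy()
    cons = out["status"] == STATUS_CONSISTENT
    out.loc[cons, "status"] = STATUS_USER
    out.loc[cons, "adopt_index"] = 0.0
    return out


def apply_scenario(
    scenario: SensitivityScenario, patients: pd.DataFrame
) -> pd.DataFrame:
    """Return the scenario's reclassified copy of the patient table."""
    if scenario.name == "baseline":
        return patients.copy()
    if scenario.name == "min_two_logins":
        return redefine_users_by_login(
            patients, int(scenario.parameters.get("min_logins", 2))
        )
    return include_consistent_users(patients)


def run_scenario(scenario: SensitivityScenario, patients, quarters, **pipeline_kwargs):
    """Run prepare -> match -> fit -> omega under a scenario; returns the bundle.

    Thin wrapper over :func:`portaldid.pipeline.analyze_cohort` on the
    reclassified patient table.
    """
    from .pipeline import analyze_cohort

    reclassified = apply_scenario(scenario, patients)
    if scenario.name == "include_consistent_users":
        pipeline_kwargs.setdefault("keep_window_start_users", True)
    return analyze_cohort(reclassified, quarters, **pipeline_kwargs)
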