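"""The nine P4P design/implementation scenarios as parameter overlays.

Each scenario is a named overlay of parameter overrides applied to the
calibrated base parameter file.  The catalogue mirrors the summary table of
the study design:

* group 1 -- no P4P (baseline facility operations);
* group 2 -- the simplest P4P scheme: bonuses flow into revenue but do not
  drive motivation, there is no gaming and no disbursement lag;
* group 3 -- one additional feature at a time: motivation (3a), low- and
  high-level gaming (3b, 3c), a disbursement delay (3d), low bonuses (3e);
* group 4 -- P4P with motivation, gaming and the bonus delay all present,
  differing only in how bonuses are distributed among staff, encoded as
  motivation-coupling configurations (equal allocation, proportionate to
  salaries, proportionate to services rendered).

"Low-level" gaming is a modest constant gaming propensity; "high-level"
gaming starts higher and is reinforced by received bonuses.  The numeric
values live in the YAML overlays frozen by the calibration script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .params import (
    InvariantError,
    ModelParams,
    iter_packaged_scenario_files,
    load_base_params,
)

__all__ = [
    "ScenarioSpec",
    "DistributionStrategy",
    "DISTRIBUTION_STRATEGIES",
    "SCENARIO_ORDER",
    "list_scenarios",
    "get_scenario",
    "build_scenario",
]

#: Catalogue order, matching the summary table rows 1 through 4c.
SCENARIO_ORDER: tuple[str, ...] = (
    "1", "2", "3a", "3b", "3c", "3d", "3e", "4a", "4b", "4c",
)


@dataclass(frozen=True)
class ScenarioSpec:
    """One named scenario: an id, a human label, and parameter overrides."""

    id: str
    label: str
    group: str
    overrides: Mapping[str, Any] = field(default_factory=dict)

    def resolve(self, base: ModelParams | None = None) -> ModelParams:
        """Apply this scenario's overrides to the base parameter set."""
        if base is None:
            base = load_base_params()
        return base.with_overrides(self.overrides)


@dataclass(frozen=True)
class DistributionStrategy:
    """How bonuses are split among staff, as aggregate motivation couplings.

    ``mu_quality``/``mu_volume`` switch whether extrinsic motivation
    modulates the quality-conversion and volume-recruitment flows;
    ``motivation_active`` says whether bonuses drive motivation at all;
    gaming is present under every strategy in group 4.
    """

    name: str
    mu_quality: int
    mu_volume: int
    motivation_active: bool
    gaming_active: bool = True


#: Equal allocation motivates only low earners appreciably: motivation can
#: lift the quality flow but not the volume flow.  Salary-proportionate
#: allocation fails to activate rank-and-file motivation and leaves the
#: scheme exposed to gaming by facility leadership.  Service-proportionate
#: allocation rewards exactly the effort that triggered payment, activating
#: motivation on both flows.
DISTRIBUTION_STRATEGIES: dict[str, DistributionStrategy] = {
    "equal": DistributionStrategy("equal", 1, 0, True),
    "salary_proportionate": DistributionStrategy("salary_proportionate", 1, 1, False),
    "service_proportionate": DistributionStrategy("service_proportionate", 1, 1, True),
}

_STRATEGY_BY_SCENARIO = {
    "4a": "equal",
    "4b": "salary_proportionate",
    "4c": "service_proportionate",
}


def _load_catalogue() -> dict[str, ScenarioSpec]:
    catalogue: dict[str, ScenarioSpec] = {}
    for sid, path in iter_packaged_scenario_files():
        with path.open() as fh:
            doc = yaml.safe_load(fh)
        if doc.get("id") != sid:
            raise InvariantError(f"id: overlay file {path.name} declares id {doc.get('id')!r}")
        catalogue[sid] = ScenarioSpec(
            id=sid,
            label=doc.get("label", sid),
            group=doc.get("group", ""),
            overrides=doc.get("overrides", {}) or {},
        )
    missing = set(SCENARIO_ORDER) - set(catalogue)
    if missing:
        raise InvariantError(f"scenarios: packaged overlays missing ids {sorted(missing)}")
    return catalogue


_CATALOGUE: dict[str, ScenarioSpec] | None = None


def _catalogue() -> dict[str, ScenarioSpec]:
    global _CATALOGUE
    if _CATALOGUE is None:
        _CATALOGUE = _load_catalogue()
    return _CATALOGUE


def list_scenarios() -> list[ScenarioSpec]:
    """The ten scenarios in summary-table order."""
    cat = _catalogue()
    return [cat[sid] for sid in SCENARIO_ORDER]


def get_scenario(scenario_id: str) -> ScenarioSpec:
    """Look one scenario up by id; raises with the valid ids listed."""
    cat = _catalogue()
    if scenario_id not in cat:
        raise InvariantError(
            f"scenario_id: unknown scenario {scenario_id!r}; "
            f"valid ids are {', '.join(SCENARIO_ORDER)}"
        )
    return cat[scenario_id]


def load_scenario_file(path: str | Path) -> ScenarioSpec:
    """Load a custom overlay file (same schema as the packaged ones)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "id" not in doc:
        raise InvariantError(f"id: overlay {path} must be a mapping with an 'id' key")
    return ScenarioSpec(
        id=str(doc["id"]),
        label=doc.get("label", str(doc["id"])),
        group=doc.get("group", "custom"),
        overrides=doc.get("overrides", {}) or {},
    )


def build_scenario(
    scenario_id: str, base: ModelParams | None = None
) -> ModelParams:
    """Fully-resolved parameters for one scenario.

    Idempotent: the overrides are absolute values, so applying a scenario to
    an already-resolved parameter set changes nothing further.
    """
    return get_scenario(scenario_id).resolve(base)


def strategy_for(scenario_id: str) -> DistributionStrategy | None:
    """The bonus-distribution strategy of a group-4 scenario, else None."""
    name = _STRATEGY_BY_SCENARIO.get(scenario_id)
    return DISTRIBUTION_STRATEGIES[name] if name else None
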