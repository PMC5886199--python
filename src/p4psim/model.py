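"""Model/Results facade over the stock-and-flow engine.

:class:`FacilityP4PModel` bundles a resolved parameter set (usually built
from a named scenario) and exposes :meth:`~FacilityP4PModel.simulate`, which
returns a :class:`SimulationResults` carrying the trajectory, equilibrium
diagnostics, export helpers and plotting.
"""

from __future__ import annotations

import io
from pathlib import Path

import yaml

from .core import Trajectory, integrate
from .equilibrium import (
    DEFAULT_EPSILON,
    DEFAULT_SNAP_BAND,
    DEFAULT_WINDOW,
    EquilibriumSummary,
    detect_equilibrium,
)
from .params import ModelParams
from .scenarios import ScenarioSpec, get_scenario

__all__ = ["FacilityP4PModel", "SimulationResults"]


class FacilityP4PModel:
    """A single modelled health facility under a P4P implementation scenario.

    Parameters
    ----------
    params : ModelParams
        Fully-resolved rates, P4P settings and initial stocks.
    scenario_id, label : str
        Optional provenance carried into trajectories and summaries.

    Examples
    --------
    >>> model = FacilityP4PModel.from_scenario("2")
    >>> res = model.simulate()
    >>> eq = res.equilibrium()
    >>> (eq.q_eq, eq.v_eq, eq.t_eq)
    (1.0, 1.0, 60.0)
    """

    def __init__(
        self, params: ModelParams, scenario_id: str = "", label: str = ""
    ) -> None:
        self.params = params
        self.scenario_id = scenario_id
        self.label = label or scenario_id

    @classmethod
    def from_scenario(
        cls, scenario_id: str, base: ModelParams | None = None
    ) -> "FacilityP4PModel":
        """Build the model for one named scenario over the calibrated base file."""
        spec = get_scenario(scenario_id)
        return cls(spec.resolve(base), scenario_id=spec.id, label=spec.label)

    @classmethod
    def from_spec(
        cls, spec: ScenarioSpec, base: ModelParams | None = None
    ) -> "FacilityP4PModel":
        return cls(spec.resolve(base), scenario_id=spec.id, label=spec.label)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FacilityP4PModel":
        """Build from a standalone parameter file (no scenario overlay)."""
        return cls(ModelParams.from_yaml(path), scenario_id=str(path))

    def simulate(self, horizon: float = 100.0, dt: float = 0.25) -> "SimulationResults":
        """Integrate the model and return the results object."""
        traj = integrate(self.params, horizon=horizon, dt=dt, scenario_id=self.scenario_id)
        return SimulationResults(self, traj)


class SimulationResults:
    """Results of one simulation run: trajectory, diagnostics, exports."""

    def __init__(self, model: FacilityP4PModel, trajectory: Trajectory) -> None:
        self.model = model
        self.trajectory = trajectory

    @property
    def params(self) -> ModelParams:
        return self.model.params

    def equilibrium(
        self,
        epsilon: float = DEFAULT_EPSILON,
        window: float = DEFAULT_WINDOW,
        snap_band: float = DEFAULT_SNAP_BAND,
    ) -> EquilibriumSummary:
        """Equilibrium levels, time and convergence flag for this run."""
        return detect_equilibrium(
            self.trajectory, epsilon=epsilon, window=window, snap_band=snap_band
        )

    def to_frame(self):
        return self.trajectory.to_frame()

    def config_header(self) -> str:
        """Comment block with the resolved configuration, for provenance."""
        doc = {
            "scenario_id": self.model.scenario_id,
            "label": self.model.label,
            "horizon": self.trajectory.horizon,
            "dt": self.trajectory.dt,
            "params": self.params.to_dict(),
        }
        lines = yaml.safe_dump(doc, sort_keys=True).rstrip().splitlines()
        return "".join(f"# {line}\n" for line in lines)

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory as CSV with the resolved config as a header."""
        with open(path, "w") as fh:
            fh.write(self.config_header())
            self.to_frame().to_csv(fh, index=False)

    def summary(self) -> str:
        """Human-readable run summary."""
        eq = self.equilibrium()
        traj = self.trajectory
        buf = io.StringIO()
        title = f"Facility P4P simulation -- scenario {self.model.scenario_id or '(custom)'}"
        buf.write(title + "\n" + "=" * len(title) + "\n")
        if self.model.label and self.model.label != self.model.scenario_id:
            buf.write(f"{self.model.label}\n")
        buf.write(
            f"horizon: {traj.horizon:g} months, dt: {traj.dt:g} months, "
            f"P4P {'enabled' if self.params.p4p.enabled else 'disabled'}\n\n"
        )
        if eq.converged:
            buf.write(
                f"equilibrium: Q = {eq.q_eq:g}, V = {eq.v_eq:g} "
                f"at t = {eq.t_eq:g} months (raw {eq.t_eq_raw:g})\n"
            )
        else:
            buf.write(
                "no equilibrium within the horizon; at "
                f"{traj.horizon:g} months Q = {eq.q_at_horizon:g}, "
                f"V = {eq.v_at_horizon:g}\n"
            )
        buf.write(
            f"final stocks: R = {traj.revenue[-1]:+.3f}, "
            f"Q = {traj.quality[-1]:+.3f}, V = {traj.volume[-1]:+.3f}\n"
        )
        buf.write(
            f"final auxiliaries: bonus = {traj.bonus[-1]:.3f}, "
            f"motivation = {traj.motivation[-1]:.3f}, gaming = {traj.gaming[-1]:.3f}\n"
        )
        return buf.getvalue()

    def plot(self, ax=None, show_auxiliaries: bool = False):
        """Quality/volume time plot (plus auxiliaries on a twin axis if asked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        t = self.trajectory.times
        ax.plot(t, self.trajectory.quality, label="quality", lw=2)
        ax.plot(t, self.trajectory.volume, label="volume", lw=2, ls="--")
        ax.axhline(0.0, color="0.7", lw=0.8)
        ax.set_xlabel("time (months)")
        ax.set_ylabel("stock level (unitless, -1 to 1)")
        ax.set_ylim(-1.05, 1.05)
        title = self.model.label or self.model.scenario_id
        ax.set_title(title)
        if show_auxiliaries:
            ax2 = ax.twinx()
            ax2.plot(t, self.trajectory.motivation, color="tab:green", alpha=0.6,
                     label="motivation")
            ax2.plot(t, self.trajectory.gaming, color="tab:red", alpha=0.6,
                     label="gaming")
            ax2.set_ylabel("auxiliaries")
        ax.legend(loc="lower right")
        return ax
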