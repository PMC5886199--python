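"""Parameter containers for the facility stock-and-flow model.

Two dataclasses hold the model constants: :class:`RateParams` for the four
flow-rate constants of basic facility operations (plus the volume-perception
delay and baseline motivation), and :class:`P4PParams` for everything the
pay-for-performance extension adds (bonus schedule, payment delays,
motivation couplings, gaming).  :class:`ModelParams` bundles both together
with the initial stock levels and knows how to load itself from the YAML
files shipped with the package and how to apply named overrides (used by the
scenario overlays and sensitivity sweeps).

All stocks are unitless on the [-1, 1] scale (-1 below-average, 0 average,
+1 above-average facility); time is in months.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping

import yaml

__all__ = [
    "InvariantError",
    "RateParams",
    "P4PParams",
    "ModelParams",
    "load_base_params",
]


class InvariantError(ValueError):
    """A parameter or state value violates a model invariant.

    The message always names the offending field.
    """


def _require(condition: bool, field_name: str, message: str) -> None:
    if not condition:
        raise InvariantError(f"{field_name}: {message}")


@dataclass(frozen=True)
class RateParams:
    """Rate constants of basic facility operations.

    Attributes
    ----------
    r_revenue : float
        Recovery rate of revenue (symbol ``rR``), the base monthly inflow of
        funds to the facility, in stock units per month.
    r_conversion : float
        Conversion rate of revenue to quality (``rRQ``): how quickly funds
        turn into service capability, per month.
    r_depletion : float
        Depletion rate of quality (``rQ``): wear on capability as client
        volume loads the facility, per month.
    r_volume : float
        Recovery rate of volume (``rV``): how quickly client volume is
        recruited toward the level indicated by (perceived, delayed)
        quality, per month.
    r_attrition : float
        Attrition rate of volume (``rA``): how quickly clients leave when
        perceived quality sits below the current volume level, per month.
        Dissatisfied clients leave faster than new ones are recruited, so
        the default calibration sets this above ``r_volume``.
    kappa_volume : float
        Sensitivity of the revenue inflow to current volume, dimensionless,
        in [0, 1] so the inflow stays non-negative at the volume floor.
    tau_perception : float
        Delay, in months, before clients perceive a change in quality and
        volume responds to it.
    motivation_baseline : float
        Baseline extrinsic motivation ``E0`` (> 0): some motivation exists
        among health workers regardless of any bonus scheme.
    """

    r_revenue: float
    r_conversion: float
    r_depletion: float
    r_volume: float
    r_attrition: float | None = None
    kappa_volume: float = 0.0
    tau_perception: float = 0.0
    motivation_baseline: float = 1.0

    def __post_init__(self) -> None:
        if self.r_attrition is None:
            # Unspecified => symmetric relaxation, attrition as fast as recruitment.
            object.__setattr__(self, "r_attrition", self.r_volume)
        for name in ("r_revenue", "r_conversion", "r_depletion", "r_volume", "r_attrition"):
            _require(getattr(self, name) >= 0.0, name, "rate must be non-negative")
        _require(0.0 <= self.kappa_volume <= 1.0, "kappa_volume", "must lie in [0, 1]")
        _require(self.tau_perception >= 0.0, "tau_perception", "delay must be non-negative")
        _require(self.motivation_baseline > 0.0, "motivation_baseline", "must be strictly positive")


@dataclass(frozen=True)
class P4PParams:
    """Parameters of the pay-for-performance extension.

    Attributes
    ----------
    enabled : bool
        Master switch.  When False every bonus-driven flow is exactly zero
        and the model reduces to basic facility operations.
    bonus_rate : float
        Bonus paid per unit of above-baseline volume (``b``), per month.
    volume_base : float
        Baseline volume threshold for payment (``vBase``), unitless.
        Facilities are never penalised for falling below it.
    tau_cycle : float
        Payment-cycle delay in months (> 0): bonuses in the current cycle are
        based on the volume of the preceding cycle.
    tau_disbursement : float
        Additional authorisation-to-disbursement lag, months (>= 0); zero
        except in the delayed-bonus scenarios.
    mu_quality, mu_volume : float
        Exponents (0 or 1 in the shipped scenarios) switching whether
        extrinsic motivation modulates the revenue-to-quality conversion and
        the volume recruitment flow, respectively.
    motivation_gain : float
        Effect of a unit of disbursed bonus on extrinsic motivation
        (``mu`` >= 0); zero when the scheme does not activate motivation.
    gaming_init : float
        Initial/exogenous gaming level, in [0, 1]: gaming already practised
        before any bonus is received.
    gaming_feedback : float
        Reinforcement rate of gaming by received bonuses (``rho`` >= 0); the
        bonus-gaming loop is reinforcing.
    gaming_max : float
        Gaming capacity, in [0, 1]: the saturation level the reinforcing
        loop can drive gaming to.  1 means verification places no effective
        ceiling; a low-gaming setting caps the propensity below that.
    gaming_inflation : float
        Unwarranted inflation of the bonus by gaming (``eta`` >= 0).
    bonus_capture : float
        Capture of gamed bonuses (``delta`` >= 0): the fraction
        ``min(1, delta*G)`` of the bonus is diverted away from facility
        operations (pocketed by whoever controls the performance data)
        instead of flowing into revenue.  How leaky the bonus pipe is
        depends on the distribution strategy: payments proportionate to the
        services that triggered them are hard to capture, salary- or
        equally-allocated ones are easy.
    gaming_motivation_loss : float
        Loss of extrinsic motivation per unit of gaming (``nu`` >= 0).
    gaming_depletion : float
        Extra quality depletion per unit of gaming (``gamma_G`` >= 0).
    """

    enabled: bool = False
    bonus_rate: float = 0.0
    volume_base: float = -0.5
    tau_cycle: float = 1.0
    tau_disbursement: float = 0.0
    mu_quality: float = 1.0
    mu_volume: float = 1.0
    motivation_gain: float = 0.0
    gaming_init: float = 0.0
    gaming_feedback: float = 0.0
    gaming_max: float = 1.0
    gaming_inflation: float = 0.0
    bonus_capture: float = 0.0
    gaming_motivation_loss: float = 0.0
    gaming_depletion: float = 0.0

    def __post_init__(self) -> None:
        _require(self.bonus_rate >= 0.0, "bonus_rate", "must be non-negative")
        _require(self.tau_cycle > 0.0, "tau_cycle", "payment-cycle delay must be positive")
        _require(self.tau_disbursement >= 0.0, "tau_disbursement", "must be non-negative")
        for name in (
            "mu_quality",
            "mu_volume",
            "motivation_gain",
            "gaming_feedback",
            "gaming_inflation",
            "bonus_capture",
            "gaming_motivation_loss",
            "gaming_depletion",
        ):
            _require(getattr(self, name) >= 0.0, name, "must be non-negative")
        _require(0.0 <= self.gaming_init <= 1.0, "gaming_init", "must lie in [0, 1]")
        _require(0.0 <= self.gaming_max <= 1.0, "gaming_max", "must lie in [0, 1]")
        _require(
            self.gaming_init <= self.gaming_max,
            "gaming_init",
            "initial gaming cannot exceed the gaming capacity",
        )

    @property
    def total_bonus_delay(self) -> float:
        """Full lag, in months, between service volume and bonus receipt."""
        return self.tau_cycle + self.tau_disbursement


# Field-name lookup used by overrides; names are unique across the
# three sections so overlays can use a flat namespace.
_SECTION_FIELDS = {
    "rates": tuple(f.name for f in dataclasses.fields(RateParams)),
    "p4p": tuple(f.name for f in dataclasses.fields(P4PParams)),
    "initial": ("revenue", "quality", "volume"),
}


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: rates, P4P extension and initial stock levels."""

    rates: RateParams
    p4p: P4PParams
    initial: tuple[float, float, float] = (0.0, 0.0, -0.5)

    def __post_init__(self) -> None:
        for value, name in zip(self.initial, ("revenue", "quality", "volume")):
            _require(-1.0 <= value <= 1.0, name, "initial stock must lie in [-1, 1]")

    @staticmethod
    def parameter_names() -> list[str]:
        """Flat list of every overridable parameter name."""
        names: list[str] = []
        for fields in _SECTION_FIELDS.values():
            names.extend(fields)
        return names

    def with_overrides(self, overrides: Mapping[str, Any]) -> "ModelParams":
        """Return a copy with the named parameters replaced.

        Raises
        ------
        InvariantError
            If a name is not a declared parameter, listing the valid names.
        """
        rate_kw: dict[str, Any] = {}
        p4p_kw: dict[str, Any] = {}
        init = dict(zip(("revenue", "quality", "volume"), self.initial))
        for name, value in overrides.items():
            if name in _SECTION_FIELDS["rates"]:
                rate_kw[name] = value
            elif name in _SECTION_FIELDS["p4p"]:
                p4p_kw[name] = value
            elif name in _SECTION_FIELDS["initial"]:
                init[name] = value
            else:
                valid = ", ".join(self.parameter_names())
                raise InvariantError(
                    f"{name}: unknown parameter; valid names are: {valid}"
                )
        return ModelParams(
            rates=dataclasses.replace(self.rates, **rate_kw),
            p4p=dataclasses.replace(self.p4p, **p4p_kw),
            initial=(init["revenue"], init["quality"], init["volume"]),
        )

    def to_dict(self) -> dict[str, Any]:
        """Nested plain-dict form, suitable for YAML provenance headers."""
        return {
            "rates": dataclasses.asdict(self.rates),
            "p4p": dataclasses.asdict(self.p4p),
            "initial": dict(zip(("revenue", "quality", "volume"), self.initial)),
        }

    @classmethod
    def from_dict(cls, doc: Mapping[str, Any]) -> "ModelParams":
        unknown = set(doc) - set(_SECTION_FIELDS)
        if unknown:
            raise InvariantError(
                f"{sorted(unknown)[0]}: unknown section; expected one of "
                f"{sorted(_SECTION_FIELDS)}"
            )
        init = doc.get("initial", {})
        return cls(
            rates=RateParams(**doc.get("rates", {})),
            p4p=P4PParams(**doc.get("p4p", {})),
            initial=(
                float(init.get("revenue", 0.0)),
                float(init.get("quality", 0.0)),
                float(init.get("volume", -0.5)),
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise InvariantError(f"{path}: parameter file must be a mapping")
        return cls.from_dict(doc)


def _packaged(name: str):
    return resources.files("p4psim").joinpath("data", name)


def load_base_params() -> ModelParams:
    """Load the frozen, calibrated base parameter file shipped with the package."""
    with _packaged("parameters.yaml").open() as fh:
        return ModelParams.from_dict(yaml.safe_load(fh))


def iter_packaged_scenario_files() -> Iterator[tuple[str, Any]]:
    """Yield (scenario id, traversable YAML path) for the shipped overlays."""
    root = _packaged("scenarios")
    for entry in sorted(root.iterdir(), key=lambda p: p.name):
        if entry.name.endswith(".yaml"):
            yield entry.name[:-5], entry
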