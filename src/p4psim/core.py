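"""Stock-and-flow engine for primary-health-facility operations under P4P.

The model has three stocks on the unitless [-1, 1] scale -- revenue ``R``,
quality of services ``Q`` and volume of services ``V`` -- connected by four
valve-controlled flows:

* an exogenous revenue inflow that grows with current volume,
* a stock-to-stock conversion of revenue into quality,
* a depletion of quality driven by client load (the balancing arrow), and
* a net recruitment of volume toward the level indicated by *delayed*
  quality (clients react to quality with a perception lag).

The pay-for-performance extension adds a bonus inflow into revenue, keyed to
above-baseline volume in a *previous* payment cycle, and two auxiliary
variables: extrinsic motivation ``E`` (>= 0), raised by received bonuses and
multiplying the quality-conversion and volume-recruitment valves, and gaming
``G`` (in [0, 1]), which inflates bonuses, erodes motivation, accelerates
quality depletion, and is itself reinforced by bonuses.

Closed-form flow equations (stocks unitless, time in months)::

    headline bonus      = b * max(0, V(t - tau) - vBase) * (1 + eta*G)
    revenue inflow      = rR * (1 + kappaV * V)
    bonus inflow        = headline bonus * (1 - min(1, delta*G))
    conversion R -> Q   = rRQ * (E/E0)^muQ * (R + 1)/2
    quality depletion   = rQ * (1 + gammaG*G^2) * (V + 1)/2
    volume net flow     = rV * (E/E0)^muV * max(0, Qd - V) - rA * max(0, V - Qd)

where ``tau = tau_cycle + tau_disbursement`` and ``Qd`` is quality delayed by
the perception lag.  The ``(x + 1)/2`` factors make -1 an inactivity floor for
each stock.  The volume flow is asymmetric: recruitment of new clients toward
the quality-indicated level runs at the recovery rate ``rV`` and is the only
component staff motivation can amplify, while attrition of dissatisfied
clients runs at its own (faster) rate ``rA`` -- word of poor quality empties
a facility more quickly than word of good quality fills it.  With P4P
disabled the auxiliary machinery is inert and the equations reduce to the
basic-operations model.

Gaming acts through three distinct channels.  It inflates the *claimed*
(headline) bonus (``eta``); it captures a share ``min(1, delta*G)`` of the
bonus money before it reaches facility operations (whoever manipulates the
performance data also controls where the payment lands); and it corrodes
operations themselves -- extra quality depletion and lost extrinsic
motivation -- with severity *quadratic* in G, so that petty report-fiddling
is operationally mild while extensive gaming is crippling.

Integration is explicit Euler on a fixed grid with flow gating at the stock
bounds (an inflow into a stock sitting at +1, or an outflow from one at -1,
contributes nothing) followed by a hard clamp, so boundary equilibria at
exactly +/-1 are representable.  Delayed look-ups read past grid values from
the trajectory itself; history before t=0 is padded with the initial state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import InvariantError, ModelParams, P4PParams, RateParams, _require

__all__ = [
    "StockState",
    "AuxiliaryState",
    "FlowRates",
    "Trajectory",
    "compute_flows",
    "p4p_bonus",
    "update_motivation",
    "update_gaming",
    "step",
    "integrate",
    "integrate_basic",
]


@dataclass(frozen=True)
class StockState:
    """The three stocks; each confined to [-1, 1].

    0 is the average-facility level, -1 the below-average bound and +1 the
    above-average bound of the calibration range.
    """

    revenue: float
    quality: float
    volume: float

    def __post_init__(self) -> None:
        for name in ("revenue", "quality", "volume"):
            _require(-1.0 <= getattr(self, name) <= 1.0, name, "stock must lie in [-1, 1]")


@dataclass(frozen=True)
class AuxiliaryState:
    """Bonus flow level (>= 0), extrinsic motivation (>= 0), gaming (in [0, 1])."""

    bonus: float
    motivation: float
    gaming: float

    def __post_init__(self) -> None:
        _require(self.bonus >= 0.0, "bonus", "P4P bonus is never negative")
        _require(self.motivation >= 0.0, "motivation", "extrinsic motivation is never negative")
        _require(0.0 <= self.gaming <= 1.0, "gaming", "gaming must lie in [0, 1]")


@dataclass(frozen=True)
class FlowRates:
    """Valve readings for one instant, in stock units per month.

    ``conversion`` leaves revenue and enters quality with the same magnitude
    (the stock-to-stock flow is conservative before any boundary gating);
    ``volume_net`` is signed.
    """

    revenue_in: float
    bonus_in: float
    conversion: float
    depletion: float
    volume_net: float


def compute_flows(
    state: StockState,
    aux: AuxiliaryState,
    delayed_quality: float,
    rates: RateParams,
    p4p: P4PParams,
) -> FlowRates:
    """Evaluate the five flow valves at one instant.

    Sign structure mirrors the causal-loop diagram: the revenue inflow grows
    with volume (A), conversion grows with revenue and motivation (B), the
    depletion valve grows with volume and gaming (C, the balancing arrow),
    and net recruitment grows with delayed quality (D) and, on its
    recruitment side, with motivation.
    """
    _require(-1.0 <= delayed_quality <= 1.0, "delayed_quality", "must lie in [-1, 1]")
    e_ratio = aux.motivation / rates.motivation_baseline
    revenue_in = rates.r_revenue * (1.0 + rates.kappa_volume * state.volume)
    received = 1.0 - min(1.0, p4p.bonus_capture * aux.gaming)
    conversion = (
        rates.r_conversion * e_ratio**p4p.mu_quality * (state.revenue + 1.0) / 2.0
    )
    depletion = (
        rates.r_depletion
        * (1.0 + p4p.gaming_depletion * aux.gaming**2)
        * (state.volume + 1.0)
        / 2.0
    )
    gap = delayed_quality - state.volume
    if gap >= 0.0:
        volume_net = rates.r_volume * e_ratio**p4p.mu_volume * gap
    else:
        volume_net = rates.r_attrition * gap
    return FlowRates(
        revenue_in=revenue_in,
        bonus_in=aux.bonus * received if p4p.enabled else 0.0,
        conversion=conversion,
        depletion=depletion,
        volume_net=volume_net,
    )


def p4p_bonus(delayed_volume: float, p4p: P4PParams, gaming: float) -> float:
    """Bonus flow earned on volume from one full payment delay ago.

    ``b * max(0, V(t - tau_cycle - tau_disbursement) - vBase) * (1 + eta*G)``.
    Facilities are never penalised: the bonus is zero whenever the delayed
    volume is at or below the baseline threshold, and always zero when the
    scheme is disabled.
    """
    if not p4p.enabled:
        return 0.0
    excess = max(0.0, delayed_volume - p4p.volume_base)
    return p4p.bonus_rate * excess * (1.0 + p4p.gaming_inflation * gaming)


def update_motivation(
    bonus: float, gaming: float, rates: RateParams, p4p: P4PParams
) -> float:
    """Extrinsic motivation ``E = max(0, E0 + mu*bonus - nu*G^2)``.

    Baseline motivation ``E0`` exists irrespective of the intervention;
    bonuses raise it (when the scheme activates motivation), gaming erodes
    it -- mildly while gaming is petty, steeply once it is extensive -- and
    it is clamped at zero from below.
    """
    raw = (
        rates.motivation_baseline
        + p4p.motivation_gain * bonus
        - p4p.gaming_motivation_loss * gaming**2
    )
    return max(0.0, raw)


def update_gaming(gaming: float, bonus: float, p4p: P4PParams, dt: float) -> float:
    """One Euler step of the bonus-reinforced gaming level.

    ``G' = clamp(G + dt * rho * bonus * (Gmax - G), 0, Gmax)`` -- received
    bonuses encourage further gaming (a reinforcing loop) with saturation at
    the gaming capacity ``Gmax`` (1 by default, so the update reduces to
    ``clamp01(G + dt * rho * bonus * (1 - G))``).
    """
    if dt <= 0.0:
        raise InvariantError("dt: step size must be positive")
    g_max = p4p.gaming_max
    return min(g_max, max(0.0, gaming + dt * p4p.gaming_feedback * bonus * (g_max - gaming)))


def _gate(stock: float, net: float) -> float:
    """Boundary gating of one stock's net derivative.

    A net inflow into a stock sitting at +1, or a net outflow from one at
    -1, contributes nothing: the bound is a sliding state while the net flux
    keeps pressing against it, so boundary equilibria at exactly +/-1 are
    representable and the update is step-size stable (per-flow gating would
    chatter at the bound with amplitude proportional to dt).
    """
    if stock >= 1.0 and net > 0.0:
        return 0.0
    if stock <= -1.0 and net < 0.0:
        return 0.0
    return net


def _gated_derivatives(state: StockState, flows: FlowRates) -> tuple[float, float, float]:
    """Stock derivatives with boundary gating applied."""
    d_rev = _gate(state.revenue, flows.revenue_in + flows.bonus_in - flows.conversion)
    d_qual = _gate(state.quality, flows.conversion - flows.depletion)
    d_vol = _gate(state.volume, flows.volume_net)
    return d_rev, d_qual, d_vol


def step(
    state: StockState,
    aux: AuxiliaryState,
    delayed_quality: float,
    delayed_volume: float,
    rates: RateParams,
    p4p: P4PParams,
    dt: float,
) -> tuple[StockState, AuxiliaryState]:
    """Advance the system one Euler step of size ``dt`` months.

    The auxiliaries passed in must already be the values at the current time
    (bonus from the delayed volume, motivation from bonus and gaming); the
    returned auxiliaries are the values at ``t + dt``.
    """
    if dt <= 0.0:
        raise InvariantError("dt: step size must be positive")
    flows = compute_flows(state, aux, delayed_quality, rates, p4p)
    d_rev, d_qual, d_vol = _gated_derivatives(state, flows)
    clamp = lambda x: min(1.0, max(-1.0, x))
    new_state = StockState(
        revenue=clamp(state.revenue + dt * d_rev),
        quality=clamp(state.quality + dt * d_qual),
        volume=clamp(state.volume + dt * d_vol),
    )
    new_gaming = update_gaming(aux.gaming, aux.bonus, p4p, dt)
    # Bonus and motivation at t+dt are recomputed by the caller from the
    # delayed look-ups there; carry them forward unchanged as placeholders.
    new_aux = AuxiliaryState(bonus=aux.bonus, motivation=aux.motivation, gaming=new_gaming)
    return new_state, new_aux


@dataclass
class Trajectory:
    """Simulated stock and auxiliary paths on a uniform monthly grid."""

    times: np.ndarray
    revenue: np.ndarray
    quality: np.ndarray
    volume: np.ndarray
    bonus: np.ndarray
    motivation: np.ndarray
    gaming: np.ndarray
    scenario_id: str = ""

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("revenue", "quality", "volume", "bonus", "motivation", "gaming"):
            if len(getattr(self, name)) != n:
                raise InvariantError(f"{name}: length must match times")
        if n >= 2:
            steps = np.diff(self.times)
            if not (steps > 0).all() or not np.allclose(steps, steps[0]):
                raise InvariantError("times: grid must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def horizon(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_months": self.times,
                "revenue": self.revenue,
                "quality": self.quality,
                "volume": self.volume,
                "p4p": self.bonus,
                "motivation": self.motivation,
                "gaming": self.gaming,
                "scenario_id": self.scenario_id,
            }
        )


def _delay_steps(tau: float, dt: float) -> int:
    """Delay as a whole number of grid steps (nearest multiple)."""
    return int(round(tau / dt))


def integrate(
    params: ModelParams,
    horizon: float = 100.0,
    dt: float = 0.25,
    scenario_id: str = "",
) -> Trajectory:
    """Integrate the model from its initial state over ``horizon`` months.

    Explicit Euler with fixed step ``dt``; delayed look-ups are rounded to
    the nearest grid multiple and padded with the initial state before t=0.
    Deterministic and bit-reproducible for fixed inputs.
    """
    if horizon <= 0.0:
        raise InvariantError("horizon: must be positive")
    if dt <= 0.0 or dt > horizon:
        raise InvariantError("dt: must be positive and no larger than horizon")
    rates, p4p = params.rates, params.p4p
    n = int(round(horizon / dt))
    times = np.arange(n + 1) * dt

    rev = np.empty(n + 1)
    qual = np.empty(n + 1)
    vol = np.empty(n + 1)
    bon = np.empty(n + 1)
    mot = np.empty(n + 1)
    gam = np.empty(n + 1)

    rev[0], qual[0], vol[0] = params.initial
    lag_pay = _delay_steps(p4p.total_bonus_delay, dt)
    lag_percep = _delay_steps(rates.tau_perception, dt)

    gaming = p4p.gaming_init if p4p.enabled else 0.0
    state = StockState(rev[0], qual[0], vol[0])
    for i in range(n + 1):
        v_del = vol[i - lag_pay] if i >= lag_pay else vol[0]
        q_del = qual[i - lag_percep] if i >= lag_percep else qual[0]
        bonus = p4p_bonus(v_del, p4p, gaming)
        motivation = update_motivation(bonus, gaming, rates, p4p)
        bon[i], mot[i], gam[i] = bonus, motivation, gaming
        if i == n:
            break
        aux = AuxiliaryState(bonus=bonus, motivation=motivation, gaming=gaming)
        state, aux = step(state, aux, q_del, v_del, rates, p4p, dt)
        rev[i + 1], qual[i + 1], vol[i + 1] = state.revenue, state.quality, state.volume
        gaming = aux.gaming

    return Trajectory(times, rev, qual, vol, bon, mot, gam, scenario_id=scenario_id)


def integrate_basic(
    params: ModelParams,
    horizon: float = 100.0,
    dt: float = 0.25,
    scenario_id: str = "",
) -> Trajectory:
    """Integrate the basic-operations model with the P4P machinery removed.

    A deliberately separate, minimal integrator (no bonus, motivation or
    gaming terms at all) used to verify that the full model with the
    intervention disabled reduces exactly -- bitwise, at the same step size
    -- to basic facility operations.
    """
    if horizon <= 0.0:
        raise InvariantError("horizon: must be positive")
    if dt <= 0.0 or dt > horizon:
        raise InvariantError("dt: must be positive and no larger than horizon")
    r = params.rates
    n = int(round(horizon / dt))
    times = np.arange(n + 1) * dt
    rev = np.empty(n + 1)
    qual = np.empty(n + 1)
    vol = np.empty(n + 1)
    rev[0], qual[0], vol[0] = params.initial
    lag = _delay_steps(r.tau_perception, dt)
    clamp = lambda x: min(1.0, max(-1.0, x))
    for i in range(n):
        R, Q, V = rev[i], qual[i], vol[i]
        q_del = qual[i - lag] if i >= lag else qual[0]
        inflow = r.r_revenue * (1.0 + r.kappa_volume * V)
        conv = r.r_conversion * (R + 1.0) / 2.0
        dep = r.r_depletion * (V + 1.0) / 2.0
        gap = q_del - V
        recruit = r.r_volume * gap if gap >= 0.0 else r.r_attrition * gap
        d_rev = _gate(R, inflow - conv)
        d_qual = _gate(Q, conv - dep)
        d_vol = _gate(V, recruit)
        rev[i + 1] = clamp(R + dt * d_rev)
        qual[i + 1] = clamp(Q + dt * d_qual)
        vol[i + 1] = clamp(V + dt * d_vol)
    zeros = np.zeros(n + 1)
    e0 = np.full(n + 1, r.motivation_baseline)
    return Trajectory(times, rev, qual, vol, zeros, e0, zeros, scenario_id=scenario_id)
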