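"""Staged grid-search calibration of the packaged parameter file.

The model's closed-form flow equations leave a family of rate constants
free; this script documents how the shipped ``parameters.yaml`` and the
scenario overlays were fixed, and re-derives them from scratch.  The
calibration targets are the published summary-table rows for the nine P4P
implementation scenarios (equilibrium quality/volume and time of
equilibrium on a 100-month horizon from (Q, V) = (0, -1/2)).

The search is staged because the parameter space is separable:

A. Baseline cluster (kappa_volume, r_volume, r_attrition, tau_perception)
   -- the no-P4P system must show a damped oscillation whose quality dips
   below average before settling at (0,0) near month 60.  r_revenue and the
   initial revenue level are pinned analytically by stationarity of the
   average facility: rR = rQ/2 and R0 = rQ/rRQ - 1.
B. Bonus schedule (bonus_rate) jointly with the high-gaming level
   (gaming_init of 3c) -- scenario 2 must escalate to (1,1) near month 60
   while unrestrained gaming crashes the system to (-1,-1) near month 20.
C. One-dimensional sweeps for the single-feature scenarios: motivation
   gain (3a, equilibrium at 40), disbursement delay (3d, 75), low bonus
   level (3e, back to baseline behaviour).
D. Low-level gaming (3b): a static petty-gaming level whose bonus is fully
   captured and whose quadratic operational damage keeps the (0,0)
   equilibrium and baseline-like settling.
E. Group 4: per-strategy gaming feedback, capacity, capture and motivation
   gain reproducing crash (4b, 60), success (4c, 60) and the non-converged
   drift of 4a ((Q,V) ~ (0,-0.15) at 100 months).

Stages B-E hold everything previously frozen fixed, so the whole search is
a few hundred desk-scale simulations.  Run from the repository root:

    python scripts/calibrate.py --out-dir src/p4psim/data

Writing into the package source is deliberate: the output IS the frozen
calibration artefact, versioned with the code.
"""

from __future__ import annotations

import argparse
import copy
import sys
from pathlib import Path

import yaml

from p4psim.core import integrate
from p4psim.equilibrium import detect_equilibrium
from p4psim.params import ModelParams

HORIZON, DT = 100.0, 0.25

# Analytically pinned pieces (stationarity of the average facility).
RQ, RRQ = 0.25, 0.5
BASE = {
    "rates": dict(r_revenue=RQ / 2, r_conversion=RRQ, r_depletion=RQ,
                  r_volume=None, r_attrition=None, kappa_volume=None,
                  tau_perception=None, motivation_baseline=1.0),
    "p4p": dict(enabled=False, bonus_rate=0.0, volume_base=-0.5,
                tau_cycle=3.0, tau_disbursement=0.0, mu_quality=1.0,
                mu_volume=1.0, motivation_gain=0.0, gaming_init=0.0,
                gaming_feedback=0.0, gaming_max=1.0, gaming_inflation=1.0,
                bonus_capture=10.0, gaming_motivation_loss=1.5,
                gaming_depletion=2.0),
    "initial": dict(revenue=RQ / RRQ - 1.0, quality=0.0, volume=-0.5),
}


def run(base: dict, overrides: dict, sid: str = ""):
    params = ModelParams.from_dict(base).with_overrides(overrides)
    traj = integrate(params, horizon=HORIZON, dt=DT, scenario_id=sid)
    return traj, detect_equilibrium(traj)


def stage_a(base: dict) -> dict:
    """Baseline shape + timing; scenario-2 and 3c feasibility filter."""
    hits = []
    for kappa in (0.25, 0.30):
        for rv in (0.09, 0.10):
            for ra in (0.20, 0.22):
                for tau_p in (3.5, 4.0):
                    cand = copy.deepcopy(base)
                    cand["rates"].update(kappa_volume=kappa, r_volume=rv,
                                         r_attrition=ra, tau_perception=tau_p)
                    traj, eq = run(cand, {}, "1")
                    if not (eq.converged and 57.5 <= eq.t_eq_raw <= 62.4
                            and traj.quality.min() <= -0.02
                            and traj.volume.max() > 0.0):
                        continue
                    # joint feasibility: some bonus rate drives 2 -> (1,1)@60
                    # and some pre-existing gaming level drives 3c -> (-1,-1)@20
                    for b in (0.45, 0.35, 0.55):
                        c2 = copy.deepcopy(cand); c2["p4p"]["bonus_rate"] = b
                        _, eq2 = run(c2, dict(enabled=True), "2")
                        if not (eq2.converged and (eq2.q_eq, eq2.v_eq) == (1, 1)
                                and 57.5 <= eq2.t_eq_raw <= 62.4):
                            continue
                        for g_high in (0.90, 0.95):
                            _, eq3 = run(c2, dict(enabled=True, gaming_init=g_high,
                                                  gaming_feedback=0.6), "3c")
                            if (eq3.converged and (eq3.q_eq, eq3.v_eq) == (-1, -1)
                                    and 17.5 <= eq3.t_eq_raw <= 22.4):
                                hits.append((kappa, rv, ra, tau_p, b, g_high))
    if not hits:
        sys.exit("stage A: no feasible baseline cluster found")
    kappa, rv, ra, tau_p, b, g_high = hits[0]
    base = copy.deepcopy(base)
    base["rates"].update(kappa_volume=kappa, r_volume=rv, r_attrition=ra,
                         tau_perception=tau_p)
    base["p4p"]["bonus_rate"] = b
    base["_g_high"] = g_high
    print(f"stage A: kappa={kappa} rV={rv} rA={ra} tauP={tau_p} "
          f"b={b} g_high={g_high} ({len(hits)} feasible)")
    return base


def pick_1d(base, overrides_of, values, want, time_band, sid):
    """First sweep value whose equilibrium matches (q, v) inside a time band."""
    for v in values:
        _, eq = run(base, overrides_of(v), sid)
        t_ok = (time_band is None and not eq.converged) or (
            time_band is not None and eq.converged
            and time_band[0] <= eq.t_eq_raw <= time_band[1])
        if (eq.q_eq, eq.v_eq) == want and t_ok:
            print(f"stage {sid}: picked {v}")
            return v
    sys.exit(f"stage {sid}: no sweep value matched")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__.splitlines()[0])
    ap.add_argument("--out-dir", default="src/p4psim/data",
                    help="where to write parameters.yaml and scenarios/")
    args = ap.parse_args()

    base = stage_a(copy.deepcopy(BASE))
    g_high = base.pop("_g_high")

    mu_3a = pick_1d(base, lambda v: dict(enabled=True, motivation_gain=v),
                    (1.3, 1.0, 1.6), (1, 1), (37.6, 42.4), "3a")
    tau_3d = pick_1d(base, lambda v: dict(enabled=True, tau_disbursement=v),
                     (18.0, 15.0, 21.0), (1, 1), (72.6, 77.4), "3d")
    b_3e = pick_1d(base, lambda v: dict(enabled=True, bonus_rate=v),
                   (0.002, 0.001), (0, 0), (52.5, 62.4), "3e")
    g_3b = pick_1d(base, lambda v: dict(enabled=True, gaming_init=v, gaming_max=v),
                   (0.10, 0.12), (0, 0), (55.0, 62.4), "3b")
    rho_4b = pick_1d(base, lambda v: dict(enabled=True, motivation_gain=0.0,
                                          gaming_feedback=v,
                                          tau_disbursement=tau_3d),
                     (0.3, 0.25, 0.35), (-1, -1), (55.0, 62.4), "4b")
    mu_4c = pick_1d(base, lambda v: dict(enabled=True, motivation_gain=v,
                                         gaming_feedback=0.2, bonus_capture=0.1,
                                         tau_disbursement=tau_3d),
                    (2.5, 3.0), (1, 1), (55.0, 62.4), "4c")
    # 4a: moderate gaming capacity; non-converged with Q ~ 0, V ~ -0.15 at 100.
    cap_4a = rho_4a = None
    for cap in (0.16, 0.15, 0.17):
        for rho in (0.45, 0.5, 0.4):
            traj, eq = run(base, dict(enabled=True, motivation_gain=2.5,
                                      gaming_feedback=rho, tau_disbursement=tau_3d,
                                      mu_volume=0.0, gaming_max=cap), "4a")
            if (not eq.converged and abs(traj.quality[-1]) <= 0.09
                    and -0.19 <= traj.volume[-1] <= -0.11):
                cap_4a, rho_4a = cap, rho
                break
        if cap_4a is not None:
            break
    if cap_4a is None:
        sys.exit("stage 4a: no capacity/feedback pair matched")
    print(f"stage 4a: cap={cap_4a} rho={rho_4a}")

    group4 = ("4. P4P with motivation, gaming and bonus delay, "
              "with different bonus distribution strategies")
    scenarios = {
        "1": ("Baseline", "1. No P4P", {}),
        "2": ("P4P only", "2. P4P", dict(enabled=True)),
        "3a": ("Motivation", "3. P4P with one additional feature",
               dict(enabled=True, motivation_gain=mu_3a)),
        "3b": ("Low-level gaming", "3. P4P with one additional feature",
               dict(enabled=True, gaming_init=g_3b, gaming_max=g_3b)),
        "3c": ("High-level gaming", "3. P4P with one additional feature",
               dict(enabled=True, gaming_init=g_high, gaming_feedback=0.6)),
        "3d": ("Bonus delay", "3. P4P with one additional feature",
               dict(enabled=True, tau_disbursement=tau_3d)),
        "3e": ("Low bonuses", "3. P4P with one additional feature",
               dict(enabled=True, bonus_rate=b_3e)),
        "4a": ("Equal allocation", group4,
               dict(enabled=True, motivation_gain=2.5, gaming_feedback=rho_4a,
                    tau_disbursement=tau_3d, mu_quality=1.0, mu_volume=0.0,
                    gaming_max=cap_4a)),
        "4b": ("Proportionate to salaries", group4,
               dict(enabled=True, motivation_gain=0.0, gaming_feedback=rho_4b,
                    tau_disbursement=tau_3d, mu_quality=1.0, mu_volume=1.0)),
        "4c": ("Proportionate to services", group4,
               dict(enabled=True, motivation_gain=mu_4c, gaming_feedback=0.2,
                    tau_disbursement=tau_3d, mu_quality=1.0, mu_volume=1.0,
                    bonus_capture=0.1)),
    }

    out = Path(args.out_dir)
    (out / "scenarios").mkdir(parents=True, exist_ok=True)
    with open(out / "parameters.yaml", "w") as fh:
        fh.write("# Calibrated base parameters, frozen by scripts/calibrate.py.\n")
        yaml.safe_dump({k: base[k] for k in ("rates", "p4p", "initial")},
                       fh, sort_keys=False)
    for sid, (label, group, ov) in scenarios.items():
        with open(out / "scenarios" / f"{sid}.yaml", "w") as fh:
            yaml.safe_dump({"id": sid, "label": label, "group": group,
                            "overrides": ov}, fh, sort_keys=False)
    print(f"wrote calibrated parameter file and {len(scenarios)} overlays to {out}")

    # final verification pass
    for sid, (_, _, ov) in scenarios.items():
        _, eq = run(base, ov, sid)
        print(f"  {sid:3s} q={eq.q_eq:+.2f} v={eq.v_eq:+.2f} "
              f"t={eq.t_eq} converged={eq.converged}")


if __name__ == "__main__":
    main()
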