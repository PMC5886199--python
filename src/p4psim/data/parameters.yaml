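# Calibrated base parameters, frozen by scripts/calibrate.py -- do not edit by hand.
# Stocks are unitless on [-1, 1]; time in months.  The baseline (P4P off) system
# is stationary at (R, Q, V) = (-0.5, 0, 0): r_revenue = r_depletion/2 and
# initial revenue = r_depletion/r_conversion - 1.
rates:
  r_revenue: 0.125        # rR: base revenue inflow, per month
  r_conversion: 0.5       # rRQ: revenue -> quality conversion, per month
  r_depletion: 0.25       # rQ: client-load depletion of quality, per month
  r_volume: 0.09          # rV: client recruitment toward perceived quality
  r_attrition: 0.22       # rA: client attrition when quality disappoints
  kappa_volume: 0.25      # sensitivity of revenue inflow to volume
  tau_perception: 3.5     # months before clients perceive quality change
  motivation_baseline: 1.0  # E0
p4p:
  enabled: false
  bonus_rate: 0.45        # b: bonus per unit above-baseline volume
  volume_base: -0.5       # vBase: the facility's own starting volume
  tau_cycle: 3.0          # quarterly authorization cadence
  tau_disbursement: 0.0   # extra authorization -> disbursement lag
  mu_quality: 1.0         # E modulates the quality-conversion flow
  mu_volume: 1.0          # E modulates the volume-recruitment flow
  motivation_gain: 0.0    # mu: bonus -> motivation (off unless a scenario enables it)
  gaming_init: 0.0
  gaming_feedback: 0.0    # rho: bonus -> gaming reinforcement
  gaming_max: 1.0         # gaming capacity
  gaming_inflation: 1.0   # eta: unwarranted bonus inflation by gaming
  bonus_capture: 10.0     # delta: gamed bonuses are fully captured once G >= 0.1
  gaming_motivation_loss: 1.5  # nu: motivation loss, quadratic in G
  gaming_depletion: 2.0   # gammaG: extra depletion, quadratic in G
initial:
  revenue: -0.5
  quality: 0.0
  volume: -0.5
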