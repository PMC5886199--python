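# Methods

## Model

`p4psim` simulates a single primary-health facility as a stock-and-flow
system with three stocks — revenue `R`, quality of services `Q`, volume of
services `V` — on a unitless scale from −1 to 1, where 0 is the
average-facility level of a national survey cohort and ±1 its
below-/above-average bounds. The causal structure is a reinforcing outer
loop (volume → revenue → quality → volume) checked by one balancing arrow
(volume loads and depletes quality), with a perception delay between quality
and the client response. The flow equations are documented in
`p4psim.core`; the salient structural choices are:

* **Inactivity floors.** The conversion and depletion valves carry factors
  `(R+1)/2` and `(V+1)/2`, so a stock at −1 is inert: a facility with no
  money converts nothing, a facility with no clients wears nothing out.
  Together with boundary gating this makes −1 (and +1) genuine equilibria
  of the scaled system.
* **Asymmetric volume flow.** Client recruitment toward the
  (delayed-)quality-indicated level runs at the recovery rate `rV`;
  attrition of dissatisfied clients runs at its own, faster rate `rA`.
  Word of poor quality empties a facility more quickly than word of good
  quality fills it; a single symmetric rate cannot produce both the slow
  (≈60-month) baseline settling and the fast (≈20-month) collapse under
  extensive gaming. Motivation multiplies only the recruitment component —
  staff effort can attract clients but does not decide whether disappointed
  clients leave.
* **Gaming acts through three channels.** It inflates the *claimed* bonus
  (`η`), it **captures** a share `min(1, δ·G)` of bonus money before the
  money reaches facility operations (whoever controls the performance data
  controls where the payment lands), and it corrodes operations — extra
  quality depletion `γG·G²` and motivation loss `ν·G²` — with severity
  *quadratic* in `G`. The quadratic form encodes that petty report-fiddling
  is operationally almost harmless while extensive gaming is crippling; it
  is also what lets a low static gaming level neutralise the bonus channel
  (via capture) yet leave facility operations essentially at baseline, the
  behaviour reported for the low-gaming scenario.
* **Gaming capacity.** The bonus→gaming reinforcement saturates at a
  capacity `G_max ≤ 1`: `dG ∝ ρ·B·(G_max − G)`. Capacity 1 means
  verification places no effective ceiling; a low capacity models settings
  (petty gaming, diffuse incentives) where manipulation cannot scale.
* **Motivation is algebraic.** `E = max(0, E0 + μ·B − ν·G²)` responds to
  the currently disbursed bonus; baseline motivation `E0 > 0` exists
  without any scheme and `E` is clamped at zero from below.

The scheme pays `B = b·max(0, V(t−τ) − v_base)·(1+η·G)` with
`τ = τ_cycle + τ_disb`: payments are authorised on the volume of a previous
cycle (quarterly cadence, `τ_cycle = 3` months) plus any
authorisation-to-disbursement lag. Facilities are never penalised for
falling below their baseline volume.

## Distribution strategies

How bonuses are split among staff is encoded as aggregate couplings, not as
individual workers:

| strategy | μQ | μV | motivation gain μ | capture δ | gaming |
|---|---|---|---|---|---|
| equal allocation | 1 | 0 | 2.5 | 10 | capacity 0.16 |
| proportionate to salaries | 1 | 1 | 0 | 10 | capacity 1 |
| proportionate to services | 1 | 1 | 2.5 | 0.1 | capacity 1 |

Equal allocation motivates only weakly where it matters (the quality flow,
not the volume flow) and its diffuse benefit caps gaming low;
salary-proportionate allocation concentrates bonuses on leadership, fails to
activate rank-and-file motivation, and leaves the bonus pipe fully
capturable; service-proportionate allocation pays the people whose effort
triggered the payment, which makes capture hard (δ = 0.1) and yields the
highest motivational return per bonus. Treating the motivation gain and the
capture coefficient as strategy fields — in addition to the coupling
switches — is this package's design choice: the distribution rule decides
both how much of the money reaches operations and how much motivation a
given bonus buys.

## Parameters

All stocks and flows are unitless per the −1..1 scaling; time is in months.
The frozen base file (`src/p4psim/data/parameters.yaml`):

| parameter | value | meaning / why |
|---|---|---|
| `r_depletion` (rQ) | 0.25 | client-load depletion of quality; sets the basic quality time-scale |
| `r_conversion` (rRQ) | 0.5 | revenue→quality conversion; with rQ fixes the baseline revenue level R0 = rQ/rRQ − 1 = −0.5 |
| `r_revenue` (rR) | 0.125 | pinned analytically to rQ/2 so the average facility (R0, 0, 0) is stationary with the scheme off |
| `r_volume` (rV) | 0.09 | client recruitment rate; principal control of baseline settling (≈60 months) |
| `r_attrition` (rA) | 0.22 | client attrition rate; controls collapse speed (≈20 months under extensive gaming) |
| `kappa_volume` (κV) | 0.25 | revenue sensitivity to volume; larger values let the revenue channel cancel the balancing loop and kill the baseline oscillation |
| `tau_perception` (τP) | 3.5 | months before clients respond to a quality change; gives the baseline its damped oscillation |
| `motivation_baseline` (E0) | 1.0 | reference motivation; flows are scaled by E/E0 |
| `bonus_rate` (b) | 0.45 | bonus per unit of above-baseline volume; large enough to drive the facility to the +1 ceiling |
| `volume_base` (v_base) | −0.5 | payment threshold = the facility's own starting volume |
| `tau_cycle` | 3.0 | quarterly payment authorisation |
| `tau_disbursement` | 0 (18 in delay scenarios) | additional disbursement lag |
| `gaming_inflation` (η) | 1.0 | claimed-bonus inflation at full gaming |
| `bonus_capture` (δ) | 10 (0.1 under service-proportionate allocation) | captured fraction is min(1, δG): capture saturates once G ≥ 0.1 |
| `gaming_motivation_loss` (ν) | 1.5 | motivation dies (E = 0, without bonuses) once G ≥ √(E0/ν) ≈ 0.82 |
| `gaming_depletion` (γG) | 2.0 | triples depletion at full gaming |

Scenario overlays set only what their narrative requires: motivation gain
1.3 (plain motivation scenario), static petty gaming `G = G_max = 0.1`
(low-level), pre-existing gaming 0.95 with feedback 0.6 (high-level),
disbursement lag 18 months (delay scenarios), bonus rate 0.002 (low
bonuses), and the strategy rows above with per-strategy gaming feedback
(0.45 / 0.3 / 0.2).

## Calibration

The closed forms fix signs and fixed points but not time-scales; the exact
source equations behind the published scenario table are not available, so
the rate constants are calibration outputs. `scripts/calibrate.py` is the
documented, staged grid search that produced (and re-derives) the frozen
file: stage A selects the baseline cluster (κV, rV, rA, τP) so the no-P4P
run shows a damped oscillation — quality rising, dipping below average,
re-converging — settling near month 60, jointly with a bonus rate that
drives the simplest scheme to (1, 1) near 60 and a gaming level that crashes
it to (−1, −1) near 20; later stages are one-dimensional sweeps for the
remaining scenario knobs, each holding everything previously frozen fixed.
Equilibrium levels snap exactly because ±1 are gated boundary equilibria
and 0 is the analytically pinned interior one; only the *times* (and the
non-converging scenario's horizon values) depend on the grid resolution of
the search.

## Numerics

* **Integrator.** Explicit Euler, fixed step `dt = 0.25` months over a
  100-month horizon (401 grid points). Euler keeps delayed-state lookup
  transparent; a step-halving test bounds the final-state error below 0.01
  on every scenario. Delays are rounded to the nearest grid multiple;
  history before t = 0 is padded with the initial state, so the first
  bonus cycle correctly sees the pre-intervention volume.
* **Boundary gating.** A stock at +1 ignores further *net* inflow (and at
  −1, net outflow), then a hard clamp guards against overshoot. Gating the
  net derivative rather than each flow separately realises the sliding
  behaviour of the continuous system at the bound; per-flow gating would
  chatter with amplitude proportional to `dt·flow`.
* **Equilibrium detection.** The settling time is the earliest grid time
  after which both Q and V stay within `epsilon = 0.02` of their
  end-of-horizon values, with at least a `window = 12`-month quiet stretch
  before the horizon; otherwise the run is reported as not converged with
  its horizon values. Reported levels snap to {−1, 0, +1} within
  `snap_band = 0.1` (the system's true anchors) and otherwise round to two
  decimals; times are reported to the nearest 5 months (the granularity of
  the published table), with raw grid times retained in all exports. The
  detection rule is this package's own — no published criterion exists —
  and reported times depend on (epsilon, window) about as strongly as on
  the rate constants, which is why all three are configuration-exposed.
* **Initial state.** (R, Q, V) = (−0.5, 0, −0.5): average quality, volume
  half-way below average (the deficit the scheme is meant to correct), and
  revenue at its baseline-stationary level R0.

## Synthetic survey

The unitless scales are anchored, in the original study, to the spread of a
641-facility national survey that is not publicly available. The
`survey` module generates a synthetic stand-in — aggregate quality scores
from a truncated normal on [0, 100] (mean 55, sd 15) and monthly client
volumes from a lognormal (median 450, log-sd 0.6, right-skewed as caseloads
are) — and fits the piecewise-linear scaling maps through the 1st/50th/99th
percentile anchors (percentiles rather than extremes keep the map robust to
generator outliers). The simulator's stocks are already unitless, so no
simulation result depends on this module; it exists so the raw-score →
stock-scale calibration step is testable end to end. The generator emulates
only distributional shape: it contains no facility covariates, no
quality-volume correlation and no real facility's data, so passing its
tests says nothing about any actual survey beyond the scaling contract.

## What the tests do and do not show

The suite verifies the model's internal contracts (bounds, signs,
reduction to basic operations, delay and bonus monotonicity, step-size
robustness, detector correctness on synthetic inputs) and that the frozen
calibration reproduces the published scenario table. Because the source
equations and parameter values are reconstructions under those constraints,
agreement with the table shows the *narrative dynamics* are recovered — not
that the parameter values are those of the original model, and not that
either model predicts real facilities. The model is supply-side only: no
client demand behaviour, no facility-to-facility interaction, no stochastic
shocks, and quality aggregated to a single index. Scenario timing claims
inherit the equilibrium-detection convention described above.
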