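# Methods

`ifflpulse` models two synthetic type-1 incoherent feed-forward loop (IFFL)
gene circuits in *E. coli* and runs the complete analysis pipeline around
them — plate-reader normalization, derivative-free fitting, Monte-Carlo
parameter perturbation, and pulse detection — on synthetic plate-reader
data with known ground truth.

## The two circuit models

Both circuits share the IFFL topology: a trigger RNA X activates the
output Z (GFP reporter) directly and represses it indirectly through an
intermediate node Y. Units are arbitrary concentration units (plasmid
totals are normalized to 1) and minutes; inducers keep experimental units
(µM for IPTG and arabinose, nM for aTc). Transcriptional induction is
phenomenological — Hill functions `H(I; K, h) = I^h / (K^h + I^h)` —
while everything downstream is elementary mass action.

**RNA-only circuit** (STAR activator + three-way-junction repressor;
state `(X, Y, Z, GFP)`):

    dX/dt   = alpha_X * P_X * H(ara; K_ara, m) - gamma*X*PY* - gamma*X*PZ* - delta_X * X
    dY/dt   = alpha_Y * gamma * X * PY* - delta_Y * Y - omega*Y*Z
    dZ/dt   = alpha_Z * gamma * X * PZ* - delta_Z * Z - omega*Y*Z
    dGFP/dt = alpha_GFP * Z - delta_GFP * GFP

with `PY* = P_Y * H(iptg; K_IPTG, n)` and `PZ*` analogous. The
`omega*Y*Z` term is the mutual annihilation of the 3WJ trigger (from Y)
and the translationally active switch RNA (Z). Because activation and
inhibition are both RNA–RNA reactions, their timescales are matched
(`omega` on the order of `gamma`), and the reporter integrates Z with a
slow protein turnover `delta_GFP`; GFP therefore rises monotonically
toward `alpha_GFP * Z* / delta_GFP` and never pulses.

**RNA–protein hybrid circuit** (toehold switch + TetR; state
`(X, Y, Z, C_XY, C_XZ, T, PZ_rep, G)`): X binds the switch RNAs Y and Z
irreversibly at rate `gamma`, forming translating complexes `C_XY` and
`C_XZ` which produce TetR (`alpha_T`) and GFP (`alpha_G`) respectively.
Free TetR partitions between operator binding (`omega * T * PZ_free`,
repressing the Z plasmid), sequestration by aTc (`k_atc * atc * T`, with
aTc treated as a constant non-depleting pool), and degradation
(`delta_T`, the knob moved by the ASV/AAV/LVA degradation-tag variants).
The free Z plasmid is the conserved remainder `P_Z - PZ_rep`; `PZ_rep`
relaxes back at `k_off` (0 by default — repression is effectively
irreversible on the 8-h experiment). Y is transcribed constitutively
(weak promoter), and Z transcription requires both a free plasmid and
IPTG induction.

## The nominal parameter regime

The experimental parameter tables behind the original study are not
available, so the package documents its own nominal sets, chosen once
from timescale analysis and then frozen. Design goals: (i) a shared RNA
stage so the pulse/no-pulse contrast is attributable to the protein arm
alone, (ii) RNA lifetimes of a few minutes against protein lifetimes of
tens of minutes, and (iii) a hybrid repression delay whose variance under
±50% joint parameter perturbation stays inside the analysis window.

Shared RNA stage (both models): `alpha_X = 5`, `gamma = 0.5` (per conc
per min), `delta_X = delta_Y = delta_Z = 0.2`/min (≈3.5 min RNA
half-life), `K_IPTG = 30 µM`, `n = 1.2`. RNA-only specifics:
`alpha_Y = alpha_Z = 1`, `alpha_GFP = 0.5`, `omega = 0.5` (matched to
`gamma`), `delta_GFP = 0.01`/min (untagged GFP, dilution-dominated),
`K_ara = 800 µM`, `m = 1`, `S_G = 1000`.

Hybrid specifics: `alpha_Y = 0.06` (weak constitutive promoter),
`alpha_Z = 2`, `alpha_T = 0.0035`, `alpha_G = 0.5`, `omega = 100` (tight
TetR–operator binding: essentially every free TetR represses a plasmid),
`delta_CY = 0.005`/min, `delta_CZ = 0.015`/min, `delta_T = 0.02`/min,
`delta_G = 0.02`/min (tagged reporter, ≈35 min half-life),
`k_atc = 0.003` per nM per min, `k_off = 0`, `S_G = 1000`.

Two deliberate features make the hybrid pulse robust rather than
fine-tuned:

1. **Titration-mode repression.** With `omega` large, TetR is absorbed by
   free operators as fast as it is made, so the repression onset time is
   set by the cumulative TetR production, not by a binding equilibrium.
2. **Quadratic accumulation.** The translating complex `C_XY` is
   long-lived (`delta_CY` ≪ RNA turnover), so TetR output ramps linearly
   and cumulative repression grows quadratically in time. The shutdown
   time then scales as the *inverse square root* of the perturbed rate
   product, compressing a ±50% joint perturbation of several parameters
   into a roughly ±30% spread of pulse timing — inside the 50–300 min
   analysis window at every inducer condition of the default grid.

Deep trigger saturation (`gamma * X` above `delta_Y` at all IPTG levels,
helped by the low `K_IPTG` and shallow `n`) additionally cancels most of
the X-dependence of TetR flux, because Y accumulates when X is scarce.

The node-Y variant presets act by overrides: `decoy` sets `omega = 0`,
`constitutive` replaces the Y production term by `alpha_Y * PY*`
(X-independent), `insulated` multiplies effective Y production by 3, and
the hybrid tags select `delta_T` ∈ {0.01 (ASV), 0.02 (AAV), 0.05 (LVA)}.
The insulation multiplier default is 3 rather than a larger value
because the required terminal-GFP ordering (decoy ≥ regular ≥ insulated ≥
constitutive) holds only while `insulation × gamma * X < 1`; with the
nominal trigger flux at the weak-arabinose test condition
(`gamma*X ≈ 0.25`) a 3× multiplier keeps the constitutive trigger the
strongest repressor, as observed experimentally. The ordering is asserted
in the weak-trigger regime; at saturating arabinose the insulated and
constitutive variants can swap.

## Simulation

Systems are integrated with LSODA (stiff-capable, `rtol = 1e-6`,
`atol = 1e-9`) on the plate-reader grid — 10-min cadence, 31 cycles
(5 h) for the RNA-only circuit and 49 cycles (8 h) for the hybrid — from
the zero state at induction (t = 0, inducers added to freshly diluted
culture). Inducers are constant, so the Hill terms are precomputed per
condition. Negative solver excursions below ten times the absolute
tolerance are clamped to zero; anything larger raises an error rather
than being silently hidden. An optional onset delay `tau_t7` (default 0)
zeroes the Hill terms for `t < tau_t7` to represent T7 RNAP build-up
after induction; it is a simulation option, never fitted. Two
independent oracles check the solver: the closed-form steady state of the
RNA-only system at `omega = 0`, and a fixed-step (0.01 min) classical
Runge–Kutta integration.

## Normalization and masking

The observed signal is `(F - F_blank(t)) / OD600(t)` with a per-cycle
blank (the mean over medium-only wells; medium autofluorescence drifts,
so a scalar blank would bias late cycles). Points with OD600 below 0.02
are masked, and the analysis windows mask early low-density and late
stationary-phase cycles: 90–200 min for the RNA-only circuit, 50–300 min
for the hybrid. Masking never alters stored values — masked points are
just excluded from objectives and pulse metrics — so unmasking restores
the raw signal exactly.

## Parameter fitting

The loss is an unweighted sum of squared residuals between replicate-mean
observed signal and `S_G * GFP_sim(t)` over all unmasked points of the
training conditions (per-point s.d. weighting exists as an option, off by
default). The training split is IPTG {500, 7.81} µM × arabinose
{6600, 1650, 103.1} µM — 6 of the 16 grid conditions — with the rest
held out for validation.

Minimization is Nelder–Mead simplex over log-parameters (positivity by
construction) for the 15 free RNA-only parameters; the hybrid fit is the
same simplex with box bounds (required for every free parameter, no
candidate evaluated outside them). Two numerical choices matter in
15+ dimensions and are worth recording:

* The initial simplex uses a uniform log-space step (default 0.1) per
  coordinate. scipy's default step is proportional to the coordinate
  value, which collapses exploration for parameters whose log is near 0.
* Restarts (default 3, 10% log-space jitter, seeded) are *warm*: each
  re-seeds a fresh simplex around the best point found so far. Cold
  restarts from the original init were measured to stall (trajectory
  recovery 2.3% versus 0.17% with warm restarts at the same budget).

Parameters are not individually identifiable from GFP output — scaling
`alpha_GFP` up and `S_G` down by the same factor changes nothing
observable — so all accuracy statements are about predicted trajectories,
never recovered parameter values. The recovery experiment (noiseless
synthetic data, ±10% jittered start, 2 restarts × 3000 evaluations — a
budget verified to reach the same objective as 3 × 5000) demands ≤1%
pointwise relative error on train and validation conditions.

## Sensitivity analysis and pulse detection

One perturbation draw multiplies every free kinetic parameter
independently by a uniform factor in [0.5, 1.5] (±50%); ten draws per
condition is the default, and the nominal trajectory is always carried
alongside. Draws are seeded and reproducible; a failed integration marks
that draw failed rather than dropping it silently.

A time course pulses when, on its unmasked window, the maximum is
strictly interior and both the rise from the window start and the decay
to the window end are at least 20% of the peak
(`theta_rise = theta_decay = 0.2`, config-exposed). The criterion is
scale invariant, and raising either threshold can only veto pulses. The
original study argues pulses from plots; this operationalization is the
package's own and is deliberately conservative (a monotone approach to
steady state never counts, however steep).

## Synthetic data generator

Each well records `F(t) = blank + S_G * GFP(t) * OD(t) * eps(t)` with
`eps` lognormal (mean 1, CV 0.05 by default), OD600 following a logistic
curve (od0 = 0.03, rate = 0.025/min, capacity = 0.7, lag = 30 min) with
its own smaller lognormal noise (CV = noise_cv/5), plus medium-only blank
wells at `blank * eps`. Defaults mirror the microplate protocol: 3
biological replicates for the RNA-only circuit, 6 for the hybrid, the
printed inducer grids (4 IPTG × 4 arabinose; 4 IPTG × 6 aTc, where the
20 nM aTc level is reconstructed from the printed mass-concentration
ladder), and 31/49 cycles. Because raw fluorescence is modelled as
per-cell signal × OD + blank, normalization recovers `S_G * GFP(t)`
exactly in the noiseless limit — the round-trip identity the pipeline
tests lean on.

What the generator does *not* emulate: growth–expression coupling
(burden), well-position and evaporation effects, saturation of the
detector, and any non-multiplicative error structure. Passing tests
therefore demonstrate the pipeline's internal correctness and the models'
qualitative behavior, not agreement with any particular experimental
dataset.

## Numerical edge cases

* OD600 = 0 or below the floor: masked, never divided through.
* Single replicate: s.d. reported as 0 with a machine-readable warning.
* Ties at the pulse peak: earliest time wins.
* All-zero signal: no pulse, fractions reported as 0.
* Simulation failure inside the objective: large penalty (1e12), logged,
  so the simplex can continue; failure at a nominal ensemble condition is
  an error.
* `fraction >= 1` perturbations are rejected (rates must stay positive).

## Known limitations

* The hybrid equations are a reconstruction from a prose description;
  alternative closures (complex dissociation, trigger recycling,
  aTc-mediated operator release) are representable only through `k_off`.
* The pulse definition is binary and window-relative; a pulse whose decay
  is cut off by the stationary-phase mask is reported as absent.
* The ±50% perturbation analysis explores a hypercube around one nominal
  point, not the full identifiable manifold; with extreme joint draws
  (several rates conspiring at their bounds) a hybrid pulse can in
  principle drift outside the analysis window — measured at order 1e-4
  probability per draw under the defaults.
* Growth parameters are condition-independent; the optional burden hook
  only rescales the growth rate.
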