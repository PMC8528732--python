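# Methods

## Model and simulation

Each species is a constraint-based metabolic model (stoichiometric matrix,
flux bounds, biomass objective). Steady-state growth is obtained by FBA:
maximize biomass flux subject to S·v = 0 and lb ≤ v ≤ ub, solved with
scipy's HiGHS interior-point/simplex LP at feasibility and optimality
tolerances of 1e−9. Infeasible problems are treated as zero growth with no
exchange — in the arena such an agent simply idles for that step. Because
the optimal face can be degenerate, flux *values* (not the objective) may
depend on the solver path; an optional parsimonious mode re-solves with the
optimum fixed and total |flux| minimized, which makes flux reports unique.
The synthetic models avoid the issue altogether by coupling every secretion
stoichiometrically to biomass, so the fluxes the cross-feeding statistic
consumes are forced at any optimum. Fluxes with magnitude below 1e−8 are
zeroed: LP noise must not masquerade as transport.

Units are fixed package-wide: flux mmol·gDW⁻¹·h⁻¹, biomass pg
(1 pg = 1e−12 gDW), substrate amounts fmol (1e−12 mmol), time h. The
pg/fmol pairing makes bookkeeping exact — a flux v carried by b pg for dt h
moves v·b·dt fmol — which is what lets the conservation tests close to
1e−9 relative.

### Arena

The spatial simulator advances in steps of dt. Per step, in a freshly
shuffled agent order (removes first-mover bias): (1) each exchange
reaction's uptake bound is tightened to −min(|lb|, local_amount/(b·dt)), so
an agent can never take up more than its own grid cell holds; (2) FBA is
solved; (3) exchange fluxes are applied to the local cell (secretion adds,
uptake subtracts; non-negativity is guaranteed by the bound in (1), with
only float dust swept to zero); (4) biomass grows by b·(e^(μ·dt) − 1) —
exponential integration is exact for constant μ and stable at dt = 1 h;
(5) an agent at or above the division threshold splits in half into a
uniformly chosen free von Neumann neighbor, deferring division when none is
free; (6) every substrate field mixes: each cell sends a `diffusion_rate`
fraction of its amount, split equally among in-grid neighbors (closed
boundaries, exactly conservative); replenished fields are then reset to
their initial concentration. Note the closed-boundary mixing operator's
stationary state is not perfectly uniform (corner cells have fewer
neighbors); the conservation property, not uniformity, is the contract.

Growth is capped twice: per agent at 2× the division threshold, and
globally so that total biomass never exceeds the arena capacity. The
capacity equals grid cells × division threshold — one "full" agent per
cell — which makes saturation exact: a fast grower on rich medium ends at
precisely the capacity. When growth is capacity-capped the solved exchange
fluxes are still applied (a maintenance-like interpretation); the
substrate-accounting invariant is defined over the solved fluxes and so
still closes.

Default configuration: 20×20 grid; total arena volume 1 µL split evenly
over cells; dt = 1 h; horizon 45 h; division threshold 1.875 pg (capacity
20·20·1.875 = 750 pg); initial agent biomass = half the threshold;
diffusion rate 0.5 for all solutes; oxygen 0.1 mM, replenished every step
(constant microaerobic environment; a one-shot supply is available by
putting oxygen in the medium without the replenished flag); 10 agents per
species inoculated uniformly at random on distinct cells. Replicate
protocols: 12 seeded runs for growth curves, 100 for metabolite-production
profiling. All randomness flows from one seeded generator; a fixed config
and seed reproduce every series bitwise.

### Cross-feeding statistic

For a species pair and each exchange reaction/timepoint the ratio
r = v_A/v_B of the biomass-weighted population-mean fluxes is formed;
when −1 < r < 1 its reciprocal is reported, so magnitude ≥ 1 always
highlights the larger flux and the sign equals sign(v_A)·sign(v_B). This
reciprocal rule is the entire normalization — nothing else is applied. A
reaction with either flux at zero, or absent from one model, is
NOT_SHARED. Detection calls a metabolite exchanged when its ratio is
negative in ≥ 80% of shared timepoints with at least 3 shared timepoints;
both thresholds are parameters. The 0.8/3 defaults encode "consistently
negative over the time course" while tolerating brief transients at
inoculation or saturation. The heatmap snapshot defaults to 32 h. The
orientation (which species is the numerator) is recorded in each entry;
the reciprocal rule makes |value| and sign orientation-invariant.

### Cumulative flux

Per reaction, fluxes are summed over all recorded timepoints per medium;
the difference d = sum_baseline − sum_comparison is reported as
log(|d| + 1) with the sign kept alongside. The log is natural by default
(base 10 by flag). Groups aggregate sum-then-transform: the signed d's are
summed over the group before the log, because the comparison is defined on
flux sums and this preserves cancellation of opposing reroutes; the choice
is echoed into output metadata. A per-timepoint variant is available by
summing over a single-element series.

### Screens and classification

Growth grids run every singleton and cross-genus pair (all pairs by flag)
on every medium via the 12-replicate protocol and bin total final biomass
at the 250/500/750 pg edges (half-open below, closed at the top).
Interaction classification compares co-culture to mono-culture finals per
species: stimulation at ≥ σ× (default 2), decrease at ≤ ι× (default 0.5),
competition when both decrease, inhibition when one decreases while the
partner does not. Two identical competitors split a saturated arena at
*exactly* ι = 0.5 of their mono value, so the decrease threshold carries a
15% multiplicative boundary tolerance — without it a single stochastic run
of the canonical competition scenario would flip labels on sampling noise.
The supplementation screen adds one candidate at a time (default 10 mM) to
the base medium and calls a metabolite promoting when the mono-culture
fold-change is ≥ 2 *and* the absolute gain is ≥ 10 pg (both configurable,
both echoed into output metadata); the absolute-gain guard stops large
folds on near-zero baselines from counting as rescue. Candidates unknown
to both the model's external metabolites and the medium are reported
not-applicable rather than failing the screen.

## Synthetic ground truth

The generators produce models small enough to solve by hand, with the
mechanistic structure the analysis assumes:

* **chain species** — substrate → transport → biomass; μ* = vmax × yield
  exactly, for any positive vmax and yield.
* **producer/consumer pair** — the producer consumes glucose slowly
  (uptake cap 3, biomass demand 10 per unit ⇒ μ* = 0.3 h⁻¹) and co-secretes
  20 units of the shared metabolite M per biomass unit; secretion is
  stoichiometrically obligate so alternate optima cannot hide it. The
  consumer needs glucose (5) and a trace of M (0.5) per biomass unit
  (μ* = 2.0 h⁻¹ with both, 0 without M). The slow-producer /
  fast-consumer / trace-requirement asymmetry makes the co-culture rescue
  decisive (≥ 5× the consumer's mono-culture biomass on every seed) rather
  than marginal, and the consumer then overgrows its benefactor — the
  designed pair classification is inhibition (producer) / stimulation
  (consumer).
* **competitor pair** — two label-distinct copies of one model; by
  symmetry the expected final share is 0.5 each and the combined biomass
  saturates the capacity.
* **heterolactic species** — secretes lactate and acetate coupled 4:2 to
  biomass, so both production curves rise monotonically and their ratio is
  exactly 0.5.
* **media suite** — rich (glucose + M), limiting (glucose only; the
  consumer's auxotrophy bites), limiting+M (10 mM supplement — the rescue
  design); oxygen 0.1 mM replenished in all three. Glucose is set at
  20 mM, far from limiting at desk scale, so space — not carbon — ends
  growth, which is the regime the competition and rescue analyses assume.

Each `GroundTruth` registry's analytic growth rates are re-verified against
the FBA solver at build time (tolerance 1e−8).

What the toys deliberately do **not** emulate: genome-scale redundancy
(thousands of reactions, alternate pathways), realistic biomass
stoichiometries, pH/toxicity growth inhibition, transporter kinetics
beyond bounds, or curated diet compositions. Passing the ground-truth
tests therefore shows the *pipeline* is correct — that designed exchanges
are recovered and designed interactions classified — not that any
particular real community behaves this way.

## Problem sizes

Scenario analyses (cross-feeding recovery, screens, classification sweeps)
run on a 10×10 arena (capacity 187.5 pg under the same cells × threshold
rule); the competitor-saturation experiment and the acceptance script use
the full default 20×20 / 750 pg configuration. Identical FBA problems are
memoized within a run (agents of one species with the same effective
bounds share a solve), which is what keeps 45-step, 400-agent arenas fast
on a single CPU.

## Known limitations

* FBA magnitudes are only as good as the bounds; absolute biomass and
  flux values are arena-convention-dependent and should be read
  comparatively, not as physical predictions.
* No inhibitory interactions via toxic metabolites (H₂O₂, H₂S) — FBA has
  no notion of growth inhibition by a compound's presence.
* The mixing operator is a per-step fraction exchange, not a calibrated
  diffusion PDE; `diffusion_rate` is a mixing intensity, not a physical
  diffusivity.
* Division defers (never forfeits) when no neighbor cell is free; under
  total gridlock biomass still grows until the per-agent and capacity caps
  bind, so late-time per-agent biomass sits between one and two division
  thresholds.
* SBML import requires cobrapy; the native `toy_json` dialect is the
  self-contained interchange format and round-trips byte-exactly.
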