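# Methods

## The update formalism

Each node carries a slow variable (transcript level) and a fast variable
(post-translational state), both on [0, 1]; activity is their product.
Every variable is driven towards

    target = clip01( sigma * (sum_activators w*a - sum_inhibitors w*a) )

with a single global saturation factor `sigma`.  We interpret `sigma`
multiplicatively: full activation requires a net positive input of
`1/sigma`, so a *larger* saturation factor makes nodes easier to
activate and (empirically, see the sweep analysis) shrinks the basin of
the all-inactive 'None' state.  Three conventions complete the rule:

* a fast variable with no incoming rules is *neutral* (target 1), so the
  node's activity is governed entirely by its slow variable;
* a slow variable with no incoming rules holds its value — except for
  nodes flagged `constitutive`, whose unregulated slow variable is pinned
  at 1 (produced by default);
* a variable whose rules are all inhibitory receives a basal drive of
  `1/sigma`: it represents a species that is on unless actively repressed
  (the WNT destruction complex is the canonical example).  The same
  constant is available explicitly through the `BASAL` pseudo-source.

Complex-formation terms (`A*B` sources) contribute the product of the two
partner activities; they model repressive complexes that require both
partners (NKX3.2 with the SMAD complex; SMAD3 with HDAC4).

**Scheduling.** General asynchronous updating with two priority classes:
while any fast variable is off its target by more than `eps = 1e-9`, one
of them, chosen uniformly at random, is assigned its target; a single
uniformly chosen slow variable is updated only when all fast variables are
in equilibrium.  Variables are *assigned* their algebraic target rather
than moved gradually, so `eps` only guards float noise.  A state in which
every variable equals its target is a fixed point; caps of 10,000 fast
updates per relaxation and 2,000 slow updates per trajectory flag
(rare) non-converging runs, which all analyses count separately rather
than classify.

Because targets are assigned outright, a negative feedback loop with gain
exactly 1 oscillates forever instead of converging to its interior
equilibrium.  The bundled network therefore carries weight 0.5 on
negative-feedback edges (see below); the random-network generator's
default weight range keeps loop gains heterogeneous for the same reason.

**Clamps.** A knockout/overactivation holds a node's *effective* activity
at the clamp level for a duration counted in slow-scale ticks (infinite =
permanent, e.g. a genetic manipulation).  Internally the level is parked
in the node's regulated variable — the slow one when it is
transcriptionally driven, otherwise the fast one.  This makes release
semantics exact: a transcriptional imprint persists until the slow
dynamics overwrite it, while a purely post-translational perturbation
relaxes immediately (the fast class re-equilibrates before any slow
update).  An earlier implementation that split the level across both
variables leaked spurious slow-variable displacements on release and made
attractors appear unstable to arbitrarily small perturbations.

## The chondrocyte network reconstruction

`data/chondrocyte.tsv` encodes the 43-node SOX9/RUNX2 fate-decision
network.  Provenance, in decreasing order of directness:

1. the node list, the constitutive flags, and the full transcriptional
   and post-translational regulator lists of RUNX2 and SOX9 are
   transcribed from the published description of the network;
2. the published wild-type attractor table is used as calibration data
   where it pins relations between nodes: the R-SMAD/SMAD7 feedback
   weight (0.5 reproduces the printed 0.67 = 2/3 loop value exactly), the
   weak IGF-1R→RAS coupling (0.3, from RAS = 0.1 with IGF-1R ≈ 0.3) and
   the absence of a direct IGF-1R→PI3K edge (PI3K = AKT = 0 in the SOX9
   column despite active IGF), the WNT→DSH weight (0.67), and the
   PTHrP module weights (PTHRP ≈ 0 in the hypertrophic column);
3. everything else is canonical pathway biology with default weight 1,
   one justification comment per edge in the model file.

The saturation factor ships at `sigma = 1`, where a single full-strength
activator exactly saturates its target; the sweep analysis exposes the
dependence of every result on this choice.

What the reconstruction reproduces: exactly three wild-type attractors
with the published identities (SOX9-positive, RUNX2-positive with SOX9
fully repressed, and an all-off 'None' state in which only the
constitutive GSK3β and destruction complex remain active); the RUNX2
basin as the smallest (≈4% vs the published 6%); stability of all three
attractors to clamp offsets up to 0.04; and the saturated entries of the
attractor table (the 0/1 pattern, the 2/3-valued WNT/SMAD loop levels,
DC = 1 − DSH).  What it does not reproduce, because the published
per-node equation coefficients are unavailable: the 64/30/6 basin split
(we find ≈46/50/4), the identity of the knockout set that eliminates the
RUNX2 basin, the +93 pp WNT-overactivation effect (WNT overactivation is
roughly RUNX2-neutral here because RUNX2's fast variable needs
PI3K/ERK/PKA/DLX5 support that WNT alone does not supply), the exact
transition probabilities, and SMAD3 as the single minimal destabiliser
(SMAD3 does destabilise the RUNX2 state here, but RUNX2's own knockdown
has a smaller threshold).  The acceptance tests encode both groups at
their stated tolerances and the second group fails openly.

## Analyses

**Attractors.** `find_attractors` runs the dynamics from random initial
states (all variables i.i.d. uniform, constitutive nodes at 1),
deduplicates converged endpoints at max-norm tolerance
`delta_attr = 0.005` (the published table prints two decimals) and
verifies each representative with one synchronous fixed-point evaluation.
Attractors with very small basins can be missed; this is inherent to the
Monte Carlo approach.  Classification threshold `theta = 0.05` on marker
activity; when both markers exceed it the larger wins and a dual flag is
set (the 3-label scheme is kept because the Markov analysis is 3-state).

**Basins / screen.** `estimate_basins` pools batches (default 3) of
random restarts; the binomial SE is reported per label.  The screen
clamps every node permanently to 0 and to 1, skipping directions at which
the node is already pinned in all wild-type attractors, and shares batch
seeds with the wild-type baseline (common random numbers) so the deltas,
which are the quantity of interest, are tighter than the absolute levels.

**Perturbation / Markov.** A perturbation clamps one node of an attractor
for a fixed number of slow ticks (default 20, on the plateau where
doubling the duration changes outcomes by < 0.02 total variation —
`saturate_duration` re-derives this per node) and classifies the settled
endpoint over repeated runs (3 × 100 by default).  Directions are
infeasible when the node already sits within `theta` of that extreme.
The transition matrix averages outcome distributions over nodes, a node
feasible in both directions contributing the mean of its two directions,
i.e. a uniform random single-node perturbation regime.  The stationary
distribution comes from the left eigenvector at eigenvalue 1,
cross-checked against power iteration to 1e-12; reducible chains are
reported as such (the returned vector is then the power-iteration limit
from uniform).  `minimal_magnitude` scans clamp offsets on a 0.01 grid
(the published thresholds are quoted at percent resolution).

**Variants and sweep.** `model2` replaces the SMAD-complex (BMP) slow
input of MEF2C with LEF/TCF; `model3` deletes it, leaving RUNX2.  The
overactivation table clamps WNT and/or BMP at activity 1.0, with a
`level` parameter for sub-maximal runs.  The sweep re-runs attractor
discovery and basin estimation per saturation value.

## Synthetic fixtures and the oracle

The generator module provides the statistical structure of the formalism
without the chondrocyte model.  The toggle switch is mutual inhibition
(weight 2) over the basal drive: under assignment-to-target updates a
self-activation of weight exactly `1/sigma` produces a continuum of fixed
points, so the textbook "mutual inhibition + self-activation" layout is
deliberately avoided; this variant has exactly the two pole attractors
and an interior saddle at 1/3.  Cascades alternate fast/slow links from a
constitutive head.  Random networks are seeded and repaired so every node
has a driven slow variable and is reachable from a constitutive root;
default weights are uniform on [0.5, 1.5] so `sigma = 1` sits mid-range.

`brute_force_attractors` enumerates a grid over the free variables
(states = (1/step + 1)^n_free, hard-capped) and iterates the *damped*
synchronous map `x <- x + 0.5 (target(x) - x)`, which preserves the fixed
points but converges where the undamped map 2-cycles.  The oracle is
complete — it also lists fixed points that are unstable under the
asynchronous dynamics (the toggle saddle) — so the equivalence property
asserted in tests is containment: every restart attractor appears in the
oracle list, with exact equality of the stable set on the curated
fixtures.  Passing these tests shows the engine and the formalism agree;
it does not validate the chondrocyte reconstruction against unpublished
coefficients, and none of the synthetic fixtures emulate features of real
expression data (noise models, measurement error, dropout).

## Problem sizes and determinism

Wild-type basin estimates use the published 3 × 10,000 restarts; the
per-node screen, the perturbation batteries and the magnitude scans in
the acceptance script run at 3 × 2,000, 3 × 100 and 25 repetitions per
condition respectively — at a 3-state multinomial these give standard
errors below one percentage point, far inside every tolerance used.  All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`-derived child streams (kept below 2^31 for
the compiled kernel); identical seeds byte-reproduce every table.  The
heavy Monte Carlo paths run in a numba kernel that shares its compiled
rule arrays with the readable Python engine; the test suite asserts the
two engines agree on attractor sets and basin fractions.

## Known limitations

* The chondrocyte model is a reconstruction; see above for exactly which
  published quantities it does and does not reproduce.
* Continuous-time dynamics, stochastic noise within a trajectory, and
  multi-node perturbations (beyond stacking clamps by hand) are out of
  scope, as is topology/weight fitting to expression data.
* The oracle is limited to models whose free-variable count keeps the
  grid enumerable (~6 variables at coarse steps).
* Under heavy clamping a trajectory can fail to converge (capped); all
  analyses report such runs separately instead of classifying them.
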