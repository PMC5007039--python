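# qualnet

Qualitative two-timescale gene-network dynamics, built around the
regulatory network that controls the switch of growth-plate chondrocytes
from a stable, SOX9-positive phenotype to RUNX2-driven hypertrophy — the
step that matters both for endochondral bone formation and for ectopic
hypertrophy in osteoarthritis.  The package is for computational
biologists who want to simulate such additive qualitative models, identify
their stable states, and screen every factor's contribution to a cell-fate
decision *in silico*.

## The model

Every node *i* (gene/protein/complex) carries two variables on [0, 1]: a
slow one *s<sub>i</sub>* for transcript-level regulation and a fast one
*f<sub>i</sub>* for post-translational regulation; its activity is
*a<sub>i</sub> = s<sub>i</sub>·f<sub>i</sub>*.  Each variable is driven
towards

&nbsp;&nbsp;&nbsp;&nbsp;target = clip₀¹ ( σ · ( Σ<sub>act</sub> w·a − Σ<sub>inh</sub> w·a ) )

an additive combination of upstream activities with a single global
saturation factor σ (larger σ ⇒ less positive input needed for full
activity).  Updating is *generally asynchronous with two priority
classes*: one randomly chosen off-target fast variable is re-set at a
time, and a slow variable may only move when every fast variable is in
equilibrium.  States where nothing moves are the attractors; the marker
nodes SOX9 and RUNX2 classify each attractor as a stable chondrocyte
(SOX9), a hypertrophic cell (RUNX2) or 'None'.

Three analyses are built on the engine:

* **canalisation** — the fraction of random initial states absorbed by
  each attractor (Monte Carlo basin size), re-estimated under a permanent
  knockout or overactivation of every node in turn;
* **perturbation** — transient single-node clamps applied to an attractor
  itself, giving per-node transition probabilities, the minimal clamp
  magnitude that destabilises a state, and a 3-state Markov chain whose
  stationary distribution is the long-run phenotype mix under continual
  random perturbation;
* **topology variants** — rewired regulation of MEF2C and a saturation
  factor sweep, for testing the robustness of conclusions.

The bundled 43-node chondrocyte network (`qualnet.chondrocyte_model()`)
is a documented reconstruction: the node set, the full SOX9/RUNX2
regulator lists and the attractor table of the published analysis are
transcribed directly, the remaining wiring follows canonical growth-plate
signalling, and every interaction in
`src/qualnet/data/chondrocyte.tsv` carries a one-line justification.  The
original per-node equation coefficients are not published, so quantitative
results deviate from the printed ones in known, documented ways (see
`docs/methods.md`); the qualitative structure — three attractors, a small
RUNX2 basin, stability to small perturbations — is reproduced.

## Worked example

```python
import qualnet as qn

m = qn.chondrocyte_model()                      # 43 nodes, 95 interactions
atts = qn.find_attractors(m, 10_000, seed=7)    # Monte Carlo restarts
est  = qn.estimate_basins(m, 10_000, 3, seed=7) # 3 batches of 10,000
tm   = qn.build_transition_matrix(m, atts, duration=20, n_reps=100,
                                  n_batches=3, seed=7)
pi   = qn.stationary(tm)
```

which prints (via the obvious loops):

```
3 attractors from 10000 restarts (2 unconverged)
  SOX9  support= 4931  SOX9=1.00  RUNX2=0.00
  None  support= 4654  SOX9=0.00  RUNX2=0.00
  RUNX2 support=  413  SOX9=0.00  RUNX2=1.00
  P(None ) = 0.459 +- 0.003
  P(SOX9 ) = 0.497 +- 0.003
  P(RUNX2) = 0.043 +- 0.001
stationary: {'SOX9': 0.63, 'RUNX2': 0.064, 'None': 0.306}
```

Read: the wild-type network has exactly three stable states.  A random
initial state most often decays to 'None' or settles into the stable
chondrocyte state; only ~4% of states canalise into hypertrophy — the
RUNX2 programme is hard to reach but, once perturbations act on the
attractors themselves (the Markov analysis), cells still spend ~6% of the
long run in it.

The same analyses are available from the shell:

```bash
qualnet info chondrocyte
qualnet basins chondrocyte --n 10000 --batches 3 --seed 7
qualnet screen chondrocyte --n 2000 --seed 7 --rank   # KO/OE screen + target ranking
qualnet markov chondrocyte --seed 7
qualnet table2 chondrocyte --seed 7                   # MEF2C topology variants
qualnet synth toggle -o toggle.tsv                    # synthetic fixtures
```

`MODEL` arguments take a model file in the package's tab-separated format
(`qualnet validate my_model.tsv` checks it), so new networks with the
same structural assumptions can be screened without code changes.

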