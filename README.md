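# rnaworld

An agent-based simulator of the replicase–parasite dynamics at the heart
of the RNA World hypothesis, in which every molecule carries an explicit
RNA sequence.

Early life, under this hypothesis, was a population of RNA strands in
which some molecules (replicases) could catalyse the copying of others
while mutation constantly generated parasites — strands that are copied
but catalyse nothing. Whether such a system can persist, and how catalytic
function can be maintained against parasite load, is a central question of
prebiotic evolution. This package simulates that contest with agents whose
behaviour is derived from their actual 50-nt sequence:

* **`l`**, the folded-state fraction — paired nucleotides / length of the
  predicted secondary structure (built-in Nussinov maximum base-pairing;
  pluggable external predictor). Folded molecules catalyse; unfolded
  molecules are copyable.
* **`a`**, the replicase efficiency — from the number of position-wise
  matches `m` between the 5'-terminal 20 nt and a catalytic motif
  (`UCAUUGAAAAAAAAAGACAA`, from the engineered polymerase ribozyme tC19Z):
  `a = 1 − exp(−10·m·Δt)` for `m ≥ 7`, else `a = 0` (a parasite).
* **`b`**, the decay rate — base rate plus per-dinucleotide phosphodiester
  hydrolysis rates summed along the strand.

Agents diffuse on a 2D torus (Brownian steps, mean squared displacement
`3·D·Δt` per step), form enzyme–template complexes with probability
`a_E · l_E · (1 − l_T)` when within the interaction radius, replicate with
per-site mutation, and are removed by decay (exponential lifetimes) or by
crowding (more than `neigh` neighbours). See `docs/methods.md` for the
full model description and its assumptions.

## Worked example

Run a scaled-down scenario 1 (ideal replicases only; parasites emerge by
mutation) — 900 agents on a 95×95 torus for 500 steps:

```sh
rnaworld run --scenario 1 --scale 0.009 --steps 500 --seed 7 --out demo
```

which prints

```
step 500: 595 replicases, 442 parasites, 221 complexes -> demo
```

i.e. after 500 steps the population has grown from 900 ideal replicases
to 1,037 agents, of which 442 are mutation-derived parasites and 221
pairs are currently locked in replication complexes. `demo/stats.csv`
holds the per-step counts and class means of `a` and `l`,
`demo/survivors.fasta` a `selProb`-sampled FASTA of surviving sequences
annotated with their derived parameters, and `demo/manifest.json` the
fully resolved configuration for exact replay. The same run from Python:

```python
from rnaworld import ScenarioSpec, build_scenario, Simulation
import numpy as np

spec = ScenarioSpec(scenario=1, scale=0.009)
params, seqs = build_scenario(spec, rng=np.random.default_rng(7))
sim = Simulation(params, seqs, seed=7)
stats = sim.run(max_steps=500)
print(stats.iloc[-1][["n_replicases", "n_parasites", "n_complexes"]])
```

Parameter sweeps over the base decay rate `d` or the diffusion constant
`D` (scenario 4) map the survival/collapse boundary:

```sh
rnaworld sweep --vary d --values 0.01,0.7 --replicates 3 --steps 3000
```

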