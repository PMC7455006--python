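# Methods

## The model

The simulator follows a population of RNA agents on a continuous
two-dimensional torus. Every agent carries an explicit 50-nt sequence over
{A, C, G, U} from which all of its behavioural parameters are derived at
birth:

* **Folded-state fraction `l`** — the fraction of nucleotides paired in the
  predicted secondary structure. A folded molecule acts as a catalyst but
  is inaccessible as a template; an unfolded molecule is copyable.
* **Replicase efficiency `a`** — the first 20 nt are compared
  position-by-position (no alignment) with a fixed catalytic motif, the
  5'-terminal 20-mer of the engineered polymerase ribozyme tC19Z
  (`UCAUUGAAAAAAAAAGACAA`). With `m` matches, the replication rate is
  `k_R = rate_per_match * m` if `m >= 7`, else 0, and
  `a = 1 - exp(-k_R * dt)` is the per-step probability that the catalytic
  step fires. Agents with `a = 0` are parasites: copyable, but unable to
  copy others.
* **Decay rate `b`** — a base rate `d` plus the sum over the 49
  phosphodiester bonds of per-dinucleotide hydrolysis rates (5'→3'
  orientation; unlisted dinucleotides contribute 0). A table of measured
  non-enzymatic hydrolysis rates ships with the package (UA 0.000953,
  CA 0.000932, UC/CC 0.000846, UG/CG/UU/CU 0.0001).

Each step runs two phases over fresh uniform-random agent orders:

1. **Decay / diffusion.** A complexed enzyme decrements its complex's
   replication countdown once per step; at zero the template is copied
   with independent per-site substitution (probability `seq_mut` per nt,
   replacement uniform over the three other bases), the offspring is
   placed at the template's exact position with parameters derived from
   its own (possibly mutated) sequence, and the complex dissociates. Free
   agents age by one step — the decay waiting time is drawn once at birth
   from an exponential with rate `b` and expressed as
   `floor(t/dt) + 1` steps — and survivors take a Brownian step of length
   `sqrt(6 * dt * D * p)` (`p` uniform on [0, 1]) in a uniformly random
   direction (per-step mean squared displacement `3 * dt * D`). Complexed
   agents neither age nor move.
2. **Interactions.** Each still-free agent gathers all agents (free or
   complexed) at toroidal distance strictly below the interaction radius.
   More than `neigh` neighbours removes the focal agent (crowding: a local
   density cap). Otherwise it scans its neighbours in random order and,
   with probability `a_E * l_E * (1 - l_T)` per free neighbour, binds the
   first success as template and stops. With `K = inf` every complex
   replicates on the following step and dissociates immediately after.

Newly born agents enter the population mid-step: they are eligible for
interactions in their birth step but neither age nor diffuse until the
next one.

## Folding

Only the paired-nucleotide count feeds the model, so the built-in
predictor maximises the number of base pairs (Nussinov dynamic
programming) over nested structures with a minimum hairpin loop of 3
unpaired nt and, by default, G·U wobble pairs allowed alongside
Watson–Crick pairs. The traceback is deterministic: in each interval the
5'-most position pairs its leftmost admissible partner whenever pairing is
optimal. The DP optimum is verified in the test-suite against exhaustive
enumeration of all nested structures for sequences up to length 14.

An external predictor can be plugged in as a callable mapping a sequence
to a dot-bracket string; its output is validated against the structure
invariants (one partner per position; crossing pairs are accepted in the
data model). The simulation loop itself always folds with the built-in
predictor — per-birth subprocess calls to an external tool would dominate
the runtime by orders of magnitude — so external backends serve
single-sequence analysis through `predict_structure` and `make_agent`.

Maximum base-pairing is a deliberately structure-agnostic choice: it
recovers the ideal replicase's designed 18-pair stem exactly (l = 0.72
from the stem alone; ≈ 0.807 averaged over random tails) but assigns
rather high `l` (≈ 0.6) to arbitrary sequences, where thermodynamic
predictors would assign ≈ 0.45 and spread a wider range. Consequences for
the population dynamics are discussed under *Limitations*.

## Ideal replicases and scenarios

An ideal replicase is motif + reverse complement of the motif + 10 random
nt: a maximal-efficiency catalyst whose designed stem also makes it a poor
template. Scenario 1 starts from ideal replicases only; scenario 2 from
fully random sequences (a `P(Binom(20, 1/4) >= 7) ≈ 21%` minority of which
carry an adequate accidental motif); scenario 3 adds the measured
hydrolysis table to scenario 1; scenario 4 sweeps `d` or `D` on a smaller
population to map the survival boundary.

The reference configuration is 10^5 agents on a 1000×1000 area (density
0.1 per unit²). Desk-scale runs shrink population and area together
(`scale = 0.09` gives 9,000 agents on 300×300) so that the local dynamics
— crowding, encounter rates — are unchanged. Scenario 4's "smaller
population" uses the same density-preserving scaling (default
`scale = 0.01`: 1,000 agents on 100×100) with replicate seeds per sweep
value; a sparse full-area alternative was evaluated and rejected because
local offspring placement makes reproduction insensitive to global
density (isolated pairs nucleate growing colonies), so sparseness does
not change the boundary behaviour.

## Numerical and design choices

* All randomness in the step loop flows through a per-simulation
  xoshiro256++ state, so trajectories replay bit-for-bit for a fixed seed
  even with several simulations interleaved in one process. Scenario
  construction and initial lifetimes use a separate generator derived from
  the same seed.
* (l, a, b) are pure functions of the sequence; the engine memoises them
  in a sequence-keyed open-addressing cache and lets unmutated copies
  inherit the template's parameters. Neither shortcut consumes randomness,
  so they cannot alter trajectories; the test-suite recomputes every
  agent's parameters through the plain Python path and compares exactly.
* Neighbour queries use a uniform grid with cell size ≥ the interaction
  radius (at most a 3×3 block per query, deduplicated on very small
  toruses); the grid query is tested against the O(n²) all-pairs scan.
* The crowding rule counts complexed agents as neighbours (they occupy
  space); a configuration flag (`crowding_counts_complexed`) exposes the
  alternative reading. In scaled scenario-1 experiments the choice did not
  change the qualitative outcome.
* Waiting times of zero-rate reactions are "never" (no decay when
  `b = 0`); an infinite rate fires on the next step (`K = inf` gives every
  complex a one-step replication countdown).
* `rate_per_match` defaults to 10 as stated for the efficiency rule, which
  pins `a >= 1 - e^-7 ≈ 0.999` for every replicase at `dt = 0.1`.
  Published equilibrium efficiencies around 0.82 are only attainable if
  the factor of 10 is dropped (then `a` spans 0.5–0.86 and is genuinely
  selectable); the field is configurable (`ReplicaseMotif(rate_per_match=1)`)
  but the default follows the stated rule.

## What the tests do and do not show

The unit and property layers verify every sequence→parameter mapping
against closed forms and hand-computed examples, the folding DP against
exhaustive enumeration, the diffusion law and waiting-time sampling
against their analytic moments at 10^6 draws, per-step population
bookkeeping (`ΔN = births − deaths − crowding removals`) over whole runs,
and bit-identical replay.

The scaled scenario-1 acceptance run (9,000 agents, 300×300, 3,000 steps)
exercises the full dynamics: growth to the crowding cap, mutational
emergence of parasites, and a parasite-driven crash. In this
implementation the crash proceeds to replicase extinction in every
configuration tried — several seeds, density-preserving scales from 0.01
up to a full-scale run (100,000 agents on 1000×1000, replicases extinct
by step 1,500), both efficiency rules (`rate_per_match` 10 and 1), and
both crowding-count readings — whereas the reference results report
stable coexistence. The trajectory matches the reported narrative through
its first phases (rapid replicase growth, mutational emergence of
parasites, replicase crash while parasites peak) and then diverges at the
stabilisation step.

The divergence is consistent with two quantitative inconsistencies
internal to the published description itself: (i) the printed efficiency
rule forces `a ≥ 0.999` for every replicase, while the published
equilibrium efficiencies (0.65–0.86) imply a tenfold smaller replication
rate; and (ii) with the printed rates, replication outpaces decay at
`d = 0.7` by about threefold, so the published extinction at `d ≥ 0.7`
cannot occur — in this implementation `d = 0.7` yields stable
coexistence (high decay clears parasites faster than replicases are
lost), and the survival window in `d` is shifted upward relative to the
published one. A further stabiliser in the reference implementation may
have been its MPI spatial partitioning (agents interact only within a
thread's block), which acts as soft compartmentalisation — a classic
parasite-suppression mechanism — and is out of scope here by design
(single-process execution with randomized agent orders). Equilibrium
quantities conditioned on stable coexistence at `d = 0.01` are therefore
not reproduced by the printed model; the corresponding acceptance checks
fail honestly rather than being loosened. The `D = 0` boundary does
reproduce: without diffusion the population decays to extinction within
the reference 10,000-step horizon in every replicate.

## Limitations

* The built-in max-pairing predictor overestimates pairing of arbitrary
  sequences relative to thermodynamic prediction, which compresses the
  heritable variance of template quality; the evolved decline of `l`
  below 0.3 reported with a pseudoknot-capable thermodynamic predictor is
  not reached under max-pairing within desk-scale horizons.
* Efficiency as printed (`rate_per_match = 10`) saturates `a ≈ 1` for all
  replicases, removing selection on motif quality beyond the threshold.
* Single-process execution; the randomized agent orders stand in for the
  randomized scheduling that multithreaded partitions would produce.
* No strand polarity, no compartments, no tertiary structure, no
  insertions/deletions.
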