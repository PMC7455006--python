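"""Scenario builders, population statistics, survivor export and sweeps.

Four canonical experiments are provided:

1. ideal replicases only — parasites emerge by mutation; the two classes
   settle into coexistence;
2. a fully random sequence pool — a minority of accidental replicases takes
   over and stabilises the system;
3. as scenario 1 but with measured phosphodiester hydrolysis rates, so the
   decay rate becomes sequence-dependent;
4. parameter sweeps (base decay rate d, diffusion constant D) mapping the
   survival/collapse boundary on a smaller population.

The reference configuration places 10^5 agents on a 1000x1000 area (density
0.1 per unit area). Desk-scale runs keep that density by shrinking area and
population together (``scale`` is the population scale factor; lengths
shrink by its square root): ``scale=0.09`` gives 9,000 agents on 300x300.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .engine import Simulation, SimulationParams
from .sequences import (
    HydrolysisTable,
    build_ideal_replicase,
    random_sequence,
    write_fasta,
)

#: Reference full-scale population and area.
FULL_SCALE_POPULATION = 100_000
FULL_SCALE_SIZE = 1000.0

#: Default desk-scale factor: 9,000 agents on a 300x300 torus.
DEFAULT_SCALE = 0.09


@dataclass(frozen=True)
class PopulationStats:
    """Per-step population summary.

    Class membership is by replicase efficiency: replicases have a > 0,
    parasites a = 0. A class mean is ``None`` when the class is empty.
    """

    step: int
    n_replicases: int
    n_parasites: int
    n_complexes: int
    mean_a_replicases: Optional[float]
    mean_l_replicases: Optional[float]
    mean_l_parasites: Optional[float]


@dataclass(frozen=True)
class ScenarioSpec:
    """Which experiment to build and how far to scale it down."""

    scenario: int
    scale: float = DEFAULT_SCALE
    init_r: Optional[int] = None
    init_p: Optional[int] = None
    hydrolysis: Optional[HydrolysisTable] = None
    sweep_var: Optional[str] = None  # "d" or "D" (scenario 4)
    sweep_values: tuple = ()
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3, 4):
            raise ValueError("scenario must be 1, 2, 3 or 4")
        if not 0 < self.scale <= 1:
            raise ValueError("scale must lie in (0, 1]")
        if self.sweep_var is not None and self.sweep_var not in ("d", "D"):
            raise ValueError("sweep variable must be 'd' or 'D'")
        if self.scenario == 4 and self.sweep_var and not self.sweep_values:
            raise ValueError("a sweep needs at least one value")


def scaled_params(
    base: Optional[SimulationParams] = None, scale: float = DEFAULT_SCALE
) -> SimulationParams:
    """Shrink the area so a scaled population keeps the reference density."""
    base = base or SimulationParams()
    factor = math.sqrt(scale)
    return base.with_overrides(
        size_x=base.size_x * factor, size_y=base.size_y * factor
    )


def build_scenario(
    spec: ScenarioSpec,
    params: Optional[SimulationParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[SimulationParams, list[str]]:
    """Resolve scenario parameters and the initial sequence pool.

    Returns the (possibly rescaled) parameters and the list of initial
    sequences; positions are drawn uniformly by the Simulation itself.
    Scenarios 1, 3 and 4 start from ideal replicases; scenario 2 starts
    from fully random sequences, a fraction of which happen to carry an
    adequate replicase motif. Scenario 3 installs the measured hydrolysis
    table so decay becomes sequence-dependent.
    """
    rng = rng if rng is not None else np.random.default_rng()
    params = scaled_params(params, spec.scale)

    n_ideal = spec.init_r
    if n_ideal is None:
        n_ideal = round(FULL_SCALE_POPULATION * spec.scale)
    n_random = spec.init_p
    if n_random is None:
        n_random = round(FULL_SCALE_POPULATION * spec.scale)

    if spec.scenario in (1, 3, 4):
        sequences = [
            build_ideal_replicase(params.motif, params.seq_length, rng)
            for _ in range(n_ideal)
        ]
        params = params.with_overrides(init_r=n_ideal, init_p=0)
    elif spec.scenario == 2:
        sequences = [
            random_sequence(params.seq_length, rng) for _ in range(n_random)
        ]
        params = params.with_overrides(init_r=0, init_p=n_random)
    if spec.scenario == 3:
        table = spec.hydrolysis or HydrolysisTable.measured()
        if not table.rates:
            raise ValueError("scenario 3 requires a nonempty hydrolysis table")
        params = params.with_overrides(hydrolysis=table)
    elif spec.hydrolysis is not None:
        params = params.with_overrides(hydrolysis=spec.hydrolysis)
    return params, sequences


def record_stats(sim: Simulation, step: Optional[int] = None) -> PopulationStats:
    """Summarise the current population of a simulation."""
    agents = sim.agents()
    repl = [ag for ag in agents if ag.a > 0]
    para = [ag for ag in agents if ag.a == 0]
    mean = lambda xs: sum(xs) / len(xs) if xs else None  # noqa: E731
    return PopulationStats(
        step=step if step is not None else sim.step_count,
        n_replicases=len(repl),
        n_parasites=len(para),
        n_complexes=sim.n_complexes,
        mean_a_replicases=mean([ag.a for ag in repl]),
        mean_l_replicases=mean([ag.l for ag in repl]),
        mean_l_parasites=mean([ag.l for ag in para]),
    )


def export_survivors(
    sim: Simulation,
    path: str | Path,
    sel_prob: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
) -> int:
    """Write a random sample of surviving agents to FASTA.

    Each survivor is included independently with probability ``sel_prob``
    (default: the simulation's own). Headers carry the agent id, its class
    and the derived parameters. Returns the number of records written.
    """
    if sel_prob is None:
        sel_prob = sim.params.sel_prob
    if not 0 <= sel_prob <= 1:
        raise ValueError("sel_prob must be a probability")
    rng = rng if rng is not None else sim.rng
    records = []
    for ag in sim.agents():
        if rng.random() < sel_prob:
            cls = "parasite" if ag.is_parasite else "replicase"
            records.append(
                (
                    f"agent_{ag.id}",
                    ag.sequence,
                    f"{cls} l={ag.l:.4f} a={ag.a:.6f} b={ag.b:.6f}",
                )
            )
    write_fasta(records, path)
    return len(records)


def run_scenario(
    spec: ScenarioSpec,
    params: Optional[SimulationParams] = None,
    seed: Optional[int] = None,
    max_steps: Optional[int] = None,
    stability_window: Optional[int] = None,
) -> tuple[Simulation, pd.DataFrame]:
    """Build and run one scenario; returns the simulation and trajectory."""
    rng = np.random.default_rng(seed)
    resolved, sequences = build_scenario(spec, params, rng)
    sim = Simulation(resolved, sequences, seed=seed)
    stats = sim.run(max_steps=max_steps, stability_window=stability_window)
    return sim, stats


def sweep(
    spec: ScenarioSpec,
    params: Optional[SimulationParams] = None,
    seed: int = 0,
    max_steps: int = 3000,
) -> pd.DataFrame:
    """Run the scenario once per sweep value per replicate seed.

    Each row reports the final population size and the class means at the
    end of the run; extinct runs report population 0 and missing means.
    """
    if spec.sweep_var not in ("d", "D"):
        raise ValueError("sweep variable must be 'd' or 'D'")
    rows = []
    for vi, value in enumerate(spec.sweep_values):
        for rep in range(spec.replicates):
            run_seed = seed + 1000 * rep + 97 * vi
            base = (params or SimulationParams()).with_overrides(
                **{spec.sweep_var: float(value)}
            )
            sim, stats = run_scenario(
                spec, base, seed=run_seed, max_steps=max_steps
            )
            final = stats.iloc[-1]
            rows.append(
                {
                    spec.sweep_var: value,
                    "seed": run_seed,
                    "steps_run": int(final["step"]),
                    "population": int(
                        final["n_replicases"] + final["n_parasites"]
                    ),
                    "mean_a_replicases": final["mean_a_replicases"],
                    "mean_l_replicases": final["mean_l_replicases"],
                    "mean_l_parasites": final["mean_l_parasites"],
                }
            )
    return pd.DataFrame(rows)
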