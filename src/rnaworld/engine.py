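"""Agent lifecycle and the two-phase simulation main loop.

Each step executes two phases:

1. **Decay / diffusion** — agents are visited once in a fresh random order.
   A complexed enzyme decrements its complex's replication countdown; at
   zero the template is copied (with mutation), the offspring appears at
   the template's position with parameters derived from its own sequence,
   and the complex dissociates. Free agents age by one step (removal at
   lifetime zero) and otherwise take a Brownian step. Complexed agents
   neither age nor move.
2. **Interactions** — free agents are visited in a fresh random order.
   A focal agent with more than ``neigh`` neighbours within the interaction
   radius is removed (crowding); otherwise it scans its neighbours in
   random order and binds the first template with probability
   ``a_E * l_E * (1 - l_T)`` per candidate.

Decay waiting times are drawn once (exponential, rate = the agent's decay
rate ``b``) and counted down in steps, instead of re-testing a hazard each
step. The state lives in flat numpy arrays and both phases run as numba
kernels (:mod:`rnaworld._kernels`); each simulation owns its kernel RNG
state, so whole trajectories replay bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import _kernels
from .folding import FoldingOptions, folded_fraction, pair_matrix, predict_structure
from .sequences import (
    HydrolysisTable,
    ReplicaseMotif,
    decay_rate,
    decode,
    encode,
    replicase_efficiency,
    replication_rate,
    validate_sequence,
)

#: Columns of the per-step trajectory record.
STATS_COLUMNS = [
    "step",
    "n_replicases",
    "n_parasites",
    "n_complexes",
    "mean_a_replicases",
    "mean_l_replicases",
    "mean_l_parasites",
    "births",
    "deaths",
    "crowding_removals",
]


@dataclass(frozen=True)
class SimulationParams:
    """Global simulation constants.

    Defaults follow the standard parameterisation of the model: interaction
    radius 3, a 1000x1000 area, 50-nt sequences, base decay rate 0.01 per
    time unit, per-site mutation probability 0.01, step length dt = 0.1,
    diffusion constant 4, instantaneous replication (K = inf), survivor
    sampling probability 0.01 and a crowding cap of 4 neighbours.
    """

    int_radius: float = 3.0
    size_x: float = 1000.0
    size_y: float = 1000.0
    seq_length: int = 50
    d: float = 0.01
    seq_mut: float = 0.01
    dt: float = 0.1
    D: float = 4.0
    K: float = math.inf
    sel_prob: float = 0.01
    init_r: int = 0
    init_p: int = 0
    neigh: int = 4
    crowding_counts_complexed: bool = True
    hydrolysis: HydrolysisTable = field(default_factory=HydrolysisTable.zero)
    folding: FoldingOptions = field(default_factory=FoldingOptions)
    motif: ReplicaseMotif = field(default_factory=ReplicaseMotif)
    max_steps: int = 10_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("int_radius", "size_x", "size_y", "seq_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("d", "D", "K"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("seq_mut", "sel_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be a probability")
        if self.neigh < 0 or self.init_r < 0 or self.init_p < 0:
            raise ValueError("counts must be >= 0")

    # Field aliases used by the configuration file format.
    _ALIASES = {
        "sizeX": "size_x",
        "sizeY": "size_y",
        "selProb": "sel_prob",
        "initR": "init_r",
        "initP": "init_p",
    }

    @classmethod
    def from_dict(cls, mapping: dict) -> "SimulationParams":
        """Build params from a config mapping (camelCase keys accepted)."""
        kwargs = {}
        for key, value in mapping.items():
            key = cls._ALIASES.get(key, key)
            if key == "hydrolysis" and isinstance(value, dict):
                value = HydrolysisTable(value)
            elif key == "folding" and isinstance(value, dict):
                value = FoldingOptions(**value)
            elif key == "motif" and isinstance(value, (str, dict)):
                value = (
                    ReplicaseMotif(bases=value)
                    if isinstance(value, str)
                    else ReplicaseMotif(**value)
                )
            elif key == "K" and isinstance(value, str):
                value = math.inf
            kwargs[key] = value
        return cls(**kwargs)

    def with_overrides(self, **kwargs) -> "SimulationParams":
        return replace(self, **kwargs)


@dataclass
class Agent:
    """A single RNA agent: sequence plus derived behavioural parameters."""

    id: int
    sequence: str
    position: Tuple[float, float]
    l: float
    a: float
    b: float
    lifetime_steps: int
    state: str = "free"  # free | enzyme | template

    @property
    def is_parasite(self) -> bool:
        return self.a == 0.0


def sample_action_steps(
    k: float, dt: float, rng: np.random.Generator
) -> int:
    """Number of steps until a rate-``k`` reaction fires.

    The waiting time ``t = -ln(X) / k`` (X uniform on (0, 1]) is converted
    to a step count ``floor(t / dt) + 1``, which is always >= 1. An
    infinite rate fires on the very next step. A zero rate means "no
    reaction" and must not be scheduled.
    """
    if k <= 0:
        raise ValueError("k must be positive; k = 0 means no reaction")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if math.isinf(k):
        return 1
    x = 1.0 - rng.random()  # uniform on (0, 1]
    t = -math.log(x) / k
    return int(t / dt) + 1


def complex_formation_probability(a_e: float, l_e: float, l_t: float) -> float:
    """Probability that a meeting enzyme/template pair binds.

    The enzyme must be folded to be catalytically active and the template
    unfolded to be copyable, giving ``a_E * l_E * (1 - l_T)``.
    """
    for name, value in (("a_E", a_e), ("l_E", l_e), ("l_T", l_t)):
        if not 0 <= value <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return a_e * l_e * (1.0 - l_t)


def derive_agent_params(
    seq: str, params: SimulationParams
) -> Tuple[float, float, float]:
    """Compute (l, a, b) for a sequence via the library surface."""
    structure = predict_structure(seq, params.folding)
    l = folded_fraction(structure)
    k_r = replication_rate(seq, params.motif)
    a = replicase_efficiency(k_r, params.dt) if k_r > 0 else 0.0
    b = decay_rate(seq, params.d, params.hydrolysis)
    return l, a, b


def make_agent(
    seq: str,
    pos: Tuple[float, float],
    params: SimulationParams,
    rng: np.random.Generator,
    agent_id: int = 0,
) -> Agent:
    """Build a free agent with parameters derived from its sequence."""
    validate_sequence(seq)
    if len(seq) != params.seq_length:
        raise ValueError(
            f"sequence length {len(seq)} != seq_length {params.seq_length}"
        )
    l, a, b = derive_agent_params(seq, params)
    lifetime = (
        sample_action_steps(b, params.dt, rng) if b > 0 else np.iinfo(np.int64).max
    )
    return Agent(
        id=agent_id,
        sequence=seq,
        position=pos,
        l=l,
        a=a,
        b=b,
        lifetime_steps=int(lifetime),
    )


class Simulation:
    """Struct-of-arrays population driven by the two jitted phase kernels.

    A fixed ``seed`` makes the whole trajectory deterministic: the kernel
    RNG stream (all in-loop draws, in documented phase order) and the
    Python-side generator (initial lifetimes) are both derived from it.
    """

    def __init__(
        self,
        params: SimulationParams,
        sequences: Sequence[str],
        positions: Optional[Sequence[Tuple[float, float]]] = None,
        seed: Optional[int] = None,
    ) -> None:
        if params.folding.backend != "builtin":
            raise NotImplementedError(
                "the simulation loop folds offspring with the builtin "
                "max-pairing predictor; external backends are available "
                "through folding.predict_structure / engine.make_agent"
            )
        self.params = params
        ss = np.random.SeedSequence(seed)
        kernel_seed, py_seed = ss.spawn(2)
        self.rng = np.random.default_rng(py_seed)
        # per-instance kernel PRNG state: concurrent simulations never
        # share a stream, so replay is bit-exact per seed
        self._rstate = _kernels.seed_state(kernel_seed)

        n0 = len(sequences)
        if positions is None:
            positions = [
                (
                    self.rng.random() * params.size_x,
                    self.rng.random() * params.size_y,
                )
                for _ in range(n0)
            ]
        if len(positions) != n0:
            raise ValueError("sequences and positions length mismatch")

        cap = max(2 * n0 + 1024, 4096)
        L = params.seq_length
        self._seqs = np.zeros((cap, L), dtype=np.uint8)
        self._x = np.zeros(cap)
        self._y = np.zeros(cap)
        self._l = np.zeros(cap)
        self._a = np.zeros(cap)
        self._b = np.zeros(cap)
        self._lifetime = np.zeros(cap, dtype=np.int64)
        self._rep_steps = np.zeros(cap, dtype=np.int64)
        self._state = np.zeros(cap, dtype=np.uint8)
        self._partner = np.full(cap, -1, dtype=np.int64)
        self._alive = np.zeros(cap, dtype=np.bool_)
        # stack sized to the full capacity: every slot may become free
        self._free_slots = np.zeros(cap, dtype=np.int64)
        self._free_slots[: cap - n0] = np.arange(
            cap - 1, n0 - 1, -1, dtype=np.int64
        )
        self._counters = np.zeros(4, dtype=np.int64)
        self._counters[_kernels.FREE_TOP] = cap - n0

        self._pairable = pair_matrix(params.folding.allow_wobble)
        self._hyd = params.hydrolysis.to_matrix()
        self._motif_codes = params.motif.codes
        # sequence-keyed memo cache for (l, a, b); purely an optimisation
        self._cache_keys = np.zeros(
            (_kernels.PARAM_CACHE_SLOTS, L), dtype=np.uint8
        )
        self._cache_vals = np.zeros((_kernels.PARAM_CACHE_SLOTS, 3))
        self._cache_used = np.zeros(_kernels.PARAM_CACHE_SLOTS, dtype=np.uint8)

        for i, (seq, pos) in enumerate(zip(sequences, positions)):
            validate_sequence(seq)
            if len(seq) != L:
                raise ValueError(
                    f"sequence {i} has length {len(seq)}, expected {L}"
                )
            self._seqs[i] = encode(seq)
            self._x[i], self._y[i] = pos
            self._alive[i] = True
        _kernels.derive_params_batch(
            self._seqs,
            n0,
            self._l,
            self._a,
            self._b,
            self._motif_codes,
            params.motif.match_threshold,
            params.motif.rate_per_match,
            params.dt,
            params.d,
            self._hyd,
            params.folding.min_loop,
            self._pairable,
        )
        for i in range(n0):
            bb = self._b[i]
            self._lifetime[i] = (
                sample_action_steps(bb, params.dt, self.rng)
                if bb > 0
                else np.iinfo(np.int64).max
            )

        self.step_count = 0
        self._stats_rows: list[tuple] = []
        self._record()

    # -- capacity -----------------------------------------------------------

    @property
    def capacity(self) -> int:
        return self._alive.size

    def _grow(self, extra: int) -> None:
        old = self.capacity
        new = old + max(extra, old // 2)
        pad = new - old

        def ext(arr, fill=0):
            return np.concatenate(
                [arr, np.full(pad, fill, dtype=arr.dtype)]
            )

        self._seqs = np.vstack(
            [self._seqs, np.zeros((pad, self._seqs.shape[1]), dtype=np.uint8)]
        )
        self._x = ext(self._x)
        self._y = ext(self._y)
        self._l = ext(self._l)
        self._a = ext(self._a)
        self._b = ext(self._b)
        self._lifetime = ext(self._lifetime)
        self._rep_steps = ext(self._rep_steps)
        self._state = ext(self._state)
        self._partner = ext(self._partner, fill=-1)
        self._alive = ext(self._alive, fill=False)
        free = np.concatenate(
            [
                self._free_slots,
                np.zeros(pad, dtype=np.int64),
            ]
        )
        top = self._counters[_kernels.FREE_TOP]
        free[top : top + pad] = np.arange(new - 1, old - 1, -1, dtype=np.int64)
        self._free_slots = free
        self._counters[_kernels.FREE_TOP] = top + pad

    # -- phases -------------------------------------------------------------

    def decay_diffusion_phase(self) -> None:
        """Phase 1: replication countdowns, aging/removal, diffusion."""
        p = self.params
        n_enzymes = int(
            np.count_nonzero(self._alive & (self._state == 1))
        )
        if self._counters[_kernels.FREE_TOP] < n_enzymes + 64:
            self._grow(n_enzymes + 1024)
        _kernels.decay_diffusion_phase(
            self._seqs,
            self._x,
            self._y,
            self._l,
            self._a,
            self._b,
            self._lifetime,
            self._rep_steps,
            self._state,
            self._partner,
            self._alive,
            self._free_slots,
            self._counters,
            p.size_x,
            p.size_y,
            p.dt,
            p.D,
            p.seq_mut,
            p.d,
            self._hyd,
            self._motif_codes,
            p.motif.match_threshold,
            p.motif.rate_per_match,
            p.folding.min_loop,
            self._pairable,
            self._cache_keys,
            self._cache_vals,
            self._cache_used,
            self._rstate,
        )

    def interactions_phase(self) -> None:
        """Phase 2: crowding removal and complex formation."""
        p = self.params
        _kernels.interactions_phase(
            self._x,
            self._y,
            self._l,
            self._a,
            self._rep_steps,
            self._state,
            self._partner,
            self._alive,
            self._free_slots,
            self._counters,
            p.size_x,
            p.size_y,
            p.int_radius,
            p.neigh,
            p.K,
            p.dt,
            p.crowding_counts_complexed,
            self._rstate,
        )

    def step(self) -> None:
        """Advance one full step (decay/diffusion, then interactions)."""
        self._counters[_kernels.BIRTHS] = 0
        self._counters[_kernels.DEATHS] = 0
        self._counters[_kernels.CROWDED] = 0
        self.decay_diffusion_phase()
        self.interactions_phase()
        self.step_count += 1
        self._record()

    def run(
        self,
        max_steps: Optional[int] = None,
        stop_on_extinction: bool = True,
        stability_window: Optional[int] = None,
        stability_cv: float = 0.01,
    ) -> pd.DataFrame:
        """Run until ``max_steps``, extinction, or (optionally) stability.

        Stability is declared when the coefficient of variation of the
        total population over the trailing ``stability_window`` steps drops
        below ``stability_cv``.
        """
        if max_steps is None:
            max_steps = self.params.max_steps
        history: list[int] = []
        for _ in range(max_steps):
            if stop_on_extinction and self.n_alive == 0:
                break
            self.step()
            if stability_window:
                history.append(self.n_alive)
                if len(history) >= stability_window:
                    tail = np.asarray(history[-stability_window:], dtype=float)
                    mean = tail.mean()
                    if mean > 0 and tail.std() / mean < stability_cv:
                        break
        return self.stats()

    # -- observation --------------------------------------------------------

    @property
    def n_alive(self) -> int:
        return int(np.count_nonzero(self._alive))

    @property
    def n_complexes(self) -> int:
        return int(np.count_nonzero(self._alive & (self._state == 1)))

    def _record(self) -> None:
        alive = self._alive
        repl = alive & (self._a > 0)
        para = alive & (self._a == 0)
        n_r = int(np.count_nonzero(repl))
        n_p = int(np.count_nonzero(para))
        self._stats_rows.append(
            (
                self.step_count,
                n_r,
                n_p,
                self.n_complexes,
                float(self._a[repl].mean()) if n_r else np.nan,
                float(self._l[repl].mean()) if n_r else np.nan,
                float(self._l[para].mean()) if n_p else np.nan,
                int(self._counters[_kernels.BIRTHS]),
                int(self._counters[_kernels.DEATHS]),
                int(self._counters[_kernels.CROWDED]),
            )
        )

    def stats(self) -> pd.DataFrame:
        """Per-step trajectory statistics (row 0 is the initial state)."""
        return pd.DataFrame(self._stats_rows, columns=STATS_COLUMNS)

    def positions_table(self) -> pd.DataFrame:
        """Current agent positions: step, agent id, x, y and class."""
        idx = np.flatnonzero(self._alive)
        cls = np.where(self._a[idx] > 0, "replicase", "parasite")
        return pd.DataFrame(
            {
                "step": self.step_count,
                "agent_id": idx,
                "x": self._x[idx],
                "y": self._y[idx],
                "class": cls,
            }
        )

    def agents(self) -> list[Agent]:
        """Snapshot the living population as :class:`Agent` objects."""
        out = []
        state_names = {0: "free", 1: "enzyme", 2: "template"}
        for i in np.flatnonzero(self._alive):
            out.append(
                Agent(
                    id=int(i),
                    sequence=decode(self._seqs[i]),
                    position=(float(self._x[i]), float(self._y[i])),
                    l=float(self._l[i]),
                    a=float(self._a[i]),
                    b=float(self._b[i]),
                    lifetime_steps=int(self._lifetime[i]),
                    state=state_names[int(self._state[i])],
                )
            )
        return out
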