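"""Agent lifecycle, waiting times, complexes and whole-trajectory behaviour."""

import math

import numpy as np
import pandas as pd
import pytest

from rnaworld.engine import (
    Agent,
    Simulation,
    SimulationParams,
    complex_formation_probability,
    derive_agent_params,
    make_agent,
    sample_action_steps,
)
from rnaworld.sequences import (
    HydrolysisTable,
    build_ideal_replicase,
    random_sequence,
)


class _FixedUniform:
    """Stub generator returning a prescribed uniform draw."""

    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestSampleActionSteps:
    def test_zero_waiting_time_gives_one_step(self):
        # X -> 1 gives t = 0, mapped to a single step
        assert sample_action_steps(1.0, 0.1, _FixedUniform(0.0)) == 1

    def test_worked_example(self):
        # X = e^-1, k = 0.01 -> t = 100 time units -> 1001 steps
        stub = _FixedUniform(1.0 - math.exp(-1.0))
        assert sample_action_steps(0.01, 0.1, stub) == 1001

    def test_always_at_least_one_step(self, rng):
        assert all(
            sample_action_steps(50.0, 0.1, rng) >= 1 for _ in range(1000)
        )

    def test_infinite_rate_fires_next_step(self, rng):
        assert sample_action_steps(math.inf, 0.1, rng) == 1

    def test_zero_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_action_steps(0.0, 0.1, rng)

    def test_empirical_mean_matches_exponential(self, rng):
        # mean waiting time in time units is 1/k
        k, dt, n = 2.0, 0.001, 1_000_000
        draws = np.array(
            [sample_action_steps(k, dt, rng) for _ in range(n)], dtype=float
        )
        mean_t = (draws * dt).mean()
        se = (1 / k) / math.sqrt(n)
        # step discretisation adds at most dt of upward bias
        assert abs(mean_t - 1 / k) < 3 * se + dt


class TestComplexFormationProbability:
    @pytest.mark.parametrize(
        "a_e,l_e,l_t,expected",
        [
            (1.0, 1.0, 0.0, 1.0),
            (0.5, 0.5, 1.0, 0.0),
            (0.999, 0.76, 0.12, 0.999 * 0.76 * 0.88),
            (0.0, 1.0, 0.0, 0.0),
        ],
    )
    def test_examples(self, a_e, l_e, l_t, expected):
        assert complex_formation_probability(a_e, l_e, l_t) == pytest.approx(
            expected
        )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            complex_formation_probability(1.5, 0.5, 0.5)


class TestMakeAgent:
    def test_ideal_replicase_parameters(self, rng):
        params = SimulationParams()
        seq = build_ideal_replicase(params.motif, 50, rng)
        agent = make_agent(seq, (1.0, 2.0), params, rng)
        assert agent.a == pytest.approx(1.0 - math.exp(-20.0))
        assert not agent.is_parasite
        assert agent.b == params.d  # empty hydrolysis table
        assert agent.lifetime_steps >= 1

    def test_motif_free_sequence_is_parasite(self, rng):
        params = SimulationParams()
        agent = make_agent("G" * 50, (0.0, 0.0), params, rng)
        assert agent.a == 0.0
        assert agent.is_parasite

    def test_wrong_length_rejected(self, rng):
        with pytest.raises(ValueError):
            make_agent("ACGU", (0, 0), SimulationParams(), rng)


def _ideal_population(n, params, seed):
    rng = np.random.default_rng(seed)
    return [build_ideal_replicase(params.motif, 50, rng) for _ in range(n)]


class TestSimulation:
    def test_empty_population_is_immediately_extinct(self):
        sim = Simulation(SimulationParams(size_x=50, size_y=50), [], seed=0)
        stats = sim.run(max_steps=100)
        assert len(stats) == 1
        assert sim.n_alive == 0

    def test_no_mutation_population_grows_to_crowding_limit(self):
        params = SimulationParams(size_x=60, size_y=60, seq_mut=0.0, d=1e-4)
        sims = Simulation(params, _ideal_population(100, params, 1), seed=1)
        stats = sims.run(max_steps=300)
        assert stats["n_parasites"].eq(0).all()  # no mutation, no parasites
        final = stats["n_replicases"].iloc[-1]
        assert final > 200  # grew
        # crowding keeps density near the cap: well below one agent per
        # interaction disc * (neigh + 1)
        assert final < 60 * 60

    def test_same_seed_is_bit_identical(self):
        params = SimulationParams(size_x=80, size_y=80)
        a = Simulation(params, _ideal_population(200, params, 3), seed=9)
        b = Simulation(params, _ideal_population(200, params, 3), seed=9)
        pd.testing.assert_frame_equal(
            a.run(max_steps=120), b.run(max_steps=120)
        )

    def test_different_seeds_diverge(self):
        params = SimulationParams(size_x=80, size_y=80)
        a = Simulation(params, _ideal_population(200, params, 3), seed=1)
        b = Simulation(params, _ideal_population(200, params, 3), seed=2)
        assert not a.run(max_steps=60).equals(b.run(max_steps=60))

    def test_population_bookkeeping_conserved(self):
        params = SimulationParams(size_x=80, size_y=80)
        sim = Simulation(params, _ideal_population(300, params, 5), seed=5)
        stats = sim.run(max_steps=200)
        total = stats["n_replicases"] + stats["n_parasites"]
        delta = total.diff().iloc[1:]
        balance = (
            stats["births"] - stats["deaths"] - stats["crowding_removals"]
        ).iloc[1:]
        assert (delta == balance).all()

    def test_offspring_parameters_recomputable_from_sequence(self):
        # dual route: kernel-derived (l, a, b) must equal the Python
        # module surface recomputation for every living agent
        params = SimulationParams(size_x=60, size_y=60)
        sim = Simulation(params, _ideal_population(150, params, 7), seed=7)
        sim.run(max_steps=150)
        agents = sim.agents()
        assert any(ag.state != "free" for ag in agents) or len(agents) > 0
        for ag in agents[::5]:
            l, a, b = derive_agent_params(ag.sequence, params)
            assert ag.l == pytest.approx(l, abs=1e-12)
            assert ag.a == pytest.approx(a, abs=1e-12)
            assert ag.b == pytest.approx(b, abs=1e-12)

    def test_no_agent_in_two_complexes(self):
        params = SimulationParams(size_x=60, size_y=60)
        sim = Simulation(params, _ideal_population(200, params, 11), seed=11)
        for _ in range(30):
            sim.step()
            partner = sim._partner
            state = sim._state
            alive = sim._alive
            enzymes = np.flatnonzero(alive & (state == 1))
            templates = np.flatnonzero(alive & (state == 2))
            assert len(enzymes) == len(templates)
            # partnerships are a perfect matching
            assert sorted(partner[enzymes]) == sorted(templates)
            for e in enzymes:
                assert partner[partner[e]] == e

    def test_complex_produces_offspring_at_template_position(self):
        # two adjacent ideal replicases, no diffusion, no mutation:
        # a complex forms and one step later an identical offspring
        # appears at the template's exact position
        params = SimulationParams(
            size_x=50, size_y=50, D=0.0, seq_mut=0.0, d=1e-6
        )
        seqs = _ideal_population(2, params, 13)
        sim = Simulation(
            params, seqs, positions=[(10.0, 10.0), (11.0, 10.0)], seed=13
        )
        for _ in range(50):
            sim.step()
            if sim.n_alive > 2:
                break
        agents = sim.agents()
        assert len(agents) >= 3
        positions = [ag.position for ag in agents]
        assert len(set(positions)) < len(positions)  # duplicated position
        sequences = {ag.sequence for ag in agents}
        assert sequences <= set(seqs)  # offspring identical without mutation

    def test_complexed_agents_do_not_move_or_age(self):
        params = SimulationParams(size_x=50, size_y=50, D=4.0, seq_mut=0.0)
        seqs = _ideal_population(2, params, 17)
        sim = Simulation(
            params, seqs, positions=[(10.0, 10.0), (11.0, 10.0)], seed=17
        )
        # find a step where a complex exists, then verify positions frozen
        for _ in range(100):
            before = {
                int(i): (float(sim._x[i]), float(sim._y[i]), int(sim._lifetime[i]))
                for i in np.flatnonzero(sim._alive & (sim._state > 0))
            }
            sim.decay_diffusion_phase()
            if before:
                moved = False
                for i, (x, y, lt) in before.items():
                    if sim._state[i] > 0:  # still complexed
                        assert (float(sim._x[i]), float(sim._y[i])) == (x, y)
                        assert int(sim._lifetime[i]) == lt
                        moved = True
                if moved:
                    break
            sim.interactions_phase()

    def test_capacity_growth_preserves_bookkeeping(self):
        params = SimulationParams(size_x=200, size_y=200, seq_mut=0.0, d=1e-4)
        sim = Simulation(params, _ideal_population(400, params, 19), seed=19)
        cap0 = sim.capacity
        stats = sim.run(max_steps=400)
        assert sim.capacity > cap0  # growth happened
        total = stats["n_replicases"] + stats["n_parasites"]
        delta = total.diff().iloc[1:]
        balance = (
            stats["births"] - stats["deaths"] - stats["crowding_removals"]
        ).iloc[1:]
        assert (delta == balance).all()

    def test_external_backend_not_supported_in_loop(self):
        from rnaworld.folding import FoldingOptions

        params = SimulationParams(
            folding=FoldingOptions(backend=lambda s: "." * len(s))
        )
        with pytest.raises(NotImplementedError):
            Simulation(params, [], seed=0)


class TestSimulationParams:
    def test_table_aliases_accepted(self):
        params = SimulationParams.from_dict(
            {"sizeX": 300, "sizeY": 300, "initR": 10, "selProb": 0.5, "K": "inf"}
        )
        assert params.size_x == 300
        assert params.init_r == 10
        assert params.sel_prob == 0.5
        assert math.isinf(params.K)

    def test_validation(self):
        with pytest.raises(ValueError):
            SimulationParams(dt=0.0)
        with pytest.raises(ValueError):
            SimulationParams(seq_mut=1.5)

    def test_hydrolysis_from_mapping(self):
        params = SimulationParams.from_dict({"hydrolysis": {"UA": 0.1}})
        assert isinstance(params.hydrolysis, HydrolysisTable)
        assert params.hydrolysis.rate("UA") == 0.1
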