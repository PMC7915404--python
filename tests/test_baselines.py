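"""Classic SEIR and classic J-A baselines."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy import stats

from seirja.baselines import (
    ClassicSeirParams,
    classic_seir_step,
    run_classic_ja,
    run_classic_seir,
)
from seirja.heterogeneity import State
from seirja.networks import OpinionNetwork, generate_ba

S, E, I, R = (int(State.UNINFORMED), int(State.SILENT),
              int(State.COMMUNICATION), int(State.IMMUNE))


def enumerate_one_step(state, neighbors, a, diss, imm):
    """Independent oracle: exact next-state distribution by exhaustive
    enumeration over contact choices and Bernoulli outcomes."""
    spreaders = [i for i, s in enumerate(state) if s == I]
    silents = [i for i, s in enumerate(state) if s == E]
    dist: dict[tuple, float] = {}
    choice_sets = [neighbors[i] for i in spreaders]
    for choices in itertools.product(*choice_sets):
        p_choice = np.prod([1.0 / len(c) for c in choice_sets]) if choice_sets else 1.0
        contacted = {}
        for j in choices:
            if state[j] == S:
                contacted[j] = contacted.get(j, 0) + 1
        targets = sorted(contacted)
        for converted in itertools.product([0, 1], repeat=len(targets)):
            p_conv = 1.0
            for j, c in zip(targets, converted):
                p_hit = 1.0 - (1.0 - a) ** contacted[j]
                p_conv *= p_hit if c else 1.0 - p_hit
            for e_out in itertools.product([0, 1], repeat=len(silents)):
                p_e = np.prod([diss if o else 1 - diss for o in e_out]) if silents else 1.0
                for i_out in itertools.product([0, 1], repeat=len(spreaders)):
                    p_i = np.prod([imm if o else 1 - imm for o in i_out]) if spreaders else 1.0
                    new = list(state)
                    for j, c in zip(targets, converted):
                        if c:
                            new[j] = E
                    for i, o in zip(silents, e_out):
                        if o:
                            new[i] = I
                    for i, o in zip(spreaders, i_out):
                        if o:
                            new[i] = R
                    key = tuple(new)
                    dist[key] = dist.get(key, 0.0) + p_choice * p_conv * p_e * p_i
    return dist


class TestClassicSeirStep:
    def test_one_step_distribution_matches_enumeration(self):
        """Chi-squared agreement between 10^4 sampled steps and the exact
        enumeration on a 5-node path."""
        net = OpinionNetwork(nx.path_graph(5))
        state = np.array([S, I, S, E, S], dtype=np.int8)
        a, diss, imm = 0.7, 0.3, 0.2
        params = ClassicSeirParams(acceptance_coef=a, dissemination_coef=diss,
                                   immune_coef=imm)
        exact = enumerate_one_step(list(state), [list(n) for n in net.neighbors],
                                   a, diss, imm)
        assert sum(exact.values()) == pytest.approx(1.0)

        rng = np.random.default_rng(777)
        n_samples = 10_000
        observed: dict[tuple, int] = {}
        for _ in range(n_samples):
            new = classic_seir_step(state, net.neighbors, params, rng)
            key = tuple(int(v) for v in new)
            observed[key] = observed.get(key, 0) + 1
        assert set(observed) <= set(exact)
        keys = sorted(exact)
        f_obs = np.array([observed.get(k, 0) for k in keys], dtype=float)
        f_exp = np.array([exact[k] * n_samples for k in keys])
        _, pval = stats.chisquare(f_obs, f_exp)
        assert pval > 1e-3

    def test_immediate_immunity_freezes_epidemic(self):
        params = ClassicSeirParams(dissemination_coef=0.0, immune_coef=1.0,
                                   init_comm_frac=0.1, N=50, ba_m_attach=5,
                                   max_steps=30)
        res = run_classic_seir(params, seed=0)
        assert res.counts[1, I] == 0                  # all spreaders gone
        assert np.all(res.counts[1:, I] == 0)
        # with zero dissemination the silent pool is frozen forever
        assert np.all(res.counts[1:, E] == res.counts[1, E])

    def test_zero_acceptance_keeps_S_constant(self):
        params = ClassicSeirParams(acceptance_coef=0.0, init_comm_frac=0.1,
                                   N=50, ba_m_attach=5, max_steps=30)
        res = run_classic_seir(params, seed=1)
        assert np.all(res.counts[:, S] == res.counts[0, S])

    def test_conservation_and_monotonicity(self):
        res = run_classic_seir(ClassicSeirParams(N=100, ba_m_attach=8,
                                                 max_steps=60), seed=4)
        assert np.all(res.counts.sum(axis=1) == 100)
        assert np.all(np.diff(res.counts[:, S]) <= 0)
        assert np.all(np.diff(res.counts[:, R]) >= 0)


class TestClassicJA:
    def test_identical_attitudes_converge_immediately(self):
        net = generate_ba(40, 4, seed=0)
        res = run_classic_ja(net, attitude_mean=0.3, attitude_sd=0.0, seed=1)
        assert res.termination == "converged"
        assert np.allclose(res.polarizability, res.polarizability[0])

    def test_opposed_pair_driven_to_extremes(self):
        # +/-0.9 straddles the rejection threshold; one encounter clips both
        from seirja.ja_core import classic_ja_interact
        out = classic_ja_interact(-0.9, 0.9, 0.5, 0.3, 0.7)
        assert (out.x_i_new, out.x_j_new) == (-1.0, 1.0)

    def test_population_mean_conserved_without_rejection_or_clipping(self):
        # universal assimilation (d1 >= 2), attitudes off the walls
        net = generate_ba(60, 5, seed=2)
        res = run_classic_ja(net, d1=2.0, d2=3.0, mu=0.5, attitude_mean=0.1,
                             attitude_sd=0.2, seed=3, max_steps=20)
        assert res.mean_attitude[-1] == pytest.approx(res.mean_attitude[0],
                                                      abs=1e-9)

    def test_deterministic_under_seed(self):
        net = generate_ba(40, 4, seed=5)
        a = run_classic_ja(net, seed=6, max_steps=10)
        b = run_classic_ja(net, seed=6, max_steps=10)
        assert np.array_equal(a.final_x, b.final_x)
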