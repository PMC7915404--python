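"""Coupled simulation loop: initialization, stepping, invariants, ensembles."""

import numpy as np
import pytest

from seirja.engine import EnsembleResult, initialize, run, run_ensemble, step
from seirja.heterogeneity import ModelParams, State

S, E, I, R = (int(State.UNINFORMED), int(State.SILENT),
              int(State.COMMUNICATION), int(State.IMMUNE))

SMALL = ModelParams(N=60, ba_m_attach=5, max_steps=60)

# transitions the state machine allows: S->E, S->I, E->I, I->E, E->R, I->R
ALLOWED = {(S, E), (S, I), (E, I), (I, E), (E, R), (I, R)}


class TestInitialize:
    def test_communicator_count(self):
        st = initialize(ModelParams(N=300, init_comm_frac=0.1), seed=0)
        counts = st.counts()
        assert counts[I] == 30 and counts[S] == 270
        assert counts.sum() == 300

    def test_seed_communicator_state(self):
        st = initialize(SMALL, seed=1)
        seeds = st.state == I
        assert np.all(st.z[seeds] == 1)
        assert np.all(st.m[seeds] == 1.0)
        assert np.all(st.w_plus[seeds] == 0.5)
        assert np.all(np.abs(st.x[seeds]) <= 1.0)
        # willingness at baseline recognition reduces to |x|
        assert np.allclose(st.P[seeds], np.abs(st.x[seeds]))

    def test_no_communicators_terminates_immediately(self):
        res = run(ModelParams(N=60, ba_m_attach=5, init_comm_frac=0.0), seed=0)
        assert res.termination == "converged"
        assert np.all(res.counts[:, S] == 60)

    def test_fixed_seed_identical_state(self):
        a = initialize(SMALL, seed=5)
        b = initialize(SMALL, seed=5)
        assert np.array_equal(a.state, b.state)
        assert np.array_equal(a.x, b.x)
        assert set(a.net.graph.edges()) == set(b.net.graph.edges())


class TestStepInvariants:
    def test_trajectory_invariants(self):
        """Conservation, monotonicity, ranges and the transition whitelist,
        asserted at every step of a full trajectory."""
        st = initialize(SMALL, seed=3)
        prev_state = st.state.copy()
        prev_counts = st.counts()
        for _ in range(60):
            step(st)
            counts = st.counts()
            assert counts.sum() == SMALL.N
            assert counts[S] <= prev_counts[S]          # S never refills
            assert counts[R] >= prev_counts[R]          # R is absorbing
            assert np.all(np.abs(st.x) <= 1.0)
            assert np.all((0.0 <= st.w_plus) & (st.w_plus <= 1.0))
            informed = st.state != S
            assert np.all(st.z[informed] >= 1)
            changed = np.flatnonzero(st.state != prev_state)
            for i in changed:
                assert (int(prev_state[i]), int(st.state[i])) in ALLOWED
            prev_state = st.state.copy()
            prev_counts = counts

    def test_no_communicators_step_is_inert(self):
        st = initialize(ModelParams(N=20, ba_m_attach=3, init_comm_frac=0.0),
                        seed=0)
        before = st.state.copy()
        step(st)
        assert np.array_equal(st.state, before)
        assert st.t == 1

    def test_forgetting_with_z0_one(self):
        """With an attention span of one step every informed agent is immune
        within two steps of receipt."""
        params = ModelParams(N=60, ba_m_attach=5, z0=1, max_steps=10,
                             stop_tol=0.0)
        st = initialize(params, seed=2)
        receipt = {int(i): 0 for i in np.flatnonzero(st.state != S)}
        for t in range(1, 11):
            step(st, params)
            for i in np.flatnonzero(st.state != S):
                receipt.setdefault(int(i), t)
            for i, t0 in receipt.items():
                if t - t0 >= 2:
                    assert st.state[i] == R

    def test_frozen_conformity_freezes_attitudes(self):
        # gamma = 0: conformity never leaves 0, so mu = 0 and an attitude
        # never moves after its initial draw; the run still halts once
        # spreading (which feeds the stop-condition sum) dies down
        params = ModelParams(N=60, ba_m_attach=5, gamma=0.0, max_steps=100)
        st = initialize(params, seed=4)
        x_prev, informed_prev = st.x.copy(), st.state != S
        for _ in range(30):
            step(st)
            assert np.array_equal(st.x[informed_prev], x_prev[informed_prev])
            x_prev, informed_prev = st.x.copy(), st.state != S
        res = run(params, seed=4)
        assert res.termination == "converged"


class TestRun:
    def test_deterministic_under_seed(self):
        a = run(SMALL, seed=11)
        b = run(SMALL, seed=11)
        assert np.array_equal(a.counts, b.counts)
        assert np.array_equal(a.final_x, b.final_x)

    def test_zero_horizon_keeps_initial_snapshot(self):
        res = run(SMALL.replace(max_steps=0), seed=0)
        assert res.n_steps == 0
        assert res.counts.shape == (1, 4)

    def test_series_lengths_agree(self):
        res = run(SMALL, seed=7)
        L = res.n_steps + 1
        assert res.counts.shape == (L, 4)
        assert len(res.polarizability) == L
        assert len(res.communicators) == L


class TestEnsemble:
    def test_single_run_mean_is_the_run(self):
        ens = run_ensemble(SMALL, n_runs=1, base_seed=9)
        assert np.array_equal(ens.mean_polarizability(),
                              ens.runs[0].polarizability)
        assert ens.average_rsd() == 0.0

    def test_identical_runs_zero_rsd(self):
        r = run(SMALL, seed=13)
        ens = EnsembleResult(runs=[r, r])
        assert ens.average_rsd() == 0.0

    def test_pointwise_rsd_two_runs(self):
        # {0.4, 0.6}: sample SD 0.1414, mean 0.5 -> 28.28%
        mat = np.array([[0.4], [0.6]])
        ens = EnsembleResult(runs=[])
        assert ens.average_rsd(mat) == pytest.approx(28.2843, abs=1e-3)

    def test_shorter_runs_carried_forward(self):
        ens = run_ensemble(SMALL, n_runs=3, base_seed=21)
        lengths = {r.n_steps for r in ens.runs}
        mat = ens.aligned_polarizability()
        assert mat.shape == (3, max(lengths) + 1)
        shortest = min(ens.runs, key=lambda r: r.n_steps)
        k = ens.runs.index(shortest)
        assert np.all(mat[k, shortest.n_steps:] ==
                      shortest.polarizability[-1])

    def test_deterministic_under_base_seed(self):
        a = run_ensemble(SMALL, n_runs=2, base_seed=33)
        b = run_ensemble(SMALL, n_runs=2, base_seed=33)
        for ra, rb in zip(a.runs, b.runs):
            assert np.array_equal(ra.counts, rb.counts)
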