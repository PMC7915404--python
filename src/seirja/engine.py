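"""The coupled dissemination/polarization simulation loop.

Each step couples two processes on the same network:

* **dissemination** — agents move through four compartments
  (uninformed S, silent E, communication I, immune R) driven by their
  communicating willingness and a forgetting clock;
* **polarization** — every communicating agent holds one bounded-confidence
  encounter with a uniformly random neighbour, with a per-pair
  susceptibility built from embeddedness, conservatism and conformity.

Within a step, encounters happen sequentially in a random order of the
communicators and attitude changes are immediately visible to later
encounters; compartment transitions are applied synchronously at step end.
The run halts when the total squared attitude change of a step falls below
the stop tolerance (uninformed agents carry a baseline attitude of 0, so a
newly informed agent's drawn attitude counts as change), or at
``max_steps``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from . import ja_core
from .heterogeneity import ModelParams, State, conservatism_profile
from .networks import OpinionNetwork, generate_ba, generate_er, generate_ws

__all__ = [
    "SimState",
    "SimulationResult",
    "EnsembleResult",
    "build_network",
    "initialize",
    "step",
    "run",
    "run_ensemble",
]

_S, _E, _I, _R = (int(State.UNINFORMED), int(State.SILENT),
                  int(State.COMMUNICATION), int(State.IMMUNE))


def build_network(params: ModelParams, seed: int | None = None) -> OpinionNetwork:
    """Construct the interaction network named by ``params.network``."""
    if params.network == "ba":
        return generate_ba(params.N, params.ba_m_attach, seed=seed)
    if params.network == "ws":
        return generate_ws(params.N, params.ws_k_ring, params.ws_p_rewire, seed=seed)
    return generate_er(params.N, params.er_p_edge, seed=seed)


@dataclass
class SimState:
    """Mutable simulation state: parallel per-agent arrays plus the network."""

    net: OpinionNetwork
    params: ModelParams
    rng: np.random.Generator
    state: np.ndarray       # int8 compartment codes
    x: np.ndarray           # attitudes; 0 baseline while uninformed
    m: np.ndarray           # external recognition
    z: np.ndarray           # receipt clock; 0 while uninformed
    w_plus: np.ndarray      # mainstream degree of the positive opinion
    P: np.ndarray           # communicating willingness
    T: np.ndarray           # conservatism (static per run)
    emb: dict               # (i, j) -> embeddedness, both orientations
    t: int = 0

    @property
    def informed(self) -> np.ndarray:
        return self.state != _S

    def counts(self) -> np.ndarray:
        return np.bincount(self.state, minlength=4)[:4]

    def agent(self, i: int):
        """A readable :class:`~seirja.heterogeneity.Agent` record for node i."""
        from .heterogeneity import Agent
        informed = self.state[i] != _S
        return Agent(
            id=i, state=State(int(self.state[i])),
            x=float(self.x[i]), m=float(self.m[i]),
            P=float(self.P[i]), z=int(self.z[i]) if informed else None,
            w_plus=float(self.w_plus[i]), w_minus=1.0 - float(self.w_plus[i]),
            T=float(self.T[i]),
        )


@dataclass
class SimulationResult:
    """Per-step time series of one run.

    Index 0 is the initial snapshot; index t the state after step t.
    """

    counts: np.ndarray                 # (T+1, 4) compartment counts S,E,I,R
    polarizability: np.ndarray         # (T+1,) extreme fraction among informed
    mean_attitude: np.ndarray          # (T+1,) mean attitude of informed
    communicators: list[frozenset]     # per-step ids in COMMUNICATION
    final_x: np.ndarray
    final_informed: np.ndarray
    termination: str                   # "converged" | "max_steps"
    params: ModelParams

    @property
    def n_steps(self) -> int:
        return len(self.polarizability) - 1

    def count_series(self, compartment: State | int) -> np.ndarray:
        return self.counts[:, int(compartment)]


def _truncated_normal(rng, mean, sd, size=None):
    return np.clip(rng.normal(mean, sd, size=size), -1.0, 1.0)


def initialize(params: ModelParams, net: OpinionNetwork | None = None,
               seed: int | None = None) -> SimState:
    """Seed the population: a random fraction starts as communicators.

    Initial communicators draw an attitude from the truncated initial
    distribution, start with recognition 1, receipt clock 1 and balanced
    mainstream degrees; everyone else is uninformed.  Conservatism is
    assigned to all nodes from the degree profile.
    """
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    if net is None:
        net = build_network(params, seed=int(rng.integers(0, 2**31 - 1)))
    n = net.n
    n_comm = int(round(params.init_comm_frac * n))
    if n_comm >= n and n > 0:
        raise ValueError("init_comm_frac leaves no uninformed agents")

    state = np.full(n, _S, dtype=np.int8)
    x = np.zeros(n)
    m = np.ones(n)
    z = np.zeros(n, dtype=np.int64)
    w_plus = np.full(n, 0.5)
    P = np.zeros(n)

    seeds = rng.choice(n, size=n_comm, replace=False) if n_comm else np.empty(0, int)
    state[seeds] = _I
    x[seeds] = _truncated_normal(rng, params.attitude_mean, params.attitude_sd, n_comm)
    z[seeds] = 1
    P[seeds] = np.abs(x[seeds])  # willingness at m=1 reduces to |x|

    return SimState(
        net=net, params=params, rng=rng, state=state, x=x, m=m, z=z,
        w_plus=w_plus, P=P, T=conservatism_profile(net, params.T0),
        emb=net.embeddedness_map(), t=0,
    )


def step(st: SimState, params: ModelParams | None = None) -> SimState:
    """Advance the coupled dynamics by one unit of time (in place).

    (a) every agent communicating at step start, in random order, picks one
    uniformly random neighbour; (b) an uninformed partner first forms an
    attitude and converts to communicating or silent by its willingness;
    an immune partner yields no encounter; (c) each encounter updates both
    parties' mainstream degrees from the partner's opinion sign, then the
    attitudes through the bounded-confidence kernel with susceptibilities
    mu = (1+E)(1-T)C±, then recognition by the encounter outcome (the
    broadcasting initiator's by default, both parties' when
    ``recognition_scope="both"``);
    (d) willingness is recomputed for all informed agents and compartment
    transitions are applied synchronously; (e) receipt clocks tick.
    """
    if params is None:
        params = st.params
    rng = st.rng
    state, x, m, z, w_plus, T = st.state, st.x, st.m, st.z, st.w_plus, st.T
    neighbors = st.net.neighbors
    emb = st.emb
    d1, d2, gamma, p = params.d1, params.d2, params.gamma, params.p
    clip = params.clip_ranges
    floor = params.recognition_floor
    both_w = params.both_update_mainstream
    both_m = params.recognition_scope == "both"

    communicators = np.flatnonzero(state == _I)
    order = rng.permutation(communicators)
    for i in order:
        nbrs = neighbors[i]
        if len(nbrs) == 0:
            continue
        j = int(nbrs[rng.integers(len(nbrs))])
        sj = state[j]
        if sj == _R:
            continue
        if sj == _S:
            # first receipt: form an attitude, start the clock, route by
            # willingness at recognition 1 (P = |x|)
            xj = float(_truncated_normal(rng, params.attitude_mean, params.attitude_sd))
            x[j] = xj
            m[j] = 1.0
            z[j] = 1
            w_plus[j] = 0.5
            Pj = abs(xj)
            state[j] = _I if Pj >= p else _E

        xi, xj = x[i], x[j]
        # judgment of the mainstream moves before susceptibility is formed
        step_i = gamma if xj >= 0 else -gamma
        w_plus[i] = min(1.0, max(0.0, w_plus[i] + step_i))
        if both_w:
            step_j = gamma if xi >= 0 else -gamma
            w_plus[j] = min(1.0, max(0.0, w_plus[j] + step_j))

        e = emb[(int(i), j)]
        ci = 2.0 * w_plus[i] - 1.0 if xj >= 0 else 1.0 - 2.0 * w_plus[i]
        cj = 2.0 * w_plus[j] - 1.0 if xi >= 0 else 1.0 - 2.0 * w_plus[j]
        if clip:
            ci = min(1.0, max(0.0, ci))
            cj = min(1.0, max(0.0, cj))
        mu_i = (1.0 + e) * (1.0 - T[i]) * ci
        mu_j = (1.0 + e) * (1.0 - T[j]) * cj
        if clip:
            mu_i = min(1.0, max(0.0, mu_i))
            mu_j = min(1.0, max(0.0, mu_j))

        diff = xi - xj
        if abs(diff) < d1:
            x[i] = min(1.0, max(-1.0, xi - mu_i * diff))
            x[j] = min(1.0, max(-1.0, xj + mu_j * diff))
            m[i] += 1.0
            if both_m:
                m[j] += 1.0
        elif abs(diff) > d2:
            x[i] = min(1.0, max(-1.0, xi + mu_i * diff))
            x[j] = min(1.0, max(-1.0, xj - mu_j * diff))
            m[i] -= 1.0
            if both_m:
                m[j] -= 1.0
        # neutral: attitudes and recognition unchanged
        if floor is not None:
            m[i] = max(floor, m[i])
            m[j] = max(floor, m[j])

    # (d) recompute willingness, then synchronous transitions
    informed = state != _S
    st.P[informed] = (np.abs(x[informed]) - 1.0) * np.exp(1.0 - m[informed]) + 1.0
    active = informed & (state != _R)
    to_immune = active & ((st.P < 0) | (z > params.z0))
    state[to_immune] = _R
    silent = (state == _E) & ~to_immune
    comm = (state == _I) & ~to_immune
    state[silent & (st.P >= p)] = _I
    state[comm & (st.P < p)] = _E

    # (e) the forgetting clock ticks for everyone still engaged
    z[(state == _E) | (state == _I)] += 1
    st.t += 1
    return st


def _polarizability(x: np.ndarray, informed: np.ndarray, threshold: float) -> float:
    k = int(informed.sum())
    if k == 0:
        return 0.0
    return float((np.abs(x[informed]) > threshold).sum() / k)


def _snapshot(st: SimState, counts, polar, meanx, comms) -> None:
    counts.append(st.counts())
    informed = st.informed
    polar.append(_polarizability(st.x, informed, st.params.polar_threshold))
    meanx.append(float(st.x[informed].mean()) if informed.any() else 0.0)
    comms.append(frozenset(np.flatnonzero(st.state == _I).tolist()))


def run(params: ModelParams, net: OpinionNetwork | None = None,
        seed: int | None = None) -> SimulationResult:
    """Run one trajectory to the stop condition or ``max_steps``.

    The stop condition (total squared attitude change of the step at most
    ``stop_tol``) is evaluated from the second step onward, so a run always
    performs at least two steps when ``max_steps`` allows.
    """
    st = initialize(params, net=net, seed=seed)
    counts: list = []
    polar: list = []
    meanx: list = []
    comms: list = []
    _snapshot(st, counts, polar, meanx, comms)
    termination = "max_steps"
    while st.t < params.max_steps:
        x_prev = st.x.copy()
        step(st, params)
        _snapshot(st, counts, polar, meanx, comms)
        if st.t >= 2 and ja_core.converged(x_prev, st.x, params.stop_tol):
            termination = "converged"
            break
    return SimulationResult(
        counts=np.array(counts), polarizability=np.array(polar),
        mean_attitude=np.array(meanx), communicators=comms,
        final_x=st.x.copy(), final_informed=st.informed.copy(),
        termination=termination, params=params,
    )


@dataclass
class EnsembleResult:
    """A bundle of independent runs with pointwise-mean and RSD summaries.

    Shorter runs are carried forward at their final value so series align.
    """

    runs: list[SimulationResult]

    def _aligned(self, extract: Callable[[SimulationResult], np.ndarray]) -> np.ndarray:
        series = [np.asarray(extract(r), dtype=float) for r in self.runs]
        L = max(len(s) for s in series)
        out = np.empty((len(series), L))
        for k, s in enumerate(series):
            out[k, : len(s)] = s
            out[k, len(s):] = s[-1]
        return out

    def aligned_counts(self, compartment: State | int) -> np.ndarray:
        return self._aligned(lambda r: r.count_series(compartment))

    def aligned_polarizability(self) -> np.ndarray:
        return self._aligned(lambda r: r.polarizability)

    def mean_counts(self, compartment: State | int) -> np.ndarray:
        return self.aligned_counts(compartment).mean(axis=0)

    def mean_polarizability(self) -> np.ndarray:
        return self.aligned_polarizability().mean(axis=0)

    def average_rsd(self, matrix: np.ndarray | None = None) -> float:
        """Time-averaged relative standard deviation across runs, percent.

        Per time point: 100 * sample SD / mean; points with zero mean are
        skipped.  Defaults to the polarizability series.
        """
        if matrix is None:
            matrix = self.aligned_polarizability()
        if matrix.shape[0] < 2:
            return 0.0
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=1)
        ok = mean != 0
        if not ok.any():
            return 0.0
        return float(np.mean(100.0 * sd[ok] / mean[ok]))


def run_ensemble(
    params: ModelParams,
    net_factory: Callable[[int], OpinionNetwork] | None = None,
    n_runs: int = 10,
    base_seed: int | None = None,
    fresh_network: bool = True,
) -> EnsembleResult:
    """Monte-Carlo ensemble of independent runs.

    Each run gets its own seed derived from ``base_seed``; by default each
    also gets a freshly generated network (``fresh_network=False`` reuses
    one network across runs).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = np.random.default_rng(base_seed)
    run_seeds = root.integers(0, 2**31 - 1, size=n_runs)
    net_seeds = root.integers(0, 2**31 - 1, size=n_runs)
    if net_factory is None:
        net_factory = lambda s: build_network(params, seed=s)  # noqa: E731
    shared = None if fresh_network else net_factory(int(net_seeds[0]))
    runs = []
    for k in range(n_runs):
        net = net_factory(int(net_seeds[k])) if fresh_network else shared
        runs.append(run(params, net=net, seed=int(run_seeds[k])))
    return EnsembleResult(runs=runs)
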