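"""Comparison baselines: a classic probabilistic SEIR rumor model and the
classic homogeneous Jager-Amblard opinion model.

Both run on the same networks and emit the same :class:`SimulationResult`
type as the coupled engine, so metrics and curve comparisons apply
unchanged.  The classic SEIR replaces the psychological transition
conditions by fixed probabilities (acceptance, dissemination, immunity);
the classic J-A has no compartments at all — every agent holds and trades
opinions from step 0 with one fixed susceptibility.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from . import ja_core
from .engine import SimulationResult, _polarizability, build_network
from .heterogeneity import ModelParams, State
from .networks import OpinionNetwork

__all__ = ["ClassicSeirParams", "classic_seir_step", "run_classic_seir", "run_classic_ja"]

_S, _E, _I, _R = (int(State.UNINFORMED), int(State.SILENT),
                  int(State.COMMUNICATION), int(State.IMMUNE))


@dataclass
class ClassicSeirParams:
    """Fixed-probability SEIR rumor model parameters.

    Defaults follow the common rumor-spreading calibration: every contacted
    uninformed agent accepts the information (acceptance 1), a silent agent
    starts spreading with probability 0.3 per step, a spreader disengages
    with probability 0.2 per step.
    """

    acceptance_coef: float = 1.0
    dissemination_coef: float = 0.3
    immune_coef: float = 0.2
    init_comm_frac: float = 0.1
    N: int = 300
    max_steps: int = 200
    seed: int | None = None
    network: str = "ba"
    ba_m_attach: int = 25
    ws_k_ring: int = 48
    ws_p_rewire: float = 0.1
    er_p_edge: float = 49.61 / 299.0

    def __post_init__(self) -> None:
        for name in ("acceptance_coef", "dissemination_coef", "immune_coef"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.init_comm_frac < 1:
            raise ValueError(f"init_comm_frac must be in [0, 1), got {self.init_comm_frac}")

    def replace(self, **kw) -> "ClassicSeirParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return ClassicSeirParams(**d)

    def _network(self, seed: int | None) -> OpinionNetwork:
        proxy = ModelParams(N=self.N, network=self.network, ba_m_attach=self.ba_m_attach,
                            ws_k_ring=self.ws_k_ring, ws_p_rewire=self.ws_p_rewire,
                            er_p_edge=self.er_p_edge)
        return build_network(proxy, seed=seed)


def classic_seir_step(state: np.ndarray, neighbors: list[np.ndarray],
                      params: ClassicSeirParams, rng: np.random.Generator) -> np.ndarray:
    """One synchronous step of the fixed-probability SEIR dynamics.

    Decisions are taken against the start-of-step state: each spreader
    contacts one uniformly random neighbour (a contacted uninformed agent
    becomes silent with the acceptance probability); each silent agent
    independently starts spreading with the dissemination probability; each
    spreader independently turns immune with the immunity probability.
    """
    new = state.copy()
    spreaders = np.flatnonzero(state == _I)
    for i in spreaders:
        nbrs = neighbors[i]
        if len(nbrs) == 0:
            continue
        j = int(nbrs[rng.integers(len(nbrs))])
        if state[j] == _S and new[j] == _S and rng.random() < params.acceptance_coef:
            new[j] = _E
    for i in np.flatnonzero(state == _E):
        if rng.random() < params.dissemination_coef:
            new[i] = _I
    for i in spreaders:
        if rng.random() < params.immune_coef:
            new[i] = _R
    return new


def run_classic_seir(params: ClassicSeirParams, net: OpinionNetwork | None = None,
                     seed: int | None = None) -> SimulationResult:
    """Run the classic SEIR baseline to absorption (no E or I left) or
    ``max_steps``.  No attitudes: polarizability is reported as 0."""
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)
    if net is None:
        net = params._network(seed=int(rng.integers(0, 2**31 - 1)))
    n = net.n
    state = np.full(n, _S, dtype=np.int8)
    n_comm = int(round(params.init_comm_frac * n))
    state[rng.choice(n, size=n_comm, replace=False)] = _I

    counts = [np.bincount(state, minlength=4)[:4]]
    comms = [frozenset(np.flatnonzero(state == _I).tolist())]
    termination = "max_steps"
    t = 0
    while t < params.max_steps:
        state = classic_seir_step(state, net.neighbors, params, rng)
        t += 1
        counts.append(np.bincount(state, minlength=4)[:4])
        comms.append(frozenset(np.flatnonzero(state == _I).tolist()))
        if counts[-1][_E] == 0 and counts[-1][_I] == 0:
            termination = "absorbed"
            break
    L = len(counts)
    return SimulationResult(
        counts=np.array(counts), polarizability=np.zeros(L),
        mean_attitude=np.zeros(L), communicators=comms,
        final_x=np.zeros(n), final_informed=state != _S,
        termination=termination,
        params=ModelParams(N=n, init_comm_frac=params.init_comm_frac,
                           max_steps=params.max_steps),
    )


def run_classic_ja(net: OpinionNetwork, d1: float = 0.3, d2: float = 0.7,
                   mu: float = 0.5, attitude_mean: float = 0.0,
                   attitude_sd: float = 0.3876, seed: int | None = None,
                   max_steps: int = 500, stop_tol: float = 0.1,
                   polar_threshold: float = 0.8) -> SimulationResult:
    """Classic homogeneous J-A baseline: pure polarization, no spreading.

    Every agent is informed from step 0 with an attitude from the truncated
    normal initial distribution; per step each agent, in random order,
    holds one bounded-confidence encounter (fixed coefficient ``mu`` on
    both sides) with a uniformly random neighbour.  Halts on the squared-
    change stop condition or ``max_steps``.
    """
    rng = np.random.default_rng(seed)
    n = net.n
    x = np.clip(rng.normal(attitude_mean, attitude_sd, size=n), -1.0, 1.0)
    informed = np.ones(n, dtype=bool)

    polar = [_polarizability(x, informed, polar_threshold)]
    meanx = [float(x.mean())]
    counts = [np.array([0, 0, n, 0])]
    comms = [frozenset(range(n))]
    termination = "max_steps"
    t = 0
    while t < max_steps:
        x_prev = x.copy()
        for i in rng.permutation(n):
            nbrs = net.neighbors[i]
            if len(nbrs) == 0:
                continue
            j = int(nbrs[rng.integers(len(nbrs))])
            out = ja_core.classic_ja_interact(x[i], x[j], mu, d1, d2)
            x[i], x[j] = out.x_i_new, out.x_j_new
        t += 1
        polar.append(_polarizability(x, informed, polar_threshold))
        meanx.append(float(x.mean()))
        counts.append(np.array([0, 0, n, 0]))
        comms.append(frozenset(range(n)))
        if t >= 2 and ja_core.converged(x_prev, x, stop_tol):
            termination = "converged"
            break
    # out-of-range thresholds (e.g. d1 >= 1 to force universal assimilation)
    # are legal for the kernel but not recordable in ModelParams
    d_kw = {"d1": d1, "d2": d2} if 0 <= d1 < d2 <= 1 else {}
    return SimulationResult(
        counts=np.array(counts), polarizability=np.array(polar),
        mean_attitude=np.array(meanx), communicators=comms,
        final_x=x, final_informed=informed, termination=termination,
        params=ModelParams(N=n, max_steps=max_steps, stop_tol=stop_tol,
                           polar_threshold=polar_threshold, **d_kw),
    )
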