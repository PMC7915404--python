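"""Individual-heterogeneity quantities.

Five agent-level quantities distinguish individuals in the coupled
dissemination/polarization model:

* **communicating willingness** ``P`` — propensity to spread, increasing in
  opinion extremity ``|x|`` and in the external recognition ``m`` the
  agent's opinion has received;
* **embeddedness** ``E_ij`` — tie strength of an adjacent pair (computed in
  :mod:`seirja.networks`);
* **conservatism** ``T_i`` — resistance to opinion change, inversely
  proportional to degree with population mean ``T0``;
* **mainstream degree** ``w±`` / **conformity** ``C±`` — the agent's running
  belief about which opinion sign dominates, stepped by ``gamma`` per
  interaction, and its linear transform gating susceptibility;
* **opinion-change coefficient** ``mu = (1+E)(1-T)C±`` — the per-interaction
  susceptibility fed to the bounded-confidence kernel.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields

import numpy as np

from .networks import OpinionNetwork

__all__ = [
    "State",
    "Agent",
    "ModelParams",
    "communicating_willingness",
    "conservatism_profile",
    "update_mainstream",
    "conformity",
    "opinion_change_coefficient",
    "update_recognition",
]


class State(enum.IntEnum):
    """Compartments: S (never received), E (received, not spreading),
    I (received and spreading), R (permanently disengaged)."""

    UNINFORMED = 0
    SILENT = 1
    COMMUNICATION = 2
    IMMUNE = 3


@dataclass
class Agent:
    """One individual's full dynamic record.

    ``z`` (receipt clock) is ``None`` while uninformed; it starts at 1 on
    first receipt of the information and ticks once per step thereafter.
    """

    id: int
    state: State = State.UNINFORMED
    x: float = 0.0              # attitude in [-1, 1]
    m: float = 1.0              # external recognition degree
    P: float = 0.0              # communicating willingness
    z: int | None = None        # receipt clock, >= 1 once informed
    w_plus: float = 0.5         # mainstream degree of the positive opinion
    w_minus: float = 0.5        # mainstream degree of the negative opinion
    T: float = 0.0              # conservatism in [0, 1]


@dataclass
class ModelParams:
    """All scalar parameters of the coupled model.

    Defaults are the baseline used throughout the parameter studies:
    bounded-confidence thresholds ``d1=0.3 < d2=0.7``, communication
    threshold ``p=0.5``, mean conservatism ``T0=0.8``, mainstream step
    ``gamma=0.1``, attention span ``z0=70`` steps, 10% initial
    communicators among ``N=300`` agents, initial attitudes
    Normal(0, 0.3876) truncated to [-1, 1].
    """

    d1: float = 0.3
    d2: float = 0.7
    p: float = 0.5
    gamma: float = 0.1
    T0: float = 0.8
    z0: int = 70
    init_comm_frac: float = 0.1
    attitude_mean: float = 0.0
    attitude_sd: float = 0.3876 ** 0.5  # N(mean, variance) convention
    N: int = 300
    stop_tol: float = 0.1
    max_steps: int = 200
    polar_threshold: float = 0.8
    seed: int | None = None
    # network specification (used when the caller does not pass a graph)
    network: str = "ba"          # one of {"ba", "ws", "er"}
    ba_m_attach: int = 25        # mean degree ~ 2*m_attach ~ 49
    ws_k_ring: int = 48
    ws_p_rewire: float = 0.1
    er_p_edge: float = 49.61 / 299.0
    # model-reading switches
    recognition_floor: float | None = None   # set to 1.0 for strict m >= 1
    clip_ranges: bool = True                 # clip C and mu into [0, 1]
    both_update_mainstream: bool = True      # partner also steps its w±
    recognition_scope: str = "initiator"     # whose m an encounter moves

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0 <= self.d1 <= 1 or not 0 <= self.d2 <= 1 or self.d1 >= self.d2:
            raise ValueError(f"require 0 <= d1 < d2 <= 1, got d1={self.d1}, d2={self.d2}")
        if not 0 <= self.p <= 1:
            raise ValueError(f"p must be in [0, 1], got {self.p}")
        if not 0 <= self.gamma <= 0.5:
            # gamma = 0 freezes conformity (degenerate but useful control)
            raise ValueError(f"gamma must be in [0, 0.5], got {self.gamma}")
        if not 0 <= self.T0 <= 1:
            raise ValueError(f"T0 must be in [0, 1], got {self.T0}")
        if self.z0 < 1:
            raise ValueError(f"z0 must be >= 1, got {self.z0}")
        if not 0 <= self.init_comm_frac < 1:
            raise ValueError(f"init_comm_frac must be in [0, 1), got {self.init_comm_frac}")
        if self.N < 1:
            raise ValueError(f"N must be positive, got {self.N}")
        if self.attitude_sd < 0:
            raise ValueError(f"attitude_sd must be nonnegative, got {self.attitude_sd}")
        if self.max_steps < 0:
            raise ValueError(f"max_steps must be nonnegative, got {self.max_steps}")
        if self.network not in ("ba", "ws", "er"):
            raise ValueError(f"unknown network family {self.network!r}")
        if self.recognition_scope not in ("initiator", "both"):
            raise ValueError(f"recognition_scope must be 'initiator' or 'both', "
                             f"got {self.recognition_scope!r}")

    def replace(self, **kw) -> "ModelParams":
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d.update(kw)
        return ModelParams(**d)


def communicating_willingness(x: float, m: float) -> float:
    """P = (|x| - 1) * exp(1 - m) + 1.

    For ``m >= 1`` the result lies in ``[|x|, 1]``; recognition below 1
    (an opinion repeatedly rejected by partners) can push P negative, which
    is precisely what routes an agent to immunity.
    """
    return (abs(x) - 1.0) * math.exp(1.0 - m) + 1.0


def conservatism_profile(net: OpinionNetwork, T0: float) -> np.ndarray:
    """Degree-based conservatism: T_i = N * T0 * k_i^-1 / sum_l k_l^-1.

    High-degree agents see more opinions and resist change less.  Before
    clipping to [0, 1] the mean over nodes equals ``T0`` exactly; raw values
    above 1 (very low-degree nodes under large ``T0``) are clipped.
    Isolated nodes never interact and are assigned ``T0`` directly.
    """
    if net.n == 0:
        raise ValueError("empty graph")
    k = net.degrees.astype(float)
    T = np.full(net.n, float(T0))
    mask = k > 0
    if mask.any():
        inv = 1.0 / k[mask]
        T[mask] = mask.sum() * T0 * inv / inv.sum()
    return np.clip(T, 0.0, 1.0)


def update_mainstream(
    w_plus: float, w_minus: float, partner_sign: int, gamma: float
) -> tuple[float, float]:
    """Step the mainstream degrees after observing a partner's opinion sign.

    A positive partner (``partner_sign >= 0``) moves ``gamma`` of belief
    mass from the negative to the positive side; a negative partner the
    reverse.  The pair is clipped jointly so ``w+ + w- = 1`` always holds.
    """
    step = gamma if partner_sign >= 0 else -gamma
    w_plus = min(1.0, max(0.0, w_plus + step))
    return w_plus, 1.0 - w_plus


def conformity(w: float, clip: bool = True) -> float:
    """C = 2w - 1: conformity toward the opinion side with mainstream degree w.

    Raw values are negative while the agent believes the side is the
    minority; by default they are clipped to the declared [0, 1] range
    (a minority opinion attracts no conformity rather than repulsion).
    """
    c = 2.0 * w - 1.0
    return min(1.0, max(0.0, c)) if clip else c


def opinion_change_coefficient(
    E_ij: float, T_i: float, C_signed: float, clip: bool = True
) -> float:
    """mu = (1 + E_ij) * (1 - T_i) * C.

    ``C`` must already be the conformity toward the partner's opinion sign
    (C+ for a nonnegative partner attitude, C- otherwise).  The ``1 + E``
    factor keeps weakly embedded ties from annihilating mu; the result is
    clipped to the declared [0, 1] range by default.
    """
    mu = (1.0 + E_ij) * (1.0 - T_i) * C_signed
    return min(1.0, max(0.0, mu)) if clip else mu


def update_recognition(m: float, outcome: str, floor: float | None = None) -> float:
    """Step external recognition after an interaction.

    An assimilative interaction endorses the opinion (``m + 1``); a
    repulsive one rejects it (``m - 1``, unbounded below so willingness can
    go negative and the immunity-by-rejection path is reachable); a neutral
    one changes nothing.  ``floor`` optionally enforces the declared
    ``m >= 1`` range.
    """
    if outcome == "assimilated":
        m = m + 1.0
    elif outcome == "rejected":
        m = m - 1.0
    elif outcome != "neutral":
        raise ValueError(f"unknown outcome {outcome!r}")
    if floor is not None:
        m = max(floor, m)
    return m
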