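"""Bounded-confidence pairwise interaction kernel (Jager-Amblard family).

Two agents compare attitudes: closer than the assimilation threshold
``d1`` they attract, farther apart than the rejection threshold ``d2``
they repel, in between they ignore each other.  Both updates use the
pre-interaction values (simultaneous pair update) and results are clipped
to the attitude range [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["InteractionOutcome", "interact", "classic_ja_interact", "converged"]

ASSIMILATED = "assimilated"
REJECTED = "rejected"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class InteractionOutcome:
    x_i_new: float
    x_j_new: float
    kind: str  # "assimilated" | "rejected" | "neutral"


def _clip(x: float) -> float:
    return min(1.0, max(-1.0, x))


def interact(
    x_i: float, x_j: float, mu_i: float, mu_j: float, d1: float, d2: float
) -> InteractionOutcome:
    """One heterogeneous bounded-confidence encounter.

    Strictly inside ``d1`` the pair assimilates (each moves toward the
    other by its own coefficient), strictly outside ``d2`` it rejects
    (each moves away), and at or between the thresholds nothing happens.
    """
    diff = abs(x_i - x_j)
    if diff < d1:
        return InteractionOutcome(
            _clip(x_i + mu_i * (x_j - x_i)),
            _clip(x_j + mu_j * (x_i - x_j)),
            ASSIMILATED,
        )
    if diff > d2:
        return InteractionOutcome(
            _clip(x_i - mu_i * (x_j - x_i)),
            _clip(x_j - mu_j * (x_i - x_j)),
            REJECTED,
        )
    return InteractionOutcome(x_i, x_j, NEUTRAL)


def classic_ja_interact(
    x_i: float, x_j: float, mu: float, d1: float, d2: float
) -> InteractionOutcome:
    """Homogeneous variant: one fixed coefficient for both agents.

    With equal coefficients an assimilative encounter conserves the pair
    mean exactly (the classic Deffuant-Weisbuch property).
    """
    return interact(x_i, x_j, mu, mu, d1, d2)


def converged(x_prev, x_curr, tol: float = 0.1) -> bool:
    """Stop condition: sum_i (x_curr_i - x_prev_i)^2 <= tol."""
    x_prev = np.asarray(x_prev, dtype=float)
    x_curr = np.asarray(x_curr, dtype=float)
    if x_prev.shape != x_curr.shape:
        raise ValueError(f"shape mismatch: {x_prev.shape} vs {x_curr.shape}")
    return float(np.sum((x_curr - x_prev) ** 2)) <= tol
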