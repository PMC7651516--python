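"""Design constants and stimulus schedules for the prey-selection foraging task.

Subjects harvest fuel by capturing serially approaching invaders over a
time-constrained session.  Each invader carries a high (80 points) or low
(30 points) reward crossed with a high (8 s) or low (3 s) capture cost,
yielding a three-tier profitability rank.  Two 720-s environments differ in
the rank mixture: a rich "boom" (high:mid:low = 4:2:1) and a poor "downturn"
(1:2:4).  A quarter of trials are forced-choice and errors carry an 8-s time
penalty.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

__all__ = [
    "InvaderType",
    "EnvironmentSpec",
    "SessionPlan",
    "INVADERS",
    "make_session_plan",
    "draw_invader",
    "profitability_rank",
]

REWARD_HIGH = 80.0
REWARD_LOW = 30.0
COST_HIGH = 8.0
COST_LOW = 3.0

#: Seconds of invader approach preceding every decision.
APPROACH_S = 2.0
#: Seconds of reward feedback, counted as the final second of the capture cost.
FEEDBACK_S = 1.0
#: Seconds of timeout following an error.
PENALTY_S = 8.0


@dataclass(frozen=True)
class InvaderType:
    """One of the four invader identities: a (reward, capture-cost) pair."""

    type_id: int
    reward_points: float
    capture_cost_s: float

    @property
    def rank(self) -> str:
        return profitability_rank(self)


def profitability_rank(invader: InvaderType) -> str:
    """Map an invader's (reward, cost) pair onto its profitability tier.

    High reward with low cost is ``high``; low reward with high cost is
    ``low``; the two mixed combinations are both ``mid``.
    """
    hi_r = invader.reward_points == REWARD_HIGH
    hi_c = invader.capture_cost_s == COST_HIGH
    if not (invader.reward_points in (REWARD_HIGH, REWARD_LOW)
            and invader.capture_cost_s in (COST_HIGH, COST_LOW)):
        raise ValueError(
            f"unknown invader configuration: reward={invader.reward_points}, "
            f"cost={invader.capture_cost_s}")
    if hi_r and not hi_c:
        return "high"
    if not hi_r and hi_c:
        return "low"
    return "mid"


#: The four invader identities.  ids 2 and 3 are the two mid-rank types.
INVADERS: Tuple[InvaderType, ...] = (
    InvaderType(1, REWARD_HIGH, COST_LOW),   # high
    InvaderType(2, REWARD_HIGH, COST_HIGH),  # mid
    InvaderType(3, REWARD_LOW, COST_LOW),    # mid
    InvaderType(4, REWARD_LOW, COST_HIGH),   # low
)

_BY_RANK = {
    "high": (INVADERS[0],),
    "mid": (INVADERS[1], INVADERS[2]),
    "low": (INVADERS[3],),
}


@dataclass(frozen=True)
class EnvironmentSpec:
    """A foraging environment: a label, a high:mid:low rank mixture, a duration.

    ``mid_split`` is the share of mid-rank draws given to the high-reward/
    high-cost type (id 2); the two mid types otherwise share the mid weight
    equally.
    """

    label: str
    mixture: Tuple[float, float, float]
    duration_s: float = 720.0
    mid_split: float = 0.5

    def __post_init__(self):
        if any(w < 0 for w in self.mixture) or sum(self.mixture) <= 0:
            raise ValueError("mixture weights must be non-negative with positive sum")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not 0.0 <= self.mid_split <= 1.0:
            raise ValueError("mid_split must lie in [0, 1]")

    @property
    def rank_probs(self) -> np.ndarray:
        w = np.asarray(self.mixture, dtype=float)
        return w / w.sum()


BOOM = EnvironmentSpec("boom", (4.0, 2.0, 1.0))
DOWNTURN = EnvironmentSpec("downturn", (1.0, 2.0, 4.0))


@dataclass(frozen=True)
class SessionPlan:
    """A full session: two environment blocks in a given order plus timing."""

    order: str  # "BD" or "DB"
    blocks: Tuple[EnvironmentSpec, EnvironmentSpec]
    forced_fraction: float = 0.25
    error_rate: float = 0.018
    approach_s: float = APPROACH_S
    feedback_s: float = FEEDBACK_S
    penalty_s: float = PENALTY_S

    def __post_init__(self):
        if self.order not in ("BD", "DB"):
            raise ValueError(f"unknown order label: {self.order!r}")
        if not 0.0 <= self.forced_fraction < 1.0:
            raise ValueError("forced_fraction must lie in [0, 1)")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must lie in [0, 1)")


_PLAN_OVERRIDE_KEYS = {"forced_fraction", "error_rate", "duration_s", "mid_split"}


def make_session_plan(order: str, overrides: dict | None = None) -> SessionPlan:
    """Build a :class:`SessionPlan` for one of the two block orders.

    Parameters
    ----------
    order:
        ``"BD"`` (boom then downturn) or ``"DB"`` (downturn then boom).
    overrides:
        Optional overrides for documented fields only: ``forced_fraction``,
        ``error_rate``, ``duration_s`` (applied to both blocks), and
        ``mid_split``.
    """
    if order not in ("BD", "DB"):
        raise ValueError(f"unknown order label: {order!r}")
    overrides = dict(overrides or {})
    unknown = set(overrides) - _PLAN_OVERRIDE_KEYS
    if unknown:
        raise ValueError(f"unknown SessionPlan override(s): {sorted(unknown)}")
    env_kwargs = {}
    if "duration_s" in overrides:
        env_kwargs["duration_s"] = float(overrides.pop("duration_s"))
    if "mid_split" in overrides:
        env_kwargs["mid_split"] = float(overrides.pop("mid_split"))
    boom = replace(BOOM, **env_kwargs)
    down = replace(DOWNTURN, **env_kwargs)
    blocks = (boom, down) if order == "BD" else (down, boom)
    return SessionPlan(order=order, blocks=blocks, **overrides)


def draw_invader(env: EnvironmentSpec, rng: np.random.Generator) -> InvaderType:
    """Draw one invader from the environment's rank mixture.

    Rank is drawn with probability proportional to the mixture weights;
    mid-rank draws are then split between the two mid identities according to
    ``env.mid_split`` (default: evenly).
    """
    p = env.rank_probs
    rank = ("high", "mid", "low")[rng.choice(3, p=p)]
    if rank == "mid":
        return INVADERS[1] if rng.random() < env.mid_split else INVADERS[2]
    return _BY_RANK[rank][0]


def draw_invader_sequence(env: EnvironmentSpec, n: int,
                          rng: np.random.Generator) -> list[InvaderType]:
    """Draw ``n`` invaders i.i.d. from the environment mixture."""
    return [draw_invader(env, rng) for _ in range(n)]
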