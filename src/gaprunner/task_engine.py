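"""Discrete-event simulation of one task session.

A session walks the schedule gap by gap.  Before each gap the response
policy (the stand-in for the human player) either names an intended jump
distance — how far before the gap's leading edge the jump starts — or
declines to jump.  A declined or non-positive jump becomes an *omission*:
the avatar reaches the gap edge and auto-jumps, recorded with distance 0.
The recorded distance is the task's primary behavioral measure.

Jump mechanics are deliberately minimal: a jump covers ``speed * airtime``
track units horizontally, so a jump clears the gap iff it starts no more
than ``span - gap_length`` units before the edge.  A FELL outcome is
logged but has no effect on the rest of the session (the avatar respawns
at the far edge), so behavioral metrics do not depend on outcomes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .errors import ConfigurationError
from .schedule import BlockConfig, ISClass, Schedule, is_class

__all__ = [
    "Outcome",
    "JumpRecord",
    "SessionLog",
    "ResponsePolicy",
    "NO_JUMP",
    "simulate_session",
    "classify_jump",
    "constant_policy",
    "never_jump_policy",
    "scripted_policy",
]

#: Sentinel a policy returns to decline jumping (an omission).
NO_JUMP = None

#: Clamp margin for intended distances at or beyond the trunk length.
_CLAMP_EPS = 1e-9

#: Contract for the player stand-in: (block, gap_index, rng) -> distance or NO_JUMP.
ResponsePolicy = Callable[[BlockConfig, int, np.random.Generator], Optional[float]]


class Outcome:
    CLEARED = "CLEARED"
    FELL = "FELL"


@dataclass(frozen=True)
class JumpRecord:
    """One gap's behavioral event."""

    participant_id: str
    block_id: str
    gap_index: int
    is_nominal: ISClass
    voluntary: bool
    omission: bool
    distance: float  # jump point to gap leading edge, track units; 0 for omissions
    outcome: str  # Outcome.CLEARED or Outcome.FELL


@dataclass
class SessionLog:
    """Ordered per-gap records of one session."""

    participant_id: str
    schedule_hash: str
    records: list[JumpRecord] = field(default_factory=list)
    n_clamped: int = 0  # intended distances >= trunk length, clamped

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.participant_id.encode())
        h.update(self.schedule_hash.encode())
        for r in self.records:
            h.update(
                f"{r.block_id}|{r.gap_index}|{r.is_nominal.value}|{int(r.voluntary)}|"
                f"{int(r.omission)}|{r.distance!r}|{r.outcome}\n".encode()
            )
        return h.hexdigest()

    @property
    def n_omissions(self) -> int:
        return sum(r.omission for r in self.records)

    @property
    def n_voluntary(self) -> int:
        return sum(r.voluntary for r in self.records)


def classify_jump(distance: float, block: BlockConfig, airtime: float = 1.0) -> str:
    """CLEARED/FELL for a jump starting ``distance`` units before the gap edge.

    The horizontal jump span is ``speed * airtime``; the avatar lands in the
    gap iff the span runs out before the far edge, i.e. iff
    ``distance > span - gap_length``.
    """
    if distance < 0:
        raise ConfigurationError("distance must be >= 0")
    span = block.speed * airtime
    if span < block.gap_length:
        raise ConfigurationError(
            f"block {block.block_id}: jump span {span} < gap {block.gap_length}; "
            "gap is unclearable at this airtime"
        )
    return Outcome.CLEARED if distance <= span - block.gap_length else Outcome.FELL


def simulate_session(
    schedule: Schedule,
    policy: ResponsePolicy,
    participant_id: str,
    seed: int | np.random.SeedSequence | np.random.Generator,
    airtime: float = 1.0,
) -> SessionLog:
    """Run one full session and return its log.

    The policy is queried once per gap with the block configuration, the
    gap index within the block and the session's random stream.  The same
    (schedule, policy, seed) triple always yields a bit-identical log.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    log = SessionLog(participant_id=participant_id, schedule_hash=schedule.digest())
    for block in schedule.blocks:
        cls = is_class(block)
        for k in range(block.n_gaps):
            d = policy(block, k, rng)
            if d is None or d <= 0:
                # omission: auto-jump at the gap edge
                log.records.append(
                    JumpRecord(
                        participant_id=participant_id,
                        block_id=block.block_id,
                        gap_index=k,
                        is_nominal=cls,
                        voluntary=False,
                        omission=True,
                        distance=0.0,
                        outcome=classify_jump(0.0, block, airtime),
                    )
                )
                continue
            if d >= block.trunk_length:
                d = block.trunk_length - _CLAMP_EPS
                log.n_clamped += 1
            log.records.append(
                JumpRecord(
                    participant_id=participant_id,
                    block_id=block.block_id,
                    gap_index=k,
                    is_nominal=cls,
                    voluntary=True,
                    omission=False,
                    distance=float(d),
                    outcome=classify_jump(d, block, airtime),
                )
            )
    return log


# -- reference policies -------------------------------------------------


def constant_policy(distance: float) -> ResponsePolicy:
    """Always jump at the same distance before the gap."""

    def policy(block: BlockConfig, gap_index: int, rng: np.random.Generator):
        return distance

    return policy


def never_jump_policy() -> ResponsePolicy:
    """Never jump voluntarily; every gap is an omission."""

    def policy(block: BlockConfig, gap_index: int, rng: np.random.Generator):
        return NO_JUMP

    return policy


def scripted_policy(script: list[Optional[float]]) -> ResponsePolicy:
    """Replay a fixed per-gap script of distances / NO_JUMP entries."""
    it = iter(script)

    def policy(block: BlockConfig, gap_index: int, rng: np.random.Generator):
        return next(it)

    return policy
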