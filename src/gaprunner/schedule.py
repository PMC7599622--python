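"""Stimulus program for the infinite-runner attention task.

The task presents a fixed sequence of gaps that the avatar must jump.
Gaps are grouped into blocks; each block fixes the trunk length (the solid
track segment before every gap), the gap width and the avatar speed.
Trunk length divided by speed is the inter-stimulus (IS) time, the interval
between consecutive gap stimuli; gap width sets jump difficulty.  The
default program has 18 blocks of 10 gaps each (180 gaps total) spanning
three nominal IS classes of roughly 1.5, 2.5 and 3.5 s, six blocks per
class, crossed with two avatar speeds and three gap widths.
"""

from __future__ import annotations

import enum
import hashlib
import io
import json
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError

__all__ = [
    "ISClass",
    "BlockConfig",
    "Schedule",
    "GapInterval",
    "build_default_schedule",
    "interstimulus_time",
    "is_class",
    "track_layout",
    "nominal_duration",
    "DEFAULT_BLOCK_TABLE",
]


class ISClass(str, enum.Enum):
    """Nominal inter-stimulus-time class of a block."""

    SHORT = "SHORT"    # IS < 2 s, nominally ~1.5 s
    MEDIUM = "MEDIUM"  # 2 s <= IS < 3 s, nominally ~2.5 s
    LONG = "LONG"      # IS >= 3 s, nominally ~3.5 s

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Default block table: (block_id, trunk, gap, speed, printed IS label).
# Lengths are in track units, speed in units/s.  The printed IS label is
# the rounded value advertised for each block; for B16-B18 it exceeds
# trunk/speed by ~0.057 s, so trunk/gap/speed are treated as ground truth
# and the label is informational only.
DEFAULT_BLOCK_TABLE: tuple[tuple[str, float, float, float, float], ...] = (
    ("B1", 8.0, 2.0, 5.0, 1.6),
    ("B2", 13.0, 2.0, 5.0, 2.6),
    ("B3", 18.0, 2.0, 5.0, 3.6),
    ("B4", 7.0, 3.0, 5.0, 1.4),
    ("B5", 12.0, 3.0, 5.0, 2.4),
    ("B6", 17.0, 3.0, 5.0, 3.4),
    ("B7", 6.0, 4.0, 5.0, 1.2),
    ("B8", 11.0, 4.0, 5.0, 2.2),
    ("B9", 16.0, 4.0, 5.0, 3.2),
    ("B10", 11.0, 3.0, 7.0, 1.6),
    ("B11", 18.0, 3.0, 7.0, 2.6),
    ("B12", 25.0, 3.0, 7.0, 3.6),
    ("B13", 9.5, 4.5, 7.0, 1.4),
    ("B14", 16.5, 4.5, 7.0, 2.4),
    ("B15", 23.5, 4.5, 7.0, 3.4),
    ("B16", 8.0, 6.0, 7.0, 1.2),
    ("B17", 15.0, 6.0, 7.0, 2.2),
    ("B18", 22.0, 6.0, 7.0, 3.2),
)


@dataclass(frozen=True)
class BlockConfig:
    """One block of identically configured gaps.

    Parameters
    ----------
    block_id
        Label, e.g. ``"B1"``.
    trunk_length
        Length of the solid track segment preceding each gap (track units).
    gap_length
        Width of each gap (track units).
    speed
        Avatar speed while in this block (track units per second).
    n_gaps
        Number of gaps in the block.
    """

    block_id: str
    trunk_length: float
    gap_length: float
    speed: float
    n_gaps: int = 10

    def __post_init__(self) -> None:
        if self.trunk_length < 0 or self.gap_length <= 0:
            raise ConfigurationError(
                f"block {self.block_id}: trunk/gap lengths must be positive"
            )
        if self.speed <= 0:
            raise ConfigurationError(f"block {self.block_id}: speed must be > 0")
        if self.n_gaps < 1:
            raise ConfigurationError(f"block {self.block_id}: n_gaps must be >= 1")

    @property
    def is_time(self) -> float:
        return interstimulus_time(self)


@dataclass(frozen=True)
class Schedule:
    """Ordered sequence of blocks defining one session's stimulus program."""

    blocks: tuple[BlockConfig, ...] = field(default_factory=tuple)

    @property
    def total_gaps(self) -> int:
        return sum(b.n_gaps for b in self.blocks)

    @property
    def gaps_per_block(self) -> int | None:
        """Common per-block gap count, or None if blocks differ."""
        counts = {b.n_gaps for b in self.blocks}
        return counts.pop() if len(counts) == 1 else None

    def digest(self) -> str:
        """Stable hex digest of the full block configuration."""
        payload = json.dumps(
            [
                [b.block_id, b.trunk_length, b.gap_length, b.speed, b.n_gaps]
                for b in self.blocks
            ],
            separators=(",", ":"),
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    # -- serialization --------------------------------------------------

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("block_id,trunk,gap,speed,n_gaps\n")
        for b in self.blocks:
            buf.write(
                f"{b.block_id},{b.trunk_length!r},{b.gap_length!r},"
                f"{b.speed!r},{b.n_gaps}\n"
            )
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "Schedule":
        from .errors import DataFormatError

        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].strip() != "block_id,trunk,gap,speed,n_gaps":
            raise DataFormatError("expected header 'block_id,trunk,gap,speed,n_gaps'", line=1)
        blocks = []
        for i, ln in enumerate(lines[1:], start=2):
            parts = ln.split(",")
            if len(parts) != 5:
                raise DataFormatError(f"expected 5 fields, got {len(parts)}", line=i)
            try:
                blocks.append(
                    BlockConfig(
                        block_id=parts[0],
                        trunk_length=float(parts[1]),
                        gap_length=float(parts[2]),
                        speed=float(parts[3]),
                        n_gaps=int(parts[4]),
                    )
                )
            except ValueError as exc:
                raise DataFormatError(str(exc), line=i) from exc
        return cls(blocks=tuple(blocks))

    def to_json(self) -> str:
        return json.dumps(
            {
                "blocks": [
                    {
                        "block_id": b.block_id,
                        "trunk": b.trunk_length,
                        "gap": b.gap_length,
                        "speed": b.speed,
                        "n_gaps": b.n_gaps,
                    }
                    for b in self.blocks
                ]
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "Schedule":
        obj = json.loads(text)
        return cls(
            blocks=tuple(
                BlockConfig(
                    block_id=d["block_id"],
                    trunk_length=float(d["trunk"]),
                    gap_length=float(d["gap"]),
                    speed=float(d["speed"]),
                    n_gaps=int(d["n_gaps"]),
                )
                for d in obj["blocks"]
            )
        )


@dataclass(frozen=True)
class GapInterval:
    """Position of one gap on the linearized 1-D track."""

    block_id: str
    gap_index: int  # 0-based within the block
    start_pos: float  # leading edge of the gap
    end_pos: float  # far edge


def build_default_schedule(gaps_per_block: int = 10) -> Schedule:
    """Return the default 18-block program with ``gaps_per_block`` gaps per block."""
    if gaps_per_block < 1:
        raise ConfigurationError("gaps_per_block must be >= 1")
    return Schedule(
        blocks=tuple(
            BlockConfig(bid, trunk, gap, speed, n_gaps=gaps_per_block)
            for bid, trunk, gap, speed, _label in DEFAULT_BLOCK_TABLE
        )
    )


def interstimulus_time(block: BlockConfig) -> float:
    """Inter-stimulus time of a block: trunk length / speed, unrounded (s)."""
    if block.speed <= 0:
        raise ConfigurationError(f"block {block.block_id}: speed must be > 0")
    return block.trunk_length / block.speed


def is_class(block: BlockConfig) -> ISClass:
    """Nominal IS class; boundaries half-open at 2 s and 3 s."""
    t = interstimulus_time(block)
    if t < 2.0:
        return ISClass.SHORT
    if t < 3.0:
        return ISClass.MEDIUM
    return ISClass.LONG


def track_layout(schedule: Schedule) -> list[GapInterval]:
    """Positions of every gap when the session is laid out on a 1-D axis.

    Each gap is preceded by one full trunk segment of its block, so gap
    intervals are strictly increasing and non-overlapping.
    """
    intervals: list[GapInterval] = []
    pos = 0.0
    for b in schedule.blocks:
        for k in range(b.n_gaps):
            start = pos + b.trunk_length
            intervals.append(
                GapInterval(block_id=b.block_id, gap_index=k,
                            start_pos=start, end_pos=start + b.gap_length)
            )
            pos = start + b.gap_length
    return intervals


def nominal_duration(schedule: Schedule) -> float:
    """Session duration in seconds if the avatar never pauses."""
    return sum(
        b.n_gaps * (b.trunk_length + b.gap_length) / b.speed for b in schedule.blocks
    )


def with_gaps_per_block(schedule: Schedule, n: int) -> Schedule:
    """Copy of ``schedule`` with every block's gap count set to ``n``."""
    return Schedule(blocks=tuple(replace(b, n_gaps=n) for b in schedule.blocks))
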