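"""Disjoint wildcard-cube representation of large state sets.

A cube is a pattern over {0,1,*} on an n-node state space, stored as a
pair of integer masks: ``care`` has a 1 where the coordinate is specified
and ``value`` holds the specified bits (zero on don't-care positions).
A :class:`CubeSet` keeps its cubes pairwise disjoint by on-insert
splitting, so the exact cardinality is just the sum of 2^(#wildcards)
over cubes — arbitrary-precision by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = ["Cube", "CubeSet"]


@dataclass(frozen=True)
class Cube:
    """A single {0,1,*} pattern on n coordinates."""

    n: int
    care: int
    value: int

    def __post_init__(self) -> None:
        mask = (1 << self.n) - 1
        if self.care & ~mask:
            raise ValueError("care mask wider than n")
        if self.value & ~self.care:
            raise ValueError("value bits outside care mask")

    @classmethod
    def from_state(cls, n: int, state: int) -> "Cube":
        return cls(n, (1 << n) - 1, state)

    @classmethod
    def from_pattern(cls, pattern: str) -> "Cube":
        """Build from a '01*' string, coordinate 0 leftmost."""
        care = value = 0
        for i, ch in enumerate(pattern):
            if ch == "*":
                continue
            if ch not in "01":
                raise ValueError(f"bad pattern character {ch!r}")
            care |= 1 << i
            value |= int(ch) << i
        return cls(len(pattern), care, value)

    def pattern(self) -> str:
        return "".join(
            "*" if not (self.care >> i) & 1 else str((self.value >> i) & 1)
            for i in range(self.n)
        )

    @property
    def free_count(self) -> int:
        return self.n - self.care.bit_count()

    def size(self) -> int:
        return 1 << self.free_count

    def contains(self, state: int) -> bool:
        return (state & self.care) == self.value

    def overlaps(self, other: "Cube") -> bool:
        common = self.care & other.care
        return (self.value & common) == (other.value & common)

    def intersect(self, other: "Cube") -> "Cube | None":
        if not self.overlaps(other):
            return None
        return Cube(self.n, self.care | other.care, self.value | other.value)

    def subtract(self, other: "Cube") -> list["Cube"]:
        """This cube minus another, as disjoint cubes.

        Standard orthogonal sharp: peel one coordinate of ``other``'s
        care set at a time, fixing it to the complementary value.
        """
        if not self.overlaps(other):
            return [self]
        out: list[Cube] = []
        care, value = self.care, self.value
        extra = other.care & ~self.care
        i = 0
        rem_care, rem_value = care, value
        for i in range(self.n):
            bit = 1 << i
            if not extra & bit:
                continue
            opp = (~other.value) & bit
            out.append(Cube(self.n, rem_care | bit, rem_value | opp))
            rem_care |= bit
            rem_value |= other.value & bit
        # the remainder (rem) is now contained in other: dropped
        return out

    def flip(self, coord: int) -> "Cube":
        """Flip one coordinate's specified value (wildcards unchanged)."""
        bit = 1 << coord
        if not self.care & bit:
            return self
        return Cube(self.n, self.care, self.value ^ bit)

    def states(self) -> Iterator[int]:
        free = [i for i in range(self.n) if not (self.care >> i) & 1]
        for m in range(1 << len(free)):
            s = self.value
            for j, i in enumerate(free):
                s |= ((m >> j) & 1) << i
            yield s


class CubeSet:
    """A set of states kept as pairwise-disjoint cubes.

    ``max_cubes`` is a memory guard: exceeding it raises, pointing the
    caller at the Monte-Carlo path for cluster-sized problems.
    """

    def __init__(self, n: int, max_cubes: int | None = None):
        self.n = n
        self.cubes: list[Cube] = []
        self.max_cubes = max_cubes

    def __len__(self) -> int:
        return len(self.cubes)

    def __iter__(self) -> Iterator[Cube]:
        return iter(self.cubes)

    def add(self, cube: Cube) -> list[Cube]:
        """Insert a cube; returns the disjoint pieces actually added."""
        if cube.n != self.n:
            raise ValueError("cube width mismatch")
        pieces = [cube]
        for existing in self.cubes:
            pieces = [p for piece in pieces for p in piece.subtract(existing)]
            if not pieces:
                return []
        self.cubes.extend(pieces)
        if self.max_cubes is not None and len(self.cubes) > self.max_cubes:
            raise MemoryError(
                f"cube count exceeded the configured cap ({self.max_cubes}); "
                "this basin is too large for exact mode — use the "
                "Monte-Carlo landscape / forward search instead"
            )
        return pieces

    def add_state(self, state: int) -> bool:
        return bool(self.add(Cube.from_state(self.n, state)))

    def remove_state(self, state: int) -> None:
        point = Cube.from_state(self.n, state)
        new: list[Cube] = []
        for c in self.cubes:
            if c.contains(state):
                new.extend(c.subtract(point))
            else:
                new.append(c)
        self.cubes = new

    def contains(self, state: int) -> bool:
        return any(c.contains(state) for c in self.cubes)

    def count(self) -> int:
        """Exact cardinality (python int, arbitrary precision)."""
        return sum(c.size() for c in self.cubes)

    def states(self) -> Iterator[int]:
        for c in self.cubes:
            yield from c.states()

    def flip(self, coord: int) -> "CubeSet":
        out = CubeSet(self.n, self.max_cubes)
        out.cubes = [c.flip(coord) for c in self.cubes]
        return out

    def set_equals(self, other: "CubeSet") -> bool:
        if self.n != other.n or self.count() != other.count():
            return False
        # disjointness makes double inclusion a subtraction check
        return self._covered_by(other) and other._covered_by(self)

    def _covered_by(self, other: "CubeSet") -> bool:
        for c in self.cubes:
            pieces = [c]
            for o in other.cubes:
                pieces = [p for piece in pieces for p in piece.subtract(o)]
                if not pieces:
                    break
            if pieces:
                return False
        return True

    def column_values(self, coord: int) -> set[int]:
        """Values coordinate can take over the set: subset of {0,1}."""
        vals: set[int] = set()
        bit = 1 << coord
        for c in self.cubes:
            if c.care & bit:
                vals.add(1 if c.value & bit else 0)
            else:
                vals.update((0, 1))
            if len(vals) == 2:
                break
        return vals

    def to_text(self) -> str:
        return "\n".join(c.pattern() for c in self.cubes) + "\n"

    @classmethod
    def from_text(cls, n: int, text: str) -> "CubeSet":
        out = cls(n)
        for line in text.splitlines():
            line = line.strip()
            if line:
                out.add(Cube.from_pattern(line))
        return out
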