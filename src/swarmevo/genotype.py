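"""Four-locus binary genotypes of a clonal swarm.

A swarm's genome ``{b1,b2,b3;p}`` has three behavioural loci and one sensory
locus.  Locus ``b_i`` sets the collision reaction taken by a robot that is
currently in behavioural state ``S_i`` (0 = Stay: halt for a fixed time,
1 = Leave: back up a fixed distance).  Locus ``p`` switches the ability to
detect the trail pheromone (0 = blind to it, 1 = can detect), which gates
the recruited trail-following state ``S3``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

STAY = 0
LEAVE = 1

_GENOTYPE_RE = re.compile(r"^\s*\{\s*([01])\s*,\s*([01])\s*,\s*([01])\s*;\s*([01])\s*\}\s*$")


@dataclass(frozen=True, order=True)
class Genotype:
    """Immutable 4-bit genome ``{b1,b2,b3;p}``."""

    b1: int
    b2: int
    b3: int
    p: int

    def __post_init__(self) -> None:
        for name in ("b1", "b2", "b3", "p"):
            v = getattr(self, name)
            if v not in (0, 1):
                raise ValueError(f"locus {name} must be 0 or 1, got {v!r}")

    @classmethod
    def from_string(cls, s: str) -> "Genotype":
        """Parse the ``{b1,b2,b3;p}`` notation (e.g. ``"{1,0,1;1}"``)."""
        m = _GENOTYPE_RE.match(s)
        if m is None:
            raise ValueError(f"not a genotype string: {s!r} (expected e.g. '{{1,0,1;1}}')")
        return cls(*(int(g) for g in m.groups()))

    def __str__(self) -> str:
        return f"{{{self.b1},{self.b2},{self.b3};{self.p}}}"

    @property
    def index(self) -> int:
        """Pack into 0..15 as ``b1*8 + b2*4 + b3*2 + p``."""
        return self.b1 * 8 + self.b2 * 4 + self.b3 * 2 + self.p

    @classmethod
    def from_index(cls, i: int) -> "Genotype":
        if not 0 <= i <= 15:
            raise ValueError(f"genotype index out of range: {i}")
        return cls((i >> 3) & 1, (i >> 2) & 1, (i >> 1) & 1, i & 1)

    def collision_allele(self, behavior_state: int) -> int:
        """Allele expressed on collision by a robot in state S1/S2/S3."""
        if behavior_state not in (1, 2, 3):
            raise ValueError(f"unknown behavior state: {behavior_state}")
        return (self.b1, self.b2, self.b3)[behavior_state - 1]

    def as_array(self) -> np.ndarray:
        return np.array([self.b1, self.b2, self.b3, self.p], dtype=np.int64)

    @classmethod
    def from_bits(cls, bits) -> "Genotype":
        return cls(int(bits[0]), int(bits[1]), int(bits[2]), int(bits[3]))


ALL_GENOTYPES = tuple(Genotype.from_index(i) for i in range(16))

#: the four genotypes of the valley-crossing story
ANCESTOR = Genotype(0, 0, 0, 0)
ORIGINAL = Genotype(1, 0, 0, 0)
NEUTRAL_INTERMEDIATE = Genotype(1, 0, 1, 0)
INFERIOR_INTERMEDIATE = Genotype(1, 0, 0, 1)
FINAL = Genotype(1, 0, 1, 1)
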