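"""Chiral indices (n, m) and the quantities they determine.

A single-walled carbon nanotube is a graphene sheet rolled along the chiral
vector C_h = n*a1 + m*a2.  Everything geometric and electronic about the
pristine tube follows from the integer pair: diameter, translational period,
atoms per period, and the metallic/semiconducting dichotomy
((n - m) mod 3 == 0 <=> metallic in the zone-folding picture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property

from .constants import A_LATTICE

# the 16 chiralities studied throughout: zigzag (m,0), armchair (m,m) and
# six chiral tubes, all with diameters in the 0.6-2 nm window typical of
# as-synthesized material
STUDY_CHIRALITIES: tuple[tuple[int, int], ...] = (
    (13, 0), (14, 0), (16, 0), (20, 0), (23, 0), (32, 0),
    (4, 4), (12, 12), (15, 15), (20, 20),
    (11, 10), (14, 4), (12, 6), (12, 8), (23, 6), (9, 4),
)


@dataclass(frozen=True)
class ChiralIndices:
    """Validated (n, m) pair with derived tube invariants."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and isinstance(self.m, int)):
            raise TypeError("chiral indices must be integers")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got n={self.n}")
        if not (0 <= self.m <= self.n):
            raise ValueError(
                f"m must satisfy 0 <= m <= n, got (n, m)=({self.n}, {self.m})"
            )

    @cached_property
    def _nmm(self) -> int:
        return self.n * self.n + self.m * self.m + self.n * self.m

    @property
    def d_R(self) -> int:
        """gcd(2n + m, 2m + n), the reduction factor of the translation vector."""
        return math.gcd(2 * self.n + self.m, 2 * self.m + self.n)

    @property
    def diameter(self) -> float:
        """Tube diameter in nm: a*sqrt(n^2 + m^2 + nm)/pi."""
        return A_LATTICE * math.sqrt(self._nmm) / math.pi

    @property
    def circumference(self) -> float:
        """|C_h| in nm."""
        return A_LATTICE * math.sqrt(self._nmm)

    @property
    def translation_period(self) -> float:
        """Length |T| of the 1D translational unit cell in nm."""
        return math.sqrt(3.0) * self.circumference / self.d_R

    @property
    def atoms_per_cell(self) -> int:
        """Carbon atoms in one translational period: 4(n^2+m^2+nm)/d_R."""
        num = 4 * self._nmm
        assert num % self.d_R == 0
        return num // self.d_R

    @property
    def is_metallic(self) -> bool:
        return (self.n - self.m) % 3 == 0

    @property
    def metallicity(self) -> str:
        return "metallic" if self.is_metallic else "semiconducting"

    @property
    def chiral_angle_deg(self) -> float:
        """Angle between C_h and the zigzag direction, 0..30 degrees."""
        return math.degrees(
            math.atan2(math.sqrt(3.0) * self.m, 2 * self.n + self.m)
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.n},{self.m})"


def diameter(chirality: ChiralIndices | tuple[int, int]) -> float:
    """Diameter in nm of the (n, m) tube."""
    return _as_chirality(chirality).diameter


def classify_metallicity(chirality: ChiralIndices | tuple[int, int]) -> str:
    """'metallic' iff (n - m) mod 3 == 0, else 'semiconducting'."""
    return _as_chirality(chirality).metallicity


def semiconductor_fraction(
    chiralities=STUDY_CHIRALITIES,
) -> float:
    """Fraction of semiconducting tubes in a chirality list (0..1)."""
    chis = [_as_chirality(c) for c in chiralities]
    if not chis:
        raise ValueError("empty chirality list")
    return sum(not c.is_metallic for c in chis) / len(chis)


def _as_chirality(c) -> ChiralIndices:
    if isinstance(c, ChiralIndices):
        return c
    n, m = c
    return ChiralIndices(int(n), int(m))
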