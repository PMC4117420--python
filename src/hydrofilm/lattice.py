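"""Periodic triangular-lattice configurations.

Sites are addressed by axial integer coordinates ``(i, j)`` with basis
``e1 = (1, 0)`` and ``e2 = (1/2, sqrt(3)/2)`` (both of unit length), 0-based,
wrapping periodically in both axes.  Each site is either vacant or carries one
of six in-plane protein orientations ``k`` (a rotation by ``k * 60``
degrees).  The six nearest-neighbour directions are indexed 0..5
counterclockwise starting from ``+e1``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

VACANT: int = -1
N_ORIENT: int = 6

#: axial offsets of the six neighbour directions, counterclockwise from +e1
DIRS: tuple[tuple[int, int], ...] = (
    (1, 0), (0, 1), (-1, 1), (-1, 0), (0, -1), (1, -1))

DIRS_ARR = np.array(DIRS, dtype=np.int64)

SQRT3 = np.sqrt(3.0)


def opposite(d: int) -> int:
    """Index of the direction antiparallel to ``d``."""
    return (d + 3) % 6


def rot60(v: tuple[int, int], k: int = 1) -> tuple[int, int]:
    """Rotate an axial vector by ``k * 60`` degrees counterclockwise.

    One 60-degree turn maps ``e1 -> e2`` and ``e2 -> e2 - e1``, i.e.
    ``(i, j) -> (-j, i + j)``.
    """
    i, j = v
    for _ in range(k % 6):
        i, j = -j, i + j
    return (i, j)


def axial_to_cart(i: float, j: float) -> tuple[float, float]:
    """Cartesian coordinates of axial position ``i*e1 + j*e2`` (unit spacing)."""
    return (i + 0.5 * j, (SQRT3 / 2.0) * j)


@dataclass
class LatticeConfig:
    """A periodic triangular lattice of vacancies and oriented proteins.

    ``spins`` has shape ``(height, width)``; ``spins[j, i]`` is the state of
    site ``(i, j)``: :data:`VACANT` or an orientation in ``0..5``.
    """

    width: int
    height: int
    spins: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.width < 2 or self.height < 2:
            raise ValueError("lattice must be at least 2x2 sites")
        if self.spins is None:
            self.spins = np.full((self.height, self.width), VACANT, dtype=np.int8)
        else:
            self.spins = np.asarray(self.spins, dtype=np.int8)
            if self.spins.shape != (self.height, self.width):
                raise ValueError("spins shape does not match (height, width)")
            if not np.all((self.spins >= VACANT) & (self.spins < N_ORIENT)):
                raise ValueError("spin values must be -1 (vacant) or 0..5")

    # -- site access -------------------------------------------------------
    def get(self, i: int, j: int) -> int:
        return int(self.spins[j % self.height, i % self.width])

    def set(self, i: int, j: int, s: int) -> None:
        self.spins[j % self.height, i % self.width] = s

    def neighbor(self, i: int, j: int, d: int) -> tuple[int, int]:
        di, dj = DIRS[d]
        return ((i + di) % self.width, (j + dj) % self.height)

    def occupied_sites(self) -> list[tuple[int, int]]:
        js, is_ = np.nonzero(self.spins >= 0)
        return list(zip(is_.tolist(), js.tolist()))

    @property
    def n_occupied(self) -> int:
        return int(np.count_nonzero(self.spins >= 0))

    def copy(self) -> "LatticeConfig":
        return LatticeConfig(self.width, self.height, self.spins.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LatticeConfig):
            return NotImplemented
        return (self.width == other.width and self.height == other.height
                and bool(np.array_equal(self.spins, other.spins)))

    # -- snapshot TSV ------------------------------------------------------
    def to_tsv(self) -> str:
        """Serialize to the snapshot TSV format (bit-exact round-trip)."""
        buf = io.StringIO()
        buf.write(f"#width\t{self.width}\n#height\t{self.height}\n")
        for j in range(self.height):
            buf.write("\t".join(str(int(v)) for v in self.spins[j]))
            buf.write("\n")
        return buf.getvalue()

    def save_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_tsv())

    @classmethod
    def from_tsv(cls, text: str) -> "LatticeConfig":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if len(lines) < 2 or not lines[0].startswith("#width") \
                or not lines[1].startswith("#height"):
            raise ValueError("malformed snapshot: missing #width/#height header")
        width = int(lines[0].split("\t")[1])
        height = int(lines[1].split("\t")[1])
        rows = [[int(tok) for tok in ln.split("\t")] for ln in lines[2:]]
        if len(rows) != height or any(len(r) != width for r in rows):
            raise ValueError("malformed snapshot: wrong number of rows/columns")
        return cls(width, height, np.array(rows, dtype=np.int8))

    @classmethod
    def load_tsv(cls, path) -> "LatticeConfig":
        with open(path) as fh:
            return cls.from_tsv(fh.read())
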