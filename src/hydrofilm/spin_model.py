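"""The spin-model Hamiltonian of the hydrophobin film.

Proteins are spins with six orientations (60-degree steps) on a periodic
triangular lattice; sites may be vacant.  Three attractive interaction
classes exist between adjacent occupied sites:

* ``TRIMER`` (coupling J0): bonds inside one three-protein trimer,
* ``P6DOCK`` (J1): bonds between neighbouring trimers in the dense P6
  crystal (6 proteins per 7-site cell),
* ``P3DOCK`` (J2): bonds between neighbouring trimers in the low-density P3
  crystal (3 proteins per 4-site cell), present only when P3 ordering is
  enabled.

Every other adjacent orientation pair is forbidden (infinite energy).  Each
occupied site additionally gains the adsorption energy -Jsurf.  The table of
allowed (direction, orientation, orientation) triples is defined
constructively: it contains exactly the triples realized in the two
reference tilings of :mod:`hydrofilm.geometry`, closed under the global
60-degree rotation (orientation +1, direction +1) and bond reciprocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .lattice import DIRS, VACANT, LatticeConfig, opposite

# interaction class codes (also used by the numba kernels)
FORBIDDEN: int = 0
TRIMER: int = 1
P6DOCK: int = 2
P3DOCK: int = 3

CLASS_NAMES = {FORBIDDEN: "forbidden", TRIMER: "trimer",
               P6DOCK: "p6dock", P3DOCK: "p3dock"}


@dataclass(frozen=True)
class ModelParams:
    """Coupling constants (positive magnitudes, in units of kT at beta=1).

    The defaults are the couplings of the film model: trimer bond J0=5,
    P6 docking J1=2, P3 docking J2=1 and adsorption benefit Jsurf=10 (all
    entering the energy with a leading minus sign).  ``p_absent`` is the
    probability that an attempted adsorption finds no protein available
    (0 = saturated subphase).
    """

    J0: float = 5.0
    J1: float = 2.0
    J2: float = 1.0
    Jsurf: float = 10.0
    p3_enabled: bool = True
    p_absent: float = 0.0

    def __post_init__(self) -> None:
        for name in ("J0", "J1", "J2", "Jsurf"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be a nonnegative magnitude")
        if not 0.0 <= self.p_absent <= 1.0:
            raise ValueError("p_absent must lie in [0, 1]")

    @property
    def couplings(self) -> np.ndarray:
        """Coupling magnitude per interaction class code (index = class)."""
        return np.array([0.0, self.J0, self.J1, self.J2])


def _closure(triples: set[tuple[int, int, int]]) -> set[tuple[int, int, int]]:
    """Close a set of (direction, s_i, s_j) triples under the global
    60-degree rotation and bond reciprocity."""
    out = set()
    frontier = set(triples)
    while frontier:
        d, s, t = frontier.pop()
        if (d, s, t) in out:
            continue
        out.add((d, s, t))
        frontier.add(((d + 1) % 6, (s + 1) % 6, (t + 1) % 6))
        frontier.add((opposite(d), t, s))
    return out


def _scan_tiling(cfg: LatticeConfig) -> set[tuple[int, int, int]]:
    """All ordered (direction, s_i, s_j) triples between adjacent occupied
    sites of a configuration."""
    triples = set()
    for j in range(cfg.height):
        for i in range(cfg.width):
            s = cfg.get(i, j)
            if s == VACANT:
                continue
            for d in range(6):
                ni, nj = cfg.neighbor(i, j, d)
                t = cfg.get(ni, nj)
                if t != VACANT:
                    triples.add((d, s, t))
    return triples


def _trimer_triples() -> set[tuple[int, int, int]]:
    """The 12 ordered TRIMER entries: closure of the canonical up-trimer
    bond (direction 0, orientations 0 -> 2)."""
    return _closure({(0, 0, 2)})


@dataclass(frozen=True)
class InteractionTable:
    """Classification of every (direction, s_i, s_j) triple.

    ``cls[d, s_i, s_j]`` is one of the class codes above.  The table is
    reciprocal (``cls[d, s, t] == cls[opposite(d), t, s]``) and rotation
    covariant (``cls[d, s, t] == cls[d+1, s+1, t+1]``).
    """

    cls: np.ndarray
    p3_enabled: bool
    # per-orientation trimer partners: directions and partner orientations
    partner_d: np.ndarray = field(default=None)  # type: ignore[assignment]
    partner_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cls.shape != (6, 6, 6):
            raise ValueError("cls must have shape (6, 6, 6)")
        if self.partner_d is None:
            pd = np.full((6, 2), -1, dtype=np.int64)
            ps = np.full((6, 2), -1, dtype=np.int64)
            for s in range(6):
                entries = [(d, t) for d in range(6) for t in range(6)
                           if self.cls[d, s, t] == TRIMER]
                if len(entries) != 2:
                    raise ValueError(
                        f"orientation {s} must have exactly 2 trimer partners")
                for k, (d, t) in enumerate(entries):
                    pd[s, k] = d
                    ps[s, k] = t
            object.__setattr__(self, "partner_d", pd)
            object.__setattr__(self, "partner_s", ps)

    def classify(self, d: int, s_i: int, s_j: int) -> int:
        return int(self.cls[d, s_i, s_j])

    def is_reciprocal(self) -> bool:
        return all(self.cls[d, s, t] == self.cls[opposite(d), t, s]
                   for d in range(6) for s in range(6) for t in range(6))

    def trimer_sites(self, cfg: LatticeConfig, i: int, j: int):
        """The complete trimer containing site ``(i, j)``, or ``None``.

        An orientation determines its two trimer partners (direction and
        orientation); the trimer is complete when both are present with
        exactly those orientations.
        """
        s = cfg.get(i, j)
        if s == VACANT:
            return None
        sites = [(i, j)]
        for k in range(2):
            d = int(self.partner_d[s, k])
            ni, nj = cfg.neighbor(i, j, d)
            if cfg.get(ni, nj) != int(self.partner_s[s, k]):
                return None
            sites.append((ni, nj))
        return tuple(sites)


def build_interaction_table(p3_enabled: bool = True) -> InteractionTable:
    """Construct the interaction table from the two reference crystals.

    TRIMER entries are the 12 ordered bonds of the canonical up/down trimers.
    P6DOCK entries are the inter-trimer triples realized in the P6 reference
    tiling; P3DOCK entries (only if ``p3_enabled``) are the inter-trimer
    triples of the P3 reference tiling not already claimed.  Everything else
    is forbidden.
    """
    trimer = _trimer_triples()

    p6_all = _scan_tiling(geometry.build_p6_tiling(2, 2))
    p6 = _closure(p6_all - trimer)

    cls = np.zeros((6, 6, 6), dtype=np.uint8)
    for d, s, t in trimer:
        cls[d, s, t] = TRIMER
    for d, s, t in p6:
        cls[d, s, t] = P6DOCK

    if p3_enabled:
        p3_all = _scan_tiling(geometry.build_p3_tiling(2, 2))
        p3 = _closure(p3_all) - trimer - p6
        for d, s, t in p3:
            cls[d, s, t] = P3DOCK

    return InteractionTable(cls=cls, p3_enabled=p3_enabled)


# ---------------------------------------------------------------------------
# energy evaluation
# ---------------------------------------------------------------------------


def bond_census(cfg: LatticeConfig, table: InteractionTable):
    """Counts of unordered adjacent occupied pairs per class, plus occupancy.

    Returns ``(n_trimer, n_p6, n_p3, n_forbidden, n_occupied)``; each
    unordered pair is counted exactly once (directions 0..2 scan each bond
    from one side).
    """
    spins = cfg.spins
    occ = spins >= 0
    counts = {TRIMER: 0, P6DOCK: 0, P3DOCK: 0, FORBIDDEN: 0}
    for d in range(3):
        di, dj = DIRS[d]
        t = np.roll(np.roll(spins, -dj, axis=0), -di, axis=1)
        tocc = np.roll(np.roll(occ, -dj, axis=0), -di, axis=1)
        mask = occ & tocc
        if not mask.any():
            continue
        c = table.cls[d, spins[mask], t[mask]]
        for code in counts:
            counts[code] += int(np.count_nonzero(c == code))
    return (counts[TRIMER], counts[P6DOCK], counts[P3DOCK],
            counts[FORBIDDEN], int(np.count_nonzero(occ)))


def config_energy(cfg: LatticeConfig, table: InteractionTable,
                  mp: ModelParams) -> float:
    """Total energy in kT units: ``-J0*nT - J1*nP6 - J2*nP3 - Jsurf*N``,
    or ``+inf`` if any adjacent occupied pair is forbidden."""
    n_t, n_p6, n_p3, n_forb, n_occ = bond_census(cfg, table)
    if n_forb > 0:
        return float("inf")
    return float(-mp.J0 * n_t - mp.J1 * n_p6 - mp.J2 * n_p3 - mp.Jsurf * n_occ)


# ---------------------------------------------------------------------------
# trial moves and incremental energy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Adsorb:
    i: int
    j: int
    s: int


@dataclass(frozen=True)
class Desorb:
    i: int
    j: int


@dataclass(frozen=True)
class HopRotate:
    """Move the protein at (i, j) to (i2, j2) with new orientation s_new;
    (i2, j2) may equal (i, j) for a pure rotation."""

    i: int
    j: int
    i2: int
    j2: int
    s_new: int


@dataclass(frozen=True)
class TrimerMove:
    """Rigid displacement/rotation of a complete trimer: three old sites,
    three new sites, and the three new orientations (index-aligned)."""

    sites_old: tuple[tuple[int, int], ...]
    sites_new: tuple[tuple[int, int], ...]
    spins_new: tuple[int, ...]


Move = Adsorb | Desorb | HopRotate | TrimerMove


def _site_delta(spins: np.ndarray, table: InteractionTable, mp: ModelParams,
                i: int, j: int, s: int, sign: int) -> float:
    """Energy change of inserting (sign=+1) or removing (sign=-1) a protein
    with orientation ``s`` at ``(i, j)``, given the current grid."""
    h, w = spins.shape
    e = -mp.Jsurf
    J = mp.couplings
    for d in range(6):
        di, dj = DIRS[d]
        t = int(spins[(j + dj) % h, (i + di) % w])
        if t != VACANT:
            code = int(table.cls[d, s, t])
            if code == FORBIDDEN:
                return sign * float("inf")
            e -= J[code]
    return sign * e


def delta_energy(cfg: LatticeConfig, table: InteractionTable, mp: ModelParams,
                 move: Move) -> float:
    """Exact energy difference of applying ``move`` to ``cfg``.

    Equals ``config_energy(after) - config_energy(before)``; infinite when
    the move creates (+inf) or removes (-inf) a forbidden contact.
    """
    spins = cfg.spins.copy()
    w, h = cfg.width, cfg.height
    delta = 0.0

    def occupied(i, j):
        return int(spins[j % h, i % w]) != VACANT

    if isinstance(move, Adsorb):
        if occupied(move.i, move.j):
            raise ValueError("adsorption onto an occupied site")
        if not 0 <= move.s < 6:
            raise ValueError("orientation must be in 0..5")
        return _site_delta(spins, table, mp, move.i, move.j, move.s, +1)

    if isinstance(move, Desorb):
        if not occupied(move.i, move.j):
            raise ValueError("desorption from a vacant site")
        s = int(spins[move.j % h, move.i % w])
        return _site_delta(spins, table, mp, move.i, move.j, s, -1)

    if isinstance(move, HopRotate):
        if not occupied(move.i, move.j):
            raise ValueError("hop/rotate from a vacant site")
        if not 0 <= move.s_new < 6:
            raise ValueError("orientation must be in 0..5")
        same = (move.i2 % w, move.j2 % h) == (move.i % w, move.j % h)
        if not same and occupied(move.i2, move.j2):
            raise ValueError("hop target is occupied")
        s_old = int(spins[move.j % h, move.i % w])
        if same and move.s_new == s_old:
            raise ValueError("null hop/rotate move")
        delta += _site_delta(spins, table, mp, move.i, move.j, s_old, -1)
        spins[move.j % h, move.i % w] = VACANT
        delta += _site_delta(spins, table, mp, move.i2, move.j2, move.s_new, +1)
        return delta

    if isinstance(move, TrimerMove):
        if len(move.sites_old) != 3 or len(move.sites_new) != 3 \
                or len(move.spins_new) != 3:
            raise ValueError("trimer move needs three sites and orientations")
        olds = []
        for (i, j) in move.sites_old:
            if not occupied(i, j):
                raise ValueError("trimer move from a vacant site")
            olds.append(int(spins[j % h, i % w]))
        for (i, j), s_old in zip(move.sites_old, olds):
            delta += _site_delta(spins, table, mp, i, j, s_old, -1)
            spins[j % h, i % w] = VACANT
        for (i, j), s in zip(move.sites_new, move.spins_new):
            if int(spins[j % h, i % w]) != VACANT:
                raise ValueError("trimer move target is occupied")
            delta += _site_delta(spins, table, mp, i, j, s, +1)
            spins[j % h, i % w] = s
        return delta

    raise ValueError(f"malformed move: {move!r}")


def apply_move(cfg: LatticeConfig, move: Move) -> LatticeConfig:
    """Return a copy of ``cfg`` with ``move`` applied (no energy check)."""
    out = cfg.copy()
    if isinstance(move, Adsorb):
        out.set(move.i, move.j, move.s)
    elif isinstance(move, Desorb):
        out.set(move.i, move.j, VACANT)
    elif isinstance(move, HopRotate):
        out.set(move.i, move.j, VACANT)
        out.set(move.i2, move.j2, move.s_new)
    elif isinstance(move, TrimerMove):
        for (i, j) in move.sites_old:
            out.set(i, j, VACANT)
        for (i, j), s in zip(move.sites_new, move.spins_new):
            out.set(i, j, s)
    else:
        raise ValueError(f"malformed move: {move!r}")
    return out
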