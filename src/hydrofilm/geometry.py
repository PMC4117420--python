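"""Hexagonal-lattice geometry and reference crystal tilings.

This module carries the continuous-space reasoning behind the model — the
hexagonal film lattice seen in scattering and microscopy, superlattice vectors
of close-packed protein discs, and the six-parameter description of the
P6-symmetric hexamer (two trimers related by a 2-fold axis) — together with
the two discrete reference tilings on the triangular lattice:

* the P6 ground-state crystal: a sqrt(7) vacancy superlattice whose 7-site
  unit cell holds one "up" trimer and one "down" trimer (6/7 occupancy), and
* the metastable low-density P3 crystal: same-parity trimers on a 2x2
  superlattice (3/4 occupancy).

The tilings define, by construction, which neighbour orientation pairs the
spin model allows (see :mod:`hydrofilm.spin_model`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .lattice import SQRT3, LatticeConfig, rot60

TWO_PI = 2.0 * math.pi

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HexLattice2D:
    """Hexagonal 2D lattice: parameter ``a`` in Angstrom, fixed 120-degree cell."""

    a: float
    gamma: float = 120.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("lattice parameter a must be positive")
        if self.gamma != 120.0:
            raise ValueError("gamma is fixed at 120 degrees")


@dataclass(frozen=True)
class SuperlatticeIndex:
    """Integer coefficients of a triangular-lattice translation m*e1 + n*e2."""

    m: int
    n: int

    def __post_init__(self) -> None:
        if self.m == 0 and self.n == 0:
            raise ValueError("superlattice index (0, 0) is not a translation")


@dataclass(frozen=True)
class DiscPacking:
    """Close packing of protein discs of diameter ``d`` (Angstrom, default 20)."""

    d: float = 20.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("disc diameter must be positive")


@dataclass(frozen=True)
class P6Params:
    """Six-parameter description of the two-trimer (hexamer) arrangement.

    ``euler`` are the angles of a protein relative to the radial axis from its
    trimer center; in the planar model only the in-plane angle ``euler[0]`` is
    active and the two out-of-plane angles must be zero.  ``r_trimer`` is the
    protein-to-trimer-center distance, ``d_trimers`` the distance between the
    two trimer centers (both Angstrom), and ``psi`` the rotation angle of the
    two trimers about their own centers relative to the inter-trimer axis.
    """

    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)
    r_trimer: float = 20.0
    d_trimers: float = 35.0
    psi: float = 0.0

    def __post_init__(self) -> None:
        if not self.r_trimer > 0:
            raise ValueError("r_trimer must be positive")
        if not self.d_trimers > 0:
            raise ValueError("d_trimers must be positive")
        if len(self.euler) != 3:
            raise ValueError("euler must have three components")
        if self.euler[1] != 0.0 or self.euler[2] != 0.0:
            raise ValueError("out-of-plane Euler angles must be 0 in the planar model")


@dataclass(frozen=True)
class Pose2D:
    """Planar rigid-body placement of one protein: position (Angstrom) + angle."""

    x: float
    y: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", self.theta % TWO_PI)


# ---------------------------------------------------------------------------
# lattice-vector arithmetic
# ---------------------------------------------------------------------------


def hex_lattice_vectors(lat: HexLattice2D) -> tuple[np.ndarray, np.ndarray]:
    """3-component lattice vectors of a hexagonal lattice, a-vector along x.

    The b-vector is rotated 120 degrees counterclockwise from the x axis.
    Components are reported to 3 decimals.
    """
    a = lat.a
    va = np.round(np.array([a, 0.0, 0.0]), 3)
    vb = np.round(np.array([-a / 2.0, a * SQRT3 / 2.0, 0.0]), 3)
    return va, vb


def superlattice_length(pack: DiscPacking, idx: SuperlatticeIndex) -> float:
    """Length (Angstrom) of the superlattice translation m*e1 + n*e2.

    On a triangular lattice of touching discs of diameter ``d`` this is
    ``d * sqrt(m^2 + m*n + n^2)``.
    """
    m, n = idx.m, idx.n
    return pack.d * math.sqrt(m * m + m * n + n * n)


def sites_per_supercell(idx: SuperlatticeIndex) -> int:
    """Number of base-lattice sites per supercell of index ``(m, n)``."""
    m, n = idx.m, idx.n
    return m * m + m * n + n * n


# ---------------------------------------------------------------------------
# reference tilings
# ---------------------------------------------------------------------------

#: generators of the sqrt(7) vacancy superlattice
SQRT7_GENERATORS: tuple[tuple[int, int], tuple[int, int]] = ((2, 1), (-1, 3))

#: transversal of the sqrt(7) lattice: the 7 sites of one P6 unit cell.
#: index 0 is the vacancy; the rest carry the canonical decoration below.
P6_CELL_SITES: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 1), (0, 2), (1, 0), (2, 0), (2, -1))

#: canonical P6 decoration: up trimer (even orientations) and down trimer
#: (odd orientations, the 180-degree image, i.e. +3 mod 6).
P6_DECORATION: dict[tuple[int, int], int] = {
    (0, 1): 0, (1, 1): 2, (0, 2): 4,       # up trimer
    (1, 0): 5, (2, 0): 3, (2, -1): 1,      # down trimer
}

#: canonical P3 decoration on the 2x2 superlattice, "up" parity; the (1, 1)
#: offset of each 2x2 cell is vacant.
P3_DECORATION_UP: dict[tuple[int, int], int] = {(0, 0): 0, (1, 0): 2, (0, 1): 4}


def in_sqrt7_lattice(m: int, n: int) -> bool:
    """Whether the axial vector ``(m, n)`` is a sqrt(7) superlattice translation."""
    return (3 * m + n) % 7 == 0 and (2 * n - m) % 7 == 0


def _p6_decoration(vacancy_sublattice: int, spin_offset: int) -> dict[tuple[int, int], int]:
    """Decorated 7-site cell, rotated by ``spin_offset`` * 60 degrees about the
    vacancy and translated to the chosen vacancy sublattice."""
    tx, ty = P6_CELL_SITES[vacancy_sublattice]
    out: dict[tuple[int, int], int] = {}
    for (oi, oj), orient in P6_DECORATION.items():
        ri, rj = rot60((oi, oj), spin_offset)
        out[(ri + tx, rj + ty)] = (orient + spin_offset) % 6
    return out


def build_p6_tiling(cells_x: int, cells_y: int, vacancy_sublattice: int = 0,
                    spin_offset: int = 0) -> LatticeConfig:
    """Construct the P6 ground-state crystal on a ``7*cells_x x 7*cells_y`` box.

    Vacancies sit on the sqrt(7) superlattice translated to the chosen
    sublattice (0..6); each 7-site cell holds an up trimer carrying the even
    orientation triple and a down trimer carrying the odd triple, globally
    rotated by ``spin_offset`` (0..5).  Occupancy is exactly 6/7.
    """
    if cells_x < 1 or cells_y < 1:
        raise ValueError("need at least one 7-site cell per direction")
    if not 0 <= vacancy_sublattice <= 6:
        raise ValueError("vacancy_sublattice must be in 0..6")
    if not 0 <= spin_offset <= 5:
        raise ValueError("spin_offset must be in 0..5")
    width, height = 7 * cells_x, 7 * cells_y
    deco = _p6_decoration(vacancy_sublattice, spin_offset)
    # residue lookup mod 7 (the sqrt(7) lattice is periodic on 7x7 sites)
    lut = np.full((7, 7), -1, dtype=np.int8)
    for a in range(7):
        for b in range(7):
            for (pi, pj), orient in deco.items():
                if in_sqrt7_lattice(a - pi, b - pj):
                    lut[a, b] = orient
                    break
    cfg = LatticeConfig(width, height)
    for j in range(height):
        for i in range(width):
            cfg.spins[j, i] = lut[i % 7, j % 7]
    return cfg


def build_p3_tiling(cells_x: int, cells_y: int, phase: int = 0,
                    parity: str = "up") -> LatticeConfig:
    """Construct the low-density P3 crystal on a ``2*cells_x x 2*cells_y`` box.

    Same-parity trimers sit on the 2x2 site superlattice (one three-protein
    trimer per cell, occupancy exactly 3/4).  ``parity="down"`` gives the
    180-degree image (odd orientations); ``phase`` (0..3) translates the
    pattern among the four 2x2 cosets.
    """
    if cells_x < 1 or cells_y < 1:
        raise ValueError("need at least one 2x2 cell per direction")
    if not 0 <= phase <= 3:
        raise ValueError("phase must be in 0..3")
    if parity not in ("up", "down"):
        raise ValueError("parity must be 'up' or 'down'")
    width, height = 2 * cells_x, 2 * cells_y
    tx, ty = ((0, 0), (1, 0), (0, 1), (1, 1))[phase]
    deco: dict[tuple[int, int], int] = {}
    for (oi, oj), orient in P3_DECORATION_UP.items():
        if parity == "down":
            oi, oj = rot60((oi, oj), 3)
            orient = (orient + 3) % 6
        deco[((oi + tx) % 2, (oj + ty) % 2)] = orient
    cfg = LatticeConfig(width, height)
    for j in range(height):
        for i in range(width):
            cfg.spins[j, i] = deco.get((i % 2, j % 2), -1)
    return cfg


def commensurate_cell(max_l: int = 100) -> tuple[int, int]:
    """Smallest square site box periodic for both reference crystals.

    Found by exhaustive search over the box side: the sqrt(7) vacancy lattice
    needs both ``(L, 0)`` and ``(0, L)`` to be superlattice translations
    (smallest ``L = 7``); the P3 superlattice needs ``L`` even.  The joint
    minimum is ``(14, 14)``.
    """
    for L in range(1, max_l + 1):
        if in_sqrt7_lattice(L, 0) and in_sqrt7_lattice(0, L) and L % 2 == 0:
            return (L, L)
    raise RuntimeError("no commensurate box found in search range")


# ---------------------------------------------------------------------------
# continuous-space P6 hexamer parameterization
# ---------------------------------------------------------------------------


def p6_generate_poses(params: P6Params) -> list[Pose2D]:
    """Ideal poses of the six proteins of a P6 hexamer.

    Trimer 1 sits at distance ``d_trimers/2`` left of the origin along the x
    axis, its three proteins at distance ``r_trimer`` from the trimer center
    at 120-degree spacing starting from angle ``psi``; each protein's in-plane
    orientation is its radial angle plus ``euler[0]``.  Trimer 2 is the
    180-degree rotation of trimer 1 about the origin (the 2-fold axis of the
    plane group).  Poses 0..2 are trimer 1, poses 3..5 trimer 2.
    """
    e0 = params.euler[0]
    r, d, psi = params.r_trimer, params.d_trimers, params.psi
    c1 = np.array([-d / 2.0, 0.0])
    poses: list[Pose2D] = []
    for k in range(3):
        ang = psi + k * TWO_PI / 3.0
        p = c1 + r * np.array([math.cos(ang), math.sin(ang)])
        poses.append(Pose2D(p[0], p[1], ang + e0))
    for k in range(3):
        q = poses[k]
        poses.append(Pose2D(-q.x, -q.y, q.theta + math.pi))
    return poses


def _circ_mean(angles: np.ndarray, period: float) -> float:
    """Mean of angles on a circle of the given period."""
    scale = TWO_PI / period
    z = np.exp(1j * scale * np.asarray(angles)).mean()
    if abs(z) < 1e-12:
        raise ValueError("degenerate angular configuration")
    return float(np.angle(z) / scale)


def p6_extract_params(
    poses: list[Pose2D],
    trimer_assignment: tuple[int, ...] = (0, 0, 0, 1, 1, 1),
) -> tuple[P6Params, float]:
    """Least-squares P6 parameters of six poses, and the residual deviation.

    The six poses are split 3+3 into two trimers by ``trimer_assignment``.
    Parameters are averaged over all symmetry-equivalent copies (both trimers,
    all three 120-degree positions); ``psi`` and ``euler[0]`` are identifiable
    modulo the 3-fold trimer symmetry and the full turn respectively.  The
    deviation is the root-mean-square distance between the input positions
    and the regenerated ideal P6 positions after optimal rigid superposition,
    so it is invariant under global rotation/translation of the input.
    """
    if len(poses) != 6:
        raise ValueError("exactly six poses are required")
    if len(trimer_assignment) != 6 or sorted(trimer_assignment).count(0) != 3 \
            or sorted(trimer_assignment).count(1) != 3:
        raise ValueError("trimer_assignment must assign 3 poses to each trimer")

    z = np.array([p.x + 1j * p.y for p in poses])
    th = np.array([p.theta for p in poses])
    lab = np.asarray(trimer_assignment)
    c1 = z[lab == 0].mean()
    c2 = z[lab == 1].mean()
    if abs(c2 - c1) < 1e-9:
        raise ValueError("degenerate input: trimer centers coincide")
    m = (c1 + c2) / 2.0
    axis = np.angle(c2 - c1)

    # gauge-fix: midpoint at origin, inter-trimer axis along +x
    zg = (z - m) * np.exp(-1j * axis)
    thg = th - axis
    # fold trimer 2 onto trimer 1 through the 2-fold axis
    zf = np.where(lab == 0, zg, -zg)
    thf = np.where(lab == 0, thg, thg + math.pi)

    d = float(abs(c2 - c1))
    c1g = -d / 2.0 + 0.0j
    rel = zf - c1g
    radii = np.abs(rel)
    if np.any(radii < 1e-9):
        raise ValueError("degenerate input: pose coincides with trimer center")
    phi = np.angle(rel)
    r = float(radii.mean())
    psi = _circ_mean(phi, TWO_PI / 3.0)
    e0 = _circ_mean(thf - phi, TWO_PI)
    params = P6Params(euler=(e0 % TWO_PI, 0.0, 0.0), r_trimer=r,
                      d_trimers=d, psi=psi % (TWO_PI / 3.0))

    # regenerate ideal positions in the gauge-fixed frame with the input's
    # own 120-degree slot assignment, then superpose optimally onto the input
    k = np.round((phi - psi) / (TWO_PI / 3.0)).astype(int) % 3
    ideal_f = c1g + r * np.exp(1j * (psi + k * TWO_PI / 3.0))
    ideal_g = np.where(lab == 0, ideal_f, -ideal_f)
    ideal = ideal_g * np.exp(1j * axis) + m

    # 2D Procrustes (rotation + translation) of ideal onto input
    xc = z - z.mean()
    yc = ideal - ideal.mean()
    cross = np.vdot(yc, xc)  # sum conj(yc) * xc
    rot = cross / abs(cross) if abs(cross) > 1e-15 else 1.0
    resid = xc - rot * yc
    deviation = float(np.sqrt(np.mean(np.abs(resid) ** 2)))
    return params, deviation
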