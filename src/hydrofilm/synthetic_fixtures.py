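"""Synthetic configurations with the statistical structure the analysis assumes.

Generators for the inputs the simulation study needs: empty lattices, random
adsorbate gases (rejection-sampled so no forbidden contact exists),
crystalline P6/P3 patches, two-domain configurations with a vacant seam
(the geometry in which metastable P3 links can glue neighbouring domains),
and defected crystals.  All fixtures are bit-reproducible from their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels, geometry
from .lattice import VACANT, LatticeConfig
from .spin_model import InteractionTable, ModelParams


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative description of a synthetic configuration."""

    kind: str                       # empty | random_gas | p6_patch | p3_patch
    #                               # | two_domain | defected
    cells: int = 2                  # 14x14-site cells per side
    density: float = 0.3            # random_gas target density
    defect_fraction: float = 0.0    # defected: per-site removal probability
    gap: int = 2                    # two_domain seam width, sites
    sublattices: tuple[int, int] = (0, 1)   # two_domain vacancy sublattices
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("empty", "random_gas", "p6_patch", "p3_patch",
                             "two_domain", "defected"):
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if not 0.0 <= self.density <= 1.0:
            raise ValueError("density must lie in [0, 1]")
        if not 0.0 <= self.defect_fraction < 1.0:
            raise ValueError("defect_fraction must lie in [0, 1)")

    def make(self, table: InteractionTable) -> LatticeConfig:
        n = 14 * self.cells
        if self.kind == "empty":
            return LatticeConfig(n, n)
        if self.kind == "random_gas":
            return make_random_config(n, n, self.density, self.seed, table)
        if self.kind == "p6_patch":
            return geometry.build_p6_tiling(2 * self.cells, 2 * self.cells)
        if self.kind == "p3_patch":
            return geometry.build_p3_tiling(7 * self.cells, 7 * self.cells)
        if self.kind == "two_domain":
            a, b = self.sublattices
            return make_two_domain_config(self.cells, self.cells, a, b,
                                          self.gap, self.seed)
        return make_defected_tiling("p6", self.cells, self.defect_fraction,
                                    self.seed)


def make_random_config(width: int, height: int, density: float, seed: int,
                       table: InteractionTable) -> LatticeConfig:
    """Random adsorbate gas by sequential rejection sampling.

    Proteins with uniform random orientation are inserted at uniform random
    vacant sites, rejecting any insertion that would create a forbidden
    contact, until the target density is reached or attempts saturate
    (30 per site).  The result always has finite energy; the achieved
    density is simply ``cfg.n_occupied / (width * height)``.
    """
    if not 0.0 <= density <= 1.0:
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    cfg = LatticeConfig(width, height)
    target = int(round(density * width * height))
    J = ModelParams().couplings
    attempts = 0
    max_attempts = 30 * width * height
    placed = 0
    while placed < target and attempts < max_attempts:
        attempts += 1
        i = int(rng.integers(width))
        j = int(rng.integers(height))
        if cfg.spins[j, i] != VACANT:
            continue
        s = int(rng.integers(6))
        de = _kernels.insert_delta(cfg.spins, table.cls, J, 10.0, i, j, s)
        if not np.isfinite(de):
            continue
        cfg.spins[j, i] = s
        placed += 1
    return cfg


def make_two_domain_config(cells_x: int, cells_y: int, sublattice_a: int,
                           sublattice_b: int, gap: int, seed: int = 0,
                           ) -> LatticeConfig:
    """Two P6 crystal domains on different vacancy sublattices, separated by
    vacant vertical strips of the given width (two strips, by periodicity).

    The two crystals are distinct clusters; the configuration has finite
    energy for any sublattice pair because the domains never touch.
    """
    if sublattice_a == sublattice_b:
        raise ValueError("the two domains must use different sublattices")
    if gap < 1:
        raise ValueError("gap must be at least 1 site")
    width, height = 14 * cells_x, 14 * cells_y
    half = width // 2
    if gap >= half:
        raise ValueError("gap too wide for the box")
    a = geometry.build_p6_tiling(2 * cells_x, 2 * cells_y, sublattice_a)
    b = geometry.build_p6_tiling(2 * cells_x, 2 * cells_y, sublattice_b)
    cfg = LatticeConfig(width, height)
    cfg.spins[:, 0:half - gap] = a.spins[:, 0:half - gap]
    cfg.spins[:, half:width - gap] = b.spins[:, half:width - gap]
    return cfg


def make_defected_tiling(base: str, cells: int, defect_fraction: float,
                         seed: int) -> LatticeConfig:
    """Reference crystal with occupied sites independently removed with the
    given probability (site dilution)."""
    if base not in ("p6", "p3"):
        raise ValueError("base must be 'p6' or 'p3'")
    if not 0.0 <= defect_fraction < 1.0:
        raise ValueError("defect_fraction must lie in [0, 1)")
    if base == "p6":
        cfg = geometry.build_p6_tiling(2 * cells, 2 * cells)
    else:
        cfg = geometry.build_p3_tiling(7 * cells, 7 * cells)
    if defect_fraction == 0.0:
        return cfg
    rng = np.random.default_rng(seed)
    occ = cfg.spins >= 0
    kill = occ & (rng.random(cfg.spins.shape) < defect_fraction)
    cfg.spins[kill] = VACANT
    return cfg


# ---------------------------------------------------------------------------
# planted growth series (ground truth for the classifier)
# ---------------------------------------------------------------------------


def planted_series(kind: str, seed: int, n: int = 100, noise: float = 0.05):
    """A synthetic largest-cluster time series with a known growth law.

    ``kind="linear"``: size = a + b t with additive Gaussian noise (sd =
    ``noise`` x mean size).  ``kind="exponential"``: size = y0 * exp(r t)
    with multiplicative log-normal noise (sd of log = ``noise``).
    Occupancy is constant and nothing percolates, so the steady-state
    window is the full series.
    """
    from .mc_engine import TimeSeries

    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    if kind == "linear":
        a = rng.uniform(20.0, 100.0)
        b = rng.uniform(1.0, 5.0)
        y = a + b * t
        y = y + rng.normal(0.0, max(noise * y.mean(), 1e-9), size=n)
        y = np.maximum(y, 1.0)
    elif kind == "exponential":
        y0 = rng.uniform(2.0, 20.0)
        r = rng.uniform(0.02, 0.06)
        y = y0 * np.exp(r * t) * np.exp(rng.normal(0.0, noise, size=n))
    else:
        raise ValueError("kind must be 'linear' or 'exponential'")
    nocc = float(np.ceil(y.max())) + 1.0
    df = pd.DataFrame({
        "sweep": t.astype(int), "n_occupied": nocc, "largest_cluster": y,
        "energy": 0.0, "n_trimer": 0, "n_p6": 0, "n_p3": 0, "percolated": 0,
    })
    return TimeSeries(df)
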