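"""Metropolis Monte Carlo dynamics with protein-mimicking trial moves.

Three move classes model how hydrophobins reach and explore the interface:

1. adsorption/desorption — a protein rising to the surface (with a uniform
   random orientation) or leaving it,
2. a single protein hopping to a vacant neighbour site and/or rotating by
   60 degrees,
3. a complete, tightly bound trimer translating one lattice site and/or
   rigidly rotating by 60 degrees (about one of its three vertices).

One sweep is ``width * height`` attempted moves.  Acceptance is Metropolis
with a Hastings factor of 6 on adsorption/desorption (an insertion proposes
one of six orientations), so the chain is in detailed balance with respect
to ``exp(-beta * E)`` over configurations.  Insertions may additionally be
thinned with probability ``p_absent`` ("no protein available"), modelling a
subsaturated subphase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import VACANT, LatticeConfig, rot60
from .spin_model import (Adsorb, Desorb, HopRotate, InteractionTable,
                         ModelParams, Move, TrimerMove, config_energy)

TS_COLUMNS = ["sweep", "n_occupied", "largest_cluster", "energy",
              "n_trimer", "n_p6", "n_p3", "percolated"]


@dataclass(frozen=True)
class MCParams:
    """Run-control parameters: sweep count, seed, inverse temperature,
    move-class weights (adsorb/desorb, hop/rotate, trimer) and recording
    cadence."""

    sweeps: int
    seed: int = 0
    beta: float = 1.0
    move_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.sweeps < 0:
            raise ValueError("sweeps must be nonnegative")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if len(self.move_mix) != 3 or any(w < 0 for w in self.move_mix) \
                or sum(self.move_mix) <= 0:
            raise ValueError("move_mix weights must be nonnegative, sum > 0")
        if self.beta < 0:
            raise ValueError("beta must be nonnegative")

    @property
    def weights(self) -> tuple[float, float, float]:
        tot = sum(self.move_mix)
        return tuple(w / tot for w in self.move_mix)  # type: ignore[return-value]


@dataclass
class TimeSeries:
    """Per-record observables of a run, stored as a DataFrame with columns
    sweep, n_occupied, largest_cluster, energy, n_trimer, n_p6, n_p3,
    percolated (0/1)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.data.columns) != TS_COLUMNS:
            raise ValueError(f"TimeSeries columns must be {TS_COLUMNS}")
        sw = self.data["sweep"].to_numpy()
        if len(sw) and np.any(np.diff(sw) <= 0):
            raise ValueError("sweeps must be strictly increasing")
        if np.any(self.data["largest_cluster"] > self.data["n_occupied"]):
            raise ValueError("largest_cluster cannot exceed n_occupied")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeSeries":
        return cls(pd.read_csv(path)[TS_COLUMNS])


def _masked_seed(seed: int) -> int:
    return int(seed) & 0x7FFFFFFF


def run_simulation(initial: LatticeConfig, table: InteractionTable,
                   mp: ModelParams, mc: MCParams,
                   ) -> tuple[TimeSeries, LatticeConfig]:
    """Run ``mc.sweeps`` sweeps of Metropolis dynamics from ``initial``.

    Returns the recorded observable time series and the final configuration.
    Fully reproducible from ``mc.seed``; raises on an infinite-energy start.
    """
    e0 = config_energy(initial, table, mp)
    if not np.isfinite(e0):
        raise ValueError("initial configuration has a forbidden contact")
    spins = initial.spins.copy()
    w_ads, w_hop, _ = mc.weights
    recs = _kernels.run_mc(
        spins, table.cls, mp.couplings, mp.Jsurf, mc.beta, mp.p_absent,
        w_ads, w_hop, mc.sweeps, _masked_seed(mc.seed), mc.record_every,
        table.partner_d, table.partner_s)
    data = pd.DataFrame({
        "sweep": recs[0], "n_occupied": recs[1], "largest_cluster": recs[2],
        "energy": recs[3], "n_trimer": recs[4], "n_p6": recs[5],
        "n_p3": recs[6], "percolated": recs[7].astype(np.int64),
    })
    final = LatticeConfig(initial.width, initial.height, spins)
    return TimeSeries(data), final


def quench(cfg: LatticeConfig, table: InteractionTable, mp: ModelParams,
           seed: int = 0, max_sweeps: int = 10_000) -> LatticeConfig:
    """Zero-temperature relaxation: only strictly energy-lowering moves are
    accepted; stops after the first sweep in which nothing is accepted."""
    e0 = config_energy(cfg, table, mp)
    if not np.isfinite(e0):
        raise ValueError("initial configuration has a forbidden contact")
    spins = cfg.spins.copy()
    mc = MCParams(sweeps=0)  # default move mix
    w_ads, w_hop, _ = mc.weights
    _kernels.run_quench(spins, table.cls, mp.couplings, mp.Jsurf,
                        mp.p_absent, w_ads, w_hop, _masked_seed(seed),
                        max_sweeps, table.partner_d, table.partner_s)
    return LatticeConfig(cfg.width, cfg.height, spins)


# ---------------------------------------------------------------------------
# exhaustive move enumeration (for local-minimum / metastability analysis)
# ---------------------------------------------------------------------------


def enumerate_moves(cfg: LatticeConfig, table: InteractionTable,
                    include_trimer: bool = True) -> list[Move]:
    """Every distinct single trial move applicable to ``cfg``.

    Covers all adsorptions (vacant site x 6 orientations), desorptions,
    hop/rotate proposals onto vacant targets, and — optionally — all rigid
    trimer translations/rotations whose target sites are free.  Used by the
    ground-state and metastability checks.
    """
    w, h = cfg.width, cfg.height
    moves: list[Move] = []
    for j in range(h):
        for i in range(w):
            s = cfg.get(i, j)
            if s == VACANT:
                for k in range(6):
                    moves.append(Adsorb(i, j, k))
                continue
            moves.append(Desorb(i, j))
            for mv in range(7):
                for rot in (0, 1, -1):
                    if mv == 0 and rot == 0:
                        continue
                    if mv == 0:
                        i2, j2 = i, j
                    else:
                        i2, j2 = cfg.neighbor(i, j, mv - 1)
                        if cfg.get(i2, j2) != VACANT:
                            continue
                    moves.append(HopRotate(i, j, i2, j2, (s + rot) % 6))
    if not include_trimer:
        return moves
    seen: set[frozenset] = set()
    for j in range(h):
        for i in range(w):
            tr = table.trimer_sites(cfg, i, j)
            if tr is None or frozenset(tr) in seen:
                continue
            seen.add(frozenset(tr))
            sites = list(tr)
            spins0 = [cfg.get(a, b) for a, b in sites]
            from .lattice import DIRS
            for t in range(7):
                for rot in (0, 1, -1):
                    pivots = range(3) if rot != 0 else (0,)
                    for piv in pivots:
                        if t == 0 and rot == 0:
                            continue
                        ti, tj = (0, 0) if t == 0 else DIRS[t - 1]
                        px, py = sites[piv]
                        new = []
                        for (a, b) in sites:
                            ra, rb = a - px, b - py
                            ra = (ra + w // 2) % w - w // 2
                            rb = (rb + h // 2) % h - h // 2
                            ra, rb = rot60((ra, rb), rot % 6)
                            new.append(((px + ra + ti) % w, (py + rb + tj) % h))
                        if len(set(new)) < 3:
                            continue
                        old_mod = {(a % w, b % h) for a, b in sites}
                        if any(cfg.get(a, b) != VACANT and (a, b) not in old_mod
                               for a, b in new):
                            continue
                        moves.append(TrimerMove(
                            tuple(sites), tuple(new),
                            tuple((sp + rot) % 6 for sp in spins0)))
    return moves
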