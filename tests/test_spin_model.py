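"""Interaction table structure, energies and incremental-move bookkeeping."""

import numpy as np
import pytest

from hydrofilm import geometry as geo
from hydrofilm import spin_model as sm
from hydrofilm.lattice import DIRS, VACANT, LatticeConfig, opposite
from hydrofilm.mc_engine import enumerate_moves
from hydrofilm.synthetic_fixtures import make_random_config


# ---------------------------------------------------------------------------
# table structure
# ---------------------------------------------------------------------------

def test_trimer_entries_count(table_p3, table_p6):
    for tab in (table_p3, table_p6):
        assert int((tab.cls == sm.TRIMER).sum()) == 12


def test_every_orientation_has_two_trimer_partners(table_p3):
    for s in range(6):
        assert int((table_p3.cls[:, s, :] == sm.TRIMER).sum()) == 2


def test_reciprocity_over_all_216_triples(table_p3, table_p6):
    for tab in (table_p3, table_p6):
        for d in range(6):
            for s in range(6):
                for t in range(6):
                    assert tab.cls[d, s, t] == tab.cls[opposite(d), t, s]
        assert tab.is_reciprocal()


def test_rotation_covariance(table_p3):
    c = table_p3.cls
    for d in range(6):
        for s in range(6):
            for t in range(6):
                assert c[d, s, t] == c[(d + 1) % 6, (s + 1) % 6, (t + 1) % 6]


def test_p6_only_table_has_no_p3_entries(table_p3, table_p6):
    assert int((table_p6.cls == sm.P3DOCK).sum()) == 0
    # triples that are P3DOCK in the full table are forbidden without P3
    p3_mask = table_p3.cls == sm.P3DOCK
    assert p3_mask.any()
    assert np.all(table_p6.cls[p3_mask] == sm.FORBIDDEN)
    # the TRIMER and P6DOCK entries coincide between the two tables
    for code in (sm.TRIMER, sm.P6DOCK):
        assert np.array_equal(table_p3.cls == code, table_p6.cls == code)


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def _isolated_trimer(width=8, height=8):
    cfg = LatticeConfig(width, height)
    for (i, j), s in geo.P6_DECORATION.items():
        if s in (0, 2, 4):     # the canonical up trimer
            cfg.set(i, j, s)
    return cfg


def test_energy_examples(table_p3, default_params):
    mp = default_params
    empty = LatticeConfig(6, 6)
    assert sm.config_energy(empty, table_p3, mp) == 0.0
    one = LatticeConfig(6, 6)
    one.set(2, 2, 3)
    assert sm.config_energy(one, table_p3, mp) == -10.0
    trimer = _isolated_trimer()
    # 3 trimer bonds x J0=5 plus 3 sites x Jsurf=10
    assert sm.config_energy(trimer, table_p3, mp) == -45.0


def test_bond_census_examples(table_p3):
    empty = LatticeConfig(6, 6)
    assert sm.bond_census(empty, table_p3) == (0, 0, 0, 0, 0)
    p6 = geo.build_p6_tiling(1, 1)
    nt, np6, np3, nforb, nocc = sm.bond_census(p6, table_p3)
    assert (nt, nforb, nocc) == (42, 0, 42)
    p3 = geo.build_p3_tiling(7, 7)
    nt, np6, np3, nforb, nocc = sm.bond_census(p3, table_p3)
    assert nforb == 0 and np3 > 0


def test_forbidden_contact_gives_infinite_energy(table_p3, default_params):
    cfg = LatticeConfig(6, 6)
    cfg.set(0, 0, 0)
    for s in range(6):
        if table_p3.classify(0, 0, s) == sm.FORBIDDEN:
            cfg.set(1, 0, s)
            break
    else:
        pytest.skip("no forbidden partner found (table degenerate)")
    assert sm.config_energy(cfg, table_p3, default_params) == float("inf")
    assert sm.bond_census(cfg, table_p3)[3] == 1


def test_energy_extensivity(table_p3, default_params):
    base = geo.build_p6_tiling(1, 1)
    e1 = sm.config_energy(base, table_p3, default_params)
    for k in (2, 3):
        big = LatticeConfig(7 * k, 7 * k, np.tile(base.spins, (k, k)))
        ek = sm.config_energy(big, table_p3, default_params)
        assert ek == pytest.approx(k * k * e1, rel=1e-12)


def test_no_site_exceeds_two_trimer_bonds(table_p3):
    """Finite-energy configurations never give a site >2 trimer bonds."""
    for seed in range(5):
        cfg = make_random_config(20, 20, 0.5, seed, table_p3)
        for (i, j) in cfg.occupied_sites():
            s = cfg.get(i, j)
            count = 0
            for d in range(6):
                ni, nj = cfg.neighbor(i, j, d)
                t = cfg.get(ni, nj)
                if t >= 0:
                    assert table_p3.classify(d, s, t) != sm.FORBIDDEN
                    if table_p3.classify(d, s, t) == sm.TRIMER:
                        count += 1
            assert count <= 2


# ---------------------------------------------------------------------------
# incremental energies
# ---------------------------------------------------------------------------

def test_delta_energy_examples(table_p3, default_params):
    mp = default_params
    empty = LatticeConfig(8, 8)
    assert sm.delta_energy(empty, table_p3, mp, sm.Adsorb(3, 3, 2)) == -10.0
    trimer = _isolated_trimer()
    site = next(iter(
        (i, j) for (i, j), s in geo.P6_DECORATION.items() if s in (0, 2, 4)))
    d = sm.delta_energy(trimer, table_p3, mp, sm.Desorb(*site))
    # loses 2 trimer bonds (2 x 5) and one adsorbed site (10)
    assert d == 20.0
    after = sm.apply_move(trimer, sm.Desorb(*site))
    assert sm.config_energy(after, table_p3, mp) \
        - sm.config_energy(trimer, table_p3, mp) == d


@pytest.mark.parametrize("density", [0.2, 0.45])
def test_delta_energy_matches_full_recompute(table_p3, default_params, density):
    """1000 random moves against the full-energy oracle."""
    rng = np.random.default_rng(int(density * 100))
    mp = default_params
    checked = 0
    seed = 0
    while checked < 1000:
        seed += 1
        cfg = make_random_config(12, 12, density, seed, table_p3)
        moves = enumerate_moves(cfg, table_p3)
        if not moves:
            continue
        e0 = sm.config_energy(cfg, table_p3, mp)
        for idx in rng.choice(len(moves), size=min(25, len(moves)),
                              replace=False):
            move = moves[int(idx)]
            d = sm.delta_energy(cfg, table_p3, mp, move)
            e1 = sm.config_energy(sm.apply_move(cfg, move), table_p3, mp)
            if np.isinf(d):
                assert np.isinf(e1)
            else:
                assert abs(d - (e1 - e0)) < 1e-9
            checked += 1


def test_delta_energy_rejects_malformed_moves(table_p3, default_params):
    cfg = LatticeConfig(6, 6)
    cfg.set(1, 1, 0)
    with pytest.raises(ValueError):
        sm.delta_energy(cfg, table_p3, default_params, sm.Adsorb(1, 1, 0))
    with pytest.raises(ValueError):
        sm.delta_energy(cfg, table_p3, default_params, sm.Desorb(2, 2))
    with pytest.raises(ValueError):
        sm.delta_energy(cfg, table_p3, default_params, sm.Adsorb(0, 0, 9))
    with pytest.raises(ValueError):
        sm.delta_energy(cfg, table_p3, default_params, "hop")


# ---------------------------------------------------------------------------
# ground states and metastability
# ---------------------------------------------------------------------------

def test_p6_tiling_is_strict_local_minimum(table_p3, table_p6):
    """No single move of any class lowers the P6 crystal's energy."""
    cfg = geo.build_p6_tiling(1, 1)
    for tab, mp in ((table_p3, sm.ModelParams()),
                    (table_p6, sm.ModelParams(p3_enabled=False))):
        deltas = [sm.delta_energy(cfg, tab, mp, m)
                  for m in enumerate_moves(cfg, tab)]
        assert deltas
        assert min(deltas) > 0


def test_seven_p6_ground_states_are_degenerate(table_p3, default_params):
    energies = [sm.config_energy(geo.build_p6_tiling(2, 2, s), table_p3,
                                 default_params) for s in range(7)]
    ref = energies[0]
    assert all(abs(e - ref) <= 1e-12 * abs(ref) for e in energies)


def test_p3_tiling_is_metastable(table_p3, default_params):
    """Every single move applied to the low-density P3 crystal raises the
    energy (exhaustive enumeration on the 14x14 commensurate box)."""
    cfg = geo.build_p3_tiling(7, 7)
    deltas = [sm.delta_energy(cfg, table_p3, default_params, m)
              for m in enumerate_moves(cfg, table_p3)]
    assert deltas
    assert min(deltas) > 0


def test_p3_tiling_is_not_stable_without_p3_interactions(table_p6):
    """Under the P6-only table the P3 tiling contains forbidden contacts."""
    cfg = geo.build_p3_tiling(7, 7)
    assert sm.config_energy(cfg, table_p6,
                            sm.ModelParams(p3_enabled=False)) == float("inf")


# ---------------------------------------------------------------------------
# snapshot format
# ---------------------------------------------------------------------------

def test_snapshot_tsv_round_trip(tmp_path, table_p3):
    cfg = make_random_config(9, 5, 0.4, 7, table_p3)
    text = cfg.to_tsv()
    back = LatticeConfig.from_tsv(text)
    assert back == cfg
    assert back.to_tsv() == text
    path = tmp_path / "snap.tsv"
    cfg.save_tsv(path)
    assert LatticeConfig.load_tsv(path) == cfg


def test_snapshot_rejects_malformed_input():
    with pytest.raises(ValueError):
        LatticeConfig.from_tsv("1\t2\n")
    with pytest.raises(ValueError):
        LatticeConfig.from_tsv("#width\t3\n#height\t2\n0\t1\t2\n")


def test_model_params_validation():
    with pytest.raises(ValueError):
        sm.ModelParams(J0=-1)
    with pytest.raises(ValueError):
        sm.ModelParams(p_absent=1.5)
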