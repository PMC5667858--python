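"""Constraint networks, pebble-game rigidity and H-bond dilution."""

import warnings

import numpy as np
import pytest

from allokin.rigidity import (
    Constraint,
    ConstraintNetwork,
    DilutionResult,
    build_constraint_network,
    detect_hbonds,
    detect_hydrophobic,
    hb_dilution,
    hbond_energy,
    pebble_game,
    weak_spot_frequency,
)
from allokin.structures import AtomStructure
from allokin.synthetic import make_allatom_helix

KIND = {2: "hydrophobic", 5: "covalent_rotatable", 6: "covalent_locked"}


def _net(n, bars_list):
    cons = [Constraint(i=i, j=j, bars=b, kind=KIND[b]) for i, j, b in bars_list]
    return ConstraintNetwork(n_bodies=n, constraints=cons)


def _structure(elements, names, coords, resnums=None, bonds=()):
    n = len(elements)
    resnums = resnums or [1] * n
    return AtomStructure(
        elements=list(elements),
        atom_names=list(names),
        res_names=["ALA"] * n,
        chains=["A"] * n,
        res_numbers=list(resnums),
        icodes=[""] * n,
        coords=np.asarray(coords, dtype=float),
        covalent_bonds=list(bonds),
    )


class TestHbondEnergy:
    def test_ideal_geometry(self):
        assert hbond_energy(2.8, 180.0) == pytest.approx(-8.0, abs=1e-12)

    def test_perpendicular_rejected(self):
        assert hbond_energy(2.8, 90.0) == 0.0

    def test_candidate_cutoff_plug_in(self):
        # direct plug-in at the 3.6 A candidate limit
        r = 2.8 / 3.6
        expect = 8.0 * (5 * r**12 - 6 * r**10)
        assert hbond_energy(3.6, 180.0) == pytest.approx(expect, abs=1e-12)


class TestDetectHydrophobic:
    def _pair(self, elements, d, names=("CB", "CG")):
        return _structure(
            elements, names, [[0, 0, 0], [d, 0, 0]], resnums=[1, 2]
        )

    def test_carbon_pair_inside(self):
        s = self._pair(["C", "C"], 3.60)
        assert detect_hydrophobic(s) == [(0, 1)]

    def test_carbon_pair_outside(self):
        s = self._pair(["C", "C"], 3.70)
        assert detect_hydrophobic(s) == []

    def test_carbon_sulfur_boundary(self):
        s = self._pair(["C", "S"], 3.74)
        assert detect_hydrophobic(s) == [(0, 1)]

    def test_backbone_excluded(self):
        s = self._pair(["C", "C"], 3.0, names=("CA", "C"))
        assert detect_hydrophobic(s) == []


class TestBuildNetwork:
    def test_rotatable_bond_five_bars(self):
        s = _structure(["C", "C"], ["CB", "CG"], [[0, 0, 0], [1.5, 0, 0]],
                       bonds=[(0, 1, False)])
        net = build_constraint_network(s, hbonds=[], tethers=[])
        (c,) = net.constraints
        assert (c.bars, c.kind) == (5, "covalent_rotatable")

    def test_peptide_bond_six_bars(self):
        s = _structure(["C", "N"], ["C", "N"], [[0, 0, 0], [1.33, 0, 0]],
                       resnums=[1, 2], bonds=[(0, 1, True)])
        net = build_constraint_network(s, hbonds=[], tethers=[])
        assert net.constraints[0].bars == 6

    def test_weak_hbond_excluded(self):
        s = _structure(["N", "O"], ["N", "O"], [[0, 0, 0], [3.0, 0, 0]],
                       resnums=[1, 2])
        net = build_constraint_network(s, hbonds=[(0, 0, 1, -0.5)], tethers=[])
        assert net.hbonds() == []
        net2 = build_constraint_network(s, hbonds=[(0, 0, 1, -1.5)], tethers=[])
        assert len(net2.hbonds()) == 1


class TestPebbleGame:
    def test_two_bodies_six_bars_rigid(self):
        d = pebble_game(_net(2, [(0, 1, 6)]))
        assert len(d.sizes) == 1
        assert d.internal_dof == 0
        assert d.free_pebbles == 6

    def test_two_bodies_five_bars_one_dof(self):
        d = pebble_game(_net(2, [(0, 1, 5)]))
        assert len(d.sizes) == 2
        assert d.internal_dof == 1
        assert d.free_pebbles == 7

    def test_chain_of_three(self):
        d = pebble_game(_net(3, [(0, 1, 5), (1, 2, 5)]))
        assert d.internal_dof == 2
        assert len(d.sizes) == 3

    def test_redundant_bars_detected(self):
        # 7 bars between two bodies: only 6 independent
        cons = [
            Constraint(i=0, j=1, bars=6, kind="covalent_locked"),
            Constraint(i=0, j=1, bars=2, kind="hydrophobic"),
        ]
        d = pebble_game(ConstraintNetwork(n_bodies=2, constraints=cons))
        assert d.free_pebbles == 6
        assert d.internal_dof == 0


def _rank_oracle(rng, n_bodies, bars_list):
    """Independent bars by generic linear algebra: each bar is one row in
    the 6B-dimensional velocity space (v_u, w_u | v_v, w_v per body)."""
    rows = []
    for u, v, bars in bars_list:
        for _ in range(bars):
            p = rng.normal(size=3)
            q = rng.normal(size=3)
            e = p - q
            row = np.zeros(6 * n_bodies)
            row[6 * u : 6 * u + 3] = e
            row[6 * u + 3 : 6 * u + 6] = np.cross(p, e)
            row[6 * v : 6 * v + 3] = -e
            row[6 * v + 3 : 6 * v + 6] = -np.cross(q, e)
            rows.append(row)
    if not rows:
        return 0
    return np.linalg.matrix_rank(np.array(rows), tol=1e-8)


class TestRankOracle:
    def test_random_small_networks(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 7))
            bars_list = []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        bars_list.append((i, j, int(rng.choice([2, 5, 6]))))
            d = pebble_game(_net(n, bars_list))
            rank = _rank_oracle(rng, n, bars_list)
            assert d.free_pebbles == 6 * n - rank

    def test_order_independence(self, rng):
        bars_list = [(0, 1, 5), (1, 2, 6), (2, 3, 5), (0, 3, 2), (1, 3, 6)]
        base = pebble_game(_net(4, bars_list))
        for _ in range(5):
            perm = rng.permutation(len(bars_list))
            d = pebble_game(_net(4, [bars_list[k] for k in perm]))
            assert d.free_pebbles == base.free_pebbles
            assert sorted(d.sizes.tolist()) == sorted(base.sizes.tolist())


@pytest.fixture(scope="module")
def helix_dilution(helix12):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = build_constraint_network(helix12)
        return hb_dilution(net)


class TestDilution:
    def test_giant_trajectory_monotone(self, helix_dilution):
        sizes = helix_dilution.giant_sizes
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_removal_order_weakest_first(self, helix_dilution):
        e = helix_dilution.removal_energies
        assert all(a <= b + 1e-12 for b, a in zip(e, e[1:]))  # decreasing E (more negative later)

    def test_deterministic_under_ties(self, helix12):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = hb_dilution(build_constraint_network(helix12))
            b = hb_dilution(build_constraint_network(helix12))
        assert a.removal_energies == b.removal_energies
        assert a.giant_sizes == b.giant_sizes
        assert a.weak_spots == b.weak_spots

    def test_weak_spots_leave_giant(self, helix_dilution):
        assert helix_dilution.transition_step is not None
        assert len(helix_dilution.weak_spots) > 0

    def test_purely_covalent_ring_no_transition(self):
        # locked hexagon: rigid without any hydrogen bonds
        coords = [[np.cos(a), np.sin(a), 0.0] for a in np.linspace(0, 2 * np.pi, 6, endpoint=False)]
        bonds = [(i, (i + 1) % 6, True) for i in range(6)]
        s = _structure(["C"] * 6, [f"C{i}" for i in range(6)], coords, bonds=bonds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = build_constraint_network(s, hbonds=[], tethers=[])
            result = hb_dilution(net)
        assert result.transition_step is None
        assert result.weak_spots == set()


class TestWeakSpotFrequency:
    def _dr(self, ids, weak):
        return DilutionResult([], [], None, set(weak), list(ids))

    def test_single_conformer_binary(self):
        ids = [("A", i, "") for i in range(1, 5)]
        prof = weak_spot_frequency([self._dr(ids, {("A", 2, "")})])
        assert set(np.unique(prof.frequencies)) <= {0.0, 1.0}

    def test_disjoint_sets_half(self):
        ids = [("A", i, "") for i in range(1, 5)]
        r1 = self._dr(ids, {("A", 1, "")})
        r2 = self._dr(ids, {("A", 3, "")})
        prof = weak_spot_frequency([r1, r2])
        flagged = prof.frequencies[prof.frequencies > 0]
        assert np.allclose(flagged, 0.5)

    def test_rank_order_with_ties(self):
        ids = [("A", i, "") for i in range(1, 4)]
        rs = [
            self._dr(ids, {("A", 2, "")}),
            self._dr(ids, {("A", 2, ""), ("A", 1, "")}),
            self._dr(ids, {("A", 3, "")}),
        ]
        prof = weak_spot_frequency(rs)
        assert prof.frequencies.tolist() == pytest.approx([1 / 3, 2 / 3, 1 / 3])
        assert prof.ranks[1] == 1  # highest frequency ranks first
        assert prof.ranks[0] == 2  # tie broken by residue order
        assert prof.ranks[2] == 3

    def test_inconsistent_ids_rejected(self):
        a = self._dr([("A", 1, ""), ("A", 2, "")], set())
        b = self._dr([("A", 1, ""), ("A", 3, "")], set())
        with pytest.raises(ValueError):
            weak_spot_frequency([a, b])
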