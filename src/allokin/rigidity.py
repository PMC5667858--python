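"""Constraint-network rigidity: body-bar pebble game and H-bond dilution.

Atoms are rigid bodies with 6 degrees of freedom; interactions are bars:
rotatable covalent bonds place 5 bars (one dihedral left free), locked
covalent bonds (peptide and planar groups) 6, hydrogen bonds 5 and
hydrophobic tethers 2.  Hydrogen bonds are scored with the empirical
geometric energy

    E_hb = V0 [5 (d0/d)^12 - 6 (d0/d)^10] cos^2(theta_DHA),

V0 = 8 kcal/mol, d0 = 2.8 A, and enter the network only when
E_hb <= E_cut = -1.0 kcal/mol.  The (6,6) pebble game decomposes the
network into rigid clusters; removing hydrogen bonds weakest-first while
keeping covalent and hydrophobic constraints emulates thermal unfolding,
and residues that leave the giant rigid cluster at the unfolding
transition are the structure's weak spots.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from allokin.structures import AtomStructure

__all__ = [
    "HBOND_V0",
    "HBOND_D0",
    "Constraint",
    "ConstraintNetwork",
    "RigidDecomposition",
    "DilutionResult",
    "WeakSpotProfile",
    "detect_hbonds",
    "detect_hydrophobic",
    "build_constraint_network",
    "pebble_game",
    "hb_dilution",
    "weak_spot_frequency",
]

HBOND_V0 = 8.0  # kcal/mol
HBOND_D0 = 2.8  # A
HBOND_DMAX = 3.6  # donor-acceptor candidate cutoff, A
VDW_RADII = {"C": 1.7, "S": 1.8}
BARS = {"covalent_rotatable": 5, "covalent_locked": 6, "hbond": 5, "hydrophobic": 2}
_BACKBONE = {"N", "CA", "C", "O", "H", "OXT"}


@dataclass
class Constraint:
    i: int
    j: int
    bars: int
    kind: str
    energy: float | None = None  # kcal/mol, hbonds only

    def __post_init__(self) -> None:
        if self.bars not in (2, 5, 6):
            raise ValueError("bar count must be 2, 5 or 6")


@dataclass
class ConstraintNetwork:
    n_bodies: int
    constraints: list[Constraint]
    structure: AtomStructure | None = None
    e_cut: float = -1.0
    d_cut_hp: float = 0.25

    def __post_init__(self) -> None:
        seen = set()
        for c in self.constraints:
            key = (min(c.i, c.j), max(c.i, c.j), c.kind)
            if key in seen:
                raise ValueError(f"duplicate constraint {key}")
            seen.add(key)
            if c.kind == "hbond" and c.energy is not None and c.energy > self.e_cut:
                raise ValueError("hbond constraint above the energy cutoff")

    def hbonds(self) -> list[Constraint]:
        return [c for c in self.constraints if c.kind == "hbond"]


@dataclass
class RigidDecomposition:
    labels: np.ndarray  # body -> cluster id
    sizes: np.ndarray  # per cluster
    giant: int  # cluster id of the largest cluster
    internal_dof: int
    free_pebbles: int

    def giant_members(self) -> set[int]:
        return set(np.nonzero(self.labels == self.giant)[0].tolist())


@dataclass
class DilutionResult:
    removal_energies: list[float]
    giant_sizes: list[int]
    transition_step: int | None
    weak_spots: set
    residue_ids: list


@dataclass
class WeakSpotProfile:
    residue_ids: list
    frequencies: np.ndarray
    ranks: np.ndarray  # descending frequency, ties by residue order

    def to_tsv(self) -> str:
        lines = ["chain\tresnum\tfrequency\trank"]
        for (chain, num, icode), f, r in zip(
            self.residue_ids, self.frequencies, self.ranks
        ):
            lines.append(f"{chain}\t{num}{icode.strip()}\t{f:.4g}\t{int(r)}")
        return "\n".join(lines) + "\n"


def _bond_neighbors(s: AtomStructure) -> list[set[int]]:
    nb: list[set[int]] = [set() for _ in range(s.n_atoms)]
    for i, j, _ in s.covalent_bonds:
        nb[i].add(j)
        nb[j].add(i)
    return nb


def hbond_energy(d: float, theta_deg: float) -> float:
    """Empirical geometric hydrogen-bond energy (kcal/mol)."""
    if theta_deg <= 90.0:
        return 0.0
    f = np.cos(np.deg2rad(theta_deg)) ** 2
    r = HBOND_D0 / d
    return float(HBOND_V0 * (5.0 * r**12 - 6.0 * r**10) * f)


def detect_hbonds(s: AtomStructure) -> list[tuple[int, int, int, float]]:
    """Backbone/side-chain H-bonds as (donor, hydrogen, acceptor, E_hb).

    Donors are N/O atoms with a covalently attached hydrogen; acceptors
    are N/O atoms.  Candidates within 3.6 A donor-acceptor distance are
    scored with the geometric energy; atoms within two covalent bonds of
    the donor are excluded.  Donors without hydrogens are skipped with a
    warning.
    """
    nb = _bond_neighbors(s)
    donors: list[tuple[int, int]] = []  # (heavy, H)
    acceptors: list[int] = []
    bare_donors = 0
    for a in range(s.n_atoms):
        if s.elements[a] not in ("N", "O"):
            continue
        acceptors.append(a)
        hs = [b for b in nb[a] if s.elements[b] == "H"]
        if hs:
            for h in hs:
                donors.append((a, h))
        elif s.elements[a] == "N":
            bare_donors += 1
    if bare_donors:
        warnings.warn(
            f"{bare_donors} nitrogen donor(s) lack hydrogens; skipped", stacklevel=2
        )
    out = []
    for d_atom, h in donors:
        near = nb[d_atom] | {x for b in nb[d_atom] for x in nb[b]} | {d_atom}
        for a in acceptors:
            if a in near:
                continue
            dda = float(np.linalg.norm(s.coords[d_atom] - s.coords[a]))
            if dda > HBOND_DMAX:
                continue
            v1 = s.coords[d_atom] - s.coords[h]
            v2 = s.coords[a] - s.coords[h]
            cosang = float(
                v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            )
            theta = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            e = hbond_energy(dda, theta)
            out.append((d_atom, h, a, e))
    return out


def detect_hydrophobic(s: AtomStructure, d_cut: float = 0.25) -> list[tuple[int, int]]:
    """Hydrophobic tethers: side-chain C/S pairs within r_vdw(i)+r_vdw(j)+d_cut."""
    cands = [
        a for a in range(s.n_atoms)
        if s.elements[a] in VDW_RADII and s.atom_names[a] not in _BACKBONE
    ]
    ridx = s.residue_index()
    out = []
    for p, a in enumerate(cands):
        for b in cands[p + 1 :]:
            if ridx[a] == ridx[b]:
                continue
            limit = VDW_RADII[s.elements[a]] + VDW_RADII[s.elements[b]] + d_cut
            if np.linalg.norm(s.coords[a] - s.coords[b]) <= limit:
                out.append((a, b))
    return out


def build_constraint_network(
    s: AtomStructure,
    hbonds: list[tuple[int, int, int, float]] | None = None,
    tethers: list[tuple[int, int]] | None = None,
    e_cut: float = -1.0,
) -> ConstraintNetwork:
    """Typed bar network from covalent bonds, H-bonds and hydrophobic tethers.

    H-bonds are filtered at ``e_cut``; when a pair carries several
    constraint types only the strongest (most bars) is kept.
    """
    if hbonds is None:
        hbonds = detect_hbonds(s)
    if tethers is None:
        tethers = detect_hydrophobic(s)
    best: dict[tuple[int, int], Constraint] = {}

    def offer(c: Constraint):
        key = (min(c.i, c.j), max(c.i, c.j))
        cur = best.get(key)
        if cur is None or c.bars > cur.bars:
            best[key] = c

    for i, j, locked in s.covalent_bonds:
        kind = "covalent_locked" if locked else "covalent_rotatable"
        offer(Constraint(i=i, j=j, bars=BARS[kind], kind=kind))
    for d_atom, _h, a, e in hbonds:
        if e <= e_cut:
            offer(Constraint(i=d_atom, j=a, bars=BARS["hbond"], kind="hbond", energy=e))
    for a, b in tethers:
        offer(Constraint(i=a, j=b, bars=BARS["hydrophobic"], kind="hydrophobic"))
    net = ConstraintNetwork(
        n_bodies=s.n_atoms, constraints=list(best.values()), structure=s, e_cut=e_cut
    )
    comps = _component_count(s.n_atoms, [(c.i, c.j) for c in net.constraints])
    if comps > 1:
        warnings.warn("constraint network is disconnected", stacklevel=2)
    return net


def _component_count(n: int, edges) -> int:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    return len({find(v) for v in range(n)})


class _PebbleGame:
    """(6,6) body-bar pebble game with directed pebble search."""

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [6] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]

    def _collect(self, start: int, forbidden: frozenset[int]) -> bool:
        """Bring one pebble to ``start`` by reversing a directed path."""
        seen = [False] * self.n
        seen[start] = True
        parent = {start: -1}
        stack = [start]
        while stack:
            u = stack.pop()
            if u != start and u not in forbidden and self.pebbles[u] > 0:
                # reverse the path start -> ... -> u
                self.pebbles[u] -= 1
                self.pebbles[start] += 1
                v = u
                while parent[v] != -1:
                    p = parent[v]
                    self.out[p][v] -= 1
                    if self.out[p][v] == 0:
                        del self.out[p][v]
                    self.out[v][p] = self.out[v].get(p, 0) + 1
                    v = p
                return True
            for w in self.out[u]:
                if not seen[w]:
                    seen[w] = True
                    parent[w] = u
                    stack.append(w)
        return False

    def insert_bar(self, u: int, v: int) -> bool:
        """Add one bar; returns False when redundant."""
        if u == v:
            return False
        forbid = frozenset((u, v))
        while self.pebbles[u] + self.pebbles[v] < 7:
            if not (self._collect(u, forbid) or self._collect(v, forbid)):
                return False
        self.pebbles[u] -= 1
        self.out[u][v] = self.out[u].get(v, 0) + 1
        return True

    def pair_rigid(self, u: int, v: int) -> bool:
        """True when no 7th pebble can be gathered on {u, v}."""
        forbid = frozenset((u, v))
        while self.pebbles[u] + self.pebbles[v] < 7:
            if not (self._collect(u, forbid) or self._collect(v, forbid)):
                return True
        return False


def pebble_game(net: ConstraintNetwork) -> RigidDecomposition:
    """Rigid-cluster decomposition via the (6,6) body-bar pebble game.

    Each body starts with 6 pebbles; every bar is inserted through a
    pebble search (redundant bars are detected and skipped).  Bodies
    joined by a constraint are merged into one rigid cluster when no
    seventh pebble can be gathered on the pair; the free-pebble count
    equals 6 x bodies minus the number of independent bars.
    """
    n = net.n_bodies
    game = _PebbleGame(n)
    for c in net.constraints:
        for _ in range(c.bars):
            game.insert_bar(c.i, c.j)
    free = sum(game.pebbles)
    comps = _component_count(n, [(c.i, c.j) for c in net.constraints])
    internal = free - 6 * comps

    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for c in net.constraints:
        if find(c.i) != find(c.j) and game.pair_rigid(c.i, c.j):
            parent[find(c.i)] = find(c.j)
    roots = {}
    labels = np.empty(n, dtype=int)
    for v in range(n):
        labels[v] = roots.setdefault(find(v), len(roots))
    sizes = np.bincount(labels)
    giant = int(np.argmax(sizes))
    return RigidDecomposition(
        labels=labels,
        sizes=sizes,
        giant=giant,
        internal_dof=int(internal),
        free_pebbles=int(free),
    )


def _residue_ca_bodies(s: AtomStructure) -> tuple[list, list[int]]:
    ids, ca = [], []
    seen = set()
    for a in range(s.n_atoms):
        rid = (s.chains[a], s.res_numbers[a], s.icodes[a])
        if s.atom_names[a] == "CA" and rid not in seen:
            seen.add(rid)
            ids.append(rid)
            ca.append(a)
    return ids, ca


def hb_dilution(net: ConstraintNetwork) -> DilutionResult:
    """Hydrogen-bond dilution: emulated thermal unfolding.

    H-bonds are removed one at a time from weakest (least negative
    energy) to strongest, ties broken by donor index, recomputing the
    rigid decomposition after each removal while covalent and
    hydrophobic constraints stay.  The transition is the step with the
    largest single drop in giant-cluster size (earliest on ties); weak
    spots are residues whose C-alpha sits in the giant cluster just
    before the transition and outside it just after.
    """
    if net.structure is None:
        raise ValueError("dilution needs the parent structure for residue mapping")
    res_ids, ca_bodies = _residue_ca_bodies(net.structure)
    hbs = net.hbonds()
    if not hbs:
        warnings.warn("no hydrogen bonds to dilute", stacklevel=2)
        return DilutionResult([], [], None, set(), res_ids)
    order = sorted(hbs, key=lambda c: (-(c.energy or 0.0), c.i, c.j))
    others = [c for c in net.constraints if c.kind != "hbond"]
    decomps = []
    for step in range(len(order) + 1):
        remaining = others + order[step:]
        sub = ConstraintNetwork(
            n_bodies=net.n_bodies, constraints=remaining,
            structure=net.structure, e_cut=net.e_cut,
        )
        decomps.append(pebble_game(sub))
    sizes = [int(d.sizes[d.giant]) for d in decomps]
    drops = np.array([sizes[s] - sizes[s + 1] for s in range(len(order))])
    if drops.size == 0 or drops.max() <= 0:
        return DilutionResult(
            [float(c.energy) for c in order], sizes, None, set(), res_ids
        )
    t = int(np.argmax(drops))  # earliest max drop
    before = decomps[t].giant_members()
    after = decomps[t + 1].giant_members()
    weak = {
        rid for rid, ca in zip(res_ids, ca_bodies)
        if ca in before and ca not in after
    }
    return DilutionResult(
        removal_energies=[float(c.energy) for c in order],
        giant_sizes=sizes,
        transition_step=t,
        weak_spots=weak,
        residue_ids=res_ids,
    )


def weak_spot_frequency(results: list[DilutionResult]) -> WeakSpotProfile:
    """Per-residue weak-spot frequency over conformers, rank descending."""
    if not results:
        raise ValueError("need at least one dilution result")
    ids = results[0].residue_ids
    for r in results[1:]:
        if r.residue_ids != ids:
            raise ValueError("inconsistent residue sets across conformers")
    freq = np.array(
        [sum(1 for r in results if rid in r.weak_spots) / len(results) for rid in ids]
    )
    order = np.lexsort((np.arange(len(ids)), -freq))
    ranks = np.empty(len(ids), dtype=int)
    ranks[order] = np.arange(1, len(ids) + 1)
    return WeakSpotProfile(residue_ids=ids, frequencies=freq, ranks=ranks)
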