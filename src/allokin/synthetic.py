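"""Synthetic structures, ensembles and alignments with planted ground truth.

Every generator is a pure function of its arguments and a seed, so each
analysis stage can be tested against a known planted signal: a two-lobe
chain with a hinge for the elastic-network stages, an ideal all-atom
helix with i -> i+4 backbone hydrogen bonds for the rigidity stage,
alignments with planted conserved and covarying columns for the
conservation/MI stage, and Gaussian ensembles with planted covariance
for PCA and generalized-correlation recovery.
"""

from __future__ import annotations

import numpy as np

from allokin.coupling import AMINO_ACIDS, Msa
from allokin.structures import AtomStructure, CaTrace, Ensemble

__all__ = [
    "make_helix",
    "make_two_lobe_toy",
    "make_allatom_helix",
    "make_synthetic_msa",
    "make_gaussian_ensemble",
]

# ideal alpha-helix C-alpha parameters
HELIX_RISE = 1.5  # A per residue
HELIX_TWIST = 100.0  # degrees per residue
HELIX_RADIUS = 2.3  # A

# backbone internal coordinates (standard amide geometry)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.010
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.8, -47.0, 180.0


def make_helix(n_res: int) -> CaTrace:
    """Ideal alpha-helical C-alpha trace (rise 1.5 A, twist 100 deg)."""
    if n_res < 2:
        raise ValueError("helix needs at least 2 residues")
    k = np.arange(n_res)
    ang = np.deg2rad(HELIX_TWIST) * k
    coords = np.column_stack(
        [HELIX_RADIUS * np.cos(ang), HELIX_RADIUS * np.sin(ang), HELIX_RISE * k]
    )
    ids = [("A", int(i) + 1, "") for i in k]
    return CaTrace(residue_ids=ids, res_names=["ALA"] * n_res, coords=coords)


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return c * np.eye(3) + s * k + (1 - c) * np.outer(axis, axis)


def _kinked_lobe(n: int, kink_deg: float) -> np.ndarray:
    """Helix folded back on itself at its midpoint into a compact hairpin.

    The second half is rotated rigidly about the midpoint bead, which
    preserves every bond length exactly.
    """
    coords = make_helix(n).coords.copy()
    m = n // 2
    rot = _rotation([0.0, 1.0, 0.0], kink_deg)
    pivot = coords[m]
    coords[m + 1 :] = (coords[m + 1 :] - pivot) @ rot.T + pivot
    return coords


def make_two_lobe_toy(n1: int, n2: int, seed: int = 0) -> CaTrace:
    """Two compact helical lobes joined by a 3-residue extended linker.

    Emulates the two-lobe kinase architecture: the linker is the hinge
    about which the lobes can open and close, so the slowest GNM mode of
    the fixture has its mobility minimum there.
    """
    if n1 < 10 or n2 < 10:
        raise ValueError("each lobe needs at least 10 residues")
    rng = np.random.default_rng(seed)
    for _ in range(64):
        kink1 = 110.0 + rng.uniform(-8.0, 8.0)
        kink2 = 110.0 + rng.uniform(-8.0, 8.0)
        lobe1 = _kinked_lobe(n1, kink1)
        lobe2 = _kinked_lobe(n2, kink2)
        c1 = lobe1.mean(axis=0)
        u = lobe1[-1] - c1
        u = u / np.linalg.norm(u)
        linker = np.array([lobe1[-1] + 3.7 * (k + 1) * u for k in range(3)])
        spin = _rotation(u, rng.uniform(0.0, 360.0))
        tilt = _rotation(np.cross(u, [0.0, 0.0, 1.0]) + 1e-9, rng.uniform(-25.0, 25.0))
        l2 = (lobe2 - lobe2[0]) @ (tilt @ spin).T + linker[-1] + 3.7 * u
        coords = np.vstack([lobe1, linker, l2])
        # accept when the lobes neither clash nor touch
        d = np.linalg.norm(lobe1[:, None, :] - l2[None, :, :], axis=2)
        c2 = l2.mean(axis=0)
        if d.min() > 4.5 and np.linalg.norm(c2 - c1) >= 15.0:
            n = coords.shape[0]
            ids = [("A", i + 1, "") for i in range(n)]
            return CaTrace(residue_ids=ids, res_names=["ALA"] * n, coords=coords)
    raise RuntimeError("could not place lobes without clashes")


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """NeRF placement of atom d bonded to c with angle b-c-d, torsion a-b-c-d."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(torsion_deg)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_allatom_helix(n_res: int) -> AtomStructure:
    """Ideal all-atom alpha-helix backbone (N, H, CA, C, O per residue).

    Built from standard amide geometry at (phi, psi) = (-57.8, -47.0),
    which puts every i -> i-4 backbone N-H...O=C pair at a donor-acceptor
    distance near 2.9 A with a near-linear angle.  Residue 1 has no amide
    hydrogen (chain terminus), so residues 5..n donate n-4 hydrogen bonds.
    """
    if n_res < 6:
        raise ValueError("all-atom helix needs at least 6 residues")
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    H = np.full((n_res, 3), np.nan)
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        N[i + 1] = _place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, _PSI)
        CA[i + 1] = _place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i + 1] = _place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, _PHI)
        O[i] = _place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0)
        hdir = -(
            (C[i] - N[i + 1]) / np.linalg.norm(C[i] - N[i + 1])
            + (CA[i + 1] - N[i + 1]) / np.linalg.norm(CA[i + 1] - N[i + 1])
        )
        H[i + 1] = N[i + 1] + _B_N_H * hdir / np.linalg.norm(hdir)
    O[n_res - 1] = _place_atom(
        N[n_res - 1], CA[n_res - 1], C[n_res - 1], _B_C_O, _A_CA_C_O, _PSI + 180.0
    )

    elements, names, resnames, chains, nums, icodes, coords = [], [], [], [], [], [], []
    bonds: list[tuple[int, int, bool]] = []
    index: dict[tuple[int, str], int] = {}

    def add(i, name, elem, xyz):
        index[(i, name)] = len(names)
        elements.append(elem)
        names.append(name)
        resnames.append("ALA")
        chains.append("A")
        nums.append(i + 1)
        icodes.append("")
        coords.append(xyz)

    for i in range(n_res):
        add(i, "N", "N", N[i])
        if i > 0:
            add(i, "H", "H", H[i])
        add(i, "CA", "C", CA[i])
        add(i, "C", "C", C[i])
        add(i, "O", "O", O[i])
    for i in range(n_res):
        bonds.append((index[(i, "N")], index[(i, "CA")], False))
        bonds.append((index[(i, "CA")], index[(i, "C")], False))
        bonds.append((index[(i, "C")], index[(i, "O")], True))
        if i > 0:
            bonds.append((index[(i, "N")], index[(i, "H")], True))
            bonds.append((index[(i - 1, "C")], index[(i, "N")], True))
    return AtomStructure(
        elements=elements,
        atom_names=names,
        res_names=resnames,
        chains=chains,
        res_numbers=nums,
        icodes=icodes,
        coords=np.array(coords),
        covalent_bonds=bonds,
    )


def make_synthetic_msa(
    n_seq: int,
    n_col: int,
    conserved_cols: set[int] = frozenset(),
    covarying_pairs: list[tuple[int, int]] = (),
    seed: int = 0,
    gap_rate: float = 0.0,
) -> Msa:
    """Alignment with planted conserved columns and covarying column pairs.

    Conserved columns carry a single amino acid (KL = ln 20 against a
    uniform background at zero pseudocount).  Covarying pairs are drawn
    jointly from a two-state model -- (A, V) or (L, I) with equal
    probability -- whose mutual information is exactly ln 2.  All other
    columns are i.i.d. uniform over the 20 amino acids.  The reference
    (sequence 0) never receives gaps.
    """
    if n_seq < 10:
        raise ValueError("need at least 10 sequences")
    conserved_cols = set(conserved_cols)
    paired = set()
    for a, b in covarying_pairs:
        for c in (a, b):
            if c in conserved_cols or c in paired:
                raise ValueError(f"column {c} assigned twice")
            paired.add(c)
    for c in conserved_cols | paired:
        if not 0 <= c < n_col:
            raise ValueError(f"column index {c} out of range")
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 20, size=(n_seq, n_col))
    for c in conserved_cols:
        mat[:, c] = AMINO_ACIDS.index(AMINO_ACIDS[c % 20])
    for a, b in covarying_pairs:
        state = rng.integers(0, 2, size=n_seq)
        mat[:, a] = np.where(state == 0, AMINO_ACIDS.index("A"), AMINO_ACIDS.index("L"))
        mat[:, b] = np.where(state == 0, AMINO_ACIDS.index("V"), AMINO_ACIDS.index("I"))
    seqs = ["".join(AMINO_ACIDS[k] for k in row) for row in mat]
    if gap_rate > 0:
        gapped = []
        for s, seq in enumerate(seqs):
            if s == 0:
                gapped.append(seq)
                continue
            mask = rng.random(n_col) < gap_rate
            gapped.append("".join("-" if m else a for a, m in zip(seq, mask)))
        seqs = gapped
    names = [f"seq_{k}" for k in range(n_seq)]
    return Msa(names=names, sequences=seqs, reference=0)


def make_gaussian_ensemble(
    trace: CaTrace,
    mode_spec: list[tuple[np.ndarray, float]],
    n_frames: int,
    seed: int = 0,
) -> Ensemble:
    """Ensemble with planted covariance: frames = trace + sum_k sqrt(v_k) z_k u_k.

    Mode vectors must be orthonormal in 3N space (Gram deviation above
    1e-6 is an error); variances must be positive.
    """
    n3 = trace.n_residues * 3
    modes = np.array([np.asarray(v, dtype=float).ravel() for v, _ in mode_spec])
    variances = np.array([float(s) for _, s in mode_spec])
    if modes.shape[1] != n3:
        raise ValueError("mode vectors must have length 3N")
    if np.any(variances <= 0):
        raise ValueError("variances must be positive")
    gram = modes @ modes.T
    if np.max(np.abs(gram - np.eye(len(mode_spec)))) > 1e-6:
        raise ValueError("mode vectors are not orthonormal")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_frames, len(mode_spec)))
    disp = (z * np.sqrt(variances)) @ modes  # (F, 3N)
    frames = trace.coords[None, :, :] + disp.reshape(n_frames, -1, 3)
    return Ensemble(
        frames=frames,
        times=np.arange(n_frames, dtype=float) + 1.0,
        residue_ids=list(trace.residue_ids),
        provenance={"generator": "gaussian_modes", "seed": int(seed),
                    "variances": variances.tolist()},
    )
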