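"""Structure and trajectory containers with PDB/XYZ I/O.

Coordinates are in Angstrom throughout.  Residues are identified by
``(chain, author_number, insertion_code)``; internal indexing is 0-based
while written tables carry the author numbering.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AtomStructure",
    "CaTrace",
    "Ensemble",
    "ResidueProfile",
    "PdbParseError",
    "read_pdb",
    "extract_ca_trace",
    "superpose",
    "compute_bfactors",
    "write_trajectory",
    "read_xyz",
]

ResidueId = tuple[str, int, str]


class PdbParseError(ValueError):
    """Raised when a PDB stream violates the fixed-column format."""


# Bonds that are part of a planar / conjugated group and therefore carry
# no dihedral freedom.  Backbone: the carbonyl, the amide N-H and the
# peptide C-N.  Side chains: aromatic rings, guanidinium, amide and
# carboxylate groups.
_LOCKED_INTRA = {
    ("C", "O"),
    ("N", "H"),
    ("CG", "CD1"), ("CG", "CD2"), ("CD1", "CE1"), ("CD2", "CE2"),
    ("CE1", "CZ"), ("CE2", "CZ"), ("CZ", "OH"),                     # PHE/TYR ring
    ("CG", "ND1"), ("CG", "CD2"), ("ND1", "CE1"), ("CD2", "NE2"),
    ("CE1", "NE2"),                                                 # HIS
    ("CD1", "NE1"), ("NE1", "CE2"), ("CE2", "CZ2"), ("CZ2", "CH2"),
    ("CH2", "CZ3"), ("CZ3", "CE3"), ("CE3", "CD2"),                 # TRP
    ("CZ", "NH1"), ("CZ", "NH2"), ("NE", "CZ"),                     # ARG guanidinium
    ("CG", "OD1"), ("CG", "OD2"), ("CG", "ND2"),                    # ASP/ASN
    ("CD", "OE1"), ("CD", "OE2"), ("CD", "NE2"),                    # GLU/GLN
}


@dataclass
class AtomStructure:
    """All-atom structure: one conformer (PDB MODEL).

    ``covalent_bonds`` holds ``(i, j, locked)`` triples; ``locked`` marks
    bonds without dihedral freedom (peptide bonds, bonds inside planar
    groups).  The bond list is populated by :func:`read_pdb` or by the
    synthetic builders.
    """

    elements: list[str]
    atom_names: list[str]
    res_names: list[str]
    chains: list[str]
    res_numbers: list[int]
    icodes: list[str]
    coords: np.ndarray  # (n_atoms, 3)
    covalent_bonds: list[tuple[int, int, bool]] = field(default_factory=list)
    model_index: int = 1

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.n_atoms
        for i, j, _ in self.covalent_bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i},{j}) references invalid atom index")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def residue_ids(self) -> list[ResidueId]:
        """Residue id of every atom (not deduplicated)."""
        return [
            (c, n, ic)
            for c, n, ic in zip(self.chains, self.res_numbers, self.icodes)
        ]

    def residue_index(self) -> np.ndarray:
        """0-based residue index per atom, in order of first appearance."""
        seen: dict[ResidueId, int] = {}
        out = np.empty(self.n_atoms, dtype=int)
        for a, rid in enumerate(self.residue_ids()):
            out[a] = seen.setdefault(rid, len(seen))
        return out


@dataclass
class CaTrace:
    """Ordered C-alpha bead positions with residue identity."""

    residue_ids: list[ResidueId]
    res_names: list[str]
    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.residue_ids)
        if n < 2:
            raise ValueError("CaTrace needs at least 2 residues")
        if len(set(self.residue_ids)) != n:
            raise ValueError("duplicate residue ids in trace")
        if self.coords.shape[0] != n:
            raise ValueError("coordinate/residue count mismatch")
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        if np.any(d > 6.0):
            k = int(np.argmax(d > 6.0))
            raise ValueError(
                f"chain break: consecutive Ca distance {d[k]:.2f} A after residue {k}"
            )
        if np.any((d < 2.8) | (d > 4.2)):
            warnings.warn("consecutive Ca distance outside [2.8, 4.2] A", stacklevel=2)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)


@dataclass
class Ensemble:
    """Conformational ensemble: frames x residues x 3 coordinates."""

    frames: np.ndarray  # (F, N, 3)
    times: np.ndarray  # (F,)
    residue_ids: list[ResidueId]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (F, N, 3)")
        self.times = np.asarray(self.times, dtype=float).ravel()
        if self.frames.shape[0] < 1:
            raise ValueError("ensemble needs at least one frame")
        if self.times.shape[0] != self.frames.shape[0]:
            raise ValueError("times/frames length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if len(self.residue_ids) != self.frames.shape[1]:
            raise ValueError("residue id / coordinate count mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_residues(self) -> int:
        return self.frames.shape[1]


@dataclass
class ResidueProfile:
    """A named per-residue scalar track (B-factors, mobility, ...)."""

    residue_ids: list[ResidueId]
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape[0] != len(self.residue_ids):
            raise ValueError("value/residue count mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    def to_tsv(self) -> str:
        lines = ["chain\tresnum\tresname\tvalue"]
        for (chain, num, icode), v in zip(self.residue_ids, self.values):
            lines.append(f"{chain}\t{num}{icode.strip()}\t-\t{v:.6g}")
        return "\n".join(lines) + "\n"


def _parse_atom_line(line: str, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise PdbParseError(
            f"line {lineno}: ATOM record truncated before coordinate columns"
        )
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21]
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PdbParseError(f"line {lineno}: malformed ATOM record ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = name[:1] if name[:1].isalpha() else name[1:2]
    return name, altloc, resname, chain, resnum, icode, (x, y, z), element


def _infer_bonds(s: AtomStructure) -> list[tuple[int, int, bool]]:
    """Covalent bonds from residue templates plus the peptide C-N link.

    Intra-residue bonds are detected by covalent distance (heavy-heavy
    < 1.9 A, X-H < 1.25 A) which reproduces the standard residue
    templates for well-formed coordinates; inter-residue bonds are
    restricted to peptide C-N pairs closer than 1.7 A.
    """
    bonds: list[tuple[int, int, bool]] = []
    ridx = s.residue_index()
    coords = s.coords
    n = s.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            hi = s.elements[i] == "H" or s.elements[j] == "H"
            same_res = ridx[i] == ridx[j]
            if same_res:
                limit = 1.25 if hi else 1.9
                if d < limit:
                    pair = (s.atom_names[i], s.atom_names[j])
                    locked = (
                        pair in _LOCKED_INTRA or pair[::-1] in _LOCKED_INTRA
                    )
                    bonds.append((i, j, locked))
            else:
                # peptide bond: C of residue k to N of residue k+1
                names = {s.atom_names[i], s.atom_names[j]}
                if names == {"C", "N"} and d < 1.7:
                    bonds.append((i, j, True))
    return bonds


def read_pdb(text: str, keep_hetatm: bool = False, infer_bonds: bool = True) -> list[AtomStructure]:
    """Parse a PDB character stream into one :class:`AtomStructure` per MODEL.

    Fixed-column parsing; MODEL/ENDMDL delimit conformers; HETATM records
    are skipped unless ``keep_hetatm``; only blank or 'A' altlocs are kept.
    """
    models: list[AtomStructure] = []
    cur: list | None = None
    model_index = 1

    def flush():
        nonlocal cur
        if cur is None or not cur[0]:
            cur = None
            return
        names, resnames, chains, resnums, icodes, xyz, elements = cur[1:]
        s = AtomStructure(
            elements=elements,
            atom_names=names,
            res_names=resnames,
            chains=chains,
            res_numbers=resnums,
            icodes=icodes,
            coords=np.array(xyz, dtype=float),
            model_index=cur[0][0],
        )
        if infer_bonds:
            s.covalent_bonds = _infer_bonds(s)
        models.append(s)
        cur = None

    def new_model(idx):
        return [[idx], [], [], [], [], [], [], []]

    for lineno, line in enumerate(io.StringIO(text), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            flush()
            try:
                model_index = int(line.split()[1])
            except (IndexError, ValueError):
                model_index = len(models) + 1
            cur = new_model(model_index)
        elif rec.startswith("ENDMDL"):
            flush()
        elif rec == "ATOM  " or (rec == "HETATM" and keep_hetatm):
            if cur is None:
                cur = new_model(model_index)
            name, altloc, resname, chain, resnum, icode, xyz, element = _parse_atom_line(
                line, lineno
            )
            if altloc not in (" ", "A"):
                continue
            cur[1].append(name)
            cur[2].append(resname)
            cur[3].append(chain)
            cur[4].append(resnum)
            cur[5].append(icode)
            cur[6].append(xyz)
            cur[7].append(element)
    flush()
    if not models:
        raise PdbParseError("no ATOM records found")
    return models


def extract_ca_trace(structure: AtomStructure, chain: str | None = None) -> CaTrace:
    """Pull the C-alpha trace of one chain (or all chains if None)."""
    ids: list[ResidueId] = []
    names: list[str] = []
    coords: list[np.ndarray] = []
    seen_res: set[ResidueId] = set()
    missing: set[ResidueId] = set()
    for a in range(structure.n_atoms):
        if chain is not None and structure.chains[a] != chain:
            continue
        rid = (structure.chains[a], structure.res_numbers[a], structure.icodes[a])
        missing.add(rid)
        if structure.atom_names[a] == "CA" and rid not in seen_res:
            seen_res.add(rid)
            ids.append(rid)
            names.append(structure.res_names[a])
            coords.append(structure.coords[a])
    skipped = missing - seen_res
    if skipped:
        warnings.warn(f"{len(skipped)} residue(s) lack a CA atom; skipped", stacklevel=2)
    if len(ids) < 2:
        raise ValueError("fewer than 2 CA atoms in selection")
    return CaTrace(residue_ids=ids, res_names=names, coords=np.array(coords))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch), no reflection.

    Returns the transformed mobile coordinates and the minimised RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate shape mismatch")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    a = mobile - mc
    b = reference - rc
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    moved = a @ rot.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return moved, rmsd


def compute_bfactors(ensemble: Ensemble, fit: bool = True) -> ResidueProfile:
    """Isotropic B-factors from an ensemble: B_i = (8 pi^2 / 3) <|dr_i|^2>.

    Frames are superposed onto the ensemble mean with one mean-refinement
    pass before the fluctuations are measured; pass ``fit=False`` to use
    raw coordinates.
    """
    if ensemble.n_frames < 2:
        raise ValueError("B-factors need at least 2 frames")
    frames = ensemble.frames.copy()
    if fit:
        for _ in range(2):  # mean, superpose, re-mean
            mean = frames.mean(axis=0)
            for f in range(frames.shape[0]):
                frames[f], _ = superpose(frames[f], mean)
    mean = frames.mean(axis=0)
    msd = np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0)
    b = (8.0 * np.pi**2 / 3.0) * msd
    return ResidueProfile(
        residue_ids=list(ensemble.residue_ids), values=b, name="B-factor", units="A^2"
    )


def write_trajectory(ensemble: Ensemble, fmt: str = "pdb") -> str:
    """Serialize an ensemble as a multi-model PDB or an XYZ trajectory."""
    if fmt == "pdb":
        out = []
        for f in range(ensemble.n_frames):
            out.append(f"MODEL     {f + 1:4d}")
            for i, (chain, num, icode) in enumerate(ensemble.residue_ids):
                x, y, z = ensemble.frames[f, i]
                out.append(
                    f"ATOM  {i + 1:5d}  CA  ALA {chain:1.1s}{num:4d}{icode or ' ':1.1s}"
                    f"   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
                )
            out.append("ENDMDL")
        return "\n".join(out) + "\n"
    if fmt == "xyz":
        n = ensemble.n_residues
        out = []
        for f in range(ensemble.n_frames):
            out.append(str(n))
            out.append(f"t={ensemble.times[f]:.6f}")
            for i in range(n):
                x, y, z = ensemble.frames[f, i]
                out.append(f"CA {x:.3f} {y:.3f} {z:.3f}")
        return "\n".join(out) + "\n"
    raise ValueError(f"unknown trajectory format: {fmt!r}")


def read_xyz(text: str) -> np.ndarray:
    """Read an XYZ trajectory back into an (F, N, 3) array."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    frames = []
    k = 0
    while k < len(lines):
        n = int(lines[k])
        block = lines[k + 2 : k + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        k += n + 2
    return np.array(frames, dtype=float)
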