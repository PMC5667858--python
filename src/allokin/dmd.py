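"""Event-driven discrete molecular dynamics of a square-well Go model.

Each residue is a C-alpha bead.  Pairs bonded along the chain and pairs
in native contact (r_ij^0 <= r_c = 8 A) are joined by infinite square
wells: the distance is free to vary between d_min = (1 - sigma) r_ij^0
and d_max = (1 + sigma) r_ij^0 and reflects elastically at the walls
(sigma = 0.05 for chain neighbours, 0.1 for native contacts).  All other
pairs interact only through a hard core.  Between collisions particles
move ballistically; temperature is controlled by Andersen-style ghost
collisions that resample single-particle velocities from the
Maxwell-Boltzmann distribution at rate nu.  Units are reduced
(k_B = 1, m = 1, lengths in Angstrom).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from allokin.structures import CaTrace, Ensemble

__all__ = [
    "SquareWellModel",
    "build_go_model",
    "next_event_time",
    "reflect",
    "run_dmd",
]


@dataclass
class SquareWellModel:
    """Hard-wall tether list defining the Go model.

    ``tethers`` rows are (i, j, d_min, d_max); ``bonded`` flags chain
    neighbours.  Non-tethered pairs interact through a hard core of
    diameter ``d_hc``.
    """

    n_particles: int
    tethers: np.ndarray  # (M, 4): i, j, d_min, d_max
    bonded: np.ndarray  # (M,) bool
    r_c: float = 8.0
    sigma_bond: float = 0.05
    sigma_native: float = 0.1
    d_hc: float = 4.0
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tethers = np.asarray(self.tethers, dtype=float).reshape(-1, 4)
        self.bonded = np.asarray(self.bonded, dtype=bool).ravel()
        if np.any(self.tethers[:, 2] <= 0) or np.any(
            self.tethers[:, 3] <= self.tethers[:, 2]
        ):
            raise ValueError("tether walls must satisfy 0 < d_min < d_max")
        pairs = {(int(i), int(j)) for i, j in self.tethers[:, :2]}
        if len(pairs) != self.tethers.shape[0]:
            raise ValueError("duplicate tether pairs")
        if self.masses is None:
            self.masses = np.ones(self.n_particles)
        # connectivity of the tether graph (soft requirement)
        parent = list(range(self.n_particles))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, j in pairs:
            parent[find(i)] = find(j)
        if len({find(i) for i in range(self.n_particles)}) > 1:
            warnings.warn("tether graph is disconnected", stacklevel=2)


def build_go_model(
    trace: CaTrace,
    r_c: float = 8.0,
    sigma_bond: float = 0.05,
    sigma_native: float = 0.1,
    d_hc: float = 4.0,
) -> SquareWellModel:
    """Tether every bonded and native-contact pair of the native trace.

    Chain neighbours get a narrow well (sigma_bond) about their native
    bond length; non-consecutive pairs closer than ``r_c`` in the native
    conformation get the wider native well (sigma_native).
    """
    coords = trace.coords
    n = trace.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues")
    rows = []
    bonded = []
    for i in range(n - 1):
        r0 = float(np.linalg.norm(coords[i] - coords[i + 1]))
        rows.append((i, i + 1, (1 - sigma_bond) * r0, (1 + sigma_bond) * r0))
        bonded.append(True)
    for i in range(n):
        for j in range(i + 2, n):
            r0 = float(np.linalg.norm(coords[i] - coords[j]))
            if r0 <= r_c:
                rows.append((i, j, (1 - sigma_native) * r0, (1 + sigma_native) * r0))
                bonded.append(False)
    return SquareWellModel(
        n_particles=n,
        tethers=np.array(rows),
        bonded=np.array(bonded),
        r_c=r_c,
        sigma_bond=sigma_bond,
        sigma_native=sigma_native,
        d_hc=d_hc,
    )


def next_event_time(dr: np.ndarray, dv: np.ndarray, d: float, side: str) -> float | None:
    """Time until ||dr + dv t|| = d, for one wall.

    ``side`` is "inner" (approaching hard wall from outside) or "outer"
    (tether wall enclosing the pair).  Returns None when the wall is
    never reached.
    """
    if d <= 0:
        raise ValueError("wall distance must be positive")
    dr = np.asarray(dr, dtype=float)
    dv = np.asarray(dv, dtype=float)
    a = float(dv @ dv)
    b = float(dr @ dv)
    c2 = float(dr @ dr)
    if a == 0.0:
        return None
    if side == "inner":
        if b >= 0.0:
            return None
        disc = b * b - a * (c2 - d * d)
        if disc <= 0.0:
            return None
        return (-b - np.sqrt(disc)) / a
    if side == "outer":
        disc = b * b + a * (d * d - c2)
        if disc < 0.0:
            disc = 0.0
        return (-b + np.sqrt(disc)) / a
    raise ValueError(f"unknown wall side {side!r}")


def reflect(
    rhat: np.ndarray,
    v_i: np.ndarray,
    v_j: np.ndarray,
    m_i: float = 1.0,
    m_j: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Elastic hard-wall reflection of a pair at contact.

    The radial component of the relative velocity is reversed; momentum
    and kinetic energy are conserved exactly.  A grazing contact (zero
    radial relative velocity) is a no-op with a warning.
    """
    rhat = np.asarray(rhat, dtype=float)
    v_i = np.asarray(v_i, dtype=float)
    v_j = np.asarray(v_j, dtype=float)
    vrel = float((v_i - v_j) @ rhat)
    if vrel == 0.0:
        warnings.warn("grazing event: zero radial relative velocity", stacklevel=2)
        return v_i.copy(), v_j.copy()
    mu = m_i * m_j / (m_i + m_j)
    imp = -2.0 * mu * vrel
    return v_i + (imp / m_i) * rhat, v_j - (imp / m_j) * rhat


def _wall_tables(model: SquareWellModel, coords: np.ndarray):
    n = model.n_particles
    big = 1.0e30
    lo2 = np.zeros((n, n))
    hi2 = np.full((n, n), big)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    core = model.d_hc
    lo = np.full((n, n), core)
    np.fill_diagonal(lo, 0.0)
    # an untethered pair already inside the default core keeps a core
    # just below its native separation instead of starting violated
    tight = d < core
    lo = np.where(tight, 0.95 * d, lo)
    for (i, j, dmin, dmax), _ in zip(model.tethers, model.bonded):
        i, j = int(i), int(j)
        lo[i, j] = lo[j, i] = dmin
        hi2[i, j] = hi2[j, i] = dmax * dmax
    lo2[:] = lo * lo
    lo2[np.arange(n), np.arange(n)] = 0.0
    hi2[np.arange(n), np.arange(n)] = big
    return lo2, hi2


def run_dmd(
    model: SquareWellModel,
    trace: CaTrace,
    n_events: int,
    temperature: float = 1.0,
    nu: float = 1.0,
    snapshot_every: int = 1000,
    seed: int = 0,
    init_velocities: np.ndarray | None = None,
) -> Ensemble:
    """Run the event loop from the native conformation.

    Velocities start Maxwell-Boltzmann at ``temperature`` (or as given);
    ghost thermostat collisions occur at rate ``nu`` per particle and
    count as events.  Snapshots are taken every ``snapshot_every``
    events; the returned ensemble's frame "times" are event counts.
    Diagnostics (kinetic energy and maximum tether-wall violation per
    snapshot) ride along in ``provenance``.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if nu < 0:
        raise ValueError("thermostat rate must be nonnegative")
    from allokin._kernels import run_dmd_kernel

    n = model.n_particles
    pos0 = np.ascontiguousarray(trace.coords, dtype=float)
    rng = np.random.default_rng(seed)
    if init_velocities is None:
        vel0 = rng.normal(0.0, np.sqrt(temperature), size=(n, 3))
    else:
        vel0 = np.asarray(init_velocities, dtype=float).reshape(n, 3).copy()
    lo2, hi2 = _wall_tables(model, pos0)
    ti = model.tethers[:, 0].astype(np.int64)
    tj = model.tethers[:, 1].astype(np.int64)
    tlo = np.ascontiguousarray(model.tethers[:, 2])
    thi = np.ascontiguousarray(model.tethers[:, 3])
    kernel_seed = int(seed) % (2**31 - 1)
    snaps, snap_ev, snap_ke, snap_viol, pos, vel, ev = run_dmd_kernel(
        pos0, vel0, lo2, hi2, ti, tj, tlo, thi,
        int(n_events), float(temperature), float(nu), int(snapshot_every),
        kernel_seed,
    )
    if snaps.shape[0] == 0:
        snaps = pos[None, :, :].copy()
        snap_ev = np.array([max(ev, 1)], dtype=np.int64)
        snap_ke = np.array([0.5 * float(np.sum(vel**2))])
        snap_viol = np.array([0.0])
    prov = {
        "generator": "dmd",
        "seed": int(seed),
        "n_events": int(n_events),
        "events_executed": int(ev),
        "temperature": float(temperature),
        "nu": float(nu),
        "snapshot_every": int(snapshot_every),
        "r_c": model.r_c,
        "sigma_bond": model.sigma_bond,
        "sigma_native": model.sigma_native,
        "d_hc": model.d_hc,
        "kinetic_energy": snap_ke,
        "max_wall_violation": snap_viol,
    }
    return Ensemble(
        frames=snaps,
        times=snap_ev.astype(float),
        residue_ids=list(trace.residue_ids),
        provenance=prov,
    )
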