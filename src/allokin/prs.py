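"""Perturbation response scanning over the GNM network.

A unit perturbation is applied at one residue at a time and the
network's displacement response follows Hooke's law, dR(i) = H^-1 F(i),
with H the Kirchhoff matrix.  Collecting the squared responses gives the
N x N PRS matrix S_ij = [(Gamma^+)_ij]^2 (row i = perturbed site).  Row
averages with the diagonal excluded are effector propensities - the
ability of a residue to propagate perturbations; column averages are the
complementary sensor propensities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from allokin.gnm import KirchhoffMatrix, gnm_modes

__all__ = ["PrsMatrix", "EffectorProfile", "prs_scan", "effector_profile", "sensor_profile"]


@dataclass
class PrsMatrix:
    values: np.ndarray
    normalized: bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ValueError("PRS matrix must be nonnegative and finite")


@dataclass
class EffectorProfile:
    values: np.ndarray
    kind: str  # "effector" | "sensor"
    normalized: bool


def prs_scan(gamma: KirchhoffMatrix, normalized: bool = False) -> PrsMatrix:
    """PRS matrix from the pseudo-inverse of the Kirchhoff matrix.

    Requires a connected contact graph (a single zero mode); the
    pseudo-inverse is assembled over the nonzero modes and squared
    entry-wise.  With ``normalized`` each row is divided by its diagonal
    element (self-response).
    """
    modes = gnm_modes(gamma)
    if modes.n_zero != 1:
        raise ValueError(
            f"PRS needs a connected network; found {modes.n_zero} zero modes"
        )
    u = modes.nonzero_vectors
    inv = u @ np.diag(1.0 / modes.nonzero_values) @ u.T
    s = inv**2
    if normalized:
        s = s / np.diag(s)[:, None]
    return PrsMatrix(values=s, normalized=normalized)


def effector_profile(s: PrsMatrix) -> EffectorProfile:
    """Row means of the PRS matrix, diagonal excluded."""
    n = s.values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues")
    off = s.values.copy()
    np.fill_diagonal(off, 0.0)
    return EffectorProfile(
        values=off.sum(axis=1) / (n - 1), kind="effector", normalized=s.normalized
    )


def sensor_profile(s: PrsMatrix) -> EffectorProfile:
    """Column means of the PRS matrix, diagonal excluded."""
    n = s.values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues")
    off = s.values.copy()
    np.fill_diagonal(off, 0.0)
    return EffectorProfile(
        values=off.sum(axis=0) / (n - 1), kind="sensor", normalized=s.normalized
    )
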