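"""Gaussian-network-model collective dynamics and ensemble PCA.

The GNM reduces a structure to C-alpha nodes joined by uniform springs
within a cutoff (7.0 A default); the Kirchhoff (graph Laplacian) matrix
Gamma encodes the contact topology.  Slow nonzero modes describe
collective motions: the mobility profile averaged over the m slowest
nonzero modes is

    <M_i>|m = sum_k lambda_k^-1 [u^(k)]_i^2 / sum_k lambda_k^-1,

whose minima mark global hinge centres.  PCA of a superposed ensemble
gives the complementary essential-dynamics view, including the
normalized squared displacement over the first three components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from allokin.structures import CaTrace, Ensemble, superpose

__all__ = [
    "KirchhoffMatrix",
    "ModeSet",
    "MobilityProfile",
    "PcaResult",
    "build_kirchhoff",
    "gnm_modes",
    "mobility_profile",
    "identify_hinges",
    "pca_ensemble",
]


@dataclass
class KirchhoffMatrix:
    matrix: np.ndarray
    cutoff: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("Kirchhoff matrix must be symmetric")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def n_components(self) -> int:
        """Connected components of the underlying contact graph."""
        n = self.n
        adj = self.matrix < 0
        seen = np.zeros(n, dtype=bool)
        comps = 0
        for s in range(n):
            if seen[s]:
                continue
            comps += 1
            stack = [s]
            seen[s] = True
            while stack:
                u = stack.pop()
                for v in np.nonzero(adj[u] & ~seen)[0]:
                    seen[v] = True
                    stack.append(int(v))
        return comps


@dataclass
class ModeSet:
    eigenvalues: np.ndarray  # ascending
    eigenvectors: np.ndarray  # columns
    n_zero: int

    @property
    def nonzero_values(self) -> np.ndarray:
        return self.eigenvalues[self.n_zero :]

    @property
    def nonzero_vectors(self) -> np.ndarray:
        return self.eigenvectors[:, self.n_zero :]


@dataclass
class MobilityProfile:
    values: np.ndarray
    n_modes: int
    weights: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class PcaResult:
    eigenvalues: np.ndarray  # descending
    components: np.ndarray  # rows are 3N component vectors
    cumulative_fractions: np.ndarray
    residue_displacement: np.ndarray  # normalized, over first 3 components


def build_kirchhoff(trace: CaTrace, r_c: float = 7.0) -> KirchhoffMatrix:
    """Contact Laplacian: Gamma_ij = -1 if residues within r_c, diag = degree."""
    coords = trace.coords
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    contact = (d <= r_c) & ~np.eye(trace.n_residues, dtype=bool)
    gamma = -contact.astype(float)
    np.fill_diagonal(gamma, contact.sum(axis=1))
    km = KirchhoffMatrix(matrix=gamma, cutoff=r_c)
    if km.n_components() > 1:
        warnings.warn("contact graph is disconnected", stacklevel=2)
    return km


def gnm_modes(gamma: KirchhoffMatrix | np.ndarray) -> ModeSet:
    """Full symmetric eigendecomposition, ascending, zero modes flagged."""
    m = gamma.matrix if isinstance(gamma, KirchhoffMatrix) else np.asarray(gamma, float)
    if not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric")
    vals, vecs = np.linalg.eigh(m)
    lam_max = max(float(vals[-1]), 1.0)
    n_zero = int(np.sum(np.abs(vals) <= 1e-8 * lam_max))
    vals = vals.copy()
    vals[:n_zero] = np.maximum(vals[:n_zero], 0.0)
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero)


def mobility_profile(modes: ModeSet, m: int) -> MobilityProfile:
    """Inverse-eigenvalue-weighted squared mode shapes over m slowest modes."""
    if m < 1:
        raise ValueError("need at least one mode")
    avail = modes.eigenvalues.shape[0] - modes.n_zero
    if m > avail:
        raise ValueError(f"only {avail} nonzero modes available, asked for {m}")
    lam = modes.nonzero_values[:m]
    u = modes.nonzero_vectors[:, :m]
    w = 1.0 / lam
    prof = (u**2) @ w / w.sum()
    return MobilityProfile(values=prof, n_modes=m, weights=w)


def identify_hinges(
    profile: MobilityProfile, window: int = 5, percentile: float = 25.0
) -> set[int]:
    """Residues at local mobility minima below the given percentile.

    A residue is a hinge when it is a minimum within +/- window//2 and
    strictly below the percentile threshold of the whole profile;
    0-based indices are returned.  A flat profile yields no hinges.
    """
    v = profile.values
    n = v.shape[0]
    if n < window:
        raise ValueError("profile shorter than window")
    half = window // 2
    thresh = np.percentile(v, percentile)
    hinges: set[int] = set()
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neigh = v[lo:hi]
        if v[i] <= neigh.min() and v[i] < neigh.max() and v[i] < thresh:
            hinges.add(i)
    return hinges


def pca_ensemble(ensemble: Ensemble, n_components: int = 3, fit: bool = True) -> PcaResult:
    """PCA of the 3N coordinate covariance of a superposed ensemble.

    Frames are superposed onto the (iterated) ensemble mean.  Returns
    the full descending spectrum, the leading component vectors, the
    cumulative variance fractions and the per-residue normalized squared
    displacement D_i over the first three components (eigenvalue
    weighted, sum_i D_i = 1).  ``fit=False`` skips the superposition
    (for ensembles whose frames share a fixed reference frame already).
    """
    f = ensemble.n_frames
    if f < 10:
        raise ValueError("PCA needs at least 10 frames")
    if np.ptp(ensemble.frames, axis=0).max() == 0.0:
        raise ValueError("ensemble has zero covariance")
    frames = ensemble.frames.copy()
    if fit:
        for _ in range(2):
            mean = frames.mean(axis=0)
            for k in range(f):
                frames[k], _ = superpose(frames[k], mean)
    mean = frames.mean(axis=0)
    x = (frames - mean).reshape(f, -1)
    total = float(np.sum(x**2)) / (f - 1)
    if total <= 0:
        raise ValueError("ensemble has zero covariance")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    lam = s**2 / (f - 1)
    frac = np.cumsum(lam) / total
    k3 = min(3, lam.shape[0])
    top = lam[:k3]
    comp = vt[:k3].reshape(k3, -1, 3)
    d = np.einsum("k,kia->i", top, comp**2) / top.sum()
    d = d / d.sum()
    return PcaResult(
        eigenvalues=lam,
        components=vt[: max(n_components, k3)],
        cumulative_fractions=frac,
        residue_displacement=d,
    )
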