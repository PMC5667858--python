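"""Sequence conservation and coupling: KL scores, mutual information,
and the generalized correlation coefficient for ensemble dynamics.

Column conservation is the Kullback-Leibler divergence of the observed
amino-acid frequencies from a background distribution (nats).  Pairwise
sequence coupling is the mutual information of column pairs, optionally
with 62%-identity sequence weighting and APC correction.  Dynamic
coupling between residues i and j is the generalized correlation

    r_MI(x_i, x_j) = sqrt(1 - exp(-2 MI_ij / 3)),

with MI estimated under a Gaussian model from the 3x3 and 6x6 blocks of
the fluctuation covariance.  Edge lengths for network analysis follow
w_ij = -ln r_MI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from allokin.structures import Ensemble, superpose

__all__ = [
    "AMINO_ACIDS",
    "BACKGROUND_FREQUENCIES",
    "Msa",
    "ConservationProfile",
    "CouplingMatrix",
    "read_msa",
    "write_msa",
    "filter_msa",
    "kl_conservation",
    "column_mi",
    "dynamic_rmi",
    "edge_weight",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_AA_INDEX = {a: k for k, a in enumerate(AMINO_ACIDS)}

# Amino-acid background frequencies (UniProt/Swiss-Prot composition,
# rounded); renormalized on use so small drift is harmless.
BACKGROUND_FREQUENCIES = {
    "A": 0.0826, "C": 0.0137, "D": 0.0546, "E": 0.0672, "F": 0.0386,
    "G": 0.0708, "H": 0.0227, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}


@dataclass
class Msa:
    """Aligned sequences over the 20-letter alphabet plus gap."""

    names: list[str]
    sequences: list[str]
    reference: int = 0
    column_map: list[int] | None = None  # column -> structure residue index

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an MSA needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: sequences differ in length")
        if not 0 <= self.reference < len(self.sequences):
            raise ValueError("reference index out of range")

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def encoded(self) -> np.ndarray:
        """(n_seq, n_col) int8 matrix; 0..19 amino acids, -1 gap/unknown."""
        out = np.full((self.n_sequences, self.n_columns), -1, dtype=np.int8)
        for s, seq in enumerate(self.sequences):
            for c, a in enumerate(seq):
                out[s, c] = _AA_INDEX.get(a.upper(), -1)
        return out


@dataclass
class ConservationProfile:
    scores: np.ndarray  # per-column, nats
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)


@dataclass
class CouplingMatrix:
    """Symmetric pairwise coupling: sequence MI (nats) or dynamic r_MI."""

    values: np.ndarray
    kind: str  # "sequence_MI" | "dynamic_rMI"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("coupling matrix must be square")


def read_msa(text: str) -> Msa:
    """Parse an aligned FASTA stream."""
    names: list[str] = []
    seqs: list[str] = []
    cur: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if names:
                seqs.append("".join(cur))
            names.append(line[1:].split()[0] if len(line) > 1 else "")
            cur = []
        else:
            cur.append(line)
    if names:
        seqs.append("".join(cur))
    if len(names) < 2:
        raise ValueError("FASTA alignment needs at least 2 records")
    return Msa(names=names, sequences=seqs)


def write_msa(msa: Msa, width: int = 60) -> str:
    out = []
    for name, seq in zip(msa.names, msa.sequences):
        out.append(">" + name)
        for k in range(0, len(seq), width):
            out.append(seq[k : k + width])
    return "\n".join(out) + "\n"


def filter_msa(msa: Msa, min_coverage: float = 0.5) -> Msa:
    """Drop sequences covering less than ``min_coverage`` of the reference.

    Coverage is the fraction of the reference's non-gap columns at which
    a sequence is also non-gap; sequences strictly below the threshold
    are removed and the reference is always retained.
    """
    ref = msa.sequences[msa.reference]
    ref_cols = [c for c, a in enumerate(ref) if a != GAP]
    if not ref_cols:
        raise ValueError("reference sequence is all gaps")
    keep: list[int] = []
    for s, seq in enumerate(msa.sequences):
        cov = sum(1 for c in ref_cols if seq[c] != GAP) / len(ref_cols)
        if cov >= min_coverage or s == msa.reference:
            keep.append(s)
    if not keep:
        raise ValueError("coverage filter removed every sequence")
    new_ref = keep.index(msa.reference)
    return Msa(
        names=[msa.names[s] for s in keep],
        sequences=[msa.sequences[s] for s in keep],
        reference=new_ref,
        column_map=msa.column_map,
    )


def _background_vector(background) -> np.ndarray:
    if background is None:
        q = np.array([BACKGROUND_FREQUENCIES[a] for a in AMINO_ACIDS])
    elif isinstance(background, dict):
        q = np.array([background[a] for a in AMINO_ACIDS])
    else:
        q = np.asarray(background, dtype=float)
    if q.shape != (20,) or np.any(q <= 0):
        raise ValueError("background must be 20 positive frequencies")
    return q / q.sum()


def kl_conservation(
    msa: Msa, background=None, pseudocount: float = 0.0
) -> ConservationProfile:
    """Per-column KL conservation score, KL = sum_a P(a) ln(P(a)/Q(a)).

    Gaps are excluded from the counts; ``pseudocount`` is added to every
    amino-acid count before normalizing when positive.  An all-gap
    column scores 0 with a warning.
    """
    q = _background_vector(background)
    enc = msa.encoded()
    n_col = msa.n_columns
    scores = np.zeros(n_col)
    for c in range(n_col):
        col = enc[:, c]
        col = col[col >= 0]
        if col.size == 0:
            warnings.warn(f"column {c} is all gaps; score set to 0", stacklevel=2)
            continue
        counts = np.bincount(col, minlength=20).astype(float) + pseudocount
        p = counts / counts.sum()
        nz = p > 0
        scores[c] = float(np.sum(p[nz] * np.log(p[nz] / q[nz])))
    return ConservationProfile(scores=scores, background=q, pseudocount=pseudocount)


def sequence_weights(msa: Msa, identity: float = 0.62) -> np.ndarray:
    """Redundancy weights: 1 / (number of sequences >= 62% identical).

    Identity between two aligned sequences counts positions where both
    are non-gap and equal, over positions where either is non-gap.
    """
    enc = msa.encoded()
    n = enc.shape[0]
    counts = _identity_cluster_sizes(enc, float(identity))
    return 1.0 / counts.astype(float) if n else np.ones(0)


def _identity_cluster_sizes(enc: np.ndarray, identity: float) -> np.ndarray:
    try:
        from allokin._kernels import identity_cluster_sizes as fast

        return fast(enc, identity)
    except ImportError:  # pragma: no cover - numba always present in practice
        n = enc.shape[0]
        counts = np.ones(n, dtype=np.int64)
        for i in range(n):
            for j in range(i + 1, n):
                both = (enc[i] >= 0) | (enc[j] >= 0)
                denom = int(both.sum())
                if denom == 0:
                    continue
                match = int(((enc[i] == enc[j]) & (enc[i] >= 0)).sum())
                if match / denom >= identity:
                    counts[i] += 1
                    counts[j] += 1
        return counts


def column_mi(
    msa: Msa,
    weighting: bool = True,
    apc: bool = False,
    bias_correction: bool = True,
    min_pairs: int = 10,
) -> CouplingMatrix:
    """Pairwise column mutual information in nats.

    Gapped rows are excluded pairwise; pairs with fewer than
    ``min_pairs`` ungapped rows are marked missing (NaN).  Sequence
    weighting clusters at 62% identity with weight 1/cluster-size; the
    default Miller-Madow correction subtracts the finite-sample bias
    (k_x - 1)(k_y - 1) / (2 n_eff) so independent columns score near 0;
    APC subtracts the average-product background.
    """
    enc = msa.encoded()
    n_seq, n_col = enc.shape
    if n_seq < 25:
        warnings.warn("fewer than 25 sequences; MI estimates will be noisy", stacklevel=2)
    w = sequence_weights(msa) if weighting else np.ones(n_seq)
    mi = np.full((n_col, n_col), np.nan)
    np.fill_diagonal(mi, 0.0)
    for x in range(n_col):
        ax = enc[:, x]
        for y in range(x + 1, n_col):
            ay = enc[:, y]
            ok = (ax >= 0) & (ay >= 0)
            if int(ok.sum()) < min_pairs:
                continue
            code = ax[ok].astype(np.int64) * 20 + ay[ok]
            wk = w[ok]
            joint = np.bincount(code, weights=wk, minlength=400).reshape(20, 20)
            joint /= joint.sum()
            px = joint.sum(axis=1)
            py = joint.sum(axis=0)
            nz = joint > 0
            val = float(np.sum(joint[nz] * np.log(joint[nz] / np.outer(px, py)[nz])))
            if bias_correction:
                # Miller-Madow, with the effective (weighted) sample size
                n_eff = float(wk.sum()) ** 2 / float(np.sum(wk**2))
                kx = int(np.sum(px > 0))
                ky = int(np.sum(py > 0))
                val -= (kx - 1) * (ky - 1) / (2.0 * n_eff)
            mi[x, y] = mi[y, x] = max(val, 0.0)
    if apc:
        off = mi.copy()
        np.fill_diagonal(off, np.nan)
        row_mean = np.nanmean(off, axis=1)
        total = np.nanmean(off)
        corr = np.outer(row_mean, row_mean) / total if total > 0 else 0.0
        mi = mi - corr
        np.fill_diagonal(mi, 0.0)
    return CouplingMatrix(values=mi, kind="sequence_MI", meta={"weighting": weighting, "apc": apc})


def dynamic_rmi(ensemble: Ensemble, fit: bool = True) -> CouplingMatrix:
    """Generalized correlation r_MI between residue fluctuation vectors.

    Frames are superposed to the ensemble mean, per-residue fluctuation
    vectors are extracted, and the Gaussian mutual information

        MI_ij = 1/2 ln( det C_i det C_j / det C_ij )

    is computed from the 3x3 marginal and 6x6 joint covariance blocks,
    then mapped to r_MI = sqrt(1 - exp(-2 MI / 3)) in [0, 1].
    """
    if ensemble.n_frames < 100:
        raise ValueError("dynamic r_MI needs at least 100 frames")
    frames = ensemble.frames.copy()
    if fit:
        for _ in range(2):
            mean = frames.mean(axis=0)
            for f in range(frames.shape[0]):
                frames[f], _ = superpose(frames[f], mean)
    mean = frames.mean(axis=0)
    dr = frames - mean  # (F, N, 3)
    n = ensemble.n_residues
    f = ensemble.n_frames
    flat = dr.transpose(1, 2, 0).reshape(n * 3, f)  # residue-major rows
    cov = flat @ flat.T / (f - 1)
    r = np.full((n, n), np.nan)
    np.fill_diagonal(r, 1.0)
    logdet3 = np.empty(n)
    for i in range(n):
        ci = cov[3 * i : 3 * i + 3, 3 * i : 3 * i + 3]
        sign, ld = np.linalg.slogdet(ci)
        logdet3[i] = ld if sign > 0 else np.nan
    for i in range(n):
        if not np.isfinite(logdet3[i]):
            continue
        for j in range(i + 1, n):
            if not np.isfinite(logdet3[j]):
                continue
            idx = np.r_[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
            cij = cov[np.ix_(idx, idx)]
            sign, ld = np.linalg.slogdet(cij)
            if sign <= 0:
                continue
            mi = 0.5 * (logdet3[i] + logdet3[j] - ld)
            mi = max(mi, 0.0)
            r[i, j] = r[j, i] = min(np.sqrt(1.0 - np.exp(-2.0 * mi / 3.0)), 1.0)
    return CouplingMatrix(values=r, kind="dynamic_rMI", meta={"n_frames": f})


def edge_weight(r: float, floor: float = 1e-4) -> float:
    """Edge length from a generalized correlation: w = -ln(max(r, floor))."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r_MI must lie in [0, 1], got {r}")
    return float(-np.log(max(r, floor)))


def gaussian_mi_1d(rho: float) -> float:
    """Closed-form scalar Gaussian MI, -1/2 ln(1 - rho^2)."""
    return -0.5 * float(np.log(1.0 - rho * rho))
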