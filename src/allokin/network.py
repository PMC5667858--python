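"""Ensemble-averaged residue interaction networks and their analysis.

Residues are nodes; edges come either from C-alpha contact maps of an
ensemble or from side-chain interaction strengths of all-atom
conformers, filtered by cross-frame occupancy.  Edge lengths are
w_ij = -ln r_MI from the coupling stage, so strongly coupled residues
are close in communication distance.  On that graph the module computes
Floyd-Warshall all-pairs shortest-path ensembles, node betweenness

    C_b(n_i) = sum_{j<k} g_jk(i) / g_jk,

edge betweenness, Girvan-Newman modularity-selected partitions, k-clique
(clique-percolation) communities with the k-1 or k-2 adjacency rule, and
cross-frame community stability (communities recurring in more than 75%
of the conformations).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ResidueGraph",
    "PathMatrix",
    "CentralityProfile",
    "CommunitySet",
    "SIDECHAIN_NORMALIZATION",
    "build_rin",
    "shortest_paths",
    "node_betweenness",
    "edge_betweenness",
    "girvan_newman",
    "modularity",
    "k_clique_communities",
    "community_stability",
]

_REL_TOL = 1e-12  # relative tie tolerance on path lengths

# Residue-type normalization values N_i for the side-chain interaction
# strength I_ij = 100 n_ij / sqrt(N_i N_j) (maximal expected contact
# counts per residue type, standard interaction-strength table).
SIDECHAIN_NORMALIZATION = {
    "ALA": 55.76, "ARG": 93.79, "ASN": 73.41, "ASP": 75.15, "CYS": 54.95,
    "GLN": 78.13, "GLU": 78.83, "GLY": 47.31, "HIS": 83.74, "ILE": 67.95,
    "LEU": 72.25, "LYS": 69.61, "MET": 69.26, "PHE": 93.31, "PRO": 51.33,
    "SER": 61.39, "THR": 63.71, "TRP": 106.70, "TYR": 100.72, "VAL": 62.37,
}
_BACKBONE = {"N", "CA", "C", "O", "H", "OXT", "HA", "H1", "H2", "H3"}


@dataclass
class ResidueGraph:
    """Weighted undirected residue interaction graph.

    ``edges`` maps (i, j) with i < j to (length w_ij, occupancy).
    """

    n_nodes: int
    edges: dict[tuple[int, int], tuple[float, float]]
    node_ids: list | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), (w, occ) in self.edges.items():
            if not (0 <= i < j < self.n_nodes):
                raise ValueError(f"bad edge ({i},{j})")
            if w < 0 or not 0 <= occ <= 1:
                raise ValueError("edge weight must be >= 0 and occupancy in [0,1]")

    def weight_matrix(self) -> np.ndarray:
        d = np.full((self.n_nodes, self.n_nodes), np.inf)
        np.fill_diagonal(d, 0.0)
        for (i, j), (w, _) in self.edges.items():
            d[i, j] = d[j, i] = w
        return d

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (i, j), (w, occ) in self.edges.items():
            g.add_edge(i, j, weight=w, occupancy=occ)
        return g

    def to_tsv(self) -> str:
        lines = ["i\tj\tw\toccupancy"]
        for (i, j) in sorted(self.edges):
            w, occ = self.edges[(i, j)]
            lines.append(f"{i}\t{j}\t{w:.6g}\t{occ:.4g}")
        return "\n".join(lines) + "\n"


@dataclass
class PathMatrix:
    distances: np.ndarray
    counts: np.ndarray  # g_jk, number of shortest paths per pair


@dataclass
class CentralityProfile:
    node_values: np.ndarray
    edge_values: dict[tuple[int, int], float] = field(default_factory=dict)


@dataclass
class CommunitySet:
    communities: list[frozenset[int]]
    modularity: float | None = None
    k: int | None = None
    stability: list[float] | None = None

    def as_partition(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c, members in enumerate(self.communities):
            for v in members:
                out[v] = c
        return out


def _couplings_as_r(coupling, n: int, floor: float = 1e-4) -> np.ndarray:
    vals = np.asarray(coupling.values if hasattr(coupling, "values") else coupling, float)
    if vals.shape != (n, n):
        raise ValueError("coupling matrix does not cover all residues")
    r = np.where(np.isfinite(vals), vals, floor)
    if np.any((r < 0) | (r > 1)):
        raise ValueError("coupling values must lie in [0, 1] for edge weighting")
    return np.maximum(r, floor)


def build_rin(
    frames,
    coupling,
    mode: str = "ca_contact",
    ca_cutoff: float = 7.5,
    atom_cutoff: float = 4.5,
    i_min: float = 3.0,
    occupancy_min: float = 0.5,
) -> ResidueGraph:
    """Residue interaction graph from an ensemble plus a coupling matrix.

    ``ca_contact`` mode takes an :class:`~allokin.structures.Ensemble`
    and places an edge wherever the C-alpha distance is within
    ``ca_cutoff`` in a frame; ``atom_interaction_strength`` takes a list
    of all-atom conformers and uses the side-chain interaction strength
    I_ij = 100 n_ij / sqrt(N_i N_j) against ``i_min``.  Edges present in
    at least ``occupancy_min`` of the frames are kept and weighted by
    w_ij = -ln r_MI from ``coupling``.
    """
    if mode == "ca_contact":
        ens = frames
        if ens.n_frames == 0:
            raise ValueError("empty frame list")
        n = ens.n_residues
        hits = np.zeros((n, n))
        for f in range(ens.n_frames):
            c = ens.frames[f]
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=2)
            hits += (d <= ca_cutoff).astype(float)
        occ = hits / ens.n_frames
        node_ids = list(ens.residue_ids)
    elif mode == "atom_interaction_strength":
        structures = list(frames)
        if not structures:
            raise ValueError("empty frame list")
        occ = None
        node_ids = None
        for s in structures:
            o, ids = _interaction_strength_contacts(s, atom_cutoff, i_min)
            if occ is None:
                occ, node_ids = o.astype(float), ids
            else:
                if ids != node_ids:
                    raise ValueError("residue mismatch between conformers")
                occ += o
        occ /= len(structures)
        n = occ.shape[0]
    else:
        raise ValueError(f"unknown RIN mode {mode!r}")
    r = _couplings_as_r(coupling, n)
    edges: dict[tuple[int, int], tuple[float, float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            if occ[i, j] >= occupancy_min:
                w = float(-np.log(max(r[i, j], 1e-4)))
                edges[(i, j)] = (w, float(occ[i, j]))
    return ResidueGraph(
        n_nodes=n, edges=edges, node_ids=node_ids,
        meta={"mode": mode, "ca_cutoff": ca_cutoff, "atom_cutoff": atom_cutoff,
              "i_min": i_min, "occupancy_min": occupancy_min},
    )


def _interaction_strength_contacts(s, atom_cutoff: float, i_min: float):
    ridx = s.residue_index()
    n = int(ridx.max()) + 1
    ids: list = []
    seen = set()
    resname_of = {}
    for a in range(s.n_atoms):
        if ridx[a] not in seen:
            seen.add(ridx[a])
            ids.append((s.chains[a], s.res_numbers[a], s.icodes[a]))
            resname_of[int(ridx[a])] = s.res_names[a]
    side = [
        a for a in range(s.n_atoms)
        if s.atom_names[a] not in _BACKBONE and s.elements[a] != "H"
    ]
    n_ij = np.zeros((n, n))
    for ai_pos, a in enumerate(side):
        for b in side[ai_pos + 1 :]:
            ri, rj = int(ridx[a]), int(ridx[b])
            if ri == rj:
                continue
            if np.linalg.norm(s.coords[a] - s.coords[b]) <= atom_cutoff:
                n_ij[ri, rj] += 1
                n_ij[rj, ri] += 1
    norm = np.array(
        [SIDECHAIN_NORMALIZATION.get(resname_of[i], 60.0) for i in range(n)]
    )
    strength = 100.0 * n_ij / np.sqrt(np.outer(norm, norm))
    return strength >= i_min, ids


def shortest_paths(g: ResidueGraph) -> PathMatrix:
    """All-pairs shortest distances (Floyd-Warshall) and path counts.

    Counts are accumulated per source over the shortest-path DAG with a
    relative tie tolerance of 1e-12 on path length; disconnected pairs
    have infinite distance and zero count.
    """
    d = g.weight_matrix()
    n = g.n_nodes
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    counts = np.zeros((n, n))
    edge_items = [(i, j, w) for (i, j), (w, _) in g.edges.items()]
    for s in range(n):
        ds = d[s]
        order = np.argsort(ds, kind="stable")
        cnt = np.zeros(n)
        cnt[s] = 1.0
        incoming: dict[int, list[tuple[int, float]]] = {v: [] for v in range(n)}
        for i, j, w in edge_items:
            incoming[j].append((i, w))
            incoming[i].append((j, w))
        for v in order:
            if v == s or not np.isfinite(ds[v]):
                continue
            tot = 0.0
            for u, w in incoming[v]:
                if np.isfinite(ds[u]) and abs(ds[u] + w - ds[v]) <= _REL_TOL * max(1.0, ds[v]):
                    tot += cnt[u]
            cnt[v] = tot
        counts[s] = cnt
    np.fill_diagonal(counts, 0.0)
    return PathMatrix(distances=d, counts=counts)


def _on_path(d: np.ndarray, i: int) -> np.ndarray:
    """Boolean (j,k) mask: node i lies on a shortest j-k path."""
    via = d[:, i, None] + d[None, i, :]
    return np.abs(via - d) <= _REL_TOL * np.maximum(1.0, np.abs(d))


def _finite_dist(d: np.ndarray) -> np.ndarray:
    # large sentinel keeps inf - inf out of the tie comparisons; the
    # finite/count masks already exclude disconnected pairs
    return np.where(np.isfinite(d), d, 1.0e30)


def node_betweenness(g: ResidueGraph, paths: PathMatrix | None = None) -> CentralityProfile:
    """Unnormalized weighted betweenness, C_b(i) = sum_{j<k} g_jk(i)/g_jk."""
    if paths is None:
        paths = shortest_paths(g)
    cnt = paths.counts
    d = _finite_dist(paths.distances)
    n = g.n_nodes
    vals = np.zeros(n)
    finite = np.isfinite(paths.distances) & (cnt > 0)
    for i in range(n):
        mask = _on_path(d, i) & finite
        mask[i, :] = False
        mask[:, i] = False
        through = np.where(mask, np.outer(cnt[:, i], cnt[i, :]), 0.0)
        frac = np.where(finite, through / np.where(cnt > 0, cnt, 1.0), 0.0)
        vals[i] = float(np.sum(np.triu(frac, k=1)))
    return CentralityProfile(node_values=vals)


def edge_betweenness(g: ResidueGraph, paths: PathMatrix | None = None) -> dict[tuple[int, int], float]:
    """Per-edge sum over node pairs of the fraction of shortest paths using it."""
    if paths is None:
        paths = shortest_paths(g)
    d = _finite_dist(paths.distances)
    cnt = paths.counts
    # endpoints reach themselves through one (empty) path
    cnt_eff = cnt.copy()
    np.fill_diagonal(cnt_eff, 1.0)
    finite = np.isfinite(paths.distances) & (cnt > 0)
    out: dict[tuple[int, int], float] = {}
    tol = _REL_TOL * np.maximum(1.0, np.abs(d))
    for (u, v), (w, _) in g.edges.items():
        use_uv = np.abs(d[:, u, None] + w + d[None, v, :] - d) <= tol
        use_vu = np.abs(d[:, v, None] + w + d[None, u, :] - d) <= tol
        through = (
            np.where(use_uv, np.outer(cnt_eff[:, u], cnt_eff[v, :]), 0.0)
            + np.where(use_vu, np.outer(cnt_eff[:, v], cnt_eff[u, :]), 0.0)
        )
        frac = np.where(finite, through / np.where(cnt > 0, cnt, 1.0), 0.0)
        np.fill_diagonal(frac, 0.0)
        out[(u, v)] = float(np.sum(np.triu(frac, k=1)))
    return out


def _components(n: int, edges) -> list[set[int]]:
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in edges:
        parent[find(i)] = find(j)
    comps: dict[int, set[int]] = {}
    for v in range(n):
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


def modularity(g: ResidueGraph, communities: list[frozenset[int]] | list[set[int]]) -> float:
    """Newman modularity with r_MI affinities A_ij = exp(-w_ij)."""
    label = {}
    for c, members in enumerate(communities):
        for v in members:
            label[v] = c
    two_m = 0.0
    strength = np.zeros(g.n_nodes)
    for (i, j), (w, _) in g.edges.items():
        a = np.exp(-w)
        two_m += 2 * a
        strength[i] += a
        strength[j] += a
    if two_m == 0:
        return 0.0
    q = 0.0
    for (i, j), (w, _) in g.edges.items():
        if label[i] == label[j]:
            q += 2 * np.exp(-w)
    for c in range(len(communities)):
        s = sum(strength[v] for v in communities[c])
        q -= s * s / two_m
    return q / two_m


def girvan_newman(g: ResidueGraph) -> CommunitySet:
    """Iterative removal of the highest-betweenness edge.

    Edge betweenness is recomputed after every removal (ties broken by
    lexicographic edge id); the partition recorded at each component
    split that maximizes the modularity (with exp(-w) affinities, on the
    original graph) is returned.
    """
    if not g.edges:
        comms = [frozenset([v]) for v in range(g.n_nodes)]
        return CommunitySet(communities=comms, modularity=modularity(g, comms))
    work = dict(g.edges)
    best_comms = [frozenset(c) for c in _components(g.n_nodes, work)]
    best_q = modularity(g, best_comms)
    n_comp = len(best_comms)
    while work:
        sub = ResidueGraph(n_nodes=g.n_nodes, edges=dict(work))
        eb = edge_betweenness(sub)
        top = max(eb.values())
        cut = min(e for e, v in eb.items() if v >= top - 1e-12 * max(1.0, top))
        del work[cut]
        comps = _components(g.n_nodes, work)
        if len(comps) > n_comp:
            n_comp = len(comps)
            q = modularity(g, comps)
            if q > best_q:
                best_q = q
                best_comms = [frozenset(c) for c in comps]
    return CommunitySet(communities=sorted(best_comms, key=min), modularity=best_q)


def _k_cliques(g: ResidueGraph, k: int) -> list[frozenset[int]]:
    out: set[frozenset[int]] = set()
    for maximal in nx.find_cliques(g.to_networkx()):
        if len(maximal) >= k:
            for sub in itertools.combinations(sorted(maximal), k):
                out.add(frozenset(sub))
    return sorted(out, key=sorted)


def k_clique_communities(
    g: ResidueGraph, k: int = 3, share: int | None = None
) -> CommunitySet:
    """Clique-percolation communities: components of the k-clique graph.

    Two k-cliques are adjacent when they share at least ``share`` nodes
    (default k-1; the k-2 variant is the relaxed adjacency rule).
    Communities are node unions and may overlap.
    """
    if k < 3:
        raise ValueError("k must be >= 3")
    if share is None:
        share = k - 1
    if not k - 2 <= share <= k - 1:
        raise ValueError("share must be k-1 or k-2")
    cliques = _k_cliques(g, k)
    m = len(cliques)
    if m == 0:
        return CommunitySet(communities=[], k=k)
    adj_edges = [
        (a, b)
        for a in range(m)
        for b in range(a + 1, m)
        if len(cliques[a] & cliques[b]) >= share
    ]
    comms = []
    for comp in _components(m, adj_edges):
        members: set[int] = set()
        for c in comp:
            members |= cliques[c]
        comms.append(frozenset(members))
    return CommunitySet(communities=sorted(comms, key=min), k=k)


def _jaccard(a: frozenset, b: frozenset) -> float:
    u = len(a | b)
    return len(a & b) / u if u else 0.0


def _similarity(p: CommunitySet, q: CommunitySet) -> float:
    if not p.communities:
        return 0.0
    return float(
        np.mean([max((_jaccard(c, d) for d in q.communities), default=0.0)
                 for c in p.communities])
    )


def community_stability(
    partitions: list[CommunitySet],
    stability_min: float = 0.75,
    match_jaccard: float = 0.6,
) -> CommunitySet:
    """Communities stable across frames.

    The consensus frame is the one whose communities have the highest
    mean similarity to all other frames; each of its communities is kept
    when some community matches it (Jaccard >= ``match_jaccard``) in
    strictly more than ``stability_min`` of the frames.
    """
    if len(partitions) < 2:
        raise ValueError("need at least 2 frames of partitions")
    node_sets = {frozenset().union(*p.communities) if p.communities else frozenset()
                 for p in partitions}
    if len(node_sets) > 1:
        raise ValueError("frame node sets differ")
    sims = [
        np.mean([_similarity(p, q) for q in partitions])
        for p in partitions
    ]
    consensus = partitions[int(np.argmax(sims))]
    kept = []
    freqs = []
    n_frames = len(partitions)
    for c in consensus.communities:
        hits = sum(
            1 for p in partitions
            if any(_jaccard(c, d) >= match_jaccard for d in p.communities)
        )
        freq = hits / n_frames
        if freq > stability_min:
            kept.append(c)
            freqs.append(freq)
    return CommunitySet(communities=kept, stability=freqs)
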