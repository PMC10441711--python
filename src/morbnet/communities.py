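"""Walktrap community detection and bootstrap community stability.

Communities are detected on the absolute edge weights |w| of an estimated
network (Ising couplings can be negative; random-walk transition
probabilities cannot), using the Walktrap algorithm: nodes whose short random
walks (t = 4 steps by default) have similar visit profiles are merged
agglomeratively, and the merge tree is cut at the level maximising weighted
modularity. Stability follows the bootstrap protocol of re-estimating the
network on resampled rows, re-running Walktrap, aligning the bootstrap labels
to the original partition by maximum-overlap (Hungarian) matching, and
summarising per-node membership across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .catalog import NETWORK_NODES
from .ising import EstimatorConfig, IsingNetwork, estimate_network


@dataclass
class CommunityPartition:
    """Node-to-community assignment with the modularity of the cut."""

    membership: dict[str, int]
    walk_length: int
    modularity: float
    method: str = "walktrap"

    def __post_init__(self):
        if not (-0.5 - 1e-12 <= self.modularity <= 1.0 + 1e-12):
            raise ValueError(f"modularity {self.modularity} outside [-0.5, 1]")

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def labels_for(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.membership[n] for n in nodes])


def _affinity_graph(network: IsingNetwork) -> tuple[ig.Graph, list[float]]:
    A = np.abs(network.weights)
    p = network.p
    edges, w = [], []
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] > 0:
                edges.append((i, j))
                w.append(float(A[i, j]))
    g = ig.Graph(p, edges)
    return g, w


def walktrap(network: IsingNetwork, t: int = 4) -> CommunityPartition:
    """Walktrap partition of a network on |w| affinities.

    Isolated nodes become singleton communities; an all-zero network yields
    all singletons with Q = 0.
    """
    g, w = _affinity_graph(network)
    if not w:
        return CommunityPartition(
            membership={n: i for i, n in enumerate(network.nodes)},
            walk_length=t, modularity=0.0,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # igraph warns on unconnected graphs
        clustering = g.community_walktrap(weights=w, steps=t).as_clustering()
    membership = {n: int(c) for n, c in zip(network.nodes, clustering.membership)}
    q = g.modularity(clustering.membership, weights=w)
    return CommunityPartition(membership=membership, walk_length=t, modularity=float(q))


def modularity_matrix_eigenvalues(network: IsingNetwork) -> np.ndarray:
    """Sorted (descending) eigenvalues of the weighted modularity matrix.

    B_ij = A_ij - k_i k_j / (2m) on A = |w|; reported per bootstrap replicate
    as the stability diagnostic ("eigenvalue verification"). An all-zero
    network returns all zeros.
    """
    A = np.abs(network.weights)
    two_m = A.sum()
    if two_m == 0:
        return np.zeros(network.p)
    k = A.sum(axis=1)
    B = A - np.outer(k, k) / two_m
    return np.sort(np.linalg.eigvalsh(B))[::-1]


def align_partition(
    reference: np.ndarray, candidate: np.ndarray
) -> np.ndarray:
    """Relabel `candidate` to maximise overlap with `reference`.

    Hungarian matching on the label co-occurrence matrix; candidate
    communities beyond the number of reference communities keep fresh labels.
    Entries may be NaN (node missing in the candidate); they stay NaN.
    """
    ref = np.asarray(reference, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    ok = ~(np.isnan(ref) | np.isnan(cand))
    ref_labels = np.unique(ref[ok]).astype(int)
    cand_labels = np.unique(cand[ok]).astype(int)
    overlap = np.zeros((len(cand_labels), len(ref_labels)))
    for a, ca in enumerate(cand_labels):
        for b, rb in enumerate(ref_labels):
            overlap[a, b] = np.sum((cand[ok] == ca) & (ref[ok] == rb))
    rows, cols = linear_sum_assignment(-overlap)
    mapping = {cand_labels[a]: ref_labels[b] for a, b in zip(rows, cols)}
    next_label = (max(ref_labels) + 1) if len(ref_labels) else 0
    out = np.full_like(cand, np.nan)
    for ca in cand_labels:
        if ca not in mapping:
            mapping[ca] = next_label
            next_label += 1
    for i in range(len(cand)):
        if not np.isnan(cand[i]):
            out[i] = mapping[int(cand[i])]
    return out


@dataclass
class CommunityStability:
    """Bootstrap summary of community membership for one stratum."""

    nodes: list[str]
    original: CommunityPartition
    memberships: np.ndarray  # (n_boot, p) aligned labels, NaN = node dropped
    consensus: np.ndarray  # (p,) modal aligned label per node
    median_label: np.ndarray  # (p,) median aligned label (wording-faithful)
    agreement: np.ndarray  # (p,) share of replicates matching consensus
    modularities: np.ndarray  # (n_boot,)
    eigen_summary: np.ndarray  # (n_boot, p) modularity-matrix spectra
    n_boot: int

    def is_stable(self, agreement_floor: float = 0.8, modularity_floor: float = 0.05) -> bool:
        """Heuristic stability flag.

        Stable when nodes agree with the consensus in at least
        ``agreement_floor`` of replicates on average, the consensus contains
        a genuine (non-singleton) community, and the bootstrap networks carry
        community structure (median modularity above ``modularity_floor``).
        Structureless (noise) data fails the modularity clause even when the
        trivial all-singleton partition is reproduced exactly.
        """
        _, counts = np.unique(self.consensus, return_counts=True)
        has_group = bool((counts >= 2).any())
        return (
            float(np.nanmean(self.agreement)) >= agreement_floor
            and has_group
            and float(np.median(self.modularities)) >= modularity_floor
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "community": self.original.labels_for(self.nodes),
                "consensus": self.consensus,
                "median_label": self.median_label,
                "agreement": self.agreement,
            }
        )


def community_bootstrap(
    table: pd.DataFrame,
    config: EstimatorConfig | None = None,
    n_boot: int = 100,
    seed: int = 0,
    t: int = 4,
    nodes: tuple[str, ...] = NETWORK_NODES,
) -> CommunityStability:
    """Re-estimate network + Walktrap on `n_boot` row resamples.

    Each replicate draws n rows with replacement, re-runs the full estimator
    and Walktrap, and aligns labels to the original partition. Nodes constant
    within a replicate are dropped there and recorded as missing membership.
    Consensus is the per-node modal aligned label (ties broken by a seeded
    uniform choice); the median aligned label is reported alongside.
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    cfg = config or EstimatorConfig()
    rng = np.random.default_rng(seed)
    node_list = list(nodes)
    X = table[node_list].to_numpy(float)
    n, p = X.shape

    original_net = estimate_network(X, node_list, cfg)
    original = walktrap(original_net, t=t)
    ref_labels = original.labels_for(original_net.nodes).astype(float)
    # reference over the full node list (NaN where dropped in the original)
    ref_full = np.full(p, np.nan)
    for i, name in enumerate(node_list):
        if name in original.membership:
            ref_full[i] = original.membership[name]

    memberships = np.full((n_boot, p), np.nan)
    modularities = np.empty(n_boot)
    spectra = np.zeros((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(n, size=n)
        net = estimate_network(X[idx], node_list, cfg)
        part = walktrap(net, t=t)
        raw = np.full(p, np.nan)
        for i, name in enumerate(node_list):
            if name in part.membership:
                raw[i] = part.membership[name]
        memberships[b] = align_partition(ref_full, raw)
        modularities[b] = part.modularity
        ev = modularity_matrix_eigenvalues(net)
        spectra[b, : len(ev)] = ev

    consensus = np.empty(p)
    agreement = np.empty(p)
    median_label = np.nanmedian(memberships, axis=0)
    for i in range(p):
        col = memberships[:, i]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            consensus[i] = np.nan
            agreement[i] = np.nan
            continue
        labels, counts = np.unique(col, return_counts=True)
        top = labels[counts == counts.max()]
        consensus[i] = top[0] if len(top) == 1 else rng.choice(top)
        agreement[i] = np.mean(col == consensus[i])

    return CommunityStability(
        nodes=node_list, original=original, memberships=memberships,
        consensus=consensus, median_label=median_label, agreement=agreement,
        modularities=modularities, eigen_summary=spectra, n_boot=n_boot,
    )


def name_communities(
    partition: CommunityPartition, naming: dict[int, str] | None = None
) -> dict[int, str]:
    """Human-readable group labels.

    Automatic names concatenate member node names (in canonical node order)
    with an en dash, so any permutation of community ids yields the same set
    of names.
    """
    groups: dict[int, list[str]] = {}
    for node, c in partition.membership.items():
        groups.setdefault(c, []).append(node)
    if naming is not None:
        missing = set(groups) - set(naming)
        if missing:
            raise KeyError(f"no names supplied for communities {sorted(missing)}")
        return {c: naming[c] for c in groups}
    node_order = {n: i for i, n in enumerate(partition.membership)}
    return {
        c: "–".join(sorted(members, key=node_order.get))
        for c, members in groups.items()
    }
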