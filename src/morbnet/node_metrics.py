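"""Node predictability and centrality measures on an estimated network.

Predictability is the correct-classification rate (CC): how well a node's
observed state is classified by the logistic conditional implied by its
estimated neighbourhood, thresholded at 0.5. It is compared with the best
constant classifier, CC_baseline = max(prevalence, 1 - prevalence), which any
informative neighbourhood must beat.

Centralities use absolute edge weights (negative couplings would break
distance semantics): strength is the summed |w|; shortest-path measures use
edge lengths 1/|w|; closeness of a node is (reachable - 1) / (sum of
distances to reachable nodes), so isolated nodes and cross-component pairs
are handled without infinities; betweenness is the unnormalised count of
weighted shortest paths through a node; the participation coefficient
P_i = 1 - sum_s (kappa_is / kappa_i)^2 measures how evenly a node's strength
spreads over communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .communities import CommunityPartition
from .ising import IsingNetwork

logger = logging.getLogger(__name__)


@dataclass
class NodeMetrics:
    table: pd.DataFrame  # node, cc, cc_baseline, strength, closeness, betweenness, participation

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def predictability_cc(
    data: pd.DataFrame, network: IsingNetwork
) -> pd.DataFrame:
    """In-sample correct classification per node, with the constant baseline.

    For each node i: predict x_i = 1 when
    logistic(tau_i + sum_j w_ij x_j) > 0.5; CC is the fraction of persons
    classified correctly. Nodes absent from the network (dropped during
    estimation) are skipped with a log note.
    """
    rows = []
    skipped = [c for c in network.dropped_nodes]
    if skipped:
        logger.info("predictability: skipping dropped nodes %s", skipped)
    X = data[network.nodes].to_numpy(float)
    for i, name in enumerate(network.nodes):
        eta = network.thresholds[i] + X @ network.weights[:, i]
        pred = (expit(eta) > 0.5).astype(float)
        cc = float(np.mean(pred == X[:, i]))
        prev = float(X[:, i].mean())
        rows.append({"node": name, "cc": cc, "cc_baseline": max(prev, 1.0 - prev)})
    return pd.DataFrame(rows)


def participation_coefficients(
    network: IsingNetwork, partition: CommunityPartition
) -> np.ndarray:
    A = np.abs(network.weights)
    strength = A.sum(axis=1)
    labels = partition.labels_for(network.nodes)
    out = np.zeros(network.p)
    for i in range(network.p):
        if strength[i] == 0:
            continue
        acc = 0.0
        for c in np.unique(labels):
            k_is = A[i, labels == c].sum()
            acc += (k_is / strength[i]) ** 2
        out[i] = 1.0 - acc
    return out


def centralities(
    network: IsingNetwork, partition: CommunityPartition
) -> pd.DataFrame:
    """Strength, closeness, betweenness and participation for every node."""
    A = np.abs(network.weights)
    strength = A.sum(axis=1)

    G = nx.Graph()
    G.add_nodes_from(range(network.p))
    for i in range(network.p):
        for j in range(i + 1, network.p):
            if A[i, j] > 0:
                G.add_edge(i, j, dist=1.0 / A[i, j])
    closeness = nx.closeness_centrality(G, distance="dist", wf_improved=False)
    betweenness = nx.betweenness_centrality(G, weight="dist", normalized=False)
    participation = participation_coefficients(network, partition)

    return pd.DataFrame(
        {
            "node": network.nodes,
            "strength": strength,
            "closeness": [closeness[i] for i in range(network.p)],
            "betweenness": [betweenness[i] for i in range(network.p)],
            "participation": participation,
        }
    )


def node_metrics(
    data: pd.DataFrame, network: IsingNetwork, partition: CommunityPartition
) -> NodeMetrics:
    """Predictability and centralities merged into one per-node table."""
    cc = predictability_cc(data, network)
    cent = centralities(network, partition)
    return NodeMetrics(table=cc.merge(cent, on="node"))


def centrality_zscores(metrics: NodeMetrics) -> pd.DataFrame:
    """Standardised centralities (the usual centrality-plot scale)."""
    df = metrics.table.copy()
    for col in ("strength", "closeness", "betweenness", "participation"):
        sd = df[col].std(ddof=0)
        df[col] = 0.0 if sd == 0 else (df[col] - df[col].mean()) / sd
    return df[["node", "strength", "closeness", "betweenness", "participation"]]
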