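"""Ising network estimation by nodewise penalised logistic regression (eLASSO).

Each of the p binary variables is regressed on the other p-1 with an L1
penalty; the penalty level per node is chosen by minimising the extended
Bayesian information criterion

    EBIC_gamma = -2 * loglik + k * ln(n) + 2 * gamma * k * ln(p - 1),

with k the number of nonzero coefficients (intercept excluded) and
gamma = 0.25 by default. The two directed coefficient estimates per pair are
symmetrised into one edge weight: under the AND rule (default) an edge exists
only if both directions are nonzero; under OR if either is. The surviving
weight is the mean of the two directed coefficients (an absent direction
contributes 0 under OR).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._lasso import fit_lasso_logistic, lasso_logistic_path, make_lambda_grid
from .catalog import NETWORK_NODES
from .preprocess import stratify


@dataclass
class EbicPath:
    """One node's regularisation path with EBIC values and selection.

    The lasso path proposes candidate neighbourhoods (the supports along the
    descending lambda grid); each distinct support is refitted by unpenalised
    maximum likelihood and the EBIC is computed from that refit, so model
    comparison is not distorted by shrinkage ("relaxed" selection). The
    selected model's coefficients are the ML refit on the winning support.
    """

    node: int
    lambdas: np.ndarray  # descending
    intercepts: np.ndarray  # (L,) penalised
    coefs: np.ndarray  # (L, p-1) penalised, order = other nodes in original order
    loglik: np.ndarray  # (L,) ML refit log-likelihood of each support
    n: int
    gamma: float
    ml_intercepts: np.ndarray  # (L,) refit
    ml_coefs: np.ndarray  # (L, p-1) refit
    n_nonzero: np.ndarray = field(init=False)
    ebic: np.ndarray = field(init=False)
    selected: int = field(init=False)

    def __post_init__(self):
        p_minus_1 = self.coefs.shape[1]
        self.n_nonzero = (self.coefs != 0).sum(axis=1)
        self.ebic = ebic_value(self.loglik, self.n_nonzero, self.n, p_minus_1, self.gamma)
        # argmin; ties go to the larger lambda (sparser side of the path)
        self.selected = int(np.argmin(self.ebic))

    @property
    def selected_coefs(self) -> np.ndarray:
        return self.ml_coefs[self.selected]

    @property
    def selected_intercept(self) -> float:
        return float(self.ml_intercepts[self.selected])


def ebic_value(loglik, k, n, p_candidates, gamma):
    """EBIC for a logistic neighbourhood model with k selected predictors."""
    loglik = np.asarray(loglik, dtype=float)
    k = np.asarray(k, dtype=float)
    return -2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(p_candidates)


@dataclass
class IsingNetwork:
    """Symmetric weighted conditional-dependence network over binary nodes."""

    nodes: list[str]
    weights: np.ndarray  # (p, p) symmetric, zero diagonal; 0 = no edge
    thresholds: np.ndarray  # (p,) selected nodewise intercepts
    gamma: float
    n: int
    rule: str = "and"
    dropped_nodes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("network weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("network weights must have zero diagonal")

    @property
    def p(self) -> int:
        return len(self.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"node_i": self.nodes[i], "node_j": self.nodes[j], "weight": self.weights[i, j]}
            for i in range(self.p)
            for j in range(i + 1, self.p)
            if self.weights[i, j] != 0.0
        ]
        return pd.DataFrame(rows, columns=["node_i", "node_j", "weight"])

    def strength(self) -> np.ndarray:
        return np.abs(self.weights).sum(axis=1)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "nodes": self.nodes,
                    "weights": self.weights.tolist(),
                    "thresholds": self.thresholds.tolist(),
                    "gamma": self.gamma,
                    "n": self.n,
                    "rule": self.rule,
                    "dropped_nodes": self.dropped_nodes,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "IsingNetwork":
        d = json.loads(Path(path).read_text())
        return cls(
            nodes=d["nodes"],
            weights=np.array(d["weights"]),
            thresholds=np.array(d["thresholds"]),
            gamma=d["gamma"],
            n=d["n"],
            rule=d.get("rule", "and"),
            dropped_nodes=d.get("dropped_nodes", {}),
        )

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        G = nx.Graph()
        for i, name in enumerate(self.nodes):
            G.add_node(name, threshold=float(self.thresholds[i]))
        for i in range(self.p):
            for j in range(i + 1, self.p):
                if self.weights[i, j] != 0.0:
                    G.add_edge(self.nodes[i], self.nodes[j], weight=float(self.weights[i, j]))
        nx.write_graphml(G, str(path))


@dataclass
class EstimatorConfig:
    """Tuning knobs of the nodewise estimator."""

    gamma: float = 0.25
    rule: str = "and"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    tol: float = 1e-6
    min_stratum_n: int = 200  # strata below this are skipped


def fit_nodewise_lasso(
    X: np.ndarray,
    node: int,
    lambdas: np.ndarray | None = None,
    gamma: float = 0.25,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-6,
    sample_weight: np.ndarray | None = None,
) -> EbicPath:
    """Penalised logistic path of one node on all others, with EBIC selection.

    Duplicate binary rows are collapsed into case weights before solving —
    the likelihood, path and EBIC are identical to the row-level fit. Pass
    `sample_weight` when X already holds unique patterns with counts (the
    stratified estimator collapses once for all nodes).
    """
    X = np.asarray(X, dtype=float)
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("design matrix must be binary (0/1)")
    if X[:, node].min() == X[:, node].max():
        raise ValueError(f"node {node} is constant; drop it before estimation")
    if sample_weight is None:
        U, counts = np.unique(X, axis=0, return_counts=True)
        c = counts.astype(float)
    else:
        U, c = X, np.asarray(sample_weight, dtype=float)
    n = int(round(c.sum()))
    y = U[:, node]
    others = np.delete(np.arange(X.shape[1]), node)
    Xo = U[:, others]
    if lambdas is None:
        lambdas = make_lambda_grid(Xo, y, n_lambda, lambda_min_ratio, sample_weight=c)
    intercepts, coefs, _ = lasso_logistic_path(
        Xo, y, np.asarray(lambdas), sample_weight=c, tol=tol
    )
    # ML refit of each distinct support for shrinkage-free EBIC comparison
    L = len(lambdas)
    ml_intercepts = np.empty(L)
    ml_coefs = np.zeros_like(coefs)
    loglik = np.empty(L)
    cache: dict[tuple, tuple] = {}
    for i in range(L):
        support = tuple(np.flatnonzero(coefs[i]))
        if support not in cache:
            cache[support] = _refit_ml(Xo, y, c, support, tol=tol)
        b0, beta, ll = cache[support]
        ml_intercepts[i] = b0
        ml_coefs[i] = beta
        loglik[i] = ll
    return EbicPath(
        node=node, lambdas=np.asarray(lambdas), intercepts=intercepts,
        coefs=coefs, loglik=loglik, n=n, gamma=gamma,
        ml_intercepts=ml_intercepts, ml_coefs=ml_coefs,
    )


def _refit_ml(
    Xo: np.ndarray, y: np.ndarray, c: np.ndarray, support: tuple, tol: float = 1e-6
) -> tuple[float, np.ndarray, float]:
    """Unpenalised logistic ML on a candidate support (weighted rows)."""
    cols = list(support)
    b0, beta_s = fit_lasso_logistic(
        Xo[:, cols] if cols else np.empty((len(y), 0)),
        y, lam=0.0, sample_weight=c, tol=tol,
    )
    beta = np.zeros(Xo.shape[1])
    beta[cols] = beta_s
    eta = b0 + Xo @ beta
    ll = float((c * y) @ eta - c @ np.logaddexp(0.0, eta))
    return b0, beta, ll


def assemble_network(
    paths: dict[int, EbicPath],
    node_labels: list[str],
    rule: str = "and",
    dropped_nodes: dict[str, str] | None = None,
) -> IsingNetwork:
    """Symmetrise the selected nodewise coefficients into one network."""
    if rule not in ("and", "or"):
        raise ValueError("rule must be 'and' or 'or'")
    p = len(node_labels)
    if set(paths) != set(range(p)):
        raise ValueError("need exactly one path per retained node")
    # directed coefficient matrix: D[i, j] = effect of j in i's regression
    D = np.zeros((p, p))
    thresholds = np.zeros(p)
    for i, path in paths.items():
        others = np.delete(np.arange(p), i)
        D[i, others] = path.selected_coefs
        thresholds[i] = path.selected_intercept
    both = (D != 0) & (D.T != 0)
    either = (D != 0) | (D.T != 0)
    keep = both if rule == "and" else either
    W = np.where(keep, (D + D.T) / 2.0, 0.0)
    np.fill_diagonal(W, 0.0)
    n = next(iter(paths.values())).n
    gamma = next(iter(paths.values())).gamma
    return IsingNetwork(
        nodes=list(node_labels), weights=W, thresholds=thresholds,
        gamma=gamma, n=n, rule=rule, dropped_nodes=dropped_nodes or {},
    )


def estimate_network(
    X: np.ndarray,
    node_labels: list[str],
    config: EstimatorConfig | None = None,
) -> IsingNetwork:
    """Full eLASSO estimate over a binary data matrix.

    Constant columns are dropped (their conditional model is undefined) and
    recorded in ``dropped_nodes``.
    """
    cfg = config or EstimatorConfig()
    X = np.asarray(X, dtype=float)
    variable = [j for j in range(X.shape[1]) if X[:, j].min() != X[:, j].max()]
    dropped = {
        node_labels[j]: f"constant column (value {X[0, j]:g})"
        for j in range(X.shape[1])
        if j not in variable
    }
    Xv = X[:, variable]
    labels = [node_labels[j] for j in variable]
    if not variable:  # every column constant: an empty (edgeless) network
        return IsingNetwork(
            nodes=[], weights=np.zeros((0, 0)), thresholds=np.zeros(0),
            gamma=cfg.gamma, n=X.shape[0], rule=cfg.rule, dropped_nodes=dropped,
        )
    U, counts = np.unique(Xv, axis=0, return_counts=True)
    c = counts.astype(float)
    paths = {
        i: fit_nodewise_lasso(
            U, i, gamma=cfg.gamma, n_lambda=cfg.n_lambda,
            lambda_min_ratio=cfg.lambda_min_ratio, tol=cfg.tol,
            sample_weight=c,
        )
        for i in range(U.shape[1])
    }
    return assemble_network(paths, labels, rule=cfg.rule, dropped_nodes=dropped)


def estimate_stratified_networks(
    table: pd.DataFrame,
    config: EstimatorConfig | None = None,
    strata_keys: tuple[str, ...] = ("sex", "age_group"),
    nodes: tuple[str, ...] = NETWORK_NODES,
) -> dict[str, IsingNetwork]:
    """One network per stratum over the 19 conditions plus hospitalisation.

    Mirrors the published analysis: separate networks for females, males and
    each age band. Strata smaller than ``config.min_stratum_n`` are skipped
    with a warning; constant nodes within a stratum are dropped per network.
    """
    cfg = config or EstimatorConfig()
    networks: dict[str, IsingNetwork] = {}
    for key in strata_keys:
        for name, sub in stratify(table, key).items():
            if len(sub) < cfg.min_stratum_n:
                warnings.warn(
                    f"stratum {name!r} has n={len(sub)} < {cfg.min_stratum_n}; skipped"
                )
                continue
            X = sub[list(nodes)].to_numpy(float)
            networks[name] = estimate_network(X, list(nodes), cfg)
    return networks
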