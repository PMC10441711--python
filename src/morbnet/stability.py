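"""Bootstrap accuracy and stability diagnostics for estimated networks.

Two schemes, following standard network-psychometrics practice:

* Nonparametric bootstrap (rows resampled with replacement, default B=500):
  full re-estimation per replicate gives per-edge 95% quantile intervals and
  bootstrap difference tests between edge magnitudes.

* Case-dropping subset bootstrap: for each retention proportion q (default
  grid 0.9 down to 0.3 in steps of 0.1, plus 0.25), B subsamples of size
  q*n are drawn without replacement, centralities are recomputed, and the
  Spearman correlation with the original centrality is recorded. The
  CS-coefficient of a measure is the largest drop proportion (1 - q) at
  which that correlation stays >= 0.7 in >= 95% of subsamples (and does so
  at every smaller drop). CS >= 0.5 is the usual comfort zone; CS < 0.25
  flags an uninterpretable ordering.

Replicate estimation failures (a degenerate resample) are tolerated up to a
10% share, recorded, and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .catalog import NETWORK_NODES
from .communities import walktrap
from .ising import EstimatorConfig, IsingNetwork, estimate_network
from .node_metrics import centralities

DEFAULT_PROPORTIONS = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.25)
MAX_FAILURE_SHARE = 0.10


def _edge_pairs(nodes: list[str]) -> list[tuple[str, str]]:
    return [(nodes[i], nodes[j]) for i in range(len(nodes)) for j in range(i + 1, len(nodes))]


def _edge_vector(net: IsingNetwork, nodes: list[str]) -> np.ndarray:
    """Upper-triangle weights aligned to the full node list (0 where dropped)."""
    pos = {n: k for k, n in enumerate(net.nodes)}
    p = len(nodes)
    out = np.zeros(p * (p - 1) // 2)
    k = 0
    for i in range(p):
        for j in range(i + 1, p):
            a, b = nodes[i], nodes[j]
            if a in pos and b in pos:
                out[k] = net.weights[pos[a], pos[b]]
            k += 1
    return out


@dataclass
class BootstrapEnsemble:
    kind: str  # "nonparametric"
    nodes: list[str]
    edge_index: list[tuple[str, str]]
    original_edges: np.ndarray  # (n_pairs,)
    edge_samples: np.ndarray  # (B_eff, n_pairs)
    strength_samples: np.ndarray  # (B_eff, p)
    original_strength: np.ndarray  # (p,)
    B: int
    n_failures: int = 0

    def edge_cis(self, level: float = 0.95) -> pd.DataFrame:
        lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
        lower = np.percentile(self.edge_samples, lo, axis=0)
        upper = np.percentile(self.edge_samples, hi, axis=0)
        return pd.DataFrame(
            {
                "node_i": [a for a, _ in self.edge_index],
                "node_j": [b for _, b in self.edge_index],
                "original": self.original_edges,
                "lower": lower,
                "upper": upper,
            }
        )

    def _edge_pos(self, edge: tuple[str, str]) -> int:
        e = tuple(edge)
        try:
            return self.edge_index.index(e)
        except ValueError:
            try:
                return self.edge_index.index((e[1], e[0]))
            except ValueError:
                raise KeyError(f"edge {edge} not indexed in ensemble") from None


def nonparametric_bootstrap(
    table: pd.DataFrame,
    config: EstimatorConfig | None = None,
    B: int = 500,
    seed: int = 0,
    nodes: tuple[str, ...] = NETWORK_NODES,
) -> BootstrapEnsemble:
    """Row-resampling bootstrap of the full network estimator."""
    cfg = config or EstimatorConfig()
    node_list = list(nodes)
    X = table[node_list].to_numpy(float)
    n = len(X)
    rng = np.random.default_rng(seed)
    original = estimate_network(X, node_list, cfg)
    orig_edges = _edge_vector(original, node_list)
    orig_strength = np.abs(original.weights).sum(axis=1)
    # map original strength onto the full node list
    pos = {nm: k for k, nm in enumerate(original.nodes)}
    strength_full = np.array(
        [orig_strength[pos[nm]] if nm in pos else 0.0 for nm in node_list]
    )

    edge_rows, strength_rows, failures = [], [], 0
    for _ in range(B):
        idx = rng.integers(n, size=n)
        try:
            net = estimate_network(X[idx], node_list, cfg)
        except Exception:
            failures += 1
            if failures > MAX_FAILURE_SHARE * B:
                raise RuntimeError(
                    f"more than {MAX_FAILURE_SHARE:.0%} of bootstrap replicates failed"
                )
            continue
        edge_rows.append(_edge_vector(net, node_list))
        sp = {nm: k for k, nm in enumerate(net.nodes)}
        s = np.abs(net.weights).sum(axis=1)
        strength_rows.append(
            np.array([s[sp[nm]] if nm in sp else 0.0 for nm in node_list])
        )

    return BootstrapEnsemble(
        kind="nonparametric",
        nodes=node_list,
        edge_index=_edge_pairs(node_list),
        original_edges=orig_edges,
        edge_samples=np.asarray(edge_rows),
        strength_samples=np.asarray(strength_rows),
        original_strength=strength_full,
        B=B,
        n_failures=failures,
    )


@dataclass
class DifferenceTest:
    edge_a: tuple[str, str]
    edge_b: tuple[str, str]
    difference: float  # original w_a - w_b
    ci_low: float
    ci_high: float
    significant: bool


def edge_difference_test(
    ensemble: BootstrapEnsemble,
    edge_a: tuple[str, str],
    edge_b: tuple[str, str],
    level: float = 0.95,
) -> DifferenceTest:
    """Bootstrap difference test between two edge magnitudes.

    Significant when the bootstrap quantile interval of w_a - w_b excludes 0.
    """
    ia, ib = ensemble._edge_pos(edge_a), ensemble._edge_pos(edge_b)
    diffs = ensemble.edge_samples[:, ia] - ensemble.edge_samples[:, ib]
    lo, hi = (1 - level) / 2 * 100, (1 + level) / 2 * 100
    ci_low, ci_high = float(np.percentile(diffs, lo)), float(np.percentile(diffs, hi))
    return DifferenceTest(
        edge_a=tuple(edge_a),
        edge_b=tuple(edge_b),
        difference=float(ensemble.original_edges[ia] - ensemble.original_edges[ib]),
        ci_low=ci_low,
        ci_high=ci_high,
        significant=not (ci_low <= 0.0 <= ci_high),
    )


def edge_difference_matrix(
    ensemble: BootstrapEnsemble, min_abs_weight: float = 0.0
) -> pd.DataFrame:
    """All pairwise difference tests among edges present in the original net."""
    present = [
        k for k, w in enumerate(ensemble.original_edges) if abs(w) > min_abs_weight
    ]
    rows = []
    for a_i, a in enumerate(present):
        for b in present[a_i + 1 :]:
            t = edge_difference_test(ensemble, ensemble.edge_index[a], ensemble.edge_index[b])
            rows.append(
                {
                    "edge_a": "--".join(t.edge_a), "edge_b": "--".join(t.edge_b),
                    "difference": t.difference, "ci_low": t.ci_low,
                    "ci_high": t.ci_high, "significant": t.significant,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CsCoefficient:
    """Correlation-stability coefficient of one centrality measure."""

    measure: str
    cs: float  # largest supported drop proportion
    at_grid_max: bool  # criterion held at every tested drop (report as >= cs)
    below_grid_min: bool  # criterion failed already at the smallest drop
    cor_threshold: float
    confidence: float
    detail: pd.DataFrame = field(repr=False, default=None)  # drop, prop_ok

    def __str__(self) -> str:
        if self.below_grid_min:
            return f"CS({self.measure}) < {self.cs:.2f}"
        prefix = ">= " if self.at_grid_max else ""
        return f"CS({self.measure}) = {prefix}{self.cs:.2f}"


def case_dropping_cs(
    table: pd.DataFrame,
    config: EstimatorConfig | None = None,
    measures: tuple[str, ...] = ("strength", "closeness", "betweenness"),
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    B: int = 500,
    seed: int = 0,
    cor_threshold: float = 0.7,
    confidence: float = 0.95,
    nodes: tuple[str, ...] = NETWORK_NODES,
) -> dict[str, CsCoefficient]:
    """Case-dropping subset bootstrap with B resamples per proportion."""
    if not proportions:
        raise ValueError("proportion grid is empty")
    cfg = config or EstimatorConfig()
    node_list = list(nodes)
    X = table[node_list].to_numpy(float)
    n = len(X)
    if min(proportions) * n < 10:
        raise ValueError("sample too small for the smallest retention proportion")
    rng = np.random.default_rng(seed)

    def metric_frame(x: np.ndarray) -> pd.DataFrame:
        net = estimate_network(x, node_list, cfg)
        part = walktrap(net)
        return centralities(net, part).set_index("node")

    original = metric_frame(X)
    drops = sorted(1.0 - np.asarray(proportions))
    corrs = {m: {d: [] for d in drops} for m in measures}
    for q in sorted(proportions, reverse=True):
        size = int(round(q * n))
        d = 1.0 - q
        for _ in range(B):
            idx = rng.choice(n, size=size, replace=False)
            try:
                sub = metric_frame(X[idx])
            except Exception:
                continue
            common = original.index.intersection(sub.index)
            for m in measures:
                a = original.loc[common, m].to_numpy()
                b = sub.loc[common, m].to_numpy()
                if len(common) < 3 or np.std(a) == 0 or np.std(b) == 0:
                    rho = 0.0
                else:
                    rho = spearmanr(a, b).statistic
                corrs[m][d].append(0.0 if np.isnan(rho) else float(rho))

    out = {}
    for m in measures:
        detail = pd.DataFrame(
            {
                "drop": drops,
                "prop_ok": [
                    np.mean(np.asarray(corrs[m][d]) >= cor_threshold) if corrs[m][d] else 0.0
                    for d in drops
                ],
            }
        )
        supported = 0.0
        below = True
        for d, ok in zip(detail["drop"], detail["prop_ok"]):
            if ok >= confidence:
                supported = d
                below = False
            else:
                break
        out[m] = CsCoefficient(
            measure=m,
            cs=float(supported if not below else min(drops)),
            at_grid_max=(not below) and supported == max(drops),
            below_grid_min=below,
            cor_threshold=cor_threshold,
            confidence=confidence,
            detail=detail,
        )
    return out
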