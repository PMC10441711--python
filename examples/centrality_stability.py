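"""Node metrics and their bootstrap stability on one stratum.

Computes predictability (correct classification) and the four centralities,
then checks how far cases can be dropped before the centrality ordering
degrades (CS-coefficients) and whether the two strongest edges differ
significantly (bootstrap difference test).
"""

from morbnet import (
    EstimatorConfig,
    case_dropping_cs,
    complete_cases,
    edge_difference_test,
    elsi_like_truth,
    estimate_network,
    generate_cohort,
    node_metrics,
    nonparametric_bootstrap,
    stratify,
    walktrap,
)
from morbnet.catalog import NETWORK_NODES

cfg = EstimatorConfig(n_lambda=50)
cohort = generate_cohort(elsi_like_truth(seed=4), n=6000, seed=4)
male = stratify(complete_cases(cohort), "sex")["male"]

net = estimate_network(male[list(NETWORK_NODES)].to_numpy(float),
                       list(NETWORK_NODES), cfg)
part = walktrap(net)
metrics = node_metrics(male, net, part).table
print(metrics.sort_values("strength", ascending=False).head(8)
      .to_string(index=False, float_format=lambda v: f"{v:.2f}"))

ens = nonparametric_bootstrap(male, cfg, B=25, seed=5)
edges = ens.edge_cis().reindex(
    ens.edge_cis().original.abs().sort_values(ascending=False).index
)
a = tuple(edges.iloc[0][["node_i", "node_j"]])
b = tuple(edges.iloc[1][["node_i", "node_j"]])
test = edge_difference_test(ens, a, b)
print(f"\nstrongest edges {a} vs {b}: difference {test.difference:+.2f} "
      f"[{test.ci_low:+.2f}, {test.ci_high:+.2f}], "
      f"{'significant' if test.significant else 'not significant'}")

cs = case_dropping_cs(male, cfg, measures=("strength",),
                      proportions=(0.9, 0.7, 0.5), B=10, seed=6)
print(f"\n{cs['strength']}")
# CC above its baseline means a node is genuinely predictable from its
# neighbours; CS(strength) >= 0.5 is the usual bar for a stable ordering.
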