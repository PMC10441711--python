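"""Estimate sex-stratified morbidity-hospitalisation networks.

Each stratum's network is fitted by nodewise L1-penalised logistic
regression with EBIC (gamma = 0.25) selection over the 19 conditions plus
hospitalisation, then partitioned into disease communities by Walktrap.
"""

from morbnet import (
    EstimatorConfig,
    complete_cases,
    elsi_like_truth,
    estimate_stratified_networks,
    generate_cohort,
    name_communities,
    walktrap,
)

cohort = generate_cohort(elsi_like_truth(seed=2), n=9412, seed=2)
complete = complete_cases(cohort)

networks = estimate_stratified_networks(
    complete, EstimatorConfig(n_lambda=50), strata_keys=("sex",)
)
for stratum, net in networks.items():
    part = walktrap(net, t=4)
    names = name_communities(part)
    multi = [v for v in names.values() if "–" in v]
    print(f"\n[{stratum}] n={net.n}, {len(net.edge_list())} edges, "
          f"modularity Q={part.modularity:.3f}")
    print(f"  {len(multi)} disease groups:")
    for g in sorted(multi):
        print(f"    - {g}")
    hub = net.edge_list().reindex(
        net.edge_list().weight.abs().sort_values(ascending=False).index
    ).head(3)
    print("  strongest edges:")
    for _, e in hub.iterrows():
        print(f"    {e.node_i} -- {e.node_j}: w = {e.weight:+.2f}")
# Edge weights are log-odds pairwise interactions: w > 0 means the two
# conditions co-occur beyond what all other conditions explain. The groups
# recover the planted comorbidity clusters (cardiovascular-cancer-eye,
# musculoskeletal-depression-renal, diabetes, respiratory, neurodegenerative).
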