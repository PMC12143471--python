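"""Estimate the normalized-MI symptom network and its communities.

Each of the 14 HADS items is a node; each of the 91 edges is the pairwise
normalized mutual information (0 = independent, 1 = deterministic). Louvain
modularity maximization then clusters the items into symptom communities.
"""

import symptomnet as sn

table = sn.generate_cohort(sn.young_default_config(n=500, seed=3))
network = sn.build_network(table)

edges = network.edge_list().sort_values("weight", ascending=False)
print(f"network: {network.n_nodes} nodes, {len(edges)} edges, "
      f"n={network.sample_size} participants")
print("strongest edges:")
print(edges.head(5).to_string(index=False))

partition = sn.detect_communities(network, seed=7, n_restarts=100)
print(f"\nLouvain found {partition.n_communities} communities "
      f"(modularity Q = {partition.modularity_q:.3f}):")
for c in range(partition.n_communities):
    print(f"  community {c}: {', '.join(partition.community(c))}")

ari = sn.compare_partitions(partition, sn.fixed_hads_partition())
print(f"\nadjusted Rand index vs the a-priori anxiety/depression split: {ari:.2f}")
print("ARI of 1 means the data-driven communities coincide exactly with the "
      "HADS subscales.")
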