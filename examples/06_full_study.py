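"""Run the complete study pipeline and the fixed-partition validation.

One call executes: simulate -> inclusion filter -> per-group networks ->
Louvain communities -> connectivity + permutation tests -> centrality ->
descriptive tables, returning a serializable report (reduced iteration
counts here to keep the demo quick).
"""

import symptomnet as sn

config = sn.RunConfig(n_iter=500, louvain_restarts=50, output_dir="scratch/demo_run")
report = sn.run_study(config)

for label, g in report.groups.items():
    print(f"{label}: n={g.n_participants}, "
          f"{g.partition.n_communities} communities, "
          f"within={ {k: round(v, 3) for k, v in g.connectivity.within.items()} }, "
          f"between={g.connectivity.between:.4f}, "
          f"top strength={g.top_strength_node}, top bridge={g.top_bridge_node}")

print("\npermutation tests:")
for p in report.permutation_tests:
    print(f"  {p.contrast}: diff={p.observed_diff:+.4f}, p={p.p_value:.4f}")

for r in report.rank_correlations:
    print(f"rank agreement ({r.field}): rho={r.rho:.3f}, p={r.p_value:.3f}")

print("\nvalidation with the fixed anxiety/depression partition:")
print(sn.validate_fixed_partition(report).round(4).to_string(index=False))
print("\nSimilar connectivity under the data-driven and fixed partitions "
      "shows the substantive conclusions do not hinge on the clustering step."
      f"\nOutputs (CSVs, GraphML, report.json) written to {config.output_dir}/")
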