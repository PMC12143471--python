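"""Strength and bridge-strength centrality, compared across cohorts.

Strength is a symptom's total connectivity; bridge strength is its
connectivity to the *other* community, flagging symptoms that link the
anxiety and depression domains.
"""

import symptomnet as sn

part = sn.fixed_hads_partition()
profiles = {}
for label, cfg in (("young", sn.young_default_config(seed=0)),
                   ("old", sn.old_default_config(seed=1))):
    net = sn.build_network(sn.generate_cohort(cfg))
    profiles[label] = sn.bridge_strength(net, part)
    print(f"{label}: top strength = {sn.top_node(profiles[label], 'strength')}, "
          f"top bridge = {sn.top_node(profiles[label], 'bridge')}")

print("\nper-item profile (young):")
print(profiles["young"].to_frame().round(3).to_string(index=False))

for field in ("strength", "bridge"):
    rho, p = sn.rank_centrality(profiles["young"], profiles["old"], field=field)
    print(f"\nSpearman rank agreement across cohorts ({field}): "
          f"rho = {rho:.3f}, p = {p:.3f}")
print("High strength agreement with weaker bridge agreement means the "
      "overall symptom hierarchy is stable while the domain-linking "
      "symptoms differ by age.")
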