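"""Generate a synthetic two-cohort HADS study and inspect its marginals.

The generator draws two latent factors (anxiety, depression) per participant
and discretizes noisy item responses onto the 0-3 scale, so the cohort has a
known community structure for every downstream analysis.
"""

import symptomnet as sn
from symptomnet.cohort import score_hads

young = sn.young_default_config(seed=0)   # n=232, ages 18-45
old = sn.old_default_config(seed=1)       # n=554, ages 65-88
table = sn.generate_two_group_study(young, old)

print(f"cohort: {len(table)} participants "
      f"({(table.group == 'young').sum()} young, {(table.group == 'old').sum()} old)")
scores = score_hads(table)
print(f"HADS-D totals: min={scores.hads_d_total.min()} "
      f"(every participant meets the >=4 inclusion rule), "
      f"mean={scores.hads_d_total.mean():.2f}")
print("\nper-item means by group (0-3 severity scale):")
print(table.groupby("group")[list(sn.ITEM_IDS)].mean().round(2).T)
print("\nHigher anxiety-item means in the young cohort mirror the stronger "
      "anxiety severity reported for younger adults.")
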