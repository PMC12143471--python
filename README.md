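# symptomnet

Network analysis of depression and anxiety symptoms for ordinal
questionnaire cohorts — mutual-information symptom networks, community
detection, connectivity contrasts with permutation inference, and
strength/bridge centrality, plus a latent-factor simulator for generating
HADS-like cohorts with known structure.

The package is aimed at researchers studying how the architecture of
depressive and anxiety symptoms (e.g. on the 14-item Hospital Anxiety and
Depression Scale, 7 anxiety items HA1–HA7 and 7 depression items HD1–HD7,
each scored 0–3) differs between groups such as young and older adults.

## The model

For each cohort, every item is a node and every pair of items carries a
weight equal to the plug-in normalized mutual information

```
NMI(X, Y) = [H(X) + H(Y) − H(X,Y)] / √(H(X)·H(Y)) ∈ [0, 1],
```

a dependence measure that captures nonlinear as well as linear association
and is zero (in the population) exactly under independence. On this fully
connected weighted graph the package computes:

- **communities** — Louvain maximization of weighted modularity
  `Q = (1/2m) Σᵢⱼ [Aᵢⱼ − kᵢkⱼ/2m] δ(cᵢ, cⱼ)`, run as a seeded
  best-of-restarts search, plus the fixed anxiety/depression split for
  validation;
- **connectivity** — mean edge weight within a community or between
  communities, with two-sided permutation tests (participant reshuffling
  for group contrasts, node relabeling for community contrasts,
  `p = (1 + #{|null| ≥ |obs|}) / (n_iter + 1)`);
- **centrality** — strength (total incident weight) and bridge strength
  (incident weight to other communities, with strength = within + bridge
  exactly), compared across cohorts by Spearman rank correlation;
- **descriptives** — Welch t, Mann–Whitney U, 2×2 χ², Cronbach's α and
  Benjamini–Hochberg FDR for the cohort-characteristics layer.

Because participant-level data from population ageing cohorts are typically
access-controlled, the `simulate` module generates synthetic cohorts from a
two-factor probit model: correlated anxiety/depression factors, per-item
loadings, and per-item thresholds calibrated so the 0–3 marginals match
published item means/SDs; an optional inclusion rule (depression total ≥ 4)
is emulated by rejection sampling.

## Worked example

```python
import symptomnet as sn

table = sn.generate_cohort(sn.young_default_config(n=500, seed=3))
network = sn.build_network(table)
partition = sn.detect_communities(network, seed=7, n_restarts=100)
```

prints (see `examples/02_network_and_communities.py`):

```
Louvain found 2 communities (modularity Q = 0.308):
  community 0: HA1, HA2, HA3, HA4, HA5, HA6, HA7
  community 1: HD1, HD2, HD3, HD4, HD5, HD6, HD7

adjusted Rand index vs the a-priori anxiety/depression split: 1.00
```

The network splits into an anxiety and a depression community that coincide
with the questionnaire's subscales (ARI = 1). Comparing two default cohorts
(`examples/03_connectivity_permutation.py`):

```
young: within-anxiety 0.109, within-depression 0.059, between 0.0230
old:   within-anxiety 0.173, within-depression 0.021, between 0.0074
within-anxiety age contrast:    diff = -0.0647, p = 0.0030 (1000 permutations)
within-depression age contrast: diff = +0.0382, p = 0.0010 (1000 permutations)
between-community age contrast: diff = +0.0156, p = 0.0180 (1000 permutations)
```

i.e. the older cohort's anxiety community is more tightly interconnected,
while depression-internal and cross-domain connectivity are stronger in the
young cohort — the qualitative age pattern the simulator is configured to
emulate. `examples/06_full_study.py` runs the entire pipeline
(`sn.run_study`) and the fixed-partition validation in one call; the other
examples cover simulation, centrality and the descriptive tables.

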