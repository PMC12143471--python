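# Methods

## Scope and data model

The package analyses participant × item tables of 14 ordinal HADS items
(HA1–HA7 anxiety, HD1–HD7 depression, each scored 0–3, severity-coded; no
reverse-scoring is applied). Analyses use complete cases only: rows with a
missing or out-of-range item are dropped at read time. The inclusion rule
`HADS-D total ≥ 4` (at least subclinical depressive symptomatology,
boundary inclusive) is applied before age grouping and before any network
computation. Age groups are integer-inclusive: young 18–45, middle 46–64,
old 65+; rows under 18 are excluded.

## Network estimation

Edges are plug-in (maximum-likelihood) mutual information estimates from
the 4×4 contingency table of each item pair, in bits, normalized by the
geometric mean of the marginal entropies:

    NMI = [H(X) + H(Y) − H(X,Y)] / sqrt(H(X) H(Y)).

Choices, and why:

- **No bias correction.** With 16 cells and cohorts in the hundreds, the
  plug-in bias (~(cells−1)/2n ln2 bits) is small relative to the edge
  weights of interest; a correction would complicate the permutation null
  without changing any contrast, since all compared quantities share n.
- **Geometric-mean normalization** is symmetric, bounds weights in [0, 1]
  and is the most common NMI variant; minimum-entropy and joint-entropy
  denominators are available through the `norm` argument for sensitivity
  analyses. NMI magnitudes are therefore comparable only within a
  normalization convention.
- **Degenerate margins:** a constant item has zero entropy; its NMI is 0 by
  convention. Results are clipped to [0, 1] against floating error.
- **Base 2 throughout**; the normalization cancels the base.
- **No sparsification.** The graph stays fully connected (91 edges); all
  downstream metrics are means or sums over edge weights, so thresholding
  would only discard information.

The estimator is vectorized (one `bincount` over pair-coded categories per
network), which is what makes rebuilding both group networks inside every
permutation draw affordable; tests verify the fast path equals a naive
double-loop estimator to ≤ 1e−12.

## Communities

Communities maximize weighted Newman–Girvan modularity at resolution 1
(no resolution parameter is scientifically motivated here; it is exposed
for exploration). Louvain is a node-order-dependent heuristic, so
`detect_communities` runs 100 restarts (default) with restart seeds spawned
from a single master seed and keeps the highest-Q partition, ties broken by
first occurrence; the result is a deterministic function of
(network, seed, n_restarts). Community labels are canonicalized by each
community's lowest node index, so label 0 always contains HA1 in a
catalog-ordered network. The fixed anxiety/depression partition implements
the validation analysis that bypasses data-driven clustering; partition
agreement is quantified by the adjusted Rand index.

## Connectivity and permutation inference

Within-community (between-community) connectivity is the mean edge weight
over node pairs inside one community (spanning two communities); the pair
sets exactly partition the 91 edges. Two permutation schemes match the two
kinds of contrast:

- **Group contrasts** exchange *participants*: the null pools both cohorts,
  reshuffles group labels preserving group sizes, and rebuilds both
  networks per draw. Each group's partition is held fixed at its
  observed-data estimate (default), which isolates connectivity differences
  from partition instability; per-draw re-detection is available
  (`partition_policy="redetect"`, with communities matched by maximal
  overlap with the observed community of interest) for sensitivity checks.
- **Community contrasts** exchange *nodes*: community labels are reassigned
  at random, preserving sizes, on the fixed network.

Both use the two-sided `p = (1 + #{|null| ≥ |observed|}) / (n_iter + 1)`,
valid under exchangeability and bounded below by 1/(n_iter+1). Default
n_iter = 5000. A caveat the tests encode: with 7+7 communities a node
relabeling recreates the planted split with probability 2/C(14,7) per draw,
so even maximal separation attains the floor only up to that chance.

## Centrality

Strength is the row sum of the weight matrix; bridge strength is the sum of
a node's weights into other communities, relative to whichever partition is
supplied (data-driven or fixed), so strength = within-strength + bridge
exactly. Only strength-based metrics are implemented: distance-based
centralities are not meaningful on fully connected weighted graphs.
Cross-cohort profiles are compared by Spearman rank correlation with
midranks and the t-approximation p (an exact/Monte-Carlo permutation p is
available for small node sets). Argmax nodes break ties by item-id order.

## Descriptive layer

Welch t (summary- or vector-based; Welch–Satterthwaite df), Mann–Whitney U
with midranks (U = wins + half-ties for the first sample; tie-corrected
normal approximation with continuity correction), Pearson 2×2 χ² without
Yates correction by default (configurable — published χ² values for such
tables are often irreproducible from printed counts under either
convention), Cronbach's α with n−1 variances, and Benjamini–Hochberg
step-up FDR. Item-severity contrasts report both the U and the Welch-t
family, each FDR-adjusted across the 14 items, because either test is
defensible for 4-level ordinal scores.

## Synthetic cohorts

`generate_cohort` draws a bivariate standard-normal factor pair
(anxiety, depression) with correlation ρ, forms each item's latent response
y_j = λ_j f + √(1−λ_j²) ε_j, and cuts y_j at three ascending thresholds
into 0–3. Since y_j is marginally N(0,1) for any loading, thresholds alone
control the marginals: `thresholds_from_moments(mean, sd)` treats the item
as N(mean, sd²) cut at 0.5/1.5/2.5 and maps the implied cumulative
probabilities back to the latent scale, matching a target item mean to
within a few hundredths for mildly skewed severity distributions. Ages are
uniform integers within the group range (no within-group age–severity
coupling: the contrasts of interest are between groups); sex is Bernoulli.
One `numpy` Generator seeded from the config drives all randomness, so a
config is bit-reproducible.

Default young/old configurations encode the study conditions: group sizes
232 and 554; per-item thresholds calibrated to published per-item
means/SDs; subscale base loadings 0.70/0.84 (young anxiety/depression) and
0.80/0.72 (old) with a fixed per-item offset profile shared by both groups
(stable item-reliability heterogeneity, which is what keeps cross-group
strength rankings aligned); inter-factor correlation 0.50 (young) vs 0.30
(old). Both defaults emulate inclusion screening by rejection-sampling
participants to `HADS-D ≥ 4`, so the generated cohorts pass the pipeline's
inclusion filter unchanged at full size. These values were fixed by forward
simulation at n = 5000 so that the *included* cohorts reproduce the
qualitative target pattern: anxiety more interconnected than depression in
both groups and more so in the old cohort, depression-internal and
cross-domain connectivity higher in the young cohort, near-perfect
cross-group strength rank agreement with only moderate bridge agreement,
and acceptable subscale consistency.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: item-pair residual dependencies beyond the two
factors (e.g. shared somatic content), any within-group age trend,
non-probit response styles (central tendency, acquiescence), missingness,
and the absolute NMI magnitudes of any particular empirical network. The
inclusion conditioning also shifts the realized marginals above their
calibration targets (the targets describe a screened sample, which a
two-factor model cannot reproduce jointly with its own screening rule);
calibration to printed marginals is therefore best-effort.

## Pipeline and validation sizes

`run_study` executes simulate/load → filter → group split → per-group
network + communities → 5 permutation tests (3 age contrasts:
within-anxiety, within-depression, between-community; plus the
anxiety-vs-depression within-network contrast per group) → centrality rank
comparisons → descriptive tables, with stage-level logging, warnings below
100 participants per group, and a pydantic-validated JSON report
(`schemas/study_report.schema.json`); CSV outputs are written with 6
significant digits, the JSON at full precision. Reports are deterministic
given the config's seeds, up to the `generated_at` stamp.

Validation experiments use deliberately modest sizes chosen to give stable
yes/no answers: estimator/oracle agreement on tables up to n = 200;
community recovery at n = 800 over 40 seeds; connectivity monotonicity in ρ
at n = 5000 over 10 seeds; permutation calibration with 200 replicates of
200-draw tests on a null 300/300 split, whose rejection rate is judged
against the exact binomial 95% band for a 5% test.

## Known limitations

Plug-in MI is upward-biased at small n (all cohort comparisons here share
n within a test, and the permutation null carries the same bias); the
geometric-mean NMI convention is one of several in use, so absolute edge
weights are not transferable across conventions; Louvain with restarts is
a heuristic without optimality guarantees (14 nodes make failures
unlikely but not impossible); and the descriptive layer performs no
covariate adjustment — group contrasts are unadjusted comparisons, as in
the analysis design it mirrors.
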