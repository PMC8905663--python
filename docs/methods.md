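# Methods

This note documents the models, conventions and design choices behind
`cfcg`, in the order the pipeline applies them.

## Screening model

The screen is the classic rule-of-five box with strict inequalities on
all five faces: MW < 500 Da, rotatable bonds < 11, H-bond acceptors
< 10, H-bond donors < 5, −2 < ClogP < 5. A record sitting exactly on a
threshold fails; the test suite asserts both sides of every boundary.
Screening is idempotent and order-preserving. A component belonging to
several herbs counts once in the global passed count and once per herb
in the per-herb membership counts — that is why a two-herb table can
legitimately report 126 components but 127 (100 + 27) memberships.

### Component identity

Rows are merged into one multi-herb component when their normalized
names (case-insensitive, whitespace-collapsed) match **across different
herbs**; identical names listed twice under the *same* herb are treated
as distinct upstream database entries and kept as separate records with
disambiguated ids. Cross-herb merging is what the merge is for —
identifying compounds the herbs share — whereas a within-herb duplicate
is ambiguous and collapsing it silently would change membership counts.
The policy is configurable (`merge="off"` keeps every row).

## Network conventions

All graphs are simple, undirected and unweighted. The C-T network is
bipartite (components vs targets); the converged network adds PPI edges
between targets already present, dropping (and counting) PPI edges with
an endpoint outside the target set. A component's neighbourhood is
always its C-T edge set, also in the converged network; PPI edges change
target degrees only.

**Eccentricity** is the maximum shortest-path length to any *reachable*
node, i.e. it is taken within the node's connected component, and an
isolated node has eccentricity 0. This is the NetworkAnalyzer convention
and avoids infinities on disconnected inputs.

**Median-degree filter.** The median is the standard lower+upper
midpoint over the *pooled* degree list of all listed components and
targets together; only targets strictly above it are retained
("over the median"). An all-equal degree pool therefore retains nothing
and emits a warning rather than an arbitrary half-split.

**Degree-group comparison** uses the pooled-variance (Student's) two
sample t-test, not Welch's, because group variances are treated as
common by convention here. Zero pooled variance with equal means returns
p = 1; with unequal means the statistic is undefined and raised as an
error.

## Contribution model

For component *i* with target *j*:

```
C_ij = Comp_i · ( C_edge/T_edge + |Comp_Hi − Comp_Ci|/(Comp_Hi + Comp_Ci) ) · Tar_j
CSC(i) = Σ_j ( NL(C_ij) + NL(dose_i) )
```

Conventions and their rationale:

- **Tar_j ambiguity.** Two readings of the target term are coherent:
  the eccentricity of target *j* itself (per-pair, consistent with the
  *ij* indexing) or the summed eccentricity over all of *i*'s targets.
  Both are implemented behind `tar_mode`; the default is `per_target`.
  For single-target components the two readings provably give identical
  rankings, which the suite checks.
- **Herb asymmetry term** is defined as 0 when both herb eccentricities
  are 0 and equals 1 exactly when a component is exclusive to one herb.
- **Normalization pools.** `NL(C_ij)` is min–max over *all*
  component–target pairs globally (the notation carries no index
  restriction, and a per-component pool would erase cross-component
  contrast). `NL(dose)` is min–max over components. A constant pool maps
  to all zeros (not 0/0) and is logged as degenerate — so a single
  isolated component scores 0 rather than NaN.
- **Dose.** With a measured concentration (mg per g of herb) the dose is
  concentration × herb grams summed over the component's herbs, in mg.
  Without one, the summed raw herb grams act as a proxy and the mode is
  recorded in every output row; with equal herb doses this proxy makes
  `NL(dose)` identically 0 for those components, which the report
  surfaces rather than hides. Min–max makes all doses scale-invariant,
  asserted as a property test.
- **Eccentricity source.** Scores are computed on the pure C-T network
  by default; `ecc_network="converged"` switches the eccentricity source
  to the PPI-merged graph. The converged network otherwise enters only
  at the knapsack stage.
- **Functional space.** Share-first selection: the shortest prefix of
  the descending ranking whose cumulative share reaches the fraction
  (default 0.90). Ties in CSC break by component id so the prefix is
  deterministic; selection size is monotone in the fraction.

## Knapsack stage

Items are the functional-space components; weight = count of the
component's retained targets, value = summed converged-network degree of
those targets; capacity = ⌈fraction × n_retained⌉ (90 % by default, so
473 retained targets give capacity 426). The dynamic program is exact
over integer weights with a lexicographic objective: maximize value,
then minimize the number of selected components, then take the
lexicographically smallest id set. The same objective is applied by the
exhaustive-enumeration oracle used in tests and `--verify` mode, and the
two agree exactly on hundreds of random instances.

Weights are per-item target counts, so a target shared by two selected
components is counted twice against the capacity — that is what the
additive recurrence defines, and "fixing" it would change the model into
weighted set cover. Instead the distinct-target union of the selection
is reported alongside as a coverage diagnostic.

Numerical notes: the capacity ceiling subtracts a 1e-9 slack before
rounding up so that an exactly integral fraction × n is not pushed up a
unit by float noise; item values are sums of integer degrees, so value
comparisons inside the DP are exact.

## Over-representation analysis

The enrichment statistic is the upper-tail hypergeometric probability
P(X ≥ k) of the observed overlap, computed per annotation term, with
Benjamini–Hochberg adjustment by default (Bonferroni optional). The
universe defaults to the union of all annotation genes; query genes
outside it are dropped with a logged count, matching common ORA
practice. Gene symbols are uppercased on input (configurable). Results
are sorted by adjusted p then term id, so output order is deterministic.

## Synthetic data generator

The generator emulates the qualitative structure the pipeline exploits,
not real chemistry or curated interactomes:

- **Two herbs**, 15 components each by default, each component assigned
  drug-like properties; a configured fraction of ordinary components is
  given exactly one out-of-range property (ADME failure mix). Planted
  core components always pass the screen — a core that cannot enter the
  analysis could never be recovered, so the screen would be untestable
  as a recovery experiment.
- **Targets** in three tiers: two herb-private pools, a shared hub pool
  (25 % of targets by default) and, inside the shared pool, a super-hub
  top tier (a third of the hubs). PPI edges are dense on shared pairs
  touching a super-hub (p = 0.5), intermediate among other shared pairs
  and sparse elsewhere (p = 0.01), so shared targets carry markedly
  higher converged degree — the signature the median filter keys on, and
  the planted analogue of the empirical observation that targets shared
  by two herbs sit high in the degree distribution.
- **Planted core**: three components (split across herbs) that attach
  only to super-hubs, with 4–5 targets each, and carry high measured
  concentrations. Ordinary components are drawn toward regular hubs
  (weight = multiplier) and more weakly toward super-hubs
  (multiplier/2). With the default multiplier 5 the core's items
  dominate the knapsack in value density while fitting the capacity;
  setting the multiplier to 1 is the null configuration in which
  everyone samples uniformly and recovery degrades toward baseline.
- Everything is drawn from a single seeded generator; a config is
  byte-reproducible file for file.

Core geometry is constrained by the model itself: item weights are
retained-target counts, so the three core items together must weigh no
more than ~90 % of the retained set. The default core degree (4–5 of
10 super-hubs) respects that budget with room for filler items; during
development, wider core degree ranges were observed to push the core's
total weight against the capacity and break recovery for no interesting
reason, which is why the default is deliberately slim.

What passing the recovery test shows: the full pipeline (screen →
score → space → filter → knapsack) preferentially selects components
planted to be functionally central, under this generative model. What
it does not show: performance on real formulas, where target prediction
noise, scale-free PPI topology and property–activity correlations are
all absent from the generator.

## Sizes and determinism

Default test and acceptance problem sizes — 30 components, 120 targets,
20 recovery seeds, 200 random knapsack instances, 50 random graphs —
were chosen so the whole suite completes in seconds while still
exercising every branch; they are stated here as the package's own
choices. All pipeline outputs are pure functions of inputs + config +
seed: tables are written in deterministic order and the run manifest
records input checksums, config and seed but no wall-clock timestamp
(the `timestamp` field exists and stays null unless explicitly set), so
re-running with identical inputs is byte-identical — asserted at the
file-digest level in the suite.

## Known limitations

- The contribution model's dose term is only as informative as the
  concentration data; with the grams fallback and equal herb doses it
  contributes nothing (reported, not hidden).
- The knapsack's additive weights double-count shared targets; the union
  coverage diagnostic quantifies, but does not remove, the discrepancy.
- Eccentricity-based terms are coarse on small or star-like networks,
  where many components share one eccentricity value and ranking falls
  back to degree-driven terms and ties.
- ORA assumes a well-chosen universe; defaulting to the annotation union
  is conventional but can overstate significance if the annotation is
  narrow.
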