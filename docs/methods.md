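# Methods

This note documents the models, conventions and numerical choices
behind `connectokit`, and what the synthetic cohorts do and do not
show about real data.

## Graph model and metric conventions

A connectome is an undirected weighted graph on N parcellation nodes;
weights are mean FA per connection, strictly in (0, 1), with 0 meaning
"no edge" and a zero diagonal. Matrices are validated on read:
asymmetries up to 1e-9 are averaged away, anything larger is an
integrity error.

Several conventions are genuinely underdetermined in the connectomics
literature; the package fixes them as follows, all switchable where it
matters:

- **Degree is always a binary count** of nonzero edges, whatever the
  weights.
- **Path length.** In `weighted` mode an edge of weight *w* has
  length 1/*w* (high-FA connections are "short"), the conventional
  mapping for FA-weighted networks; `binary` mode uses hop counts.
  Both modes are implemented and tested for every metric.
- **Efficiency.** Global efficiency is the mean of 1/d(i, j) over all
  ordered pairs i ≠ j, with disconnected pairs contributing 0 (this
  keeps Eglob finite and in [0, 1] for binary graphs). Local
  efficiency of node *v* is the global efficiency of the subgraph
  induced by *v*'s neighbors, *v* excluded; nodes with fewer than two
  neighbors score 0.
- **Betweenness** is unnormalized and accumulates over unordered
  source–target pairs, each counted once, with all equal-length
  shortest paths counted through path-counting (no tie-breaking).
  Computation is delegated to networkx's Brandes implementation;
  shortest paths use scipy's Dijkstra. Both are cross-checked in the
  test suite against an independent brute-force enumeration of all
  simple paths on small random graphs (agreement to 1e-9).

## Hub rule and the hub disruption index

Hubs of a group are nodes whose group-mean degree exceeds the mean of
the group-mean degrees by strictly more than one sample SD (ddof = 1),
the spread taken **across nodes**. Strictness and the sample SD are
explicit choices so boundary nodes are handled reproducibly.

The hub disruption index κ of a subject for a metric is the unweighted
OLS slope of (subject − reference) on the reference, across nodes,
where the reference is the control-group mean profile. Patients are
scored against the full control mean; each control is scored against
the leave-one-out mean of the remaining controls, because scoring a
subject against a mean that contains it biases its slope toward
−1/n_c. The choice is recorded in the output (`control_reference:
leave-one-out`). Exact identities used as tests: κ(reference) = 0,
κ(0) = −1, κ(a·reference) = a − 1.

## Network-based statistics

Edge-wise statistic: pooled-variance two-sample t (or a tie-corrected
rank-sum z), oriented control − patient so FA reductions in patients
are positive; the default test is one-sided in that direction since
reduced tract integrity is the phenomenon of interest (two-sided is a
flag). Edges enter testing only when nonzero in at least
`edge_mask_rule` (default 0.9) of subjects, so group means are not
taken over wildly differing support; edges whose pooled within-group
variance is zero get statistic 0 and are recorded as warnings.
Components of the supra-threshold graph are found by union-find;
inference uses the permutation distribution of the maximal component
extent over random relabelings of the group labels, with the
positively biased estimator p = (1 + #{null ≥ observed}) / (K + 1),
which is valid and never zero. Subjects are put in a canonical order
internally, so p-values do not depend on cohort ordering; for tiny
cohorts with fewer distinct labelings than requested permutations the
test refuses and offers exhaustive enumeration (`fit(exact=True)`),
which the suite uses to validate the Monte-Carlo p-values.

Defaults — primary threshold t = 3.0, 5000 permutations, α = 0.05 —
are conventional extent-based NBS practice; no claim is made that they
match any particular published run, and all are exposed in
`NBSConfig`. One property worth knowing: at high primary thresholds
the supra-threshold graph on null data is sparse, the extent null
concentrates on very small integers, and the test becomes
conservative (family-wise rejection well below α) purely through
discreteness. The FWER calibration test therefore runs at t = 2.5,
where the extent distribution is rich enough for the rejection rate
to resolve the nominal level; FWER control itself holds at every
threshold.

## Statistical layer

Group comparisons use the unpaired two-sided Mann–Whitney rank-sum
test (exact for small untied samples, tie-corrected normal
approximation otherwise). A signed-rank test is undefined for
unpaired groups of unequal size, so the unpaired test is the primary
method throughout. Nodal tables carry two flags per test: Bonferroni
(α/n, 0.05/164 ≈ 0.000305) and exploratory (1/n ≈ 0.0061); both
cutoffs are kept exact internally and rounded only for display. The
exploratory threshold passes about one null node per 164 by
construction, which the null-cohort simulations confirm. Clinical
correlations are Spearman with fixed significance levels 0.0125
(global metrics) and 0.004 (nodal metrics), preserving the
two-family correction scheme rather than recomputing it. Demographics
use Kruskal–Wallis (continuous) and chi-squared without Yates
correction (categorical); on a 25-vs-26 cohort with a 16/9 vs 15/11
sex split the uncorrected chi-squared gives p = 0.645, matching
conventional reporting for tables of this size, while the Yates
correction would give 0.86.

## Synthetic cohorts

The generator's defaults are the study conditions: 164 nodes, 25
patients vs 26 controls, mean nodal degree ≈ 111.5
(`base_density = 0.6838`), across-node degree spread
`degree_sd = 29`, FA weights ≈ 0.35 ± 0.08, a planted 10-edge star
spanning 11 nodes with FA reduced by 0.15 in patients, six deficit
nodes losing 10% of their edges, and a Spearman coupling of −0.54
between deficit-node degree and the disease progression rate.

**Structure.** Each cohort has one *backbone*: a maximum-entropy
("beta-model") random graph fitted by fixed-point iteration to a
target degree profile drawn from Normal(base_density·(N−1),
degree_sd), clipped and recentred so the expected mean degree is
exact. A homogeneous Erdős–Rényi baseline was rejected for a concrete
statistical reason: with a flat expected degree profile, the
across-node variance of the control mean profile is pure sampling
noise shared with every subject's deviation, which drives each
per-subject hub-disruption slope toward −1 regardless of the planted
value (classical errors-in-variables with correlated noise). A
heterogeneous backbone gives the reference profile real structure
(and, incidentally, a hub minority under the one-SD rule, as real
connectomes have). Subjects are the backbone plus independent edge
noise: each backbone edge dropped with probability
`subject_edge_noise = 0.03`, each non-edge added with the
density-balancing probability, so expected degree transforms affinely
and identically in both groups. FA weights are i.i.d. per present
edge and subject, Normal(fa_mean, fa_sd) clipped into (0, 1) — the
clipped mass at the default location/scale is negligible.

**Planting.** Planted-component edges are forced into the backbone
and their FA lowered by `fa_effect` in patients (floored above 0).
Deficit nodes lose incident edges independently with
`edge_removal_prob` in patients. A hub-disruption target κ redraws
each patient's adjacency from a beta-model fitted to
b + κ(b − mean(b)), where b is the realized backbone degree profile —
an expected-value construction whose recovered slope is unbiased
because the same subject noise is applied to both groups. The
clinical coupling is a Gaussian copula: patients' realized metric
values are rank-transformed to normal scores, the progression rate is
sampled from a lognormal marginal matched to 0.9 ± 0.9 per month
(durations 18 ± 15 months, range-clipped) with copula correlation
2·sin(π·ρ/6) so the *Spearman* correlation hits the target; ALSFRS-R
is an integer in [0, 48] and the duration is back-solved so
(48 − ALSFRS-R)/duration reproduces the sampled rate exactly.

**Reproducibility.** One global seed expands into per-purpose and
per-subject substreams keyed by CRC32 of the subject id, so cohorts
are bit-reproducible and growing a cohort never reshuffles existing
subjects.

**What the simulations do not show.** Real connectomes have spatially
correlated edges, distance-dependent connection probabilities,
subject-level global FA offsets and much larger between-subject degree
variance (per-node SDs of order 8–20 versus ≈ 2.5 here). Passing the
recovery and calibration suites therefore demonstrates that the
*estimators and tests* behave as designed under a controlled
generative model — not that any particular empirical effect size
would be detected in real data. One visible consequence of the small
between-subject variance: tiny systematic group differences (e.g. the
slight negative κ induced by deficit planting) can reach significance
at study scale, which real-data noise would mask.

## Problem sizes and numerical choices

Simulation-based tests run at the study scale of 164 nodes and 25+26
subjects with replicate counts chosen to keep the full suite in the
minutes range: 100 cohorts per planted κ value, 200 null cohorts at
500 permutations for FWER calibration, 50 replicates for component
recovery, 60/30 cohorts for the nodal two-tier checks, 150 for the
clinical coupling. The acceptance script runs one full study-scale
analysis at 5000 permutations. Beta-model fits iterate to a 1e-9
fixed-point tolerance; degenerate inputs (constant references,
all-tied samples, zero-variance edges, groups of size < 2) raise
typed errors rather than returning silent NaNs, except inside the
nodal table, where per-node degeneracies are recorded as NaN rows so
one bad node cannot abort a 164-node table.
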