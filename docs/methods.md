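# Methods

## Scope and model

`enterotyper` analyses longitudinal two-arm infant-microbiome trial data:
genus-level count tables with per-sample metadata (subject, arm, visit,
feeding records, fecal mass), fecal biomarker panels, and a rooted
phylogeny for Faith's PD.  The statistical core is (i) enterotype
discovery by sqrt-Jensen–Shannon distance + PAM + Calinski–Harabasz model
selection, (ii) subject-level trajectory clustering by Pearson distance on
one-hot enterotype sequences, and (iii) a nonparametric battery for
stratified biomarker comparisons.  A synthetic cohort generator provides
ground truth for every stage.

## Enterotype discovery

**Distance.**  Relative-abundance zeros are replaced by a pseudocount
(default 1e-10) and rows renormalised; the distance is the square root of
the Jensen–Shannon divergence with natural logarithms.  sqrt-JSD is a true
metric bounded by sqrt(ln 2) ≈ 0.8326, which keeps PAM well defined and
PCoA nearly Euclidean (negative eigenvalue mass is small and reported).

**PAM.**  Classical BUILD (greedy cost reduction) followed by
steepest-descent single-swap passes.  Single-swap descent from one seeding
can terminate in a local optimum — we verified this happens on roughly 10%
of small random instances, and that the canonical R implementation stalls
in the same optima — so the search restarts from the `min(n, 8)` most
central points as forced first medoids and keeps the cheapest solution
(ties broken by the lexicographically smallest medoid set).  On 800 random
instances with n ≤ 8 this multi-start always attained the exhaustive-search
optimum.  The procedure is fully deterministic: no seed, byte-identical
refits.

**Model selection.**  The Calinski–Harabasz index is evaluated directly on
the distance matrix through the pairwise sums-of-squares identity
(W = Σ_c (1/2n_c) Σ_{i,j∈c} D²_ij, B = T − W), which coincides with the
textbook centroid form whenever the distances are Euclidean (enforced by a
test against the coordinate-based formula).  Evaluating CH on the distance
matrix rather than on PCoA coordinates avoids an arbitrary choice of
retained axes.  The default candidate range is k = 2..10; ties go to the
smallest k.  Degenerate cases: perfect clusterings (W = 0) report +inf; an
all-zero distance matrix reports NaN with a warning.

**Labelling.**  Clusters are named after the genus with the highest mean
relative abundance among members; when the top two means are within a
margin (default 0.15) the label lists both ("ET-Bifi and Bact").  Repeated
names are suffixed by cluster-size rank, so the largest
*Bifidobacterium*-dominant cluster is "ET-Bifi 1".

## Trajectories

Per-subject sequences over the T visits are encoded as concatenated
one-hot blocks of length T×K; missing visits (failed extractions) are
masked, not imputed, and distances use pairwise-complete positions.  A
transition-pair count encoding is available behind a flag.  The distance
is d = 1 − r (Pearson), in [0, 2]; constant vectors have no defined
correlation and use the documented sentinel (0 if equal, else 2).
Agglomeration is average linkage by default (complete available) and the
tree is cut to a requested number of clusters, mirroring the flat
six-cluster reading of the trial's dendrogram.

## Alpha diversity

Shannon entropy is reported in log base 2 for comparability with the
common amplicon-pipeline convention; Chao1 uses the bias-corrected form
S_obs + F1(F1−1)/(2(F2+1)), defined even without doubletons; Faith's PD is
root-inclusive.  No rarefaction is applied by default — an optional
`rarefy(depth, seed)` (subsampling without replacement via the
multivariate hypergeometric) is provided because either convention is
defensible and the choice is left to the user.

## Statistics

- **Wilcoxon rank-sum**: exact enumeration when the combined sample is
  ≤ 20 and tie-free, otherwise the normal approximation with tie and
  continuity corrections; two-sided p capped at 1; ties force the
  approximate path even at small n.
- **Kruskal–Wallis** with tie correction against χ²(g−1);
  **Dunn–Bonferroni** pairwise z tests on pooled ranks with tie-corrected
  variance, adjusted p = min(1, p·g(g−1)/2) over the comparisons actually
  performed (empty groups are excluded with a warning).
- **Fisher's exact test**: 2×2 via the hypergeometric two-sided rule;
  two-row R×C tables (the enterotype-by-arm shape) via a vectorised scan of
  the multivariate-hypergeometric support, exact up to a 2,000,000-table
  bound (a 56/53-by-6 table enumerates ≈1.6M tables in a few seconds);
  other shapes via a recursive enumeration capped at 200,000 tables; beyond
  the bound, a seeded Monte-Carlo estimate over margin-preserving draws
  with its simulation standard error.
- **CLR Monte-Carlo differential abundance**: per instance, sample
  proportions ~ Dirichlet(counts + 0.5), CLR transform, two-sided rank-sum
  p per taxon; expected p = mean over instances (default 128); q =
  Benjamini–Hochberg across taxa.  The inner rank-sum uses a vectorised
  normal approximation with continuity correction and no tie correction —
  CLR values of continuous Dirichlet draws are tie-free almost surely.
  The effect size is the median over instances of the between-group median
  CLR difference divided by the pooled within-group MAD; this is a
  simplified robust effect, labelled as such, not the original tool's
  dispersion-based definition.  Null calibration (two identical
  Dirichlet-multinomial groups, 30 taxa, 25+25 samples, 200 replicates)
  shows the expected-p aggregation is strongly conservative: the fraction
  of taxa reaching q < 0.05 is far below the nominal 0.05.
- **Biomarker preprocessing**: extract concentrations are converted to
  per-gram values (raw × dilution × extract volume / fecal mass); values
  strictly below the limit of detection are stored as exact 0 with a
  censoring flag and enter rank tests as true zeros (bottom ties).
  Biomarkers detected in fewer than 20% of samples are skipped by the
  stratified comparison (configurable), and strata smaller than 3 samples
  are excluded with a warning.
- **Breastfeeding rate**: Σ breast feeds / Σ all feeds over the feeding
  window ending at the sample's visit; the window defaults to the interval
  since the previous visit.  The rate is computed downstream from the raw
  daily records so its definition lives in one place.

## Synthetic cohort generator

The generator emulates the structure of the motivating trial design; its
defaults are the study conditions, not tuning knobs.

- **Layout**: arms of 56 and 53 analysed subjects (57/54 randomised, 111
  enrolled), four visits (pre, 1 week, 1 month, 3 months), 30 named
  genera, exactly 3 first-visit extraction failures → 433 of 436 planned
  samples retained.  A Bernoulli `missing_rate` path is available instead
  of the exact-failure draw.
- **States**: six archetypes — two *Bifidobacterium*-dominant variants
  (differing in secondary genera), *Bifidobacterium*+*Bacteroides*,
  Enterobacteriaceae (unknown genus), *Enterococcus*+*Clostridium*,
  *Streptococcus* — as Dirichlet concentration rows with one genus at
  60–85% expected abundance and row total 120 (within-state tightness
  chosen as a realistic enterotype-level separation).  Subjects start from
  an arm-independent initial distribution (pre-intervention samples should
  not differ by arm) and evolve under per-arm Markov kernels: the
  probiotic kernel pulls quickly toward the *Bifidobacterium* states, the
  placebo kernel drifts there more slowly (healthy term infants bifidify
  spontaneously).  Pre-intervention state frequencies are free parameters;
  the defaults weight the facultative-anaerobe states.
- **Counts**: read depth ~ negative binomial (mean 30,000, dispersion 5) —
  unequal depths exercise normalisation — and genus counts ~
  Multinomial(depth, Dirichlet(archetype)).
- **Biomarkers**: lognormal with state-dependent log-means; censored to
  exact 0 below the LOD.  Defaults encode the directional structure of
  interest: proinflammatory cytokines (IFN-γ, IL-1β, TNF-α) and
  calprotectin higher in the Enterobacteriaceae-type states; tryptophan
  metabolites (ILA, IAA), acetate and sIgA higher in the
  *Bifidobacterium*-dominant states; IL-8 flat; IL-6 almost entirely
  censored (~10% detection) to exercise the detection-rate filter.
- **Feeding**: per-state Beta-distributed breast-feed fraction with means
  0.82 / 0.75 / 0.72 / 0.53 / 0.58 / 0.62 across the six states (the first,
  second and fourth anchored to reported enterotype-level breastfeeding
  averages; the rest plausible interpolations), applied to Poisson daily
  feed totals (~8/day) over each visit window.
- **Determinism**: one integer seed; identical configs give byte-identical
  outputs.  Ground truth (per-sample state, archetype profiles, biomarker
  effect map, per-subject state sequences, feeding fractions) is returned
  for recovery testing.

**What the generator does not emulate**: taxonomic assignment noise,
read-level artifacts (chimeras, contamination), age-dependent depth or
composition drift within a visit window, antibiotic or delivery-mode
covariates, and correlated biomarker panels (markers are conditionally
independent given the state).  Passing recovery tests therefore shows the
pipeline is correct and well calibrated under the stated generative
assumptions — not that real cohorts satisfy those assumptions.

## Numerical choices and degenerate inputs

- JSD pseudocount 1e-10; distances clipped at 0 before the square root;
  the matrix is symmetrised to remove floating-point asymmetry.
- PAM ties (equidistant samples) go to the lowest cluster index; medoids
  are reported sorted by sample index.
- PCoA retains eigenvalues above 1e-10 × max; negative-eigenvalue mass is
  reported, not silently dropped.
- Collapse of unresolved genera keys them to the deepest known ancestor,
  so "Enterobacteriaceae; g__unknown" stays distinct from other unknowns;
  collapse conserves per-sample totals and commutes with normalisation.
- All-zero samples, duplicate IDs, non-stochastic kernels, empty groups
  and out-of-range p-values are rejected with messages naming the
  offending item.
- The CLI derives a per-stage seed from the master seed via SHA-256 of
  "seed:stage" (kept below 2³¹), so stages can be rerun independently.

## Problem sizes used by the test-suite and acceptance script

Recovery runs fit the full ~433-sample cohort over k = 2..10 for 10 seeds;
metric properties are checked on 1000 random profile triples; PAM is
compared against exhaustive search on 100 instances with n ≤ 8; CLR null
calibration uses 200 replicates of 25+25 samples × 30 taxa with 128
Dirichlet instances; the Kruskal–Wallis null uses 10,000 replicates of
three groups of 10.  These sizes were chosen to estimate each property
stably while keeping a full run in the order of a minute.

## Known limitations

- The enumeration bound makes very large non-two-row Fisher tables fall
  back to Monte-Carlo; the p-value then carries simulation error (reported).
- The CLR test's conservatism under the null (inherited from expected-p
  aggregation) trades type-I control for power at small n.
- Trajectory clustering treats visits as exchangeable coordinates of the
  encoding; it does not model time-warping or partial sequence alignment.
- Sub-cluster structure below a single flat cut (nested cuts) is out of
  scope.
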