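# enterotyper

Enterotype discovery and biomarker statistics for longitudinal infant
gut-microbiome trials.

In the first months of life the infant gut is colonised by a small number of
recognisable community states — *Bifidobacterium*-dominant configurations,
an Enterobacteriaceae-dominated state, *Enterococcus*/*Clostridium* and
*Streptococcus* states — and which state an infant occupies is linked to
feeding mode, probiotic supplementation and mucosal immune markers
(cytokines, secretory IgA, calprotectin, short-chain fatty acids and
tryptophan metabolites such as indole-3-lactic acid).  `enterotyper`
implements the complete desk analysis for a two-arm placebo-controlled
trial of this kind, together with a synthetic cohort generator with known
ground truth so that every stage of the pipeline can be validated without
access to subject-level data.

## What it computes

**Enterotype discovery.**  Genus-level relative-abundance profiles
$p, q \in \Delta^{G-1}$ are compared by the Jensen–Shannon distance

$$d(p,q) = \sqrt{\tfrac12 \mathrm{KL}(p\,\|\,m) + \tfrac12 \mathrm{KL}(q\,\|\,m)},
\qquad m = \tfrac12(p+q),$$

with natural logarithms (so $d \le \sqrt{\ln 2}$) and a small pseudocount
replacing zeros.  Samples are clustered by partitioning around medoids
(PAM) — a deterministic multi-start BUILD + SWAP search that needs no random
initialisation — and the number of enterotypes $k$ is chosen by maximising
the Calinski–Harabasz index, evaluated directly on the distance matrix via
the pairwise sums-of-squares identity

$$W = \sum_c \frac{1}{2 n_c} \sum_{i,j \in c} D_{ij}^2, \quad
B = T - W, \quad
\mathrm{CH} = \frac{B/(k-1)}{W/(n-k)}.$$

Principal coordinates (Gower double-centering + eigendecomposition) give
the standard ordination view, and clusters are named after their dominant
genus ("ET-Bifi 1", "ET-Ent", "ET-Bifi and Bact", …).

**Trajectories.**  Each subject's enterotype sequence over the visit
schedule is one-hot encoded over (time × enterotype), subjects are compared
by Pearson-correlation distance $d = 1 - r$ (pairwise-complete over missing
visits), and grouped by average-linkage hierarchical clustering with a flat
cut at a requested number of clusters.

**Alpha diversity.**  Shannon entropy (bits), bias-corrected Chao1,
observed features, and Faith's phylogenetic diversity against a rooted
tree.

**Statistics.**  Wilcoxon rank-sum (exact for small tie-free samples),
Kruskal–Wallis with Dunn–Bonferroni post-hoc comparisons, Fisher's exact
test for R×C enterotype-by-arm tables (vectorised exact enumeration for
two-row tables, seeded Monte-Carlo beyond the enumeration bound), an
ALDEx2-style differential-abundance test — Dirichlet(counts + ½) Monte-Carlo
instances, centred log-ratio transform, per-taxon rank-sum expected p,
Benjamini–Hochberg q — plus cytokine fecal-weight normalisation with
below-LOD censoring to exact zero and breastfeeding-rate computation from
daily feed records.

**Synthetic cohorts.**  The generator draws per-subject enterotype
trajectories from per-arm Markov kernels, genus counts from
Dirichlet-multinomial archetypes at negative-binomial depth, lognormal
state-linked biomarkers with LOD censoring, and state-linked daily
breast/formula feed counts; the default configuration reproduces the
layout of a 111-enrolled, 56 + 53-analysed, four-visit trial in which 433
of 436 planned stools yield data.

## Worked example

```python
import enterotyper as E

table, metadata, panel, truth = E.generate_cohort(E.GeneratorConfig(seed=42))
rel = E.to_relative(table)
model = E.select_k(E.jsd_matrix(rel), range(2, 11))
labels = E.label_enterotypes(model, rel)
print(len(table.sample_ids), model.k)
```

prints `433 6`: the cohort keeps 433 samples and the Calinski–Harabasz
curve peaks at six enterotypes.  The fitted clusters and their mean
breastfeeding rates (fraction of breast feeds over the window before each
visit) come out as:

```
  ET-Bifi 1          n=134   breastfeeding 81.1%
  ET-Bifi 2          n= 84   breastfeeding 74.3%
  ET-Bifi and Bact   n= 72   breastfeeding 74.0%
  ET-Ent             n= 70   breastfeeding 50.5%
  ET-Eco and Clo     n= 38   breastfeeding 58.6%
  ET-St              n= 35   breastfeeding 59.7%
```

— the *Bifidobacterium*-dominant states carry the highest breastfeeding
rates and the Enterobacteriaceae state the lowest, matching the generator's
configured feeding model.

The same pipeline is available from the shell:

```
enterotyper run --simulate --seed 7 --out runs/demo
```

which writes the cohort (counts, metadata, biomarkers, tree, truth), the
enterotype model JSON, PCoA coordinates, per-sample alpha diversity,
subject trajectory clusters and the stratified biomarker statistics table,
all with provenance headers.

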