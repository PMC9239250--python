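# Methods

This note documents the models and procedures implemented in `phyllodyn`,
the parameters that matter, and the choices made where the design was
genuinely open.

## The analysis problem

Monthly amplicon surveys of leaf microbiomes yield OTU count tables
(taxa × samples) for bacteria, fungi and oomycetes, with sample metadata
(experiment/year, month, host ecotype, plant replicate). The counts are
*compositional* — sequencing depth is arbitrary, so only relative
information is meaningful — and highly sparse. The pipeline asks four
questions of such data: how diversity and community variability move over
the season; which taxa are persistently present across experiments; how
month-wise co-abundance networks are inherited and rewired between
consecutive months; and which taxa act as network hubs.

## Filters and transforms

* **Low-abundance filter**: an OTU is dropped when its total reads fall
  below 50 (kept at exactly 50), following the `split.abund` convention.
  By default the filter is applied within each experiment and survivors
  are unioned, matching the semantics of independently processed
  per-experiment tables that are merged afterwards; a pooled mode is
  available.
* **Network input filter**: an OTU must have strictly more than 10 reads
  in at least 5 samples. The strict ">" and inclusive "≥ 5" follow the
  stated rule verbatim.
* **Relative abundance**: per-sample closure to proportions; the optional
  log10(x+1) transform is applied after closure on the proportion scale
  (0–1), not on percentages. All-zero samples stay zero columns and are
  logged.
* **Presence** anywhere in the pipeline means ≥ 1 read after the
  low-abundance filter — one consistent definition, since occurrence on
  unfiltered singletons would be dominated by noise.

## Community statistics

* **Shannon's H** uses natural log on positive proportions and is
  computed on counts without rarefaction (configurable upstream by
  subsampling if desired).
* **PERMANOVA** partitions the Gower-centred matrix
  G = J(−½D²)J (J the centring matrix) by sequential (Type-I) sums of
  squares in the stated term order, the convention of the reference
  implementation for crossed designs like experiment × month × ecotype.
  SS of a term is tr(H_k G) − tr(H_{k−1} G) with H_k the projection onto
  the design columns of terms 1..k; pseudo-F uses the residual mean
  square; p-values come from free (unrestricted) permutation of sample
  labels, p = (1 + #{F* ≥ F})/(1 + n_perm), with an exact-enumeration
  mode for tiny n. A 1e−12 slack on the exceedance comparison makes
  permutations that recreate the observed grouping count as ties despite
  float rounding. Factors with one level are skipped with a warning.
  The implementation agrees with R vegan's `adonis2` (`by="terms"`) to
  numerical precision; a test asserts this.
* **Beta-dispersion** embeds the dissimilarity matrix by principal
  coordinates; axes with negative eigenvalues contribute *imaginary*
  coordinates whose squared distances are subtracted (floored at zero),
  the `betadisper` convention, so non-Euclidean Bray–Curtis matrices are
  handled. Group centroids are means in both subspaces. Agreement with
  vegan's `betadisper(type="centroid")` is asserted in a test.
* **Dunn's test** uses pooled mid-ranks with the tie correction
  Σ(t³−t)/(12(N−1)), pairwise z statistics, two-sided normal p-values
  and Bonferroni correction over all pairs. The compact letter display
  uses the insert-and-absorb algorithm; groups sharing a letter are not
  significantly different.
* **Between-month variability** lists all cross-pair Bray–Curtis
  distances between samples of consecutive months.
* Diversity and dispersion are computed per kingdom (the three
  communities are profiled by different markers); tables are merged only
  for network inference.

## Core taxa

Occurrence = fraction of an experiment's samples with presence. An OTU is
core iff its occurrence meets the kingdom threshold (bacteria 0.98;
fungi and oomycetes 0.95) in every experiment; the higher bacterial
cutoff compensates for their higher average occurrence. Raising a
threshold can only shrink the core set (tested as an invariant). Core
taxa are summarised by their summed within-kingdom relative abundance
per month and clustered by average-linkage (UPGMA) agglomeration on
Gower distances over the six taxonomy ranks (kingdom..genus, equally
weighted; a missing rank is its own category, so two missing entries
match). UPGMA is the conventional default for Gower matrices; the
linkage choice was otherwise open.

## SparCC network inference

Counts are converted to posterior fractions by a Dirichlet draw with unit
pseudocount per sample. From the log-ratio variance matrix
t_ij = Var[log(xᵢ/xⱼ)], the sparsity assumption (most true correlations
are zero) gives the linear system M ω = T with T the row sums of t and
M = 1·1ᵀ + (D−2)I; correlations follow as
ρᵢⱼ = (ωᵢ + ωⱼ − tᵢⱼ)/(2√(ωᵢωⱼ)), clipped to [−1, 1]. The strongest pair
exceeding the exclusion threshold (0.1) is then removed from the system
and ω re-solved, up to 10 rounds; the whole pass is repeated over 20
Dirichlet resamplings and the element-wise median taken. Negative
estimated basis variances are clipped to 1e−6 with a warning. These
defaults (20 inner iterations, 10 exclusion rounds, threshold 0.1, unit
pseudocount) are the estimator's reference defaults and are all exposed.

Significance comes from a permutation null: each taxon's counts are
independently shuffled across samples, destroying association while
preserving marginals (this is what the estimator's reference
implementation calls "bootstraps"), the full estimator is re-run, and
two-sided pseudo-p = (1 + #{|ρ*| ≥ |ρ|})/(1 + n_boot). The minimum
attainable p is 1/(1+n_boot) — with 1000 replicates, 0.000999 —
consistent with an edge gate of p < 0.001: only correlations that beat
every null replicate become edges. Note a consequence at scale: each of
the P pairs independently beats its own null with probability
1/(1+n_boot) under independence, so roughly P/(1+n_boot) noise edges are
expected per network; this is a property of the published procedure, not
of this implementation.

The **Spearman mode** computes rank correlations (Pearson on mid-ranks;
constant taxa yield undefined entries and are skipped with a warning) on
log10(x+1) relative abundances, selects the top and bottom 5 % of the
pair-correlation distribution as candidates (exactly round(q·n_pairs)
each, ties broken by absolute value then lexical pair id; quantiles are
per month), attaches Fisher-Z p-values (z = atanh ρ·√(n−3), two-sided
normal) and keeps candidates with Bonferroni-adjusted p ≤ 0.001. The
Bonferroni denominator is the number of selected candidates — the
procedure corrects after edge selection — switchable to all pairs.

Month networks pool a month's samples across experiments; taxa with zero
counts in that month are dropped before inference. Edges store sign,
correlation weight and p; isolated nodes are excluded from the graph.

## Network dynamics

A node (edge) of month m+1 is *inherited* iff the same OTU id (unordered
id pair) exists in month m; sign is ignored by default (an option
requires sign match). Percentages are expressed relative to the later
month — the share of the network already present the month before — with
the earlier-month denominator as an option.

The per-node **Dn rewiring score** compares a node's neighbourhood
between the two states: its weight vectors over the union of neighbours
(binary by default, since edges are already significance-thresholded;
|ρ| weights optional) are normalised to unit length, and the raw score is
the mean Euclidean distance of the two vectors to their centroid —
equivalently half the distance between them: 0 when nothing changed,
√2⁄2 when the neighbourhoods are disjoint (orthogonal unit vectors). The
degree correction divides by the number of distinct neighbours across
both states, so small changes at high-degree nodes score low. The exact
normalisation inside the original dynamic-network tool is not published;
this formula is pinned, documented, and covered by closed-form tests.

## Hubs

Centralities are computed on the unweighted, sign-blind graph:
betweenness normalised by (n−1)(n−2)/2 and closeness with the
Wasserman–Faust component rescaling so fragmented networks are handled.
A node is a hub iff it reaches the top ceil(0.05·n) values of *both*
metrics within its month network (all ties with the cutoff value
included — deterministic and inclusive; the cut is taken over all nodes
present in the network). The product betweenness × closeness summarises
a taxon's monthly connectivity (0 when absent from the network), and hub
sets from the SparCC and Spearman networks are compared by containment
and Jaccard fractions.

## Synthetic surveys

The generator emulates the field design: 3 experiments × 5 ordered
months (Nov..Mar) × 4 ecotypes × 3 plants (180 samples) and three
kingdoms (default 120/60/20 taxa). Counts are produced by the
log-normal/multinomial scheme the compositional estimator assumes, so
parameter recovery is a fair test:

1. per-taxon baseline log-means ~ N(0, 1.2²) (≈3 decades of abundance);
2. per month, latent log abundances are multivariate normal with
   correlation matrix I plus the planted pairs, repaired to the nearest
   PSD correlation by eigenvalue clipping (a planted value shifted by
   more than 0.2 by the repair raises an error naming the pairs);
3. within-month log-sd is 1.2 in the first month, shrinking by
   `dispersion_decay` per month (stabilisation);
4. monotone seasonal trends shift group log-means linearly over months;
5. core occupancy is exact: for a planted occurrence p, ceil(p·n)
   samples per experiment contain the taxon, so realized occurrence
   never falls below target; a core taxon included in a sample but drawn
   zero by the multinomial receives one read from the sample's largest
   count, preserving the sample's depth;
6. non-core taxa get abundance-dependent zero-inflation — dropout
   propensity 0.2 + 0.8(1−rank)² over abundance ranks, scaled by a
   factor solved by bisection so the expected zero fraction hits
   `sparsity_target` (Poisson approximation for sampling zeros). Zeros
   therefore concentrate in rare taxa, which is what lets the abundance
   filters cut sparsity the way they do in real surveys (e.g. ~74 %
   before filtering to ~50–55 % after); the floor keeps even abundant
   non-core taxa transient so only planted core taxa can pass occurrence
   thresholds;
7. depths are Poisson around the configured mean (default 10,000) and
   counts multinomial at each sample's depth.

Month labels are ordered categoricals throughout; "consecutive months"
never depends on string sort order. Identical config + seed reproduces
byte-identical tables.

What the generator does **not** emulate: taxonomic mis-assignment,
chimeras or any read-level noise; phylogenetic correlation between taxa;
overdispersion beyond the log-normal (no taxon-specific dispersion);
dependence of dropout on month or ecotype; and real ecological
interaction structure beyond planted pairwise correlations. Tests
passing on these surveys show the estimators recover what the model
plants under the model's own assumptions — they do not certify behaviour
on real field data.

A note on benchmark design: parameter-recovery studies pin the
correlated taxa to 1 % relative abundance and full occupancy (via the
core mechanism). Planting correlations on taxa at arbitrary lognormal
baselines conflates estimator error with read-depth censoring — a taxon
at ~20 reads/sample cannot carry a recoverable correlation at any
estimator's precision — so abundance is controlled and the planted
correlation is the only estimand.

## Numerical choices and degenerate inputs

* Bray–Curtis between two all-zero samples is defined as 0 with a
  warning (scipy yields NaN).
* PERMANOVA exact mode enumerates all n! relabelings and is guarded to
  n ≤ 8.
* Beta-dispersion for a singleton group returns 0 with a warning.
* Dunn on constant data yields all p = 1 (variance collapses to zero).
* Spearman candidate ties are broken by absolute value then lexical pair
  id, making edge selection deterministic.
* The pipeline fans a single global seed out to stages by
  `SeedSequence((seed, stage_index))` with fixed stage indices, so adding
  a stage never reshuffles the randomness of later ones; all derived
  seeds are < 2³¹.

## Problem sizes

Tests and the reproduction script run at desk scale: surveys of 95–200
taxa × 120–200 samples, 100–200 permutation replicates for network
pseudo-p-values (with the edge gate set to the corresponding minimum
attainable level, e.g. p < 0.005 at 200 replicates), and 999 PERMANOVA
permutations, chosen so a full run completes in minutes on one CPU. The
defaults of the library itself keep the survey-scale values (1000
replicates, p < 0.001, 10,000 permutations).

## Known limitations

* SparCC assumes a sparse true correlation network; dense planted
  structure violates the basis-variance solve and estimates shrink.
* Pseudo-p-values are granular (multiples of 1/(1+n_boot)); edge sets
  are therefore sensitive to n_boot through the attainable gate.
* The Dn normalisation is pinned to the formula above; other tools may
  scale differently, so compare scores only within a run.
* Occurrence thresholds interact with sample counts per experiment
  (ceil(p·n)/n > p for small n); with very few samples the realized
  occupancy of planted "prevalent but not core" taxa can cross a core
  threshold.
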