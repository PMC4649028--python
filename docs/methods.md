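# Methods

This note documents the statistical procedures implemented in `soilnet`,
the parameters that matter, the design choices made where several
reasonable options existed, and what the synthetic-data tests do and do not
demonstrate about real data.

## Study design and data model

The pipeline targets a crossed soil design: two depths (topsoil, subsoil) ×
three compartments (bulk soil, drilosphere, rhizosphere) × replicated field
plots, with one OTU × sample table of 16S rRNA amplicon read counts per
marker gene. Archaeal and bacterial tables are analyzed as separate runs;
the pipeline never merges domains. All tables are held OTU-rows ×
sample-columns internally; mothur `.shared` files (sample-rows) are
transposed on read. Raw tables must contain integers — pre-normalized
files are rejected so that networks are never silently built on
already-closed data.

## Preprocessing

**Subsampling.** Every sample is drawn down to a common depth (default: the
minimum sample sum) by multivariate hypergeometric sampling — i.e. reads
are drawn without replacement, matching the semantics of mothur's
`sub.sample`. The draw is seeded and a sample already at target depth is
returned unchanged.

**Prevalence filter.** The network stage uses only OTUs with ≥ 6 reads in
≥ 3 samples (both thresholds configurable). The filter is applied to the
*subsampled raw* counts, and the network is computed on relative abundances
of the filtered table. Applying the read-count criterion after equalizing
depths keeps "6 reads" comparable across samples; the filter is idempotent
and never touches the sample set.

**Transforms.** Relative abundance closes each sample to sum 1 (all-zero
samples stay zero, with a warning). The Hellinger transform is
√(count / sample sum); each non-empty sample becomes a unit vector, so
Euclidean distances on Hellinger data are suitable for ordination and
PerMANOVA.

**Copy-number adjustment.** Amplicon read counts over-represent taxa with
many 16S rRNA gene copies per genome. Each OTU's reads are divided by the
mean copy number of its deepest classifiable taxon, walking
genus → family → order → class → phylum → domain through an rrnDB-style
lookup and falling back to a mandatory "root" average, so the adjustment
never fails silently on unclassified lineages. The per-sample ratio of
adjusted to raw read sums then rescales qPCR-derived total 16S abundances
(copies · g⁻¹ dry weight) to genome equivalents; with a uniform copy number
c the total rescales by exactly 1/c.

## Supporting statistics

Shannon diversity uses the natural log (H' = −Σ pᵢ ln pᵢ over non-zero
proportions). Rarefaction is the analytic hypergeometric expectation
E[S_d] = Σ_o [1 − C(N−N_o, d)/C(N, d)], evaluated with log-gamma — no Monte
Carlo, so curves are deterministic and end exactly at observed richness.

Per-OTU group differences use one-way ANOVA with Tukey HSD post-hoc pairs
(α = 0.05) and a compact letter display; Bonferroni adjustment is applied
across the family of OTUs tested for one factor. OTUs with zero variance in
every group are flagged degenerate rather than tested; groups with < 2
replicates are skipped with a warning.

PerMANOVA computes Anderson's pseudo-F from among/within sums of squared
Euclidean distances on Hellinger data,
F = (SS_A/(a−1)) / (SS_W/(N−a)), with p = (1 + #{F* ≥ F}) / (1 + n_perm)
under free permutation of sample labels (no strata), 999 permutations by
default, seeded. Note that the pseudo-F is not invariant under duplicating
every sample: the SS ratio is, but the degrees-of-freedom factor
(N−a) changes — the test suite asserts this exact relation.

## Compositionality-corrected co-occurrence

Relative abundances are compositions: closure alone induces correlation
between taxa (mostly negative with abundant partners), so raw Spearman
significance overstates co-exclusion. For every OTU pair the package
computes:

* **Permutation null** — in each iteration every OTU row is independently
  permuted across samples and each sample re-closed to proportions; the
  full Spearman matrix is recorded. Re-closure preserves the artifact that
  closure would induce among independent rows with the observed marginals,
  while permutation destroys real association. Permuting all rows at once
  (one matrix per iteration) is the standard ReBoot formulation and costs
  one rank/correlation pass per iteration rather than one per pair.
* **Bootstrap distribution** — samples resampled with replacement,
  re-closed, Spearman recomputed.
* **p-value** — both distributions are Fisher-z transformed and compared
  with the classical pooled-variance statistic for two equal-size samples,
  z = (m_boot − m_null) / √((v_boot + v_null)/2), two-sided normal tail.
  The additive pooling √(v_boot + v_null) was rejected during design: both
  variances estimate the sampling variance of ρ̂, so adding them inflates
  the denominator by √2 and makes the test conservative by a factor ~2.8 in
  rejection rate; the /2 form is calibrated (measured rejection 0.047 at
  α = 0.05 on an exchangeable Dirichlet-multinomial null with 120 OTUs).

Pairs involving a constant row get p = 1 and never become edges. Defaults:
n_iter = 1000 (≥ 100 enforced), seed mandatory. Edges are thresholded on
the *observed* ρ of the re-closed filtered table: positive if ρ > 0.6,
negative if ρ < −0.6, both conjunctive with p < 0.05; thresholds are strict
inequalities. No multiple-testing correction is applied to edges by
default (the network definition is a fixed ρ/p rule, not an inference
claim); a Benjamini–Hochberg screen can be applied downstream by the user
from the exported p matrix.

**Limitation.** The renormalization null reproduces the closure artifact
only to the extent that re-closed column sums fluctuate like the original
composition. When a single OTU holds an extreme share (≳ 90 %) with little
relative variance, the artifact in the observed data (driven by the
dominant taxon's absolute swings) exceeds what permutation can regenerate,
and residual false positives remain. The artifact-suppression test
therefore uses the moderate-dominance regime (dominant share ~40–60 %),
where the correction restores the nominal error rate (naive ≈ 0.57 vs
corrected ≈ 0.04–0.05 at α = 0.05).

## Markov-stability clustering

The positive subgraph (unweighted: one edge per surviving pair; a
|ρ|-weighted mode exists but is off by default) is clustered as a single
graph including all connected components; isolated nodes are excluded and
reported separately as "gray" OTUs. With adjacency A, degrees d, total
weight m and stationary distribution π = d/2m, the quality matrix is

* exponential mode: B(t) = ½[Π e^{−t(I − D⁻¹A)} + transpose] − ππᵀ,
* linearized mode: B(t) = (1−t)Π + t·A/(2m) − ππᵀ,

and a partition H scores R(t, H) = trace(Hᵀ B(t) H). The all-in-one
partition scores exactly 0 at any t; at t = 1 the linearized form equals
Newman–Girvan modularity (asserted to 1e−12 against networkx); at t = 0
singletons score 1 − Σπᵢ². Small t favors fine partitions, large t coarse
ones; disjoint components never merge (the cross-term is −2π_cπ_c' < 0).

Optimization is a generalized Louvain on B(t): greedy node moves (including
moves to a fresh singleton when every community has negative affinity)
followed by aggregation, repeated to convergence; best of n_restarts = 20
seeded random node orders. The scan covers 60 log-spaced times in
[10⁻², 10²] by default, exponential mode up to 2000 nodes and linearized
beyond (exponential requires a dense matrix exponential per time point).

**Plateau selection.** Among community counts k ≥ 3, the selected partition
is the midpoint of the longest contiguous run of grid points with identical
k whose partitions also agree pairwise within vi_tol = 0.05·ln n in
variation of information (VI = H₁ + H₂ − 2·MI, natural log) — the VI guard
rejects runs where k is constant but labels churn. Ties go to larger k,
then to the earlier Markov time (keyed on the time value, so the selection
is invariant to reversing the grid). The all-singletons partition (k = n)
is excluded from candidacy: it is the degenerate t → 0 limit, and the
length of its run measures how far the grid extends below the graph's
intrinsic time scale, not the stability of any community structure.

## Compartment-level analyses

**Core microbiome.** An OTU is core iff (a) it has count > 0 in at least 2
replicates of *every* design cell in scope, and (b) the standard deviation
of its relative abundance over all in-scope samples does not exceed its
mean. "Present" means count > 0 after subsampling; the sd screen uses all
samples in scope rather than per-cell values, implementing a single
low-variation criterion. Scopes: all six cells, or the three cells of one
depth. The reported fraction of reads is the members' share of the
evaluated table. A design cell with < 2 replicates is an error.

**Ternary coordinates.** Per OTU, the mean relative abundance over each
compartment's replicates is taken first and the three means are then
re-closed to sum 1 — so duplicating a replicate cannot move a point. OTUs
with total reads below min_abundance = 5 in scope, or absent from all three
compartments, are excluded.

**Cluster attribution.** A community's profile is the summed relative
abundance of its members ("community biomass", not membership counts),
averaged within each design cell and normalized across cells; the
attribution is the argmax cell, lexicographic-first on exact ties with a
tie flag. A complete-linkage dendrogram order of samples on the community ×
sample matrix is emitted alongside.

**Negative-correlation table.** For every ordered cluster pair (X, Y), the
OTUs of Y are ranked by their number of negative edges into X; nodes that
carry negative edges but no positive ones are labeled "unclustered". All
entries are reported; truncation ("most negatively correlated") is left to
the reader, since no principled cutoff exists.

## Synthetic data generator

`generate_dataset` emulates the *output* of an upstream amplicon pipeline
for this design — it does not simulate sequences, chimeras or error. One
seeded generator draws, per sample: expected abundances → Dirichlet (total
concentration `dirichlet_alpha · n_otus`, so `dirichlet_alpha` is the
symmetric-equivalent per-OTU concentration; 200 by default, a mild
overdispersion of the multinomial) → multinomial at a depth uniform in
[4500, 5000] reads, near typical subsampling minima.

Planted structure and default scales (in expected-reads units at these
depths):

* **Clusters** — 4 clusters × 12 OTUs, each assigned a home depth ×
  compartment cell (bulk-topsoil, bulk-subsoil, drilosphere-topsoil,
  rhizosphere-subsoil). Members sit at ~12 expected reads away from home
  and `effect_size` = 8× that in the home cell's 3 samples, and share a
  per-sample log-normal latent factor (σ = 0.8) plus member-specific jitter
  (σ = 0.3). The latent factor is what drives within-cluster Spearman ρ
  above the 0.6 edge threshold; the home-cell enrichment is what makes the
  clusters compartment-attributable and mutually negatively correlated.
* **Core** — 3 ubiquitous OTUs with constant expected abundance (~900
  reads each, jitter σ = 0.3). They deliberately hold most of the read
  mass: a realistic community needs abundant taxa, and concentrating that
  mass in a few *stable* OTUs keeps the sample denominators steady, so
  closure does not induce artificial co-occurrence among unrelated taxa.
* **Background** — the remaining ~250 OTUs form a rare tail (~1 expected
  read, jitter σ = 0.3, base spread σ = 0.4), sitting below the 6-read
  prevalence filter. This mirrors the real situation in which thousands of
  rare OTUs never reach the network stage; with hundreds of OTUs the
  closure bias of the null table is negligible.

Taxonomy is assigned round-robin over 10 synthetic genera with copy numbers
1–10 (every 7th OTU left unclassified at genus level to exercise the
nearest-classifiable-level fallback); qPCR totals are proportional to read
depth times a log-normal noise factor. The returned truth records roles,
cluster memberships, expected per-cell compositions and copy numbers.

Two auxiliary generators support calibration tests:
`exchangeable_null_table` (one shared composition, pure
Dirichlet-multinomial noise — the null for rejection-rate checks) and
`dominant_closed_table` (4 independent absolute-abundance processes, one
moderately dominant — the classic closure-artifact demonstration).

**What passing tests show — and don't.** Planted-cluster recovery (k = 4
selected, ARI ≥ 0.9 in ≥ 18/20 seeds at ReBoot n_iter = 500, linearized
mode, 60 time points, 20 restarts; ~1 min total on one CPU) demonstrates
that the pipeline's stages compose correctly and that the plateau rule
identifies a planted mesoscale. It does not demonstrate power on real
soils, where cluster signals are weaker, sample sizes identical (n = 18)
but effect structure far messier, and where OTU abundance distributions are
heavier-tailed than this generator's. Likewise the calibration result is
for exchangeable DM noise; real data violate exchangeability in ways the
permutation null only partially captures (see the dominance limitation
above). The hand-sized `worked_micro_example` (12 OTUs × 18 samples, equal
column sums of 120) has fully hand-checkable filter, core and rarefaction
outcomes.

## Numerical and reproducibility choices

* Fisher-z values are clipped at |ρ| = 1 − 10⁻⁷ before arctanh; p-values
  are floored at the smallest positive float and NaN statistics map to
  p = 1.
* Louvain move gains use a 10⁻¹² tolerance; best-of-restarts ties keep the
  earlier restart. All Louvain/scan randomness derives from
  `SeedSequence((seed, time_index, restart))`.
* Every source of randomness in the pipeline (subsampling, ReBoot,
  restarts, PerMANOVA) takes an explicit seed from the run configuration;
  a config with a missing seed fails validation before any computation, and
  two runs of one config write byte-identical numeric artifacts (floats
  serialized with `%.10g`).
* Degenerate inputs are handled explicitly: all-zero samples stay zero with
  a warning; constant OTUs have undefined ρ (never edges, p = 1); empty
  graphs and cells with < 2 replicates raise; the prevalence filter may
  return an empty table.

## Known limitations

* The ReBoot correction under-corrects in extreme single-taxon dominance
  (see above); archaeal-like tables dominated by one genus should be
  interpreted with that in mind.
* PerMANOVA offers no restricted/stratified permutation schemes.
* The exponential stability mode computes a dense matrix exponential per
  time point; above ~2000 network nodes the linearized mode is used.
* Rarefaction-free normalizations (CSS/TMM) and variance-stabilizing
  transforms are out of scope, as are richness estimators (Chao1/ACE),
  SparCC/SPIEC-EASI-style alternatives to the correlation network, and
  indicator-species statistics.
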