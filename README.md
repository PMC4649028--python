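# soilnet

Compartment-resolved co-occurrence analysis of soil microbial communities
from OTU count tables.

Soil is not homogeneous: nutrient-rich hotspots — the **rhizosphere** (soil
adhering to roots) and the **drilosphere** (the ~1 mm lining of earthworm
burrows) — host different prokaryotic communities than the surrounding bulk
soil, in both topsoil and subsoil. `soilnet` implements the statistical
pipeline for detecting this spatial structure from 16S rRNA gene amplicon
data in a 2 depths × 3 compartments × replicated-plot design:

1. **Preprocessing** — subsampling all samples to equal depth (multivariate
   hypergeometric, i.e. without replacement), a prevalence filter (≥ 6 reads
   in ≥ 3 samples) for the network stage, relative abundance and Hellinger
   transforms, 16S copy-number adjustment against an rrnDB-style lookup
   (reads divided by mean copies per genome of the nearest classifiable
   taxon), and the matching correction of qPCR totals.
2. **Compositionality-corrected co-occurrence network** — pairwise Spearman
   ρ between OTUs, with two-sided p-values from a permutation-renormalization
   null (ReBoot/CCREPE-style): each OTU's counts are permuted across samples
   and every sample re-closed to proportions, which preserves the spurious
   correlation that closure (relative abundances summing to 1) induces while
   destroying real association. The Fisher-z means of this null and of a
   sample bootstrap are compared with a pooled-variance normal statistic.
   Edges require ρ > 0.6 (or < −0.6 for negative edges) **and** p < 0.05.
3. **Markov-stability clustering** — the positive subgraph is partitioned by
   maximizing R(t, H) = trace(Hᵀ B(t) H), where B(t) is the Markov-stability
   quality matrix of an unbiased random walk at Markov time t (full
   matrix-exponential or linearized mode; at t = 1 the linearized form is
   exactly Newman–Girvan modularity). A generalized Louvain optimizer scans
   a logarithmic grid of times, and the community number k > 2 with the
   longest plateau of stable assignments (variation of information within
   tolerance) is selected.
4. **Compartment biology** — the soil-intrinsic **core microbiome** (OTUs
   present in ≥ 2 of 3 replicates of every depth × compartment cell whose
   relative-abundance s.d. does not exceed its mean), cluster-to-compartment
   attribution, ternary (bulk/drilosphere/rhizosphere) coordinates,
   Venn-style shared-OTU counts, and a table of negative correlations
   between clusters. Supporting statistics: richness, analytic
   (hypergeometric) rarefaction, Shannon diversity, per-OTU ANOVA with
   Tukey HSD and Bonferroni adjustment, and PerMANOVA on Hellinger
   distances.
5. **Synthetic data** — a Dirichlet-multinomial generator that emulates the
   study design (18 samples, planted compartment-linked clusters of
   co-occurring OTUs, a ubiquitous low-variability core, a rare background
   tail, per-genus copy numbers, qPCR totals) with full ground truth, so the
   entire pipeline is testable without sequence data.

Input formats: mothur `.shared` / `.cons.taxonomy` files or plain TSV,
a sample-metadata TSV (`sample_id, depth, compartment, replicate`), a
copy-number TSV (`rank, name, mean_copies`), and optional per-sample qPCR
totals. Networks export as edge-list TSV and GraphML.

## Worked example

Simulate the default design and run the full pipeline (library API; the
equivalent CLI is `soilnet run -c config.yaml`):

```python
from soilnet.pipeline import RunConfig, run_pipeline

cfg = RunConfig.from_dict({
    "output_dir": "run1",
    "simulate": {"seed": 4},                      # synthetic default design
    "preprocess": {"seed": 1},                    # subsample to min depth
    "network": {"seed": 2, "n_iter": 300},        # ReBoot iterations
    "stability": {"seed": 3, "mode": "linearized",
                  "n_restarts": 10, "n_times": 30},
    "permanova_seed": 4, "permanova_n_perm": 99,
})
outdir = run_pipeline(cfg)
print((outdir / "summary.json").read_text())
```

prints

```json
{
  "core_fraction_of_reads": 0.8123309232206974,
  "core_size": 21,
  "n_gray_otus": 3,
  "n_negative_edges": 12,
  "n_otus_networked": 51,
  "n_otus_subsampled": 300,
  "n_positive_edges": 254,
  "selected_k": 4
}
```

Of 300 simulated OTUs, 51 pass the ≥6-reads-in-≥3-samples filter; the
corrected network has 254 positive and 12 negative edges, 3 OTUs have no
positive correlation (they stay unclustered, "gray"), and the Markov-time
plateau selects k = 4 clusters — the four planted ones. `attribution.tsv`
assigns each cluster to its home cell; for this run the four clusters map to
`topsoil:bulk`, `subsoil:bulk`, `topsoil:drilosphere` and
`subsoil:rhizosphere` with 51–61 % of each cluster's relative-abundance
profile in its home cell. `permanova.tsv` shows the compartment effect
(pseudo-F = 1.99, p = 0.01 at 99 permutations) and the weaker depth effect
on this draw. The reported core covers 81 % of reads because the default
design concentrates read mass in a few stable core OTUs.

Every stage writes its artifacts (`subsampled.tsv`, `filtered.tsv`,
`rho.tsv`, `pvalues.tsv`, `edges.tsv`, `network.graphml`,
`stability_scan.tsv`, `membership.tsv`, `core_*.tsv`, `ternary_*.tsv`,
`negative_correlations.tsv`, …) into the run directory; reruns with the same
config are byte-identical.

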