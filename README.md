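# dielnet

Comparative diel transcriptomics for two species: detect genes whose
expression tracks the 24-hour day/night cycle, cluster their temporal
profiles, infer mutual-information co-expression networks, and find the gene
families whose network connectivity differs most between the species.

The package targets the study design of a two-species diel RNA-seq
experiment — for example a CAM plant against a C3 relative — sampled every
4 h across a 12:12 photoperiod with 4 replicates per time point (24 samples
per species), with genes grouped into orthogroups (cross-species gene
families). It is aimed at plant physiologists and systems biologists who want
the full analysis chain as tested, scriptable Python, plus a synthetic-data
generator with planted ground truth so every stage can be validated before it
touches real data.

## The methods

1. **Time-structured gene detection.** Each gene's profile over zeitgeber
   time *t* is fit with a negative-binomial GLM (log link) on a polynomial
   basis up to degree 4, with per-gene dispersion θ estimated by profile
   maximum likelihood. Time structure is tested by an F-type analysis of
   deviance of the degree-4 model against the intercept-only model;
   Benjamini-Hochberg correction is applied across genes, and genes whose fit
   hinges on single observations (exact leave-one-out |DFBETAS| above the
   influence cutoff) are removed. Forward stepwise F tests report each gene's
   selected polynomial terms.
2. **Fuzzy clustering.** Z-scored profiles of the significant genes are
   clustered by fuzzy c-means with the data-driven fuzzifier
   m(D, N) = 1 + (1418/N + 22.05)·D⁻² + (12.33/N + 0.243)·D^(−0.0406 ln N − 0.1134),
   k chosen at the elbow of the within-group variance curve; clusters are
   labeled day- or night-biased from their median profile over the dark
   samples.
3. **MI network inference.** Pairwise mutual information by adaptive
   partitioning of the rank-transformed joint distribution; a permutation-null
   MI threshold (generalized-Pareto tail fit at p = 10⁻⁸); removal of the
   weakest edge of every triangle (data processing inequality); and a
   consensus over bootstrap resamples keeping edges whose support beats a
   Bonferroni-corrected Poisson test.
4. **Cross-species comparison.** Per-orthogroup mean degree in each species'
   network, standardized to Z-scores and subtracted (z_diff = z_B − z_A);
   orthogroups outside the Tukey fences (Q1/Q3 ∓ 1.5·IQR) are the
   differential-connectivity outliers. Focal subnetworks spread unit heat
   from a seed gene by the Laplacian heat kernel exp(−Lt) and keep the
   hottest 10% of nodes; subnetwork contents and GO annotations are compared
   by exact hypergeometric tests with BH correction.

## Worked example

```
$ dielnet pipeline demo --seed 1 --outdir demo
```

simulates a two-species dataset (500 genes/species, 24 samples each) and runs
every stage. The manifest it prints includes, for this seed:

```
"timecourse_speciesA": { "n_tested": 500, "n_significant": 170 },
"cluster_speciesA":    { "k": 5, "m": 1.1662, "n_night": 2 },
"network_speciesA":    { "n_nodes": 82, "n_edges": 236, "mean_degree": 5.756 },
"compare":             { "n_shared": 89, "n_outliers": 6 },
"overlap":             { "shared": 4, "n_a": 7, "n_b": 6, "p": 0.9999970246442813 }
```

Reading it: of 500 simulated genes, 170 were significantly time-structured
in species A (200 were planted; the rest fall below the 5% FDR); their
Z-profiles grouped into k = 5 clusters at fuzzifier m ≈ 1.17; the
25-bootstrap consensus MI network connects 82 genes with 236 edges; 89
orthogroups are comparable between the species' networks and 6 are called
differential-connectivity outliers; the two focal diffusion subnetworks
share 4 orthogroups, not significantly fewer than chance (hypergeometric
p ≈ 1). Rerunning with the same seed reproduces every output
byte for byte. The same stages are available as library calls
(`dielnet.timecourse.TimeCourseDetector`, `dielnet.clustering.FuzzyCMeans`,
`dielnet.network.MutualInfoNetwork`, `dielnet.compare`) and as individual CLI
subcommands (`simulate`, `preprocess`, `timecourse`, `cluster`, `network`,
`compare`, `diffuse`, `enrich`).

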