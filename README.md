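# ecoassembly

Phylogenetic null-model partitioning of microbial community assembly, plus
co-occurrence networks, diversity metrics and permutation statistics, for
OTU tables from amplicon surveys — built around the mesocosm warming-
experiment design (18 outdoor tanks under ambient, +4 °C constant-warming
and ±4 °C heatwave scenarios, sampled over four seasons in water and
sediment).

## Who this is for

Microbial ecologists who have an OTU abundance table (samples × OTUs), a
rooted phylogeny of the OTUs, and sample metadata, and who want to answer:
*is community turnover driven by deterministic selection or by stochastic
processes (dispersal and drift), and how are taxa organised into
co-occurrence networks?*

## The statistics at the core

**βMNTD / βNTI.** For communities *k* and *m* with relative abundances
*p*, the between-community mean nearest taxon distance is

    βMNTD(k, m) = ½ [ Σᵢ pᵢₖ · minⱼ d(i, j∈m)  +  Σⱼ pⱼₘ · minᵢ d(j, i∈k) ]

where *d* is patristic distance. βNTI is the z-score of the observed βMNTD
against a null distribution obtained by shuffling taxon labels across the
distance matrix (999 shuffles by default):

    βNTI = (βMNTD_obs − mean(βMNTD_null)) / sd(βMNTD_null)

|βNTI| > 2 indicates deterministic turnover — variable selection (> +2) or
homogeneous selection (< −2). The within-community analogues MNTD and NTI
(= −z of MNTD) measure phylogenetic clustering per sample.

**RC_bray.** For pairs not dominated by selection, the Bray–Curtis-based
Raup–Crick statistic compares observed dissimilarity against pairs of
null communities that preserve each sample's richness and total abundance
(membership drawn ∝ occurrence frequency, individuals ∝ total relative
abundance):

    RC_bray = 2 · [ #(BC_null < BC_obs) + ½·#(ties) ] / n_null − 1

**Five-process classification** (strict inequalities, selection first):
βNTI > +2 → variable selection; βNTI < −2 → homogeneous selection; else
RC_bray > +0.95 → dispersal limitation; RC_bray < −0.95 → homogenizing
dispersal; otherwise drift (undominated).

**Networks.** Per sample group, OTUs with > 0.1 % total relative abundance
enter pairwise Spearman correlation; edges need |r| > 0.6 and
Benjamini–Hochberg-adjusted p < 0.05 across all tested pairs. The topology
panel reports nodes, edges, average degree, transitivity, mean local
clustering, average path length, diameter (largest component), greedy
modularity, density and the percentage of positive edges.

A synthetic-community module generates all of the above inputs under known
assembly regimes (selection, drift, dispersal limitation, homogenizing
dispersal) and a full mesocosm design with seasonal, treatment-linked
environmental covariates — so every stage can be validated against ground
truth.

## Worked example

Generate a 12-sample community assembled under temperature-like selection
(three optimum groups), then recover the process from the table + tree
alone:

```python
from ecoassembly import (beta_nti, raup_crick_bray, partition_processes,
                         regime_fixture)
from ecoassembly.io import patristic_distances

table, tree = regime_fixture("selection", seed=42)   # 12 samples, 200 OTUs
D = patristic_distances(tree, table.otu_ids)
bnti = beta_nti(table, D=D, n_null=999, seed=1)
rc = raup_crick_bray(table, n_null=999, seed=2)
part = partition_processes(bnti, rc)
print(part.proportions.to_string(index=False))
```

prints

```
group                process  proportion  n_pairs
  all     variable_selection    0.727273       66
  all  homogeneous_selection    0.015152       66
  all   dispersal_limitation    0.000000       66
  all homogenizing_dispersal    0.257576       66
  all                  drift    0.000000       66
```

74 % of the 66 sample pairs are classified as selection (|βNTI| > 2): the
between-optimum pairs are variable selection, as the generator intended,
while most same-optimum pairs — compositionally near-identical — fall into
the homogenizing-dispersal bin, the expected signature of convergent
communities under this framework.

The same pipeline runs end to end from the shell:

```sh
ecoassembly fixture --outdir fixture/ --seed 1        # mesocosm dataset
ecoassembly run --table fixture/otu_table.tsv --tree fixture/tree.nwk \
    --metadata fixture/metadata.csv --outdir report/ --seed 1
```

which writes per-sample alpha diversity, Bray–Curtis matrices, PERMANOVA
tables, network exports (CSV + GraphML) with the topology panel, per-sample
NTI, βNTI/RC_bray matrices, process proportions per
habitat × treatment × season group, and Mantel correlations of βNTI against
every environmental covariate, plus a manifest that reproduces the run bit
for bit.

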