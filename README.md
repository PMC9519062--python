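# seasonscan

Seasonal partitioning of plankton community time series by cumulative
indicator-value maximisation.

## The problem

In seasonally ice-covered lakes, the bacterioplankton community contains
taxa that bloom in particular seasonal/spatial windows and taxa whose
abundance barely moves all year. Imposing calendar seasons on such data
begs the question; instead, the "seasons" should emerge from the community
itself. `seasonscan` implements that emergent-partition analysis for OTU
count tables from depth-resolved time series: it finds the sample
partition best supported by indicator taxa, separates the seasonal
indicators from the stable core and sporadic background, compares
cluster diversity, and characterises the environmental conditions each
cluster occupies. It is aimed at microbial ecologists working with
amplicon surveys of stratified lakes (or any repeated-measures community
table with suspected habitat states).

## The method

Counts are rarefied to a common depth (sampling without replacement) and
Hellinger-transformed, `y = sqrt(x / x_+)`, so Euclidean geometry on the
transformed profiles equals the Hellinger distance between raw profiles.
For each k in a scan range, samples are clustered by k-means in Hellinger
space. For every taxon *t* and cluster *c* the indicator value combines

- specificity `A(t,c)` = mean abundance of *t* in *c* / Σ over clusters of
  its mean abundances, and
- fidelity `B(t,c)` = fraction of samples of *c* in which *t* occurs,

as `IndVal = sqrt(A·B)` (group-equalised default; the classic `A·B`
product is available). Only the per-taxon maximum over clusters is
tested: its null distribution comes from random reallocation of samples
among clusters (999 permutations by default, shared across taxa), with
Benjamini–Hochberg FDR control at 5% across taxa. The selected partition
is the k whose **sum of significant taxa's IndVal** is highest — the
partition the indicator structure itself supports best.

Downstream, taxa are classified as seasonal indicators (significant),
stable core (non-significant, occurrence ≥ 80%), or sporadic
(non-significant, occurrence < 10%); per-sample diversity is the
exponential Shannon entropy `D = exp(H)` (Hill number of order 1),
compared across clusters by one-way ANOVA with Tukey HSD; and the cluster
environments are characterised by Fisher linear discriminant analysis of
the chemistry table (all variables retained, everything except pH and
stoichiometric ratios log-transformed).

Because real surveys of this design are rarely public, the package ships
a synthetic lake-survey generator (`seasonscan.synthetic`) with planted
"resistant", "ice-on-resilient", "ice-off-resilient", deep-specialist and
sporadic taxa over a six-state habitat template (70 samples: 14 four-weekly
dates × 5 depths), Dirichlet-multinomial counts, and ground-truth labels
for every taxon and sample.

## Worked example

```bash
seasonscan simulate --seed 1 --out demo
seasonscan run --otu demo/otu.tsv --metadata demo/samples.tsv \
    --env demo/env.tsv --out demo/out --seed 1
```

prints the scan trajectory and the result:

```
INFO seasonscan.partition: scan k=2: 54 significant taxa, cum IndVal 45.183
INFO seasonscan.partition: scan k=5: 111 significant taxa, cum IndVal 75.241
INFO seasonscan.partition: scan k=6: 119 significant taxa, cum IndVal 78.462
INFO seasonscan.partition: scan k=7: 106 significant taxa, cum IndVal 66.465
best_k = 6; 119 significant taxa; artifacts in demo/out
```

The cumulative IndVal rises from k = 2, peaks at the six planted habitat
states, and falls once clusters split real states. `demo/out/summary.json`
holds the headline numbers — for this seed, 119 of 191 retained taxa are
significant indicators (76% of reads per sample on average), the recovered
clusters match the planted states, cluster sizes are 31/13/10/6/6/4, and
indicator taxa are more diverse (median D ≈ 62) than the non-seasonal
background (median D ≈ 35). Per-stage artifacts (`scan.tsv`, `indval.tsv`,
`typology.tsv`, `diversity.tsv`, `lda_scores.tsv`, ...) are plain TSV.

The same analysis is available as a library:

```python
from seasonscan import (SyntheticConfig, generate_community, filter_min_count,
                        rarefy, scan_partitions)

table, samples, env, truth = generate_community(SyntheticConfig(), seed=1)
rt = rarefy(filter_min_count(table, min_reads=5), seed=2)
scan = scan_partitions(rt, n_perm=999, seed=3)
print(scan.best_k, scan.to_frame())
```

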