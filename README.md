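# coexnet

Seed-gene co-expression screening across paired expression datasets, with
cross-dataset candidate intersection, direction-concordance checking, and
size-capped interaction-network construction scored by right-tailed Fisher's
exact tests.

## The problem

A recurring discovery pattern in systems biology: given one gene of interest
(the *seed* — e.g. the kinase GSK3β in lung epithelial cells), find putative
upstream regulators by (1) correlating every transcript with the seed in two
*independent* expression cohorts, (2) keeping only transcripts that pass a
fixed absolute-correlation threshold in **both** cohorts with the **same
sign** of correlation, and (3) connecting those candidates over a gene–gene
interaction knowledge base into small, densely interconnected networks whose
central hub is the regulator candidate (e.g. the RNA-binding protein
ELAVL-1/HuR). `coexnet` implements that pipeline as a reusable, tested
library plus CLI, with an open TSV edge list replacing proprietary
interaction databases.

## Method

**Screen.** Within each dataset, every non-seed feature *g* is scored by the
Pearson correlation `r_g = cov(x_g, x_seed) / (sd(x_g) · sd(x_seed))` over
pairwise-complete samples; *g* passes when `|r_g| > τ` (default `τ = 0.55`,
strict) with at least `min_pairs` complete pairs. Two-sided p-values use the
transform `t = r·√((n−2)/(1−r²)) ~ t(n−2)`; a seeded permutation p-value
`(1 + #{|r_perm| ≥ |r_obs|}) / (1 + B)` is available as a
distribution-free check.

**Intersect.** Candidates are features (or gene symbols, for cross-platform
runs) passing in both screens. Each candidate carries per-dataset `r` and
`p`, a concordance flag (`r₁·r₂ > 0`), and a rank score (the weaker of the
two `|r|` by default). The union identity
`union = passing₁ + passing₂ − intersection` is asserted on every run.

**Network.** Candidates become *focus genes*. Greedy growth seeds each
network with the unassigned focus gene best connected to other unassigned
focus genes, then repeatedly adds the gene (focus preferred, then most edges
added, then lexicographic) contributing at least one edge, up to a 35-node
cap. Each network is the induced evidence subgraph on its nodes and is
scored by a right-tailed Fisher's exact test on the 2×2 table of focus
membership × network membership over the evidence gene universe
(`score = −log₁₀ p`, computed in log space). Hubs rank by degree, then
betweenness, then name.

**Synthetic truth.** A single-latent-factor generator plants a co-expression
module (seed + hub + module genes; gene value `= sign·β·z + N(0, σ²)`,
background `N(0,1)`) in two independent cohorts of 166 and 76 samples, plus
a hub-star evidence list — so recovery, concordance, and hub identification
are measurable against known ground truth. Two module genes with loadings β
have population correlation `r = sign_g·sign_h·β_g·β_h /
√((β_g²+σ²)(β_h²+σ²))`.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (writing small tables to `results/` and bulky matrices to `scratch/`):

```bash
python analysis/01_simulate_cohorts.py
python analysis/02_screen_correlates.py
python analysis/03_intersect_candidates.py
python analysis/04_build_networks.py
python analysis/05_operating_point.py
```

prints

```
planted module of 21 genes (|r| to seed = 0.80) among 5000 background genes; ...
ds1: 21 of 5021 genes pass |r| > 0.55 against GSK3B (n = 166 samples)
ds2: 21 of 5021 genes pass |r| > 0.55 against GSK3B (n = 76 samples)
21 candidates common to both cohorts out of 21 total correlates (21 + 21
  passing per cohort); direction concordance 1.000 (0 discordant)
1 networks built from 21 focus genes; best network: 35 nodes (21 focus),
  score 48.6 (-log10 Fisher p), hub ELAVL1 with degree 20
population |r| = 0.30: mean module recall 0.48% at n = 76
population |r| = 0.80: mean module recall 100.00% at n = 76
```

i.e. every planted module gene — and no background gene — survives both
screens with fully concordant signs; the planted regulator ELAVL1 emerges as
the top-degree hub of the best-scoring network; and the same module at
population |r| = 0.3 is invisible to the 0.55 threshold in the 76-sample
cohort, showing the screen's operating point.

The same pipeline runs from the command line on any pair of expression
matrices (plain TSV or GEO Series Matrix format):

```bash
coexnet simulate --out bundle/
coexnet run --config run.yaml          # ingest → screen ×2 → meta → network
coexnet screen --expression ds1.tsv --annotation ann.tsv --seed GSK3B --out s1.tsv
```

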