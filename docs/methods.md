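# Methods

## Scope and model

`coexnet` reconstructs an in-silico regulator-discovery procedure: a
seed-gene Pearson screen run independently in two expression cohorts, the
intersection of the thresholded hit lists with a sign-concordance check, and
greedy construction of small interaction networks from the surviving
candidates, scored by focus-gene enrichment. The package treats the three
stages as separable library modules (`screen`, `meta`, `netbuild`) over a
thin ingest layer, with a planted-module simulator (`synthetic`) supplying
ground truth for every stage.

## Correlation screen

Correlations are Pearson product-moment coefficients over pairwise-complete
observations. A feature's record is *undefined* (r = NaN, never passing)
when fewer than `min_pairs` complete pairs exist (default 10, floor 3) or
when either vector is constant on the complete pairs; undefined records do
not abort a screen, since flat probes are routine in microarray data. The
pass rule is strict: `|r| > τ`, default τ = 0.55, so a boundary correlation
of exactly τ fails. The threshold acts on r, not on adjusted p; no
multiple-testing correction is applied, by design — the cross-dataset
intersection is the false-positive control.

Analytic p-values use `t = r·√((n−2)/(1−r²))` against Student's t with n−2
degrees of freedom, two-sided, clamped to the smallest positive float at
r = ±1. This transform is an assumption of the package (the procedure it
reimplements reports p-values without a formula). The permutation
alternative permutes one vector over the complete pairs B ≥ 99 times with a
seeded generator and applies the add-one correction
`p = (1 + #{|r_perm| ≥ |r_obs|})/(1 + B)`, which keeps p in (0, 1] and is
exactly uniform on its support under the null; the comparison uses a 1e-15
slack so ties at machine precision count as exceedances.

When the seed is given as a gene symbol with several probes, the
highest-variance probe represents it (ties: lexicographically smallest id) —
a deterministic rule chosen over alias resolution or probe averaging.

## Intersection and concordance

Matching is at feature (probeset) level by default, appropriate when both
cohorts share a platform, or at symbol level, where a symbol passes if any
of its probes passes and the max-|r| probe represents it (ties by probe id).
A candidate is concordant when `r₁·r₂ > 0`. Discordant candidates are
flagged, not dropped. The concordance fraction is undefined on an empty set:
the property returns the 1.0 convention but carries a `concordance_defined`
flag, and `concordance_report` raises instead of reporting silently.
Candidates rank by `min(|r₁|, |r₂|)` by default (the weaker cohort bounds
the evidence); `mean_abs_r` is available. Union counts always satisfy
`union = passing₁ + passing₂ − intersection`, asserted at run time.

## Network construction and scoring

The growth algorithm is a documented greedy interpretation of a one-sentence
commercial description ("maximize interconnectivity within a size cap");
exact reproduction of that proprietary tool is explicitly not claimed, and
evidence comes from a user-supplied TSV/SIF edge list rather than a
proprietary knowledge base. Edges are undirected, deduplicated with `direct`
winning over `indirect`, self-loops dropped with a warning; both relation
types count equally in growth and scoring (the distinction is retained for
display only). Greedy details, all deterministic without seeds:

- seed each network with the unassigned focus gene having most evidence
  edges to other unassigned focus genes (tie: lexicographic);
- repeatedly admit the neighbor adding ≥ 1 edge to the current node set,
  preferring focus genes over connectors, then more edges added, then
  lexicographic order; stop at `max_nodes` (default 35) or when nothing
  qualifies;
- a network's edge set is the evidence subgraph induced on its nodes; focus
  genes join exactly one network, connectors may recur; focus genes with no
  evidence edges are reported as singletons, not networked.

Scoring uses a right-tailed Fisher's exact test on the table (a = focus in
network, b = connectors in network, c = remaining focus, d = remaining
background), background defaulting to the number of distinct genes in the
evidence (overridable for genome-scale universes). The hypergeometric tail
is summed in log space via log-binomials (`gammaln`) and `logsumexp`, so
`score = −log₁₀ p` stays finite far below float underflow; the linear-scale
`fisher_p` is clamped into (0, 1]. Hubs rank by within-network degree, then
exact betweenness centrality, then name.

## Synthetic data generator

The generator emulates the study design the pipeline targets — two
independent cohorts whose sizes default to 166 and 76 samples (the sizes of
the two lung cancer cell-line cohorts that motivated the method) sharing one
latent-factor module — with the minimal structure that produces the
phenomenon of interest: a transcript set correlated to the seed in both
cohorts with fully concordant signs, and a star-shaped interaction
neighborhood around a hub regulator.

Per sample, a latent `z ~ N(0,1)` is drawn; module gene g takes
`sign_g·β_g·z + N(0, σ²)` and background genes are iid `N(0,1)`. The
population correlation between module genes is then
`r = sign_g·sign_h·β_g·β_h / √((β_g²+σ²)(β_h²+σ²))`, so
`β = σ·√(r/(1−r))` places the module exactly at a chosen |r|. Defaults: a
20-gene module plus seed (GSK3B) and hub (ELAVL1), equal loadings at
population |r| = 0.8 with σ = 1, five members with negative sign (to
exercise sign-concordance logic and negative-correlation display), 5000
background genes, background evidence edges Erdős–Rényi at p = 0.001.
Streams are split per (rng_seed, stream label) through numpy's seed-sequence
mechanism, making every artifact byte-reproducible.

What the generator does **not** emulate: probe effects, batch effects,
intensity-dependent variance, heavy-tailed expression, correlated background
structure, or probe-to-gene multiplicity. Passing recovery tests therefore
demonstrates the pipeline's correctness and its power behavior around the
threshold under clean single-factor co-expression — not robustness to
microarray artifacts.

## Numerical and design choices

- Missing-value tokens on ingest: "null", "NA", "NaN", "" (case-insensitive),
  the permissive union of GEO Series Matrix and plain-TSV dialects.
- Values are assumed log-scale; `log2(x+1)` is opt-in and errors on negative
  inputs. No auto-detection — silent transforms would corrupt the screen.
- Gene symbols are uppercased at load; matching is case-insensitive exact
  string equality, no alias dictionaries (deterministic by construction).
- All orderings (passing lists, candidate tables, network elements) are
  fully specified (magnitude desc, then lexicographic), so repeated runs are
  byte-identical; only the simulator consumes random seeds.
- Pearson r is clipped to [−1, 1] after computation to absorb rounding.

## Problem sizes used in tests and the acceptance script

Replicated experiments use the default study conditions (5022 genes ×
166/76 samples) with 20 replicates for recovery and hub identification and
10–20 for the weak-module operating-point check; the Fisher implementation
is verified against exact integer enumeration over all 2×2 tables with
margins ≤ 30 (~164k tables), and permutation calibration uses 500 null
replicates at n = 50, B = 200. These sizes give stable statistics (binomial
noise on a 20-replicate rate is ~±10 points; the recovery and hub rates sit
at 100%) while a full run stays around half a minute.

## Known limitations

- The greedy network growth is a plausible, documented stand-in for an
  unpublished commercial algorithm; on dense evidence graphs different
  admission orders could partition focus genes differently.
- The enrichment background treats the evidence gene universe as the
  eligible population; a genome-scale background inflates scores and should
  be set explicitly when the evidence file is sparse.
- Symbol-level matching collapses probes by max |r| and ignores aliases;
  cross-platform runs with divergent symbol vocabularies will under-match.
- Analytic p-values assume bivariate normality; for heavy-tailed data use
  `p_method: permutation`.
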