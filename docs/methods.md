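# Methods notes

## Compositional-bias model

The N/Q-rich prion-like (NQP) detector is a lowest-probability-
subsequence (LPS) scan. Given a success-residue set *S* and a background
composition *f*, the success probability is p = Σ_{a∈S} f(a) and a
region of length n with k successes is scored by the exact binomial
upper tail P(X ≥ k | n, p), evaluated by log-space summation of the
individual terms (`log_binomial_tail`), so scores far below double
underflow remain ordered.

The search is exact without enumerating substrings: at fixed length the
tail is strictly decreasing in the count, so only the maximal-count
window of each length can be the global minimizer. Scanning the best
window per length (sliding-window maxima over prefix sums) therefore
equals the exhaustive O(L²) all-substrings scan — the test suite checks
this identity against the brute-force oracle on 100 random sequences.
Ties are broken by lower P, then greater length, then smaller start,
which makes output deterministic; tied or underflowed float tails are
re-ranked in log space.

Classification evaluates the candidate sets {N}, {Q}, {N,Q} and each of
their unions with a single subsidiary residue (Y, S or G). Thresholds:

| parameter | default | meaning |
|---|---|---|
| `main_p` | 1e−10 | best region's binomial tail must not exceed this |
| `subsidiary_p` | 1e−4 | a subsidiary residue joins a candidate set only if its own within-region bias is below this |
| `exclusion_p` | 1e−4 | any charged (D,E,R,K) or major hydrophobic (V,I,L,M) within-region bias below this disqualifies |
| `min_region_length` | 20 | prion-like domains span tens of residues; prevents trivially short hits |

The subsidiary and exclusion biases are evaluated *within the winning
region* (a flanking bias elsewhere in the protein is irrelevant to the
domain call); whether the original heuristic evaluated overlapping
rather than strictly nested subsidiary regions is not recoverable, so
within-region was adopted. The background composition defaults to the
supplied proteome's aggregate residue frequencies — the standard choice
for compositional-bias statistics — with a uniform 1/20 background
available. Only the single minimal-P region per protein decides
classification; merging multiple disjoint biased regions is not
attempted.

## Interaction-level enrichment and its null behaviour

For sample set S and target set T over N unique undirected interactions:
K = interactions involving a T member, n = interactions involving an S
member, and k = interactions of the S list whose *partner* endpoint is a
T member — so an interaction internal to both sets counts once in each
of K, n and k, and when S = T, k counts internal interactions. This is
the convention that reproduces the published table structure (its
diagonal prion-like cell counts 251 internal interactions out of 4405).
P-values are one-tailed exact hypergeometric tails, the reported
direction being the side of the expectation nK/N the observed k falls
on; the correction family is every test executed in a run
(Holm–Bonferroni step-down).

**Known structural limitation.** The hypergeometric model treats the
sample's n interactions as an exchangeable draw from the N interactions,
of which K are "successes". In any edge-random graph this overstates the
null overlap roughly two-fold for small sets: K/N ≈ 2b (either endpoint
may hit T, b the per-endpoint probability), while for an interaction
already conditioned to involve S only the partner endpoint is free, so
the true null success rate is ≈ b. The test is therefore structurally
biased toward depletion under a uniform random-graph null: null
p-values are far from uniform and the family-wise error of Holm over 72
such tests was measured at 0.19 rather than ≤ 0.05. Two acceptance
tests document this by failing under the published convention and
passing under an oriented per-endpoint counting variant
(`convention="endpoint"`: population = 2N oriented endpoint slots,
n = slots with an S tail, k = S tails with a T partner), which is
calibrated under the same null. The per-interaction convention remains
the default because it is the published method and reproduces the
printed totals; results of depletion cells should be interpreted with
the ~2× structural handicap in mind — strong printed depletions (such
as the prion-like↔prion-like diagonal) may be partly or wholly
structural, and printed enrichments are, if anything, understated.

## Verifying the printed contingency cells

Every reference cell's P-value is recomputed from its printed
(N, K, n, k) and compared under a factor-of-two rule (printed values
carry 1–2 significant figures and the underlying snapshot counts may
differ marginally). All enrichment-direction cells agree (ratios
0.91–1.53), and the bounded diagonal claim recomputes to 1.6e−51,
far below its 1e−30 bound. Four depletion cells do not: under the
inclusive lower tail P(X ≤ k) they recompute 2.4–5.1× above print,
while three of the four instead match P(X ≤ k−1) to within 10% and the
remaining one (the prion-like × highly-disordered cell, printed 1e−20,
recomputed 5.1e−20 inclusive / 2.5e−20 exclusive) matches neither; a
k = 0 hub cell conversely matches only the inclusive tail. The printed
depletion values therefore mix tail conventions. This package uses the
inclusive tails P(X ≥ k) / P(X ≤ k) throughout (the standard definition,
and the one whose two tails satisfy P(X ≥ k) + P(X ≤ k−1) = 1); the
verification table reports the four out-of-tolerance rows honestly and a
regression test pins that set so it can never silently grow.

## GO analysis

The ontology is restricted to the biological_process namespace;
ancestry follows is_a and (by default) part_of edges; annotations are
propagated to all ancestors before any counting — propagation is the
GO-standard choice and is required for the nested-term collapse rule to
be exercisable at all. NOT-qualified GAF rows are dropped; terms
annotating fewer than 2 universe proteins are skipped as uninformative
(a fraction-1 singleton would otherwise dominate high-membership
ranking). The high-membership collapse applies the published rule
literally: a less specific term is dropped only when a nested more
specific term is driven by the identical member list *and* has a
strictly lower P-value — with propagated annotations the specific
term's P is never higher at an identical member list, so equality keeps
both. The interaction flavour counts deduplicated protein↔term pairs;
its correction family is all terms tested for the sample set.

## Monte-Carlo disorder test

Samples are drawn without replacement within a sample (a protein
appears once, as in the real set being mimicked) and independently
across samples. The final fractional protein's disorder is prorated
(fraction × disordered count) rather than positionally truncated:
proration is unbiased in expectation and independent of where disorder
sits in the sequence; an N-terminal-prefix mode exists for per-residue
tracks. "Greater disorder" is strict inequality. Default 10 000
samples. For a randomly drawn protein set the exceedance fraction is
approximately uniform (property-tested by KS), so the statistic is
calibrated — unlike the interaction test above, the resampling null
here matches the data-generating process by construction.

## Synthetic data generator

Defaults describe a small yeast-like study and are fixed once:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 500 | desk-scale proteome |
| length distribution | log-normal, median 350, σ 0.45, min 60 | yeast-like protein lengths |
| background | yeast proteome aggregate frequencies | N+Q ≈ 10%, as in the real proteome |
| planted_nqp_fraction | 0.08 | 40 planted prion-like proteins per 500 |
| bias_nq_fraction | 0.55 | planted 60-mer domains realize ~60% N/Q, matching genuine prion-like domains (poly-N/Q cores of Sup35/Rnq1/Ure2-type domains); the 1e−10 main threshold was derived from such domains, so planted truth sits clearly past it and recovery measures detector correctness rather than boundary luck |
| n_interactions | 2000 | sparse, mean degree ≈ 8 |
| GO | 60-term random tree, depth 3, ~3 leaf annotations/protein | exercises propagation and collapse without general-DAG complexity |
| disorder | Beta around base 0.2 (concentration 20), +0.5 mean for planted NQPs | matches the elevated-disorder phenotype of prionogenic sets |

Interaction sampling is rejection sampling of uniform unique pairs with
acceptance weight odds[cat(a)][cat(b)]/max(odds): exact for the
acceptance-odds semantics; an all-ones odds matrix yields a uniform
random graph. Every generator is deterministic under its seed and
writes files the package's own readers parse (round-trip tested); truth
tables are written beside outputs and tests read truth rather than
regenerating it.

What the generator does **not** emulate: scale-free degree
distributions, correlated annotation structure, spoke-expanded
complexes, false-positive interaction noise, or sequence structure
beyond i.i.d. residues plus one planted domain. Passing tests
demonstrate correctness of the counting, search and resampling
machinery under planted truth, not robustness to those real-data
features.

## Problem sizes and numerics

Simulation-based checks run at desk scale chosen for tight statistical
resolution at interactive runtimes: 200 replicate networks (200
proteins, 1500 interactions) for null uniformity, 500 replicates × 72
tests for family-wise error, 100 replicates for preference-odds power,
one 500-protein proteome per scan check, 10 000 Monte-Carlo samples per
disorder test. Hypergeometric and binomial tails are exact log-space
summations (vectorized `gammaln`/`logsumexp`); tails that underflow
`exp` are floored at 5e−324 so probabilities stay positive, with
log-scale values carried alongside for ranking. Exhaustive rational
enumeration (`math.comb`) is the oracle for all N ≤ 30.

## Pipeline conventions

Accessions are matched after stripping isoform suffixes ("P12345-2" →
"P12345") because MITAB files mix isoform and canonical identifiers.
Self-interactions are retained and count once (toggleable); the MITAB
taxon filter keeps 559292/4932 rows and passes rows without taxon
columns. MOD5 and NEW1 remain in the known-prion set by default (their
exclusion only marginally affects enrichment, as both interact with no
NQP); a flag drops them. The ">0.5 disordered" composite uses strict
inequality. The proteome universe is whatever FASTA is supplied —
no assumption about dubious-ORF filtering is made.
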