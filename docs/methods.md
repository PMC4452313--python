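# Methods

## The analysis chain

The package implements a four-stage inference chain over bacterial
pangenomes, plus the synthetic data that validates it.

1. **Signature inference and paralog calls.** For a pathway component with
   reference proteins in several organisms, the *signature* is the domain
   present in every reference; among several universal domains the one
   with the greatest mean merged-envelope length wins (ties: higher mean
   best-hit bit score, then lexicographic name). When no domain is
   universal, a greedy set cover returns the smallest co-occurring domain
   set (capped at 3; beyond that the component is declared to have no
   usable signature). Homolog detection is then purely architectural: a
   protein qualifies iff it carries every signature domain under the
   chosen annotation filter — either hits above the model's trusted
   cutoff (conservative, used for drawing architectures) or hits with
   e-value ≤ 1 (permissive, to retain weak similarity). Copies of a
   multi-copy component are classified by a *discriminator* domain
   (SecA_SW for SecA): merged envelope coverage ≥ `fragment_fraction`
   (default 0.5, inclusive) of the domain model length is canonical,
   anything less — including absence — is secondary. Coverage merges
   overlapping hits first so split fragments are not double-counted. The
   0.5 default operationalizes "small fragment"; it is a declared,
   configurable choice, as is the 30-aa gap that separates "split into
   fragments" from jitter in the rearrangement flag.

2. **Signal-peptide enrichment.** Families are classified SP-positive when
   at least 50% of members carry a call of the requested classes; the
   threshold is inclusive (a 2-of-4 family is positive), taking "at least
   50%" literally. The enrichment p-value is the hypergeometric upper
   tail of the overlap k between K SP-positive and n trait-associated
   families out of N. Two conventions are computed: inclusive P(X ≥ k)
   and exclusive P(X > k). The inclusive tail is the statistically
   standard one-sided test and is what the calibration study uses; the
   exclusive tail is the survival-function convention of several
   statistical environments and is the headline convention here because
   it is the one that reproduces published values of this quantity
   (inclusive is ≈20× larger at the twin-arginine counts). The tail is
   accumulated in log space from exact log-factorials (`gammaln`) with
   `logsumexp`, so values far below 1e-300 are computed exactly; when the
   summation range covers the whole support the function returns exactly
   1.0. Reported p-values are floored in formatting at "< 1e-300", never
   printed as 0.

3. **Neighborhood clustering.** Windows are rank-based and
   strand-agnostic: the up-to-10 genes on each side of a focal gene on
   the same replicon, truncated at linear ends and wrapped (deduplicated)
   on circular replicons. Clustering is single linkage: keep an edge iff
   percent identity ≥ threshold and coverage satisfies the rule (default
   `both`: min of the two sides ≥ threshold; `either` available), then
   take connected components, singletons included. Thresholds are
   inclusive. Defaults are 25% / 0.60 for neighborhoods and 80% / 0.85
   for marker-gene dereplication, where the cluster representative is the
   genome with the longest marker (ties lexicographic). The `both`
   coverage rule and best-bit-score-HSP handling of multi-HSP BLAST pairs
   are declared simplifications of blastclust's undocumented internals.
   The in-package aligner is local BLOSUM62 with gap open 11 / extend 1;
   identity is identical columns over all alignment columns (gap columns
   included), coverage is the aligned span over each sequence length, and
   a pair with no positive-scoring local alignment yields a zero edge.

4. **ROC benchmarking.** Truth pairs are pairs sharing ≥ 1 complex (or
   pathway); the universe is all unordered pairs over the scored
   proteome. Prediction at threshold t is score ≥ t (so t = 0 anchors at
   (1,1)); unscored pairs default to score 0, with exclusion available.
   When scores are keyed by orthologous groups, a protein-to-group map is
   applied first and same-group pairs are dropped as self-association.
   Sweeps run over integer thresholds 0..905 by default.

## The synthetic generator

Defaults are the package's study conditions: 40 genomes (one linear
replicon each), 200 one-member-per-genome background families of which 20
are trait-associated, trait prevalence 0.5, per-protein signal-peptide
probability 0.9 in trait-associated families vs 0.15 elsewhere, a planted
locus in 12 genomes (secondary SecA_DEAD gene plus three partner families
at distinct random offsets within ±10), one canonical SecA per genome,
sequence lengths ~ Normal(300, 50) truncated at 50 aa (longer for SecA
architectures), within-cluster identities 60 ± 2% and coverage 0.90 ± 0.03
against a 10 ± 2% background with a 5% background-edge rate. All
randomness flows from a counter-based Philox generator, so bundles are
byte-identical across platforms for a fixed seed.

Two deliberate simplifications. Sequences are i.i.d. random amino acids —
the similarity table is *drawn* from the configured identity
distributions, not computed by alignment, which separates clustering-logic
validation from alignment validation (the aligner has its own
dynamic-programming oracle). And families have no phylogenetic structure:
members are exchangeable across genomes. Consequently, passing tests show
that the inference chain recovers planted structure under its stated
statistical model; they do not show robustness to correlated evolution,
annotation noise, or genuinely ambiguous domain architectures in real
data.

The null-calibration study (equal SP probabilities in both family groups)
sets both probabilities to 0.5. The reason is structural: a family of 40
members at a 0.15 SP rate essentially never reaches the 50% classification
threshold, so under the null at the background rate K = k = 0 in every
replicate and the test degenerates (inclusive p ≡ 1). Placing the rate at
the classification boundary makes K fluctuate mid-range, which is the
regime where calibration is informative; the measured rejection rate at
α = 0.05 over 500 seeds is ≈0.05 for the inclusive tail. The exclusive
tail is anti-conservative under the null (≈0.13 at the same α) — one more
reason the calibration and any real testing should use the inclusive
convention, with the exclusive one reserved for cross-environment
reproduction.

## Numerical and edge-case choices

- All gene positions are 0-based ranks per replicon (GFF start
  coordinates are converted on read; start ties break by end then id);
  amino-acid coordinates are 1-based inclusive.
- Similarity edges are undirected and stored canonically (smaller id
  first, coverages swapped accordingly).
- phi with any zero marginal is reported as 0.0 with a
  `degenerate_marginal` flag rather than NaN; genomes with unknown
  phenotype are excluded before tabulation and counted.
- Domain tables without a trusted-cutoff column fall back, under the
  trusted filter, to e-value ≤ 1e-5 with a loud warning.
- Cluster output order is deterministic: size descending, then smallest
  member id; conservation reports sort by window recurrence, then genome
  span, then size.
- `hypergeometric_tail` validates margins and support before computing
  and raises on impossible counts rather than returning 0.

## Problem sizes used in the test suite

Unit tests run on reduced pangenomes (12 genomes × ~60 genes). The
end-to-end studies use the default conditions above: 20 full generator
bundles for the planted-enrichment power sweep, 500 family-level
replicates for null calibration, 200 random ≤50-node graphs for the
clustering oracle, 500 random 2×2 tables for the phi oracle, exhaustive
subset enumeration for every hypergeometric input with N ≤ 20, and 100
random-score ROC sweeps for AUC calibration. These sizes keep the full
suite around a minute while leaving each statistical check well-powered.

## Known limitations

- GFF3 support is a CDS-with-ID subset, not the full specification;
  nucleotide sequences are out of scope.
- The rearrangement flag compares first-occurrence order of shared
  domains; it does not attempt optimal architecture alignment.
- Multi-HSP BLAST pairs use the single best HSP; chained/merged HSP
  coverage is not modeled.
- The ROC stage benchmarks supplied scores; it does not recompute
  gene-neighbor scores from genomic context.
- Published phi values for trait–rearrangement association depend on
  per-genome phenotype tables that are not distributed in tabular form;
  the package establishes phi correctness against the Pearson equivalence
  instead of reproducing those specific numbers.
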