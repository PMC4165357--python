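# Methods

This note records the models, parameter choices and numerical conventions
behind `smtdedup`, and what the synthetic-data results do and do not say
about real sequencing data.

## Read-to-target assignment

Amplicon reads begin inside a locus-specific primer, so the first 22
sequenced bases identify the target. Read 1 prefixes are compared against
the reverse complement of each downstream primer (its first 22 bases as
sequenced), Read 2 prefixes against each upstream primer, with bounded
Levenshtein distance (edlib, banded, default `max_dist = 2`). Levenshtein
rather than Hamming is deliberate: a single synthesis or sequencing indel
shifts every downstream base and would otherwise reject the read. `N` in a
read mismatches every base.

A pair is `ASSIGNED` only when both mates have a *unique* minimal-distance
target and the two targets agree. Ties are `AMBIGUOUS`, disagreement is
`CROSS_TARGET`, and no hit within the bound is `NO_MATCH`; all three are
excluded from every downstream statistic rather than resolved by list order
— mis-assignment is worse than loss. Design sets whose comparison windows
are mutually within the edit bound are rejected up front
(`TargetMatcher(validate_separation=True)`), since no read could ever be
assigned unambiguously against them.

Trimming removes the full primer prefix from each mate and caps the read at
the insert length (discarding 3′ read-through into the opposite primer).
Mates whose trimmed length is not strictly greater than 35 bases are
dropped with a QC count. By default the trimmed Read 1 is
reverse-complemented so both mates live in insert-forward coordinates;
allele extraction then indexes the annotated SNP offset directly (a Read 1
covering the insert's 3′ end uses `insert_offset = len(insert) − len(read)`).

## Duplicate marking

Within one sample, reads are grouped by (target, tag); the first occurrence
in input order is `UNIQUE`, later ones `DUPLICATE` with consecutive cluster
ranks. "First" follows file order: permuting the input changes which read
represents a cluster but never the duplicate rate, cluster sizes or any
downstream statistic (property-tested). Tags containing `N` cannot establish
molecular identity and are excluded with a QC tally before marking. Reads
failing the trim-length filter never reach dedup and therefore do not enter
duplicate-rate denominators. No tag error-correction (merging of 1-mismatch
tags) is applied: pairwise tag distances in uniform 12-mer data average 9
with distance-1 pairs at ~2×10⁻⁶, so verbatim treatment loses essentially
nothing; the diversity statistics let a user verify this on their own data.

The per-target rate report carries coverage and three GC covariates (insert,
upstream primer, downstream primer, computed separately) so duplicate-rate
regressions on PCR-bias factors can be run with any standard linear-model
package; the regression itself is out of scope.

## Chance-collision model

Two independent templates can receive the same tag by chance, and such a
collision is indistinguishable from a PCR duplicate. With K = 4^L equally
likely tags and n independent draws, per-tag usage counts are approximately
Poisson with λ = n/K, giving

- E[distinct tags observed] = K(1 − e^(−λ)),
- E[tags seen ≥ k times] = K · P(Pois(λ) ≥ k),

the latter evaluated through the Poisson survival function so extreme tails
(K × 10⁻³⁰⁰-scale probabilities) do not cancel to garbage. The resampling
estimator draws `depth` tags per target i.i.d. from either the uniform model
or an empirical tag-frequency distribution (one count per tag per target per
sample) and counts repeats within a target; per-target generator streams are
spawned from one root `SeedSequence`, so results are reproducible and
parallelisable. For uniform usage the estimator is cross-checked against the
closed-form occupancy value 1 − K(1 − (1 − 1/K)^d)/d. Uniform usage
minimises collisions, so any empirical bias (e.g. poly-T enrichment in tag
synthesis) only raises the estimate; prefix truncation
(`truncate_to_prefix`) models restricting 12-mer data to its first 8 bases.
PCR amplification-efficiency modelling (branching processes) is deliberately
absent: the estimator is occupancy-based.

## Allele statistics

Alleles are read off by position within the assigned, trimmed read — one
count per read pair, Read 1 only — so no halving correction for
twice-sequenced fragments is needed (a genotyper that counts both mates
would need one). Sites where more than 10% of covering reads show a third
allele are excluded. The het caller is a simple surrogate for a full
genotyper: a site is heterozygous when ref+alt depth ≥ 50 and alt frequency
lies in [0.2, 0.8]; thresholds are conservative at ~1,000X and exposed as
parameters.

`fisher_2x2` uses the minimum-likelihood two-sided definition (sum of tables
no more probable than the observed), matching R's `fisher.test`, via
`scipy.stats.fisher_exact`. The 2×k exact test conditions on all margins
(multivariate hypergeometric null) and enumerates the allocation space
vectorised in log-space (`gammaln`), with the same 1 + 10⁻⁷ relative slack
as R when comparing table probabilities; for k = 3 enumeration is O(A²)
tables and is used up to total count 5,000, beyond which a seeded Monte
Carlo sampler (`numpy`'s `multivariate_hypergeometric`) estimates p with a
reported standard error. Benjamini–Hochberg is the textbook step-up rule.
Somatic sites require ≥ 50X ref+alt depth in every sample (applied per site
per sample), BH-significance at FDR 0.05 across the patient's sites, and
germline alternate frequency < 10%. Multi-allelic sites, indels, genotype
likelihoods and strand-bias filters are out of scope.

## Synthetic data generator

The generator emulates the study conditions of a deep targeted amplicon
experiment; defaults are fixed once and are not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| `n_targets` | 1,225 | panel size of the motivating design |
| `insert_length` | 150 bp | typical amplicon insert |
| `primer_length` | 24 bp | typical locus-specific primer (≥ 22 required) |
| `smt_length` | 12 (8 allowed) | the two tag lengths in use |
| `read_length` | 151 | MiSeq v2 run format |
| `mean_depth` | 1,000X | between the 850X average and 1,500X tumor runs |
| `depth_dispersion` | 10 (NB size) | per-target coverage CV ≈ 0.33, a realistic amplicon spread; the depth law is otherwise unconstrained |
| `duplicate_rate` | 0.10 | the observed median germline duplicate rate |
| `het_fraction` | 0.16 | ~200 common-SNP targets out of 1,225 |
| `error_rate` | 0.005 | typical per-base substitution error after filtering |
| `smt_error_rate` | 0 | see below |
| `gc_range` | (0.3, 0.7) | uniform insert GC across the panel |

Per target, depth d is drawn, m = round(d(1 − duplicate_rate)) templates
each receive a tag (uniform, or poly-T biased: with probability `weight` a
run of `run_length` T's is planted at a random offset) and — on het targets
— a Bernoulli(0.5) allele; the remaining d − m reads are sampled with
replacement from the templates and inherit tag and allele, so duplicates
can disagree only through sequencing error. Reads are shuffled within the
target. Sequencing error is applied to R1/R2 bases at rendering time, not
to the tag read: the generator's contract is that the configured duplicate
rate is recoverable by dedup within binomial error, which defines the tag
as read faithfully; tag-read errors (separately exposed as
`smt_error_rate`) would systematically deflate measured rates and are off
by default. Quality strings are constant Q30 — the pipeline never consumes
qualities.

Duplicate injection at constant depth keeps m = round(n(1 − rate)) uniques
and adds n − m resampled copies, so total depth is preserved and the
injected rate is exact by construction. Splitting produces disjoint
⌊n/2⌋/⌈n/2⌉ halves. The experimental-duplicate allocator routes each
observed duplicate to the half holding its (target, tag) unique read,
dropping (and counting) orphans. The FPR experiment chains these: generate
uniques → call het SNPs from them → split → inject per half → 2×2 Fisher at
every callable het SNP → FPR; everything is a pure function of the root
seed via spawned `SeedSequence` streams.

What the generator does **not** emulate: GC- or efficiency-dependent
amplification (duplicate rate is independent of coverage and GC by
construction, so the covariate tables are plumbing, not a validation of
those effects), indels and adapter chimeras, per-template PCR lineages, and
quality-score structure. Passing tests therefore demonstrate the
correctness of the pipeline's logic and statistics under the stated
conditions — not that real libraries have these error or bias profiles.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the injection experiments at
200 het targets × 1,000X × 10 replicates (the FPR control and ordering
checks), 100 replicate injections for the variance-growth check, a 50-target
grid over duplicate rates 0–0.9 at depths 200 and 1,000 for parameter
recovery, and 40 targets at a fixed 1,074X for the 12- vs 8-mer collision
contamination comparison — sizes at which binomial error bands are tight
enough for 3σ assertions while the whole suite stays fast. Exact-test
oracles enumerate all 2×2 tables with total ≤ 30 and hand-picked 2×3
margins with exact integer arithmetic.

Tag packing uses 2 bits per base (A=0, C=1, G=2, T=3). Bounded edit
distances return −1 beyond the bound. All within-insert coordinates are
0-based, half-open. Degenerate Fisher tables (a zero margin) give p = 1.
Empty inputs raise rather than return silent zeros wherever a statistic
would be undefined (FPR of nothing, positional frequencies of no tags);
`paired_read_concordance` of no overlapping pairs is reported as NaN, as a
missing value is the honest summary there.

## Known limitations

- The het caller is a threshold surrogate, not a genotyper; at depths below
  ~100X its band boundaries interact with binomial noise.
- The exact 2×k test is implemented for k ≤ 3 plus a Monte Carlo fallback;
  larger k always uses Monte Carlo.
- The collision resampler's empirical mode reflects whatever distribution it
  is given; an empirical distribution estimated from few draws carries its
  own sampling inflation (tests construct exactly-uniform distributions
  where the analytic value is the oracle).
- Consensus-calling within duplicate clusters (error correction) is not
  implemented; the cluster machinery exposes everything such an extension
  would need.
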