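# Methods

## Scope and model

`svforest` scores exon-altering deletions and duplications for
pathogenicity. The unit of analysis is one SV with 0-based half-open
coordinates; inversions, insertions, breakends and multi-sample genotypes
are out of scope, and SVs that do not overlap at least one base of a
principal-transcript exon are refused rather than scored (the score is not
defined for purely intronic or intergenic events). Copy-number loss is
treated as DEL and copy-number gain as DUP.

The classifier is a random forest: 1000 trees, max depth 10, **one** feature
considered per split, minimum 2 samples per leaf and 4 per split, no
out-of-bag scoring. The unusually small per-split feature budget is
deliberate — with 17 partially redundant features it decorrelates trees and
limits overfitting to any single dominant feature. The score is the mean
pathogenic probability across trees (the voting fraction when leaves are
pure), so it is a rank score, not a calibrated probability. Training
excludes SVs larger than 3 Mb; at inference such SVs are assigned score 1.0
outright, reflecting that benign events of that size are essentially
unobserved in population data.

## Annotation model

Gene models come from an Ensembl-dialect GTF or an equivalent flat TSV.
Each gene uses a single **principal transcript**: best (lowest) APPRIS rank,
ties broken by greatest summed exon length, then by transcript id for
determinism. Transcripts without APPRIS annotation are dropped with a
logged count. Exon indices, CDS intervals, exon counts and codon positions
all refer to the principal transcript; alternative transcripts are consulted
only by the constitutive-exon test (an exon is constitutive when its exact
coordinates occur in every transcript of its gene).

Per-base signals (phyloP conservation, exon expression, exon inclusion) are
run-length encoded: sorted non-overlapping (interval, value) runs per
chromosome with adjacent equal values merged; a base outside every run has
*no value* (distinct from zero). Expression at a nucleotide is the summed
TPM of all transcripts with an exon covering it, after pooling TPM across
tissues per transcript (sum by default, mean configurable). Inclusion is
that coverage divided by the gene's total TPM; where exons of two genes
overlap, expression sums across both while inclusion keeps the per-gene
maximum, and bases of zero-TPM genes get no inclusion value rather than 0.

## Features and aggregation

Seventeen features per SV. Multi-gene SVs aggregate toward the most
severely impacted gene: min for the two undisrupted-CDS fractions, LOEUF
and exon count; max for the CDS-overlap fraction, pLI, TAD strength and
overlapped-exon count; AND across genes for "all exons in-frame skippable";
OR for "any exon constitutive". The high-impact pLI (LOEUF) variants
consider only genes whose principal start (stop) codon base lies inside the
SV or with CDS-overlap fraction strictly greater than 0.5; when no gene
qualifies the feature is missing.

The conservation/expression summaries use a **top-400 rule** restricted to
the SV's exonic span (SV ∩ principal exons of overlapped genes, merged):
the track is decomposed into run-length intervals there, and the mean of the
400 highest-valued intervals is taken — each interval counting once,
unweighted by length — or the mean of all intervals when fewer than 400 are
covered. A per-nucleotide mode (top 400 bases, length-weighted) is
available behind a switch; the interval mode is the default because the
"fewer than 400" fallback is defined on intervals. In-frame skippability is
evaluated per overlapped exon (length ≡ 0 mod 3 and internal), not on the
joint length of the overlapped exons.

Missing values are imputed with training-set medians, computed before
imputation and stored on the model; boolean features use the majority value
(ties to false) so a single imputation rule covers both kinds. The feature
correlation matrix is pairwise-complete Spearman, with a configurable list
of sign-flipped features (the LOEUF pair and the two undisrupted-CDS
fractions by default, whose natural direction is "lower/larger = more
severe") and rows ordered by average-linkage clustering on 1 − ρ; constant
features get correlation 0 with a warning.

## Curation

Reciprocal overlap is min(shared/|a|, shared/|b|), zero across chromosomes.
Deduplication is a greedy sweep — input order for `keep="first"`,
size-ascending for `keep="smallest"` — retaining a record iff its RO with
every previously retained record is below the threshold; RO at or above
0.9 counts as duplicate (the threshold and comparison are configurable).
DEL and DUP are deduplicated separately. Removal against common variation
uses exact (chrom, start, end, type) matches for one source class and
strict RO > 0.9 same-type matches for the other.

CNV allele frequency from event-count tables is observed/(2 × samplesize),
capped at 1 with a warning. Rarity: common if MAF > 1 %; otherwise
rare-benign with ≥ 1 homozygote, rare-unlabeled with none.

Size matching walks pathogenic SVs in input order (size-ascending
configurable); an SV of size N accepts benign sizes in
[N/α − slack, N·α + slack] with α = 1.06101 and slack = 20 bp. The printed
form of this window in the source literature is typographically corrupted,
so both parameters are explicit configuration; the implemented reading is
the only size-local multiplicative one. Tiers are searched in preference
order; within a tier the size-closest same-type candidate wins (ties to the
smaller) and is consumed permanently. Unmatched pathogenic SVs are dropped
and reported. Feature-identical dedup keeps one representative per
identical-vector group within a label and removes groups spanning both
labels entirely.

Splits are chromosome-based to prevent positional leakage: a held-out split
on a named chromosome set (default {1, 3, 5, 7}) and leave-one-chromosome-out
folds. The one-SV-per-gene subsample visits SVs in seeded random order and
keeps an SV iff its overlapped gene set is disjoint from all previously
kept SVs.

## Evaluation

ROC curves come from a descending threshold sweep with tied scores grouped;
the trapezoidal AUC equals the Mann–Whitney statistic with half credit for
ties (asserted to 1e-9 in tests against an exhaustive pairwise oracle). The
AUC standard error is Hanley–McNeil's closed form and the 95 % CI is
A ± 1.96·SE clipped to [0, 1]; no rank transform is applied to the interval.
A score equal to the threshold counts as a positive call, so the exact 1.0
of the > 3 Mb rule is always called pathogenic. The sensitivity threshold
for target s is the ⌈s·n₁⌉-th largest pathogenic score — the largest
threshold whose sensitivity is ≥ s by construction. The paired comparison
across genomes is the two-sided Wilcoxon signed-rank test with zero
differences dropped.

## Synthetic data

The fixtures module emulates the statistical structure the features
exploit, not real genomes. Defaults: 80 genes round-robin over 8
chromosomes of 2.5 Mb; 3–12 exons of 60–300 bp separated by 0.5–5 kb
introns; CDS trimmed inside the first and last exon; 5 % of genes
non-coding; up to 2 alternative isoforms per gene skipping internal exons
(so constitutive and skippable exons both occur). A quarter of genes are
"constrained" (pLI ~ Beta(8,1), LOEUF ~ U(0.1, 0.35)) versus Beta(1,8) /
U(0.8, 1.8) otherwise, with scores missing for 10 % of genes to exercise
imputation. Conservation is Normal(1.0, 1.5) per 3–15 bp run, +2.0 on
constrained genes' exons — a detectable but not trivially separable boost.
Transcript TPMs are log-normal over 3 tissues; 20 TAD boundaries of
5–20 kb with U(0, 1) strength per chromosome.

Labeled SVs are log-uniform in size over [50 bp, 100 kb]. Benign SVs anchor
on a base drawn uniformly from exonic space; pathogenic SVs target a
constrained gene with probability 0.85 and cover its start codon with
probability 0.7, falling back to benign-style placement otherwise, so
setting both effect sizes to zero makes the classes exchangeable (a built-in
null). The 100 kb cap for *labeled* sets is a deliberate choice: real benign
exon-altering SVs are overwhelmingly sub-100 kb, and at multi-Mb scale a
synthetic SV spans so many genes that every gene-level feature saturates for
both classes — a property of the compressed synthetic gene density, not of
the biology being emulated. Interval-algebra fixtures (deduplication, size
matching) instead draw log-uniform over the full [50 bp, 3 Mb] working
range to exercise the matching window across scales.

What passing tests on these fixtures shows: the feature definitions match
an independent per-nucleotide implementation; curation obeys its contracts;
the forest recovers a planted, feature-mediated signal (held-out AUC ≈ 0.9)
and finds nothing in label-shuffled controls. What they cannot show:
performance on real ClinVar/gnomAD-style data, realistic feature
correlation structure, annotation-version effects, or calibration of any
particular score threshold.

## Numerical choices and degenerate inputs

Coordinates are integers; feature fractions are exact ratios of base
counts. Track restriction preserves run boundaries exactly, so the worked
single-gene case reproduces its closed-form features to equality, not just
tolerance. Principal-transcript selection, exon ordering and all curation
sweeps are deterministic and independent of input row order; every
stochastic step (fixture generation, subsampling, forest training) takes an
explicit seed, and fixed-seed training is bit-reproducible (single-threaded
forest). Degenerate inputs fail loudly: zero-size or label-less records,
CDS outside every exon, overlapping track intervals with different values,
single-class training sets, all-chromosome held-out sets, single-chromosome
LOCO. Record-level VCF problems (no resolvable end) are collected on a
read report rather than aborting the file.

## Known limitations

- Breakpoint uncertainty (CIPOS/CIEND) is ignored; point estimates are used.
- One MAF per record; multi-allelic frequency nuance is not modelled.
- Principal-transcript exons define exon-overlap eligibility; an SV touching
  only a non-principal exon is considered not scoreable.
- Scores are not probabilities and thresholds derived on synthetic fixtures
  do not transfer to real cohorts.
- The grid-search helper is desk-scale; the full 576-combination product is
  supported but intended for reduced fixtures.
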