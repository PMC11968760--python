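# Methods

## The profiling model

Type IIB restriction enzymes cut on both sides of their recognition site
and release a fragment of fixed length.  A library built on such fragments
(a 2bRAD library) therefore samples every genome at a deterministic,
enzyme-defined set of loci, and ~100 bp reads each carry exactly one
fragment.  `twobrad` ships the BcgI geometry: recognition core
`CGA(N6)TGC`, 10 bp flanks on each side, 32 bp tags.  The flank length is a
modelling choice (the blunt 32 bp window around the 12 bp core, ignoring
the enzyme's 2 nt overhangs); it is configurable per enzyme through the
registry, and nothing downstream depends on the specific value.  Tags are
canonicalised as `min(tag, revcomp(tag))` because sequencing does not
preserve strand.  Sites whose flanks run off a contig end are dropped
rather than padded: a padded tag could never be matched exactly by a read.
Circular replicons can be flagged, in which case the sequence is virtually
wrapped by `tag_length − 1` bases.

**Markers.**  A species marker is a canonical tag that occurs exactly once
within at least one genome of its species and in no genome of any other
species at any copy number.  The single-copy filter is applied per genome
and the per-species candidate set is the union across conspecific genomes;
a tag single-copy in one genome but duplicated in a conspecific genome is
kept (and counted in the build report).  Cross-species exclusion is
absolute.  `T_i` is the size of species *i*'s marker set.  The database is
persisted as sorted flat tables and identified by a SHA-256 digest, so
rebuild determinism is checkable bit-for-bit.

**Profiling.**  Reads pass a three-stage funnel: *raw* → *enzyme* (the
recognition motif present with complete flanks) → *clean* (exactly one
extraction locus — two loci are ambiguous and rejected — no `N` in the tag,
mean Phred ≥ 20 over the tag when qualities are available; the quality and
ambiguity rules are this package's own choices, stated here because no
standard exists).  Clean tags are matched exactly (hash lookup, no
mismatch tolerance: markers are 32-mers and a single mismatch would break
species specificity).  Per species, `S` = reads assigned to its markers and
`t` = distinct markers observed.  The confidence score

    G = sqrt(S * t)

must reach 5 for the species to be reported; `G = S*t` is available as
`gscore_form="product"`, but the conventional threshold of 5 is calibrated
on the geometric-mean scale and that is the default.  Relative abundance is
coverage-normalised over the species that passed:

    a_i = (S_i / T_i) / sum_j (S_j / T_j)

Dividing by `T_i` converts read counts into per-marker coverage, which
tracks genome-copy (cell) proportions regardless of how many markers a
genome happens to carry.

## The synthetic study

`simulate` and `study` generate data with known truth so every stage is
testable without external downloads.

*Genomes* are random sequences with an exact number of planted,
non-overlapping recognition sites; background occurrences on either strand
are scrubbed by point mutation, so in-silico digestion yields exactly one
tag per planted site.  *Reads* are drawn multinomially over three classes:
member reads (a member genome's tag embedded at a random offset and strand
in a 100 bp read of motif-free filler), host-contaminant reads (tags of a
genome absent from the database), and junk reads (motif-free random
sequence).  Member genomes are weighted by proportion × tag count ("tag
molarity"): proportions are cell proportions and every tag locus in a cell
is an equally likely template, which is the sampling model under which the
`S/T` normalisation above is consistent.  Reads are error-free by default
(`error_rate` exists; planted substitutions simply fail the exact match).
PCR duplicates, indels and quality decay are not modelled, so the recovery
tests bound only counting noise, not wet-lab bias.

The reference cohort is 12 species (15–45 markers each, 12 kb genomes),
10 + 10 samples in groups M and H, per-sample compositions drawn from a
Dirichlet (concentration 300) around group means with three planted
effects (one species enriched in M at 0.20 vs 0.03, two in H), 20,000
reads per sample, 5% host and 10% junk reads.  Group sizes follow the
two-sample power calculation `n = 2((z_a + z_b)σ/δ)²`, which gives 9.5 per
group at σ = 1.56, δ = 2.0 (α = 0.05, power 0.80), rounded up to 10.
These sizes keep the full pipeline run under a few minutes on one core
while leaving the planted effects comfortably detectable; they are the
package's reference conditions, not tuned values.

## Statistics

* **Alpha diversity** — Chao1 on integer assigned-read counts (`S` per
  species; singleton/doubleton logic needs counts, not proportions):
  `S_obs + F1²/(2 F2)`, or the bias-corrected `S_obs + F1(F1−1)/2` when
  `F2 = 0`.  Shannon uses the natural log; Simpson is Gini–Simpson
  `1 − Σp²` (higher = more diverse).  Counts are not rarefied.
* **Beta diversity** — binary Jaccard, Bray–Curtis, Euclidean (scipy), and
  PCoA via scikit-bio's Gower double-centering.  Negative eigenvalues
  (non-Euclidean input) are reported but truncated — no Cailliez/Lingoes
  correction — and excluded from the explained-fraction denominator.  Axis
  signs are fixed by making each axis's largest-magnitude loading positive.
* **Differential abundance** — per-taxon two-sided Mann–Whitney tests;
  exact null when `m + n ≤ 16` and tie-free, otherwise the tie-corrected
  normal approximation with continuity correction.  The groups are
  independent patients, so the unpaired test is the default throughout
  (a paired option exists).  Raw p-values are primary; Benjamini–Hochberg
  q-values are reported alongside but do not drive the p < 0.05 filter.
* **Co-occurrence** — Spearman rho (average ranks) among the top-k most
  abundant taxa; constant taxa get undefined (NaN) correlations rather
  than a fabricated value.
* **LEfSe-style scoring** — abundances rescaled per sample to one million;
  Kruskal–Wallis screen at α = 0.05; for each of 30 bootstrap iterations,
  2/3 of each group is subsampled and a shrinkage LDA (`lsqr`, Ledoit–Wolf)
  is fitted on the surviving features.  A feature's effect per iteration is
  the mean of (a) its contribution `w_f · (wᵀΔm)` to the projected
  class-mean difference (unit-norm discriminant `w`) and (b) its raw
  class-mean difference `Δm_f`; the score is `log10(1 + mean |effect|)`
  and the reporting threshold is 2.0.  The single-factor design has no
  subclass step.  Because the score lives on the counts-per-million scale,
  the 2.0 threshold suppresses mean gaps below ~100 CPM; the package's
  null-calibration fixture uses low-noise profiles (sd 30 CPM) precisely so
  that this thresholding behaviour — not the KW screen — is what the test
  exercises.  On realistic overdispersed data, features passing KW will
  usually also clear 2.0, so false positives occur at roughly α per
  feature; that is a property of the method, not of this implementation.

## Random-forest marker selection

The candidate pool is the top-30 most abundant taxa.  The user-facing
importance table is permutation importance (seeded); note that permutation
importance of mutually redundant discriminative features is legitimately
near zero, because permuting one leaves the others carrying the signal.

The cross-validation error curve re-ranks features *inside every training
fold* (by the training forest's impurity importances) before evaluating
the top-s subset on the held-out fold, in the spirit of
`randomForest::rfcv`; ranking outside the folds would leak selection into
the error estimate and make pure-noise data look predictive.  The selected
set is the smallest size attaining the minimum mean error (parsimony
tie-break), taken from the full-data impurity ranking — the same criterion
the folds optimise.

**POD.**  The probability of disease of a sample is the fraction of
out-of-bag trees voting the disease class.  Two calibration details
matter at cohort sizes of tens of samples:

1. Bootstraps are stratified per class.  A plain bootstrap leaves an
   out-of-bag sample's own class under-represented in the trees that judge
   it, which biases OOB votes *against* the true label even on
   uninformative features.
2. The group comparison uses the rank-sum statistic, but its p-value is
   obtained by refitting the forest under label permutations (mid-p, with
   a deterministic tie-break folded into the statistic) rather than from
   the theoretical Wilcoxon null.  Each sample's POD depends on the other
   samples' labels, so the theoretical null is invalid — empirically it
   rejects a true null 3–6× too often.  The permutation version is exact
   by construction; the plain Wilcoxon p is available as
   `pod_test="wilcoxon"` for comparison with conventional reports.

AUC is computed by concordant-pair counting with half-weight ties (it
equals `U/(n₊ n₋)`), with the cross-validated mean AUC reported for the
selected marker set.

## Numerical and degenerate-input conventions

Identical multisets give Wilcoxon p = 1 by definition; constant taxa are
never reported as differential.  Zero passed species yields an empty
profile with a warning, not an error.  All generators and fits are pure
functions of their seeds; database tables are sorted so rebuilds are
byte-identical.  Distances of all-zero sample pairs are 0 (Jaccard
convention).  Profiles renormalise over passed species only, so relative
abundances always sum to 1 when any species passes.

## Problem sizes

Defaults were chosen so the full test suite and the acceptance run fit
comfortably on a single core: 12-species genomes of 12 kb, 20 k reads per
sample (100 k for the recovery bound), 200-replicate calibration loops with
40-tree forests and 39 permutations.  All are parameters, not constants.

## Known limitations

The synthetic generator does not emulate real taxonomic structure, PCR
bias, sequencing error or strain-level variation, so passing recovery
tests demonstrate correctness of the accounting, not field accuracy.  The
marker database scales linearly in total tags and is held in memory —
adequate for thousands of genomes, not for a 400k-genome build.  LEfSe
effect sizes follow the original formulation in spirit but are pinned to
the specific combination documented above; absolute score values are
comparable only within this implementation.
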