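# Methods

This note documents the models, parameter defaults and numerical choices
behind `hyperhet`, and what the synthetic-data tests do and do not show
about real assemblies.

## The synthetic diploid

The generator models a diploid whose haplotypes have evolved independently
for long enough that ~5–6% of aligned sites differ, as in obligate
parthenogens. Haplotype A is i.i.d. random sequence carrying non-overlapping
gene models (exons = CDS, introns ≥ 50 bp, even intergenic spacers);
haplotype B is derived from A by, in order:

1. **Indel events.** Bernoulli event positions at `indel_event_rate`
   (default 0.0066 per bp, the aggregate short-indel rate of a
   hyper-heterozygous nematode assembly), geometric lengths
   (p = 0.35, capped at 50 bp), insertion/deletion with equal probability.
   Events are kept out of CDS so both haplotypes stay in frame, and they
   keep a dead time of 50 bp + event length from each other: two nearby
   opposite-sign indels are *mathematically indistinguishable* from a
   mismatch run under any optimal alignment, so allowing them would make
   the planted ledger unrecoverable in principle, not just in practice.
   The candidate rate is compensated for both the dead time and the CDS
   exclusion so the realized genome-wide event rate matches the configured
   value.
2. **Substitutions.** Per-site Bernoulli draws with class-specific rates
   (defaults CDS 0.037, intron 0.071, intergenic 0.056 — coding sequence
   most constrained, introns least). Sites within 6 bp of an indel
   boundary are excluded: a gap shifted by d bases can silently absorb an
   adjacent substitution with probability ~4^-d, and 6 bp pushes the
   expected number of such absorptions at the scales used here below
   0.01. The per-class planting probability is scaled by the class's
   eligible fraction, so realized densities over *all* sites of a class
   match the configured rates.
3. **Structural events.** Inversions (reverse-complement in place) and
   translocations (excision, reinsertion into a *different* scaffold),
   sizes 2–5 kb by default, placed in a gene-free reserve with ≥ 600 bp
   between events so every event retains alignable flanks. Gene
   coordinates on B are remapped through all shifts.

Every change is recorded; `apply_ledgers` literally replays the ledgers and
is asserted byte-equal to haplotype B on every generated instance, so any
bookkeeping error fails loudly.

Expression truth assigns each allelic pair one log-normal base level
(log-mean 5, log-sd 1 → mean ≈ 250 fragments/allele); a deviant fraction
(default 121/7306 ≈ 1.7%) has one allele multiplied by a uniform 2–10×
fold. Observed counts are Poisson around expectation (switchable off).
Reads are uniform over both haplotypes with independent per-base errors
(default 1%); 3'-EST families copy a gene 3' region with 5' length jitter,
a poly-A tail, and per-base error (default 2% — typical single-pass EST
quality; at 5% the within-family pairwise identity falls to ~0.90, exactly
at the clustering threshold, and family recovery becomes a coin flip by
construction rather than a property of the algorithm).

All randomness flows from one integer seed through named per-stage
substreams (`genome`, `expression`, `reads`, `est`), so stages are
individually reproducible.

**What passing these tests does not show:** the simulator has no repeat
families, no GC or codon-usage structure, no sequencing error profiles and
no assembly artifacts, so real-data performance of the pairing stage —
especially repeat suppression and coverage fractions — is not certified by
it. The ~89% pairing coverage of a real assembly reflects repeats and
collapsed regions the simulator deliberately omits; on clean simulations
coverage is ~99.9%.

## Pairing by self-alignment

* **Anchors**: exact canonical 15-mers shared between scaffold positions;
  windows containing N never seed; k-mers occurring more than 10 times in
  the assembly are skipped (repeat suppression); trivial self-hits removed.
* **Chaining**: within each (scaffold pair, orientation) group, repeated
  longest-increasing-subsequence extraction (patience DP on positions,
  strictly increasing in both coordinates; decreasing in B for reverse),
  then splitting wherever the inter-anchor gap exceeds 500 bp on either
  sequence. Chains with fewer than 3 anchors are noise and dropped.
* **Refinement**: inter-anchor intervals are aligned with an affine-gap
  Gotoh aligner (match +1, mismatch −1, gap open −2, extend −1; a gap of
  length L costs 2 + L), row-vectorised with the prefix-max trick for the
  horizontal affine pass, and banded: the band doubles until the score is
  stable across a doubling, falling back to the full matrix, so the result
  is always score-optimal. Equal-length intervals ≤ 6 bp are compared
  column-wise (provably optimal for isolated substitution runs at this
  scoring). Tie-breaking prefers substitution over gap, then gap in the
  first sequence.
* **Reciprocal-best tiling**: per-base best segment on *both* sides by
  score density (score / alignment columns), ties broken by segment
  length then coordinates; segments are trimmed to maximal consistent
  runs, pieces shorter than 200 bp dropped, and trimmed pieces inherit
  the parent's density, which makes the tiling idempotent.
* **Summary convention**: assembly tables for unphased diploids count
  covered bases and variants on *both* sides of each alignment (that is
  the only convention under which a published SNV total equal to 5.7% of
  the paired length is self-consistent). `PairingSummary` therefore
  doubles column counts for its headline fields and keeps raw column
  counts alongside for ledger comparisons.

Detection is exact against the ledger on clean simulations: mismatch
positions equal planted SNV positions, and indel events match planted
events 1:1 up to equivalent gap placement (an optimal alignment may slide
a gap within a repeat; type, length and count are preserved). Events at
segment edges (within a clearance of the first/last anchor) are not
claimed.

## Heterozygosity statistics

Aligned A-side bases are partitioned CDS > intron > intergenic (intron =
gene span minus exons of any gene; exonic non-coding bases fall to
intergenic). Window tracks use fixed 100-bp windows anchored at
coordinate 0, last partial window kept; each indel is one signed length at
the base before the gap. Structural calls: a segment paired with a
non-dominant partner scaffold is a translocation; a segment whose
orientation opposes *both* flanking same-partner segments is an inversion
(requiring both flanks avoids edge artifacts). On default-profile
simulations with events ≥ 1 kb, sensitivity and precision are 1.0 across
seeds.

## Ortholog classification and gene number

Categories are a pure function of the focal/reference member counts:
(2,1)→2:1, (2,≥2)→2:2+, (≥3,≥1)→3+:N, (1,≥1)→1:1+, (2,0)→2:0, (≥3,0)→3+:0,
(1,0)→1:0. The two focal members of any doubleton are taken as the allelic
pair without a synteny check. The collapsed diploid gene number is
pairs + singletons + half the family genes with the half rounded *up*
(the published arithmetic 11,345 + 7,774 + 3,957/2 = 21,098 forces
round-half-up). Ortholog inference itself is consumed as a neutral TSV,
not reimplemented.

## Allelic expression

FPKM = count / ((CDS length/1000) × (total fragments/10^6)). Pairs with
CDS length difference ≥ 100 bp are excluded as not comparable. Fold bins
are cumulative (>1.5 ⊇ >2 ⊇ >5). Pairs with one silent allele have an
undefined ratio and are reported separately rather than given a
pseudocount; they are excluded from the Pearson correlation of higher vs
lower FPKM.

## CDS divergence and dN/dS

Allelic CDS pairs are globally aligned over codon units (codon-pair score
= per-base matches − mismatches; affine whole-codon gaps, open 5 extend 2),
so gaps always respect frame. Identities are computed over gapless codon
columns: overall (base level), third positions, and third positions of
columns where both codons share a 4-fold degenerate prefix (GC*, GG*, CC*,
AC*, GT*, CT*, CG*, TC* under the standard code).

dN/dS uses Nei–Gojobori counting: per-codon synonymous site fractions
(number of synonymous single-base alternatives / 3 per position, averaged
over the two sequences; changes to stop codons count as nonsynonymous),
substitutions averaged over minimal mutation paths with stop-crossing
paths excluded unless all paths cross a stop. Proportions are
Jukes–Cantor corrected; at the 0.75 saturation bound the uncorrected
proportion is reported with a flag (this also covers degenerate one-codon
inputs). Significance is a two-sided Fisher exact test on the rounded
(synonymous/nonsynonymous × substituted/unsubstituted) site table — a
documented choice, since counting-method pipelines differ here. This is a
counting estimator, not a maximum-likelihood one; on near-identical
alleles the difference is marginal, and the count tables are exposed so
other estimators can be added.

Note the simulator mutates CDS uniformly at random, so simulated dN/dS is
near 1 by design; the purifying-selection signature of real allelic pairs
is a property of real data, and the tests only verify the estimator
(against brute-force path enumeration) and a synonymous-biased regime.

## EST clustering

One pass in input order; a tag joins the first cluster in creation order
containing a member whose best local alignment to it has identity ≥ 0.90
over ≥ 50 columns (identity = matches / all alignment columns, gap columns
included). Comparing against *all* members (single-linkage flavour) is the
default, matching the described procedure of comparing each clone with all
previous ones; representative-only and best-match variants are available
and their order sensitivity is tested, not hidden. Poly-A tails (≥ 8 A's)
are trimmed first. The local alignment is scikit-bio's striped
implementation; an 11-mer sharing prescreen skips hopeless comparisons
(a qualifying 90%-identity overlap essentially always contains an exact
11-mer; the prescreen can be disabled).

## k-mer spectrum and genome size

Canonical 21-mers (odd k so a k-mer is never its own reverse complement);
windows with N skipped. The error cutoff is the first local minimum of
the histogram. Above it, a two-component negative-binomial mixture with
shared dispersion and the hard diploid constraint μ₂ = 2μ₁ is fitted by
maximum likelihood (Nelder–Mead on log-parameters, three initialisations;
dispersion clamped to [0.01, 10⁴] — beyond that the NB is numerically a
Poisson). An unconstrained two-mean refit is reported as a diagnostic
(its peak ratio should be ≈ 2 for a true diploid), and a single-NB fit is
compared by BIC: when the single component wins, the spectrum is flagged
haploid-like and the genome size uses the single peak's mean. Genome size
= above-cutoff k-mer mass / single-copy depth, which counts fully
diverged diploid regions twice (the diploid-span convention, comparable
to the total assembly length of an unphased diploid). The expected
single-copy depth of a read set is coverage × (L−k+1)/L × (1−e)^k; the
error factor matters (≈ 0.81 at 1% error) and is easy to forget when
sanity-checking fits.

## Scales used in tests

Simulation-backed tests run at 60–500 kb ancestral length, 5 fixed seeds
for the recovery checks, 30× per-haplotype coverage for spectrum tests —
sizes at which every binomial acceptance band is a few relative percent
wide and the full suite stays fast. All stochastic tests assert 3-standard-
deviation (or wider) bounds at fixed seeds.
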