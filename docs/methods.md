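# Methods

## Coordinate conventions

All coordinates are 0-based, half-open, throughout. GFF output is converted
to 1-based inclusive on write. Calendar years are plain integers.

## TE consensus model and LTR detection

An LTR retrotransposon begins and ends with near-identical long terminal
repeats. `detect_ltrs` aligns the 5′ terminal window of the consensus
against the 3′ terminal window for every candidate length *L* from
`min_ltr` (default 100 nt) up to half the consensus, counting mismatches
positionally (no gaps — the two LTR copies of one element differ almost
exclusively by substitutions while the element is young). Windows with a
mismatch fraction above `max_mismatch_frac` (default 0.05) are rejected;
among the rest the boundary maximises *matches − 5·mismatches* rather than
raw length, because a pure longest-window rule drifts a few dozen bases
into the core on chance matches (a ~25% per-base match rate makes short
spurious extensions pass a 5% mismatch budget). `N` counts as a mismatch
even against `N` (conservative). Detection is invariant under
reverse-complementing the consensus, since the mismatch pattern between
the two windows is symmetric. Automated boundaries can differ by a few
nucleotides from curated ones; the recovery tests allow ±5 nt.

## Synthetic data: what it emulates, and what it does not

The generator provides every input with planted truth:

- **Genomes** are i.i.d. uniform-base backgrounds with non-overlapping TE
  copies spliced in, each independently mutated at `insertion_divergence`
  (substitutions only). Placement draws sorted cut points from a shrunken
  interval and re-expands, guaranteeing at least `min_insertion_spacing`
  (default 500 nt) of background between insertions in a single pass.
- **TE-internal SNPs** are planted per `te_snp_spec`: at each specified
  consensus position, `round(freq · n_copies)` copies (chosen at random)
  carry the alternate base, and non-carriers are reset to the consensus
  base at that site. Deterministic rounding makes the realised frequency
  the closest achievable value, so downstream recall measures the caller,
  not planting luck; the realised frequency is recorded in the truth set.
- **Short reads** are single-end, uniformly placed,
  `round(depth·genome/read_length)` in count, with per-base substitution
  errors at `error_rate` and constant quality. Defaults follow the study
  design downstream analyses assume: 100-nt reads, depth 30, 0.5% error.
  No indel errors are simulated, which keeps pileup columns exact; no
  target-site duplications, since no downstream statistic uses them.
- **piRNA pools** are 23–29-nt reads from the consensus: a
  `pingpong_fraction` of reads forms sense/antisense pairs whose 5′ ends
  overlap by exactly 10 nt; the rest are uniform, antisense with
  probability `antisense_fraction`.
- **Cohorts** give each strain a true copy number of 0 up to the species'
  invasion year and `min(copy_cap, growth_rate·(year − invasion_year))`
  after it (defaults: growth 2 copies/year, cap 30). Linear growth with a
  cap is a deliberate simplification — only presence/absence over time
  matters downstream. An optional contaminant strain (early year, high copy
  number) is plantable and flagged in the truth set. Reads per strain are
  generated on request; presence/absence analyses can run on truth copy
  numbers directly.

Passing tests on these data show the estimators recover what was planted
under idealised conditions. Real data add mappability structure, indels,
GC and library biases, and non-uniform coverage that the generator does not
model; the recovery rates here are upper bounds, not field performance.

Generators draw from `numpy` PCG64 streams keyed as `[seed, domain]` with a
distinct domain constant per generator, so the same integer seed can safely
parameterise the consensus, a genome, and a read set without stream
collisions.

## Read mapping, pileups, copy number, TE SNPs

Reads are trimmed to exactly 100 nt from the 3′ end, shorter reads
discarded. The built-in mapper seeds candidate references by exact 31-mers
(sampled across the read) and extends with a banded edit-distance alignment
in infix mode (read end-to-end, reference locally; `edlib` backend), both
strands, keeping the single best hit (ties: forward strand, then reference
order, then leftmost). Alignments below 85% identity are unmapped —
permissive enough for 10%-diverged copies plus sequencing error, strict
enough that a random 100-mer essentially never maps. Externally produced
SAM is accepted interchangeably; soft-clips are excluded from pileups.

Pileups count match/mismatch bases per consensus column; deletions skip
columns, insertions are ignored. Copy number is the mean TE column depth
divided by the unweighted mean of per-gene mean depths over three
single-copy genes (per-gene-then-overall averaging; the pooled-positions
alternative differs only when gene lengths differ). Presence is strictly
`copy number > 1`, which ignores sub-single-copy coverage from degraded
ancient fragments. Note the consequence: a genome carrying exactly one copy
has its true value *on* the decision boundary, so its presence call flips
with sampling noise by construction; recovery checks therefore treat the
one-copy presence call as uninformative (the estimate itself is still
required to land within ±0.2 of 1).

A TE SNP is called where column depth ≥ `min_depth` (default 10 — below
that, binomial noise makes a 0.1 frequency threshold meaningless) and the
second-most-frequent base exceeds a minor allele frequency of 0.1,
strictly. Since the minor allele is the second-most frequent base,
maf ≤ 0.5 always. Positions inside the LTRs are ambiguous by construction
(the two LTR copies are near-identical, so reads from either end pile up
together and dilute allele frequencies); SNP recovery is therefore
evaluated at internal positions.

## Assembly scanning

`smith_waterman` is a full affine-gap local-alignment dynamic program
(match +1, mismatch −2, gap open −3, gap extend −1; a gap of length *L*
costs open + extend·*L*). Rows are vectorised; the within-row horizontal
gap state folds into a running prefix maximum, which is exact because with
a negative open cost a single gap always dominates any chain of gaps over
the same columns. Traceback prefers diagonal steps on score ties, so
co-optimal alignments resolve deterministically. Divergence is
100·mismatches/(match+mismatch columns) — gap columns excluded, which
matters for the strict <10% filter and is stated for that reason.

`scan_assembly` finds candidate loci by exact 13-mer seeding (clusters
merged within 400 nt — at 10% divergence, seed gaps above ~200 nt are
vanishingly rare), then resolves each locus with the full DP on a ±300 nt
padded window; for targets no larger than one window the scan therefore
reduces to the exact optimum. Same-strand hits within 100 nt are chained
(young elements are reported fragmented around indels): the chain keeps
the best component's score, unions the spans, and length-weights the
divergence. Chained hits scoring below 50 are discarded as seed-level
noise (a chance k-mer match in unrelated sequence never extends that far).
Insertion counting then applies the strict filters — aligned genomic
length > 750 nt AND divergence < 10% — whereas the similarity statistic
*s* = best score/max best score is computed from unfiltered best hits, as
it measures relatedness, not countable insertions. Full-length
classification requires > 80% of the consensus covered and ≥ 80% of each
LTR interval inside the consensus span.

Genic context gives promoters precedence: an insertion within 1 kb
upstream of a transcription start site (strand-aware) is a promoter
insertion; otherwise the innermost overlapping feature wins (UTR over exon
over intron), and no overlap is intergenic.

Trap-model accounting counts hits overlapping a piRNA-cluster interval by
≥ 1 bp: exactly one insertion is `consistent` with the trap model, zero is
`pre_trap`, two or more `multi`. Across strains, cluster insertions are
the same event iff the ordered TE names within 2 kb of the site match on
at least one flank; counting is by transitive closure, and empty flank
signatures never merge strains (absence of annotation is not evidence of
synteny).

The horizontal-transfer divergence test is deliberately stark: HT is
`supported` iff the between-species TE identity strictly exceeds the
*maximum* of ≥ 10 host ortholog identities, with the margin reported.
Requiring the maximum (not the mean) makes the test conservative.

## piRNA profiles

The adaptor (default `GAATTCTCGGGTGCCAAGG`) is removed at its first
occurrence allowing one mismatch; reads outside 18–35 nt are dropped.
Mapping is full-length with at most one mismatch (pigeonhole over read
halves, both strands); a read's best matches within the TE share weight
1/n. An antisense read's 5′ end is the rightmost coordinate of its matched
interval.

The overlap histogram counts weighted sense/antisense pairs by 5′–5′
distance o ∈ 1..20, in both arrangements (whichever strand carries the
upstream 5′ end), which makes the histogram symmetric in the strand
labels; genuine ping-pong pairs populate the antisense-downstream
arrangement at o = 10. z10 standardises the o = 10 count against the
sample mean and s.d. (ddof = 1) of bins {1..9, 11..20} and is undefined
when reads map to a single strand or the background s.d. is zero. Under a
uniform-5′-end null at the default pool size the |z10| < 2 rate is ~99%.

## Invasion windows and the cascade

A window is data-defined: last absent year before the first present year,
and the first present year, using presence = copy number > 1. A present
strain is a contamination-style outlier iff the next-oldest present strain
is more than 10 years later *and* at least two absent strains fall in
between — both knobs configurable; the rule is this package's
formalisation of a judgement the motivating analyses made narratively.
Windows from sparse sampling are wide; they bracket, not date, the
invasion.

Co-occurrence of two TEs is the concordance of presence states plus a
two-sided Fisher exact p (scipy), which the tests verify against exhaustive
hypergeometric enumeration for all 2×2 tables with n ≤ 20. Shared TE SNPs
intersect consensus coordinates by default; requiring the same minor allele
is available as a stricter option.

Cascade reconstruction is a transparent rule engine, not an optimiser.
For each TE, every invaded species is linked to the contact-connected
invaded donor with the earliest first-present year not later than its own;
candidate donors sharing > 1 TE SNP outrank hybridization contacts, which
outrank range overlap (> 1 shared segregating variant implies transfer of
multiple TE copies — hybridization-compatible — while one or zero implies
a single-founder horizontal transfer). Edges record which evidence fired
(`time_order`, `contact`, `hybridization`, `shared_snps`); recipients with
no eligible donor are returned as unresolved, which is the expected
outcome for cascade roots whose donors were never sampled. Exact
first-present ties emit both orderings without `time_order`, leaving the
ambiguity visible.

## Problem sizes

The default study conditions use a 2 kb synthetic LTR element (300 nt
LTRs), three 2 kb single-copy genes, 100 kb genomes (250 kb for the
50-copy SNP design), depth 30–50, piRNA pools of 20,000 reads, and 100
replicate cohorts with three pre- and three post-invasion samples — sizes
at which every recovery property is measurable with comfortable margins
while the full suite runs in well under a minute per module.

## Known limitations

- The scanner resolves one insertion per seeded window; two copies closer
  than ~400 nt merge into one reported locus (the generator's spacing floor
  keeps this out of the tests, and tandem arrays are rare for young
  elements, but real nested insertions would need a segmented traceback).
- The mapper has no mapping-quality model and assigns multi-mapping reads
  to a single best hit; within-family ambiguity (e.g., LTR positions)
  shows up as coordinate-level dilution, not as flagged uncertainty.
- Divergence dating is not attempted: windows come from sampling years
  only, and the cascade engine ranks donors by rule, without a likelihood.
- The HT divergence test takes identities as given; it does not model
  alignment uncertainty in them.
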