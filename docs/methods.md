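# Methods

## The mapping problem

A recessive mutant allele segregating in a selfed family from a heterozygous
parent appears in 1/4 of progeny (3:1 phenotype ratio). Pooling
mutant-phenotype plants into one sequenced bulk and wildtype-phenotype plants
into another turns linkage into allele frequency: at the causal locus the
mutant bulk is fixed for the mutant allele (expected alternate-read fraction
f = 1), while the wildtype bulk contains it only through carriers. With `h`
known heterozygotes among `n` pooled wildtype plants, each contributing the
allele at half dose, f = h/(2n); with unknown composition, 2/3 of phenotypic
wildtypes are carriers, so f = (2/3)(1/2) = 1/3. Everywhere else, variants
are either shared between bulks, private artifacts, or unlinked segregating
background — none of which matches both expectations simultaneously.

`bvf` automates this logic in four stages over two per-bulk VCFs:

1. **Hard filtering** (`prioritize.hard_filter`): retain calls with
   `dp >= min_dp` (default 6), `gq >= min_gq` (0), `qd >= min_qd` (2), and a
   major-allele balance of at least `min_ab` (0.8). The allele-balance rule is
   deliberately one-sided: balanced heterozygous calls fail, strongly skewed
   or homozygous-support calls pass. This is what removes a causal allele
   observed in ~1/4 of wildtype-bulk reads from the *wildtype call set* while
   keeping it in the mutant one — the asymmetry that lets bulk subtraction
   work. The semantics are documented here precisely because they control
   that behaviour; `min_ab` is configurable.
2. **Consequence restriction** (`prioritize.consequence_filter`): keep
   variants with at least one missense or frameshift annotation (both the
   machine dialect `missense_variant` and the human-readable
   `missense variation` are accepted, case-insensitively).
3. **Bulk subtraction** (`prioritize.bulk_subtract`): drop calls shared
   between the bulks by identity key (chrom, pos, ref, alt). "Presence"
   means a *passing filtered call*, not read-level support; read evidence is
   consulted only in the next stage. The partition is exact:
   |specific| + |common| = |bulk|.
4. **Segregation-consistency scoring** (`prioritize.score_candidates`): for
   each mutant-specific candidate, test the mutant-bulk allele depths
   against f = 1 and the wildtype-bulk depths against the design-predicted
   fraction with an exact two-sided binomial test, and combine:
   `combined = -2 (ln p_mut + ln p_wt)` (Fisher's method; smaller = more
   consistent; both p-values are also reported separately). Candidates whose
   mutant-bulk alternate fraction falls below a hard floor (default 0.9,
   tolerating error reads) cannot be homozygous in the mutant bulk and are
   flagged `incompatible`; they rank after all unflagged candidates.
   Remaining ties break by effect severity (frameshift > stop gain >
   missense) and then genomic order, so output order is deterministic.

The two-sided binomial p-value uses the minimum-likelihood summation
definition (sum of all outcome probabilities no larger than the observed
one), which is well defined for asymmetric expectations; `scipy`'s
`binomtest` implements exactly this and is cross-checked against exhaustive
enumeration in the test suite. Expected fractions are clamped to
`[error_rate, 1 - error_rate]` (default 0.01) so nominal expectations of 0
or 1 still tolerate sequencing-error reads and never produce p = 0.
Zero-depth sites carry no evidence: the candidate is reported unranked with
status `no-evidence` rather than given a fabricated p-value.

A per-site SNP-index (alt fraction) with a sliding-window mean is provided
as a comparison statistic, and an IGV batch script (`new` / `genome` /
`snapshotDirectory` / `goto` / `snapshot`) is emitted for visual review of
ranked candidates.

## Segregation tests

`mendel.chisq_segregation` is the Pearson goodness-of-fit statistic against
an arbitrary two-class ratio (default 3:1), df = 1, without Yates continuity
correction by default (the correction is available via a flag; practice for
3:1 tests varies and the uncorrected statistic is the common default). The
test size is asymptotic: for discrete counts at small family sizes the exact
size deviates from the nominal level (e.g. 0.041 at n = 200), which is a
property of the Pearson test, not of the implementation; the calibration
test therefore uses large null families (n = 2000, exact size 0.0528) and
compares the empirical rejection rate to the exact size computed by binomial
enumeration.

## Deletion scanning

A homozygous multi-gene deletion leaves near-zero aligned coverage (DNA) and
zero expression for the genes inside it (RNA). `svscan.detect_deletions`
calls maximal runs of coverage windows at or below `zero_threshold`
(default 2 reads, absolute — stray mis-mapped reads occur in practice),
merging runs separated by at most `max_gap` bases (default 2 kb, about two
windows: bridges isolated mis-mapping windows without joining distinct
events) and keeping runs spanning at least `min_length` (default 50 kb,
suppressing single-window dropouts). Boundaries are reported at window
resolution; no split-read refinement is attempted, since the input is a
windowed track. `svscan.deleted_genes_from_expression` applies the same idea
to a gene-level expression table: runs of at least `min_run` (default 3)
consecutive genes at or below 0.1 expression units become calls. A gene
missing from the table carries no evidence and conservatively breaks the
run. Gene lists collapse splice-variant suffixes (`.N`) to primary loci, and
`count_locus_id_range` reproduces the count arithmetic of stride-numbered
locus identifiers.

## Coding-consequence prediction

`cdsfx` maps a variant from genomic to CDS coordinates through the gene
model (reverse-complementing on the minus strand), applies the edit, and
translates both alleles with the standard nuclear code. Protein length
counts residues before the first in-frame stop, excluding the stop codon
(a 1734 bp CDS encodes 1734/3 − 1 = 577 residues). Classification: a length
change not divisible by 3 is a frameshift; otherwise the stop structure
decides (earlier stop than the in-frame length change explains → stop gain;
destroyed stop or run-off → stop loss; altered protein → missense). Only
the primary transcript per gene is modelled; variants outside the CDS
report `non-coding`, and edits whose reference span crosses a CDS/intron
boundary are rejected rather than guessed at, since their transcript-level
effect needs a splicing model. A mutant CDS with no stop is flagged
`no-stop` rather than silently truncated.

The worked truncation example uses a synthetic 1734 bp ORF
(`simbulk.synthetic_truncation_cds`) engineered so that a 4 bp deletion in
its distal third puts the first shifted-frame stop at codon 381, giving a
380-residue product, 197 residues short of the 577-residue wildtype — the
structural shape of a frameshift that removes a third of a protein. It is a
construct, not a real gene.

## The synthetic-data generator

`simbulk` emulates the full experiment: progeny genotypes drawn from selfed
1:2:1 proportions; bulks of 4 mutant and 6 wildtype-phenotype plants with 3
known heterozygotes (fixable or drawn conditional on phenotype); a 2 Mb
single-chromosome genome carrying 200 three-exon genes with valid ORFs;
1,000 background variants of which half are shared between bulks; per-site,
per-bulk depth ~ Poisson(30) and alternate reads ~ Binomial(depth, f'),
where f' = f(1 − e) + (1 − f)e/3 with e = 0.01 — an error read loses an
alt-supporting read with probability e but converts a reference read into
one specific alternate base only a third of the time. Background variants
are homozygous (f = 1) or segregating-heterozygous at f = 0.5 × carrier
fraction (carrier fraction uniform on [0.2, 1]), the nuisance load that
makes naive allele-frequency peak methods noisy; 5% are low-quality
artifacts (QD < 2) that exercise the hard filters. A bulk "calls" a site
when at least 2 alternate reads reach a 20% fraction, a rough model of a
caller's heterozygous sensitivity; full read evidence at every site is kept
in a separate table, standing in for read-level inspection of candidate
loci. The deletion scenario (`large_deletion_scenario`) zeroes the mutant bulk's
coverage (residual Poisson(0.05) mis-mapping noise) and the expression of
genes overlapping a planted 300 kb interval.

Everything derives from one `numpy` generator stream seeded per scenario, so
identical scenarios produce byte-identical files. Default sizes run in well
under a second per experiment, which is what makes 100-experiment recovery
sweeps in the test suite cheap.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: alignment and calling artifacts beyond a scalar QD/GQ
draw, indel-realignment effects, linked background variation around the
causal locus (background sites are unlinked), multi-chromosome genomes,
GC-dependent coverage, and annotation errors (effect labels for background
variants are drawn from a configured mix rather than derived from sequence;
the causal variant's annotation is consistent by construction, and the
consequence module verifies it independently from genome + gene model).

## Numerical and design choices

* Coordinates: VCF/GFF3 are 1-based inclusive, bedGraph 0-based half-open;
  all internal interval math is 0-based half-open, converted at I/O.
* Multi-allelic records are decomposed per alternate allele, never dropped;
  indels are consumed as given (no left-alignment — the tool operates on
  caller output as-is).
* Absent GQ/QD fields pass their thresholds (permissive, logged), matching
  the permissive intent of a zero GQ threshold; absent depth fails any
  positive depth threshold.
* INFO floats are stored in single precision by htslib; QD is rounded to
  4 decimals on read so records round-trip exactly.
* Recovery expectations are stochastic: across 100 simulated experiments at
  the default conditions the planted frameshift ranks first in ≥ 95 and the
  planted deletion is recovered within one window width on each boundary in
  all of them. The residual causal-ranking failures are binomial tails (a
  wildtype-bulk draw near 0.5, or a decoy locus drawing a spurious
  error read or two at low depth), not systematic biases.

## Known limitations

Single-gene recessive inheritance from a selfed heterozygous parent only;
no distorted-segregation or multi-locus models. One sample per VCF (with a
named-sample selector for multi-sample files). No BAM-level evidence, no
split-read SV refinement, no re-annotation of variants. The predicted
wildtype-bulk fraction and the observed read ratio are both reported; the
tool does not attempt to reconcile disagreements between them.
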