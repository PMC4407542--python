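# Methods

This document describes the typing method implemented by `hlacall`, stage by
stage, together with the reasoning behind each threshold and rule.

## Problem setting

HLA genes are the most polymorphic loci in the human genome and sit among
near-identical paralogs and pseudogenes. Aligning short reads to a single
reference haplotype biases read recovery toward reference-like alleles and
misassigns paralog reads, so a caller built on one reference both loses true
signal and gains false signal. `hlacall` instead types against the full known
allele repertoire and demands *exact* sequence agreement at every step after
mapping: assembly is zero-mismatch, and allele matching is exact over the
exons that define each allele.

## Reference databases (`refdb`)

Three structures are derived from the input allele set.

**Composite reference panel (CRP).** For every allele of every targeted gene
and every listed confounding paralog, each *key exon* is emitted as a panel
entry flanked by up to 50 bp of adjoining intron. Key exons are the
peptide-binding exons that define typing resolution: exons 2, 3 and 4 for
class I genes, exons 2 and 3 for class II genes. Flanks let reads that
straddle an exon boundary map with their intronic overhang instead of being
penalized for it; alleles recorded without introns borrow flanks from a
same-gene sibling that has them. Panel entries carry a *target* or
*competitor* role; competitor entries exist solely to absorb paralog reads.

**Major-exon database (mDB).** Alleles identical across their major exons
(class I: exons 2 and 3; class II: exon 2) cannot be distinguished by those
exons and are collapsed into a single group entry. The group's label is the
lexicographically smallest member name truncated to three colon-fields with a
`G` suffix; ungrouped alleles keep their full name. Typing initially reports
at this resolution, which is exactly the resolution the major exons support.

**Minor-exon database (aDB).** For grouped alleles only, the minor exons
(class I: exon 4; class II: exon 3) are kept per member. When contigs cover a
group's minor exons, members whose minor exons contradict the assembled
sequence are eliminated; if the surviving members agree on a longer name
prefix, the call is upgraded to that higher resolution.

## Read classification (`classify`)

Every read is mapped against the whole panel with a banded, affine-gap
aligner (match +1, mismatch −1, gap open −3, extend −1) seeded by exact
15-mers on both strands; a hit requires a score of at least 0.6 × read
length. Binning rules:

- A read whose best hits include a *perfect* match to exactly one gene is
  binned to that gene (or absorbed if the gene is a competitor).
- A read perfectly matching two or more different genes is **excluded as
  ambiguous** — between near-identical paralogs, a guess would corrupt the
  downstream assembly of both genes.
- Otherwise the read is binned to every target gene tied for its best score,
  oriented to the panel strand of its best hit.

Every read ends in exactly one of four ledgers — binned, ambiguous-excluded,
competitor-absorbed, unmapped — so read counts are conserved by
construction, and the report asserts it per run.

## Contig assembly (`assemble`)

Each gene's bin is assembled independently under a zero-mismatch rule: a
read joins a contig only by perfect overlap agreement (minimum overlap
20 bp), and consensus is never voted base-by-base from conflicting reads.
Contigs are grown base by base from a seed read, rightward and then leftward
(via reverse complement):

- **Corroboration ≥ 3.** An extension base is eligible only if the k-mer it
  completes occurs at least three times in the bin. A threshold of two is
  defeated by two reads that happen to share the same sequencing error; at
  the design coverage (≈30× per haplotype) requiring three loses nothing.
- **Longest-overlap arbitration.** Among eligible alternatives, the base
  supported by the read with the longest perfect overlap with the contig
  end wins.
- **Divergence anchoring.** At a site with two or more corroborated
  alternatives (a heterozygous site), only reads anchored across the
  *previous* divergent site may decide — such a read provably continues the
  contig's own haplotype. If no read reaches back that far, growth stops:
  a shorter, correct contig is strictly better than a chimera that welds
  the two haplotypes, and the unused reads assemble into their own contig.
- Reads wholly contained in a finished contig are absorbed into its depth
  profile; a contig is split wherever its per-base depth reaches zero; and
  contigs with mean depth below 5× are discarded as error artifacts.

Variants farther apart than a read length cannot be phased by any assembler;
those cases are detected and reported downstream (phase ambiguity) rather
than resolved by guessing.

## Allele matching and scoring (`calling`)

Each contig is compared against each database exon by diagonal
anchor-and-extend matching. A match is a perfect (zero-mismatch) shared
block of at least the minimum overlap, with unmatched contig overhang on
either side tolerated up to *flank + intrusion* bases, where intrusion =
read-length × (1 − 0.6)/2: a read passes the mapper with up to that many
bases outside the panel window, so assembled contigs legitimately overhang
the exon by the flank plus that intrusion. Any larger unmatched overhang
means a real sequence conflict and the match is rejected.

Each matching contig contributes `length × mean depth × exonic fraction` to
an allele's score; a contig counts once per allele (at its best placement),
and a contig shared by several alleles counts for each. Designation walks
the ranked scores: the top allele is designated, and a second allele is
designated if its contigs are not wholly explained by the first. Additional
distinct candidates beyond two are flagged for review (possible
contamination). High-depth contigs that match nothing are reported as
potential novel alleles rather than silently dropped.

**Homozygote gate.** A single consistent designation is reported homozygous
only when the gene's coverage passed QC *without* the below-20× warning. A
dropout-induced false homozygote is indistinguishable from a true homozygote
by content, but dropout implies the lost haplotype's coverage was too thin
to assemble — which the warning detects, since each haplotype of a
heterozygote sees roughly half the gene's depth. On warned coverage the call
becomes a possible-dropout no-call: accuracy may degrade only through
ambiguity or no-calls, never through a wrong confident call.

## Phase ambiguity and tie-breaking

For a two-allele call, the heterozygous positions of the pair are split into
blocks separated by identical runs longer than the read length. No read can
bridge such a run (nor the gap between two exons), so every complementary
re-assignment of blocks between the two haplotypes is equally consistent
with the data. All resulting pairs whose haplotypes exist in the database
are enumerated; if more than one pair survives, the call is flagged
phase-ambiguous, all alternatives are listed, and the *reported* pair is the
one preferred by population frequency (highest combined frequency, then
highest single-allele frequency, then lexicographic order; a group's
frequency is the sum over its members). Frequencies never override sequence
evidence — they only order pairs the sequence data cannot distinguish.

## Coverage QC (`qc`)

Per gene, reads are placed on the key exons of the best-supported allele and
per-position depth is profiled. Tiers, from strictest to weakest:

| tier | requirement |
|---|---|
| `10x=100% & 20x>=98%` | every position ≥ 10× and ≥ 98% of positions ≥ 20× |
| `10x=100% & 20x>=90%` | every position ≥ 10× and ≥ 90% of positions ≥ 20× |
| `10x>=95%` | ≥ 95% of positions ≥ 10× |
| `fail` | below all of the above |

"Every position ≥ 10×" is evaluated on the minimum depth, not a rounded
fraction. Independently, a **warning** is raised when more than 2% of
positions fall below 20× — the condition that gates homozygote reporting —
and a mean depth below 30× adds a recommendation to sequence deeper. Typed
results at the strict tier are full-confidence; lower tiers signal that
ambiguity or no-calls may occur.

## Simulation (`simulate`)

The mock panel generator and read simulator exist so the whole method is
testable end to end with known truth. The generator plants class I and
class II target genes (random exon/intron scaffolds, 250–300 bp key exons),
per-gene allele families with jittered-grid substitutions that bound
identical runs between alleles, allele groups sharing major exons but
differing on a minor exon, diverged paralogs, a fraction of intron-less
records (to exercise flank borrowing), and Dirichlet-distributed allele
frequencies. The read simulator draws Poisson read counts per haplotype
(mean interior depth 2 × balance × coverage), uniform start positions over
donor-flanked key exons (exome mode) or whole gene sequences (genome mode),
random strands, and independent per-base substitution errors. Heterozygous
genotypes are rejection-sampled to keep identical runs between the two
haplotypes comfortably below the read length, so simulated truth is
phase-recoverable unless a test asks otherwise. Everything is deterministic
in the configuration seed.

## Evaluation (`evaluate`)

Calls are scored against simulated truth at four-digit-equivalent
resolution: a reported group label stands for exactly its member alleles,
any other label stands for itself, and each truth allele is matched under
the best assignment of the reported pair. The acceptance script
(`scripts/acceptance.py`) simulates 30 exome samples at the default scale,
types them against a shared panel, and reports the percentage of correctly
typed alleles over genes meeting the strict coverage tier.
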