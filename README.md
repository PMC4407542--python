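# hlacall

Targeted HLA genotyping from short sequencing reads by gene-specific read
classification, zero-mismatch contig assembly and exact exon matching against
an allele database.

The caller works from standard exome or whole-genome FASTQ data. Instead of
aligning reads to a single reference haplotype — which systematically loses
reads from alleles that diverge from that reference — it maps every read
against a *composite reference panel* holding the flanked key exons of every
known allele of every targeted gene, plus the corresponding regions of
confounding paralogous genes. Reads that fit a paralog as well as a target
gene are excluded rather than guessed. The reads binned to each gene are then
assembled into haplotype contigs under a zero-mismatch overlap rule, matched
exactly against the exon database, scored, and reported as an allele pair
with coverage-based quality tiers, phase-ambiguity enumeration and
population-frequency tie-breaking.

## Quick start

```sh
# simulate a sample against a generated mock allele panel
hlacall simulate --out-dir sim --seed 7

# build the typing databases from a segmented allele FASTA
hlacall build-db sim/alleles.fasta --out-dir db

# type a sample
hlacall type sim/reads.fastq \
    --alleles sim/alleles.fasta \
    --frequencies sim/frequencies.tsv \
    --out-dir typed \
    -c HLA-SP1 -c HLA-SP2        # confounding paralogs to absorb

# coverage QC only
hlacall qc sim/reads.fastq --alleles sim/alleles.fasta --out qc.json
```

`hlacall type` writes `report.json` (full evidence trail: designated pair,
resolution, QC tier, phase alternatives, score trace, novel-contig notes) and
`report.tsv` (one row per gene). Exit status 2 signals that at least one gene
could not be called.

The same pipeline is available in-process:

```python
from hlacall import PipelineConfig, run_pipeline

cfg = PipelineConfig(allele_set="sim/alleles.fasta",
                     fastq=["sim/reads.fastq"],
                     competitor_genes=["HLA-SP1", "HLA-SP2"])
result = run_pipeline(cfg)
print({g: c.reported_pair for g, c in result.calls.items()})
```

## Input formats

- **Allele set** — FASTA of genomic allele sequences with segmented headers
  (`>HLA-A*01:01:01 exon2|intron2|exon3|...` style; see
  `hlacall.refdb.parse_allele_set`), or a sequence FASTA plus a segment
  sidecar table.
- **Reads** — FASTQ, single-end or interleaved pairs; exome or whole-genome.
- **Frequencies** — optional two-column TSV (`allele<Tab>frequency`) used
  only to order otherwise-equivalent reported pairs.

## How it works

1. **Databases** (`refdb`): from the allele set, build the composite
   reference panel (key exons ± 50 bp intron flanks), a major-exon exact
   database in which alleles identical across the major exons collapse into
   one group, and a minor-exon database used to resolve those groups.
2. **Classification** (`classify`): map each read to the panel; bin by gene,
   absorb paralog reads, exclude reads that are perfect matches to two
   different genes. Read counts are conserved by construction.
3. **Assembly** (`assemble`): per gene, extend contigs base by base; an
   extension must be corroborated by at least three reads, and at sites
   where two corroborated alternatives diverge only reads anchored across
   the previous divergent site may decide — otherwise growth stops, keeping
   haplotypes separate.
4. **Typing** (`calling`): match contigs exactly to the major-exon database,
   score candidates by matched length × depth × exonic fraction, designate
   up to two alleles, resolve grouped alleles with minor-exon evidence,
   enumerate phase-consistent alternative pairs, and break ties by
   population frequency.
5. **QC** (`qc`): per-gene coverage tiers with a warning when more than 2%
   of positions fall below 20×; homozygous calls require warning-free
   coverage, so allele dropout yields a no-call instead of a confident
   error.

See `docs/methods.md` for the full method description and the reasoning
behind each rule.

## Development

```sh
pip install --no-build-isolation -e ".[test]"
pytest                                   # unit + acceptance suite
python scripts/acceptance.py --seed 1 --out acceptance.json
```

`hlacall.simulate` generates the mock allele panels and reads (exome or
whole-genome, with planted allele groups, paralogs and sequencing errors)
that the test-suite and the acceptance script run against; every run is
deterministic in its seed.
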