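"""Read classification: map raw reads against the CRP and bin them by gene.

The binning rule follows the method's ambiguity handling:

* a read with perfect (full-length, zero-mismatch) hits in two or more
  distinct genes is *excluded* as ambiguous — this is the paralog guard
  (e.g. DRB1 vs DRB5 in real data);
* a read with perfect hits in exactly one gene is binned there;
* a read with no perfect hit anywhere is binned into every gene that
  reaches its best (imperfect) alignment score — that level of similarity
  is expected between HLA alleles and such reads are retained;
* reads whose hits are confined to competitor genes are absorbed and never
  reach a target bin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .mapper import MappingParams, PanelIndex, revcomp
from .refdb import CRPEntry


@dataclass
class Read:
    """One sequencing read."""

    id: str
    sequence: str
    qualities: str | None = None
    mate: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass
class ReadBin:
    """Reads classified to one gene, oriented to the reference strand."""

    gene: str
    reads: list[Read] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ClassificationStats:
    total: int = 0
    binned: int = 0
    ambiguous_excluded: int = 0
    unmapped: int = 0
    competitor_absorbed: int = 0
    too_short: int = 0  # subset of unmapped
    per_gene: Counter = field(default_factory=Counter)
    # (gene, source allele label) -> reads whose best hit in that gene came
    # from that allele; used downstream to pick a QC reference
    allele_support: Counter = field(default_factory=Counter)

    def conserved(self) -> bool:
        return (
            self.binned
            + self.ambiguous_excluded
            + self.unmapped
            + self.competitor_absorbed
            == self.total
        )


def classify_reads(
    reads: Iterable[Read],
    panel: Sequence[CRPEntry] | PanelIndex,
    params: MappingParams | None = None,
    target_genes: set[str] | None = None,
) -> tuple[dict[str, ReadBin], ClassificationStats]:
    """Bin reads by gene with ambiguity exclusion.

    ``panel`` may be a prebuilt :class:`PanelIndex` (reuse it across samples;
    building the index is the expensive part).
    """
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel, params)
    if target_genes is None:
        target_genes = {e.gene for e in index.entries if e.role == "target"}

    bins: dict[str, ReadBin] = {}
    stats = ClassificationStats()
    warned_before = index.short_read_warnings
    for read in reads:
        stats.total += 1
        hits = index.map_read(read)
        if not hits:
            stats.unmapped += 1
            continue
        perfect_genes = sorted({h.entry.gene for h in hits if h.perfect})
        if len(perfect_genes) >= 2:
            stats.ambiguous_excluded += 1
            continue
        if len(perfect_genes) == 1:
            gene = perfect_genes[0]
            if gene not in target_genes:
                stats.competitor_absorbed += 1
                continue
            dest = [gene]
        else:
            genes = {h.entry.gene for h in hits}  # all hits share the best score
            dest = sorted(genes & target_genes)
            if not dest:
                stats.competitor_absorbed += 1
                continue
        stats.binned += 1
        for gene in dest:
            gene_hits = [h for h in hits if h.entry.gene == gene]
            top = max(gene_hits, key=lambda h: (h.score, h.strand == "+"))
            oriented = read if top.strand == "+" else _flip(read)
            bins.setdefault(gene, ReadBin(gene)).reads.append(oriented)
            stats.per_gene[gene] += 1
            stats.allele_support[(gene, top.entry.source_allele)] += 1
    stats.too_short = index.short_read_warnings - warned_before
    return bins, stats


def _flip(read: Read) -> Read:
    return Read(
        id=read.id,
        sequence=revcomp(read.sequence),
        qualities=read.qualities[::-1] if read.qualities else None,
        mate=read.mate,
    )


def best_supported_allele(stats: ClassificationStats, gene: str) -> str | None:
    """Source allele that recruited the most reads of a gene (QC reference)."""
    items = [(n, lab) for (g, lab), n in stats.allele_support.items() if g == gene]
    if not items:
        return None
    items.sort(key=lambda t: (-t[0], t[1]))
    return items[0][1]
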