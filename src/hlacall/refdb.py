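"""Allele reference set parsing and construction of the three typing databases.

The typing method needs three views of the known-allele set:

* the **comprehensive reference panel (CRP)** used only for read mapping:
  every targeted exon of every allele with up to 50 bp of flanking intron
  sequence appended on each side, plus all alleles of a set of *competitor*
  genes whose sole job is to absorb reads from close paralogs;
* the **major database (mDB)** of exact major-exon sequences (exons 2 and 3
  for class I genes, exon 2 for class II genes), with alleles that are
  identical across the major exons collapsed into a G-group;
* the **additional database (aDB)** of minor-exon sequences (exon 4 for
  class I, exon 3 for class II) for every member of every G-group, used to
  push a G-group call to six-digit resolution.

The input dialect is documented in :func:`parse_allele_set`.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

DNA_RE = re.compile(r"^[ACGT]+$")

CLASS_I_MAJOR_EXONS = (2, 3)
CLASS_I_MINOR_EXONS = (4,)
CLASS_II_MAJOR_EXONS = (2,)
CLASS_II_MINOR_EXONS = (3,)


class ParseError(ValueError):
    """Raised for a malformed allele-set record."""


class IntegrityError(ValueError):
    """Raised when the allele set violates a structural invariant."""


def gene_class(gene: str, overrides: Mapping[str, int] | None = None) -> int:
    """Return 1 or 2 for an HLA gene symbol.

    Follows the HLA naming convention: class II gene symbols start with "D"
    (DRB1, DQB1, DPA1, DMA, ...), everything else (A, B, C, E, F, G, ...) is
    class I.  ``overrides`` maps gene symbols to an explicit class.
    """
    if overrides and gene in overrides:
        return overrides[gene]
    sym = gene.split("-", 1)[-1]
    return 2 if sym.startswith("D") else 1


def major_exons(gene: str, overrides: Mapping[str, int] | None = None) -> tuple[int, ...]:
    return CLASS_I_MAJOR_EXONS if gene_class(gene, overrides) == 1 else CLASS_II_MAJOR_EXONS


def minor_exons(gene: str, overrides: Mapping[str, int] | None = None) -> tuple[int, ...]:
    return CLASS_I_MINOR_EXONS if gene_class(gene, overrides) == 1 else CLASS_II_MINOR_EXONS


def targeted_exons(gene: str, overrides: Mapping[str, int] | None = None) -> tuple[int, ...]:
    """All exons a gene is typed and mapped on (major plus minor)."""
    return tuple(sorted(major_exons(gene, overrides) + minor_exons(gene, overrides)))


@dataclass(frozen=True)
class Segment:
    """One annotated exon or intron of an allele."""

    kind: str  # "exon" | "intron"
    index: int
    sequence: str

    def __post_init__(self) -> None:
        if self.kind not in ("exon", "intron"):
            raise ParseError(f"segment kind must be exon|intron, got {self.kind!r}")
        if self.index < 1:
            raise ParseError(f"segment index must be positive, got {self.index}")
        if not self.sequence or not DNA_RE.match(self.sequence):
            raise ParseError(
                f"{self.kind}{self.index}: sequence must be non-empty uppercase DNA"
            )


@dataclass
class AlleleRecord:
    """One named allele with its ordered exon/intron segments.

    ``name`` is the colon-delimited designation without the gene symbol
    (e.g. ``"02:01:01"``); the full label is ``gene + "*" + name``.
    """

    gene: str
    name: str
    segments: list[Segment]
    frequency: float | None = None

    def __post_init__(self) -> None:
        exo = [s.index for s in self.segments if s.kind == "exon"]
        if any(b <= a for a, b in zip(exo, exo[1:])):
            raise IntegrityError(
                f"{self.label}: exon indices must be strictly increasing, got {exo}"
            )
        if self.frequency is not None and not 0.0 <= self.frequency <= 1.0:
            raise IntegrityError(f"{self.label}: frequency outside [0,1]")

    @property
    def label(self) -> str:
        return f"{self.gene}*{self.name}"

    def exon(self, index: int) -> str | None:
        for s in self.segments:
            if s.kind == "exon" and s.index == index:
                return s.sequence
        return None

    def intron(self, index: int) -> str | None:
        for s in self.segments:
            if s.kind == "intron" and s.index == index:
                return s.sequence
        return None

    @property
    def exons(self) -> dict[int, str]:
        return {s.index: s.sequence for s in self.segments if s.kind == "exon"}

    @property
    def has_introns(self) -> bool:
        return any(s.kind == "intron" for s in self.segments)

    def full_sequence(self) -> str:
        """Segments concatenated in genomic order (introns interleaved)."""
        return "".join(s.sequence for s in sorted(self.segments, key=_genomic_key))


def _genomic_key(seg: Segment) -> tuple[int, int]:
    # intron i precedes exon i+1; within an index, intron before exon of the
    # same number would be wrong (intron i follows exon i), so order by
    # (index, kind) with exon first.
    return (seg.index, 0 if seg.kind == "exon" else 1)


_SEG_ID_RE = re.compile(r"^(?P<gene>[^*]+)\*(?P<name>[^|]+)\|segkind=(?P<kind>exon|intron)(?P<idx>\d+)$")


def parse_allele_set(path: str | Path) -> list[AlleleRecord]:
    """Parse an allele reference set.

    Two dialects are auto-detected:

    1. *segmented FASTA*: one record per segment with ids of the form
       ``GENE*NAME|segkind=exon2``;
    2. *FASTA + sidecar TSV*: one FASTA record per allele (id ``GENE*NAME``,
       full sequence) plus ``<path>.segments.tsv`` with columns
       ``allele  gene  segment  start  end`` (0-based half-open), where
       ``segment`` is e.g. ``exon2`` or ``intron1``.

    Records with no intron segments are returned with introns absent; the
    CRP builder borrows their flanks from a same-gene allele later.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar = Path(str(path) + ".segments.tsv")
    if sidecar.exists():
        return _parse_sidecar_dialect(path, sidecar)
    return _parse_segmented_fasta(path)


def _parse_segmented_fasta(path: Path) -> list[AlleleRecord]:
    segments: dict[tuple[str, str], list[Segment]] = {}
    order: list[tuple[str, str]] = []
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        m = _SEG_ID_RE.match(rec.id)
        if not m:
            raise ParseError(
                f"{path}: record #{n} ({rec.id!r}) does not match "
                "'GENE*NAME|segkind=<exon|intron><i>'"
            )
        seq = str(rec.seq).upper()
        try:
            seg = Segment(m["kind"], int(m["idx"]), seq)
        except ParseError as exc:
            raise ParseError(f"{path}: record #{n} ({rec.id!r}): {exc}") from exc
        key = (m["gene"], m["name"])
        if key not in segments:
            segments[key] = []
            order.append(key)
        if any(s.kind == seg.kind and s.index == seg.index for s in segments[key]):
            raise IntegrityError(
                f"{path}: duplicate segment {seg.kind}{seg.index} for allele "
                f"{key[0]}*{key[1]} (record #{n})"
            )
        segments[key].append(seg)
    return [_make_record(g, a, segs) for (g, a), segs in ((k, segments[k]) for k in order)]


def _parse_sidecar_dialect(path: Path, sidecar: Path) -> list[AlleleRecord]:
    import pandas as pd

    seqs: dict[str, str] = {}
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in seqs:
            raise IntegrityError(f"{path}: duplicate allele record {rec.id!r} (record #{n})")
        seqs[rec.id] = str(rec.seq).upper()
    tab = pd.read_csv(
        sidecar, sep="\t", header=None,
        names=["allele", "gene", "segment", "start", "end"],
    )
    seg_re = re.compile(r"^(exon|intron)(\d+)$")
    segments: dict[tuple[str, str], list[Segment]] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(tab.itertuples(index=False), start=1):
        if row.allele not in seqs:
            raise ParseError(f"{sidecar}: line {i}: allele {row.allele!r} not in {path}")
        m = seg_re.match(str(row.segment))
        if not m:
            raise ParseError(f"{sidecar}: line {i}: bad segment {row.segment!r}")
        start, end = int(row.start), int(row.end)
        full = seqs[row.allele]
        if not 0 <= start < end <= len(full):
            raise ParseError(f"{sidecar}: line {i}: span [{start},{end}) outside record")
        key = (str(row.gene), str(row.allele).split("*", 1)[-1])
        if key not in segments:
            segments[key] = []
            order.append(key)
        segments[key].append(Segment(m.group(1), int(m.group(2)), full[start:end]))
    return [_make_record(g, a, segs) for (g, a), segs in ((k, segments[k]) for k in order)]


def _make_record(gene: str, name: str, segs: list[Segment]) -> AlleleRecord:
    segs = sorted(segs, key=_genomic_key)
    return AlleleRecord(gene=gene, name=name, segments=segs)


def check_unique_names(records: Sequence[AlleleRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.label in seen:
            raise IntegrityError(f"duplicate allele name {r.label}")
        seen.add(r.label)


def write_allele_set(records: Sequence[AlleleRecord], path: str | Path) -> None:
    """Write records in the segmented-FASTA dialect (round-trips with the parser)."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in records:
            for s in sorted(r.segments, key=_genomic_key):
                fh.write(f">{r.gene}*{r.name}|segkind={s.kind}{s.index}\n")
                for i in range(0, len(s.sequence), 70):
                    fh.write(s.sequence[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Comprehensive reference panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CRPEntry:
    """One flanked-exon mapping reference.

    ``sequence`` is ``left_flank + exon + right_flank`` with each flank at
    most ``flank_len`` bp of intron sequence; ``exon_span`` is the half-open
    interval of the exonic core within ``sequence``.
    """

    source_allele: str  # full label GENE*NAME
    gene: str
    role: str  # "target" | "competitor"
    sequence: str
    exon_span: tuple[int, int]
    flank_len: int
    exon_index: int

    def __post_init__(self) -> None:
        lo, hi = self.exon_span
        if not (0 <= lo <= hi <= len(self.sequence)):
            raise IntegrityError(f"{self.source_allele}: exon_span outside sequence")
        if lo > self.flank_len or len(self.sequence) - hi > self.flank_len:
            raise IntegrityError(f"{self.source_allele}: flank exceeds flank_len")

    @property
    def exon_sequence(self) -> str:
        lo, hi = self.exon_span
        return self.sequence[lo:hi]


def build_crp(
    records: Sequence[AlleleRecord],
    target_genes: Iterable[str],
    competitor_genes: Iterable[str] = (),
    flank_len: int = 50,
    class_overrides: Mapping[str, int] | None = None,
) -> list[CRPEntry]:
    """Build the mapping panel: one flanked entry per (allele, targeted exon).

    Alleles whose record lacks the flanking introns of an exon borrow them
    from the first same-gene allele (by lexicographic label) that has the
    needed intron; if no allele of the gene carries it, the entry is emitted
    with a zero-length flank on that side and a warning is logged.
    """
    targets, competitors = set(target_genes), set(competitor_genes)
    if targets & competitors:
        raise ValueError(f"genes in both roles: {sorted(targets & competitors)}")
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    check_unique_names(records)

    by_gene: dict[str, list[AlleleRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)
    for g in by_gene:
        by_gene[g].sort(key=lambda r: r.name)

    entries: list[CRPEntry] = []
    for gene in sorted(by_gene):
        if gene in targets:
            role = "target"
        elif gene in competitors:
            role = "competitor"
        else:
            continue
        siblings = by_gene[gene]
        for rec in siblings:
            for e in targeted_exons(gene, class_overrides):
                exon = rec.exon(e)
                if exon is None:
                    continue
                left = _flank(rec, siblings, e - 1, flank_len, side="left")
                right = _flank(rec, siblings, e, flank_len, side="right")
                if flank_len > 0 and (left == "" or right == ""):
                    logger.warning(
                        "%s exon %d: no intron sequence available in gene %s for "
                        "a flank; emitting zero-length flank", rec.label, e, gene
                    )
                seq = left + exon + right
                entries.append(
                    CRPEntry(
                        source_allele=rec.label,
                        gene=gene,
                        role=role,
                        sequence=seq,
                        exon_span=(len(left), len(left) + len(exon)),
                        flank_len=flank_len,
                        exon_index=e,
                    )
                )
    return entries


def _flank(
    rec: AlleleRecord,
    siblings: Sequence[AlleleRecord],
    intron_index: int,
    flank_len: int,
    side: str,
) -> str:
    if flank_len == 0 or intron_index < 1:
        return ""
    intron = rec.intron(intron_index)
    if intron is None:
        for sib in siblings:  # lexicographic order by name
            intron = sib.intron(intron_index)
            if intron is not None:
                break
    if intron is None:
        return ""
    return intron[-flank_len:] if side == "left" else intron[:flank_len]


# ---------------------------------------------------------------------------
# Exact-match databases (mDB / aDB)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExactEntry:
    label: str  # full label; G-group labels end in "G"
    exon_sequences: dict[int, str]


@dataclass
class ExactDB:
    """Exact-match allele database.

    ``tier`` is ``"major"`` (mDB: major polymorphic exons, G-collapsed) or
    ``"additional"`` (aDB: minor exons of G-group members).  ``g_members``
    maps every G-group label to its member allele labels.  No intron
    sequence and no competitor alleles are included.
    """

    tier: str
    entries: dict[str, list[ExactEntry]] = field(default_factory=dict)
    g_members: dict[str, set[str]] = field(default_factory=dict)

    def genes(self) -> list[str]:
        return sorted(self.entries)

    def labels(self, gene: str) -> list[str]:
        return [e.label for e in self.entries.get(gene, [])]

    def entry(self, label: str) -> ExactEntry | None:
        gene = label.split("*", 1)[0]
        for e in self.entries.get(gene, []):
            if e.label == label:
                return e
        return None

    def members(self, label: str) -> set[str]:
        """Member allele labels represented by ``label`` (itself if not a G-group)."""
        return set(self.g_members.get(label, {label}))

    def to_json(self) -> str:
        return json.dumps(
            {
                "tier": self.tier,
                "entries": {
                    g: [{"label": e.label, "exons": e.exon_sequences} for e in es]
                    for g, es in self.entries.items()
                },
                "g_members": {k: sorted(v) for k, v in self.g_members.items()},
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "ExactDB":
        d = json.loads(text)
        return cls(
            tier=d["tier"],
            entries={
                g: [
                    ExactEntry(e["label"], {int(k): v for k, v in e["exons"].items()})
                    for e in es
                ]
                for g, es in d["entries"].items()
            },
            g_members={k: set(v) for k, v in d["g_members"].items()},
        )


def g_group_label(gene: str, member_names: Iterable[str]) -> str:
    """IMGT-style G-group label: lexicographically smallest member name
    truncated to three colon-fields, with suffix ``G``."""
    smallest = min(member_names)
    truncated = ":".join(smallest.split(":")[:3])
    return f"{gene}*{truncated}G"


def build_exact_dbs(
    records: Sequence[AlleleRecord],
    class_overrides: Mapping[str, int] | None = None,
) -> tuple[ExactDB, ExactDB]:
    """Build (mDB, aDB) from an allele set.

    Alleles identical over all major exons of their gene collapse into one
    mDB entry; singleton alleles keep their own label.  The aDB records the
    minor-exon sequences for every member of every G-group (members with no
    minor-exon sequence are present with an empty map).
    """
    if not records:
        raise ValueError("records must be non-empty")
    check_unique_names(records)
    by_gene: dict[str, list[AlleleRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene, []).append(r)

    mdb = ExactDB(tier="major")
    adb = ExactDB(tier="additional")
    for gene in sorted(by_gene):
        majors = major_exons(gene, class_overrides)
        usable = [r for r in by_gene[gene] if all(r.exon(e) is not None for e in majors)]
        skipped = [r for r in by_gene[gene] if r not in usable]
        for r in skipped:
            logger.warning("%s: missing a major exon, excluded from mDB", r.label)
        if not usable:
            logger.warning("gene %s: no allele carries the major exons; excluded", gene)
            continue
        groups: dict[tuple[str, ...], list[AlleleRecord]] = {}
        for r in sorted(usable, key=lambda r: r.name):
            key = tuple(r.exon(e) for e in majors)  # type: ignore[misc]
            groups.setdefault(key, []).append(r)
        gene_entries: list[ExactEntry] = []
        for key, members in groups.items():
            exon_seqs = dict(zip(majors, key))
            if len(members) >= 2:
                label = g_group_label(gene, [m.name for m in members])
                mdb.g_members[label] = {m.label for m in members}
                adb.g_members[label] = {m.label for m in members}
                for m in members:
                    minor = {
                        e: m.exon(e)
                        for e in minor_exons(gene, class_overrides)
                        if m.exon(e) is not None
                    }
                    adb.entries.setdefault(gene, []).append(
                        ExactEntry(m.label, minor)  # may be empty: minor info absent
                    )
            else:
                label = members[0].label
            gene_entries.append(ExactEntry(label, exon_seqs))
        gene_entries.sort(key=lambda e: e.label)
        mdb.entries[gene] = gene_entries
        if gene in adb.entries:
            adb.entries[gene].sort(key=lambda e: e.label)
    return mdb, adb
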