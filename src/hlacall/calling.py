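"""Allele calling: match contigs to the exact databases, score candidates,
designate two alleles per gene, resolve G-groups on the minor exons, and
report phase ambiguity with frequency-based tie-breaking.

The scoring system: the score of a contig supporting a candidate allele is
``contig length (bp) x mean coverage depth x exonic fraction``; the score of
an allele supported by several contigs is the sum of its contig scores.
Candidates are walked in descending score order and designated whenever a
uniquely matching, not-yet-assigned contig supports them; a third or fourth
candidate with independent support is documented as possible contamination,
and high-depth contigs matching no known allele are documented as potential
novel alleles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .assemble import Contig
from .mapper import revcomp
from .refdb import ExactDB, major_exons

logger = logging.getLogger(__name__)

UNKNOWN_ALLELE = "unknown"

RES_FULL = "full"
RES_G_GROUP = "G-group"
RES_SIX_DIGIT = "six-digit"


@dataclass(frozen=True)
class ContigMatch:
    """A perfect exonic match between a contig and a database allele."""

    contig_id: int  # index into the contig list handed to match_contigs
    allele_label: str
    gene: str
    exon: int
    exonic_span: tuple[int, int]  # half-open, on the contig (match orientation)
    exonic_fraction: float
    strand: str  # orientation of the contig relative to the exon sequence
    contig: Contig = field(compare=False, hash=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.exonic_fraction <= 1.0:
            raise ValueError("exonic_fraction must be in (0, 1]")


@dataclass
class AlleleScore:
    allele_label: str
    contig_scores: list[tuple[int, float]]  # (contig_id, score)

    @property
    def total(self) -> float:
        return float(sum(s for _, s in self.contig_scores))


@dataclass
class QCRef:
    """Minimal view of a QC report the caller needs (duck-typed)."""

    tier: str = "fail"
    warning: bool = True


@dataclass
class TypingCall:
    """Reported allele pair for one gene with its evidence trail."""

    gene: str
    alleles: list[str] = field(default_factory=list)  # 0-2 designated labels
    resolution: list[str] = field(default_factory=list)  # per designated allele
    homozygous: bool = False
    no_call: bool = False
    phase_ambiguous: bool = False
    phase_alternatives: list[tuple[str, str]] = field(default_factory=list)
    extra_allele_contigs: list[int] = field(default_factory=list)  # contig ids
    novel_contigs: list[int] = field(default_factory=list)
    score_trace: list[tuple[str, float]] = field(default_factory=list)
    qc: object | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def reported_pair(self) -> tuple[str, ...]:
        """Allele pair as reported (homozygote repeated)."""
        if self.no_call or not self.alleles:
            return ()
        if len(self.alleles) == 1:
            return (self.alleles[0], self.alleles[0]) if self.homozygous else (self.alleles[0],)
        return tuple(self.alleles)


def label_resolution(label: str) -> str:
    return RES_G_GROUP if label.endswith("G") else RES_FULL


# ---------------------------------------------------------------------------
# Contig -> allele matching
# ---------------------------------------------------------------------------


def _overlap_match(
    contig_seq: str, exon_seq: str, min_overlap: int, flank_len: int
) -> tuple[int, int] | None:
    """Best zero-mismatch overlap placement of a contig on an exon.

    Returns the half-open exonic span on the contig, or None.  The matched
    block must be verbatim over at least ``min_overlap`` bases; up to
    ``flank_len`` contig bases per side may be left unmatched (intron flank
    overhang, or an untrusted low-coverage contig end), and they never count
    toward the exonic span.
    """
    C, E = contig_seq, exon_seq
    lc, le = len(C), len(E)
    if lc < min_overlap or le < min_overlap:
        return None
    k = min_overlap
    best: tuple[int, tuple[int, int]] | None = None  # (overlap, span)
    # anchor k-mers near the contig start (any valid block must begin within
    # flank_len of it), extend maximally along the diagonal, and accept
    # blocks leaving at most flank_len unmatched contig bases per side
    tried: dict[int, list[tuple[int, int]]] = {}  # diagonal -> blocks found
    for a in range(0, min(flank_len + k, lc - k) + 1):
        kmer = C[a : a + k]
        q = E.find(kmer)
        while q != -1:
            d = a - q
            blocks = tried.setdefault(d, [])
            if not any(lo <= a < hi for lo, hi in blocks):
                i, j = a, q
                while i > 0 and j > 0 and C[i - 1] == E[j - 1]:
                    i -= 1
                    j -= 1
                i2, j2 = a + k, q + k
                while i2 < lc and j2 < le and C[i2] == E[j2]:
                    i2 += 1
                    j2 += 1
                blocks.append((i, i2))
                blk = i2 - i
                if (
                    blk >= min_overlap
                    and i <= flank_len
                    and lc - i2 <= flank_len
                    and (best is None or blk > best[0])
                ):
                    best = (blk, (i, i2))
            q = E.find(kmer, q + 1)
    return best[1] if best is not None else None


def match_contigs(
    contigs: Sequence[Contig],
    db: ExactDB,
    gene: str,
    min_overlap: int = 20,
    flank_len: int = 50,
) -> tuple[list[ContigMatch], list[int]]:
    """Match depth-filtered contigs against one gene's database entries.

    A match requires a zero-mismatch alignment of the contig (or its reverse
    complement) to an allele exon over their overlap, with overlap >=
    ``min_overlap``; flank overhang beyond the exon ends is ignored up to
    ``flank_len`` per side.  Returns (matches, indices of unmatched contigs).
    """
    matches: list[ContigMatch] = []
    matched_ids: set[int] = set()
    for cid, contig in enumerate(contigs):
        for entry in db.entries.get(gene, []):
            for exon, eseq in sorted(entry.exon_sequences.items()):
                hit = None
                for strand, cseq in (("+", contig.sequence), ("-", revcomp(contig.sequence))):
                    span = _overlap_match(cseq, eseq, min_overlap, flank_len)
                    if span is not None:
                        hit = (strand, span)
                        break
                if hit is None:
                    continue
                strand, span = hit
                matches.append(
                    ContigMatch(
                        contig_id=cid,
                        allele_label=entry.label,
                        gene=gene,
                        exon=exon,
                        exonic_span=span,
                        exonic_fraction=(span[1] - span[0]) / len(contig),
                        strand=strand,
                        contig=contig,
                    )
                )
                matched_ids.add(cid)
    unmatched = [i for i in range(len(contigs)) if i not in matched_ids]
    return matches, unmatched


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def contig_score(contig: Contig, exonic_fraction: float) -> float:
    """Score of one contig supporting an allele."""
    return len(contig) * contig.mean_depth * exonic_fraction


def score_alleles(matches: Sequence[ContigMatch]) -> list[AlleleScore]:
    """Sum contig scores per candidate allele, sorted descending by total.

    A contig matching the same allele on several placements counts once, at
    its largest exonic fraction; a contig shared between alleles contributes
    its full score to each.  Ties in total are broken by label (population
    frequency settles any remaining tie at designation time).
    """
    per_allele: dict[str, dict[int, float]] = {}
    for m in matches:
        d = per_allele.setdefault(m.allele_label, {})
        s = contig_score(m.contig, m.exonic_fraction)
        if s > d.get(m.contig_id, -1.0):
            d[m.contig_id] = s
    scores = [
        AlleleScore(label, sorted(d.items()))
        for label, d in per_allele.items()
    ]
    scores.sort(key=lambda a: (-a.total, a.allele_label))
    return scores


# ---------------------------------------------------------------------------
# Designation
# ---------------------------------------------------------------------------


def designate_alleles(
    scores: Sequence[AlleleScore],
    matches: Sequence[ContigMatch],
    freq: Mapping[str, float] | "FrequencyTable" | None = None,
    qc: object | None = None,
    max_alleles: int = 2,
) -> TypingCall:
    """Walk candidates in descending score order and designate up to two.

    A candidate is designated when at least one of its supporting contigs is
    uniquely matched — it matches no *other not-yet-designated* candidate —
    and is not already assigned to a designated allele.  If the strict walk
    designates fewer than two alleles while unassigned matched contigs
    remain (which happens when every contig is shared, e.g. with recombinant
    candidates in the database), a relaxed second walk designates the
    highest-scoring candidates supported by any still-unassigned contig;
    phase-ambiguity reporting then enumerates the alternatives.

    With a single surviving designation consistent with every matched contig
    the gene is reported homozygous, provided coverage QC passed without the
    below-20x warning; otherwise it becomes a possible allele-dropout
    no-call.
    """
    gene = matches[0].gene if matches else ""
    call = TypingCall(gene=gene, qc=qc)
    call.score_trace = [(s.allele_label, round(s.total, 3)) for s in scores[:10]]
    if not scores:
        call.no_call = True
        call.notes.append("no contig matched any database allele")
        return call

    support: dict[str, set[int]] = {}
    contig_labels: dict[int, set[str]] = {}
    for m in matches:
        support.setdefault(m.allele_label, set()).add(m.contig_id)
        contig_labels.setdefault(m.contig_id, set()).add(m.allele_label)

    order = list(scores)
    designated: list[str] = []
    assigned: set[int] = set()
    extra: list[int] = []

    for cand in order:  # strict walk
        label = cand.allele_label
        if label in designated:
            continue
        unique = [
            c
            for c in sorted(support[label])
            if c not in assigned and contig_labels[c] - set(designated) == {label}
        ]
        if not unique:
            continue
        if len(designated) < max_alleles:
            designated.append(label)
            assigned |= support[label]
        else:
            extra.extend(c for c in unique if c not in extra)

    if len(designated) < max_alleles:  # relaxed walk
        for cand in order:
            if len(designated) >= max_alleles:
                break
            label = cand.allele_label
            if label in designated:
                continue
            if any(c not in assigned for c in support[label]):
                designated.append(label)
                assigned |= support[label]
                call.notes.append(
                    f"{label} designated without a uniquely matching contig "
                    "(all evidence shared with other candidates)"
                )

    if not designated:
        call.no_call = True
        call.notes.append("no candidate could be designated from the match table")
        return call

    call.alleles = designated
    call.resolution = [label_resolution(l) for l in designated]
    call.extra_allele_contigs = extra
    if extra:
        call.notes.append(
            "additional candidate alleles supported by unique contigs; possible "
            "sample contamination (third/fourth allele) documented"
        )

    if len(designated) == 1:
        consistent = all(designated[0] in labs for labs in contig_labels.values())
        # A dropout-induced false homozygote is indistinguishable from a true
        # homozygote by content, but dropout implies the second haplotype's
        # coverage was too thin to assemble — which the below-20x warning
        # detects (a heterozygote's haplotypes each see roughly half the
        # gene's depth).  Homozygosity is therefore only reported on
        # warning-free coverage; otherwise the call is a possible-dropout
        # no-call.
        qc_ok = qc is None or (
            getattr(qc, "tier", "fail") != "fail"
            and not getattr(qc, "warning", True)
        )
        if consistent and qc_ok:
            call.homozygous = True
        elif consistent:
            call.no_call = True
            call.notes.append(
                "single allele designated under failed coverage QC: possible "
                "allele dropout, reported as no-call"
            )
        else:
            call.notes.append(
                "single designation but additional inconsistent contigs present"
            )
    return call


# ---------------------------------------------------------------------------
# Minor-exon (aDB) resolution of G-groups
# ---------------------------------------------------------------------------


def resolve_minor_exons(
    call: TypingCall,
    contigs: Sequence[Contig],
    adb: ExactDB,
    min_overlap: int = 20,
    flank_len: int = 50,
) -> TypingCall:
    """Examine minor-exon contigs to push G-group designations to six digits.

    For each designated G-group, members whose minor-exon sequence is
    perfectly matched by some contig are retained.  If exactly one minor-exon
    sequence class survives and its members share a six-digit (three-field)
    name, the designation is upgraded to that six-digit name; intronic
    (eight-digit) distinctions are never resolved.  With several surviving
    classes, or no minor-exon contig at all, the G-group label is kept.
    """
    if not any(l.endswith("G") for l in call.alleles):
        return call
    matches, _ = match_contigs(contigs, adb, call.gene, min_overlap, flank_len)
    by_member: dict[str, list[ContigMatch]] = {}
    for m in matches:
        by_member.setdefault(m.allele_label, []).append(m)

    for i, label in enumerate(list(call.alleles)):
        if not label.endswith("G"):
            continue
        members = sorted(adb.g_members.get(label, ()))
        if not members:
            continue
        member_entries = {m: adb.entry(m) for m in members}
        retained = [m for m in members if by_member.get(m)]
        if not retained:
            continue
        classes: dict[tuple[tuple[int, str], ...], list[str]] = {}
        for m in retained:
            e = member_entries[m]
            key = tuple(sorted(e.exon_sequences.items())) if e else ()
            classes.setdefault(key, []).append(m)
        if len(classes) != 1:
            continue
        survivors = next(iter(classes.values()))
        six = {":".join(m.split("*", 1)[1].split(":")[:3]) for m in survivors}
        if len(six) == 1:
            gene = label.split("*", 1)[0]
            call.alleles[i] = f"{gene}*{six.pop()}"
            call.resolution[i] = RES_SIX_DIGIT
            call.notes.append(
                f"{label} resolved on the minor exon to {call.alleles[i]} "
                f"(members {'/'.join(m.split('*',1)[1] for m in survivors)})"
            )
    # minor-exon contigs matching no member of any designated G-group stay
    # available as novel-allele evidence; the pipeline routes them.
    return call


# ---------------------------------------------------------------------------
# Phase ambiguity
# ---------------------------------------------------------------------------


def _diff_blocks(x: str, y: str, read_length: int) -> list[list[int]] | None:
    """Partition differing positions of two equal-length sequences into
    blocks separated by identical runs longer than ``read_length``.

    Returns None when the sequences differ in length (treated as one
    unswappable block by the caller).
    """
    if len(x) != len(y):
        return None
    diffs = [i for i, (a, b) in enumerate(zip(x, y)) if a != b]
    if not diffs:
        return []
    blocks: list[list[int]] = [[diffs[0]]]
    for prev, cur in zip(diffs, diffs[1:]):
        gap = cur - prev - 1  # identical bases between consecutive diffs
        if gap > read_length:
            blocks.append([cur])
        else:
            blocks[-1].append(cur)
    return blocks


def enumerate_consistent_pairs(
    x_exons: Mapping[int, str],
    y_exons: Mapping[int, str],
    read_length: int,
    mdb: ExactDB,
    gene: str,
    max_blocks: int = 12,
) -> list[tuple[str, str]]:
    """All allele pairs consistent with the observed genotype of (X, Y).

    Heterozygous variant blocks separated by an identical run longer than
    the read length cannot be phased by any single read, and the two exons
    of a class I gene are never bridged by a read; every complementary
    re-assignment of such blocks yields an alternative haplotype pair.
    Haplotypes are mapped back to database labels where their major-exon
    sequences exist, and to the ``unknown`` placeholder otherwise; pairs of
    two unknowns are not reported.
    """
    exon_ids = sorted(set(x_exons) | set(y_exons))
    blocks: list[tuple[int, list[int] | None]] = []  # (exon, positions or whole-exon)
    for e in exon_ids:
        xs, ys = x_exons.get(e, ""), y_exons.get(e, "")
        if xs == ys:
            continue
        bl = _diff_blocks(xs, ys, read_length)
        if bl is None:
            blocks.append((e, None))
        else:
            blocks.extend((e, b) for b in bl)
    if not blocks:
        return [_sorted_pair(_label_of(x_exons, mdb, gene), _label_of(y_exons, mdb, gene))]
    if len(blocks) > max_blocks:
        logger.warning("%s: %d phase blocks, enumeration truncated", gene, len(blocks))
        blocks = blocks[:max_blocks]

    pairs: set[tuple[str, str]] = set()
    for bits in itertools.product((0, 1), repeat=len(blocks)):
        h1 = {e: list(x_exons.get(e, "")) for e in exon_ids}
        h2 = {e: list(y_exons.get(e, "")) for e in exon_ids}
        for (e, pos), bit in zip(blocks, bits):
            if bit == 0:
                continue
            if pos is None:  # whole-exon swap (length-divergent exon)
                h1[e], h2[e] = h2[e], h1[e]
            else:
                for i in pos:
                    h1[e][i], h2[e][i] = h2[e][i], h1[e][i]
        e1 = {e: "".join(h1[e]) for e in exon_ids}
        e2 = {e: "".join(h2[e]) for e in exon_ids}
        l1, l2 = _label_of(e1, mdb, gene), _label_of(e2, mdb, gene)
        if l1 == UNKNOWN_ALLELE and l2 == UNKNOWN_ALLELE:
            continue
        pairs.add(_sorted_pair(l1, l2))
    return sorted(pairs)


def _sorted_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _label_of(exons: Mapping[int, str], mdb: ExactDB, gene: str) -> str:
    majors = major_exons(gene)
    want = {e: exons.get(e, "") for e in majors}
    for entry in mdb.entries.get(gene, []):
        if all(entry.exon_sequences.get(e, "") == want[e] for e in majors):
            return entry.label
    return UNKNOWN_ALLELE


def detect_phase_ambiguity(
    call: TypingCall,
    matches: Sequence[ContigMatch],
    read_length: int,
    mdb: ExactDB,
    freq: "FrequencyTable | Mapping[str, float] | None" = None,
) -> TypingCall:
    """Enumerate alternative pairs explaining the genotype and pick by frequency.

    Applies only to calls with two designations.  If more than one consistent
    pair exists the call is flagged phase-ambiguous, all pairs are listed,
    and the reported pair is the one preferred by population frequency.
    """
    if len(call.alleles) != 2:
        return call
    x, y = call.alleles
    ex, ey = mdb.entry(x), mdb.entry(y)
    if ex is None or ey is None:  # designations already upgraded/renamed
        return call
    pairs = enumerate_consistent_pairs(
        ex.exon_sequences, ey.exon_sequences, read_length, mdb, call.gene
    )
    original = _sorted_pair(x, y)
    if original not in pairs:
        pairs.append(original)
        pairs.sort()
    if len(pairs) <= 1:
        return call
    call.phase_ambiguous = True
    call.phase_alternatives = pairs
    chosen = break_ties_by_frequency(pairs, freq, mdb)
    if set(chosen) != set(original):
        call.notes.append(
            f"phase-ambiguous: reported pair {chosen} preferred over "
            f"{original} by population frequency"
        )
    call.alleles = list(chosen)
    call.resolution = [
        label_resolution(l) if l != UNKNOWN_ALLELE else "none" for l in chosen
    ]
    return call


# ---------------------------------------------------------------------------
# Frequency tie-breaking
# ---------------------------------------------------------------------------


def allele_frequency(
    label: str,
    freq: "FrequencyTable | Mapping[str, float] | None",
    db: ExactDB | None = None,
) -> float:
    """Population frequency of a (possibly G-group) label; unknown -> 0.

    A G-group's frequency is the summed frequency of its members.
    """
    if freq is None or label == UNKNOWN_ALLELE:
        return 0.0
    get = freq.get if hasattr(freq, "get") else None
    if get is None:
        return 0.0
    v = get(label)
    if v is not None:
        return float(v)
    if db is not None and label in db.g_members:
        return float(sum(get(m) or 0.0 for m in db.g_members[label]))
    return 0.0


def break_ties_by_frequency(
    pairs: Sequence[tuple[str, str]],
    freq: "FrequencyTable | Mapping[str, float] | None" = None,
    db: ExactDB | None = None,
) -> tuple[str, str]:
    """Pick the pair with the highest summed member frequency.

    Ranking key: summed frequency, then the larger single-member frequency,
    then lexicographic label order; unknown frequencies count as zero.
    """
    if not pairs:
        raise ValueError("at least one pair required")

    def key(pair: tuple[str, str]):
        f = [allele_frequency(l, freq, db) for l in pair]
        return (-sum(f), -max(f), pair)

    return sorted(pairs, key=key)[0]
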