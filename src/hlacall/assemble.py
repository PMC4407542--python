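"""Targeted de-novo assembly of a gene's read bin into zero-mismatch contigs.

Greedy overlap assembly in the style of targeted short-read assemblers:
starting from a seed read, the contig is extended one base at a time in each
direction.  A read may vote for the next base only while its entire overlap
with the contig (>= ``min_overlap`` bases) matches with **zero mismatches**;
a read disagreeing at any overlapped position drops out of that contig but
remains available to seed or join other contigs — this is what separates the
two haplotypes of a heterozygote.

Two greedy-order choices keep the consensus clean without ever admitting a
mismatching overlap:

* Base corroboration.  A proposed extension base is *corroborated* when the
  k-mer it completes occurs in at least three reads of the bin.  A base that
  exists only as one or two reads' sequencing errors fails this test and is ignored
  whenever any corroborated alternative exists, so isolated errors cannot be
  grafted into a long consensus.  (At the very ends of the covered region no
  base may be corroborated; the longest-overlap voter then decides.)
* Longest-overlap arbitration with divergence anchoring.  When corroborated
  voters disagree — the two haplotypes diverging at the next base — the
  voter with the longest perfect overlap wins, and once a divergent site has
  been passed only voters anchored across it may decide the next one: a read
  spanning consecutive divergent sites can only come from the contig's own
  haplotype.  If no anchored voter exists, growth stops rather than guess,
  leaving clean partial contigs instead of a chimeric join.

Seed hygiene: seeds are taken in descending order of the read's minimum
k-mer abundance within the bin.  A read carrying a sequencing error contains
k-mers seen (almost) nowhere else, so it sinks to the bottom of the seed
order and cannot graft its error into a consensus interior; the ordering is
fully deterministic (ties broken by read id).

After growth, every unused read that is an exact substring of the consensus
(either orientation) is incorporated, which defines per-base depth.  Reads
joining no contig seed their own (typically removed by the 5x depth filter).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classify import Read, ReadBin
from .mapper import revcomp


@dataclass
class Contig:
    """Assembled consensus with per-base read coverage."""

    gene: str
    sequence: str
    depth: np.ndarray  # int array, len == len(sequence)
    support: int  # number of reads incorporated

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if len(self.depth) != len(self.sequence):
            raise ValueError("depth length != sequence length")
        if self.support < 1 or (len(self.depth) and self.depth.min() < 1):
            raise ValueError("contig must be supported by at least one read everywhere")

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean())

    def __len__(self) -> int:
        return len(self.sequence)


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmer_counts(reads: Sequence[Read], k: int) -> Counter:
    counts: Counter = Counter()
    for r in reads:
        s = r.sequence
        for i in range(len(s) - k + 1):
            counts[_canon(s[i : i + k])] += 1
    return counts


def _seed_order(reads: Sequence[Read], counts: Counter, k: int) -> list[Read]:
    def min_abundance(r: Read) -> int:
        s = r.sequence
        if len(s) < k:
            return 0
        return min(counts[_canon(s[i : i + k])] for i in range(len(s) - k + 1))

    return sorted(reads, key=lambda r: (-min_abundance(r), r.id))


def _occurrence_index(
    seqs: list[tuple[str, str]], k: int
) -> dict[str, list[tuple[int, int]]]:
    """k-mer -> [(sequence index, position)] over oriented read sequences."""
    occ: dict[str, list[tuple[int, int]]] = {}
    for si, (_, s) in enumerate(seqs):
        for i in range(len(s) - k + 1):
            occ.setdefault(s[i : i + k], []).append((si, i))
    return occ


def _grow_right(
    contig: str,
    seqs: list[tuple[str, str]],
    occ: dict[str, list[tuple[int, int]]],
    available: set[str],
    counts: Counter,
    k: int,
) -> str:
    """Extend ``contig`` rightward base by base; returns the grown sequence.

    ``seqs`` holds (read id, oriented sequence) for both orientations of
    every read; ``available`` restricts which reads may vote.
    """
    # active voters: seq index -> current perfect overlap length
    active: dict[int, int] = {}
    dead: set[int] = set()
    last_div: int | None = None  # contig index of the last divergent base

    def admit(si: int, pos: int) -> None:
        if si in active or si in dead:
            return
        rid, s = seqs[si]
        if rid not in available:
            return
        ov = pos + k
        if ov >= len(s) or ov > len(contig):
            return
        if contig[-ov:] == s[:ov]:
            active[si] = ov

    for si, pos in occ.get(contig[-k:], ()):
        admit(si, pos)

    while active:
        votes: dict[str, list[tuple[int, int]]] = {}
        for si, ov in active.items():
            base = seqs[si][1][ov]
            votes.setdefault(base, []).append((ov, si))
        # Threshold 3, not 2: with per-base error rates around 0.5% two
        # reads can share the same error at the same position within one
        # bin, but three sharing it is vanishingly unlikely.
        corroborated = {
            b: v
            for b, v in votes.items()
            if counts[_canon(contig[-(k - 1) :] + b)] >= 3
        }
        pool = corroborated or votes
        if len(corroborated) >= 2:
            # Haplotype-divergent site.  Only a voter anchored across the
            # previous divergent site is guaranteed to continue the contig's
            # own haplotype; without one, extending would be a guess that can
            # weld the two haplotypes together, so growth stops instead and
            # the remaining reads assemble separately.
            if last_div is not None:
                span = len(contig) - last_div
                anchored = {
                    b: [v for v in vv if v[0] >= span]
                    for b, vv in corroborated.items()
                }
                anchored = {b: vv for b, vv in anchored.items() if vv}
                if not anchored:
                    break
                pool = anchored
            last_div = len(contig)
        # longest perfect overlap wins; ties broken by sequence index
        base = max(pool, key=lambda b: (max(v[0] for v in pool[b]),
                                        -min(v[1] for v in pool[b])))
        contig += base
        for si in list(active):
            rid, s = seqs[si]
            ov = active[si]
            if s[ov] != base:
                del active[si]
                dead.add(si)
            elif ov + 1 == len(s):
                del active[si]  # fully merged; containment pass will place it
                dead.add(si)
            else:
                active[si] = ov + 1
        for si, pos in occ.get(contig[-k:], ()):
            admit(si, pos)
    return contig


def _covered_runs(depth: np.ndarray) -> list[tuple[int, int]]:
    """Maximal half-open intervals where depth > 0."""
    runs: list[tuple[int, int]] = []
    start = None
    for i, d in enumerate(depth):
        if d > 0 and start is None:
            start = i
        elif d == 0 and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(depth)))
    return runs


def assemble_bin(bin: ReadBin, min_overlap: int = 20, seed: int = 0) -> list[Contig]:
    """Assemble a read bin into contigs admitting only perfect overlaps.

    Deterministic for any input read order: seeds are chosen by k-mer
    abundance (ties by id), extension is by corroborated longest-overlap
    voting, and the output is canonically ordered by sequence.  ``seed`` is
    reserved for optional randomized restarts and currently unused.
    """
    if min_overlap < 15:
        raise ValueError("min_overlap must be >= 15")
    del seed
    k = min_overlap
    unique: dict[str, Read] = {}
    for r in bin.reads:
        unique.setdefault(r.id, r)
    reads = sorted(unique.values(), key=lambda r: r.id)
    if not reads:
        return []
    counts = _kmer_counts(reads, k)
    order = _seed_order(reads, counts, k)
    seqs: list[tuple[str, str]] = []
    for r in reads:
        seqs.append((r.id, r.sequence))
        seqs.append((r.id, revcomp(r.sequence)))
    occ = _occurrence_index(seqs, k)

    available = {r.id for r in reads}
    contigs: list[Contig] = []
    for seed_read in order:
        if seed_read.id not in available:
            continue
        available.discard(seed_read.id)
        grown = _grow_right(seed_read.sequence, seqs, occ, available, counts, k)
        grown = revcomp(_grow_right(revcomp(grown), seqs, occ, available, counts, k))
        available.add(seed_read.id)
        # containment pass: place every read lying verbatim in the consensus
        depth = np.zeros(len(grown), dtype=np.int64)
        placements: list[tuple[int, int]] = []
        grown_rc = revcomp(grown)
        for r in reads:
            if r.id not in available:
                continue
            p = grown.find(r.sequence)
            if p < 0:
                prc = grown_rc.find(r.sequence)
                p = len(grown) - prc - len(r.sequence) if prc >= 0 else -1
            if p >= 0:
                depth[p : p + len(r.sequence)] += 1
                placements.append((p, p + len(r.sequence)))
                available.discard(r.id)
        # A stretch no incorporated read covers can arise when a voter
        # contributes bases but conflicts before its end; such consensus is
        # unsupported, so the contig is split at zero-depth positions.
        for lo, hi in _covered_runs(depth):
            contigs.append(
                Contig(
                    gene=bin.gene,
                    sequence=grown[lo:hi],
                    depth=depth[lo:hi],
                    support=sum(1 for a, b in placements if a >= lo and b <= hi),
                )
            )
    contigs.sort(key=lambda c: c.sequence)
    return contigs


def filter_contigs(contigs: Sequence[Contig], min_mean_depth: float = 5.0) -> list[Contig]:
    """Keep exactly the contigs with mean depth >= ``min_mean_depth``.

    Contigs of five-fold mean depth or above are considered regardless of
    length; no length filter is applied.
    """
    if min_mean_depth < 0:
        raise ValueError("min_mean_depth must be >= 0")
    return [c for c in contigs if c.mean_depth >= min_mean_depth]
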