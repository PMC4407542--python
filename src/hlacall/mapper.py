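"""Internal seed-and-extend read mapper over the comprehensive reference panel.

The classification stage only consumes two things from an aligner: the set
of best-scoring hits of a read across the panel, and a per-hit *perfect*
flag (full-length, zero-mismatch, zero-indel alignment).  This module
provides exactly that contract with a k-mer-seeded end-to-end aligner:

* exact k-mer seeds (default k=15) locate candidate (entry, diagonal)
  placements on both strands;
* each candidate diagonal is scored end-to-end over the read with unit
  match/mismatch costs (bases falling outside the reference entry count as
  mismatches), which is exact for substitution-only divergence;
* when no diagonal reaches the score threshold, a banded affine-gap
  alignment (gap open -3, extend -1) rescues candidates with small indels.

Hits scoring below ``min_score_frac * read_length`` are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .refdb import CRPEntry

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappingParams:
    """Alignment scoring and seeding parameters."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = -3
    gap_extend: int = -1
    min_score_frac: float = 0.6
    seed_len: int = 15
    n_seed_positions: int = 5
    band: int = 5
    gapped: bool = True
    # candidates scoring below this fraction ungapped are not worth a gapped
    # rescue (they are dominated by off-target or out-of-bounds placements)
    gap_rescue_floor: float = 0.3


@dataclass(frozen=True)
class MappingHit:
    """Best alignment of a read against one panel entry."""

    read_id: str
    entry: CRPEntry
    entry_index: int
    score: int
    mismatches: int
    perfect: bool
    strand: str  # "+" | "-"
    offset: int  # read start position on the entry (may be negative)

    def __post_init__(self) -> None:
        if self.perfect and self.mismatches != 0:
            raise ValueError("perfect hit must have zero mismatches")


class PanelIndex:
    """K-mer index over a CRP used to map reads.

    Build once per panel and reuse across samples; construction indexes every
    ``seed_len``-mer of every entry (forward strand only; read orientation is
    handled by also mapping the reverse complement of the read).
    """

    def __init__(self, panel: Sequence[CRPEntry], params: MappingParams | None = None):
        if not panel:
            raise ValueError("panel must be non-empty")
        self.params = params or MappingParams()
        self.entries = list(panel)
        self._arrays = [
            np.frombuffer(e.sequence.encode("ascii"), dtype=np.uint8) for e in panel
        ]
        k = self.params.seed_len
        index: dict[bytes, list[tuple[int, int]]] = {}
        for ei, e in enumerate(panel):
            b = e.sequence.encode("ascii")
            for p in range(len(b) - k + 1):
                index.setdefault(b[p : p + k], []).append((ei, p))
        self._index = index
        self.short_read_warnings = 0

    # -- scoring helpers ---------------------------------------------------

    def _diag_score(self, ei: int, off: int, read_arr: np.ndarray) -> tuple[int, int]:
        """Ungapped end-to-end score of the read at diagonal ``off``.

        Returns (score, mismatches); read bases falling outside the entry
        count as mismatches.
        """
        ref = self._arrays[ei]
        L = len(read_arr)
        lo = max(0, off)
        hi = min(len(ref), off + L)
        if hi <= lo:
            matches = 0
        else:
            matches = int(
                np.count_nonzero(ref[lo:hi] == read_arr[lo - off : hi - off])
            )
        mm = L - matches
        p = self.params
        return p.match * matches + p.mismatch * mm, mm

    def _banded_affine_score(self, ei: int, off: int, read: str) -> int:
        """Affine-gap score of the read aligned end-to-end within a band
        around diagonal ``off`` (reference overhang is free)."""
        p = self.params
        ref = self.entries[ei].sequence
        b = p.band
        lo = max(0, off - b)
        hi = min(len(ref), off + len(read) + b)
        window = ref[lo:hi]
        if not window:
            return -(10**9)
        return banded_affine(read, window, off - lo, p)

    # -- mapping -----------------------------------------------------------

    def map_read(self, read: "ReadLike") -> list[MappingHit]:
        """All best-scoring hits of the read across the panel.

        A perfect hit (full-length exact substring of an entry) always scores
        ``match * len(read)``, the maximum, so the returned best-score set
        contains every perfect hit.
        """
        p = self.params
        seq = read.sequence.upper()
        L = len(seq)
        if L < p.seed_len:
            self.short_read_warnings += 1
            return []
        min_score = int(np.ceil(p.min_score_frac * p.match * L))
        k = p.seed_len

        best: dict[tuple[int, str], tuple[int, int, int]] = {}  # (ei,strand)->(score,mm,off)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            sb = s.encode("ascii")
            arr = np.frombuffer(sb, dtype=np.uint8)
            n = max(2, p.n_seed_positions)
            positions = sorted({round(i * (L - k) / (n - 1)) for i in range(n)})
            seen: set[tuple[int, int]] = set()
            candidates: list[tuple[int, int]] = []
            for sp in positions:
                for ei, pos in self._index.get(sb[sp : sp + k], ()):
                    key = (ei, pos - sp)
                    if key not in seen:
                        seen.add(key)
                        candidates.append(key)
            ungapped: list[tuple[int, int, int, int]] = []
            for ei, off in candidates:
                score, mm = self._diag_score(ei, off, arr)
                ungapped.append((score, mm, ei, off))
                cur = best.get((ei, strand))
                if cur is None or score > cur[0]:
                    best[(ei, strand)] = (score, mm, off)
            if (
                p.gapped
                and ungapped
                and max(u[0] for u in ungapped) < min_score
            ):
                floor = p.gap_rescue_floor * p.match * L
                rescue = sorted(ungapped, reverse=True)[:3]
                for score, _mm, ei, off in rescue:
                    if score < floor:
                        continue
                    gs = self._banded_affine_score(ei, off, s)
                    cur = best.get((ei, strand))
                    if gs > (cur[0] if cur else -(10**9)):
                        # gapped alignment: mismatches no longer well-defined;
                        # report edit distance proxy via score deficit
                        mm_proxy = max(0, (p.match * L - gs) // (p.match - p.mismatch))
                        best[(ei, strand)] = (gs, mm_proxy, off)

        if not best:
            return []
        top = max(v[0] for v in best.values())
        if top < min_score:
            return []
        hits = []
        for (ei, strand), (score, mm, off) in sorted(best.items()):
            if score != top:
                continue
            perfect = mm == 0 and score == p.match * L
            hits.append(
                MappingHit(
                    read_id=read.id,
                    entry=self.entries[ei],
                    entry_index=ei,
                    score=score,
                    mismatches=0 if perfect else mm,
                    perfect=perfect,
                    strand=strand,
                    offset=off,
                )
            )
        return hits


def banded_affine(read: str, ref: str, center: int, p: MappingParams) -> int:
    """Affine-gap DP score: read aligned end-to-end, reference ends free,
    restricted to a band of +/- ``p.band`` columns around the diagonal
    through ``center`` (the expected read start on ``ref``).

    The first base of a gap costs ``gap_open``, each further base
    ``gap_extend``.
    """
    NEG = -(10**9)
    band = p.band
    n, L = len(ref), len(read)
    # three states per cell: M (read base aligned to ref base),
    # X (ref base consumed by a gap in the read), Y (read base inserted).
    prev_m = [0] * (n + 1)  # free reference prefix
    prev_x = [NEG] * (n + 1)
    prev_y = [NEG] * (n + 1)
    for i in range(1, L + 1):
        cur_m = [NEG] * (n + 1)
        cur_x = [NEG] * (n + 1)
        cur_y = [NEG] * (n + 1)
        lo = max(1, center + i - band)
        hi = min(n, center + i + band)
        for j in range(lo, hi + 1):
            sub = p.match if read[i - 1] == ref[j - 1] else p.mismatch
            diag = max(prev_m[j - 1], prev_x[j - 1], prev_y[j - 1])
            if diag > NEG:
                cur_m[j] = diag + sub
            x = max(cur_m[j - 1] + p.gap_open, cur_x[j - 1] + p.gap_extend)
            if x > NEG:
                cur_x[j] = x
            y = max(prev_m[j] + p.gap_open, prev_y[j] + p.gap_extend)
            if y > NEG:
                cur_y[j] = y
        prev_m, prev_x, prev_y = cur_m, cur_x, cur_y
    return max(max(prev_m), max(prev_y))


@dataclass
class ReadLike:
    id: str
    sequence: str
    qualities: str | None = None
    mate: str | None = None
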