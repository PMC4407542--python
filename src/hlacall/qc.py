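"""Per-exon coverage profiles and quality tiers for typing calls.

Quality standards follow the validated coverage tiers: the strictest tier
requires every targeted exonic position at >= 10x with >= 98% of positions
at >= 20x; a call made with more than 2% of exonic positions below 20-fold
coverage carries a warning, and 30-fold everywhere is recommended.  The
10x/20x thresholds are applied inclusively on integer depths (a "10x =
100%" tier is only attainable under the inclusive reading).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .classify import ReadBin
from .mapper import revcomp

TIER_STRICT = "10x=100% & 20x>=98%"
TIER_MID = "10x=100% & 20x>=90%"
TIER_LOW = "10x>=95%"
TIER_FAIL = "fail"

WARNING_FRAC_BELOW_20X = 0.02
RECOMMENDED_DEPTH = 30


@dataclass
class ExonCoverage:
    frac_ge_10x: float
    frac_ge_20x: float
    min_depth: int
    mean_depth: float


@dataclass
class QCReport:
    """Coverage QC over the targeted exons of one gene."""

    gene: str
    per_exon: dict[int, ExonCoverage] = field(default_factory=dict)
    frac_ge_10x: float = 0.0
    frac_ge_20x: float = 0.0
    min_depth: int = 0
    mean_depth: float = 0.0
    tier: str = TIER_FAIL
    warning: bool = True
    recommend_more_depth: bool = True  # any position below 30x

    def summary(self) -> dict:
        return {
            "gene": self.gene,
            "tier": self.tier,
            "warning": self.warning,
            "frac_ge_10x": round(self.frac_ge_10x, 4),
            "frac_ge_20x": round(self.frac_ge_20x, 4),
            "min_depth": int(self.min_depth),
            "mean_depth": round(self.mean_depth, 2),
            "recommend_more_depth": self.recommend_more_depth,
        }


def assign_tier(frac_ge_10x: float, frac_ge_20x: float, min_depth: int) -> str:
    """Strictest quality standard satisfied by the coverage fractions."""
    full_10x = min_depth >= 10  # exact "10x = 100%" without float comparison
    if full_10x and frac_ge_20x >= 0.98:
        return TIER_STRICT
    if full_10x and frac_ge_20x >= 0.90:
        return TIER_MID
    if frac_ge_10x >= 0.95:
        return TIER_LOW
    return TIER_FAIL


def profile_from_depths(gene: str, depths: Mapping[int, np.ndarray]) -> QCReport:
    """Build a QC report from per-exon depth vectors."""
    report = QCReport(gene=gene)
    all_depth: list[np.ndarray] = []
    for exon in sorted(depths):
        d = np.asarray(depths[exon], dtype=np.int64)
        if d.size == 0:
            continue
        report.per_exon[exon] = ExonCoverage(
            frac_ge_10x=float((d >= 10).mean()),
            frac_ge_20x=float((d >= 20).mean()),
            min_depth=int(d.min()),
            mean_depth=float(d.mean()),
        )
        all_depth.append(d)
    if not all_depth:
        return report  # tier fail, zero fractions
    d = np.concatenate(all_depth)
    n = d.size
    below20 = int((d < 20).sum())
    report.frac_ge_10x = float((d >= 10).sum()) / n
    report.frac_ge_20x = (n - below20) / n
    report.min_depth = int(d.min())
    report.mean_depth = float(d.mean())
    report.tier = assign_tier(report.frac_ge_10x, report.frac_ge_20x, report.min_depth)
    report.warning = below20 / n > WARNING_FRAC_BELOW_20X
    report.recommend_more_depth = bool(report.min_depth < RECOMMENDED_DEPTH)
    return report


def coverage_profile(
    bin: ReadBin,
    exons: Mapping[int, str],
    seed_len: int = 15,
    max_mismatch_frac: float = 0.1,
) -> QCReport:
    """Depth profile of a read bin over a gene's reference exon sequences.

    Depth at each exonic position counts the binned reads whose best
    placement covers it.  Placement is by exact k-mer anchor plus mismatch
    counting; reads may overhang the exon ends (only the exonic overlap
    contributes).  Computed from raw binned reads, so QC is available even
    for genes that end in a no-call.
    """
    exon_ids = sorted(exons)
    depths = {e: np.zeros(len(exons[e]), dtype=np.int64) for e in exon_ids}
    if not bin.reads or not exon_ids:
        return profile_from_depths(bin.gene, depths)

    k = seed_len
    index: dict[str, list[tuple[int, int]]] = {}
    arrays: dict[int, np.ndarray] = {}
    for e in exon_ids:
        seq = exons[e]
        arrays[e] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        for p in range(len(seq) - k + 1):
            index.setdefault(seq[p : p + k], []).append((e, p))

    for read in bin.reads:
        best: tuple[int, int, int, int] | None = None  # (net, exon, off, overlap)
        for seq in (read.sequence, revcomp(read.sequence)):
            L = len(seq)
            if L < k:
                continue
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            n_pos = max(2, (L - k) // 20 + 1)
            positions = sorted({round(i * (L - k) / max(1, n_pos - 1)) for i in range(n_pos)})
            seen: set[tuple[int, int]] = set()
            for sp in positions:
                for e, p in index.get(seq[sp : sp + k], ()):
                    off = p - sp
                    if (e, off) in seen:
                        continue
                    seen.add((e, off))
                    ref = arrays[e]
                    lo, hi = max(0, off), min(len(ref), off + L)
                    if hi - lo < k:
                        continue
                    matches = int(np.count_nonzero(ref[lo:hi] == arr[lo - off : hi - off]))
                    overlap = hi - lo
                    if overlap - matches > max_mismatch_frac * overlap:
                        continue
                    net = 2 * matches - overlap
                    if best is None or net > best[0]:
                        best = (net, e, off, overlap)
        if best is not None:
            _, e, off, _ = best
            L = len(read.sequence)
            lo, hi = max(0, off), min(len(depths[e]), off + L)
            if hi > lo:
                depths[e][lo:hi] += 1
    return profile_from_depths(bin.gene, depths)
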