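"""Mock allele databases and simulated sequencing reads.

The generator emulates the structure that makes HLA typing hard, at a
desk-testable scale: several class I and class II genes with 10-50 alleles
each, planted G-groups (members identical across the major exons, divergent
on the minor exon), and paralogous competitor genes at a controlled per-base
divergence to exercise the ambiguous-read exclusion rule.  Reads are drawn
from two alleles per gene (WES mode: targeted exons plus 50 bp flanks,
emulating capture; WGS mode: the whole allele including introns) with
configurable coverage, allelic balance, read length and substitution error
rate.  Everything is deterministic per seed.

Divergence placement is grid-jittered so that no two sampled haplotypes are
separated by an identical run approaching the read length — by default the
sampled genotypes are additionally rejection-checked for this, keeping the
study conditions inside the regime the assembly-based method is defined for
(variants co-coverable by single reads; longer identical runs are exactly
the documented phase-ambiguity regime).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import Read
from .io import FrequencyTable
from .mapper import revcomp
from .refdb import AlleleRecord, Segment, major_exons, minor_exons, targeted_exons

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(ValueError):
    """Raised for an infeasible simulation configuration."""


@dataclass
class SimConfig:
    """Study conditions for the mock database and read simulation."""

    # database structure
    n_class1_genes: int = 3
    n_class2_genes: int = 3
    alleles_per_gene: int = 20
    g_group_fraction: float = 0.2  # fraction of alleles that sit in a G-group
    allele_divergence: float = 0.015  # per-base substitution rate vs the gene base
    max_snp_gap: int = 70  # jittered-grid cap on identical runs between variants
    n_paralog_genes: int = 2
    alleles_per_paralog: int = 5
    paralog_divergence: float = 0.03
    paralog_max_gap: int = 70
    exon_len_range: tuple[int, int] = (250, 300)
    intron_len_range: tuple[int, int] = (120, 160)
    missing_intron_fraction: float = 0.15
    # sample / sequencing
    sample_genotype: dict[str, tuple[str, str]] | None = None
    coverage: float = 30.0  # per-haplotype mean depth at balance 0.5
    read_length: int = 100
    error_rate: float = 0.005
    allelic_balance: float = 0.5  # fraction of a gene's reads from allele 1
    homozygous_fraction: float = 0.1
    paired: bool = False
    mode: str = "wes"  # "wes" | "wgs"
    flank_len: int = 50
    include_paralog_reads: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.coverage <= 0:
            raise ConfigError("coverage must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigError("error_rate must be in [0,1)")
        if not 0.0 < self.allelic_balance < 1.0:
            raise ConfigError("allelic_balance must be in (0,1)")
        if self.mode not in ("wes", "wgs"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.alleles_per_gene < 1:
            raise ConfigError("alleles_per_gene must be >= 1")
        if self.g_group_fraction > 0 and self.alleles_per_gene < 2:
            raise ConfigError("g_group_fraction > 0 needs at least 2 alleles per gene")
        if not 0.0 <= self.g_group_fraction <= 1.0:
            raise ConfigError("g_group_fraction must be in [0,1]")
        if self.read_length < 30:
            raise ConfigError("read_length must be >= 30")


@dataclass
class MockPanel:
    """Generated reference set plus the gene roles to map with."""

    records: list[AlleleRecord]
    frequencies: FrequencyTable
    target_genes: list[str]
    competitor_genes: list[str]

    def records_for(self, genes: Sequence[str]) -> list[AlleleRecord]:
        gs = set(genes)
        return [r for r in self.records if r.gene in gs]


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return bytes(BASES[rng.integers(0, 4, n)]).decode("ascii")


def _mutate(
    rng: np.random.Generator, seq: str, rate: float, max_gap: int | None = None
) -> str:
    """Substitute bases at ``rate`` with positions on a jittered grid.

    With ``max_gap`` set, successive substitution positions are at most
    ``max_gap`` identical bases apart, which bounds the identical runs
    between any mutated sequence and its template.
    """
    n = len(seq)
    if rate <= 0 or n == 0:
        return seq
    arr = bytearray(seq.encode("ascii"))
    step = max(1, int(round(1.0 / rate)))
    if max_gap is not None:
        step = min(step, max_gap)
    pos = int(rng.integers(0, step))
    while pos < n:
        old = arr[pos]
        choices = [b for b in b"ACGT" if b != old]
        arr[pos] = choices[int(rng.integers(0, 3))]
        pos += 1 + int(rng.integers(max(1, step // 2), step + 1))
    return arr.decode("ascii")


def make_mock_alleles(cfg: SimConfig) -> MockPanel:
    """Generate a mock allele database with planted G-groups and paralogs.

    Class I genes carry exons 2, 3, 4; class II genes exons 2, 3 (the
    class convention the typing databases are built on).  Non-G alleles are
    pairwise distinct across the major exons and carry distinct first-two-
    field names, so full-resolution recovery is checkable from names alone;
    G-group members share the major exons, differ on the minor exon and on
    the third name field.  A fraction of alleles is emitted without introns
    to exercise flank borrowing.  Frequencies are Dirichlet-distributed per
    gene.  Deterministic per ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    target_genes = [f"HLA-S{i + 1:02d}" for i in range(cfg.n_class1_genes)] + [
        f"HLA-DS{i + 1:02d}" for i in range(cfg.n_class2_genes)
    ]
    records: list[AlleleRecord] = []
    freqs: dict[str, float] = {}
    gene_bases: dict[str, dict] = {}

    for gene in target_genes:
        base = _gene_base(rng, gene, cfg)
        gene_bases[gene] = base
        records.extend(_gene_alleles(rng, gene, base, cfg, freqs))

    competitor_genes: list[str] = []
    n_par = min(cfg.n_paralog_genes, len(target_genes))
    for i in range(n_par):
        src_gene = target_genes[i * len(target_genes) // max(1, n_par)]
        is_class2 = src_gene.split("-", 1)[-1].startswith("D")
        par_gene = f"HLA-DSP{i + 1}" if is_class2 else f"HLA-SP{i + 1}"
        competitor_genes.append(par_gene)
        src = gene_bases[src_gene]
        base = {
            "exons": {
                e: _mutate(rng, s, cfg.paralog_divergence, cfg.paralog_max_gap)
                for e, s in src["exons"].items()
            },
            "introns": {
                i_: _mutate(rng, s, cfg.paralog_divergence, cfg.paralog_max_gap)
                for i_, s in src["introns"].items()
            },
        }
        par_cfg = replace(
            cfg,
            alleles_per_gene=cfg.alleles_per_paralog,
            g_group_fraction=0.0,
            missing_intron_fraction=0.0,
        )
        records.extend(_gene_alleles(rng, par_gene, base, par_cfg, freqs))

    records.sort(key=lambda r: (r.gene, r.name))
    return MockPanel(
        records=records,
        frequencies=FrequencyTable(freqs),
        target_genes=target_genes,
        competitor_genes=competitor_genes,
    )


def _gene_base(rng: np.random.Generator, gene: str, cfg: SimConfig) -> dict:
    exons = {}
    for e in targeted_exons(gene):
        n = int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
        exons[e] = _random_dna(rng, n)
    intron_ids = sorted(
        {e - 1 for e in exons} | {e for e in exons}
    )
    intron_ids = [i for i in intron_ids if i >= 1]
    introns = {}
    for i in intron_ids:
        n = int(rng.integers(cfg.intron_len_range[0], cfg.intron_len_range[1] + 1))
        introns[i] = _random_dna(rng, n)
    return {"exons": exons, "introns": introns}


def _gene_alleles(
    rng: np.random.Generator,
    gene: str,
    base: dict,
    cfg: SimConfig,
    freqs: dict[str, float],
) -> list[AlleleRecord]:
    majors = major_exons(gene)
    minors = minor_exons(gene)
    n_members = int(round(cfg.g_group_fraction * cfg.alleles_per_gene))
    n_groups = n_members // 2
    n_families = cfg.alleles_per_gene - n_groups  # G pairs share one family

    family_exons: list[dict[int, str]] = []
    seen_major: set[tuple[str, ...]] = set()
    for _ in range(n_families):
        for _attempt in range(50):
            exons = {
                e: _mutate(rng, s, cfg.allele_divergence, cfg.max_snp_gap)
                for e, s in base["exons"].items()
            }
            key = tuple(exons[e] for e in majors)
            if key not in seen_major:
                seen_major.add(key)
                family_exons.append(exons)
                break
        else:  # pragma: no cover - astronomically unlikely
            raise ConfigError(f"could not generate distinct alleles for {gene}")

    alleles: list[tuple[str, dict[int, str]]] = []
    for fam, exons in enumerate(family_exons, start=1):
        name = f"{fam:02d}:01:01"
        alleles.append((name, exons))
        if fam <= n_groups:  # plant a G sibling: same majors, mutated minor exon
            sib = dict(exons)
            for e in minors:
                for _attempt in range(50):
                    mutated = _mutate(rng, exons[e], 0.01, cfg.max_snp_gap)
                    if mutated != exons[e]:
                        sib[e] = mutated
                        break
            alleles.append((f"{fam:02d}:01:02", sib))

    n_alleles = len(alleles)
    dirich = rng.dirichlet(np.ones(n_alleles))
    drop_introns = rng.random(n_alleles) < cfg.missing_intron_fraction
    if drop_introns.all():
        drop_introns[0] = False  # keep at least one flank donor per gene

    out: list[AlleleRecord] = []
    for i, (name, exons) in enumerate(alleles):
        segments = [Segment("exon", e, s) for e, s in sorted(exons.items())]
        if not drop_introns[i]:
            segments += [
                Segment("intron", j, s) for j, s in sorted(base["introns"].items())
            ]
        rec = AlleleRecord(gene=gene, name=name, segments=segments)
        freqs[rec.label] = float(dirich[i])
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _regions(
    rec: AlleleRecord,
    cfg: SimConfig,
    mode: str | None = None,
    donor: AlleleRecord | None = None,
) -> list[tuple[str, str]]:
    """(region name, sequence) pairs reads are drawn from.

    A record without intron segments describes a *database* gap, not a
    physical one — the sampled chromosome still has introns.  Flanks for such
    haplotypes are borrowed from ``donor`` (a same-gene record with introns),
    mirroring the flank-borrowing convention of the reference-panel builder.
    """
    if (mode or cfg.mode) == "wgs" and rec.has_introns:
        return [("wgs", rec.full_sequence())]
    out = []
    for e in targeted_exons(rec.gene):
        exon = rec.exon(e)
        if exon is None:
            continue
        left = rec.intron(e - 1)
        right = rec.intron(e)
        if donor is not None:
            left = left or donor.intron(e - 1)
            right = right or donor.intron(e)
        lf = left[-cfg.flank_len :] if left else ""
        rf = right[: cfg.flank_len] if right else ""
        out.append((f"exon{e}", lf + exon + rf))
    return out


def _flank_donors(records: Sequence[AlleleRecord]) -> dict[str, AlleleRecord]:
    """Per gene, the lexicographically first record carrying introns."""
    donors: dict[str, AlleleRecord] = {}
    for r in sorted(records, key=lambda r: r.label):
        if r.has_introns and r.gene not in donors:
            donors[r.gene] = r
    return donors


def _max_identical_gap(a: str, b: str) -> int:
    """Longest identical run (bases) between consecutive differences of two
    equal-length sequences; 0 when they differ nowhere or everywhere densely,
    and a large sentinel when lengths differ (unswappable, not a phase risk)."""
    if len(a) != len(b):
        return 0
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if len(diffs) < 2:
        return 0
    return max(q - p - 1 for p, q in zip(diffs, diffs[1:]))


def _pair_phase_safe(
    r1: AlleleRecord,
    r2: AlleleRecord,
    cfg: SimConfig,
    margin: int = 25,
    donor: AlleleRecord | None = None,
) -> bool:
    """True when every identical run between the two haplotypes' targeted
    regions is comfortably shorter than the read length, so single reads can
    phase all heterozygous variants."""
    for (_, s1), (_, s2) in zip(
        _regions(r1, cfg, mode="wes", donor=donor),
        _regions(r2, cfg, mode="wes", donor=donor),
    ):
        if _max_identical_gap(s1, s2) > cfg.read_length - margin:
            return False
    return True


def draw_genotypes(
    panel: MockPanel, cfg: SimConfig, rng: np.random.Generator
) -> dict[str, tuple[str, str]]:
    """Sample a two-allele genotype per target gene (phase-safe pairs).

    Heterozygous with probability ``1 - homozygous_fraction``; heterozygous
    pairs are rejection-sampled until no identical run between the two
    haplotypes approaches the read length (see module docstring).
    """
    by_gene: dict[str, list[AlleleRecord]] = {}
    for r in panel.records:
        by_gene.setdefault(r.gene, []).append(r)
    donors = _flank_donors(panel.records)
    genotype: dict[str, tuple[str, str]] = {}
    for gene in panel.target_genes:
        recs = sorted(by_gene[gene], key=lambda r: r.name)
        if len(recs) == 1 or rng.random() < cfg.homozygous_fraction:
            a = recs[int(rng.integers(0, len(recs)))]
            genotype[gene] = (a.label, a.label)
            continue
        chosen = None
        for _ in range(300):
            i, j = rng.choice(len(recs), size=2, replace=False)
            r1, r2 = recs[int(i)], recs[int(j)]
            if _pair_phase_safe(r1, r2, cfg, donor=donors.get(gene)):
                chosen = (r1.label, r2.label)
                break
        if chosen is None:  # fall back to any pair; phase flag will handle it
            i, j = rng.choice(len(recs), size=2, replace=False)
            chosen = (recs[int(i)].label, recs[int(j)].label)
        genotype[gene] = tuple(sorted(chosen))
    return genotype


def simulate_reads(
    records: Sequence[AlleleRecord] | MockPanel,
    cfg: SimConfig,
) -> tuple[list[Read], pd.DataFrame, dict[str, tuple[str, str]]]:
    """Simulate reads from two alleles per gene.

    Returns (reads, truth table, genotype).  The truth table has one row per
    read: ``read_id, gene, allele, region, start, strand, n_errors``.  Mean
    per-haplotype depth over a region's interior approximates
    ``2 * balance_i * coverage`` (so the default balance of 0.5 yields
    ``coverage`` per haplotype); read counts are Poisson.
    """
    cfg.validate()
    rng = np.random.default_rng([max(0, cfg.seed), 1])
    if isinstance(records, MockPanel):
        panel = records
    else:
        panel = MockPanel(
            records=list(records),
            frequencies=FrequencyTable(),
            target_genes=sorted({r.gene for r in records}),
            competitor_genes=[],
        )
    by_label = {r.label: r for r in panel.records}
    genotype = cfg.sample_genotype or draw_genotypes(panel, cfg, rng)
    for gene, (a1, a2) in genotype.items():
        if a1 not in by_label or a2 not in by_label:
            raise ConfigError(f"{gene}: genotype allele not in the record set")

    source_genes = list(genotype)
    extra_genotype: dict[str, tuple[str, str]] = {}
    if cfg.include_paralog_reads:
        for gene in panel.competitor_genes:
            recs = sorted(
                (r for r in panel.records if r.gene == gene), key=lambda r: r.name
            )
            if not recs:
                continue
            idx = rng.choice(len(recs), size=min(2, len(recs)), replace=False)
            pair = tuple(sorted(recs[int(i)].label for i in idx))
            extra_genotype[gene] = pair if len(pair) == 2 else (pair[0], pair[0])

    reads: list[Read] = []
    truth_rows: list[tuple] = []
    serial = itertools.count()
    donors = _flank_donors(panel.records)
    all_genotypes = {**genotype, **extra_genotype}
    for gene in sorted(all_genotypes):
        a1, a2 = all_genotypes[gene]
        hom = a1 == a2
        hap_depths = (
            [(a1, 2.0 * cfg.coverage)]
            if hom
            else [
                (a1, 2.0 * cfg.allelic_balance * cfg.coverage),
                (a2, 2.0 * (1.0 - cfg.allelic_balance) * cfg.coverage),
            ]
        )
        for label, depth in hap_depths:
            rec = by_label[label]
            for region_name, region in _regions(rec, cfg, donor=donors.get(gene)):
                _emit_region_reads(
                    rng, gene, label, region_name, region, depth, cfg, serial,
                    reads, truth_rows,
                )
    truth = pd.DataFrame(
        truth_rows,
        columns=["read_id", "gene", "allele", "region", "start", "strand", "n_errors"],
    )
    return reads, truth, all_genotypes


def _emit_region_reads(
    rng, gene, label, region_name, region, depth, cfg, serial, reads, truth_rows
) -> None:
    rl = cfg.read_length
    L = len(region)
    if L < rl:
        return
    n_starts = L - rl + 1
    n = int(rng.poisson(depth * n_starts / rl))
    starts = np.sort(rng.integers(0, n_starts, n))
    for s in starts:
        s = int(s)
        seq = region[s : s + rl]
        n_err = int(rng.binomial(rl, cfg.error_rate))
        if n_err:
            arr = bytearray(seq.encode("ascii"))
            for p in rng.choice(rl, size=n_err, replace=False):
                old = arr[int(p)]
                choices = [b for b in b"ACGT" if b != old]
                arr[int(p)] = choices[int(rng.integers(0, 3))]
            seq = arr.decode("ascii")
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = revcomp(seq)
        rid = f"r{next(serial):07d}"
        reads.append(Read(id=rid, sequence=seq, qualities="I" * rl))
        truth_rows.append((rid, gene, label, region_name, s, strand, n_err))
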