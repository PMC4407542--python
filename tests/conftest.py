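"""Shared fixtures: hand-built allele records and a small simulated sample."""

from __future__ import annotations

import pytest

from hlacall import PipelineConfig, SimConfig, make_mock_alleles, run_pipeline, simulate_reads
from hlacall.refdb import AlleleRecord, Segment, build_exact_dbs


def make_record(
    gene: str,
    name: str,
    exons: dict[int, str],
    introns: dict[int, str] | None = None,
) -> AlleleRecord:
    segments = [Segment("exon", e, s) for e, s in sorted(exons.items())]
    if introns:
        segments += [Segment("intron", i, s) for i, s in sorted(introns.items())]
    return AlleleRecord(gene=gene, name=name, segments=segments)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated WES sample: (cfg, panel, reads, truth, genotype)."""
    cfg = SimConfig(seed=7, n_class1_genes=2, n_class2_genes=2, alleles_per_gene=10)
    panel = make_mock_alleles(cfg)
    reads, truth, genotype = simulate_reads(panel, cfg)
    return cfg, panel, reads, truth, genotype


@pytest.fixture(scope="session")
def small_result(small_sim):
    """Full pipeline result on the small simulated sample."""
    cfg, panel, reads, truth, genotype = small_sim
    pcfg = PipelineConfig(
        seed=cfg.seed,
        target_genes=panel.target_genes,
        competitor_genes=panel.competitor_genes,
    )
    result = run_pipeline(
        pcfg, records=panel.records, reads=reads, frequencies=panel.frequencies
    )
    return pcfg, result


@pytest.fixture(scope="session")
def small_dbs(small_sim):
    _, panel, *_ = small_sim
    targets = set(panel.target_genes)
    return build_exact_dbs([r for r in panel.records if r.gene in targets])
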