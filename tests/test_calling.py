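"""Contig matching, scoring, designation, G-group resolution, phase, frequency."""

import numpy as np
import pytest

from conftest import make_record
from hlacall.assemble import Contig
from hlacall.calling import (
    ContigMatch,
    break_ties_by_frequency,
    designate_alleles,
    detect_phase_ambiguity,
    enumerate_consistent_pairs,
    match_contigs,
    resolve_minor_exons,
    score_alleles,
)
from hlacall.mapper import revcomp
from hlacall.qc import QCReport, TIER_STRICT, TIER_FAIL
from hlacall.refdb import build_exact_dbs
from hlacall.calling import TypingCall


def _dna(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def _contig(seq, depth=20):
    return Contig("HLA-DRB1", seq, np.full(len(seq), depth, dtype=int), support=depth)


def _mdb_two_alleles(seed=0, exon_len=280):
    rng = np.random.default_rng(seed)
    e_a = _dna(rng, exon_len)
    e_b = e_a[:100] + _dna(rng, 10) + e_a[110:]
    ra = make_record("HLA-DRB1", "01:01", {2: e_a, 3: _dna(rng, exon_len)})
    rb = make_record("HLA-DRB1", "02:01", {2: e_b, 3: _dna(rng, exon_len)})
    mdb, adb = build_exact_dbs([ra, rb])
    return ra, rb, mdb, adb


def _qc_good():
    return QCReport(gene="HLA-DRB1", tier=TIER_STRICT, warning=False)


# -- matching ---------------------------------------------------------------


def test_match_exact_exon_full_fraction():
    ra, rb, mdb, _ = _mdb_two_alleles()
    contigs = [_contig(ra.exon(2))]
    matches, unmatched = match_contigs(contigs, mdb, "HLA-DRB1")
    assert unmatched == []
    m = next(m for m in matches if m.allele_label == "HLA-DRB1*01:01" and m.exon == 2)
    assert m.exonic_fraction == 1.0
    assert m.exonic_span == (0, len(ra.exon(2)))


def test_match_flank_overhang_fraction():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=1)
    rng = np.random.default_rng(42)
    exon = ra.exon(2)
    seq = _dna(rng, 30) + exon + _dna(rng, 30)
    matches, unmatched = match_contigs([_contig(seq)], mdb, "HLA-DRB1", flank_len=50)
    m = next(m for m in matches if m.allele_label == "HLA-DRB1*01:01")
    assert m.exonic_span == (30, 30 + len(exon))
    assert m.exonic_fraction == pytest.approx(len(exon) / (len(exon) + 60))


def test_match_rejects_overhang_beyond_flank():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=2)
    rng = np.random.default_rng(43)
    seq = _dna(rng, 80) + ra.exon(2)  # 80 > flank_len 50
    matches, unmatched = match_contigs([_contig(seq)], mdb, "HLA-DRB1", flank_len=50)
    assert matches == [] and unmatched == [0]


def test_match_reverse_complement_contig():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=3)
    matches, _ = match_contigs([_contig(revcomp(ra.exon(2)))], mdb, "HLA-DRB1")
    m = next(m for m in matches if m.allele_label == "HLA-DRB1*01:01")
    assert m.strand == "-" and m.exonic_fraction == 1.0


def test_match_single_mismatch_unmatched():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=4)
    s = list(ra.exon(2))
    s[140] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[140]]
    matches, unmatched = match_contigs([_contig("".join(s))], mdb, "HLA-DRB1")
    # the mutated middle splits every alignment into blocks with >50 bp
    # unmatched tails, so the zero-tolerance rule rejects the contig
    assert unmatched == [0]


def test_match_partial_contig_inside_exon():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=5)
    part = ra.exon(2)[60:220]
    matches, unmatched = match_contigs([_contig(part)], mdb, "HLA-DRB1")
    m = next(m for m in matches if m.allele_label == "HLA-DRB1*01:01")
    assert m.exonic_span == (0, len(part)) and unmatched == []


# -- scoring ----------------------------------------------------------------


def test_score_arithmetic():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=6, exon_len=270)
    contigs = [_contig(ra.exon(2), depth=20)]
    matches, _ = match_contigs(contigs, mdb, "HLA-DRB1")
    own = [m for m in matches if m.allele_label == "HLA-DRB1*01:01"]
    scores = score_alleles(own)
    assert scores[0].total == pytest.approx(270 * 20 * 1.0)


def test_score_sum_rule_and_sharing():
    c0 = _contig("A" * 100, depth=10)
    c1 = _contig("C" * 200, depth=5)
    mk = lambda cid, c, label, frac: ContigMatch(
        contig_id=cid, allele_label=label, gene="HLA-DRB1", exon=2,
        exonic_span=(0, int(frac * len(c))), exonic_fraction=frac,
        strand="+", contig=c,
    )
    matches = [
        mk(0, c0, "X", 1.0),
        mk(1, c1, "X", 0.5),
        mk(0, c0, "Y", 1.0),  # shared contig counts fully for both
    ]
    scores = {s.allele_label: s.total for s in score_alleles(matches)}
    assert scores["X"] == pytest.approx(100 * 10 * 1.0 + 200 * 5 * 0.5)
    assert scores["Y"] == pytest.approx(100 * 10 * 1.0)


def test_score_ordering_and_tiebreak():
    c = _contig("A" * 100, depth=10)
    mk = lambda label: ContigMatch(
        contig_id=0, allele_label=label, gene="HLA-DRB1", exon=2,
        exonic_span=(0, 100), exonic_fraction=1.0, strand="+", contig=c,
    )
    scores = score_alleles([mk("B"), mk("A")])
    assert [s.allele_label for s in scores] == ["A", "B"]  # tie -> lexicographic


# -- designation ------------------------------------------------------------


def test_designate_heterozygote():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=7)
    contigs = [_contig(ra.exon(2)), _contig(rb.exon(2), depth=18)]
    matches, _ = match_contigs(contigs, mdb, "HLA-DRB1")
    call = designate_alleles(score_alleles(matches), matches, qc=_qc_good())
    assert sorted(call.alleles) == ["HLA-DRB1*01:01", "HLA-DRB1*02:01"]
    assert not call.homozygous and not call.no_call


def test_designate_homozygote_under_good_qc():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=8)
    contigs = [_contig(ra.exon(2)), _contig(ra.exon(3))]
    matches, _ = match_contigs(contigs, mdb, "HLA-DRB1")
    call = designate_alleles(score_alleles(matches), matches, qc=_qc_good())
    assert call.alleles == ["HLA-DRB1*01:01"] and call.homozygous
    assert call.reported_pair == ("HLA-DRB1*01:01", "HLA-DRB1*01:01")


def test_single_designation_under_bad_qc_is_no_call():
    ra, rb, mdb, _ = _mdb_two_alleles(seed=9)
    contigs = [_contig(ra.exon(2))]
    matches, _ = match_contigs(contigs, mdb, "HLA-DRB1")
    for qc in (
        QCReport(gene="HLA-DRB1", tier=TIER_FAIL, warning=True),
        QCReport(gene="HLA-DRB1", tier="10x>=95%", warning=True),  # dropout regime
    ):
        call = designate_alleles(score_alleles(matches), matches, qc=qc)
        assert call.no_call and not call.homozygous


def test_third_allele_documented_as_contamination():
    rng = np.random.default_rng(10)
    exons = [_dna(rng, 280) for _ in range(3)]
    recs = [
        make_record("HLA-DRB1", f"{i + 1:02d}:01", {2: e, 3: _dna(rng, 280)})
        for i, e in enumerate(exons)
    ]
    mdb, _ = build_exact_dbs(recs)
    contigs = [_contig(e, depth=30 - i) for i, e in enumerate(exons)]
    matches, _ = match_contigs(contigs, mdb, "HLA-DRB1")
    call = designate_alleles(score_alleles(matches), matches, qc=_qc_good())
    assert len(call.alleles) == 2
    assert call.extra_allele_contigs  # the third allele's unique contig
    assert any("contamination" in n for n in call.notes)


def test_no_matches_is_no_call():
    call = designate_alleles([], [], qc=_qc_good())
    assert call.no_call and call.reported_pair == ()


# -- minor-exon resolution --------------------------------------------------


def _g_group_set(seed=11):
    rng = np.random.default_rng(seed)
    shared2 = _dna(rng, 280)
    minor_a = _dna(rng, 280)
    minor_b = minor_a[:50] + ("A" if minor_a[50] != "A" else "C") + minor_a[51:]
    a = make_record("HLA-DRB1", "03:03:02:01", {2: shared2, 3: minor_a})
    b = make_record("HLA-DRB1", "03:03:03", {2: shared2, 3: minor_b})
    other = make_record("HLA-DRB1", "04:01", {2: _dna(rng, 280), 3: _dna(rng, 280)})
    mdb, adb = build_exact_dbs([a, b, other])
    assert "HLA-DRB1*03:03:02G" in mdb.labels("HLA-DRB1")
    return a, b, mdb, adb


def test_resolve_minor_exon_to_six_digits():
    a, b, mdb, adb = _g_group_set()
    call = TypingCall(gene="HLA-DRB1", alleles=["HLA-DRB1*03:03:02G"],
                      resolution=["G-group"], homozygous=True)
    out = resolve_minor_exons(call, [_contig(a.exon(3))], adb)
    assert out.alleles == ["HLA-DRB1*03:03:02"]
    assert out.resolution == ["six-digit"]


def test_resolve_keeps_group_without_minor_contig():
    a, b, mdb, adb = _g_group_set(seed=12)
    call = TypingCall(gene="HLA-DRB1", alleles=["HLA-DRB1*03:03:02G"],
                      resolution=["G-group"])
    out = resolve_minor_exons(call, [], adb)
    assert out.alleles == ["HLA-DRB1*03:03:02G"]


def test_resolve_identical_minors_keeps_group():
    rng = np.random.default_rng(13)
    shared2, shared3 = _dna(rng, 280), _dna(rng, 280)
    a = make_record("HLA-DRB1", "05:01:01", {2: shared2, 3: shared3})
    b = make_record("HLA-DRB1", "05:01:02", {2: shared2, 3: shared3})
    mdb, adb = build_exact_dbs([a, b])
    # both members identical on the minor exon: both survive, two member
    # sequence classes collapse to one, but six-digit names differ
    label = mdb.labels("HLA-DRB1")[0]
    call = TypingCall(gene="HLA-DRB1", alleles=[label], resolution=["G-group"])
    out = resolve_minor_exons(call, [_contig(shared3)], adb)
    assert out.alleles == [label]  # no unique six-digit name -> unchanged


# -- phase ambiguity --------------------------------------------------------


def _phase_fixture(gap, read_length=100, seed=14):
    """Two alleles heterozygous at two positions separated by ``gap``
    identical bases, plus both recombinants in the database."""
    rng = np.random.default_rng(seed)
    n = max(300, gap + 120)
    base = _dna(rng, n)
    p = 50
    q = p + gap + 1
    sub = {"A": "C", "C": "G", "G": "T", "T": "A"}

    def put(s, i, c):
        return s[:i] + c + s[i + 1 :]

    x = base
    y = put(put(base, p, sub[base[p]]), q, sub[base[q]])
    r1 = put(base, p, sub[base[p]])  # X with Y's block 1
    r2 = put(base, q, sub[base[q]])
    e3 = _dna(rng, 280)
    recs = [
        make_record("HLA-DRB1", "01:01", {2: x, 3: e3}),
        make_record("HLA-DRB1", "02:01", {2: y, 3: e3}),
        make_record("HLA-DRB1", "03:01", {2: r1, 3: e3}),
        make_record("HLA-DRB1", "04:01", {2: r2, 3: e3}),
    ]
    mdb, _ = build_exact_dbs(recs)
    return recs, mdb


@pytest.mark.parametrize("gap,ambiguous", [(30, False), (100, False), (101, True), (160, True)])
def test_phase_rule_boundary(gap, ambiguous):
    recs, mdb = _phase_fixture(gap)
    call = TypingCall(
        gene="HLA-DRB1",
        alleles=["HLA-DRB1*01:01", "HLA-DRB1*02:01"],
        resolution=["full", "full"],
    )
    out = detect_phase_ambiguity(call, [], read_length=100, mdb=mdb)
    assert out.phase_ambiguous == ambiguous
    if ambiguous:
        assert len(out.phase_alternatives) >= 2
        assert ("HLA-DRB1*03:01", "HLA-DRB1*04:01") in out.phase_alternatives


def test_phase_unknown_partner_reported():
    # recombinant r2 absent from the database: the alternative pair pairs the
    # known recombinant with the unknown placeholder
    recs, _ = _phase_fixture(150, seed=15)
    mdb, _ = build_exact_dbs(recs[:3])  # drop 04:01
    pairs = enumerate_consistent_pairs(
        recs[0].exons, recs[1].exons, 100, mdb, "HLA-DRB1"
    )
    assert ("HLA-DRB1*01:01", "HLA-DRB1*02:01") in pairs
    assert any("unknown" in p for p in pairs)


def test_phase_frequency_prefers_common_pair():
    recs, mdb = _phase_fixture(150, seed=16)
    freq = {
        "HLA-DRB1*01:01": 0.30,
        "HLA-DRB1*02:01": 0.20,
        "HLA-DRB1*03:01": 0.001,
        "HLA-DRB1*04:01": 0.0,
    }
    call = TypingCall(
        gene="HLA-DRB1",
        alleles=["HLA-DRB1*03:01", "HLA-DRB1*04:01"],
        resolution=["full", "full"],
    )
    out = detect_phase_ambiguity(call, [], read_length=100, mdb=mdb, freq=freq)
    assert out.phase_ambiguous
    assert sorted(out.alleles) == ["HLA-DRB1*01:01", "HLA-DRB1*02:01"]


# -- frequency tie-break ----------------------------------------------------


def test_break_ties_orderings():
    freq = {"A": 0.10, "B": 0.05, "C": 0.001, "D": 0.0}
    assert break_ties_by_frequency([(("C"), ("D")), (("A"), ("B"))], freq) == ("A", "B")
    # equal sums: decided by max member
    freq2 = {"A": 0.08, "B": 0.02, "C": 0.05, "D": 0.05}
    assert break_ties_by_frequency([("A", "B"), ("C", "D")], freq2) == ("A", "B")
    # all unknown: lexicographic
    assert break_ties_by_frequency([("Y", "Z"), ("W", "X")], {}) == ("W", "X")
    assert break_ties_by_frequency([("A", "B")], None) == ("A", "B")
    with pytest.raises(ValueError):
        break_ties_by_frequency([], {})
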