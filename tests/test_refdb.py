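"""Reference-set parsing and construction of CRP / mDB / aDB."""

import random

import pytest

from conftest import make_record
from hlacall.refdb import (
    AlleleRecord,
    IntegrityError,
    ParseError,
    Segment,
    build_crp,
    build_exact_dbs,
    g_group_label,
    gene_class,
    major_exons,
    minor_exons,
    parse_allele_set,
    targeted_exons,
    write_allele_set,
)

E = {  # fixed sequences reused across tests
    2: "ACGT" * 70,          # 280 bp
    3: "TTGACCGA" * 35,      # 280 bp
    4: "GATTACA" * 40,       # 280 bp
}
I100 = "AC" * 50
I2 = "GT" * 50


def test_gene_class_convention():
    assert gene_class("HLA-A") == 1
    assert gene_class("HLA-DRB1") == 2
    assert gene_class("HLA-DS01") == 2
    assert gene_class("HLA-S01") == 1
    assert gene_class("HLA-S01", overrides={"HLA-S01": 2}) == 2


def test_exon_conventions():
    assert major_exons("HLA-A") == (2, 3)
    assert minor_exons("HLA-A") == (4,)
    assert major_exons("HLA-DRB1") == (2,)
    assert minor_exons("HLA-DRB1") == (3,)
    assert targeted_exons("HLA-A") == (2, 3, 4)
    assert targeted_exons("HLA-DRB1") == (2, 3)


def test_segment_validation():
    with pytest.raises(ParseError):
        Segment("exon", 2, "ACGTN")
    with pytest.raises(ParseError):
        Segment("exon", 2, "")
    with pytest.raises(ParseError):
        Segment("promoter", 1, "ACGT")
    with pytest.raises(ParseError):
        Segment("exon", 0, "ACGT")


def test_record_invariants():
    with pytest.raises(IntegrityError):
        AlleleRecord(
            gene="HLA-A",
            name="01:01",
            segments=[Segment("exon", 3, "ACGT"), Segment("exon", 2, "ACGT")],
        )


def test_roundtrip_segmented_fasta(tmp_path):
    records = [
        make_record("HLA-A", "01:01:01", {2: E[2], 3: E[3], 4: E[4]}, {1: I100, 2: I2}),
        make_record("HLA-A", "02:01:01", {2: E[3], 3: E[2], 4: E[4]}),
        make_record("HLA-DRB1", "01:01:01", {2: E[2], 3: E[3]}, {1: I100}),
    ]
    path = tmp_path / "alleles.fasta"
    write_allele_set(records, path)
    back = parse_allele_set(path)
    assert len(back) == len(records)
    for a, b in zip(sorted(records, key=lambda r: r.label), sorted(back, key=lambda r: r.label)):
        assert a.label == b.label
        assert a.exons == b.exons
        assert {s.index: s.sequence for s in a.segments if s.kind == "intron"} == {
            s.index: s.sequence for s in b.segments if s.kind == "intron"
        }


def test_parse_sidecar_dialect(tmp_path):
    full = I100 + E[2] + I2
    fasta = tmp_path / "set.fasta"
    fasta.write_text(f">HLA-A*01:01\n{full}\n")
    (tmp_path / "set.fasta.segments.tsv").write_text(
        f"HLA-A*01:01\tHLA-A\tintron1\t0\t{len(I100)}\n"
        f"HLA-A*01:01\tHLA-A\texon2\t{len(I100)}\t{len(I100) + len(E[2])}\n"
        f"HLA-A*01:01\tHLA-A\tintron2\t{len(I100) + len(E[2])}\t{len(full)}\n"
    )
    recs = parse_allele_set(fasta)
    assert len(recs) == 1
    assert recs[0].exon(2) == E[2]
    assert recs[0].intron(1) == I100
    assert recs[0].full_sequence() == full


def test_parse_errors(tmp_path):
    bad = tmp_path / "bad.fasta"
    bad.write_text(">not-a-valid-id\nACGT\n")
    with pytest.raises(ParseError):
        parse_allele_set(bad)
    missing = tmp_path / "nope.fasta"
    with pytest.raises(FileNotFoundError):
        parse_allele_set(missing)


def test_parse_empty_file(tmp_path):
    empty = tmp_path / "empty.fasta"
    empty.write_text("")
    assert parse_allele_set(empty) == []


def test_duplicate_segment_rejected(tmp_path):
    p = tmp_path / "dup.fasta"
    p.write_text(
        ">HLA-A*01:01|segkind=exon2\nACGTACGTACGTACGTACGT\n"
        ">HLA-A*01:01|segkind=exon2\nACGTACGTACGTACGTACGT\n"
    )
    with pytest.raises(IntegrityError):
        parse_allele_set(p)


def test_crp_entry_arithmetic():
    exon = "A" * 270
    rec = make_record("HLA-DRB1", "01:01", {2: exon, 3: E[3]}, {1: "C" * 100, 2: "G" * 100, 3: "T" * 100})
    entries = build_crp([rec], {"HLA-DRB1"}, flank_len=50)
    e2 = next(e for e in entries if e.exon_index == 2)
    assert len(e2.sequence) == 370
    assert e2.exon_span == (50, 320)
    assert e2.exon_sequence == exon
    assert e2.role == "target"


def test_crp_flank_len_zero_identity():
    rec = make_record("HLA-DRB1", "01:01", {2: E[2], 3: E[3]}, {1: I100, 2: I2})
    entries = build_crp([rec], {"HLA-DRB1"}, flank_len=0)
    for e in entries:
        assert e.sequence == rec.exon(e.exon_index)


def test_crp_flank_borrowing_from_sibling():
    donor = make_record(
        "HLA-DRB1", "01:01", {2: E[2], 3: E[3]}, {1: I100, 2: I2, 3: "TG" * 60}
    )
    orphan = make_record("HLA-DRB1", "02:01", {2: E[3], 3: E[2]})
    entries = build_crp([donor, orphan], {"HLA-DRB1"}, flank_len=50)
    o2 = next(
        e for e in entries if e.source_allele == "HLA-DRB1*02:01" and e.exon_index == 2
    )
    assert o2.sequence == I100[-50:] + E[3] + I2[:50]


def test_crp_no_intron_anywhere_gives_zero_flank():
    rec = make_record("HLA-DRB1", "01:01", {2: E[2], 3: E[3]})
    entries = build_crp([rec], {"HLA-DRB1"}, flank_len=50)
    assert all(e.sequence == rec.exon(e.exon_index) for e in entries)


def test_crp_roles_and_overlap_error():
    t = make_record("HLA-A", "01:01", {2: E[2], 3: E[3], 4: E[4]})
    c = make_record("HLA-H", "01:01", {2: E[3], 3: E[4], 4: E[2]})
    entries = build_crp([t, c], {"HLA-A"}, {"HLA-H"}, flank_len=0)
    assert {e.role for e in entries if e.gene == "HLA-A"} == {"target"}
    assert {e.role for e in entries if e.gene == "HLA-H"} == {"competitor"}
    with pytest.raises(ValueError):
        build_crp([t], {"HLA-A"}, {"HLA-A"})


def test_crp_strip_flanks_recovers_exon():
    rec = make_record("HLA-A", "01:01", {2: E[2], 3: E[3], 4: E[4]}, {1: I100, 2: I2, 3: I100, 4: I2})
    for e in build_crp([rec], {"HLA-A"}, flank_len=37):
        lo, hi = e.exon_span
        assert e.sequence[lo:hi] == rec.exon(e.exon_index)


def test_g_group_label_rule():
    assert g_group_label("HLA-A", ["03:03:02:01", "03:03:02:02"]) == "HLA-A*03:03:02G"
    assert g_group_label("HLA-A", ["02:01", "01:01:01"]) == "HLA-A*01:01:01G"


def test_exact_dbs_g_collapse_class1():
    shared = {2: E[2], 3: E[3]}
    a = make_record("HLA-A", "01:01:01", {**shared, 4: E[4]})
    b = make_record("HLA-A", "01:01:02", {**shared, 4: E[4][:-4] + "TTTT"})
    c = make_record("HLA-A", "02:01:01", {2: E[3], 3: E[2], 4: E[4]})
    mdb, adb = build_exact_dbs([a, b, c])
    labels = mdb.labels("HLA-A")
    assert "HLA-A*01:01:01G" in labels and "HLA-A*02:01:01" in labels
    assert len(labels) == 2
    assert mdb.g_members["HLA-A*01:01:01G"] == {"HLA-A*01:01:01", "HLA-A*01:01:02"}
    # aDB records the minor exon (4) for every member
    adb_labels = {e.label: e.exon_sequences for e in adb.entries["HLA-A"]}
    assert adb_labels["HLA-A*01:01:01"] == {4: E[4]}
    assert adb_labels["HLA-A*01:01:02"] == {4: E[4][:-4] + "TTTT"}
    # mDB carries exactly the major exons, no introns
    for e in mdb.entries["HLA-A"]:
        assert set(e.exon_sequences) == {2, 3}


def test_exact_dbs_every_allele_in_exactly_one_membership():
    recs = [
        make_record("HLA-DRB1", "01:01:01", {2: E[2], 3: E[3]}),
        make_record("HLA-DRB1", "01:01:02", {2: E[2], 3: E[4]}),
        make_record("HLA-DRB1", "02:01:01", {2: E[3], 3: E[3]}),
        make_record("HLA-DRB1", "03:01:01", {2: E[4], 3: E[3]}),
    ]
    mdb, _ = build_exact_dbs(recs)
    covered: list[str] = []
    for label in mdb.labels("HLA-DRB1"):
        covered.extend(sorted(mdb.members(label)))
    assert sorted(covered) == sorted(r.label for r in recs)


def test_exact_dbs_all_distinct_no_groups():
    recs = [
        make_record("HLA-DRB1", "01:01", {2: E[2], 3: E[3]}),
        make_record("HLA-DRB1", "02:01", {2: E[3], 3: E[3]}),
    ]
    mdb, adb = build_exact_dbs(recs)
    assert mdb.g_members == {} and adb.entries == {}


def test_exact_dbs_order_independence(small_sim):
    _, panel, *_ = small_sim
    records = list(panel.records)
    mdb1, adb1 = build_exact_dbs(records)
    rng = random.Random(3)
    shuffled = list(records)
    rng.shuffle(shuffled)
    mdb2, adb2 = build_exact_dbs(shuffled)
    assert mdb1.to_json() == mdb2.to_json()
    assert adb1.to_json() == adb2.to_json()


def test_exact_dbs_errors():
    with pytest.raises(ValueError):
        build_exact_dbs([])
    dup = make_record("HLA-A", "01:01", {2: E[2], 3: E[3]})
    with pytest.raises(IntegrityError):
        build_exact_dbs([dup, dup])


def test_exact_db_json_roundtrip(small_dbs):
    from hlacall.refdb import ExactDB

    mdb, adb = small_dbs
    assert ExactDB.from_json(mdb.to_json()).to_json() == mdb.to_json()
    assert ExactDB.from_json(adb.to_json()).to_json() == adb.to_json()
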