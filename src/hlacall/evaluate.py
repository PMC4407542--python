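"""Comparison of typing calls against a simulated truth genotype."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .calling import TypingCall, UNKNOWN_ALLELE
from .refdb import ExactDB


def four_digit(name_or_label: str) -> str:
    """First two colon-fields of an allele name (gene prefix kept if present)."""
    if "*" in name_or_label:
        gene, name = name_or_label.split("*", 1)
        prefix = gene + "*"
    else:
        prefix, name = "", name_or_label
    name = name.rstrip("G")
    return prefix + ":".join(name.split(":")[:2])


def label_four_digit_set(label: str, mdb: ExactDB | None = None) -> set[str]:
    """Four-digit designations a reported label may stand for.

    A G-group label expands to its members; a plain or six-digit label
    stands for itself.
    """
    if label == UNKNOWN_ALLELE:
        return set()
    if label.endswith("G") and mdb is not None and label in mdb.g_members:
        return {four_digit(m) for m in mdb.g_members[label]}
    return {four_digit(label)}


def pair_correct(
    called: Sequence[str], truth: tuple[str, str], mdb: ExactDB | None = None
) -> tuple[bool, bool]:
    """Per-truth-allele correctness at four-digit-equivalent resolution.

    ``called`` is the reported pair (a homozygote passed twice).  The best
    assignment of called labels to truth alleles is used; each truth allele
    is correct when its four-digit name is covered by its assigned label.
    """
    t = [four_digit(x) for x in truth]
    sets = [label_four_digit_set(c, mdb) for c in called]
    if not sets:
        return (False, False)
    if len(sets) == 1:
        sets = sets * 2

    def assignment(order: tuple[int, int]) -> tuple[bool, bool]:
        return (t[0] in sets[order[0]], t[1] in sets[order[1]])

    a, b = assignment((0, 1)), assignment((1, 0))
    return a if sum(a) >= sum(b) else b


def score_calls(
    calls: Mapping[str, TypingCall],
    genotype: Mapping[str, tuple[str, str]],
    mdb: ExactDB | None = None,
    genes: Iterable[str] | None = None,
) -> tuple[int, int]:
    """(correct alleles, total alleles) over the given genes."""
    genes = list(genes) if genes is not None else sorted(genotype)
    n_correct = total = 0
    for gene in genes:
        truth = genotype[gene]
        call = calls.get(gene)
        reported = call.reported_pair if call is not None else ()
        ok = pair_correct(reported, truth, mdb)
        n_correct += sum(ok)
        total += 2
    return n_correct, total
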