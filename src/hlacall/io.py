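"""Readers and writers for the standard formats the pipeline touches:
FASTQ reads, the allele-set dialects (see :mod:`hlacall.refdb`), the
allele-frequency TSV, and contig/report output."""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .assemble import Contig
from .classify import Read


class FrequencyTable:
    """Allele population frequencies keyed by full label (``GENE*NAME``)."""

    def __init__(self, mapping: dict[str, float] | None = None):
        self._map = dict(mapping or {})

    def get(self, label: str, default: float | None = None) -> float | None:
        return self._map.get(label, default)

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, label: str) -> bool:
        return label in self._map

    def items(self):
        return self._map.items()


def load_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a two-column TSV ``allele<TAB>frequency`` (no header)."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["allele", "frequency"])
    # tolerate an optional header row
    if len(tab) and not _is_number(tab.iloc[0]["frequency"]):
        tab = tab.iloc[1:]
    mapping = {str(a): float(f) for a, f in zip(tab["allele"], tab["frequency"])}
    for label, f in mapping.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency of {label} outside [0,1]: {f}")
    return FrequencyTable(mapping)


def write_frequency_table(freq: FrequencyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, f in sorted(freq.items()):
            fh.write(f"{label}\t{f:.6g}\n")


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTQ file (plain or gzipped)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            quals = rec.letter_annotations.get("phred_quality")
            yield Read(
                id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities="".join(chr(q + 33) for q in quals) if quals else None,
            )


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for r in reads:
            q = r.qualities or "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{q}\n")


def write_contig_fasta(contigs: Sequence[Contig], path: str | Path) -> None:
    """Contigs as FASTA with depth statistics on the description line."""
    with open(path, "w") as fh:
        for i, c in enumerate(contigs):
            fh.write(
                f">{c.gene}|contig{i} length={len(c)} mean_depth={c.mean_depth:.2f} "
                f"support={c.support}\n"
            )
            for j in range(0, len(c.sequence), 70):
                fh.write(c.sequence[j : j + 70] + "\n")


def write_depth_tsv(contigs: Sequence[Contig], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tposition\tdepth\n")
        for i, c in enumerate(contigs):
            for j, d in enumerate(c.depth):
                fh.write(f"{c.gene}|contig{i}\t{j}\t{int(d)}\n")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    import numpy as np

    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, set):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
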