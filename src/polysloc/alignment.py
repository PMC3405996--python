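"""Aligned nucleotide sequence container and FASTA I/O.

Sequences are stored as uppercase strings over the alphabet ``{A, C, G, T,
-, N}``; any other IUPAC ambiguity code is treated like ``N`` (excluded from
pairwise comparisons). All rows of an alignment must have equal length and
unique labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")


@dataclass
class Alignment:
    """A labeled multiple sequence alignment.

    Parameters
    ----------
    labels
        Unique sequence identifiers, one per row.
    rows
        Aligned nucleotide strings, all of the same length.
    """

    labels: list[str]
    rows: list[str]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows must have the same length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("alignment labels must be unique")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows must all have the same length")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return self.n_sequences

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.labels, self.rows))

    def sequence(self, label: str) -> str:
        return self.rows[self._index[label]]

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def subset(self, labels: Sequence[str]) -> "Alignment":
        """Return the sub-alignment restricted to ``labels`` (kept in the
        given order)."""
        return Alignment(list(labels), [self.sequence(lab) for lab in labels])

    def comparable_columns(self) -> list[int]:
        """Columns where every sequence has an unambiguous base (complete
        deletion)."""
        cols = []
        for j in range(self.length):
            if all(row[j] in VALID_BASES for row in self.rows):
                cols.append(j)
        return cols


def read_fasta(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`."""
    labels, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        labels.append(rec.id)
        rows.append(str(rec.seq))
    if not labels:
        raise ValueError(f"no sequences found in {path}")
    return Alignment(labels, rows)


def write_fasta(aln: Alignment, path) -> None:
    """Write an :class:`Alignment` to FASTA (one line per sequence)."""
    records = [
        SeqRecord(Seq(row), id=lab, description="") for lab, row in aln
    ]
    SeqIO.write(records, str(path), "fasta-2line")
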