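"""Multiple-alignment container shared by the consensus and conservation modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGTN-"
GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """Gapped rows over shared columns.

    Rows are ``(name, gapped_sequence)`` pairs; all gapped sequences have the
    same length and names are unique. The alphabet is {A, C, G, T, N, -}.
    """

    rows: tuple[tuple[str, str], ...]
    n_columns: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment must contain at least one row")
        lengths = {len(seq) for _, seq in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        names = [name for name, _ in self.rows]
        if len(set(names)) != len(names):
            raise ValueError("row names must be unique")
        object.__setattr__(self, "n_columns", lengths.pop())
        for name, seq in self.rows:
            bad = set(seq) - set(ALPHABET)
            if bad:
                raise ValueError(f"row {name!r} contains invalid characters {bad}")
        # All-gap columns are tolerated (they can arise when subsetting rows);
        # consensus building drops them and conservation never counts them.

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.rows]

    def row(self, name: str) -> str:
        for n, seq in self.rows:
            if n == name:
                return seq
        raise KeyError(name)

    def subset(self, names: list[str]) -> "MultipleAlignment":
        """Alignment restricted to the given rows (columns are kept as-is)."""
        wanted = dict(self.rows)
        return MultipleAlignment(tuple((n, wanted[n]) for n in names))

    def to_array(self) -> np.ndarray:
        """Character matrix of shape (n_rows, n_columns), dtype '<U1'."""
        return np.array([list(seq) for _, seq in self.rows])

    def ungapped(self, name: str) -> str:
        return self.row(name).replace(GAP, "")


def read_alignment(path) -> MultipleAlignment:
    """Read an aligned-FASTA file into a :class:`MultipleAlignment`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return MultipleAlignment(tuple((r.id, str(r.seq).upper()) for r in records))


def write_alignment(msa: MultipleAlignment, path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in msa.rows]
    SeqIO.write(records, str(path), "fasta")
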