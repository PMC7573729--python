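"""Aligned sequence containers and FASTA input/output.

Alignments are consumed pre-aligned (external aligners produce them); this
module only validates and stores them.  Two alphabets are supported:
``nucleotide`` (ACGT, ambiguity N) and ``amino-acid`` (the 20 standard
residues, ambiguity X).  The gap symbol is ``-``; gaps and ambiguity codes
are treated as missing data by every downstream likelihood or counting
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AlignmentShapeError, AlphabetError, IdError, ParseError

GAP = "-"
NUCLEOTIDES = "ACGT"
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_ALPHABETS = {
    "nucleotide": (set(NUCLEOTIDES), {"N"}),
    "amino-acid": (set(AMINO_ACIDS), {"X"}),
}


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped sequences with unique identifiers.

    Parameters
    ----------
    ids : tuple of str
        Sequence identifiers, order-preserving and unique.
    rows : tuple of str
        Aligned sequences (upper case), one per id, all of equal length.
    alphabet : {"nucleotide", "amino-acid"}
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str
    gap: str = GAP

    def __post_init__(self):
        if self.alphabet not in _ALPHABETS:
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in count")
        if len(self.ids) != len(set(self.ids)) or any(not i for i in self.ids):
            raise IdError("sequence ids must be unique and non-empty")
        if not self.rows or not self.rows[0]:
            raise AlignmentShapeError("alignment must contain at least one column")
        width = len(self.rows[0])
        letters, ambig = _ALPHABETS[self.alphabet]
        allowed = letters | ambig | {self.gap}
        for sid, row in zip(self.ids, self.rows):
            if len(row) != width:
                raise AlignmentShapeError(
                    f"sequence {sid!r} has length {len(row)}, expected {width}"
                )
            for pos, ch in enumerate(row):
                if ch not in allowed:
                    raise AlphabetError(
                        f"illegal character {ch!r} in sequence {sid!r} at position {pos}"
                    )

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise IdError(f"no sequence with id {sid!r}") from None

    def select_columns(self, cols) -> "Alignment":
        """Return a new alignment keeping the given column indices (in order)."""
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Alignment(self.ids, rows, self.alphabet, self.gap)


@dataclass(frozen=True)
class CodonAlignment(Alignment):
    """Nucleotide alignment whose length is a multiple of three.

    Codon structure is positional: codon ``k`` spans columns ``3k..3k+2``.
    """

    alphabet: str = field(default="nucleotide")

    def __post_init__(self):
        if self.alphabet != "nucleotide":
            raise AlphabetError("codon alignments must be nucleotide")
        super().__post_init__()
        if self.n_cols % 3 != 0:
            raise AlignmentShapeError(
                f"codon alignment length {self.n_cols} is not a multiple of 3"
            )

    @property
    def n_codons(self) -> int:
        return self.n_cols // 3

    def codons(self, sid: str) -> list[str]:
        row = self.row(sid)
        return [row[i : i + 3] for i in range(0, len(row), 3)]


def read_fasta(path, alphabet: str) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Record order is preserved; sequences are upper-cased.  Ragged lengths or
    characters outside the declared alphabet raise immediately.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"no FASTA records in {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq).upper() for r in records)
    cls = CodonAlignment if alphabet == "codon" else Alignment
    if alphabet == "codon":
        return cls(ids, rows)
    return cls(ids, rows, alphabet)


def write_fasta(aln: Alignment, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in zip(aln.ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def translate(codon_aln: CodonAlignment) -> Alignment:
    """Translate a codon alignment under the standard genetic code.

    Gap codons become ``-``; codons containing ambiguity become ``X``.
    """
    rows = []
    for sid in codon_aln.ids:
        aas = []
        for codon in codon_aln.codons(sid):
            if GAP in codon:
                aas.append(GAP)
            elif "N" in codon:
                aas.append("X")
            else:
                aa = str(Seq(codon).translate())
                aas.append("X" if aa == "*" else aa)
        rows.append("".join(aas))
    return Alignment(codon_aln.ids, tuple(rows), "amino-acid")
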