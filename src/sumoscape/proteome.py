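"""Species-tagged protein sequence collections.

A :class:`Proteome` is the universe over which orthology calling, motif
scanning and SUMOylation prediction operate.  Sequences are plain
amino-acid strings over the 20 standard residues plus the ambiguity codes
``B``/``Z``/``X`` and selenocysteine ``U``; a single trailing ``*`` (stop)
is stripped on input.  Identifiers are the first whitespace-delimited
header token and must be unique within a proteome.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")
EXTENDED_RESIDUES = STANDARD_RESIDUES | set("XUBZ")


class ProteomeError(ValueError):
    """Raised on malformed or inconsistent proteome input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a stable identifier and species tag."""

    id: str
    species: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ProteomeError(f"invalid identifier {self.id!r}")
        seq = self.sequence.upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise ProteomeError(f"record {self.id!r}: empty sequence")
        for pos, residue in enumerate(seq, start=1):
            if residue not in EXTENDED_RESIDUES:
                raise ProteomeError(
                    f"record {self.id!r}: residue {residue!r} at position {pos} "
                    "outside the amino-acid alphabet"
                )
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Proteome:
    """Ordered, uniquely-identified collection of :class:`ProteinRecord`."""

    species: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.species != self.species:
                raise ProteomeError(
                    f"record {rec.id!r} tagged {rec.species!r}, expected {self.species!r}"
                )
            if rec.id in self._index:
                raise ProteomeError(f"duplicate identifier {rec.id!r}")
            self._index[rec.id] = rec

    @property
    def size(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.size

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._index

    def __getitem__(self, protein_id: str) -> ProteinRecord:
        return self._index[protein_id]

    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]


def read_fasta(path: str | Path, species: str) -> Proteome:
    """Read an amino-acid FASTA file into a :class:`Proteome`.

    The identifier is the first whitespace-delimited token of each header;
    the remainder of the header is kept as the record description but never
    used for joins.  Sequences are upper-cased and a single trailing stop
    symbol is stripped.  Duplicate identifiers, an empty file, or residues
    outside the allowed alphabet are hard errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        desc = seqrec.description
        if desc.startswith(seqrec.id):
            desc = desc[len(seqrec.id):].strip()
        records.append(
            ProteinRecord(
                id=seqrec.id,
                species=species,
                sequence=str(seqrec.seq),
                description=desc,
            )
        )
    if not records:
        raise ProteomeError(f"{path}: no FASTA records found")
    return Proteome(species=species, records=records)


def write_fasta(proteome: Proteome, path: str | Path) -> None:
    """Write a proteome back to FASTA (round-trips with :func:`read_fasta`)."""
    seqrecs = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        for rec in proteome
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def proteome_stats(proteome: Proteome) -> dict:
    """Size and residue-composition summary.

    Returns ``size``, ``total_residues`` and ``composition`` (fraction per
    residue, summing to 1 within 1e-9).  Invariant to record order.
    """
    counts: Counter[str] = Counter()
    for rec in proteome:
        counts.update(rec.sequence)
    total = sum(counts.values())
    return {
        "species": proteome.species,
        "size": proteome.size,
        "total_residues": total,
        "composition": {res: n / total for res, n in sorted(counts.items())},
    }


def subset(proteome: Proteome, ids: Iterable[str]) -> list[ProteinRecord]:
    """Records for the given identifiers; unknown ids are a hard error."""
    out = []
    for protein_id in ids:
        if protein_id not in proteome:
            raise ProteomeError(f"unknown identifier {protein_id!r}")
        out.append(proteome[protein_id])
    return out
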