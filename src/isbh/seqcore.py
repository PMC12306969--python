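"""Nucleic-acid sequence primitives shared by all design modules.

All internal work happens in the RNA alphabet {A, C, G, U}. DNA input is
accepted (T is normalised to U on ingestion) and the original alphabet is
remembered so sequences can be re-exported faithfully. Coordinates in
user-facing reports are 1-based inclusive; internal slicing is 0-based
half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Watson-Crick + G·U wobble pairs (RNA).
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})
LEGAL_PAIRS = WC_PAIRS | WOBBLE_PAIRS


class SequenceError(ValueError):
    """Raised for malformed or non-canonical sequence input."""


class FastaError(ValueError):
    """Raised for malformed FASTA input (headers, duplicates, empties)."""


@dataclass(frozen=True)
class NucSeq:
    """An RNA sequence with a name.

    ``residues`` is stored uppercase over {A,C,G,U}. ``source_alphabet`` is
    "RNA" or "DNA" depending on what was ingested, so exports can restore T.
    """

    name: str
    residues: str
    source_alphabet: str = field(default="RNA", compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.name!r} is empty")
        raw = self.residues.upper()
        alphabet = "DNA" if "T" in raw and "U" not in raw else "RNA"
        normalised = raw.replace("T", "U")
        for i, base in enumerate(normalised):
            if base not in RNA_ALPHABET:
                raise SequenceError(
                    f"sequence {self.name!r}: non-canonical symbol "
                    f"{base!r} at position {i + 1}"
                )
        object.__setattr__(self, "residues", normalised)
        if alphabet == "DNA":
            object.__setattr__(self, "source_alphabet", "DNA")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    def __getitem__(self, key) -> str:
        return self.residues[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)

    def rename(self, name: str) -> "NucSeq":
        return NucSeq(name, self.residues, self.source_alphabet)

    def as_dna(self) -> str:
        """Return the residues in the DNA alphabet (U -> T)."""
        return self.residues.replace("U", "T")


def complement_base(base: str) -> str:
    """WC complement of a single RNA base."""
    if base not in RNA_ALPHABET:
        raise SequenceError(f"non-canonical symbol {base!r}")
    return base.translate(_COMPLEMENT)


def revcomp(seq: NucSeq) -> NucSeq:
    """Reverse complement under RNA pairing (A<->U, C<->G).

    An involution: ``revcomp(revcomp(s)) == s``.
    """
    return NucSeq(
        f"{seq.name}_rc",
        seq.residues.translate(_COMPLEMENT)[::-1],
        seq.source_alphabet,
    )


def gc_content(seq: NucSeq) -> float:
    """Fraction of G+C residues, in [0, 1]."""
    n = len(seq)
    return (seq.residues.count("G") + seq.residues.count("C")) / n


def can_pair(a: str, b: str, wobble: bool = True) -> bool:
    """Whether two bases can form a WC (optionally G·U wobble) pair."""
    pair = (a, b)
    return pair in WC_PAIRS or (wobble and pair in WOBBLE_PAIRS)


# ---------------------------------------------------------------------------
# FASTA / TSV I/O (Biopython-backed)
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> List[NucSeq]:
    """Read a multi-record FASTA into a list of :class:`NucSeq`.

    Duplicate identifiers and empty records are rejected; non-canonical
    residues raise :class:`SequenceError` naming the record.
    """
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaError(f"{path}: malformed header ({exc})") from exc
    with open(path) as fh:
        first = fh.read(1)
        if first and first not in ">;":
            raise FastaError(f"{path}: malformed header (expected '>')")
    seen: set[str] = set()
    out: List[NucSeq] = []
    for rec in records:
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        if not str(rec.seq):
            raise FastaError(f"{path}: record {rec.id!r} is empty")
        out.append(NucSeq(rec.id, str(rec.seq)))
    return out


def write_fasta(seqs: Iterable[NucSeq], path: str | os.PathLike) -> None:
    """Write records to FASTA, wrapped at 60 columns, RNA alphabet as stored
    unless the record was ingested as DNA."""
    records = []
    for s in seqs:
        text = s.as_dna() if s.source_alphabet == "DNA" else s.residues
        records.append(SeqRecord(Seq(text), id=s.name, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_table(seqs: Iterable[NucSeq], path: str | os.PathLike) -> None:
    """TSV summary table with columns name, length, sequence."""
    import pandas as pd

    df = pd.DataFrame(
        [{"name": s.name, "length": len(s), "sequence": s.residues} for s in seqs]
    )
    df.to_csv(path, sep="\t", index=False)
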