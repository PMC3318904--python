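"""Sequence container, FASTA I/O, validation, and the random-sequence generator.

The package works on protein sequences over the 24-letter NCBI alphabet used
by BLOSUM62 (20 standard amino acids plus the ambiguity codes B, Z, X and the
stop/any symbol ``*``).  Every sequence entering an alignment is validated
against that alphabet up front so scoring lookups can never fail mid-DP.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: NCBI protein alphabet in BLOSUM62 row order.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"

#: The 20 standard amino acids (the first 20 letters of the alphabet).
STANDARD_AA = PROTEIN_ALPHABET[:20]

_ALPHABET_INDEX = {aa: i for i, aa in enumerate(PROTEIN_ALPHABET)}

#: Columns per line when writing FASTA.
FASTA_LINE_WIDTH = 60


class SequenceError(ValueError):
    """Raised for empty inputs or residues outside the protein alphabet."""


@dataclass(frozen=True)
class Sequence:
    """A validated protein sequence.

    Parameters
    ----------
    id : str
        Free-text identifier (FASTA header up to first whitespace).
    residues : str
        Uppercase residue string over :data:`PROTEIN_ALPHABET`.
    """

    id: str
    residues: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        object.__setattr__(self, "residues", residues)
        if len(residues) < 1:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, aa in enumerate(residues):
            if aa not in _ALPHABET_INDEX:
                raise SequenceError(
                    f"sequence {self.id!r}: illegal residue {aa!r} at position "
                    f"{pos + 1} (alphabet is {PROTEIN_ALPHABET})"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def codes(self) -> np.ndarray:
        """Residues as uint8 indices into :data:`PROTEIN_ALPHABET`."""
        return np.array([_ALPHABET_INDEX[aa] for aa in self.residues], dtype=np.uint8)


def codes_to_residues(codes: np.ndarray) -> str:
    """Inverse of :meth:`Sequence.codes`."""
    return "".join(PROTEIN_ALPHABET[c] for c in codes)


def read_fasta(path, *, map_unknown_to_x: bool = False) -> list[Sequence]:
    """Read a protein FASTA file into a list of :class:`Sequence`.

    Residues are uppercased; record order is preserved.  Validation is strict:
    a residue outside the 24-letter alphabet raises :class:`SequenceError`
    naming the record and position.  With ``map_unknown_to_x=True`` unknown
    residues are replaced by ``X`` instead (for real-world data containing
    rare codes such as U or O).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no sequences found in {path}")
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        if map_unknown_to_x:
            residues = "".join(
                aa if aa in _ALPHABET_INDEX else "X" for aa in residues
            )
        out.append(Sequence(id=rec.id, residues=residues, description=rec.description))
    return out


def write_fasta(sequences, path) -> None:
    """Write sequences as wrapped FASTA (60 columns, bit-stable output)."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in sequences
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_LINE_WIDTH)
        writer.write_file(records)


def fasta_string(sequences) -> str:
    """FASTA text for a sequence collection (same format as :func:`write_fasta`)."""
    buf = io.StringIO()
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description or "")
        for s in sequences
    ]
    SeqIO.FastaIO.FastaWriter(buf, wrap=FASTA_LINE_WIDTH).write_file(records)
    return buf.getvalue()


def generate_random_sequences(
    count: int,
    length: int,
    composition="uniform",
    seed: int = 0,
    id_prefix: str = "seq",
) -> list[Sequence]:
    """Generate random protein sequences with a given residue composition.

    ``composition`` is either ``"uniform"`` (equal frequency over the 20
    standard amino acids) or a mapping residue -> frequency summing to 1
    within 1e-9.  Output is reproducible for a fixed ``seed``.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")

    if composition == "uniform":
        residues = list(STANDARD_AA)
        probs = np.full(len(residues), 1.0 / len(residues))
    else:
        residues = list(composition.keys())
        for aa in residues:
            if aa not in _ALPHABET_INDEX:
                raise SequenceError(f"composition residue {aa!r} not in alphabet")
        probs = np.array([composition[aa] for aa in residues], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"composition frequencies sum to {probs.sum()}, not 1")

    rng = np.random.default_rng(seed)
    letters = np.array(residues)
    out = []
    for i in range(count):
        draw = rng.choice(letters, size=length, p=probs)
        out.append(Sequence(id=f"{id_prefix}{i}", residues="".join(draw)))
    return out
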