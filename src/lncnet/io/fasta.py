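"""FASTA reading/writing with a single normalized nucleotide alphabet.

Sequences are stored uppercase on the DNA alphabet (U -> T) so genome logic
and the duplex engine share one representation; pairing rules elsewhere are
stated on the RNA sense.
"""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO

ALPHABET = set("ACGTN")


class FastaError(ValueError):
    pass


def normalize_sequence(seq: str, name: str = "<seq>") -> str:
    """Uppercase, U->T; raise naming the first illegal character position."""
    norm = seq.upper().replace("U", "T")
    for pos, char in enumerate(norm):
        if char not in ALPHABET:
            raise FastaError(
                f"illegal character {char!r} at position {pos} in {name}"
            )
    return norm


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> normalized sequence map.

    Raises
    ------
    FastaError
        On duplicate ids, empty records, or characters outside {A,C,G,T,U,N}.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FastaError(f"duplicate sequence id {record.id!r} in {path}")
        seq = str(record.seq)
        if not seq:
            raise FastaError(f"empty record {record.id!r} in {path}")
        sequences[record.id] = normalize_sequence(seq, record.id)
    return sequences


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")
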