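"""Light-weight readers/writers for the plain-text formats used throughout."""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> ordered {id: sequence} (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def iter_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) triples; raises on malformed records."""
    with open(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for title, seq, qual in reads:
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


def sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


_COMP = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement in DNA space (U treated as T)."""
    return seq.translate(_COMP)[::-1]


def to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")
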