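"""In-memory genome container with FASTA round-trip."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import decode, encode


@dataclass
class Genome:
    """A set of chromosomes stored as uint8 base codes (A=0..T=3, N=4)."""

    chromosomes: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.chromosomes = {
            name: np.asarray(seq, dtype=np.uint8) for name, seq in self.chromosomes.items()
        }

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def length(self, name: str) -> int:
        return int(self.chromosomes[name].size)

    def sequence(self, name: str) -> str:
        return decode(self.chromosomes[name])

    def copy(self) -> "Genome":
        return Genome({n: s.copy() for n, s in self.chromosomes.items()})

    @classmethod
    def from_sequences(cls, sequences: dict[str, str]) -> "Genome":
        return cls({name: encode(seq) for name, seq in sequences.items()})

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        chroms: dict[str, np.ndarray] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            chroms[rec.id] = encode(str(rec.seq))
        if not chroms:
            raise ValueError(f"no sequences found in FASTA {path}")
        return cls(chroms)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(self.sequence(name)), id=name, description="")
            for name in self.chromosomes
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)
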