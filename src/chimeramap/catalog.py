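"""Mature miRNA catalog: sequences, seed-derived families, precursor loci.

The family key is the subsequence at miRNA positions 2-8 (7 nt, 5'->3'):
the target-side 8mer site consists of Watson-Crick matches to these seven
positions plus an adenosine opposite position 1, so two miRNAs share a
family exactly when positions 2-8 are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from . import seq
from .intervals import GenomicInterval

MIN_MIRNA_LEN = 17
MAX_MIRNA_LEN = 26


class InvalidMiRNAError(ValueError):
    pass


def family_key(mirna_sequence: str) -> str:
    """Seed-derived family key: miRNA positions 2-8 (0-based slice [1:8])."""
    s = seq.normalize(mirna_sequence)
    if len(s) < 9:
        raise InvalidMiRNAError(
            f"miRNA sequence too short for a family key ({len(s)} < 9 nt)"
        )
    return s[1:8]


@dataclass(frozen=True)
class MiRNA:
    name: str
    sequence: str  # DNA alphabet after normalization
    precursor_locus: Optional[GenomicInterval] = None
    arm: Optional[str] = None  # "5p" or "3p"

    @property
    def family_key(self) -> str:
        return family_key(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


class MiRNACatalog:
    """Ordered collection of mature miRNAs, indexed by name."""

    def __init__(self, mirnas: Iterable[MiRNA]):
        self._by_name: dict[str, MiRNA] = {}
        for m in mirnas:
            s = seq.normalize(m.sequence)
            if not set(s) <= seq.VALID_BASES:
                raise InvalidMiRNAError(f"{m.name}: non-ACGT bases after normalization")
            if not (MIN_MIRNA_LEN <= len(s) <= MAX_MIRNA_LEN):
                raise InvalidMiRNAError(
                    f"{m.name}: length {len(s)} outside {MIN_MIRNA_LEN}-{MAX_MIRNA_LEN} nt"
                )
            if m.name in self._by_name:
                raise InvalidMiRNAError(f"duplicate miRNA name {m.name}")
            self._by_name[m.name] = MiRNA(m.name, s, m.precursor_locus, m.arm)

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> MiRNA:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def families(self) -> dict[str, list[MiRNA]]:
        fams: dict[str, list[MiRNA]] = {}
        for m in self:
            fams.setdefault(m.family_key, []).append(m)
        return fams

    @classmethod
    def from_fasta(cls, path: str) -> "MiRNACatalog":
        from .io import read_fasta

        return cls(MiRNA(name, s) for name, s in read_fasta(path).items())
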