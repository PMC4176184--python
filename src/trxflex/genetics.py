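"""Genetic-code helpers shared across the package.

The standard genetic code (NCBI table 1) is used by default; any
:class:`Bio.Data.CodonTable` id can be plugged in.  For the statistics
implemented here (synonymy, degenerate-family entropy) the bacterial
table 11 is equivalent to table 1 — the codon→amino-acid assignments are
identical, only start-codon annotations differ.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Tuple

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_BASE_BYTES = np.frombuffer(BASES.encode(), dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOP_AA = "*"


def revcomp(seq: str) -> str:
    """Reverse complement of an unambiguous DNA string."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def is_transition(from_base: str, to_base: str) -> bool:
    """True if the pair is purine↔purine or pyrimidine↔pyrimidine."""
    pair = {from_base, to_base}
    return pair <= PURINES or pair <= PYRIMIDINES


def encode(seq: str) -> np.ndarray:
    """Map an ACGT string to a uint8 code array (A=0, C=1, G=2, T=3).

    Raises ``ValueError`` naming the first offending position for any
    character outside the unambiguous alphabet.
    """
    arr = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = _ENCODE_LUT[arr]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        raise ValueError(
            f"invalid base {seq[bad[0]]!r} at position {int(bad[0])}"
        )
    return codes


def decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


_ENCODE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_LUT[ord(_b)] = _i


@dataclass(frozen=True)
class GeneticCode:
    """A genetic code: codon→amino-acid map plus derived synonym structure."""

    table_id: int
    codon_to_aa: Dict[str, str]
    stop_codons: Tuple[str, ...]
    # amino acid -> sorted tuple of codons (sense codons only)
    aa_to_codons: Dict[str, Tuple[str, ...]] = field(default_factory=dict)

    @property
    def sense_codons(self) -> Tuple[str, ...]:
        return tuple(
            c for c in sorted(self.codon_to_aa) if self.codon_to_aa[c] != STOP_AA
        )

    @property
    def degenerate_families(self) -> Dict[str, Tuple[str, ...]]:
        """Amino acids encoded by ≥2 codons (Met/Trp and stops excluded)."""
        return {
            aa: codons
            for aa, codons in self.aa_to_codons.items()
            if aa != STOP_AA and len(codons) >= 2
        }

    def translate_codon(self, codon: str) -> str:
        """Amino acid for a codon; stops return '*'."""
        return self.codon_to_aa[codon]

    def translate(self, seq: str) -> str:
        if len(seq) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        return "".join(
            self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3)
        )

    def synonyms(self, codon: str) -> Tuple[str, ...]:
        """All codons (incl. the input) encoding the same amino acid."""
        return self.aa_to_codons[self.codon_to_aa[codon]]

    def is_synonymous_change(self, codon: str, pos_in_codon: int, new_base: str) -> bool:
        """Does substituting one base into this codon preserve the amino acid?

        Stops count as their own 'amino acid': stop→stop is synonymous,
        stop→sense (or the reverse) is not.
        """
        mutated = codon[:pos_in_codon] + new_base + codon[pos_in_codon + 1 :]
        return self.codon_to_aa[mutated] == self.codon_to_aa[codon]


@lru_cache(maxsize=None)
def get_code(table_id: int = 1) -> GeneticCode:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    codon_to_aa = dict(table.forward_table)
    for stop in table.stop_codons:
        codon_to_aa[stop] = STOP_AA
    # ensure all 64 codons present
    for codon in ("".join(c) for c in itertools.product(BASES, repeat=3)):
        codon_to_aa.setdefault(codon, STOP_AA)
    aa_to_codons: Dict[str, List[str]] = {}
    for codon, aa in codon_to_aa.items():
        aa_to_codons.setdefault(aa, []).append(codon)
    return GeneticCode(
        table_id=table_id,
        codon_to_aa=codon_to_aa,
        stop_codons=tuple(sorted(table.stop_codons)),
        aa_to_codons={aa: tuple(sorted(cs)) for aa, cs in aa_to_codons.items()},
    )


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding sequence.

    The sequence is uppercased at construction; only unambiguous A/C/G/T
    is accepted (ambiguity codes would silently corrupt flexibility and
    bias scores, so they are rejected up front).  Divisibility by 3 is
    enforced by the codon-level operations, not here, so nucleotide-level
    scores remain usable on arbitrary fragments.
    """

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) < 3:
            raise ValueError(f"{self.id}: sequence shorter than one codon")
        encode(self.seq)  # validates alphabet

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def n_codons(self) -> int:
        if len(self.seq) % 3:
            raise ValueError(f"{self.id}: length {len(self.seq)} is not in frame")
        return len(self.seq) // 3

    def codons(self) -> List[str]:
        n = self.n_codons
        return [self.seq[3 * i : 3 * i + 3] for i in range(n)]

    def translate(self, code: GeneticCode | None = None) -> str:
        code = code or get_code()
        return code.translate(self.seq)
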