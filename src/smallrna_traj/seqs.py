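"""Sequence alphabet helpers shared across the package.

Internally the package canonicalizes to the DNA alphabet (U -> T); outputs
facing miRNA conventions are re-emitted as RNA.
"""
from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_RNA_TO_DNA = str.maketrans("Uu", "Tt")
_DNA_TO_RNA = str.maketrans("Tt", "Uu")

DNA_BASES = frozenset("ACGT")
RNA_BASES = frozenset("ACGU")

#: IUPAC ambiguity codes keyed by the set of DNA bases they stand for.
IUPAC_CODES = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}


def to_dna(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().translate(_RNA_TO_DNA)


def to_rna(seq: str) -> str:
    """Uppercase and convert T to U."""
    return seq.upper().translate(_DNA_TO_RNA)


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet (accepts RNA input)."""
    return to_dna(seq).translate(_DNA_COMP)[::-1]


def random_dna(rng, length: int) -> str:
    """Uniform random DNA string drawn from a numpy Generator."""
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
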