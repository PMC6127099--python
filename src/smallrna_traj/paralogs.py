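"""Genomic mapping of mature miRNA sequences, paralog clustering, precursor
extraction and consensus building.

Loci are located by perfect-match search of the mature sequence on both
strands (coordinates 1-based inclusive on the forward scaffold), grouped into
paralog clusters by single-linkage within a gap threshold, and evaluated as
hairpins via the base-pair-maximization fold in :mod:`smallrna_traj.fold`.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import io as sio
from .fold import HairpinFold
from .seqs import DNA_BASES, IUPAC_CODES, revcomp, to_dna, to_rna

PARALOG_LETTERS = "abcdefghijklmnopqrstuvwxyz"


@dataclass(frozen=True)
class GenomicLocus:
    """A perfect-match position of a mature sequence on the genome."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # '+' or '-'
    mature: str  # DNA, as matched (strand-aware)
    arm: str = "unknown"  # '5p', '3p' or 'unknown'


@dataclass
class ParalogCluster:
    """Single-linkage group of same-scaffold, same-strand loci."""

    cluster_id: str
    name: str  # letter: a, b, c ... by (scaffold, start)
    scaffold: str
    strand: str
    loci: list[GenomicLocus] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(l.start for l in self.loci)

    @property
    def end(self) -> int:
        return max(l.end for l in self.loci)


def _resolve_genome(genome: Mapping[str, str] | str | Path) -> Mapping[str, str]:
    if isinstance(genome, (str, Path)):
        return sio.read_fasta(genome)
    return genome


def find_perfect_matches(
    mature: str, genome: Mapping[str, str] | str | Path
) -> list[GenomicLocus]:
    """All exact occurrences of ``mature`` on both strands of the genome.

    Minus-strand hits are reported in forward-scaffold coordinates with
    strand '-'. Ambiguous bases in the query raise ValueError (perfect match
    is undefined for them).
    """
    query = to_dna(mature)
    bad = set(query) - DNA_BASES
    if bad:
        raise ValueError(f"ambiguous bases in query: {sorted(bad)}")
    genome = _resolve_genome(genome)
    rc = revcomp(query)
    loci = []
    for scaffold in genome:
        seq = to_dna(genome[scaffold])
        for probe, strand in ((query, "+"), (rc, "-")):
            i = seq.find(probe)
            while i != -1:
                loci.append(
                    GenomicLocus(scaffold, i + 1, i + len(probe), strand, query)
                )
                i = seq.find(probe, i + 1)
    return sorted(loci, key=lambda l: (l.scaffold, l.start, l.strand))


def cluster_loci(
    loci: Iterable[GenomicLocus], max_gap: int = 10_000
) -> list[ParalogCluster]:
    """Single-linkage clustering of loci within ``max_gap`` nt.

    Loci on different scaffolds or strands never merge. Clusters are ordered
    and lettered by (scaffold, min start); the result is invariant to input
    order.
    """
    groups: dict[tuple[str, str], list[GenomicLocus]] = {}
    for locus in loci:
        groups.setdefault((locus.scaffold, locus.strand), []).append(locus)
    raw: list[tuple[str, str, list[GenomicLocus]]] = []
    for (scaffold, strand), members in groups.items():
        members = sorted(members, key=lambda l: (l.start, l.end))
        current = [members[0]]
        max_end = members[0].end
        for locus in members[1:]:
            if locus.start - max_end - 1 > max_gap:
                raw.append((scaffold, strand, current))
                current = []
            current.append(locus)
            max_end = max(max_end, locus.end)
        raw.append((scaffold, strand, current))
    raw.sort(key=lambda t: (t[0], min(l.start for l in t[2])))
    return [
        ParalogCluster(f"cluster_{i + 1}", PARALOG_LETTERS[i], scaffold, strand, members)
        for i, (scaffold, strand, members) in enumerate(raw)
    ]


def extract_precursor(
    locus: GenomicLocus, genome: Mapping[str, str] | str | Path, flank: int = 60
) -> str:
    """Strand-aware candidate precursor window around a locus.

    Returns the sequence of [start - flank, end + flank] clipped to scaffold
    bounds, reverse-complemented for minus-strand loci so the mature arm
    reads 5'->3'.
    """
    genome = _resolve_genome(genome)
    seq = to_dna(genome[locus.scaffold])
    lo = max(1, locus.start - flank)
    hi = min(len(seq), locus.end + flank)
    window = seq[lo - 1 : hi]
    return window if locus.strand == "+" else revcomp(window)


def assign_arm(fold: HairpinFold, mature_offset: int, mature_len: int) -> str:
    """Place a mature sequence on the 5p or 3p arm of a classified hairpin.

    ``mature_offset`` is the 0-based position of the mature within the folded
    sequence. Returns 'unknown' unless the fold is a single-loop hairpin and
    the mature lies entirely on one side of the terminal loop.
    """
    if not fold.is_hairpin:
        return "unknown"
    from .fold import pairs_from_structure

    pairs = pairs_from_structure(fold.structure)
    innermost = [(i, j) for i, j in pairs if not any(i < a and b < j for a, b in pairs)]
    if len(innermost) != 1:
        return "unknown"
    loop_lo, loop_hi = innermost[0]
    if mature_offset + mature_len - 1 <= loop_lo:
        return "5p"
    if mature_offset >= loop_hi:
        return "3p"
    return "unknown"


def consensus_sequence(variants: Sequence[str]) -> tuple[str, list[float]]:
    """Majority consensus of 5'-aligned variants + per-position agreement.

    Length differences are padded at the 3' end (shorter variants simply do
    not vote at trailing positions). Ties produce IUPAC ambiguity codes. The
    output alphabet follows the input (RNA in, RNA out).
    """
    if not variants:
        raise ValueError("consensus of an empty variant set is undefined")
    is_rna = any("U" in v.upper() for v in variants)
    seqs = [to_dna(v) for v in variants]
    length = max(len(s) for s in seqs)
    consensus = []
    fractions = []
    for pos in range(length):
        votes = Counter(s[pos] for s in seqs if len(s) > pos)
        top = max(votes.values())
        winners = frozenset(b for b, c in votes.items() if c == top)
        base = next(iter(winners)) if len(winners) == 1 else IUPAC_CODES[winners]
        consensus.append(base)
        fractions.append(top / sum(votes.values()))
    out = "".join(consensus)
    return (to_rna(out) if is_rna else out), fractions


def loci_to_bed(loci: Iterable[GenomicLocus], names: Iterable[str] | None = None) -> str:
    """BED6 text for loci (0-based half-open conversion on write)."""
    lines = []
    names = list(names) if names is not None else None
    for idx, locus in enumerate(loci):
        name = names[idx] if names else locus.mature
        lines.append(
            f"{locus.scaffold}\t{locus.start - 1}\t{locus.end}\t{name}\t0\t{locus.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
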