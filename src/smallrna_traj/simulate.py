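"""Synthetic study generator: toy genome, annotation, references and libraries.

The generator emulates the design of the killifish two-trajectory study: seven
morphological stages (DC, NK, 6S, 10S, 16S, 20S, 24S) x two temperature-induced
trajectories (escape 30 degC, diapause 20 degC) x three replicate small-RNA
libraries; a declining, escape-enriched maternal-clearing miRNA family of five
paralogs in two genomic clusters; an increasing family of four paralogs near
toy Hox-like gene clusters with an earlier onset in escape embryos; read-length
peaks at 22 and 17 nt; and seed-complement target sites written into a subset
of 3'UTRs. Every downstream stage can therefore be tested against a known
ground truth without any downloads.

All randomness derives from ``SimConfig.seed`` via labelled sub-streams, so
identical configs produce byte-identical outputs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from ._rng import spawn_rng
from .seqs import random_dna, revcomp, to_dna, to_rna

STAGES = ("DC", "NK", "6S", "10S", "16S", "20S", "24S")
TRAJECTORIES = ("escape", "diapause")
PARALOG_LETTERS = "abcdefghijklmnopqrstuvwxyz"

#: relative abundance of successive paralogs within a family (the first
#: paralog dominates by orders of magnitude, as for the real miR-430a)
def _paralog_factors(n: int) -> tuple[float, ...]:
    return tuple(0.5**i for i in range(n))


#: relative abundance of the canonical tag and its two isomiRs (3'-trimmed,
#: templated 3'-extended) within one paralog
ISOMIR_WEIGHTS = (("", 1.0), (".iso21", 0.35), (".iso23", 0.2))


@dataclass(frozen=True)
class FamilySpec:
    """A simulated miRNA family: shared ends, unique central k-mer per paralog.

    ``profile`` maps trajectory -> per-stage relative expression weights (one
    value per stage, arbitrary units relative to the other weights in the
    library).
    """

    name: str
    n_paralogs: int
    n_clusters: int
    shared_5p: str
    shared_3p: str
    profile: Mapping[str, Sequence[float]]
    central_kmer_length: int = 4

    def __post_init__(self) -> None:
        if self.n_paralogs < 0 or self.n_clusters < 0:
            raise ValueError("n_paralogs and n_clusters must be non-negative")
        if self.n_paralogs and self.n_clusters > self.n_paralogs:
            raise ValueError("n_clusters cannot exceed n_paralogs")

    @property
    def mature_length(self) -> int:
        return len(self.shared_5p) + self.central_kmer_length + len(self.shared_3p)

    @property
    def seed_7mer(self) -> str:
        """7-nt seed on the 5' arm (RNA), positions 4-10 of the mature."""
        return to_rna(to_dna(self.shared_5p)[3:10])

    @property
    def seed_6mer(self) -> str:
        return to_rna(to_dna(self.shared_5p)[4:10])


def default_families() -> tuple[FamilySpec, ...]:
    """The two-family study design the generator defaults to.

    The declining family mirrors the maternal-clearing miR-430-like pattern:
    high maternal-phase abundance falling monotonically through somitogenesis,
    with a strong escape-trajectory enrichment at the first three stages. The
    increasing family mirrors the miR-10-like pattern: near-silent early, with
    a sharp onset at stage index 3 (10S) in escape embryos and index 4 (16S)
    in diapause embryos.
    """
    declining = FamilySpec(
        name="mir430",
        n_paralogs=5,
        n_clusters=2,
        shared_5p="AGTAAGTGCT",
        shared_3p="TGTTGGGG",
        profile={
            "escape": (1200.0, 800.0, 480.0, 20.0, 10.0, 4.0, 2.0),
            "diapause": (120.0, 80.0, 48.0, 20.0, 10.0, 4.0, 2.0),
        },
    )
    increasing = FamilySpec(
        name="mir10",
        n_paralogs=4,
        n_clusters=4,
        shared_5p="TACCCTGTAG",
        shared_3p="AATTTGCG",
        profile={
            "escape": (2.0, 2.0, 2.0, 120.0, 240.0, 400.0, 520.0),
            "diapause": (2.0, 2.0, 2.0, 2.0, 120.0, 240.0, 400.0),
        },
    )
    return (declining, increasing)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study; see module docstring for defaults."""

    seed: int = 0
    n_scaffolds: int = 6
    scaffold_length: int = 50_000
    stages: tuple[str, ...] = STAGES
    trajectories: tuple[str, ...] = TRAJECTORIES
    replicates_per_group: int = 3
    library_size: int = 10_000
    nb_dispersion: float = 0.1
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    # 50-nt reads leave >= 20 adapter nt after the longest (30 nt) insert,
    # so every insert retains enough adapter evidence for trimming
    read_length: int = 50
    family_specs: tuple[FamilySpec, ...] = field(default_factory=default_families)
    background_fraction_17nt: float = 0.30
    decoy_counts: Mapping[str, int] = field(
        default_factory=lambda: {"rRNA": 8, "tRNA": 6, "snRNA": 4}
    )
    decoy_weight: float = 120.0
    n_genes: int = 60
    target_gene_fraction: float = 0.25
    max_sites_per_utr: int = 12
    target_family: str | None = None  # defaults to the first family

    def __post_init__(self) -> None:
        if self.replicates_per_group < 2:
            raise ValueError("replicates_per_group must be >= 2")
        if self.library_size < 0:
            raise ValueError("library_size must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if not (0 <= self.background_fraction_17nt < 1):
            raise ValueError("background_fraction_17nt must be in [0, 1)")
        for fam in self.family_specs:
            for traj in self.trajectories:
                if len(fam.profile[traj]) != len(self.stages):
                    raise ValueError(
                        f"family {fam.name}: profile for {traj} must have "
                        f"{len(self.stages)} stage values"
                    )

    @property
    def scaffold_names(self) -> tuple[str, ...]:
        return tuple(f"scaf{i + 1:02d}" for i in range(self.n_scaffolds))

    def family(self, name: str) -> FamilySpec:
        for fam in self.family_specs:
            if fam.name == name:
                return fam
        raise KeyError(name)

    @property
    def site_family(self) -> FamilySpec | None:
        """The family whose seed is written into 3'UTR target sites."""
        if self.target_family is not None:
            return self.family(self.target_family)
        return self.family_specs[0] if self.family_specs else None


@dataclass
class GroundTruth:
    """Everything the simulator knows, for downstream truth comparisons."""

    config: SimConfig
    scaffolds: dict[str, str]
    loci: pd.DataFrame  # family,paralog,scaffold,start,end,strand,mature,precursor_start,precursor_end
    mature_tags: dict[str, str]  # tag name -> DNA sequence (incl. isomiRs)
    tag_families: dict[str, str]  # tag name -> family name
    tag_paralogs: dict[str, str]  # tag name -> paralog name
    design: pd.DataFrame  # library, stage, trajectory, replicate
    expected_means: pd.DataFrame  # named tags x libraries, expected counts
    de_tags: pd.DataFrame  # stage, tag, log2_ratio (escape/diapause proportions)
    genes: pd.DataFrame  # gene, transcript, scaffold, strand, utr_length
    target_sites: pd.DataFrame  # gene, transcript, n_sites_6mer, n_sites_7mer, utr_length
    expressed_by_stage: dict[str, frozenset[str]]
    de_genes_by_stage: dict[tuple[str, str], frozenset[str]]


# ---------------------------------------------------------------------------
# deterministic building blocks shared by genome + reference writers


def _central_kmers(config: SimConfig, fam: FamilySpec) -> list[str]:
    """Distinct central k-mers, one per paralog, deterministic from the seed."""
    rng = spawn_rng(config.seed, f"kmers:{fam.name}")
    k = fam.central_kmer_length
    codes = rng.permutation(4**k)[: fam.n_paralogs]
    kmers = []
    for code in codes:
        kmer = ""
        for _ in range(k):
            kmer += "ACGT"[code % 4]
            code //= 4
        kmers.append(kmer)
    return kmers


@dataclass(frozen=True)
class _ParalogParts:
    name: str  # e.g. mir430-a
    mature: str  # DNA, canonical 22-mer
    ext: str  # 14-nt templated 3' extension of the 5' arm
    loop: str  # 8-nt terminal loop


def paralog_parts(config: SimConfig, fam: FamilySpec) -> list[_ParalogParts]:
    """Per-paralog sequences (mature, arm extension, loop) from the seed alone."""
    parts = []
    for idx, kmer in enumerate(_central_kmers(config, fam)):
        letter = PARALOG_LETTERS[idx]
        rng = spawn_rng(config.seed, f"prec:{fam.name}:{letter}")
        mature = to_dna(fam.shared_5p) + kmer + to_dna(fam.shared_3p)
        parts.append(
            _ParalogParts(
                name=f"{fam.name}-{letter}",
                mature=mature,
                ext=random_dna(rng, 14),
                loop=random_dna(rng, 8),
            )
        )
    return parts


def _wobble_arm3(arm5: str, mature_len: int) -> str:
    """Reverse-complement arm with up to 3 G.U wobble substitutions.

    Substitutions are placed opposite mature-sequence positions so the DNA
    reverse complement of the mature tag does not occur in the precursor,
    while the RNA duplex remains fully paired (A->G opposite U, C->T
    opposite G).
    """
    arm3 = list(revcomp(arm5))
    L = len(arm5)
    candidates = [a for a in range(mature_len) if arm5[a] in "TG"]
    if not candidates:
        return "".join(arm3)
    # spread three substitution sites across the mature span
    picks = sorted(
        {
            min(candidates, key=lambda a: abs(a - target))
            for target in (mature_len // 6, mature_len // 2, 5 * mature_len // 6)
        }
    )
    for a in picks:
        arm3[L - 1 - a] = "G" if arm5[a] == "T" else "T"
    return "".join(arm3)


def precursor_sequence(parts: _ParalogParts) -> str:
    """5' arm (mature + extension) + loop + wobbled reverse-complement arm."""
    arm5 = parts.mature + parts.ext
    return arm5 + parts.loop + _wobble_arm3(arm5, len(parts.mature))


def _isomir_tags(parts: _ParalogParts) -> list[tuple[str, str]]:
    """(tag name, DNA sequence) for the canonical tag and its isomiRs."""
    tags = []
    for suffix, _w in ISOMIR_WEIGHTS:
        if suffix == "":
            seq = parts.mature
        elif suffix == ".iso21":
            seq = parts.mature[:-1]
        else:  # templated extension by the first base of the arm extension
            seq = parts.mature + parts.ext[0]
        tags.append((parts.name + suffix, seq))
    return tags


def decoy_records(config: SimConfig) -> list[tuple[str, str, str]]:
    """(name, category, DNA sequence) decoys for the non-miRNA references.

    Lengths cycle over 15-30 nt excluding 17 and 22 so that the two length
    peaks of the simulated libraries stay at the miRNA and background modes.
    """
    lengths = [18, 19, 20, 21, 23, 24, 25, 26, 27, 28, 29, 30, 15, 16]
    records = []
    li = 0
    for cat in sorted(config.decoy_counts):
        n = config.decoy_counts[cat]
        rng = spawn_rng(config.seed, f"decoys:{cat}")
        for i in range(n):
            records.append(
                (f"{cat}-{i + 1}", cat, random_dna(rng, lengths[li % len(lengths)]))
            )
            li += 1
    return records


# ---------------------------------------------------------------------------
# expression design


def _tag_weight_table(config: SimConfig) -> pd.DataFrame:
    """Named tag -> relative weight per (stage, trajectory) column."""
    cols = pd.MultiIndex.from_product(
        [config.stages, config.trajectories], names=["stage", "trajectory"]
    )
    rows: dict[str, np.ndarray] = {}
    for fam in config.family_specs:
        factors = _paralog_factors(fam.n_paralogs)
        for idx, parts in enumerate(paralog_parts(config, fam)):
            for (suffix, iso_w), (tag_name, _seq) in zip(
                ISOMIR_WEIGHTS, _isomir_tags(parts)
            ):
                w = np.array(
                    [
                        fam.profile[traj][si] * factors[idx] * iso_w
                        for si, _stage in enumerate(config.stages)
                        for traj in config.trajectories
                    ]
                )
                rows[tag_name] = w
    for name, _cat, _seq in decoy_records(config):
        rows[name] = np.full(len(cols), config.decoy_weight)
    return pd.DataFrame(rows, index=cols).T


def _expected_proportions(config: SimConfig) -> pd.DataFrame:
    """Per-tag expected read proportions, after the 17-nt background share."""
    W = _tag_weight_table(config)
    totals = W.sum(axis=0)
    bf = config.background_fraction_17nt
    denom = totals / (1.0 - bf) if bf > 0 else totals
    return W.div(denom.replace(0.0, np.nan), axis=1).fillna(0.0)


def build_design(config: SimConfig) -> pd.DataFrame:
    rows = [
        {
            "library": f"{stage}_{traj}_r{rep}",
            "stage": stage,
            "trajectory": traj,
            "replicate": rep,
        }
        for stage in config.stages
        for traj in config.trajectories
        for rep in range(1, config.replicates_per_group + 1)
    ]
    return pd.DataFrame(rows)


def _expected_means(config: SimConfig, design: pd.DataFrame) -> pd.DataFrame:
    P = _expected_proportions(config)
    data = {
        row.library: P[(row.stage, row.trajectory)] * config.library_size
        for row in design.itertuples()
    }
    return pd.DataFrame(data)


def _de_truth(config: SimConfig) -> pd.DataFrame:
    """Tags whose expected proportions differ >=1.5x between trajectories."""
    if set(("escape", "diapause")) - set(config.trajectories):
        return pd.DataFrame(columns=["stage", "tag", "log2_ratio"])
    P = _expected_proportions(config)
    out = []
    for stage in config.stages:
        pe = P[(stage, "escape")]
        pd_ = P[(stage, "diapause")]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(
                (pe == 0) & (pd_ == 0), 1.0, pe / pd_.replace(0.0, np.nan)
            )
        ratio = pd.Series(ratio, index=P.index).fillna(np.inf)
        hits = ratio[(ratio >= 1.5) | (ratio <= 1 / 1.5)]
        for tag, r in hits.items():
            out.append(
                {"stage": stage, "tag": tag, "log2_ratio": float(np.log2(r))}
            )
    return pd.DataFrame(out, columns=["stage", "tag", "log2_ratio"])


# ---------------------------------------------------------------------------
# genome + annotation


def _tx_chunks(
    exons: list[tuple[int, int]], strand: str, t0: int, t1: int
) -> list[tuple[int, int, int]]:
    """Map transcript span [t0, t1) to genomic chunks in transcript order.

    Returns (transcript_offset, genomic_lo, genomic_hi) with 1-based inclusive
    genomic coordinates; for minus-strand transcripts chunks descend the
    genome while transcript offsets ascend.
    """
    chunks = []
    off = 0
    ordered = exons if strand == "+" else list(reversed(exons))
    for s, e in ordered:
        length = e - s + 1
        lo = max(t0, off)
        hi = min(t1, off + length)
        if lo < hi:
            if strand == "+":
                chunks.append((lo, s + (lo - off), s + (hi - 1 - off)))
            else:
                chunks.append((lo, e - (hi - 1 - off), e - (lo - off)))
        off += length
    return chunks


@dataclass
class _GeneModel:
    gene_id: str
    tx_id: str
    scaffold: str
    strand: str
    exons: list[tuple[int, int]]  # 1-based inclusive, genomic ascending
    cds: list[tuple[int, int]]
    u5: int
    u3: int
    tx_len: int


def _spliced(scaffold_seq: str, exons: list[tuple[int, int]], strand: str) -> str:
    seq = "".join(scaffold_seq[s - 1 : e] for s, e in exons)
    return seq if strand == "+" else revcomp(seq)


def _count_overlapping(hay: str, needle: str) -> int:
    count, i = 0, hay.find(needle)
    while i != -1:
        count += 1
        i = hay.find(needle, i + 1)
    return count


def generate_genome(config: SimConfig, outdir: str | Path | None = None) -> GroundTruth:
    """Build the toy genome + annotation and return the full ground truth.

    If ``outdir`` is given, writes genome.fa, annotation.gff3 and the truth
    tables there.
    """
    rng = spawn_rng(config.seed, "genome")
    scaffolds: dict[str, bytearray] = {
        name: bytearray(random_dna(rng, config.scaffold_length).encode())
        for name in config.scaffold_names
    }

    # --- precursor clusters -------------------------------------------------
    loci_rows = []
    mature_tags: dict[str, str] = {}
    tag_families: dict[str, str] = {}
    tag_paralogs: dict[str, str] = {}
    exclusions: dict[str, list[tuple[int, int]]] = {n: [] for n in scaffolds}
    scaffold_iter = iter(config.scaffold_names)
    for fam in config.family_specs:
        parts = paralog_parts(config, fam)
        for p in parts:
            for tag_name, seq in _isomir_tags(p):
                mature_tags[tag_name] = seq
                tag_families[tag_name] = fam.name
                tag_paralogs[tag_name] = p.name
        if fam.n_paralogs == 0:
            continue
        groups = np.array_split(np.arange(fam.n_paralogs), fam.n_clusters)
        for group in groups:
            try:
                scaf = next(scaffold_iter)
            except StopIteration:
                raise ValueError(
                    "n_scaffolds too small for the requested number of clusters"
                ) from None
            strand = str(rng.choice(["+", "-"]))
            cursor = 1000 + int(rng.integers(0, 1001))
            for idx in group:
                p = parts[idx]
                prec = precursor_sequence(p)
                L = len(prec)
                if cursor + L > config.scaffold_length - 500:
                    raise ValueError(
                        f"scaffold {scaf} too short to host cluster of "
                        f"family {fam.name}"
                    )
                insert = prec if strand == "+" else revcomp(prec)
                scaffolds[scaf][cursor : cursor + L] = insert.encode()
                m = len(p.mature)
                if strand == "+":
                    start, end = cursor + 1, cursor + m
                else:
                    start, end = cursor + L - m + 1, cursor + L
                loci_rows.append(
                    {
                        "family": fam.name,
                        "paralog": p.name,
                        "scaffold": scaf,
                        "start": start,
                        "end": end,
                        "strand": strand,
                        "mature": p.mature,
                        "precursor_start": cursor + 1,
                        "precursor_end": cursor + L,
                    }
                )
                exclusions[scaf].append((max(0, cursor - 200), cursor + L + 200))
                cursor += L + 500 + int(rng.integers(0, 1501))
    loci = pd.DataFrame(
        loci_rows,
        columns=[
            "family",
            "paralog",
            "scaffold",
            "start",
            "end",
            "strand",
            "mature",
            "precursor_start",
            "precursor_end",
        ],
    )

    # --- gene models ----------------------------------------------------------
    rng_genes = spawn_rng(config.seed, "genes")
    genes: list[_GeneModel] = []
    scaf_names = list(config.scaffold_names)
    cursors = {s: 400 + int(rng_genes.integers(0, 301)) for s in scaf_names}
    exhausted: set[str] = set()
    gi = 0
    while len(genes) < config.n_genes:
        if len(exhausted) == len(scaf_names):
            raise ValueError(
                "scaffolds too short to place the requested number of genes"
            )
        scaf = scaf_names[gi % len(scaf_names)]
        gi += 1
        if scaf in exhausted:
            continue
        n_exons = int(rng_genes.integers(2, 4))
        exon_lens = rng_genes.integers(200, 601, n_exons)
        intron_lens = rng_genes.integers(150, 401, max(n_exons - 1, 0))
        span = int(exon_lens.sum() + intron_lens.sum())
        start0 = cursors[scaf]
        moved = True
        while moved:
            moved = False
            for a, b in exclusions[scaf]:
                if start0 < b and start0 + span > a:
                    start0 = b + 50
                    moved = True
        if start0 + span > config.scaffold_length - 400:
            exhausted.add(scaf)
            continue
        exons = []
        pos = start0
        for k in range(n_exons):
            exons.append((pos + 1, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursors[scaf] = pos + 200 + int(rng_genes.integers(0, 601))
        strand = str(rng_genes.choice(["+", "-"]))
        T = int(exon_lens.sum())
        has_utr = rng_genes.random() < 0.9
        u5 = int(rng_genes.integers(30, 101))
        u3 = int(rng_genes.integers(150, 501)) if has_utr else 0
        if T - u5 - u3 < 90:
            u3 = max(0, T - u5 - 90)
        cds_chunks = _tx_chunks(exons, strand, u5, T - u3)
        cds = sorted((lo, hi) for _off, lo, hi in cds_chunks)
        gid = f"g{len(genes) + 1:03d}"
        genes.append(
            _GeneModel(gid, f"{gid}.t1", scaf, strand, exons, cds, u5, u3, T)
        )

    # --- seed-complement target sites in a subset of 3'UTRs -------------------
    site_fam = config.site_family
    rng_sites = spawn_rng(config.seed, "sites")
    if site_fam is not None and site_fam.n_paralogs >= 0:
        motif6 = revcomp(to_dna(site_fam.seed_6mer))
        utr_genes = [g for g in genes if g.u3 >= 40]
        n_target = int(round(config.target_gene_fraction * len(utr_genes)))
        chosen = list(
            rng_sites.choice(len(utr_genes), size=n_target, replace=False)
        ) if n_target else []
        for ci in chosen:
            g = utr_genes[int(ci)]
            n_sites = int(rng_sites.integers(1, config.max_sites_per_utr + 1))
            chunks = _tx_chunks(g.exons, g.strand, g.tx_len - g.u3, g.tx_len)
            used: list[tuple[int, int]] = []
            placed = 0
            for _ in range(n_sites * 30):
                if placed >= n_sites:
                    break
                clo, glo, ghi = chunks[int(rng_sites.integers(0, len(chunks)))]
                clen = ghi - glo + 1
                if clen < 6:
                    continue
                p = clo + int(rng_sites.integers(0, clen - 5))
                if any(p < ue + 8 and p + 6 > us - 8 for us, ue in used):
                    continue
                scaf_seq = scaffolds[g.scaffold]
                if g.strand == "+":
                    g0 = glo + (p - clo)  # 1-based start
                    scaf_seq[g0 - 1 : g0 + 5] = motif6.encode()
                else:
                    ghi_pos = ghi - (p - clo)  # 1-based genomic of transcript pos p
                    glo_pos = ghi_pos - 5
                    scaf_seq[glo_pos - 1 : ghi_pos] = revcomp(motif6).encode()
                used.append((p, p + 6))
                placed += 1

    final_scaffolds = {name: bytes(b).decode() for name, b in scaffolds.items()}

    # --- truth tables computed back from the finished genome ------------------
    gene_rows, site_rows = [], []
    if site_fam is not None:
        motif6 = revcomp(to_dna(site_fam.seed_6mer))
        motif7 = revcomp(to_dna(site_fam.seed_7mer))
    for g in genes:
        tx_seq = _spliced(final_scaffolds[g.scaffold], g.exons, g.strand)
        utr_seq = tx_seq[g.tx_len - g.u3 :] if g.u3 else ""
        gene_rows.append(
            {
                "gene": g.gene_id,
                "transcript": g.tx_id,
                "scaffold": g.scaffold,
                "strand": g.strand,
                "utr_length": g.u3,
            }
        )
        if site_fam is not None:
            n6 = _count_overlapping(utr_seq, motif6)
            n7 = _count_overlapping(utr_seq, motif7)
            if n6 or n7:
                site_rows.append(
                    {
                        "gene": g.gene_id,
                        "transcript": g.tx_id,
                        "n_sites_6mer": n6,
                        "n_sites_7mer": n7,
                        "utr_length": g.u3,
                    }
                )
    genes_df = pd.DataFrame(
        gene_rows, columns=["gene", "transcript", "scaffold", "strand", "utr_length"]
    )
    sites_df = pd.DataFrame(
        site_rows,
        columns=["gene", "transcript", "n_sites_6mer", "n_sites_7mer", "utr_length"],
    )

    # --- per-stage expressed / DE mRNA sets (external input emulation) --------
    rng_sets = spawn_rng(config.seed, "genesets")
    gene_ids = [g.gene_id for g in genes]
    perm = [gene_ids[i] for i in rng_sets.permutation(len(gene_ids))]
    n_stages = len(config.stages)
    expressed_by_stage = {}
    for si, stage in enumerate(config.stages):
        frac = 0.4 + 0.6 * (si / max(n_stages - 1, 1))
        expressed_by_stage[stage] = frozenset(perm[: math.ceil(frac * len(perm))])
    de_genes_by_stage = {}
    for stage in config.stages:
        pool = sorted(expressed_by_stage[stage])
        for traj in config.trajectories:
            k = int(rng_sets.integers(5, 13)) if len(pool) >= 13 else len(pool)
            picks = rng_sets.choice(len(pool), size=k, replace=False)
            de_genes_by_stage[(stage, traj)] = frozenset(pool[int(i)] for i in picks)

    design = build_design(config)
    truth = GroundTruth(
        config=config,
        scaffolds=final_scaffolds,
        loci=loci,
        mature_tags=mature_tags,
        tag_families=tag_families,
        tag_paralogs=tag_paralogs,
        design=design,
        expected_means=_expected_means(config, design),
        de_tags=_de_truth(config),
        genes=genes_df,
        target_sites=sites_df,
        expressed_by_stage=expressed_by_stage,
        de_genes_by_stage=de_genes_by_stage,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_fasta(outdir / "genome.fa", final_scaffolds)
        _write_gff3(outdir / "annotation.gff3", config, genes)
        truth.loci.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
        truth.target_sites.to_csv(
            outdir / "truth_target_sites.tsv", sep="\t", index=False
        )
        truth.de_tags.to_csv(outdir / "truth_de_tags.tsv", sep="\t", index=False)
        truth.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    return truth


def _write_gff3(path: Path, config: SimConfig, genes: list[_GeneModel]) -> None:
    lines = ["##gff-version 3"]
    for name in config.scaffold_names:
        lines.append(f"##sequence-region {name} 1 {config.scaffold_length}")
    for g in genes:
        gstart = min(s for s, _e in g.exons)
        gend = max(e for _s, e in g.exons)
        lines.append(
            f"{g.scaffold}\tsim\tgene\t{gstart}\t{gend}\t.\t{g.strand}\t.\tID={g.gene_id}"
        )
        lines.append(
            f"{g.scaffold}\tsim\tmRNA\t{gstart}\t{gend}\t.\t{g.strand}\t.\t"
            f"ID={g.tx_id};Parent={g.gene_id}"
        )
        for k, (s, e) in enumerate(g.exons, 1):
            lines.append(
                f"{g.scaffold}\tsim\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.tx_id}.exon{k};Parent={g.tx_id}"
            )
        # CDS phase: cumulative coding length before each piece, transcript order
        ordered = g.cds if g.strand == "+" else list(reversed(g.cds))
        cum = 0
        phased = []
        for s, e in ordered:
            phased.append((s, e, (3 - cum % 3) % 3))
            cum += e - s + 1
        for k, (s, e, phase) in enumerate(sorted(phased), 1):
            lines.append(
                f"{g.scaffold}\tsim\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                f"ID={g.tx_id}.cds{k};Parent={g.tx_id}"
            )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# libraries


def sample_counts(
    weights: np.ndarray, library_size: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one library's tag counts summing exactly to ``library_size``.

    Gamma-multinomial construction: per-tag gamma rates with shape
    1/dispersion and mean proportional to the weights, then a single
    multinomial conditioned on the library total. Marginal counts follow the
    targeted negative-binomial mean/dispersion while per-library sums are
    exact.
    """
    w = np.asarray(weights, dtype=float)
    if library_size == 0 or w.sum() == 0:
        return np.zeros(len(w), dtype=np.int64)
    shape = 1.0 / dispersion
    g = rng.gamma(shape, w * dispersion)
    if g.sum() == 0:  # pathological underflow guard
        g = w
    return rng.multinomial(library_size, g / g.sum())


def generate_libraries(
    config: SimConfig, truth: GroundTruth, outdir: str | Path
) -> pd.DataFrame:
    """Write per-library FASTQ files and return the truth count table.

    The count table has one row per named tag plus a ``*background*`` row
    aggregating the anonymous 17-nt tags, so per-library column sums equal
    ``library_size`` exactly.
    """
    outdir = Path(outdir)
    reads_dir = outdir / "reads"
    reads_dir.mkdir(parents=True, exist_ok=True)
    W = _tag_weight_table(config)
    names = list(W.index)
    seqs = dict(truth.mature_tags)
    for name, _cat, seq in decoy_records(config):
        seqs[name] = seq
    bf = config.background_fraction_17nt
    counts: dict[str, np.ndarray] = {}
    for row in truth.design.itertuples():
        lib = row.library
        w = W[(row.stage, row.trajectory)].to_numpy(float)
        bw = bf / (1.0 - bf) * w.sum() if bf > 0 else 0.0
        rng = spawn_rng(config.seed, f"lib:{lib}")
        drawn = sample_counts(
            np.append(w, bw), config.library_size, config.nb_dispersion, rng
        )
        counts[lib] = drawn
        reads: list[tuple[str, str]] = []
        serial = 0
        for name, c in zip(names, drawn[:-1]):
            insert = seqs[name] + config.adapter
            read = insert[: config.read_length]
            for _ in range(int(c)):
                serial += 1
                reads.append((f"{lib}.{serial}", read))
        for _ in range(int(drawn[-1])):
            serial += 1
            tag = random_dna(rng, 17)
            read = (tag + config.adapter)[: config.read_length]
            reads.append((f"{lib}.{serial}", read))
        sio.write_fastq(reads_dir / f"{lib}.fastq", reads)
    table = pd.DataFrame(
        {lib: c for lib, c in counts.items()}, index=names + ["*background*"]
    )
    table.to_csv(outdir / "truth_counts.tsv", sep="\t")
    truth.design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    # a copy next to the FASTQs so the quant stage can run standalone
    truth.design.to_csv(reads_dir / "design.tsv", sep="\t", index=False)
    return table


# ---------------------------------------------------------------------------
# stand-alone count simulation for DE operating characteristics


def simulate_de_counts(
    n_tags: int,
    n_per_group: int,
    dispersion: float,
    fold_change: float,
    frac_de: float,
    rng: np.random.Generator,
    base_mean_range: tuple[float, float] = (50.0, 500.0),
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Two-group negative-binomial count matrix with known DE labels.

    A fraction ``frac_de`` of tags carries a true ``fold_change`` between the
    groups, applied symmetrically (x sqrt(fold) in one group, / sqrt(fold) in
    the other, alternating direction) so the expected library mass is the
    same in both groups and CPM normalization introduces no compositional
    shift of the null tags. Base means are uniform on ``base_mean_range``
    counts. Returns (count matrix, design frame, boolean truth vector). Used
    to measure sensitivity and empirical FDR of the per-stage test under the
    study's replication (n = 3 per group).
    """
    n_de = int(round(frac_de * n_tags))
    is_de = np.zeros(n_tags, dtype=bool)
    is_de[:n_de] = True
    base = rng.uniform(*base_mean_range, size=n_tags)
    direction = np.where(np.arange(n_tags) % 2 == 0, 1.0, -1.0)
    half = np.sqrt(fold_change)
    shift = np.where(is_de, np.where(direction > 0, half, 1.0 / half), 1.0)
    shape = 1.0 / dispersion

    def draw(mu: np.ndarray, n_cols: int) -> np.ndarray:
        lam = rng.gamma(shape, np.tile(mu[:, None], (1, n_cols)) * dispersion)
        return rng.poisson(lam)

    counts = np.hstack(
        [draw(base * shift, n_per_group), draw(base / shift, n_per_group)]
    )
    libs = [f"escape_r{i + 1}" for i in range(n_per_group)] + [
        f"diapause_r{i + 1}" for i in range(n_per_group)
    ]
    design = pd.DataFrame(
        {
            "library": libs,
            "stage": "S",
            "trajectory": ["escape"] * n_per_group + ["diapause"] * n_per_group,
            "replicate": list(range(1, n_per_group + 1)) * 2,
        }
    )
    matrix = pd.DataFrame(
        counts, index=[f"tag{i:04d}" for i in range(n_tags)], columns=libs
    )
    return matrix, design, is_de


# ---------------------------------------------------------------------------
# references


def write_references(
    config: SimConfig, outdir: str | Path, truth: GroundTruth | None = None
) -> dict[str, Path]:
    """Write mature-miRNA and decoy reference FASTAs plus a term-to-gene map.

    miRNA references are emitted in the RNA alphabet (miRBase-like) and
    include every simulated variant tag. The term map covers four toy
    molecular-function terms; when ``truth`` is supplied the ``mf_binding``
    term is built around the genes that genuinely carry seeded target sites,
    so the enrichment stage has a known positive.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    mirna: dict[str, str] = {}
    for fam in config.family_specs:
        for parts in paralog_parts(config, fam):
            for tag_name, seq in _isomir_tags(parts):
                mirna[tag_name] = to_rna(seq)
    paths["miRNA"] = outdir / "mirna.fa"
    sio.write_fasta(paths["miRNA"], mirna)

    by_cat: dict[str, dict[str, str]] = {}
    for name, cat, seq in decoy_records(config):
        by_cat.setdefault(cat, {})[name] = to_rna(seq)
    for cat, records in by_cat.items():
        p = outdir / f"{cat.lower()}.fa"
        sio.write_fasta(p, records)
        paths[cat] = p

    rng = spawn_rng(config.seed, "terms")
    gene_ids = (
        list(truth.genes["gene"])
        if truth is not None
        else [f"g{i + 1:03d}" for i in range(config.n_genes)]
    )
    target_genes = (
        sorted(set(truth.target_sites["gene"])) if truth is not None else []
    )
    other = [g for g in gene_ids if g not in set(target_genes)]
    terms: list[tuple[str, str, str]] = []
    binding = sorted(target_genes) + sorted(
        rng.choice(other, size=min(3, len(other)), replace=False).tolist()
    )
    for g in binding:
        terms.append(("MF:0001", "binding", g))
    for tid, label in (("MF:0002", "signaling"), ("MF:0003", "metabolic"), ("MF:0004", "transport")):
        k = min(max(4, len(gene_ids) // 6), len(gene_ids))
        for g in sorted(rng.choice(gene_ids, size=k, replace=False).tolist()):
            terms.append((tid, label, g))
    term_df = pd.DataFrame(terms, columns=["term_id", "term_label", "gene_id"])
    paths["terms"] = outdir / "terms.tsv"
    term_df.to_csv(paths["terms"], sep="\t", index=False)
    return paths
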