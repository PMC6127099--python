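"""3'UTR inference from GFF3 and seed-complement target scanning.

3'UTRs are inferred as the exonic positions strictly downstream of the CDS
end in transcript orientation (higher coordinates on '+', lower on '-').
Target sites are all (including overlapping) occurrences of the reverse
complement of a 6- or 7-nt seed within the spliced UTR, U/T-insensitive.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from scipy import stats

from .seqs import revcomp, to_dna

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Seed:
    """A miRNA seed (5'->3' on the miRNA) and its target-site motif."""

    name: str
    sequence: str  # 6 or 7 nt

    def __post_init__(self) -> None:
        if len(self.sequence) not in (6, 7):
            raise ValueError("seed length must be 6 or 7 nt")

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def site_motif(self) -> str:
        """Reverse complement of the seed in the DNA target alphabet."""
        return revcomp(to_dna(self.sequence))


@dataclass(frozen=True)
class UtrRecord:
    """Spliced 3'UTR of one transcript.

    ``intervals`` are 1-based inclusive genomic intervals ordered 5'->3' in
    transcript orientation (descending genomic coordinates on '-').
    """

    gene_id: str
    transcript_id: str
    scaffold: str
    strand: str
    intervals: tuple[tuple[int, int], ...]

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.intervals)


@dataclass(frozen=True)
class SeedSite:
    transcript_id: str
    seed_name: str
    start: int  # 1-based within the spliced UTR
    k: int


def infer_three_prime_utrs(
    gff_path: str | Path,
) -> tuple[list[UtrRecord], list[dict]]:
    """Infer per-transcript 3'UTRs by exon-minus-CDS interval arithmetic.

    Transcripts without CDS children are skipped with a logged warning;
    transcripts whose CDS falls outside their exons produce an error record
    instead of aborting. Empty UTRs are allowed (intervals=()).
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[UtrRecord] = []
    errors: list[dict] = []
    for mrna in db.features_of_type("mRNA"):
        tx_id = mrna.id
        gene_id = mrna.attributes.get("Parent", [tx_id])[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not cds:
            logger.warning("transcript %s has no CDS; skipped", tx_id)
            continue
        if not exons:
            errors.append({"transcript": tx_id, "error": "no exons"})
            continue
        if not all(any(s >= es and e <= ee for es, ee in exons) for s, e in cds):
            errors.append({"transcript": tx_id, "error": "CDS outside exons"})
            continue
        if mrna.strand == "+":
            bound = max(e for _s, e in cds)
            utr = [(max(s, bound + 1), e) for s, e in exons if e > bound]
        else:
            bound = min(s for s, _e in cds)
            utr = [(s, min(e, bound - 1)) for s, e in exons if s < bound]
            utr = sorted(utr, reverse=True)  # transcript orientation
        records.append(
            UtrRecord(gene_id, tx_id, mrna.seqid, mrna.strand, tuple(utr))
        )
    return records, errors


def extract_utr_sequence(utr: UtrRecord, genome: Mapping[str, str]) -> str:
    """Spliced UTR sequence, 5'->3' of the mRNA (strand-aware)."""
    scaffold = to_dna(genome[utr.scaffold])
    parts = []
    for s, e in utr.intervals:
        if s < 1 or e > len(scaffold):
            raise ValueError(
                f"interval {s}-{e} outside scaffold {utr.scaffold} "
                f"(length {len(scaffold)})"
            )
        chunk = scaffold[s - 1 : e]
        parts.append(chunk if utr.strand == "+" else revcomp(chunk))
    return "".join(parts)


def scan_seed_sites(
    sequence: str, seed: Seed, transcript_id: str = ""
) -> list[SeedSite]:
    """All (including overlapping) site-motif occurrences, 1-based starts."""
    s = to_dna(sequence)
    motif = seed.site_motif
    sites = []
    i = s.find(motif)
    while i != -1:
        sites.append(SeedSite(transcript_id, seed.name, i + 1, seed.k))
        i = s.find(motif, i + 1)
    return sites


def map_site_position(utr: UtrRecord, pos: int) -> tuple[str, int]:
    """Map a 1-based spliced-UTR position to (scaffold, genomic position)."""
    offset = 0
    for s, e in utr.intervals:
        length = e - s + 1
        if pos <= offset + length:
            within = pos - offset - 1
            g = s + within if utr.strand == "+" else e - within
            return utr.scaffold, g
        offset += length
    raise ValueError(f"position {pos} beyond UTR length {utr.length}")


def count_sites(
    sites: Iterable[SeedSite], utrs: Sequence[UtrRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-transcript and per-gene site-count tables.

    The gene-level count for each seed is the maximum over the gene's
    transcripts (preserving "the transcript with the most binding sites"
    semantics). The gene ranking uses the 6-mer seed when present (the more
    inclusive count), with lexicographic gene-id tie-breaking. Genes without
    any site are absent (empty ranking when there are no sites at all).
    """
    gene_of = {u.transcript_id: u.gene_id for u in utrs}
    rows = [
        {"transcript": s.transcript_id, "seed": s.seed_name, "k": s.k} for s in sites
    ]
    if not rows:
        empty_t = pd.DataFrame(columns=["gene", "transcript", "seed", "n_sites"])
        empty_g = pd.DataFrame(columns=["gene"])
        return empty_t, empty_g
    df = pd.DataFrame(rows)
    per_tx = (
        df.groupby(["transcript", "seed"], as_index=False)
        .size()
        .rename(columns={"size": "n_sites"})
    )
    per_tx.insert(0, "gene", per_tx["transcript"].map(gene_of))
    gene_wide = (
        per_tx.pivot_table(
            index=["gene", "transcript"], columns="seed", values="n_sites", fill_value=0
        )
        .groupby(level="gene")
        .max()
    )
    gene_wide.columns.name = None
    k_by_seed = df.drop_duplicates("seed").set_index("seed")["k"]
    six_seeds = [s for s in gene_wide.columns if k_by_seed.get(s) == 6]
    rank_col = six_seeds[0] if six_seeds else sorted(gene_wide.columns)[0]
    gene_counts = (
        gene_wide.reset_index()
        .sort_values([rank_col, "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return per_tx, gene_counts


def stage_target_profile(
    target_genes: Iterable[str],
    expressed_by_stage: Mapping[str, Iterable[str]],
    de_by_stage: Mapping[tuple[str, str], Iterable[str]] | None = None,
) -> pd.DataFrame:
    """Per-stage counts of expressed target genes and DE target genes.

    ``de_by_stage`` is keyed by (stage, trajectory); one column per
    trajectory is emitted.
    """
    targets = set(target_genes)
    trajectories = sorted({traj for _s, traj in (de_by_stage or {})})
    rows = []
    for stage, expressed in expressed_by_stage.items():
        row = {"stage": stage, "expressed_targets": len(targets & set(expressed))}
        for traj in trajectories:
            de = set(de_by_stage.get((stage, traj), ()))
            row[f"de_{traj}_targets"] = len(targets & de)
        rows.append(row)
    return pd.DataFrame(rows)


def utr_length_anova(
    lengths: pd.Series, site_counts: pd.Series, max_bin: int = 3
) -> tuple[float, float]:
    """One-way ANOVA of 3'UTR length across site-count bins (0,1,...,>=max_bin).

    Tests the length-confounding hypothesis: genes with more seed sites
    should not differ in UTR length if site count reflects targeting rather
    than opportunity. Returns (F, p); identical data in all bins gives
    (0, 1) by convention.
    """
    lengths, site_counts = lengths.align(site_counts, join="inner")
    bins = np.minimum(site_counts.to_numpy(int), max_bin)
    groups = [
        lengths.to_numpy(float)[bins == b] for b in np.unique(bins)
    ]
    if sum(len(g) >= 2 for g in groups) < 2:
        raise ValueError("need >=2 bins with >=2 observations")
    values = np.concatenate(groups)
    if np.all(values == values[0]):
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
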