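"""Unique-tag quantification: adapter trimming, collapsing, CPM normalization,
length distributions, reference annotation and top-contributor summaries.

Tags are canonicalized to the DNA alphabet internally; annotation is exact
full-length matching against reference mature sequences with U/T equivalence.
"""
from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .seqs import to_dna

#: category priority when a tag matches references from several categories
DEFAULT_PRIORITY = ("miRNA", "rRNA", "tRNA", "snRNA")

#: canonical category labels derived from reference file stems
_CATEGORY_CANONICAL = {"mirna": "miRNA", "rrna": "rRNA", "trna": "tRNA", "snrna": "snRNA"}


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = 8,
    min_len: int = 15,
    max_len: int = 30,
) -> str | None:
    """Remove the 3' adapter from a read; return the tag or None if rejected.

    The leftmost occurrence of an adapter prefix of length >= ``min_overlap``
    is removed together with everything 3' of it. Reads without adapter
    evidence, or whose trimmed length falls outside [min_len, max_len], are
    rejected (returned as None, never raised).
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    read = to_dna(read)
    adapter = to_dna(adapter)
    probe = adapter[: min_overlap]
    i = read.find(probe)
    while i != -1:
        overlap = min(len(adapter), len(read) - i)
        if read[i : i + overlap] == adapter[:overlap]:
            tag = read[:i]
            return tag if min_len <= len(tag) <= max_len else None
        i = read.find(probe, i + 1)
    return None


def collapse_and_count(libraries: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Distinct-sequence x library raw count matrix, rows lexicographic."""
    data = {lib: Counter(to_dna(t) for t in tags) for lib, tags in libraries.items()}
    matrix = pd.DataFrame(data, dtype=float).fillna(0).astype(np.int64)
    return matrix.sort_index()


def cpm(matrix: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million normalization; errors on zero-total libraries."""
    totals = matrix.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total libraries cannot be normalized: {list(zero.index)}")
    return matrix * 1e6 / totals


def normalize_and_filter(matrix: pd.DataFrame, min_norm: float = 2.0) -> pd.DataFrame:
    """CPM-normalize and keep tags reaching ``min_norm`` in >=1 library."""
    norm = cpm(matrix)
    return norm[(norm >= min_norm).any(axis=1)]


def length_distribution(matrix: pd.DataFrame, mode: str = "reads") -> pd.DataFrame:
    """Per-length proportions per library.

    ``mode="reads"`` weights each length by read counts; ``mode="unique"``
    counts each distinct tag once (per library in which it occurs).
    """
    if matrix.empty:
        raise ValueError("empty tag matrix")
    if mode not in ("reads", "unique"):
        raise ValueError("mode must be 'reads' or 'unique'")
    weights = matrix if mode == "reads" else (matrix > 0).astype(float)
    lengths = matrix.index.str.len()
    table = weights.groupby(lengths).sum()
    table.index.name = "length"
    totals = table.sum(axis=0)
    return table / totals.replace(0, np.nan)


def load_references(refs_dir: str | Path) -> dict[str, dict[str, str]]:
    """Load category -> {name: sequence} from per-category FASTA files."""
    refs: dict[str, dict[str, str]] = {}
    for path in sorted(Path(refs_dir).glob("*.fa")):
        category = _CATEGORY_CANONICAL.get(path.stem.lower(), path.stem)
        refs[category] = sio.read_fasta(path)
    return refs


def annotate_tags(
    tags: Sequence[str],
    references: Mapping[str, Mapping[str, str]],
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Exact full-length annotation of tags against reference categories.

    Returns a frame indexed by tag with ``category`` and ``ref_name`` columns;
    tags matching several categories get the highest-priority one, unmatched
    tags are labelled ``unannotated``.
    """
    names = [n for refs in references.values() for n in refs]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate reference names: {dupes}")
    order = [c for c in priority if c in references] + sorted(
        c for c in references if c not in priority
    )
    lookup: list[tuple[str, dict[str, str]]] = []
    for cat in order:
        seq_to_name: dict[str, str] = {}
        for name in sorted(references[cat]):
            seq = to_dna(references[cat][name])
            seq_to_name.setdefault(seq, name)
        lookup.append((cat, seq_to_name))
    rows = []
    for tag in tags:
        canon = to_dna(tag)
        category, ref_name = "unannotated", ""
        for cat, seq_to_name in lookup:
            if canon in seq_to_name:
                category, ref_name = cat, seq_to_name[canon]
                break
        rows.append({"tag": tag, "category": category, "ref_name": ref_name})
    return pd.DataFrame(rows).set_index("tag")


def annotation_summary(
    annotation: pd.DataFrame, matrix: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per-category percentages of annotated tags (and of reads if given)."""
    annotated = annotation[annotation["category"] != "unannotated"]
    out = pd.DataFrame(
        {
            "percent_of_annotated_tags": annotated["category"]
            .value_counts(normalize=True)
            .mul(100.0)
        }
    )
    if matrix is not None:
        reads = matrix.sum(axis=1)
        by_cat = reads.groupby(annotation["category"]).sum()
        by_cat = by_cat.drop(index="unannotated", errors="ignore")
        out["percent_of_annotated_reads"] = by_cat / by_cat.sum() * 100.0
    out.index.name = "category"
    return out.sort_index()


def top_contributors(
    norm_matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    design: pd.DataFrame,
    k: int = 10,
) -> pd.DataFrame:
    """Per-stage percent contribution of the k most abundant annotated tags.

    Normalized counts are summed across each stage's libraries; the top k
    annotated tags are reported as a percent of the stage total over all
    tags. Ties break lexicographically by tag sequence.
    """
    rows = []
    annotated = annotation.index[annotation["category"] != "unannotated"]
    for stage in design["stage"].unique():
        libs = design.loc[design["stage"] == stage, "library"]
        libs = [l for l in libs if l in norm_matrix.columns]
        stage_sum = norm_matrix[libs].sum(axis=1)
        total = stage_sum.sum()
        ranked = (
            stage_sum.loc[stage_sum.index.intersection(annotated)]
            .to_frame("abundance")
            .reset_index(names="tag")
            .sort_values(["abundance", "tag"], ascending=[False, True])
            .head(k)
        )
        for rank, row in enumerate(ranked.itertuples(), 1):
            rows.append(
                {
                    "stage": stage,
                    "rank": rank,
                    "tag": row.tag,
                    "ref_name": annotation.loc[row.tag, "ref_name"],
                    "percent": 100.0 * row.abundance / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["stage", "rank", "tag", "ref_name", "percent"])


def quantify_reads_dir(
    reads_dir: str | Path,
    design: pd.DataFrame,
    adapter: str,
    min_overlap: int = 8,
) -> pd.DataFrame:
    """Trim + collapse every library FASTQ named ``<library>.fastq``."""
    reads_dir = Path(reads_dir)
    libraries = {}
    for lib in design["library"]:
        path = reads_dir / f"{lib}.fastq"
        tags = []
        for seq in sio.iter_fastq_seqs(path):
            tag = trim_adapter(seq, adapter, min_overlap=min_overlap)
            if tag is not None:
                tags.append(tag)
        libraries[lib] = tags
    return collapse_and_count(libraries)
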