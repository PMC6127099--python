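"""Independent brute-force oracles used to freeze expected test values.

These deliberately avoid the package's own algorithms: structures are
enumerated explicitly, UTRs are classified base by base, and scans slide a
window one position at a time.
"""
from __future__ import annotations

import numpy as np

RNA_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

_COMP = str.maketrans("ACGTU", "TGCAA")


def revcomp_dna(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def enumerate_structures(s: str, i: int, j: int, min_loop: int = 3):
    """All non-crossing pair sets of s[i..j] as tuples of (i, j) pairs."""
    if i >= j:
        return [()]
    out = list(enumerate_structures(s, i + 1, j, min_loop))
    for t in range(i + min_loop + 1, j + 1):
        if (s[i], s[t]) in RNA_PAIRS:
            for inner in enumerate_structures(s, i + 1, t - 1, min_loop):
                for outer in enumerate_structures(s, t + 1, j, min_loop):
                    out.append(((i, t),) + inner + outer)
    return out


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    s = seq.upper().replace("T", "U")
    return max(len(st) for st in enumerate_structures(s, 0, len(s) - 1, min_loop))


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def naive_scan(sequence: str, motif: str) -> list[int]:
    """1-based starts of all (overlapping) motif occurrences, one-by-one."""
    s = sequence.upper().replace("U", "T")
    m = motif.upper().replace("U", "T")
    return [
        i + 1 for i in range(len(s) - len(m) + 1) if s[i : i + len(m)] == m
    ]


def brute_hypergeom_sf(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by enumerating all C(N, n) draws."""
    from itertools import combinations

    universe = list(range(N))
    members = set(range(K))
    total = hits = 0
    for draw in combinations(universe, n):
        total += 1
        if sum(1 for g in draw if g in members) >= k:
            hits += 1
    return hits / total


def random_gene_model(rng: np.random.Generator) -> dict:
    """A random toy gene model (exons + CDS inside them, either strand)."""
    n_exons = int(rng.integers(1, 4))
    exons = []
    pos = int(rng.integers(1, 50))
    for _ in range(n_exons):
        length = int(rng.integers(30, 120))
        exons.append((pos, pos + length - 1))
        pos += length + int(rng.integers(20, 80))
    strand = "+" if rng.random() < 0.5 else "-"
    tx_len = sum(e - s + 1 for s, e in exons)
    u5 = int(rng.integers(0, max(tx_len // 3, 1)))
    u3 = int(rng.integers(0, max(tx_len - u5 - 10, 1)))
    cds_t0, cds_t1 = u5, tx_len - u3  # transcript coords, half-open
    # map to genomic chunks
    chunks = []
    off = 0
    ordered = exons if strand == "+" else list(reversed(exons))
    for s, e in ordered:
        length = e - s + 1
        lo, hi = max(cds_t0, off), min(cds_t1, off + length)
        if lo < hi:
            if strand == "+":
                chunks.append((s + lo - off, s + hi - 1 - off))
            else:
                chunks.append((e - (hi - 1 - off), e - (lo - off)))
        off += length
    return {
        "exons": exons,
        "cds": sorted(chunks),
        "strand": strand,
        "scaffold_len": pos + 50,
    }


def brute_utr_bases(model: dict) -> set[int]:
    """Per-base classification: exonic, not CDS, downstream of the CDS end."""
    exonic = {b for s, e in model["exons"] for b in range(s, e + 1)}
    cds = {b for s, e in model["cds"] for b in range(s, e + 1)}
    if not cds:
        return set()
    if model["strand"] == "+":
        bound = max(cds)
        return {b for b in exonic if b > bound}
    bound = min(cds)
    return {b for b in exonic if b < bound}


def gene_model_gff(model: dict, gene_id: str = "g1") -> str:
    """GFF3 text for one toy gene model."""
    s = min(a for a, _b in model["exons"])
    e = max(b for _a, b in model["exons"])
    strand = model["strand"]
    lines = [
        "##gff-version 3",
        f"##sequence-region chr1 1 {model['scaffold_len']}",
        f"chr1\ttest\tgene\t{s}\t{e}\t.\t{strand}\t.\tID={gene_id}",
        f"chr1\ttest\tmRNA\t{s}\t{e}\t.\t{strand}\t.\tID={gene_id}.t1;Parent={gene_id}",
    ]
    for k, (a, b) in enumerate(model["exons"], 1):
        lines.append(
            f"chr1\ttest\texon\t{a}\t{b}\t.\t{strand}\t.\tID={gene_id}.t1.e{k};Parent={gene_id}.t1"
        )
    for k, (a, b) in enumerate(model["cds"], 1):
        lines.append(
            f"chr1\ttest\tCDS\t{a}\t{b}\t.\t{strand}\t0\tID={gene_id}.t1.c{k};Parent={gene_id}.t1"
        )
    return "\n".join(lines) + "\n"
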