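"""Base-pair-maximization RNA folding (Nussinov recursion) and hairpin calls.

This deliberately trades thermodynamic accuracy for a transparent, exactly
testable model: the classification task here is "does this precursor window
fold into one dominant stem-loop", for which maximum Watson-Crick + G·U
pairing under the no-pseudoknot / minimum-loop constraints is sufficient.
The dynamic program returns the global maximum pair count; the traceback is
made deterministic by preferring the (i, j) pair, then the smallest split
point.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .seqs import RNA_BASES, to_rna

#: allowed RNA pairs: Watson-Crick plus G·U wobble
PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")]
)


def can_pair(a: str, b: str) -> bool:
    return (a, b) in PAIRS


@dataclass
class HairpinFold:
    """A folded sequence with the pairing statistics used for classification."""

    sequence: str  # RNA alphabet
    structure: str  # dot-bracket, same length
    n_pairs: int
    longest_stem_run: int  # longest run of stacked pairs (i,j),(i+1,j-1),...
    paired_fraction: float  # 2 * n_pairs / length
    n_terminal_loops: int  # hairpin loops in the structure
    is_hairpin: bool | None = None
    reasons: list[str] = field(default_factory=list)


def pairs_from_structure(structure: str) -> list[tuple[int, int]]:
    """Dot-bracket -> sorted list of 0-based (i, j) pairs."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return sorted(pairs)


def nussinov(seq: str, min_loop: int = 3) -> tuple[str, int]:
    """Maximum-pairing fold; returns (dot-bracket, pair count).

    Raises ValueError on alphabet violations (only A/C/G/U, T accepted as U).
    """
    s = to_rna(seq)
    bad = set(s) - RNA_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGU characters: {sorted(bad)}")
    n = len(s)
    if n == 0:
        return "", 0

    # M[i][j] = max pairs in s[i..j]; recurrence: i unpaired, or i pairs t.
    M = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i1 = M[i + 1]
            best = row_i1[j]
            for t in range(i + min_loop + 1, j + 1):
                if (s[i], s[t]) in PAIRS:
                    v = 1 + (row_i1[t - 1] if t - 1 > i else 0)
                    if t < j:
                        v += M[t + 1][j]
                    if v > best:
                        best = v
            M[i][j] = best

    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        target = M[i][j]
        if target == 0:
            continue
        # prefer closing the (i, j) pair
        if (s[i], s[j]) in PAIRS:
            v = 1 + (M[i + 1][j - 1] if j - 1 > i else 0)
            if v == target:
                structure[i], structure[j] = "(", ")"
                stack.append((i + 1, j - 1))
                continue
        if M[i + 1][j] == target:
            stack.append((i + 1, j))
            continue
        # otherwise pair i with the smallest admissible split point t
        for t in range(i + min_loop + 1, j):
            if (s[i], s[t]) in PAIRS:
                v = 1 + (M[i + 1][t - 1] if t - 1 > i else 0) + M[t + 1][j]
                if v == target:
                    structure[i], structure[t] = "(", ")"
                    stack.append((i + 1, t - 1))
                    stack.append((t + 1, j))
                    break
        else:  # pragma: no cover - DP and traceback agree by construction
            raise AssertionError("traceback failed to reproduce DP optimum")
    return "".join(structure), M[0][n - 1]


def _longest_stack_run(pairs: list[tuple[int, int]]) -> int:
    pset = set(pairs)
    best = 0
    run_end: dict[tuple[int, int], int] = {}
    for i, j in sorted(pairs):
        run_end[(i, j)] = run_end.get((i - 1, j + 1), 0) + 1
        best = max(best, run_end[(i, j)])
    return best


def _terminal_loop_count(pairs: list[tuple[int, int]]) -> int:
    # hairpin loops = pairs enclosing no other pair
    count = 0
    for i, j in pairs:
        if not any(i < a and b < j for a, b in pairs):
            count += 1
    return count


def fold_hairpin(seq: str, min_loop: int = 3) -> HairpinFold:
    """Fold a candidate precursor window and compute pairing statistics."""
    if len(seq) < min_loop + 2:
        raise ValueError(f"sequence shorter than min_loop + 2 = {min_loop + 2}")
    structure, n_pairs = nussinov(seq, min_loop=min_loop)
    pairs = pairs_from_structure(structure)
    return HairpinFold(
        sequence=to_rna(seq),
        structure=structure,
        n_pairs=n_pairs,
        longest_stem_run=_longest_stack_run(pairs),
        paired_fraction=2.0 * n_pairs / len(seq) if seq else 0.0,
        n_terminal_loops=_terminal_loop_count(pairs),
    )


def classify_hairpin(
    fold: HairpinFold, min_stem: int = 16, min_paired_fraction: float = 0.5
) -> tuple[bool, list[str]]:
    """Call a fold a miRNA-like hairpin; returns (flag, failure reasons).

    A hairpin requires a single terminal loop on the maximal-pair structure,
    a longest stacked-stem run of at least ``min_stem`` pairs, and a paired
    fraction of at least ``min_paired_fraction``. The fold object is updated
    in place.
    """
    reasons: list[str] = []
    if fold.n_terminal_loops != 1:
        reasons.append("terminal_loops")
    if fold.longest_stem_run < min_stem:
        reasons.append("stem_run")
    if fold.paired_fraction < min_paired_fraction:
        reasons.append("paired_fraction")
    fold.is_hairpin = not reasons
    fold.reasons = reasons
    return fold.is_hairpin, reasons
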