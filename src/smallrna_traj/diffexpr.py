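"""Per-stage two-trajectory differential expression and heatmap matrices.

The test is a classical two-sample (pooled-variance) t-test on
log2(CPM + 1) per tag, BH-adjusted within each stage. At n = 3 per group
the Satterthwaite degrees-of-freedom estimate of the unequal-variance
variant is extremely noisy (routinely near 2), which costs roughly a third
of the achievable sensitivity under realistic overdispersion; the pooled
test keeps its 4 degrees of freedom and the log transform makes the group
variances comparable. Heatmap inputs are median-centered (by tag)
normalized counts ordered by average-linkage clustering under uncentered
Pearson correlation distance.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stage_ttest(
    norm_matrix: pd.DataFrame,
    design: pd.DataFrame,
    stage: str,
    alpha: float = 0.05,
    groups: tuple[str, str] = ("escape", "diapause"),
) -> pd.DataFrame:
    """Two-sample t-test per tag between the two trajectories at one stage.

    Pooled-variance t on log2(CPM + 1); see the module docstring for why the
    pooled form is used at this replication level. Returns one row per tag
    with group means (CPM), log2 fold change (pseudocount 1), t, p,
    BH-adjusted q and a significance flag at ``alpha``. Zero-variance
    conventions: both groups constant and equal -> p = 1; constant but
    unequal -> p = 0 with the ``degenerate`` flag set.
    """
    g1, g2 = groups
    libs1 = design.loc[
        (design["stage"] == stage) & (design["trajectory"] == g1), "library"
    ]
    libs2 = design.loc[
        (design["stage"] == stage) & (design["trajectory"] == g2), "library"
    ]
    libs1 = [l for l in libs1 if l in norm_matrix.columns]
    libs2 = [l for l in libs2 if l in norm_matrix.columns]
    if len(libs1) < 2 or len(libs2) < 2:
        raise ValueError(f"need >=2 replicates per group at stage {stage}")
    a = np.log2(norm_matrix[libs1].to_numpy(float) + 1.0)
    b = np.log2(norm_matrix[libs2].to_numpy(float) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a scipy precision warning; the exact
        # zero-variance cases are handled by the conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    both_flat = (var_a == 0) & (var_b == 0)
    equal = both_flat & (mean_a == mean_b)
    unequal = both_flat & (mean_a != mean_b)
    t = np.where(equal, 0.0, t)
    p = np.where(equal, 1.0, p)
    if unequal.any():
        t[unequal] = np.sign(mean_a - mean_b)[unequal] * np.inf
        p[unequal] = 0.0
    m1 = norm_matrix[libs1].mean(axis=1)
    m2 = norm_matrix[libs2].mean(axis=1)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "stage": stage,
            f"mean_{g1}": m1,
            f"mean_{g2}": m2,
            "log2_fc": np.log2((m1 + 1.0) / (m2 + 1.0)),
            "t": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
            "degenerate": unequal,
        },
        index=norm_matrix.index,
    )


def median_center(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Subtract each row's median (mid-point median for even lengths)."""
    medians = matrix.median(axis=1)
    return matrix.sub(medians, axis=0), medians


def uncentered_pearson_distance(matrix: pd.DataFrame) -> np.ndarray:
    """1 - sum(xy)/sqrt(sum(x^2) sum(y^2)) square distance matrix.

    Zero-vector rows are assigned distance 1 to every other row (the
    similarity is undefined for them).
    """
    X = matrix.to_numpy(float)
    norms = np.sqrt((X**2).sum(axis=1))
    safe = norms > 0
    Xn = np.zeros_like(X)
    Xn[safe] = X[safe] / norms[safe, None]
    S = Xn @ Xn.T
    S[~safe, :] = 0.0
    S[:, ~safe] = 0.0
    D = 1.0 - S
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


@dataclass
class HclustResult:
    linkage: np.ndarray
    order: list[str]  # leaf order for heatmap rendering
    newick: str


def hcluster(matrix: pd.DataFrame) -> HclustResult:
    """Average-linkage clustering under uncentered Pearson distance."""
    if len(matrix) < 2:
        raise ValueError("clustering needs >=2 rows")
    D = uncentered_pearson_distance(matrix)
    Z = linkage(squareform(D, checks=False), method="average")
    labels = list(matrix.index)
    order = [labels[i] for i in leaves_list(Z)]

    def _newick(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        left, right = node.get_left(), node.get_right()
        dl = max(node.dist - left.dist, 0.0)
        dr = max(node.dist - right.dist, 0.0)
        return f"({_newick(left)}:{dl:.6g},{_newick(right)}:{dr:.6g})"

    return HclustResult(Z, order, _newick(to_tree(Z)) + ";")


def paralog_totals(
    norm_matrix: pd.DataFrame,
    membership: pd.DataFrame | dict[str, str],
    design: pd.DataFrame,
) -> pd.DataFrame:
    """Per-paralog (stage, trajectory) expression profiles.

    Member tags' normalized counts are summed per library, then averaged over
    replicates of each (stage, trajectory) group. ``membership`` maps tag ->
    paralog and must partition: a tag assigned to two paralogs is an error.
    """
    if isinstance(membership, dict):
        pairs = pd.DataFrame(
            {"tag": list(membership), "paralog": list(membership.values())}
        )
    else:
        pairs = membership[["tag", "paralog"]].copy()
    dupes = pairs["tag"][pairs["tag"].duplicated()]
    if len(dupes):
        raise ValueError(f"tags assigned to multiple paralogs: {sorted(set(dupes))}")
    sub = norm_matrix.reindex(pairs["tag"]).fillna(0.0)
    sub.index = pd.Index(pairs["paralog"], name="paralog")
    per_library = sub.groupby(level=0).sum()
    stages = list(dict.fromkeys(design["stage"]))
    trajectories = list(dict.fromkeys(design["trajectory"]))
    cols = pd.MultiIndex.from_product(
        [stages, trajectories], names=["stage", "trajectory"]
    )
    out = pd.DataFrame(index=per_library.index, columns=cols, dtype=float)
    for stage in stages:
        for traj in trajectories:
            libs = design.loc[
                (design["stage"] == stage) & (design["trajectory"] == traj), "library"
            ]
            libs = [l for l in libs if l in per_library.columns]
            out[(stage, traj)] = (
                per_library[libs].mean(axis=1) if libs else 0.0
            )
    return out
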