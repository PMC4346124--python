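"""Differential copy-number screening between lineage clusters.

Per-gene Welch t-tests with Bonferroni correction over the averaged log2
tumour/reference values, run for the five standard contrasts between the
stable / intermediate / unstable clusters, followed by two-dimensional
supervised clustering of the selected genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import Dendrogram, complete_linkage
from .profile import GeneMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Contrast:
    name: str
    group1: frozenset[str]
    group2: frozenset[str]

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ValueError("contrast groups must be non-empty")
        if self.group1 & self.group2:
            raise ValueError("contrast groups must be disjoint")


def _c(name: str, g1, g2) -> Contrast:
    return Contrast(name, frozenset(g1), frozenset(g2))


#: The five standard comparisons between the three lineage clusters.
DEFAULT_CONTRASTS: tuple[Contrast, ...] = (
    _c("stable_vs_intermediate", {"stable"}, {"intermediate"}),
    _c("stable_vs_unstable", {"stable"}, {"unstable"}),
    _c("intermediate_vs_unstable", {"intermediate"}, {"unstable"}),
    _c("stable_intermediate_vs_unstable", {"stable", "intermediate"}, {"unstable"}),
    _c("stable_vs_unstable_intermediate", {"stable"}, {"unstable", "intermediate"}),
)


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test.

    Returns ``(t, Welch-Satterthwaite df, two-sided p)``.  Requires n >= 2
    per group and positive variance in at least one group.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        raise ValueError("degenerate test: both variances zero")
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0,1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


@dataclass
class DifferentialResult:
    """Full test table plus the gene sets selected per contrast."""

    table: pd.DataFrame
    per_contrast: dict[str, list[str]]
    selected: list[str]  # union over contrasts
    intersection: list[str]
    alpha: float


def find_differential_genes(
    matrix: GeneMatrix,
    lineages: pd.Series,
    contrasts: tuple[Contrast, ...] = DEFAULT_CONTRASTS,
    alpha: float = 0.05,
) -> DifferentialResult:
    """Screen every gene for copy-number differences between clusters.

    Per contrast, a Welch t-test per gene over that contrast's samples;
    Bonferroni correction with m = number of genes actually tested in that
    contrast.  A gene enters the selected set if significant (adjusted
    p <= alpha) in at least one contrast (union rule); per-contrast and
    intersection sets are also reported.  Genes failing test preconditions
    (fewer than two values per group, or zero variance in both groups) are
    recorded as untestable.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0,1]")
    lineages = lineages.reindex(matrix.values.index)
    rows = []
    per_contrast: dict[str, list[str]] = {}
    genes = np.asarray(matrix.genes)
    for contrast in contrasts:
        s1 = lineages.index[lineages.isin(contrast.group1)]
        s2 = lineages.index[lineages.isin(contrast.group2)]
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError(
                f"contrast {contrast.name}: each group needs >= 2 samples "
                f"(got {len(s1)}, {len(s2)})"
            )
        X1 = matrix.values.loc[s1].to_numpy(dtype=float)
        X2 = matrix.values.loc[s2].to_numpy(dtype=float)

        n1 = (~np.isnan(X1)).sum(axis=0)
        n2 = (~np.isnan(X2)).sum(axis=0)
        v1 = np.nanvar(X1, axis=0, ddof=1)
        v2 = np.nanvar(X2, axis=0, ddof=1)
        with np.errstate(invalid="ignore"):
            untestable = (n1 < 2) | (n2 < 2) | ((v1 == 0.0) & (v2 == 0.0))

        import warnings as _warnings

        with _warnings.catch_warnings():
            # constant genes are masked as untestable below; silence the
            # near-identical-data precision warning they trigger
            _warnings.simplefilter("ignore", RuntimeWarning)
            res = stats.ttest_ind(
                X1, X2, equal_var=False, nan_policy="omit", axis=0
            )
        t = np.array(res.statistic, dtype=float)
        p = np.array(res.pvalue, dtype=float)
        df = np.array(res.df, dtype=float)
        t[untestable] = np.nan
        p[untestable] = np.nan
        df[untestable] = np.nan

        m = int((~untestable).sum())
        p_adj = np.minimum(1.0, p * m)
        sig = (p_adj <= alpha) & ~untestable
        per_contrast[contrast.name] = sorted(genes[sig])
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "contrast": contrast.name,
                    "t": t,
                    "df": df,
                    "p": p,
                    "p_adj": p_adj,
                    "m": m,
                    "significant": sig,
                    "untestable": untestable,
                }
            )
        )
    table = pd.concat(rows, ignore_index=True)
    sets = [set(v) for v in per_contrast.values()]
    selected = sorted(set().union(*sets))
    intersection = sorted(set.intersection(*sets)) if sets else []
    logger.info(
        "differential screen: %d genes selected (union) of %d at alpha=%g",
        len(selected), matrix.n_genes, alpha,
    )
    return DifferentialResult(table, per_contrast, selected, intersection, alpha)


def supervised_2d_cluster(
    matrix: GeneMatrix, selected_genes: list[str]
) -> tuple[Dendrogram, Dendrogram, GeneMatrix]:
    """Cluster samples and the selected genes (same distance and linkage).

    Returns ``(sample_tree, gene_tree, restricted matrix)``; viewer files
    can then be written with :func:`cnalineage.io.write_cdt_gtr`.
    """
    if len(selected_genes) < 2:
        raise ValueError(
            "fewer than 2 significant genes; consider relaxing alpha"
        )
    sub = matrix.subset_genes(selected_genes)
    sample_tree = complete_linkage(sub, axis="samples")
    gene_tree = complete_linkage(sub, axis="genes")
    return sample_tree, gene_tree, sub
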